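# Methods

## Scope and model

The package post-processes end-point binding-energy calculations; it never
computes GB or SASA terms, docks ligands or runs dynamics. Its inputs are
per-snapshot energy components, isotype abundances, experimental
affinities and pre-aligned binding-site sequences; its outputs are
replicate-aggregated binding energies, context-weighted affinities, Kd
predictions, selectivity reports, isotherm fits, conservation calls and
prediction/experiment correlations.

### Snapshot assembly and replicate aggregation

Each species' snapshot free energy is the component sum
`e_elec + e_vdw + e_internal + e_gb + e_sasa − ts_solute`, all kcal/mol.
`ts_solute` is stored as the already-multiplied T·S product because no
single temperature convention covers normal-mode and quasi-harmonic
entropy estimates; the assembly function accepts a temperature argument
for interface symmetry but does not use it. The default `ts_solute = 0`
omits the entropy term: end-point entropy estimates are the method's
best-known weakness and no computable recipe is assumed. The field is
honored verbatim when supplied.

Binding energies follow the single-trajectory convention: complex,
receptor and ligand rows belong to the same complex snapshot, so internal
energies largely cancel in the subtraction.

Aggregation keeps, per run, snapshots with `time_ps > t_max − window`
(default window 1000 ps, i.e. the last nanosecond of a 2 ns run). A window
larger than the run span keeps everything and logs a warning rather than
failing — short test fixtures should pass through. The estimate is the
mean of per-run means; its uncertainty is the sample SD (ddof = 1) across
run means, which is the replicate-level spread of a
several-runs-with-different-initial-conditions design, not the
per-snapshot SD (those differ by roughly √n_snapshots) and not the SEM.
With equal snapshot counts per run the mean of run means equals the pooled
snapshot mean. A single-run table yields SD 0 and a `degenerate` flag.

### Abundance-Boltzmann weighting

The weighted affinity is
`⟨BE⟩ = Σ ΔG_i f_i exp(−ΔG_i/RT) / Σ f_i exp(−ΔG_i/RT)`. Units are mixed
deliberately: ΔG_i is kcal/mol (the native MM/GBSA scale) and the exponent
is evaluated after conversion with 4184 J/kcal against R = 8.31 J/(mol·K),
T = 298 K. R is kept at the two-digit 8.31 rather than 8.314 so the
conversions and the weighting share one constant; at these magnitudes the
difference is far below replicate noise.

At ΔG ≈ −42 kcal/mol the raw exponent is ≈ 71, so the sum is evaluated
with the maximum exponent subtracted (log-sum-exp). The stabilized form
equals naive extended-precision evaluation wherever the latter is finite
(property-tested on random tables with |ΔG| ≤ 30) and remains finite past
|ΔG| = 150. Consequences of the form: equal energies return themselves for
any abundances, a common shift of all ΔG_i shifts ⟨BE⟩ by exactly that
constant, the result is bounded by the input extremes, and a sufficiently
strong binder with any nonzero abundance dominates (its weight exceeds
1 − 1e-10 at a 40 kcal/mol gap) — the average is close to a
best-binder selector at MM/GBSA magnitudes, which is a property of the
formula, not of the implementation.

Zero-abundance isotypes carry zero weight and may lack estimates (the
brain table has three 0% rows); nonzero-abundance isotypes without an
estimate raise a coverage error naming the isotype — silent dropping would
bias the average. Isotype labels are normalized case-insensitively
("bIII", "beta3", "βIII" → "III") because abundance sources spell them
inconsistently.

### Kd / ΔG conversion and isotherm fitting

`Kd = exp(ΔG/RT)` and `ΔG = RT ln Kd` under a 1 M standard state, exact
inverses by construction (round-trip verified to 1e-12 relative over
[−60, +5] kcal/mol). Applying the exponential to raw MM/GBSA-scale
energies yields sub-attomolar constants; the conversion performs it
verbatim and logs a caution below 1e-15 M, because end-point energies are
comparative scores, not absolute binding free energies.

The isotherm fit uses the exact 1:1 depletion solution
`f = ((T0 + L + Kd) − √((T0 + L + Kd)² − 4·T0·L)) / (2·T0)`, valid whether
or not ligand is in excess, with a fitted amplitude and baseline mapping
fraction bound to the instrument's normalized signal. Kd is fitted on a
log scale (positivity by construction); the start point is deterministic —
Kd₀ = geometric mean of the concentrations, amplitude = signal range,
baseline = signal minimum — so fits are reproducible without seed
plumbing. Guards: at least five points spanning a decade; a flat series
returns `converged = False` ("no binding signal") rather than an arbitrary
Kd.

### Selectivity arithmetic

Ratios are stored at full precision and rounded only for display, since
published tables round from unprinted intermediates (printed means of
−27.1 and −27.2 give 0.996, which a table may show as 0.99). Interval
bounds are mean ± 1 SD with the lower bound clamped at zero and flagged
when SD ≥ mean. The preference verdict is the literal overlap rule —
"overlapping" when the weaker binder's lower bound does not exceed the
stronger binder's upper bound — and both bounds are surfaced so callers
can see near-touching cases (5.8 vs 4.9 µM is "separated" by 0.9 µM
against SDs of 86% and 36%; the rule reports the arithmetic, the caller
judges the biology). No hypothesis test is attached: the argument is
arithmetic on printed numbers, and pretending otherwise would overstate
it.

### Conservation classification

"PAM250 score above 0.5" is implemented through the Clustal convention:
the strong groups (STA, NEQK, NHQK, NDEQ, QHRK, MILV, MILF, HY, FYW) are
exactly the residue classes scoring > 0.5 in the Gonnet PAM250 matrix, and
the weak groups (CSA, ATV, SAG, STNK, STPA, SGND, SNDEQK, NDEQHK, NEQHRK,
FVLIM, HFY) those scoring ≤ 0.5 — integer log-odds PAM250 entries cannot
be compared with 0.5 directly, and Clustal Omega is the aligner these
site alignments come from. Note the strong groups make (A, T) a
conservative pair (Gonnet score 0.6 via STA), which surprises readers who
expect strict chemical-class conservation. The scheme is pluggable
(`MatrixScheme` takes any matrix plus strong/weak thresholds) because
other PAM250 normalizations exist. Identity requires equal characters;
gap-residue columns are never conserved; classification is symmetric and
total over the 20×20 residue pairs. Alignment construction itself is out
of scope — inputs are pre-aligned, equal-length site strings.

`similar_isotype_groups` selects subjects whose columns are all identity
or conservative (up to an allowed violation count, default 0) — the
criterion for pooling computational results for isotypes whose binding
site is effectively identical to a reference species' site, as when human
β isotypes are compared against the porcine tubulin used in bench assays.

### Correlation

Predicted ΔG is correlated against ΔG_exp = RT ln Kd for dissociation
constants and against log10(IC50) for cytotoxicity potencies — IC50 spans
decades, and a linear axis would let the weakest binders dominate the
regression. Pearson r is primary, Spearman ρ reported alongside (ranks are
informative at n ≈ 15–19). Fewer than three shared ligands is an error; a
constant axis returns NaN with a `degenerate` flag. Correlation magnitudes
are property-tested on synthetic data (exact affine relations give
|r| = 1; the noise-free generator/fitter pair closes to 1e-12) — no
empirical correlation strength is asserted for real systems.

## Synthetic data: what it emulates and what it does not

The generator reproduces the statistical design the aggregation assumes —
n_runs replicate runs (default 5) of run_length_ps (default 2000) sampled
every snapshot_interval_ps (default 10), a per-run Gaussian offset
(`sigma_run`, emulating different initial conditions) and i.i.d. Gaussian
snapshot noise (`sigma_snapshot`) around a configurable true binding
energy per (ligand, target, isotype, site). Species totals sit at
realistic MM/GBSA magnitudes (receptor −1000, ligand −20 kcal/mol) and are
split over the five components in fixed proportions per species, with the
last component taken as the exact remainder so component sums re-assemble
the intended total bit-for-bit. One seeded RNG stream drives each call.

It does not emulate autocorrelated trajectories (snapshots are
independent, so real effective sample sizes are smaller than synthetic
ones), force-field or conformational effects, entropy estimates
(`ts_solute` is generated as 0), or any relationship between docking
scores and MM/GBSA energies. Passing recovery tests therefore demonstrates
that the estimator chain is unbiased and correctly assembled under the
assumed noise model — not that MM/GBSA energies of real complexes carry
those error bars.

Default noise scales used in tests (snapshot SD 2 kcal/mol; isotherm
signal SD 0.02; affinity log-SD 0.5) sit at the scale of the replicate
SDs and assay scatter typical of such studies.

## Numerical choices

- Energy tables are CSV written at `%.17g` and read with pandas'
  round-trip float parser, so write→read preserves doubles exactly.
- "Noise-free exact" recovery is asserted at 1e-9 kcal/mol absolute: the
  binding energy is recovered by cancelling ~10³ kcal/mol species totals,
  where 1 ulp is ~2e-13, so this is machine precision at the intermediate
  magnitudes rather than literal bit equality.
- The trailing-window rule uses a strict inequality
  (`time > t_max − window`), so a 1000 ps window on a 2 ns run keeps
  exactly the snapshots in (1000, 2000].
- Run-mean SD uses ddof = 1 (five replicates; the n−1 estimator is the
  convention replicate ± values imply).
- Boltzmann weights renormalize over the isotypes present; abundance
  tables renormalize to sum to one per context on load, so percentage and
  fraction inputs behave identically.
- Tie-break in the overlap verdict: exactly touching bounds
  (low_a == high_b) count as overlapping.

## Problem sizes

The test suite and the reproduction script run replicate tables of 5 × 100
to 5 × 200 snapshots, 50-seed recovery ensembles, 100-seed isotherm
ensembles and 1000-case numerical-equivalence sweeps; these sizes put
sampling error well below the asserted tolerances while keeping a full run
in the tens of seconds on one CPU.

## Known limitations

- The γ-tubulin target is treated as a single isotype; weighting over α
  isotypes is not implemented (models pair a single αIa with each β).
- The entropy term is pass-through only; no normal-mode or quasi-harmonic
  estimator is provided.
- The isotherm model is strict 1:1 binding — no Hill coefficients,
  cooperative or two-site models, and no thermophoresis physics; what is
  fitted is the shape a normalized dose-response series shares with the
  depletion isotherm.
- `preference_verdict` is arithmetic, not inference: it cannot distinguish
  "barely separated" from "convincingly separated"; it exposes the bounds
  for that judgement.
- Fixture Kd values are reported means and SDs of the underlying assays;
  the package does not model inter-assay systematics (the fluorescence and
  thermophoresis columns disagree ~20-fold in absolute Kd while agreeing
  ~1.3-fold in ratio, which is why ratios, not absolute values, are the
  acceptance surface of the selectivity stage).
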