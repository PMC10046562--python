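# tubulinsel

Post-processing and selectivity analysis for tubulin ligand-binding
predictions. The package takes the outputs that an end-point binding-energy
workflow produces — per-snapshot MM/GBSA energy components from replicate
molecular-dynamics runs, β-tubulin isotype abundance tables, and
experimental dissociation constants — and turns them into the quantities a
selectivity argument is actually made of: per-complex binding energies with
replicate uncertainties, abundance-weighted affinities per cell context,
predicted and experimental Kd values on a common scale, interval-based
selectivity verdicts, and binding-site conservation calls.

It was built around the question of whether gatastatin and its derivatives
prefer γ tubulin over the α-β dimer — a question that matters because γ
tubulin is scarce in healthy cells but overexpressed in glioblastoma — but
every stage is generic over ligands, targets, isotypes and binding sites.

## The model

**Snapshot free energy (MM/GBSA).** For each trajectory snapshot and each
species (complex, receptor, ligand),

    G = E_elec + E_vdw + E_internal + E_GB + E_SASA − T·S_solute,

and the per-snapshot binding energy is ΔG_bind = G_complex − (G_receptor +
G_ligand). The entropy product defaults to 0 (omitted) and is honored when
supplied. Estimates aggregate the last nanosecond of each of n replicate
runs: ΔG is averaged within runs, and the reported value is the mean of run
means ± the sample SD across run means.

**Isotype weighting.** A cell's α-β pool is a mixture of β isotypes with
fractions f_i, so a ligand's effective affinity is the
abundance-and-Boltzmann weighted average

    ⟨BE⟩ = Σ_i ΔG_i f_i exp(−ΔG_i/RT) / Σ_i f_i exp(−ΔG_i/RT),

with R = 8.31 J/(mol·K), T = 298 K, and ΔG in kcal/mol converted to J/mol
inside the exponent. The implementation is log-sum-exp stabilized. Packaged
abundance tables cover healthy human brain, a glioblastoma cell line, and
HeLa cells.

**Thermodynamic conversion.** Kd = exp(ΔG/RT) and ΔG = RT ln Kd under a
1 M standard state. A separate least-squares routine estimates Kd from a
dose-response series via the exact 1:1 depletion isotherm (the shape a
microscale-thermophoresis experiment measures).

**Selectivity arithmetic.** |ΔG| site ratios, Kd target ratios, mean ± 1 SD
interval bounds and relative SDs, plus a literal interval-overlap verdict —
no distributional claims.

**Site conservation.** Columns of a pre-aligned binding-site alignment are
classified as identity / conservative / semiconservative / not conserved
using the Clustal strong and weak similarity groups (Gonnet PAM250 scores
above / at-most 0.5); a raw matrix with explicit thresholds can be plugged
in instead.

## Worked example

```python
from tubulinsel import (
    SimulationSpec, generate_energy_table, estimate_binding_energy,
    load_fixture_abundances, load_fixture_affinities, weight_all,
    build_report, preference_verdict, dg_from_kd,
)

# 1. Synthetic replicate-MD table: six isotypes, known truth of -27.1 kcal/mol
spec = SimulationSpec(
    true_dg={("gatastatin", "alpha_beta", iso, "colchicine_ab"): -27.1
             for iso in ("bI", "bIIa", "bIIb", "bIII", "bIVa", "bIVb")},
    n_runs=5, sigma_snapshot=2.0, seed=1,
)
estimates = estimate_binding_energy(generate_energy_table(spec), window_ps=1000)
weighted = weight_all(estimates, load_fixture_abundances("brain"), "brain")
print(f"brain-weighted <BE> = {weighted[0].be_avg:.2f} kcal/mol")

# 2. Experimental selectivity: gatastatin on alpha-beta vs gamma tubulin
recs = {r.target: r for r in load_fixture_affinities("chinen")}
rep = build_report("gatastatin",
                   (recs["alpha_beta"].kd_mean, recs["alpha_beta"].kd_sd),
                   (recs["gamma"].kd_mean, recs["gamma"].kd_sd))
print(f"Kd ratio = {rep.ratio:.1f}, bounds {rep.kd_low_a:.1f} vs "
      f"{rep.kd_high_b:.1f} uM -> {preference_verdict(rep)}")
print(f"relative SDs: {rep.rel_sd_a}% and {rep.rel_sd_b}%")
print(f"dG_exp(gamma) = {dg_from_kd(recs['gamma'].kd_mean * 1e-6):.2f} kcal/mol")
```

prints

```
brain-weighted <BE> = -27.16 kcal/mol
Kd ratio = 11.8, bounds 5.8 vs 4.9 uM -> separated
relative SDs: 86% and 36%
dG_exp(gamma) = -7.42 kcal/mol
```

The weighted average recovers the configured −27.1 kcal/mol truth to within
the replicate noise. The experimental comparison reproduces the published
worst-case bounds: the α-β interval's lower edge (5.8 µM) sits just above
the γ interval's upper edge (4.9 µM), so the literal 1-SD rule calls the
intervals "separated" — but by only 0.9 µM against SDs of 86% and 36%,
which is why the claimed ~12-fold γ preference should be treated with
caution.

A `tubulinsel` command-line tool exposes each stage (`simulate`,
`aggregate`, `weight`, `convert`, `fitkd`, `selectivity`, `conserve`,
`correlate`) and an end-to-end `run` driven by a YAML config; see
`tubulinsel --help`.

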