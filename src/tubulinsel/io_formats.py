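"""Reading, writing and validation of the pipeline's table and sequence formats.

All delimited tables are comma-separated UTF-8 with a mandatory header row and
``.`` decimals. The printed abundance and affinity values from the study this
pipeline post-processes ship here as packaged fixtures: β-isotype abundances
for healthy human brain and a glioblastoma (GBM) cell line, the HeLa-cell
fractions, and the experimental dissociation constants (tryptophan-fluorescence
values from Chinen et al. and microscale-thermophoresis values) for gatastatin
and colchicine on α-β and γ tubulin.

Energy tables carry one row per (snapshot, species) with the decomposed
MM/GBSA components in kcal/mol: gas-phase electrostatic, van der Waals and
internal (bond/angle/dihedral) energies, the generalized-Born polar solvation
term, the surface-area nonpolar term, and optionally the solute entropy
product T·S.
"""

from __future__ import annotations

import re
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .errors import (
    AlignmentLengthError,
    IntegrityError,
    LookupFixtureError,
    SchemaError,
)

# --------------------------------------------------------------------------
# Controlled vocabularies
# --------------------------------------------------------------------------

SPECIES = ("complex", "receptor", "ligand")
SITES = ("gtp", "colchicine_putative", "colchicine_ab")
TARGETS = ("alpha_beta", "gamma")
CONTEXTS = ("brain", "gbm", "hela")

ENERGY_COLUMNS = (
    "complex_id", "ligand", "target", "isotype", "site", "run", "time_ps",
    "species", "e_elec", "e_vdw", "e_internal", "e_gb", "e_sasa",
)
# ts_solute is optional on read; it defaults to 0 (entropy omitted).
ENERGY_COMPONENT_COLUMNS = ("e_elec", "e_vdw", "e_internal", "e_gb", "e_sasa", "ts_solute")


# --------------------------------------------------------------------------
# Isotype label normalization
# --------------------------------------------------------------------------

_ARABIC_TO_ROMAN = {
    "1": "I", "2": "II", "3": "III", "4": "IV",
    "5": "V", "6": "VI", "7": "VII", "8": "VIII",
}
_ISOTYPE_RE = re.compile(r"([ivx]+|\d)\s*([ab]?)")


def normalize_isotype(label: str) -> str:
    """Map a β-isotype spelling to a canonical key.

    ``"bIII"``, ``"beta3"``, ``"βIII"`` and ``"β III"`` all normalize to
    ``"III"``; suffix letters are kept lowercase (``"bIVa"`` → ``"IVa"``).
    ``"gamma"``/``"γ"`` pass through as ``"gamma"``.
    """
    s = str(label).strip()
    low = s.lower()
    if low in {"gamma", "γ", "y", "g", "γi", "gammai"}:
        return "gamma"
    for prefix in ("beta", "β", "b"):
        if low.startswith(prefix):
            low = low[len(prefix):]
            break
    low = low.strip(" -_")
    m = _ISOTYPE_RE.fullmatch(low)
    if m is None:
        raise SchemaError(f"unrecognized isotype label: {label!r}")
    core, suffix = m.groups()
    core = _ARABIC_TO_ROMAN[core] if core.isdigit() else core.upper()
    return core + suffix


# --------------------------------------------------------------------------
# Energy tables
# --------------------------------------------------------------------------

def validate_energy_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate schema and invariants of an energy table; return it augmented.

    Checks: required columns present; species/site vocabularies; every
    (complex_id, run, time_ps) triple carries exactly one row per species;
    run ids form a contiguous 1..n set per complex; time_ps non-decreasing
    within each run. A missing ``ts_solute`` column is filled with 0.
    """
    for col in ENERGY_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"energy table missing required column '{col}'")
    df = df.copy()
    if "ts_solute" not in df.columns:
        df["ts_solute"] = 0.0
    df["ts_solute"] = df["ts_solute"].fillna(0.0)

    bad_species = set(df["species"].unique()) - set(SPECIES)
    if bad_species:
        raise SchemaError(f"unknown species values: {sorted(bad_species)}")
    bad_sites = set(df["site"].unique()) - set(SITES)
    if bad_sites:
        raise SchemaError(f"unknown site values: {sorted(bad_sites)}")

    for (cid, run, t), grp in df.groupby(["complex_id", "run", "time_ps"], sort=False):
        if sorted(grp["species"]) != sorted(SPECIES):
            raise IntegrityError(
                f"snapshot ({cid!r}, run={run}, time_ps={t}) lacks a complete "
                f"complex/receptor/ligand species triple (has {sorted(grp['species'])})"
            )
    for cid, grp in df.groupby("complex_id", sort=False):
        runs = sorted(grp["run"].unique())
        if runs != list(range(1, len(runs) + 1)):
            raise IntegrityError(
                f"complex {cid!r}: run ids {runs} are not a contiguous 1..n set"
            )
        for run, rgrp in grp.groupby("run", sort=False):
            times = rgrp["time_ps"].to_numpy()
            # per-species file order must be time-sorted
            for _, sgrp in rgrp.groupby("species", sort=False):
                ts = sgrp["time_ps"].to_numpy()
                if len(ts) > 1 and (ts[1:] < ts[:-1]).any():
                    raise IntegrityError(
                        f"complex {cid!r} run {run}: time_ps not non-decreasing"
                    )
            if (times < 0).any():
                raise IntegrityError(f"complex {cid!r} run {run}: negative time_ps")
    return df


def read_energy_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a per-snapshot energy-component table (CSV)."""
    df = pd.read_csv(path, float_precision="round_trip")
    return validate_energy_table(df)


def write_energy_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write an energy table as CSV at full (round-trip) float precision."""
    df.to_csv(path, index=False, float_format="%.17g")


# --------------------------------------------------------------------------
# Abundance tables (fixtures carry the printed percentages)
# --------------------------------------------------------------------------

# Relative quantities of β tubulin isotypes (%), healthy human brain and
# an untreated GBM cell line.
_BRAIN_PCT = {
    "I": 4.0, "IIa": 30.0, "IIb": 7.0, "III": 4.0, "IVa": 46.0,
    "IVb": 9.0, "V": 0.0, "VI": 0.0, "VIII": 0.0,
}
_GBM_PCT = {
    "I": 10.0, "IIa": 19.0, "IIb": 17.0, "III": 12.0, "IVa": 10.0,
    "IVb": 17.0, "V": 12.0, "VI": 1.0, "VIII": 2.0,
}
# HeLa cells express isotype classes I/II/III/IV at 45/14/35/6 %.
_HELA_PCT = {"I": 45.0, "II": 14.0, "III": 35.0, "IV": 6.0}

_ABUNDANCE_FIXTURES = {"brain": _BRAIN_PCT, "gbm": _GBM_PCT, "hela": _HELA_PCT}


def normalize_abundances(df: pd.DataFrame) -> pd.DataFrame:
    """Normalize fractions to sum to 1 within each context; validate signs."""
    for col in ("isotype", "context", "fraction"):
        if col not in df.columns:
            raise SchemaError(f"abundance table missing required column '{col}'")
    df = df.copy()
    df["isotype"] = df["isotype"].map(normalize_isotype)
    if (df["fraction"] < 0).any():
        raise IntegrityError("abundance fractions must be non-negative")
    for ctx, grp in df.groupby("context"):
        total = grp["fraction"].sum()
        if total <= 0:
            raise IntegrityError(f"context {ctx!r}: abundances sum to zero")
        df.loc[grp.index, "fraction"] = grp["fraction"] / total
    return df


def load_fixture_abundances(context: str) -> pd.DataFrame:
    """Packaged isotype abundances for ``brain``, ``gbm`` or ``hela``.

    Percentages are stored as printed and normalized to fractions on load;
    zero-abundance isotypes (brain βV/βVI/βVIII) are retained with f_i = 0.
    """
    try:
        pct = _ABUNDANCE_FIXTURES[context]
    except KeyError:
        raise LookupFixtureError(
            f"unknown abundance context {context!r}; expected one of {CONTEXTS}"
        ) from None
    df = pd.DataFrame(
        {"isotype": list(pct), "context": context, "fraction": list(pct.values())}
    )
    return normalize_abundances(df)


def read_abundance_table(path: str | Path) -> pd.DataFrame:
    """Read an abundance CSV (isotype, context, fraction-or-percent) and normalize."""
    return normalize_abundances(pd.read_csv(path))


def write_abundance_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


# --------------------------------------------------------------------------
# Experimental affinity records
# --------------------------------------------------------------------------

@dataclass
class AffinityRecord:
    """One experimental affinity: Kd ± SD (µM) and/or IC50 (µM) for a ligand-target pair."""

    ligand: str
    target: str
    kd_mean: float | None = None
    kd_sd: float | None = None
    ic50: float | None = None
    source: str = ""

    def __post_init__(self):
        if self.target not in TARGETS:
            raise SchemaError(f"target must be one of {TARGETS}, got {self.target!r}")
        if self.kd_mean is None and self.ic50 is None:
            raise IntegrityError(
                f"affinity record for {self.ligand!r} needs kd_mean or ic50"
            )
        for name in ("kd_mean", "kd_sd", "ic50"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise IntegrityError(f"{name} must be strictly positive, got {v}")


# Kd ± SD in µM for gatastatin and colchicine on α-β tubulin: tryptophan
# fluorescence (Chinen et al.) vs microscale thermophoresis.
_TABLE8 = [
    AffinityRecord("gatastatin", "alpha_beta", 42.5, 36.7, source="chinen"),
    AffinityRecord("colchicine", "alpha_beta", 17.5, 2.7, source="chinen"),
    AffinityRecord("gatastatin", "alpha_beta", 2.16, 0.47, source="mst"),
    AffinityRecord("colchicine", "alpha_beta", 0.676, 0.11, source="mst"),
]
# Chinen et al. gatastatin Kd on both targets (the γ value appears in the
# selectivity interval argument).
_CHINEN = [
    AffinityRecord("gatastatin", "alpha_beta", 42.5, 36.7, source="chinen"),
    AffinityRecord("gatastatin", "gamma", 3.6, 1.3, source="chinen"),
]

_AFFINITY_FIXTURES = {"table8": _TABLE8, "chinen": _CHINEN}


def load_fixture_affinities(name: str) -> list[AffinityRecord]:
    """Packaged experimental affinities: ``table8`` or ``chinen``."""
    try:
        records = _AFFINITY_FIXTURES[name]
    except KeyError:
        raise LookupFixtureError(
            f"unknown affinity fixture {name!r}; expected one of "
            f"{tuple(_AFFINITY_FIXTURES)}"
        ) from None
    return [AffinityRecord(**asdict(r)) for r in records]


def read_affinity_table(path: str | Path) -> list[AffinityRecord]:
    """Read affinity records from CSV (ligand, target, kd_mean, kd_sd, ic50, source)."""
    df = pd.read_csv(path)
    for col in ("ligand", "target"):
        if col not in df.columns:
            raise SchemaError(f"affinity table missing required column '{col}'")
    records = []
    for row in df.to_dict("records"):
        kwargs = {"ligand": str(row["ligand"]), "target": str(row["target"])}
        for key in ("kd_mean", "kd_sd", "ic50"):
            v = row.get(key)
            kwargs[key] = None if v is None or pd.isna(v) else float(v)
        kwargs["source"] = "" if pd.isna(row.get("source", "")) else str(row.get("source", ""))
        records.append(AffinityRecord(**kwargs))
    return records


def write_affinity_table(records: list[AffinityRecord], path: str | Path) -> None:
    pd.DataFrame([asdict(r) for r in records]).to_csv(path, index=False)


# --------------------------------------------------------------------------
# FASTA binding-site sequences
# --------------------------------------------------------------------------

def read_fasta_sites(
    path: str | Path, require_aligned: bool = True
) -> list[tuple[str, str]]:
    """Read pre-aligned binding-site residue strings from FASTA.

    Labels and sequences are preserved verbatim apart from uppercase
    normalization. With ``require_aligned`` (the default for column-wise
    classification), unequal sequence lengths raise
    :class:`AlignmentLengthError`. An empty file yields an empty list.
    """
    records = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
    if require_aligned and records:
        lengths = {len(seq) for _, seq in records}
        if len(lengths) > 1:
            raise AlignmentLengthError(
                f"pre-aligned sequences must share one length; got {sorted(lengths)}"
            )
    return records


def write_fasta_sites(records: list[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for label, seq in records:
            fh.write(f">{label}\n{seq}\n")
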