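"""Binding-site residue conservation classification across aligned isotypes.

Columns of a pre-aligned binding-site alignment are classified against a
reference sequence into four categories: identity, conservative
(strong similarity), semiconservative (weak similarity) and not conserved.
The default scheme is the Clustal convention: residue groups scoring above
0.5 in the Gonnet PAM250 matrix are "strong" and mark conservative
replacements; the "weak" groups (score ≤ 0.5) mark semiconservative ones;
pairs in neither group, and gap-against-residue columns, are not conserved.
A raw substitution matrix with explicit thresholds can be plugged in
instead, since integer log-odds PAM250 entries cannot be compared to 0.5
directly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .errors import AlignmentLengthError, AlphabetError

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"

# Clustal strong-similarity groups (Gonnet PAM250 pair score > 0.5).
CLUSTAL_STRONG_GROUPS = (
    "STA", "NEQK", "NHQK", "NDEQ", "QHRK", "MILV", "MILF", "HY", "FYW",
)
# Clustal weak-similarity groups (Gonnet PAM250 pair score <= 0.5).
CLUSTAL_WEAK_GROUPS = (
    "CSA", "ATV", "SAG", "STNK", "STPA", "SGND", "SNDEQK", "NDEQHK",
    "NEQHRK", "FVLIM", "HFY",
)

CATEGORIES = ("identity", "conservative", "semiconservative", "not_conserved")


@dataclass(frozen=True)
class ConservationCall:
    """Classification of one alignment column for one subject sequence."""

    column_index: int
    reference_residue: str
    subject_residue: str
    category: str


class GroupScheme:
    """Similarity from membership in strong/weak residue groups (Clustal style)."""

    def __init__(
        self,
        strong_groups: Iterable[str] = CLUSTAL_STRONG_GROUPS,
        weak_groups: Iterable[str] = CLUSTAL_WEAK_GROUPS,
    ):
        self.strong = [frozenset(g) for g in strong_groups]
        self.weak = [frozenset(g) for g in weak_groups]

    def is_strong(self, a: str, b: str) -> bool:
        return any(a in g and b in g for g in self.strong)

    def is_weak(self, a: str, b: str) -> bool:
        return any(a in g and b in g for g in self.weak)


class MatrixScheme:
    """Similarity from a substitution matrix with explicit thresholds.

    ``matrix`` maps unordered residue pairs to scores; a pair is strongly
    similar when its score exceeds ``strong_threshold`` and weakly similar
    when it exceeds ``weak_threshold``.
    """

    def __init__(
        self,
        matrix: Mapping[tuple[str, str], float],
        strong_threshold: float = 0.5,
        weak_threshold: float = 0.0,
    ):
        if weak_threshold > strong_threshold:
            raise ValueError("weak_threshold must not exceed strong_threshold")
        self.matrix = {frozenset(k): v for k, v in matrix.items()}
        self.strong_threshold = strong_threshold
        self.weak_threshold = weak_threshold

    def _score(self, a: str, b: str) -> float:
        return self.matrix.get(frozenset((a, b)), float("-inf"))

    def is_strong(self, a: str, b: str) -> bool:
        return self._score(a, b) > self.strong_threshold

    def is_weak(self, a: str, b: str) -> bool:
        return self._score(a, b) > self.weak_threshold


DEFAULT_SCHEME = GroupScheme()


def classify_pair(a: str, b: str, scheme=DEFAULT_SCHEME) -> str:
    """Category of a residue pair: identity / conservative / semiconservative / not_conserved.

    Identity requires equal characters; gap-versus-residue is never
    conserved. Classification is symmetric in the two residues.
    """
    a, b = a.upper(), b.upper()
    for ch in (a, b):
        if ch != GAP and ch not in AMINO_ACIDS:
            raise AlphabetError(f"not a standard amino-acid letter or gap: {ch!r}")
    if a == b:
        return "identity"
    if GAP in (a, b):
        return "not_conserved"
    if scheme.is_strong(a, b):
        return "conservative"
    if scheme.is_weak(a, b):
        return "semiconservative"
    return "not_conserved"


def classify_alignment(
    reference: str,
    subjects: Sequence[tuple[str, str]] | Sequence[str],
    scheme=DEFAULT_SCHEME,
) -> dict[str, list[ConservationCall]]:
    """Classify every column of each subject against the reference.

    ``subjects`` may be (label, sequence) pairs or bare sequences (labeled
    ``subject_0``, ``subject_1``, …). All sequences must share the
    reference's length.
    """
    labeled: list[tuple[str, str]] = []
    for i, item in enumerate(subjects):
        if isinstance(item, str):
            labeled.append((f"subject_{i}", item))
        else:
            labeled.append((item[0], item[1]))
    calls: dict[str, list[ConservationCall]] = {}
    for label, seq in labeled:
        if len(seq) != len(reference):
            raise AlignmentLengthError(
                f"subject {label!r} length {len(seq)} != reference length "
                f"{len(reference)}"
            )
        calls[label] = [
            ConservationCall(i, ra.upper(), sa.upper(),
                             classify_pair(ra, sa, scheme))
            for i, (ra, sa) in enumerate(zip(reference, seq))
        ]
    return calls


def summarize_calls(calls: Sequence[ConservationCall]) -> dict:
    """Per-subject summary: category counts and fraction of identical columns."""
    counts = {cat: 0 for cat in CATEGORIES}
    for call in calls:
        counts[call.category] += 1
    n = len(calls)
    return {
        "n_columns": n,
        "counts": counts,
        "fraction_identical": counts["identity"] / n if n else float("nan"),
    }


def similar_isotype_groups(
    calls_by_subject: Mapping[str, Sequence[ConservationCall]],
    max_nonconservative: int = 0,
) -> list[str]:
    """Subjects similar enough to the reference to pool results with it.

    A subject qualifies when at most ``max_nonconservative`` of its columns
    fall outside {identity, conservative} — the criterion under which
    computational results for near-identical binding sites are averaged
    against a single reference measurement.
    """
    selected = []
    for label, calls in calls_by_subject.items():
        violations = sum(
            1 for c in calls if c.category not in ("identity", "conservative")
        )
        if violations <= max_nonconservative:
            selected.append(label)
    return selected


def calls_to_rows(calls_by_subject: Mapping[str, Sequence[ConservationCall]]) -> list[dict]:
    """Flatten calls into delimited-text-ready rows."""
    return [
        {
            "subject": label, "column_index": c.column_index,
            "reference_residue": c.reference_residue,
            "subject_residue": c.subject_residue, "category": c.category,
        }
        for label, calls in calls_by_subject.items()
        for c in calls
    ]
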