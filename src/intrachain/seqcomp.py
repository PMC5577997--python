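"""Pairwise ortholog comparison: global alignment, percent identity,
conservation class of substitutions, and polarity-change flags.

Alignment is Needleman-Wunsch (Biopython's PairwiseAligner) with BLOSUM62
and affine gaps, open -10 / extend -0.5 by default.  Substitutions are
classed by the Clustal strong/weak group convention; polarity is a 3-class
scheme (nonpolar / polar-uncharged / charged).
"""
from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

from Bio import Align
from Bio.Align import substitution_matrices

STANDARD_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")

#: Clustal "strong" groups (conservative substitutions)
STRONG_GROUPS = ("STA", "NEQK", "NHQK", "NDEQ", "QHRK", "MILV", "MILF", "HY", "FYW")
#: Clustal "weak" groups (semi-conservative substitutions)
WEAK_GROUPS = ("CSA", "ATV", "SAG", "STNK", "STPA", "SGND", "SNDEQK",
               "NDEQHK", "NEQHRK", "FVLIM", "HFY")

POLARITY_CLASSES = {
    "nonpolar": set("AVLIMFWPG"),
    "polar_uncharged": set("STCYNQ"),
    "charged": set("DEKRH"),
}
_POLARITY_OF = {aa: cls for cls, members in POLARITY_CLASSES.items() for aa in members}

GAP = "-"


@dataclass(frozen=True)
class PairwiseAlignment:
    seq_a: str
    seq_b: str
    aligned_a: str
    aligned_b: str
    score: float

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned strings must have equal length")
        if self.aligned_a.replace(GAP, "") != self.seq_a:
            raise ValueError("aligned_a does not recover seq_a")
        if self.aligned_b.replace(GAP, "") != self.seq_b:
            raise ValueError("aligned_b does not recover seq_b")

    @property
    def positions(self) -> list[tuple[int | None, int | None]]:
        """Per-column (index into seq_a or None, index into seq_b or None)."""
        out = []
        ia = ib = 0
        for ca, cb in zip(self.aligned_a, self.aligned_b):
            pa = ia if ca != GAP else None
            pb = ib if cb != GAP else None
            if ca != GAP:
                ia += 1
            if cb != GAP:
                ib += 1
            out.append((pa, pb))
        return out


@dataclass(frozen=True)
class SubstitutionRecord:
    position: int          # 0-based aligned column
    residue_a: str
    residue_b: str
    klass: str             # identical | conservative | semi_conservative | non_conservative
    polarity_change: bool


def _check_sequence(seq: str, label: str) -> None:
    if not seq:
        raise ValueError(f"{label}: empty sequence")
    for i, ch in enumerate(seq):
        if ch not in STANDARD_ALPHABET:
            raise ValueError(f"{label}: non-standard character {ch!r} at position {i}")


def align_global(seq_a: str, seq_b: str,
                 gap_open: float = -10.0, gap_extend: float = -0.5,
                 matrix: str = "BLOSUM62") -> PairwiseAlignment:
    """Optimal global alignment; deterministic first co-optimal traceback."""
    _check_sequence(seq_a, "seq_a")
    _check_sequence(seq_b, "seq_b")
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    aligner.mode = "global"
    best = aligner.align(seq_a, seq_b)[0]
    return PairwiseAlignment(seq_a=seq_a, seq_b=seq_b,
                             aligned_a=str(best[0]), aligned_b=str(best[1]),
                             score=float(best.score))


def percent_identity(aln: PairwiseAlignment,
                     denominator: str = "alignment_length") -> float:
    """100 x identical columns / denominator, in [0, 100]."""
    length = len(aln.aligned_a)
    if length == 0:
        raise ValueError("zero-length alignment")
    identical = sum(1 for a, b in zip(aln.aligned_a, aln.aligned_b)
                    if a == b and a != GAP)
    if denominator == "alignment_length":
        denom = length
    elif denominator == "shorter_seq":
        denom = min(len(aln.seq_a), len(aln.seq_b))
    else:
        raise ValueError("denominator must be 'alignment_length' or 'shorter_seq'")
    return 100.0 * identical / denom


def classify_substitution(residue_a: str, residue_b: str) -> tuple[str, bool]:
    """(conservation class, polarity-change flag) for an aligned residue pair."""
    for r in (residue_a, residue_b):
        if r == GAP:
            raise ValueError("gap characters are reported separately, not classified")
        if r not in STANDARD_ALPHABET:
            raise ValueError(f"non-standard residue {r!r}")
    if residue_a == residue_b:
        return ("identical", False)
    polarity_change = _POLARITY_OF[residue_a] != _POLARITY_OF[residue_b]
    pair = {residue_a, residue_b}
    if any(pair <= set(g) for g in STRONG_GROUPS):
        return ("conservative", polarity_change)
    if any(pair <= set(g) for g in WEAK_GROUPS):
        return ("semi_conservative", polarity_change)
    return ("non_conservative", polarity_change)


def substitution_report(aln: PairwiseAlignment
                        ) -> tuple[list[SubstitutionRecord], dict]:
    """One record per non-identical, non-gap column, plus summary counts."""
    records: list[SubstitutionRecord] = []
    gap_columns = 0
    for pos, (a, b) in enumerate(zip(aln.aligned_a, aln.aligned_b)):
        if a == GAP or b == GAP:
            gap_columns += 1
            continue
        if a == b:
            continue
        klass, polarity_change = classify_substitution(a, b)
        records.append(SubstitutionRecord(pos, a, b, klass, polarity_change))
    summary = {
        "columns": len(aln.aligned_a),
        "identical": sum(1 for a, b in zip(aln.aligned_a, aln.aligned_b)
                         if a == b and a != GAP),
        "gap_columns": gap_columns,
        "conservative": sum(r.klass == "conservative" for r in records),
        "semi_conservative": sum(r.klass == "semi_conservative" for r in records),
        "non_conservative": sum(r.klass == "non_conservative" for r in records),
        "polarity_changes": sum(r.polarity_change for r in records),
    }
    return records, summary


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding (0.65 -> 0.7), used for reported percentages."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))
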