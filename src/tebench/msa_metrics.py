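"""Accuracy metrics for predicted MSAs against a ground-truth reference.

Three metrics are provided:

* **SPS** (sum-of-pairs score): the fraction of residue pairs aligned in the
  reference MSA that are also aligned in the predicted MSA.  A residue pair
  is two residues (identified by sequence id and ungapped coordinate) sharing
  a column.
* **CS** (column score): the fraction of reference columns whose exact
  residue content — which residues, by ungapped coordinate — appears as an
  identical column in the predicted MSA.  A single misplaced sequence can
  collapse CS while leaving SPS high.
* **CSL** (consensus score loss): compares the consensus derived from the
  predicted MSA (Cp) to the consensus from the reference MSA (Cr) by global
  alignment: ``(score(Cr~Cr) - score(Cp~Cr)) / score(Cr~Cr)``.  0 means the
  predicted MSA supports perfect consensus recovery; values above 1 occur
  when Cp aligns to Cr with a negative score.

Pairwise alignment uses affine gap scoring (``gap_open + k*gap_extend`` for a
length-``k`` gap).  The default nucleotide scoring — match +10, transition
-6, transversion -10, N neutral, gap open -25, extend -5 — has magnitudes in
line with neutral-DNA comparison matrices; the metrics that matter here are
ratio-based, so the exact values are pinned for reproducibility rather than
criticality.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .formats_io import Msa, SeqRecord

__all__ = [
    "ScoreParams",
    "MetricReport",
    "residue_pairs",
    "sps",
    "column_score",
    "nw_global_align",
    "csl",
    "self_score",
    "metric_report",
]

_ALPHABET = "ACGTN"
_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


@dataclass(frozen=True)
class ScoreParams:
    """Symmetric nucleotide scoring with affine gaps.

    A gap of length ``k`` scores ``gap_open + k * gap_extend`` (both are
    non-positive).
    """

    match: int = 10
    transition: int = -6
    transversion: int = -10
    n_score: int = 0
    gap_open: int = -25
    gap_extend: int = -5

    def __post_init__(self) -> None:
        if self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("gap penalties must be <= 0")
        if self.match <= max(self.transition, self.transversion):
            raise ValueError("match score must exceed mismatch scores")

    def score(self, a: str, b: str) -> int:
        if a == "N" or b == "N":
            return self.n_score
        if a == b:
            return self.match
        if (a, b) in _TRANSITIONS:
            return self.transition
        return self.transversion

    def matrix(self) -> substitution_matrices.Array:
        arr = substitution_matrices.Array(alphabet=_ALPHABET, dims=2)
        for a in _ALPHABET:
            for b in _ALPHABET:
                arr[a, b] = self.score(a, b)
        return arr

    def aligner(self, mode: str) -> Align.PairwiseAligner:
        """A configured Biopython aligner; ``mode`` is "global" or "local"."""
        al = Align.PairwiseAligner()
        al.mode = mode
        al.substitution_matrix = self.matrix()
        # Biopython charges open on the first gap position
        al.open_gap_score = self.gap_open + self.gap_extend
        al.extend_gap_score = self.gap_extend
        return al


@dataclass
class MetricReport:
    sps: float
    cs: float
    csl: float
    score_rr: float
    score_pr: float


# ---------------------------------------------------------------------------
# residue-pair machinery
# ---------------------------------------------------------------------------

def _residue_columns(msa: Msa) -> dict[str, np.ndarray]:
    """Per row: array mapping ungapped residue index -> column index."""
    out: dict[str, np.ndarray] = {}
    for rid, row in msa.rows:
        cols = np.flatnonzero(np.frombuffer(row.encode(), dtype=np.uint8) != ord("-"))
        out[rid] = cols
    return out


def residue_pairs(msa: Msa) -> set[tuple[tuple[str, int], tuple[str, int]]]:
    """All unordered pairs of residues sharing a column (ungapped coords).

    Materialises the full pair set — intended for small alignments and as the
    definitional oracle; :func:`sps` scores large alignments without it.
    """
    pairs: set = set()
    counters = {rid: -1 for rid, _ in msa.rows}
    for c in range(msa.ncols):
        members = []
        for rid, row in msa.rows:
            if row[c] != "-":
                counters[rid] += 1
                members.append((rid, counters[rid]))
        for a, b in combinations(members, 2):
            pairs.add((a, b) if a <= b else (b, a))
    return pairs


def _check_comparable(predicted: Msa, reference: Msa) -> None:
    pred_ids = set(predicted.ids)
    ref_ids = set(reference.ids)
    if pred_ids != ref_ids:
        raise ValueError(
            f"MSAs cover different sequences: only-in-predicted="
            f"{sorted(pred_ids - ref_ids)} only-in-reference={sorted(ref_ids - pred_ids)}"
        )
    for rid in reference.ids:
        if predicted.ungapped(rid) != reference.ungapped(rid):
            raise ValueError(f"ungapped sequence mismatch for id {rid!r}")


def _predicted_columns_by_reference_column(
    predicted: Msa, reference: Msa
) -> list[list[int]]:
    """For each reference column, the predicted-column index of each residue."""
    pred_cols = _residue_columns(predicted)
    ref_cols = _residue_columns(reference)
    groups: list[list[int]] = [[] for _ in range(reference.ncols)]
    for rid, _ in reference.rows:
        for rc, pc in zip(ref_cols[rid], pred_cols[rid]):
            groups[rc].append(int(pc))
    return groups


def sps(predicted: Msa, reference: Msa) -> float:
    """Fraction of reference residue pairs correctly aligned in ``predicted``.

    Returns 1.0 when the reference induces no pairs (vacuous truth).
    """
    _check_comparable(predicted, reference)
    groups = _predicted_columns_by_reference_column(predicted, reference)
    total = 0
    correct = 0
    # residues of a reference column are correctly aligned in the prediction
    # iff they occupy the same predicted column
    for members in groups:
        k = len(members)
        total += k * (k - 1) // 2
        seen: dict[int, int] = {}
        for pc in members:
            seen[pc] = seen.get(pc, 0) + 1
        for g in seen.values():
            correct += g * (g - 1) // 2
    if total == 0:
        return 1.0
    return correct / total


def column_score(predicted: Msa, reference: Msa) -> float:
    """Fraction of reference columns perfectly reconstructed in ``predicted``.

    A column counts as reconstructed when its residues (by id and ungapped
    coordinate) all share one predicted column and that column holds nothing
    else.
    """
    _check_comparable(predicted, reference)
    occupancy = np.zeros(predicted.ncols, dtype=int)
    for cols in _residue_columns(predicted).values():
        occupancy[cols] += 1
    groups = _predicted_columns_by_reference_column(predicted, reference)
    correct = 0
    for members in groups:
        first = members[0]
        if all(pc == first for pc in members) and occupancy[first] == len(members):
            correct += 1
    return correct / reference.ncols


# ---------------------------------------------------------------------------
# pairwise alignment and consensus score loss
# ---------------------------------------------------------------------------

def _seq(x) -> str:
    return x.seq if isinstance(x, SeqRecord) else str(x)


def nw_global_align(
    a, b, params: ScoreParams | None = None
) -> tuple[float, tuple[str, str]]:
    """Optimal Needleman–Wunsch global alignment with affine gaps.

    Returns the score and one optimal alignment as a pair of gapped strings.
    Ties among co-optimal tracebacks are broken by the engine's canonical
    enumeration order (deterministic).
    """
    params = params or ScoreParams()
    sa, sb = _seq(a), _seq(b)
    if not sa or not sb:
        raise ValueError("sequences must be non-empty")
    aligner = params.aligner("global")
    alignments = aligner.align(sa, sb)
    best = alignments[0]
    return float(best.score), (str(best[0]), str(best[1]))


def self_score(seq, params: ScoreParams | None = None) -> float:
    """Score of a sequence globally aligned to itself (sum of match scores)."""
    params = params or ScoreParams()
    return float(sum(params.score(c, c) for c in _seq(seq)))


def csl(
    predicted_consensus, reference_consensus, params: ScoreParams | None = None
) -> MetricReport | float:
    """Consensus score loss: ``(score(Cr~Cr) - score(Cp~Cr)) / score(Cr~Cr)``.

    Returns a plain float.  Raises on a degenerate reference whose
    self-alignment score is not positive.
    """
    params = params or ScoreParams()
    cr = _seq(reference_consensus)
    cp = _seq(predicted_consensus)
    if not cr:
        raise ValueError("reference consensus is empty")
    score_rr = self_score(cr, params)
    if score_rr <= 0:
        raise ValueError(f"degenerate reference consensus (self-score {score_rr})")
    score_pr, _ = nw_global_align(cp, cr, params)
    return (score_rr - score_pr) / score_rr


def metric_report(
    predicted: Msa,
    reference: Msa,
    predicted_consensus,
    reference_consensus,
    params: ScoreParams | None = None,
) -> MetricReport:
    """All three metrics plus the CSL component scores in one report."""
    params = params or ScoreParams()
    score_rr = self_score(reference_consensus, params)
    score_pr, _ = nw_global_align(predicted_consensus, reference_consensus, params)
    return MetricReport(
        sps=sps(predicted, reference),
        cs=column_score(predicted, reference),
        csl=(score_rr - score_pr) / score_rr,
        score_rr=score_rr,
        score_pr=score_pr,
    )
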