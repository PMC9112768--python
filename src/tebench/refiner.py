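"""Iterative transitive alignment with consensus refinement.

The Refiner algorithm builds a family MSA and consensus from a set of
(possibly fragmented, possibly highly diverged) TE copies:

1. Pick a template: the input sequence with the best cumulative pairwise
   local-alignment score to all others (roughly the centroid of the set).
2. Locally align every sequence to the template (any sensitive affine-gap
   local aligner suffices; this implementation uses Smith–Waterman scoring
   through Biopython's pairwise engine, recursing on unaligned query segments
   so fragmented matches yield multiple alignments per query).
3. Merge the alignments into an MSA through the shared template coordinates
   (a *transitive* alignment): one anchored column per covered template
   position; insertion runs at the same template junction are left-justified
   into shared columns.
4. Residues outside any local alignment are padded in as private columns —
   aligned to nothing — so every input character appears exactly once.
5. Call a consensus from the MSA and iterate with it as the new template
   (expectation–maximisation on a discrete consensus), until the consensus
   repeats (including oscillation) or ``max_iterations`` is reached.

The consensus caller runs in two stages.  Stage one picks, per column, the
character in {A,C,G,T,N,-} with the highest summed score against the column's
residues, restricted to sequences whose alignment spans the column; columns
won by '-' are dropped.  Stage two re-examines every consensus dinucleotide
for CpG restoration: methylated CG decays predominantly to CA and TG, so a
dinucleotide whose underlying aligned pairs are dominated by CA+TG (by
default at least half the pairs, and more than the literal stage-one call) is
reassigned to CG.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

import numpy as np

from .formats_io import Msa, SeqRecord
from .msa_metrics import ScoreParams

__all__ = [
    "LocalAlignment",
    "TransitiveMsa",
    "RefinerState",
    "ConsensusParams",
    "RefinerError",
    "choose_centroid",
    "local_align",
    "transitive_msa",
    "pad_unaligned",
    "call_consensus",
    "refine",
]


class RefinerError(RuntimeError):
    pass


@dataclass
class LocalAlignment:
    """One local alignment of a query to the template.

    ``pairs`` lists aligned positions ``(template_pos | None, query_pos |
    None)``; a None marks a gap on that side.  Intervals are 0-based
    half-open.
    """

    query_id: str
    t_start: int
    t_end: int
    q_start: int
    q_end: int
    pairs: list[tuple[int | None, int | None]]
    score: float


@dataclass
class TransitiveMsa:
    """An MSA anchored to a template, with per-column provenance.

    ``columns[i]`` is ``("anchor", t)`` for a column mapping to template
    position ``t``, or ``("ins", t, slot)`` for the ``slot``-th shared
    insertion column after template position ``t``.  ``residue_columns`` maps
    each query id to its residues' ``{query_pos: column_index}`` (residues
    that could not be placed — e.g. a second alignment of the same query over
    an already-occupied template position — are absent and handled by
    :func:`pad_unaligned`).
    """

    msa: Msa
    columns: list[tuple]
    residue_columns: dict[str, dict[int, int]]
    template: SeqRecord


@dataclass
class RefinerState:
    iteration: int
    template: SeqRecord
    msa: Msa
    consensus: SeqRecord
    converged: bool
    history: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# template choice and local alignment
# ---------------------------------------------------------------------------

def choose_centroid(seqs: list[SeqRecord], params: ScoreParams | None = None) -> SeqRecord:
    """The sequence with the best cumulative local-alignment score to the rest.

    Ties are broken by lowest input index.  If every pairwise score is zero
    (no sequence resembles any other) the longest sequence is returned as a
    fallback.
    """
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    params = params or ScoreParams()
    aligner = params.aligner("local")
    n = len(seqs)
    scores = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            s = float(aligner.score(seqs[i].seq, seqs[j].seq))
            scores[i, j] = scores[j, i] = s
    totals = scores.sum(axis=1)
    if totals.max() <= 0:
        return max(seqs, key=lambda r: len(r.seq))
    return seqs[int(np.argmax(totals))]


def _alignment_pairs(aln) -> tuple[list[tuple[int | None, int | None]], int, int, int, int]:
    """Extract (template, query) position pairs from a Biopython alignment."""
    blocks_t, blocks_q = aln.aligned
    pairs: list[tuple[int | None, int | None]] = []
    prev_t = prev_q = None
    for (ts, te), (qs, qe) in zip(blocks_t, blocks_q):
        if prev_t is not None:
            for t in range(prev_t, ts):  # deletion in query (gap run)
                pairs.append((t, None))
            for q in range(prev_q, qs):  # insertion in query
                pairs.append((None, q))
        for t, q in zip(range(ts, te), range(qs, qe)):
            pairs.append((t, q))
        prev_t, prev_q = te, qe
    t_start, q_start = int(blocks_t[0][0]), int(blocks_q[0][0])
    t_end, q_end = int(blocks_t[-1][1]), int(blocks_q[-1][1])
    return pairs, t_start, t_end, q_start, q_end


def local_align(
    query: SeqRecord,
    template: SeqRecord,
    params: ScoreParams | None = None,
    min_score: float = 30.0,
    min_segment: int = 15,
    max_fragments: int = 16,
) -> list[LocalAlignment]:
    """Best non-overlapping local alignments of ``query`` to ``template``.

    Greedy: the highest-scoring alignment is taken, then the unaligned query
    prefix/suffix segments are re-aligned recursively, so a query whose
    matches are split (fragmented or rearranged copies) yields several
    alignments.  Alignments below ``min_score`` are discarded; an empty list
    means the query failed to align this round.  Returned ordered by score,
    descending.
    """
    params = params or ScoreParams()
    aligner = params.aligner("local")
    results: list[LocalAlignment] = []

    def recurse(a: int, b: int) -> None:
        if b - a < min_segment or len(results) >= max_fragments:
            return
        segment = query.seq[a:b]
        alignments = aligner.align(template.seq, segment)
        if len(alignments) == 0:
            return
        best = alignments[0]
        if float(best.score) < min_score:
            return
        pairs, ts, te, qs, qe = _alignment_pairs(best)
        shifted = [(t, None if q is None else q + a) for t, q in pairs]
        results.append(
            LocalAlignment(
                query_id=query.id,
                t_start=ts,
                t_end=te,
                q_start=qs + a,
                q_end=qe + a,
                pairs=shifted,
                score=float(best.score),
            )
        )
        recurse(a, a + qs)
        recurse(a + qe, b)

    recurse(0, len(query.seq))
    results.sort(key=lambda la: (-la.score, la.q_start))
    return results


# ---------------------------------------------------------------------------
# transitive MSA construction
# ---------------------------------------------------------------------------

def _colinear_chain(las: list[LocalAlignment]) -> list[LocalAlignment]:
    """Largest-score-first subset of one query's alignments that is colinear.

    Alignments are usable together only if their query and template intervals
    are ordered the same way (a row's residues must appear in increasing
    column order).  Accepted greedily by score; rejected alignments' residues
    fall through to :func:`pad_unaligned`.  Returned sorted by query start.
    """
    accepted: list[LocalAlignment] = []
    for la in sorted(las, key=lambda x: (-x.score, x.q_start)):
        ok = True
        for other in accepted:
            before = la.q_end <= other.q_start and la.t_end <= other.t_start
            after = la.q_start >= other.q_end and la.t_start >= other.t_end
            if not (before or after):
                ok = False
                break
        if ok:
            accepted.append(la)
    return sorted(accepted, key=lambda x: x.q_start)


def transitive_msa(
    alignments: list[LocalAlignment],
    template: SeqRecord,
    queries: list[SeqRecord],
    include_template: bool = False,
) -> TransitiveMsa:
    """Merge per-query local alignments through shared template coordinates.

    ``queries`` supplies the residue characters (and the output row order for
    queries that have at least one alignment).
    """
    if not alignments:
        raise RefinerError("no alignments to merge")
    seq_of = {q.id: q.seq for q in queries}
    missing = {la.query_id for la in alignments} - set(seq_of)
    if missing:
        raise RefinerError(f"alignments reference unknown queries: {sorted(missing)}")
    # group by query, process each query's alignments left-to-right in q
    by_query: dict[str, list[LocalAlignment]] = {}
    for la in alignments:
        by_query.setdefault(la.query_id, []).append(la)

    # residue -> column key; key sorts as (t, 0, 0) anchored, (t, 1, slot) ins
    residue_keys: dict[str, dict[int, tuple]] = {}
    used_keys: set[tuple] = set()
    for qid, las in by_query.items():
        keymap: dict[int, tuple] = {}
        taken_t: set[int] = set()  # template positions already used by this query
        for la in _colinear_chain(las):
            prev_t = la.t_start - 1
            slot = 0
            for t, q in la.pairs:
                if q is None:
                    prev_t, slot = t, 0
                    continue
                if t is not None:
                    if t in taken_t:
                        continue  # duplicate coverage; residue left for padding
                    keymap[q] = (t, 0, 0)
                    taken_t.add(t)
                    prev_t, slot = t, 0
                else:
                    keymap[q] = (prev_t, 1, slot)
                    slot += 1
        residue_keys[qid] = keymap
        used_keys.update(keymap.values())

    ordered = sorted(used_keys)
    col_of = {k: i for i, k in enumerate(ordered)}
    ncols = len(ordered)

    rows: list[tuple[str, str]] = []
    residue_columns: dict[str, dict[int, int]] = {}
    if include_template:
        trow = ["-"] * ncols
        for key, c in col_of.items():
            if key[1] == 0:
                trow[c] = template.seq[key[0]]
        rows.append((template.id, "".join(trow)))
    for q in queries:
        if q.id not in by_query:
            continue
        keymap = residue_keys[q.id]
        row = ["-"] * ncols
        colmap: dict[int, int] = {}
        for qpos, key in keymap.items():
            c = col_of[key]
            row[c] = q.seq[qpos]
            colmap[qpos] = c
        rows.append((q.id, "".join(row)))
        residue_columns[q.id] = colmap

    columns = [("anchor", k[0]) if k[1] == 0 else ("ins", k[0], k[2]) for k in ordered]
    return TransitiveMsa(
        msa=Msa(rows),
        columns=columns,
        residue_columns=residue_columns,
        template=template,
    )


def pad_unaligned(tmsa: TransitiveMsa, full_queries: list[SeqRecord]) -> Msa:
    """Add every residue not covered by a local alignment as a private column.

    Each such residue occupies its own column (all other rows gapped), placed
    immediately after the column of its nearest aligned neighbour to the left
    (or before all columns for an unaligned prefix).  The output contains one
    row per query in ``full_queries`` order — including queries that failed to
    align at all — and every row ungaps to its original sequence bit-exactly.
    """
    ncols = tmsa.msa.ncols
    seq_of = {q.id: q.seq for q in full_queries}
    # pads bucketed next to their nearest aligned neighbour: a run between two
    # aligned residues (or a suffix) goes after the left neighbour's column, a
    # prefix run goes before the right neighbour's column, and a fully
    # unaligned query sits at the far left; (row order, residue order) within
    # a bucket keeps runs contiguous and in sequence
    pads_after: dict[int, list[tuple[str, int]]] = {}
    pads_before: dict[int, list[tuple[str, int]]] = {}
    unanchored: list[tuple[str, int]] = []
    aligned_cols: dict[str, dict[int, int]] = {}
    for q in full_queries:
        colmap = tmsa.residue_columns.get(q.id, {})
        aligned_cols[q.id] = colmap
        sorted_qpos = sorted(colmap)
        for qpos in range(len(q.seq)):
            if qpos in colmap:
                continue
            i = bisect.bisect_left(sorted_qpos, qpos) - 1
            if i >= 0:
                pads_after.setdefault(colmap[sorted_qpos[i]], []).append((q.id, qpos))
            elif sorted_qpos:
                pads_before.setdefault(colmap[sorted_qpos[0]], []).append((q.id, qpos))
            else:
                unanchored.append((q.id, qpos))

    order: list[tuple] = []  # ("col", c) or ("pad", qid, qpos)
    order.extend(("pad", qid, qpos) for qid, qpos in unanchored)
    for c in range(ncols):
        order.extend(("pad", qid, qpos) for qid, qpos in pads_before.get(c, []))
        order.append(("col", c))
        order.extend(("pad", qid, qpos) for qid, qpos in pads_after.get(c, []))

    out_index_of_col = {entry[1]: i for i, entry in enumerate(order) if entry[0] == "col"}
    row_of = {q.id: ["-"] * len(order) for q in full_queries}
    for qid, colmap in aligned_cols.items():
        for qpos, c in colmap.items():
            row_of[qid][out_index_of_col[c]] = seq_of[qid][qpos]
    for i, entry in enumerate(order):
        if entry[0] == "pad":
            _, qid, qpos = entry
            row_of[qid][i] = seq_of[qid][qpos]
    msa = Msa([(q.id, "".join(row_of[q.id])) for q in full_queries])
    for q in full_queries:  # universal round-trip invariant
        if msa.ungapped(q.id) != q.seq:
            raise RefinerError(f"padding broke row {q.id!r}: ungap != input")
    return msa


# ---------------------------------------------------------------------------
# consensus calling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConsensusParams:
    """Scoring tables for the two-stage consensus caller.

    Base-vs-base scores reuse :class:`ScoreParams`; the gap character scores
    ``gap_gap`` against a gap vote and ``gap_base`` against any base (and
    symmetrically), so a column is dropped once gaps dominate.  ``cpg_min_fraction``
    is the fraction of aligned dinucleotide pairs that must be CA or TG for a
    stage-two CG reassignment.
    """

    scores: ScoreParams = field(default_factory=ScoreParams)
    gap_gap: int = 10
    gap_base: int = -25
    cpg_min_fraction: float = 0.5
    cpg_pass: bool = True

    def table(self) -> np.ndarray:
        syms = "ACGTN-"
        arr = np.zeros((6, 6))
        for i, a in enumerate(syms):
            for j, b in enumerate(syms):
                if a == "-" and b == "-":
                    arr[i, j] = self.gap_gap
                elif a == "-" or b == "-":
                    arr[i, j] = self.gap_base
                else:
                    arr[i, j] = self.scores.score(a, b)
        return arr


_SYMS = "ACGTN-"
_SYM_INDEX = {s: i for i, s in enumerate(_SYMS)}


def call_consensus(
    msa: Msa, params: ConsensusParams | None = None
) -> SeqRecord:
    """Two-stage consensus call over an MSA.

    Stage one scores each candidate character against each column's votes
    (only rows whose alignment spans the column vote; a fragment casts no
    votes outside its extent) and keeps the argmax, dropping gap-won columns.
    Ties prefer A > C > G > T > N > '-'.  Stage two reassigns dinucleotides
    dominated by aligned CA/TG pairs — the products of CpG deamination — back
    to CG.
    """
    params = params or ConsensusParams()
    chars = np.array([list(row) for _, row in msa.rows])
    nrows, ncols = chars.shape
    codes = np.zeros((nrows, ncols), dtype=np.int8)
    for s, i in _SYM_INDEX.items():
        codes[chars == s] = i
    nongap = codes != _SYM_INDEX["-"]
    # coverage: a row votes only between its first and last residue
    first = np.argmax(nongap, axis=1)
    last = ncols - 1 - np.argmax(nongap[:, ::-1], axis=1)
    cols = np.arange(ncols)
    covered = (cols >= first[:, None]) & (cols <= last[:, None])
    counts = np.zeros((6, ncols))
    for s in range(6):
        counts[s] = ((codes == s) & covered).sum(axis=0)
    scores = params.table() @ counts  # (candidate, column)
    winners = np.argmax(scores, axis=0)  # first index wins ties: A>C>G>T>N>-
    keep = winners != _SYM_INDEX["-"]
    stage1 = [_SYMS[w] for w in winners[keep]]
    src_cols = cols[keep]
    if not stage1:
        raise RefinerError("consensus is empty: every column was gap-dominated")

    if params.cpg_pass and len(stage1) > 1:
        i = 0
        while i < len(stage1) - 1:
            c1, c2 = int(src_cols[i]), int(src_cols[i + 1])
            mask = covered[:, c1] & covered[:, c2] & nongap[:, c1] & nongap[:, c2]
            if mask.any():
                left = chars[mask, c1]
                right = chars[mask, c2]
                pairs_ca = int(np.sum((left == "C") & (right == "A")))
                pairs_tg = int(np.sum((left == "T") & (right == "G")))
                cur = stage1[i] + stage1[i + 1]
                pairs_cur = int(np.sum((left == cur[0]) & (right == cur[1])))
                valid = int(mask.sum())
                products = pairs_ca + pairs_tg
                if (
                    cur != "CG"
                    and products >= params.cpg_min_fraction * valid
                    and products > pairs_cur
                ):
                    stage1[i], stage1[i + 1] = "C", "G"
                    i += 2
                    continue
            i += 1

    return SeqRecord("consensus", "".join(stage1))


# ---------------------------------------------------------------------------
# the refinement loop
# ---------------------------------------------------------------------------

def refine(
    seqs: list[SeqRecord],
    params: ScoreParams | None = None,
    consensus_params: ConsensusParams | None = None,
    max_iterations: int = 20,
    min_score: float = 30.0,
) -> RefinerState:
    """Iterate transitive alignment and consensus calling to convergence.

    Convergence: the new consensus string equals the previous one, or has
    been seen in an earlier iteration (oscillation), or ``max_iterations`` is
    reached.  Raises :class:`RefinerError` if no sequence aligns to the
    template in some round.
    """
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    params = params or ScoreParams()
    consensus_params = consensus_params or ConsensusParams()
    template = choose_centroid(seqs, params)
    history: list[str] = []
    state: RefinerState | None = None
    for iteration in range(1, max_iterations + 1):
        alignments: list[LocalAlignment] = []
        for q in seqs:
            alignments.extend(local_align(q, template, params, min_score=min_score))
        if not alignments:
            raise RefinerError(
                f"iteration {iteration}: no sequence aligned to the template "
                f"({len(template.seq)} bp) above score {min_score}"
            )
        tmsa = transitive_msa(alignments, template, seqs)
        padded = pad_unaligned(tmsa, seqs)
        consensus = call_consensus(padded, consensus_params)
        converged = consensus.seq == template.seq or consensus.seq in history
        state = RefinerState(
            iteration=iteration,
            template=template,
            msa=padded,
            consensus=consensus,
            converged=converged,
            history=history + [consensus.seq],
        )
        history.append(consensus.seq)
        if converged:
            break
        template = SeqRecord("consensus", consensus.seq)
    return state
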