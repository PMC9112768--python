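"""Metric tests, each checked against an independent brute-force oracle."""

import itertools

import numpy as np
import pytest

from tebench import (
    Msa,
    ScoreParams,
    SeqRecord,
    column_score,
    csl,
    nw_global_align,
    residue_pairs,
    self_score,
    sps,
)

PARAMS = ScoreParams()


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def pairs_oracle(msa: Msa):
    """Definitional double loop over columns and row pairs."""
    out = set()
    ids = msa.ids
    residx = {rid: -1 for rid in ids}
    for c in range(msa.ncols):
        present = []
        for rid in ids:
            if msa.row(rid)[c] != "-":
                residx[rid] += 1
                present.append((rid, residx[rid]))
        for a in range(len(present)):
            for b in range(a + 1, len(present)):
                pair = tuple(sorted((present[a], present[b])))
                out.add(pair)
    return out


def enumerate_global_score(a: str, b: str, p: ScoreParams) -> float:
    """Max affine score over every explicit global alignment path."""

    best = [-np.inf]

    def walk(i, j, cols):
        if i == len(a) and j == len(b):
            score = 0.0
            run = None
            for kind, x, y in cols:
                if kind == "M":
                    score += p.score(x, y)
                    run = None
                else:
                    if run != kind:
                        score += p.gap_open
                        run = kind
                    score += p.gap_extend
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            walk(i + 1, j + 1, cols + [("M", a[i], b[j])])
        if i < len(a):
            walk(i + 1, j, cols + [("A", a[i], None)])
        if j < len(b):
            walk(i, j + 1, cols + [("B", None, b[j])])

    walk(0, 0, [])
    return best[0]


def gotoh_global(a: str, b: str, p: ScoreParams) -> float:
    """Plain-Python affine-gap global DP (Gotoh), written independently."""
    n, m = len(a), len(b)
    NEG = -1e18
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    Ga = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (consume a)
    Gb = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (consume b)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        Ga[i][0] = p.gap_open + i * p.gap_extend
    for j in range(1, m + 1):
        Gb[0][j] = p.gap_open + j * p.gap_extend
    for i in range(n + 1):
        for j in range(m + 1):
            if i > 0 and j > 0:
                s = p.score(a[i - 1], b[j - 1])
                M[i][j] = max(M[i - 1][j - 1], Ga[i - 1][j - 1], Gb[i - 1][j - 1]) + s
            if i > 0:
                Ga[i][j] = max(
                    Ga[i][j],
                    M[i - 1][j] + p.gap_open + p.gap_extend,
                    Ga[i - 1][j] + p.gap_extend,
                    Gb[i - 1][j] + p.gap_open + p.gap_extend,
                )
            if j > 0:
                Gb[i][j] = max(
                    Gb[i][j],
                    M[i][j - 1] + p.gap_open + p.gap_extend,
                    Gb[i][j - 1] + p.gap_extend,
                    Ga[i][j - 1] + p.gap_open + p.gap_extend,
                )
    return max(M[n][m], Ga[n][m], Gb[n][m])


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


# ---------------------------------------------------------------------------
# residue pairs / SPS / CS
# ---------------------------------------------------------------------------

class TestResiduePairs:
    def test_three_residue_column(self):
        msa = Msa([("a", "A"), ("b", "C"), ("c", "G")])
        assert len(residue_pairs(msa)) == 3

    def test_single_sequence_empty(self):
        assert residue_pairs(Msa([("a", "ACGT")])) == set()

    def test_matches_bruteforce_on_random_msas(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            rows = []
            for i in range(5):
                chars = rng.choice(list("ACGT-"), size=20, p=[0.2] * 4 + [0.2])
                rows.append((f"s{i}", "".join(chars) + "A"))
            msa = Msa(rows, drop_all_gap_columns=True)
            assert residue_pairs(msa) == pairs_oracle(msa)


class TestSps:
    def test_identity_is_one(self, small_family):
        ref = small_family.reference_msa
        assert sps(ref, ref) == 1.0

    def test_fully_disjoint_prediction_is_zero(self):
        ref = Msa([("a", "AC"), ("b", "GT")])
        pred = Msa([("a", "AC--"), ("b", "--GT")])
        assert sps(pred, ref) == 0.0

    def test_matches_pair_set_intersection_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            seqs = {f"s{i}": random_seq(rng, 6) for i in range(4)}
            ref = _random_alignment(rng, seqs)
            pred = _random_alignment(rng, seqs)
            expected_pairs = pairs_oracle(ref)
            got = len(pairs_oracle(pred) & expected_pairs) / len(expected_pairs)
            assert sps(pred, ref) == pytest.approx(got)

    def test_mismatched_sequences_rejected(self):
        ref = Msa([("a", "AC"), ("b", "GT")])
        pred = Msa([("a", "AG"), ("b", "GT")])
        with pytest.raises(ValueError, match="a"):
            sps(pred, ref)

    def test_row_order_invariance(self, small_family):
        ref = small_family.reference_msa
        shuffled = Msa(list(reversed(ref.rows)))
        assert sps(shuffled, ref) == 1.0


class TestColumnScore:
    def test_identity_is_one(self, small_family):
        ref = small_family.reference_msa
        assert column_score(ref, ref) == 1.0

    def test_single_misaligned_sequence_collapses_cs_not_sps(self):
        """Shifting one row by a single gap wrecks nearly every column while
        leaving most residue pairs intact."""
        rng = np.random.default_rng(3)
        seqs = {f"s{i}": random_seq(rng, 30) for i in range(10)}
        ref = Msa([(rid, s) for rid, s in seqs.items()])
        rows = [
            (rid, s + "-" if rid != "s0" else "-" + s) for rid, s in seqs.items()
        ]
        pred = Msa(rows)
        assert column_score(pred, ref) == 0.0
        # only pairs involving the shifted row are lost: 9/45 of all pairs
        assert sps(pred, ref) == pytest.approx(0.8)

    def test_matches_bruteforce_column_comparison(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            seqs = {f"s{i}": random_seq(rng, 5) for i in range(3)}
            ref = _random_alignment(rng, seqs)
            pred = _random_alignment(rng, seqs)
            # oracle: a reference column is reconstructed iff its residue set
            # equals some predicted column's residue set
            ref_cols = _columns_as_residue_sets(ref)
            pred_cols = {frozenset(c) for c in _columns_as_residue_sets(pred)}
            expected = sum(1 for c in ref_cols if frozenset(c) in pred_cols) / len(ref_cols)
            assert column_score(pred, ref) == pytest.approx(expected)


def _columns_as_residue_sets(msa: Msa):
    residx = {rid: -1 for rid in msa.ids}
    out = []
    for c in range(msa.ncols):
        members = []
        for rid in msa.ids:
            if msa.row(rid)[c] != "-":
                residx[rid] += 1
                members.append((rid, residx[rid]))
        out.append(members)
    return out


def _random_alignment(rng, seqs: dict) -> Msa:
    """Random gap-placement alignment of the given sequences."""
    width = max(len(s) for s in seqs.values()) + 4
    rows = []
    for rid, s in seqs.items():
        gaps = sorted(rng.choice(width, size=width - len(s), replace=False))
        row = []
        si = 0
        for c in range(width):
            if c in gaps:
                row.append("-")
            else:
                row.append(s[si])
                si += 1
        rows.append((rid, "".join(row)))
    return Msa(rows, drop_all_gap_columns=True)


# ---------------------------------------------------------------------------
# pairwise alignment
# ---------------------------------------------------------------------------

class TestNwGlobalAlign:
    def test_self_alignment_score(self):
        score, (ga, gb) = nw_global_align("ACGT", "ACGT", PARAMS)
        assert score == 40.0
        assert ga == gb == "ACGT"
        assert self_score("ACGT", PARAMS) == 40.0

    def test_gotoh_oracle_agrees_with_enumeration(self):
        """Validate the DP oracle itself against explicit path enumeration."""
        rng = np.random.default_rng(5)
        for _ in range(40):
            a = random_seq(rng, int(rng.integers(1, 5)))
            b = random_seq(rng, int(rng.integers(1, 5)))
            assert gotoh_global(a, b, PARAMS) == pytest.approx(
                enumerate_global_score(a, b, PARAMS)
            )

    def test_matches_independent_dp_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(200):
            a = random_seq(rng, int(rng.integers(1, 9)))
            b = random_seq(rng, int(rng.integers(1, 9)))
            score, _ = nw_global_align(a, b, PARAMS)
            assert score == pytest.approx(gotoh_global(a, b, PARAMS))

    def test_alignment_strings_rescore_to_reported_score(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            a, b = random_seq(rng, 12), random_seq(rng, 10)
            score, (ga, gb) = nw_global_align(a, b, PARAMS)
            assert _score_gapped_pair(ga, gb, PARAMS) == pytest.approx(score)


def _score_gapped_pair(ga: str, gb: str, p: ScoreParams) -> float:
    score = 0.0
    run = None
    for x, y in zip(ga, gb):
        if x == "-" or y == "-":
            kind = "A" if x == "-" else "B"
            if run != kind:
                score += p.gap_open
                run = kind
            score += p.gap_extend
        else:
            score += p.score(x, y)
            run = None
    return score


class TestCsl:
    def test_perfect_reconstruction_is_zero(self):
        c = SeqRecord("c", "ACGTACGTAC")
        assert csl(c, c, PARAMS) == 0.0

    def test_single_substitution_arithmetic(self):
        cr = SeqRecord("r", "ACGTACGTAC")
        cp = SeqRecord("p", "ACGTACGTAA")  # C->A transversion at the end
        expected = (PARAMS.match - PARAMS.transversion) / self_score(cr, PARAMS)
        assert csl(cp, cr, PARAMS) == pytest.approx(expected)

    def test_score_loss_can_exceed_one(self):
        """A hopeless prediction aligns with negative score: >100% loss."""
        rng = np.random.default_rng(8)
        cr = "".join(rng.choice(list("AT"), size=50))
        comp = {"A": "C", "T": "G"}  # every aligned column is a transversion
        cp = "".join(comp[c] for c in cr)
        value = csl(SeqRecord("p", cp), SeqRecord("r", cr), PARAMS)
        assert value > 1.0

    def test_degenerate_reference_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            csl(SeqRecord("p", "ACGT"), SeqRecord("r", "NNNN"), PARAMS)
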