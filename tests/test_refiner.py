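import numpy as np
import pytest

from tebench import (
    ConsensusParams,
    FragmentationModel,
    Msa,
    ScoreParams,
    SeqRecord,
    SimConfig,
    TreeConfig,
    call_consensus,
    choose_centroid,
    csl,
    generate_dna_transposon_tree,
    local_align,
    pad_unaligned,
    refine,
    self_score,
    simulate,
    transitive_msa,
)
from test_msa_metrics import PARAMS, random_seq


def gotoh_local(a: str, b: str, p: ScoreParams) -> float:
    """Plain-Python affine-gap local DP (Smith–Waterman / Gotoh)."""
    n, m = len(a), len(b)
    NEG = -1e18
    best = 0.0
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    Ga = [[NEG] * (m + 1) for _ in range(n + 1)]
    Gb = [[NEG] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = p.score(a[i - 1], b[j - 1])
            M[i][j] = max(
                0.0,
                M[i - 1][j - 1] + s,
                Ga[i - 1][j - 1] + s,
                Gb[i - 1][j - 1] + s,
            )
            Ga[i][j] = max(
                M[i - 1][j] + p.gap_open + p.gap_extend, Ga[i - 1][j] + p.gap_extend
            )
            Gb[i][j] = max(
                M[i][j - 1] + p.gap_open + p.gap_extend, Gb[i][j - 1] + p.gap_extend
            )
            best = max(best, M[i][j])
    return best


class TestChooseCentroid:
    def test_identical_sequences_tie_break_first(self):
        seqs = [SeqRecord(f"s{i}", "ACGTACGTACGTACGT") for i in range(3)]
        assert choose_centroid(seqs).id == "s0"

    def test_full_length_seed_beats_fragments(self):
        rng = np.random.default_rng(0)
        full = random_seq(rng, 200)
        seqs = [
            SeqRecord("fragA", full[:80]),
            SeqRecord("full", full),
            SeqRecord("fragB", full[120:]),
        ]
        assert choose_centroid(seqs).id == "full"

    def test_matches_pairwise_score_matrix_oracle(self, small_family):
        seqs = small_family.extant
        params = ScoreParams()
        aligner = params.aligner("local")
        totals = []
        for i, a in enumerate(seqs):
            totals.append(
                sum(
                    float(aligner.score(a.seq, b.seq))
                    for j, b in enumerate(seqs)
                    if j != i
                )
            )
        chosen = choose_centroid(seqs, params)
        assert totals[seqs.index(chosen)] == max(totals)


class TestLocalAlign:
    def test_identical_query_full_length(self):
        rng = np.random.default_rng(1)
        t = SeqRecord("t", random_seq(rng, 300))
        out = local_align(SeqRecord("q", t.seq), t)
        assert len(out) == 1
        la = out[0]
        assert (la.t_start, la.t_end) == (0, 300)
        assert (la.q_start, la.q_end) == (0, 300)
        assert la.score == self_score(t)

    def test_planted_fragment_recovered(self):
        rng = np.random.default_rng(2)
        t = SeqRecord("t", random_seq(rng, 600))
        q = SeqRecord("q", t.seq[200:500])
        out = local_align(q, t)
        assert (out[0].t_start, out[0].t_end) == (200, 500)

    def test_scores_match_local_dp_oracle(self):
        rng = np.random.default_rng(3)
        checked = 0
        for _ in range(100):
            a = random_seq(rng, int(rng.integers(4, 11)))
            b = random_seq(rng, int(rng.integers(4, 11)))
            oracle = gotoh_local(a, b, PARAMS)
            out = local_align(
                SeqRecord("q", a), SeqRecord("t", b), PARAMS, min_score=1.0, min_segment=1
            )
            got = out[0].score if out else 0.0
            if oracle >= 1.0:
                assert got == pytest.approx(oracle)
                checked += 1
        assert checked > 50

    def test_unalignable_query_returns_empty(self):
        t = SeqRecord("t", "A" * 100)
        q = SeqRecord("q", "C" * 40)
        assert local_align(q, t) == []


class TestTransitiveMsa:
    def test_identical_queries_gap_free(self):
        rng = np.random.default_rng(4)
        t = SeqRecord("t", random_seq(rng, 100))
        queries = [SeqRecord("a", t.seq), SeqRecord("b", t.seq)]
        als = [la for q in queries for la in local_align(q, t)]
        tm = transitive_msa(als, t, queries)
        assert tm.msa.ncols == 100
        assert all("-" not in row for _, row in tm.msa.rows)

    def test_disjoint_fragments_occupy_disjoint_columns(self):
        rng = np.random.default_rng(5)
        t = SeqRecord("t", random_seq(rng, 400))
        queries = [SeqRecord("a", t.seq[0:150]), SeqRecord("b", t.seq[250:400])]
        als = [la for q in queries for la in local_align(q, t)]
        tm = transitive_msa(als, t, queries)
        row_a = tm.msa.row("a")
        row_b = tm.msa.row("b")
        a_cols = {i for i, ch in enumerate(row_a) if ch != "-"}
        b_cols = {i for i, ch in enumerate(row_b) if ch != "-"}
        assert a_cols and b_cols and not (a_cols & b_cols)
        assert max(a_cols) < min(b_cols)

    def test_insertion_creates_insertion_columns(self):
        rng = np.random.default_rng(6)
        t = SeqRecord("t", random_seq(rng, 120))
        with_ins = t.seq[:60] + "GG" + t.seq[60:]
        queries = [SeqRecord("plain", t.seq), SeqRecord("ins", with_ins)]
        als = [la for q in queries for la in local_align(q, t)]
        tm = transitive_msa(als, t, queries)
        ins_cols = [i for i, c in enumerate(tm.columns) if c[0] == "ins"]
        assert len(ins_cols) == 2
        row_plain = tm.msa.row("plain")
        assert all(row_plain[i] == "-" for i in ins_cols)
        row_ins = tm.msa.row("ins")
        assert "".join(row_ins[i] for i in ins_cols) == "GG"


class TestPadUnaligned:
    def test_noop_when_everything_aligned(self):
        rng = np.random.default_rng(7)
        t = SeqRecord("t", random_seq(rng, 80))
        queries = [SeqRecord("a", t.seq), SeqRecord("b", t.seq)]
        als = [la for q in queries for la in local_align(q, t)]
        tm = transitive_msa(als, t, queries)
        padded = pad_unaligned(tm, queries)
        assert padded == tm.msa

    def test_unaligned_prefix_gets_private_columns(self):
        rng = np.random.default_rng(8)
        t = SeqRecord("t", random_seq(rng, 100))
        tail = "TTTTT"
        queries = [SeqRecord("a", t.seq), SeqRecord("b", tail + t.seq)]
        als = [la for q in queries for la in local_align(q, t)]
        tm = transitive_msa(als, t, queries)
        padded = pad_unaligned(tm, queries)
        assert padded.ncols == tm.msa.ncols + 5
        row_b = padded.row("b")
        first_b = next(i for i, ch in enumerate(row_b) if ch != "-")
        assert row_b[first_b : first_b + 5] == tail
        # private: the other row is gapped across the pad columns
        row_a = padded.row("a")
        assert all(row_a[i] == "-" for i in range(first_b, first_b + 5))
        assert padded.ungapped("b") == tail + t.seq

    def test_roundtrip_on_fragmented_simulation(self, seed_1200, rate_matrix):
        tree = generate_dna_transposon_tree(TreeConfig(n_leaves=12, rng_seed=9))
        frag = FragmentationModel(mean_length=300.0)
        res = simulate(
            tree, seed_1200, rate_matrix,
            SimConfig(gput=1000, rng_seed=9, fragmentation=frag),
        )
        template = choose_centroid(res.extant)
        als = [la for q in res.extant for la in local_align(q, template)]
        tm = transitive_msa(als, template, res.extant)
        padded = pad_unaligned(tm, res.extant)  # raises if the invariant breaks
        for rec in res.extant:
            assert padded.ungapped(rec.id) == rec.seq


class TestCallConsensus:
    def test_unanimous_column(self):
        msa = Msa([("a", "AAA"), ("b", "AAA"), ("c", "AAA")])
        assert call_consensus(msa).seq == "AAA"

    def test_gap_majority_column_dropped(self):
        rows = [
            ("a", "CAT"), ("b", "CAT"),
            ("c", "C-T"), ("d", "C-T"), ("e", "C-T"),
        ]
        # middle column: 40% A vs 60% gap -> score(A)=2*10+3*(-25)<score(-)
        assert call_consensus(Msa(rows)).seq == "CT"

    def test_cpg_reassignment_from_mixed_products(self):
        # 12 CA, 6 TG, 2 CG: stage one calls "CA"; CA+TG = 90% of pairs
        rows = [("r%d" % i, "CA") for i in range(12)]
        rows += [("t%d" % i, "TG") for i in range(6)]
        rows += [("g%d" % i, "CG") for i in range(2)]
        assert call_consensus(Msa(rows)).seq == "CG"
        # disabled pass keeps the literal majority call
        assert call_consensus(Msa(rows), ConsensusParams(cpg_pass=False)).seq == "CA"

    def test_unanimous_ca_not_reassigned(self):
        rows = [("r%d" % i, "CA") for i in range(20)]
        # products never exceed the literal call's own count
        assert call_consensus(Msa(rows)).seq == "CA"

    def test_fragment_casts_no_votes_outside_extent(self):
        # the short row covers only the last 2 columns; 'G' wins column 0
        rows = [("a", "GAT"), ("b", "GAT"), ("frag", "-AT")]
        assert call_consensus(Msa(rows)).seq == "GAT"


class TestRefine:
    def test_fixed_point_on_identical_copies(self):
        rng = np.random.default_rng(10)
        base = random_seq(rng, 100)
        seqs = [SeqRecord(f"c{i}", base) for i in range(10)]
        state = refine(seqs)
        assert state.converged
        assert state.iteration <= 2
        assert state.consensus.seq == base

    def test_fixed_point_on_consensus_triplet(self, small_family):
        first = refine(small_family.extant)
        cons = first.consensus
        again = refine([SeqRecord(f"r{i}", cons.seq) for i in range(3)])
        assert again.consensus.seq == cons.seq
        assert again.converged

    def test_improves_over_centroid(self, small_family, seed_300):
        state = refine(small_family.extant)
        centroid = choose_centroid(small_family.extant)
        assert csl(state.consensus, seed_300) < csl(centroid, seed_300)

    def test_msa_rows_ungap_to_inputs(self, small_family):
        state = refine(small_family.extant)
        for rec in small_family.extant:
            assert state.msa.ungapped(rec.id) == rec.seq
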