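"""Protein similarity graphs, Markov clustering, progressive MSA and
profile compilation."""
from __future__ import annotations

import numpy as np
import pytest
from Bio import Align
from Bio.Align import substitution_matrices

from viresig.genome_io import ConfigurationError
from viresig.profiles import (
    AA,
    AA_INDEX,
    BACKGROUND,
    DegenerateProfileError,
    PPHMMDatabase,
    ProteinSeq,
    SimilarityGraph,
    align_cluster,
    build_pphmm_database,
    build_profile,
    markov_cluster,
    pairwise_similarity,
)


def _random_protein(rng, n):
    return "".join(rng.choice(list(AA), size=n))


def _proteins(seqs):
    return [ProteinSeq(f"p{i}", f"g{i}", s) for i, s in enumerate(seqs)]


class TestPairwiseSimilarity:
    def test_identical_pair_maximal(self, rng):
        s = _random_protein(rng, 120)
        for method in ("alignment_score", "kmer_sketch"):
            g = pairwise_similarity(_proteins([s, s]), method=method)
            assert g.weight("p0", "p1") == pytest.approx(1.0)

    def test_unrelated_pair_below_threshold(self, rng):
        a, b = _random_protein(rng, 200), _random_protein(rng, 200)
        g = pairwise_similarity(_proteins([a, b]))
        assert g.edges == {}
        # cross-check against a direct full-alignment computation
        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score, aligner.extend_gap_score = -11, -1
        norm = aligner.score(a, b) / min(aligner.score(a, a), aligner.score(b, b))
        assert norm < 0.25

    def test_symmetry_both_backends(self, rng):
        seqs = [_random_protein(rng, 80) for _ in range(4)]
        seqs.append(seqs[0][:60] + seqs[1][:20])  # ensure some edges
        for method in ("alignment_score", "kmer_sketch"):
            g = pairwise_similarity(_proteins(seqs), method=method, threshold=0.0)
            for (a, b), w in g.edges.items():
                assert g.weight(b, a) == w

    def test_sketch_determinism_with_seed(self, rng):
        seqs = [_random_protein(rng, 90) for _ in range(3)]
        g1 = pairwise_similarity(_proteins(seqs), method="kmer_sketch", threshold=0.0, seed=5)
        g2 = pairwise_similarity(_proteins(seqs), method="kmer_sketch", threshold=0.0, seed=5)
        assert g1.edges == g2.edges

    def test_unknown_method(self):
        with pytest.raises(ConfigurationError):
            pairwise_similarity(_proteins(["MKL"]), method="blast")


def _mcl_oracle(graph: SimilarityGraph, inflation=2.0):
    """Independent dense MCL run to strict idempotency; clusters from
    attractor rows (nonzero diagonal), overlaps merged."""
    nodes = sorted(graph.nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    M = np.zeros((n, n))
    for (a, b), w in graph.edges.items():
        M[idx[a], idx[b]] = M[idx[b], idx[a]] = w
    np.fill_diagonal(M, 1.0)
    M /= M.sum(axis=0)
    for _ in range(1000):
        new = np.linalg.matrix_power(M, 2) ** inflation
        new /= new.sum(axis=0)
        if np.allclose(new, M, atol=1e-12):
            break
        M = new
    clusters = []
    for i in range(n):
        if M[i, i] > 1e-8:  # attractor
            members = {nodes[j] for j in range(n) if M[i, j] > 1e-8}
            for c in clusters:
                if c & members:
                    c |= members
                    break
            else:
                clusters.append(members)
    return {frozenset(c) for c in clusters}


def _graph(edges, nodes=None):
    ns = sorted(nodes or {x for e in edges for x in e[:2]})
    return SimilarityGraph(
        nodes=ns,
        edges={tuple(sorted((a, b))): w for a, b, w in edges},
        method="alignment_score",
    )


class TestMarkovCluster:
    def test_two_disconnected_cliques(self):
        edges = [(a, b, 1.0) for a, b in (("a", "b"), ("b", "c"), ("a", "c"),
                                          ("x", "y"), ("y", "z"), ("x", "z"))]
        clusters = markov_cluster(_graph(edges))
        parts = sorted(frozenset(c.members) for c in clusters)
        assert parts == [frozenset("abc"), frozenset("xyz")]

    def test_isolated_node_is_singleton(self):
        g = _graph([("a", "b", 1.0)], nodes={"a", "b", "solo"})
        clusters = markov_cluster(g)
        assert frozenset(["solo"]) in {frozenset(c.members) for c in clusters}

    def test_path_graph_matches_oracle(self):
        g = _graph([("a", "b", 1.0), ("b", "c", 1.0), ("c", "d", 1.0)])
        got = {frozenset(c.members) for c in markov_cluster(g, inflation=2.0)}
        assert got == _mcl_oracle(g, inflation=2.0)

    def test_random_graphs_match_oracle(self, rng):
        for trial in range(10):
            n = int(rng.integers(3, 13))
            nodes = [f"n{i}" for i in range(n)]
            edges = []
            for i in range(n):
                for j in range(i + 1, n):
                    if rng.random() < 0.35:
                        edges.append((nodes[i], nodes[j], float(rng.uniform(0.3, 1.0))))
            g = _graph(edges, nodes=set(nodes))
            got = {frozenset(c.members) for c in markov_cluster(g)}
            assert got == _mcl_oracle(g), f"trial {trial}"

    def test_partition_property(self, rng):
        nodes = [f"n{i}" for i in range(8)]
        edges = [(nodes[i], nodes[j], 0.8) for i in range(8) for j in range(i + 1, 8)
                 if rng.random() < 0.4]
        clusters = markov_cluster(_graph(edges, nodes=set(nodes)))
        all_members = [m for c in clusters for m in c.members]
        assert sorted(all_members) == sorted(nodes)


def _nw_oracle(a, b, gap_open=11, gap_extend=1):
    """Hand Needleman-Wunsch (affine) on BLOSUM62, score only."""
    B = substitution_matrices.load("BLOSUM62")
    n, m = len(a), len(b)
    NEG = -1e9
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)
    Y = np.full((n + 1, m + 1), NEG)
    M[0, 0] = 0
    for i in range(1, n + 1):
        X[i, 0] = -gap_open - (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0, j] = -gap_open - (j - 1) * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + B[a[i - 1], b[j - 1]]
            X[i, j] = max(M[i - 1, j] - gap_open, X[i - 1, j] - gap_extend)
            Y[i, j] = max(M[i, j - 1] - gap_open, Y[i, j - 1] - gap_extend)
    return max(M[n, m], X[n, m], Y[n, m])


def _alignment_score(rows, gap_open=11, gap_extend=1):
    """Score a pairwise alignment (2 rows) under the stated scheme."""
    B = substitution_matrices.load("BLOSUM62")
    score = 0.0
    in_gap = None
    for ca, cb in zip(*rows):
        if ca != "-" and cb != "-":
            score += B[ca, cb]
            in_gap = None
        else:
            which = 0 if ca == "-" else 1
            score -= gap_extend if in_gap == which else gap_open
            in_gap = which
    return score


class TestAlignCluster:
    def test_single_sequence(self):
        assert align_cluster(["MKL"]) == ["MKL"]

    def test_identical_pair_gap_free(self):
        out = align_cluster(["MKLV", "MKLV"])
        assert out == ["MKLV", "MKLV"]

    def test_gap_placement_matches_nw_oracle(self):
        out = align_cluster(["ACD", "AD"])
        assert len(out[0]) == len(out[1]) == 3
        assert sum(c == "-" for c in out[1]) == 1
        assert _alignment_score(out) == _nw_oracle("ACD", "AD")

    def test_pairwise_scores_equal_oracle(self, rng):
        for _ in range(5):
            a = _random_protein(rng, int(rng.integers(20, 60)))
            # relative of a with a deletion and a few substitutions
            b = list(a[: int(rng.integers(10, len(a)))] + a[int(rng.integers(10, len(a))):])
            b = "".join(b)
            out = align_cluster([a, b])
            assert _alignment_score(out) == _nw_oracle(a, b)

    def test_all_rows_equal_length(self, rng):
        seqs = [_random_protein(rng, int(rng.integers(30, 60))) for _ in range(5)]
        out = align_cluster(seqs)
        assert len({len(r) for r in out}) == 1
        for orig, row in zip(seqs, out):
            assert row.replace("-", "") == orig


class TestBuildProfile:
    def test_pseudocount_formula(self):
        alpha = 0.1
        p = build_profile(["MA", "MA", "MA"], pseudocount=alpha)
        expected = (3 + alpha) / (3 + 20 * alpha)
        assert p.probs[0, AA_INDEX["M"]] == pytest.approx(expected)
        assert p.n_columns == 2

    def test_gap_majority_column_dropped(self):
        p = build_profile(["MA", "-A", "-A"])
        assert p.n_columns == 1  # first column is 2/3 gaps

    def test_columns_sum_to_one(self, rng):
        rows = ["".join(rng.choice(list(AA + "-"), size=12)) for _ in range(6)]
        try:
            p = build_profile(rows)
        except DegenerateProfileError:
            pytest.skip("random fixture degenerate")
        assert np.allclose(p.probs.sum(axis=1), 1.0)

    def test_row_order_invariance(self, rng):
        rows = ["MKL-", "MK-V", "MKLV", "M-LV"]
        p1 = build_profile(rows)
        p2 = build_profile(rows[::-1])
        assert np.allclose(p1.probs, p2.probs)

    def test_all_gap_columns_error(self):
        with pytest.raises(DegenerateProfileError):
            build_profile(["--", "--", "M-"])

    def test_identical_protein_scores_high(self, rng):
        s = _random_protein(rng, 150)
        p = build_profile(align_cluster([s, s, s]), pphmm_id="PP1")
        assert p.score(s) > 100  # bits: an exact member is unmistakable
        assert p.score(_random_protein(rng, 150)) < 15

    def test_database_json_roundtrip(self, tmp_path, rng):
        s = _random_protein(rng, 60)
        db = PPHMMDatabase([build_profile([s], pphmm_id="PP0001", members=["p0"])])
        path = tmp_path / "db.json"
        db.to_json(path)
        back = PPHMMDatabase.from_json(path)
        assert back.ids == ["PP0001"]
        assert np.allclose(back[0].probs, db[0].probs)
        assert back[0].score(s) == pytest.approx(db[0].score(s))


class TestEndToEndClustering:
    def test_planted_families_recovered(self, rng):
        """Proteins sampled with <=10% point mutations from disjoint seed
        families must produce exactly one cluster per family."""
        n_fam, per_fam = 4, 5
        seeds = [_random_protein(rng, 160) for _ in range(n_fam)]
        proteins = []
        for f, seed in enumerate(seeds):
            for k in range(per_fam):
                chars = list(seed)
                for i in np.flatnonzero(rng.random(len(chars)) < 0.1):
                    chars[i] = AA[rng.integers(0, 20)]
                proteins.append(ProteinSeq(f"f{f}k{k}", f"g{f}{k}", "".join(chars)))
        db, clusters = build_pphmm_database(proteins)
        assert len(clusters) == n_fam
        for c in clusters:
            fams = {m.split("k")[0] for m in c.members}
            assert len(fams) == 1
        assert len(db) == n_fam
        assert all(p.n_columns >= 1 for p in db)
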