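"""Generalized Jaccard, composite scores, groupings, Theil's U and MI."""
from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from viresig.annotate import HitLocation, SignatureTable
from viresig.classify import (
    bootstrap_support,
    build_dendrogram,
    build_similarity_matrix,
    composite_score,
    generalized_jaccard,
    pphmm_mutual_information,
    theils_u,
    virus_grouping,
)
from viresig.genome_io import ConfigurationError


class TestGeneralizedJaccard:
    def test_hand_example(self):
        assert generalized_jaccard([1, 2, 3], [2, 1, 3]) == pytest.approx(5 / 7)

    def test_identity(self):
        assert generalized_jaccard([0.5, 2.0], [0.5, 2.0]) == 1.0

    def test_double_zero_convention(self):
        assert generalized_jaccard([0, 0], [0, 0]) == 0.0

    def test_contract_errors(self):
        with pytest.raises(ValueError, match="length"):
            generalized_jaccard([1], [1, 2])
        with pytest.raises(ValueError, match="non-negative"):
            generalized_jaccard([-1, 2], [1, 2])

    @settings(deadline=None, max_examples=100)
    @given(
        st.lists(st.booleans(), min_size=1, max_size=20),
        st.lists(st.booleans(), min_size=1, max_size=20),
    )
    def test_binary_equals_classic_jaccard(self, a, b):
        n = min(len(a), len(b))
        a, b = a[:n], b[:n]
        av = np.array(a, dtype=float)
        bv = np.array(b, dtype=float)
        inter = sum(x and y for x, y in zip(a, b))
        union = sum(x or y for x, y in zip(a, b))
        expected = inter / union if union else 0.0
        assert generalized_jaccard(av, bv) == pytest.approx(expected)

    @settings(deadline=None, max_examples=50)
    @given(st.integers(0, 2**31 - 1))
    def test_range_and_symmetry(self, seed):
        r = np.random.default_rng(seed)
        a, b = r.random(8) * 5, r.random(8) * 5
        j = generalized_jaccard(a, b)
        assert 0.0 <= j <= 1.0
        assert j == generalized_jaccard(b, a)


class TestCompositeScore:
    @pytest.mark.parametrize(
        "jp,jg,expected", [(0.25, 0.04, 0.1), (1.0, 1.0, 1.0), (0.8, 0.0, 0.0)]
    )
    def test_examples(self, jp, jg, expected):
        assert composite_score(jp, jg) == pytest.approx(expected)

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            composite_score(1.2, 0.5)


def _sig(scores, genome_ids=None):
    scores = np.asarray(scores, dtype=float)
    g = genome_ids or [f"g{i}" for i in range(scores.shape[0])]
    p = [f"P{j}" for j in range(scores.shape[1])]
    locs = {}
    for i, gid in enumerate(g):
        for j, pid in enumerate(p):
            if scores[i, j] > 0:
                mid = 200 * (j + 1)
                locs[(gid, pid)] = HitLocation(mid - 100, mid + 100, "+", 0)
    return SignatureTable(g, p, scores, locs)


class TestSimilarityMatrix:
    def test_identical_signatures_cjs_one(self, small_run):
        sim, truth = small_run["sim"], small_run["truth"]
        fam = dict(zip(truth.genome_id, truth.family))
        ids = sim.genome_ids
        for i, a in enumerate(ids):
            for j, b in enumerate(ids):
                if fam[a] == fam[b]:  # rate 0: identical within family
                    assert sim.values[i, j] == 1.0
                else:  # disjoint repertoires
                    assert sim.values[i, j] == 0.0

    def test_matrix_matches_elementwise_oracle(self, small_run):
        sig, gsigs, sim = small_run["sig"], small_run["gsigs"], small_run["sim"]
        G = {g.genome_id: g.scores for g in gsigs}
        for i, a in enumerate(sig.genome_ids):
            for j, b in enumerate(sig.genome_ids):
                if i == j:
                    continue
                jp = generalized_jaccard(sig.scores[i], sig.scores[j])
                jg = generalized_jaccard(G[a], G[b])
                assert sim.values[i, j] == pytest.approx(composite_score(jp, jg), abs=1e-12)

    def test_pphmm_only_scheme(self):
        t = _sig([[1, 2, 0], [2, 1, 0]])
        sim = build_similarity_matrix(t, scheme="pphmm_only")
        assert sim.values[0, 1] == pytest.approx(generalized_jaccard([1, 2, 0], [2, 1, 0]))

    def test_shared_ratio_weighted_scheme(self):
        t = _sig([[1, 2, 0, 0], [1, 0, 3, 4]])
        sim = build_similarity_matrix(t, scheme="shared_ratio_weighted")
        jp = generalized_jaccard([1, 2, 0, 0], [1, 0, 3, 4])
        assert sim.values[0, 1] == pytest.approx(jp * 1 / 3)

    def test_unknown_scheme(self):
        with pytest.raises(ConfigurationError):
            build_similarity_matrix(_sig([[1.0]]), scheme="cosine")

    def test_cjs_needs_gsigs(self):
        with pytest.raises(ConfigurationError):
            build_similarity_matrix(_sig([[1.0]]), scheme="cjs")

    def test_symmetry_and_range(self, small_run):
        v = small_run["sim"].values
        assert np.allclose(v, v.T)
        assert (v >= 0).all() and (v <= 1).all()


class TestTheilsU:
    def test_perfect_prediction(self):
        assert theils_u(["A", "A", "B", "B"], [1, 1, 2, 2]) == pytest.approx(1.0)

    def test_contingency_examples(self):
        # {(A,x):2,(B,y):2} -> U=1 ; uniform 2x2 -> U=0
        assert theils_u(["A", "A", "B", "B"], ["x", "x", "y", "y"]) == pytest.approx(1.0)
        assert theils_u(["A", "A", "B", "B"], ["x", "y", "x", "y"]) == pytest.approx(0.0, abs=1e-12)

    def test_constant_reference_conventions(self):
        assert theils_u(["A", "A"], [1, 1]) == 1.0
        assert theils_u(["A", "A"], [1, 2]) == 0.0


class TestVirusGrouping:
    def test_perfect_recovery_u_one(self, small_run):
        sim, truth = small_run["sim"], small_run["truth"]
        tree = build_dendrogram(sim)
        ref = dict(zip(truth.genome_id, truth.family))
        grouping = virus_grouping(sim, tree, reference_labels=ref)
        groups = {}
        for gid, lab in grouping.labels.items():
            groups.setdefault(lab, set()).add(gid)
        expected = {}
        for gid, fam in ref.items():
            expected.setdefault(fam, set()).add(gid)
        assert set(map(frozenset, groups.values())) == set(map(frozenset, expected.values()))
        assert grouping.theils_u == pytest.approx(1.0)

    def test_explicit_threshold(self, small_run):
        sim = small_run["sim"]
        tree = build_dendrogram(sim)
        grouping = virus_grouping(sim, tree, threshold=1e-9)
        # cut below any merge: every genome with nonzero distance separates
        assert len(set(grouping.labels.values())) >= 2

    def test_requires_labels_or_threshold(self, small_run):
        sim = small_run["sim"]
        tree = build_dendrogram(sim)
        with pytest.raises(ConfigurationError):
            virus_grouping(sim, tree)


class TestMutualInformation:
    def _grouping(self, sim, tree, labels):
        from viresig.classify import Grouping

        return Grouping(labels=labels, threshold=0.5)

    def test_constant_column_zero(self):
        t = _sig([[1, 1], [1, 2], [1, 3], [1, 4]])
        from viresig.classify import Grouping

        g = Grouping(labels={f"g{i}": i % 2 for i in range(4)}, threshold=0.1)
        mi = dict(pphmm_mutual_information(t, g))
        assert mi["P0"] == 0.0

    def test_perfect_binary_split_ln2(self):
        scores = [[5, 1]] * 4 + [[0, 1]] * 4
        t = _sig(scores)
        from viresig.classify import Grouping

        g = Grouping(labels={f"g{i}": int(i < 4) for i in range(8)}, threshold=0.1)
        mi = dict(pphmm_mutual_information(t, g))
        assert mi["P0"] == pytest.approx(math.log(2))
        assert mi["P1"] == pytest.approx(0.0)

    def test_sorted_descending_and_nonnegative(self, rng):
        t = _sig((rng.random((10, 6)) < 0.5) * rng.random((10, 6)))
        from viresig.classify import Grouping

        g = Grouping(labels={f"g{i}": i % 3 for i in range(10)}, threshold=0.1)
        mi = pphmm_mutual_information(t, g)
        vals = [v for _, v in mi]
        assert vals == sorted(vals, reverse=True)
        assert all(v >= 0 for v in vals)

    def test_single_group_warns_zero(self):
        t = _sig([[1, 2], [3, 4]])
        from viresig.classify import Grouping

        g = Grouping(labels={"g0": 0, "g1": 0}, threshold=0.1)
        with pytest.warns(UserWarning, match="single"):
            mi = pphmm_mutual_information(t, g)
        assert all(v == 0.0 for _, v in mi)


class TestBootstrap:
    def test_duplicate_pairs_fully_supported(self, small_run):
        """Each genome duplicated: every duplicate-pair clade must have
        support 1.0 under both methods (present in every replicate)."""
        sig = small_run["sig"]
        ids = sig.genome_ids
        dup_ids = ids + [f"{g}+copy" for g in ids]
        scores = np.vstack([sig.scores, sig.scores])
        locs = dict(sig.locations)
        for g in ids:
            for p in sig.pphmm_ids:
                if (g, p) in sig.locations:
                    locs[(f"{g}+copy", p)] = sig.locations[(g, p)]
        dup = SignatureTable(dup_ids, list(sig.pphmm_ids), scores, locs)
        for method in ("consensus", "transfer"):
            tree = bootstrap_support(dup, n_boot=25, support_method=method, seed=3)
            for t, clade in enumerate(tree.clades()):
                if len(clade) == 2 and {x.split("+")[0] for x in clade} == {min(clade).split("+")[0]}:
                    assert tree.supports[t] == pytest.approx(1.0), (method, clade)

    def test_supports_within_unit_interval(self, small_run):
        tree = bootstrap_support(small_run["sig"], n_boot=10, seed=1)
        assert all(0.0 <= v <= 1.0 for v in tree.supports.values())

    def test_reproducible_given_seed(self, small_run):
        t1 = bootstrap_support(small_run["sig"], n_boot=8, seed=42)
        t2 = bootstrap_support(small_run["sig"], n_boot=8, seed=42)
        assert t1.supports == t2.supports

    def test_nboot_validation(self, small_run):
        with pytest.raises(ConfigurationError):
            bootstrap_support(small_run["sig"], n_boot=0)
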