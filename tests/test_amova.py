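"""AMOVA tests, including an independently coded direct-summation oracle."""

import numpy as np
import pytest

from polypopgen.amova import (
    amova_three_level,
    amova_two_level,
    pairwise_fst,
    slatkin_nm,
    squared_distances,
)
from polypopgen.genotypes import DominantMatrix


def make_dm(values, pops, missing=None):
    values = np.asarray(values, dtype=np.int8)
    n, B = values.shape
    return DominantMatrix(
        [f"i{k}" for k in range(n)],
        [("L", 100 + 2 * j) for j in range(B)],
        values,
        np.zeros((n, B), bool) if missing is None else missing,
        {f"i{k}": pops[k] for k in range(n)},
    )


# --- independent oracle: nested ANOVA by direct summation over vectors ------

def oracle_three_level(X, pops, clusters_of):
    """df, SS and variance components computed from centroid deviations of the
    raw vectors (valid for squared Euclidean distances), written without
    reference to the distance-based implementation."""
    X = np.asarray(X, float)
    pops = np.asarray(pops)
    clus = np.asarray([clusters_of[p] for p in pops])
    N = len(X)
    pop_list = list(dict.fromkeys(pops))
    clu_list = list(dict.fromkeys(clus))
    P, G = len(pop_list), len(clu_list)

    grand = X.mean(axis=0)
    ss_total = ((X - grand) ** 2).sum()
    ss_wp = sum(
        ((X[pops == p] - X[pops == p].mean(axis=0)) ** 2).sum() for p in pop_list
    )
    ss_wc = sum(
        ((X[clus == c] - X[clus == c].mean(axis=0)) ** 2).sum() for c in clu_list
    )
    ss_ap, ss_ac = ss_wc - ss_wp, ss_total - ss_wc
    df = (G - 1, P - G, N - P)

    n_p = {p: np.sum(pops == p) for p in pop_list}
    N_c = {c: np.sum(clus == c) for c in clu_list}
    sum_np2_by_c = {
        c: sum(n_p[p] ** 2 for p in pop_list if clusters_of[p] == c) for c in clu_list
    }
    n1 = (N - sum(sum_np2_by_c[c] / N_c[c] for c in clu_list)) / df[1]
    n2 = (sum(sum_np2_by_c[c] / N_c[c] for c in clu_list) - sum(v**2 for v in n_p.values()) / N) / df[0]
    n3 = (N - sum(v**2 for v in N_c.values()) / N) / df[0]

    sw = ss_wp / df[2]
    sb = (ss_ap / df[1] - sw) / n1
    sa = (ss_ac / df[0] - sw - n2 * sb) / n3
    return df, (ss_ac, ss_ap, ss_wp, ss_total), (sa, sb, sw)


class TestThreeLevel:
    def test_pure_cluster_divergence(self):
        """Identical individuals within clusters: 100% among clusters."""
        X = [[1, 0, 0]] * 4 + [[0, 1, 1]] * 4
        pops = ["A", "A", "B", "B", "C", "C", "D", "D"]
        res = amova_three_level(
            make_dm(X, pops),
            clusters={"A": "c1", "B": "c1", "C": "c2", "D": "c2"},
            permutations=0,
        )
        assert res.table.loc["within_pops", "percentage"] == pytest.approx(0.0, abs=1e-9)
        assert res.table.loc["among_clusters", "percentage"] == pytest.approx(100.0)

    def test_matches_oracle_on_hand_built_fixture(self):
        rng = np.random.default_rng(5)
        X = rng.integers(0, 2, size=(12, 7))
        pops = ["A"] * 3 + ["B"] * 3 + ["C"] * 3 + ["D"] * 3
        clusters = {"A": "c1", "B": "c1", "C": "c2", "D": "c2"}
        res = amova_three_level(make_dm(X, pops), clusters=clusters, permutations=0)
        df, sss, comps = oracle_three_level(X, pops, clusters)
        assert tuple(res.table["df"][:3]) == df
        assert res.table["SS"][:4].values == pytest.approx(sss, abs=1e-9)
        assert res.table["variance"][:3].values == pytest.approx(comps, abs=1e-9)

    @pytest.mark.parametrize("trial", range(5))
    def test_matches_oracle_on_random_unbalanced_fixtures(self, trial):
        rng = np.random.default_rng(100 + trial)
        sizes = rng.integers(2, 7, size=6)  # 6 pops, <=30 individuals
        pops = [f"P{j}" for j in range(6) for _ in range(sizes[j])]
        clusters = {f"P{j}": f"c{j % 3}" for j in range(6)}
        X = rng.integers(0, 2, size=(len(pops), 9))
        # ensure every band is observed somewhere
        X[0] = 1
        res = amova_three_level(make_dm(X, pops), clusters=clusters, permutations=0)
        df, sss, comps = oracle_three_level(X, pops, clusters)
        assert tuple(res.table["df"][:3]) == df
        assert res.table["SS"][:4].values == pytest.approx(sss, abs=1e-9)
        assert res.table["variance"][:3].values == pytest.approx(comps, abs=1e-9)

    def test_ss_additivity(self, rng):
        X = rng.integers(0, 2, size=(15, 6))
        X[0] = 1
        pops = ["A"] * 5 + ["B"] * 4 + ["C"] * 6
        res = amova_three_level(
            make_dm(X, pops),
            clusters={"A": "c1", "B": "c1", "C": "c2"},
            permutations=0,
        )
        s = res.table["SS"]
        assert s["among_clusters"] + s["among_pops_within_clusters"] + s["within_pops"] == pytest.approx(
            s["total"], abs=1e-9
        )

    def test_single_population_cluster_flagged(self, rng):
        X = rng.integers(0, 2, size=(9, 5))
        X[0] = 1
        pops = ["A"] * 3 + ["B"] * 3 + ["C"] * 3
        res = amova_three_level(
            make_dm(X, pops),
            clusters={"A": "c1", "B": "c2", "C": "c2"},
            permutations=0,
        )
        assert any("single population" in f for f in res.flags)

    def test_significance_on_structured_data(self):
        rng = np.random.default_rng(2)
        blocks = []
        for c in range(2):
            base = rng.integers(0, 2, size=12)
            for p in range(2):
                pb = np.clip(base + rng.integers(-1, 2, size=12), 0, 1)
                for _ in range(4):
                    ind = np.where(rng.random(12) < 0.15, rng.integers(0, 2, 12), pb)
                    blocks.append(ind)
        X = np.array(blocks)
        X[0] = 1
        pops = [f"P{c}{p}" for c in range(2) for p in range(2) for _ in range(4)]
        res = amova_three_level(
            make_dm(X, pops),
            clusters={"P00": "c0", "P01": "c0", "P10": "c1", "P11": "c1"},
            permutations=99,
            seed=1,
        )
        assert res.p_values["phi_st"] <= 0.05


class TestPairwiseFst:
    def test_disjoint_fixation_gives_one(self):
        X = [[1, 1, 0, 0]] * 4 + [[0, 0, 1, 1]] * 4
        pops = ["P"] * 4 + ["Q"] * 4
        res = pairwise_fst(make_dm(X, pops), permutations=0)
        assert res.fst.loc["P", "Q"] == pytest.approx(1.0)

    def test_identical_populations_zero_after_truncation(self):
        X = [[1, 0], [0, 1]] * 4
        pops = ["P", "P", "P", "P", "Q", "Q", "Q", "Q"]
        res = pairwise_fst(make_dm(X, pops), permutations=0)
        assert res.fst.loc["P", "Q"] == 0.0

    def test_pairwise_equals_two_level_oracle(self, rng):
        X = rng.integers(0, 2, size=(15, 8))
        X[0] = 1
        pops = ["A"] * 5 + ["B"] * 5 + ["C"] * 5
        res = pairwise_fst(make_dm(X, pops), permutations=0)
        for a, b in (("A", "B"), ("A", "C"), ("B", "C")):
            keep = [i for i, p in enumerate(pops) if p in (a, b)]
            sub_pops = [pops[i] for i in keep]
            # oracle via centroid sums of squares (two-level)
            Xs = X[keep].astype(float)
            labels = np.array(sub_pops)
            ss_total = ((Xs - Xs.mean(axis=0)) ** 2).sum()
            ss_w = sum(((Xs[labels == p] - Xs[labels == p].mean(axis=0)) ** 2).sum() for p in (a, b))
            N = len(keep)
            counts = np.array([np.sum(labels == p) for p in (a, b)], float)
            n_c = (N - (counts**2).sum() / N) / 1
            sw = ss_w / (N - 2)
            sa = ((ss_total - ss_w) / 1 - sw) / n_c
            expected = max(sa / (sa + sw), 0.0)
            assert res.fst.loc[a, b] == pytest.approx(expected, abs=1e-9)

    def test_singleton_population_skipped(self, rng):
        X = rng.integers(0, 2, size=(5, 4))
        X[0] = 1
        pops = ["A"] * 4 + ["B"]
        res = pairwise_fst(make_dm(X, pops), permutations=0)
        assert ("A", "B") in res.skipped
        assert np.isnan(res.fst.loc["A", "B"])


class TestSlatkin:
    def test_closed_form_values(self):
        assert slatkin_nm(0.2) == pytest.approx(1.0)
        assert slatkin_nm(0.5) == pytest.approx(0.25)
        assert slatkin_nm(0.2, form="haploid") == pytest.approx(2.0)

    def test_monotone_decreasing(self):
        fs = np.linspace(0.01, 0.99, 25)
        nms = [slatkin_nm(f) for f in fs]
        assert all(b < a for a, b in zip(nms, nms[1:]))

    def test_edge_cases(self):
        assert slatkin_nm(0.0) == 1e6  # capped
        assert slatkin_nm(1.0) == 0.0


class TestMissingData:
    def test_pairwise_deletion_rescaling(self):
        values = np.array([[1, 0, 1], [0, 1, 1]], dtype=np.int8)
        missing = np.array([[False, False, True], [False, False, False]])
        dm = make_dm(values, ["P", "Q"], missing)
        D2 = squared_distances(dm)
        # two shared bands differ in both -> raw 2, rescaled by 3/2
        assert D2[0, 1] == pytest.approx(3.0)
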