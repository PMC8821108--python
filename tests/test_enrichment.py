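import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

import hapattern as hp


def oracle_es(values, genes, set_genes, alpha):
    """Brute-force running-sum enrichment score for one sample.

    Walks the (value desc, gene asc) ordering position by position,
    accumulating the difference between the weighted in-set ECDF and the
    uniform out-of-set ECDF.
    """
    order = sorted(range(len(genes)), key=lambda i: (-values[i], genes[i]))
    G = len(genes)
    members = set(set_genes)
    m = sum(1 for g in genes if g in members)
    total_w = 0.0
    for pos, i in enumerate(order):
        if genes[i] in members:
            total_w += (G - pos) ** alpha
    es, cum_in, cum_out = 0.0, 0.0, 0.0
    for pos, i in enumerate(order):
        if genes[i] in members:
            cum_in += (G - pos) ** alpha / total_w
        else:
            cum_out += 1.0 / (G - m)
        es += cum_in - cum_out
    return es


class TestSsgsea:
    @pytest.mark.parametrize("alpha", [0.0, 0.25, 1.0])
    def test_matches_bruteforce_on_random_instances(self, alpha):
        rng = np.random.default_rng(int(alpha * 100))
        for _ in range(30):
            n_genes = rng.integers(8, 50)
            n_samples = rng.integers(1, 5)
            genes = [f"G{i:02d}" for i in range(n_genes)]
            mat = pd.DataFrame(rng.normal(size=(n_genes, n_samples)),
                               index=genes,
                               columns=[f"s{j}" for j in range(n_samples)])
            m = rng.integers(2, n_genes - 1)
            members = list(rng.choice(genes, size=m, replace=False))
            got = hp.ssgsea_score(mat, hp.GeneSet("gs", tuple(members)),
                                  alpha=alpha)
            for j, s in enumerate(mat.columns):
                exp = oracle_es(mat[s].to_numpy(), genes, members, alpha)
                assert abs(got[s] - exp) < 1e-10

    def test_top_ranked_set_attains_maximum(self):
        """With the set occupying the top ranks the score equals the
        maximum over all possible placements (enumerated by the oracle)."""
        genes = [f"G{i}" for i in range(10)]
        values = np.arange(10, 0, -1, dtype=float)
        top3 = genes[:3]
        mat = pd.DataFrame({"s": values}, index=genes)
        got = hp.ssgsea_score(mat, hp.GeneSet("top", tuple(top3)), alpha=0.0)["s"]
        best = max(oracle_es(values, genes, c, 0.0)
                   for c in itertools.combinations(genes, 3))
        assert math.isclose(got, best, abs_tol=1e-12)
        assert math.isclose(
            got, oracle_es(values, genes, top3, 0.0), abs_tol=1e-12)

    def test_rank_invariance_to_constant_shift(self, toy_expr):
        gs = hp.GeneSet("gs", ("G1", "G4", "G7"))
        base = hp.ssgsea_score(toy_expr, gs)
        shifted = toy_expr.copy()
        shifted["S2"] = shifted["S2"] + 100.0
        after = hp.ssgsea_score(shifted, gs)
        assert math.isclose(base["S2"], after["S2"], abs_tol=1e-12)

    def test_promoting_a_set_gene_never_decreases_es(self):
        rng = np.random.default_rng(8)
        genes = [f"G{i}" for i in range(12)]
        values = np.sort(rng.normal(size=12))[::-1].copy()
        members = ["G3", "G7", "G9"]
        for pos in range(1, 12):
            if genes[pos] in members and genes[pos - 1] not in members:
                swapped = values.copy()
                swapped[[pos - 1, pos]] = swapped[[pos, pos - 1]]
                mat = pd.DataFrame({"s": swapped}, index=genes)
                base = pd.DataFrame({"s": values}, index=genes)
                es_up = hp.ssgsea_score(mat, hp.GeneSet("m", tuple(members)),
                                        alpha=0.0)["s"]
                es_base = hp.ssgsea_score(base, hp.GeneSet("m", tuple(members)),
                                          alpha=0.0)["s"]
                assert es_up >= es_base - 1e-12

    def test_errors(self, toy_expr):
        with pytest.raises(ValueError, match="no gene"):
            hp.ssgsea_score(toy_expr, hp.GeneSet("none", ("ZZ",)))
        with pytest.raises(ValueError, match="every gene"):
            hp.ssgsea_score(toy_expr,
                            hp.GeneSet("all", tuple(toy_expr.index)))

    def test_transformer_interface(self, toy_expr):
        est = hp.SSGSEA(gene_sets={"a": ["G0", "G1"], "b": ["G5", "G6"]})
        out = est.fit_transform(toy_expr.T)
        assert out.shape == (6, 2)
        assert list(est.get_feature_names_out()) == ["a", "b"]


class TestNormalizeScores:
    def test_linear_rescale_and_idempotence(self):
        raw = pd.DataFrame([[2.0, 4.0, 6.0]], index=["gs"],
                           columns=list("abc"))
        out = hp.normalize_scores(raw)
        assert list(out.loc["gs"]) == [0.0, 0.5, 1.0]
        again = hp.normalize_scores(out)
        assert np.allclose(out.to_numpy(), again.to_numpy())

    def test_constant_row_warns_and_zeroes(self):
        raw = pd.DataFrame([[5.0, 5.0, 5.0]], index=["flat"],
                           columns=list("abc"))
        with pytest.warns(UserWarning, match="constant"):
            out = hp.normalize_scores(raw)
        assert (out.to_numpy() == 0).all()


class TestOraHypergeom:
    def test_closed_form_full_overlap(self):
        universe = [f"U{i}" for i in range(20)]
        gs = hp.GeneSet("s", tuple(universe[:5]))
        tab = hp.ora_hypergeom(universe[:5], [gs], universe)
        expected = 1.0 / math.comb(20, 5)
        assert math.isclose(tab.loc[0, "p"], expected, rel_tol=1e-9)

    def test_zero_overlap_and_exhaustive_draw(self):
        universe = [f"U{i}" for i in range(12)]
        gs = hp.GeneSet("s", tuple(universe[:4]))
        tab = hp.ora_hypergeom(universe[4:8], [gs], universe)
        assert tab.loc[0, "p"] == 1.0      # P(X >= 0) = 1
        tab2 = hp.ora_hypergeom(universe, [gs], universe)
        assert tab2.loc[0, "overlap"] == 4
        assert tab2.loc[0, "p"] == 1.0

    def test_matches_exact_combinatorial_sum_small_universes(self):
        rng = np.random.default_rng(4)
        for _ in range(25):
            M = int(rng.integers(5, 26))
            universe = [f"U{i}" for i in range(M)]
            K = int(rng.integers(1, M))
            N = int(rng.integers(1, M))
            gs = hp.GeneSet("s", tuple(rng.choice(universe, K, replace=False)))
            query = list(rng.choice(universe, N, replace=False))
            tab = hp.ora_hypergeom(query, [gs], universe)
            k = tab.loc[0, "overlap"]
            exact = sum(
                math.comb(K, j) * math.comb(M - K, N - j) / math.comb(M, N)
                for j in range(k, min(K, N) + 1))
            assert math.isclose(tab.loc[0, "p"], exact, rel_tol=1e-9)
            assert 0 < tab.loc[0, "p"] <= 1

    def test_query_outside_universe_dropped(self):
        universe = ["A", "B", "C", "D"]
        with pytest.warns(UserWarning, match="outside"):
            tab = hp.ora_hypergeom(["A", "Z"], [hp.GeneSet("s", ("A", "B"))],
                                   universe)
        assert tab.loc[0, "overlap"] == 1
        with pytest.raises(ValueError, match="empty"):
            hp.ora_hypergeom(["Z"], [hp.GeneSet("s", ("A",))], universe)
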