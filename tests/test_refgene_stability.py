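import itertools

import numpy as np
import pandas as pd
import pytest

from qpcrsig.refgene_stability import (
    AlgorithmError,
    bestkeeper_stats,
    comprehensive_ranking,
    delta_ct_stability,
    genorm_pairwise_variation,
    genorm_stability,
    normfinder_stability,
    ranking_correlation,
    relative_quantities,
)

from .conftest import make_table


TOY = pd.DataFrame(
    {
        "A": [20.0, 20.5, 21.0, 20.2],
        "B": [25.0, 25.8, 25.9, 25.1],
        "C": [30.0, 31.5, 30.2, 31.0],
    },
    index=["S1", "S2", "S3", "S4"],
)


class TestRelativeQuantities:
    def test_one_cycle_halving(self):
        q = relative_quantities(pd.DataFrame({"G": [20.0, 21.0, 22.0]}))
        assert list(q["G"]) == [1.0, 0.5, 0.25]

    def test_constant_column(self):
        q = relative_quantities(pd.DataFrame({"G": [25.0, 25.0, 25.0]}))
        assert (q["G"] == 1.0).all()

    def test_custom_efficiency(self):
        q = relative_quantities(pd.DataFrame({"G": [30.0, 31.0]}), efficiency=1.9)
        assert q["G"].iloc[0] == pytest.approx(1.0)
        assert q["G"].iloc[1] == pytest.approx(1 / 1.9)

    @pytest.mark.parametrize("eff", [1.0, 0.5, 2.5])
    def test_invalid_efficiency(self, eff):
        with pytest.raises(ValueError):
            relative_quantities(TOY, efficiency=eff)

    def test_range_invariant(self):
        q = relative_quantities(TOY)
        assert ((q > 0) & (q <= 1)).all().all()
        assert (q.max(axis=0) == 1.0).all()


def brute_force_m(ct: pd.DataFrame) -> pd.Series:
    """Oracle: M_j = mean over k != j of SD(log2 Q_j - log2 Q_k).

    With efficiency 2, log2 Q_j - log2 Q_k differs from Ct_k - Ct_j by a
    constant, so the SD can be computed straight from Ct differences.
    """
    out = {}
    for j in ct.columns:
        sds = []
        for k in ct.columns:
            if k != j:
                sds.append(np.std(ct[k] - ct[j], ddof=1))
        out[j] = np.mean(sds)
    return pd.Series(out)


class TestGenorm:
    def test_m_matches_brute_force(self):
        report = genorm_stability(relative_quantities(TOY))
        expected = brute_force_m(TOY)
        pd.testing.assert_series_equal(
            report.scores.sort_index(), expected.sort_index(),
            check_names=False, atol=1e-12,
        )

    def test_constant_offset_pair_has_zero_variation(self):
        # B == A + 5 exactly: the A/B log-ratio SD is 0, so M_A and M_B
        # reduce to half the SD against C alone
        ct = pd.DataFrame(
            {"A": TOY["A"], "B": TOY["A"] + 5.0, "C": TOY["C"]}
        )
        report = genorm_stability(relative_quantities(ct))
        sd_ac = np.std(ct["C"] - ct["A"], ddof=1)
        assert report.scores["A"] == pytest.approx(sd_ac / 2)
        assert report.scores["B"] == pytest.approx(sd_ac / 2)
        assert report.extras["final_pair"] == ("A", "B")

    def test_duplicated_gene_survives_to_final_pair(self, rng):
        ct = pd.DataFrame(
            rng.normal(25, 1, size=(8, 4)), columns=["A", "B", "C", "D"]
        )
        ct["Adup"] = ct["A"]
        report = genorm_stability(relative_quantities(ct))
        assert report.extras["final_pair"] == ("A", "Adup")
        assert report.ranks["A"] == report.ranks["Adup"] == 1.5

    def test_ranks_are_permutation(self):
        report = genorm_stability(relative_quantities(TOY))
        n = len(TOY.columns)
        assert report.ranks.sum() == n * (n + 1) / 2

    def test_needs_three_genes(self):
        with pytest.raises(AlgorithmError):
            genorm_stability(relative_quantities(TOY[["A", "B"]]))

    def test_pairwise_variation_series(self):
        ct = pd.DataFrame(np.random.default_rng(0).normal(25, 1, (10, 5)),
                          columns=list("ABCDE"))
        v = genorm_pairwise_variation(relative_quantities(ct))
        assert list(v.index) == ["V2/3", "V3/4", "V4/5"]
        assert (v >= 0).all()


def normfinder_oracle(x: np.ndarray, group_sizes: list[int]) -> np.ndarray:
    """Straight-line scalar implementation of the grouped estimator.

    x: genes x samples of log-quantities, samples ordered by group.
    """
    k = x.shape[0]
    G = len(group_sizes)
    starts = np.cumsum([0] + group_sizes)
    var = np.zeros((k, G))
    gmean = np.zeros((k, G))
    for g in range(G):
        xg = x[:, starts[g]: starts[g + 1]]
        n = group_sizes[g]
        z = np.zeros(k)
        for i in range(k):
            for j in range(n):
                r = (xg[i, j] - xg[i, :].mean() - xg[:, j].mean() + xg.mean())
                z[i] += r * r
            z[i] /= n - 1
        for i in range(k):
            var[i, g] = max(0.0, (z[i] - z.sum() / (k * (k - 1))) / (1 - 2 / k))
            gmean[i, g] = xg[i, :].mean()
    d = np.zeros((k, G))
    for i in range(k):
        for g in range(G):
            d[i, g] = gmean[i, g] - gmean[i, :].mean()
    for g in range(G):
        d[:, g] -= d[:, g].mean()
    samp = var / np.array(group_sizes)
    gamma2 = max(0.0, (d**2).sum() / ((k - 1) * (G - 1)) - samp.mean())
    stab = np.zeros(k)
    for i in range(k):
        acc = 0.0
        for g in range(G):
            dd = d[i, g] * gamma2 / (gamma2 + samp[i, g]) if (gamma2 + samp[i, g]) > 0 else 0.0
            acc += abs(dd) + np.sqrt(samp[i, g])
        stab[i] = acc / G
    return stab


class TestNormfinder:
    def _toy(self, rng):
        q = pd.DataFrame(
            2.0 ** -rng.normal(2, 0.5, size=(8, 3)), columns=["A", "B", "C"],
            index=[f"S{i}" for i in range(8)],
        )
        groups = pd.Series(["viral"] * 4 + ["bacterial"] * 4, index=q.index)
        return q, groups

    def test_matches_straight_line_oracle(self, rng):
        q, groups = self._toy(rng)
        report = normfinder_stability(q, groups=groups)
        expected = normfinder_oracle(np.log2(q.to_numpy()).T, [4, 4])
        np.testing.assert_allclose(report.scores.to_numpy(), expected, atol=1e-12)

    def test_zero_variance_gene_scores_zero(self):
        # noise patterns in B/C cancel in every per-sample and per-group mean
        noise = np.array([0.1, -0.1, 0.2, -0.2])
        q = pd.DataFrame(
            {
                "A": 2.0 ** -np.zeros(4),
                "B": 2.0 ** -(1.0 + noise),
                "C": 2.0 ** -(2.0 - noise),
            },
            index=["S1", "S2", "S3", "S4"],
        )
        groups = pd.Series(["viral", "viral", "bacterial", "bacterial"],
                           index=q.index)
        report = normfinder_stability(q, groups=groups)
        assert report.scores["A"] == 0.0
        assert (report.scores[["B", "C"]] > 0).all()
        assert report.ranks["A"] == 1.0

    def test_gene_level_offset_invariance(self, rng):
        q, groups = self._toy(rng)
        shifted = q.copy()
        shifted["A"] = shifted["A"] * 2.0 ** -3.1  # +3.1 on the Ct scale
        a = normfinder_stability(q, groups=groups)
        b = normfinder_stability(shifted, groups=groups)
        np.testing.assert_allclose(
            a.scores.to_numpy(), b.scores.to_numpy(), atol=1e-12
        )

    def test_ungrouped_variant(self, rng):
        q, _ = self._toy(rng)
        report = normfinder_stability(q, groups=None)
        assert not report.extras["grouped"]
        assert (report.scores >= 0).all()

    def test_single_sample_group_rejected(self, rng):
        q, _ = self._toy(rng)
        groups = pd.Series(["viral"] * 7 + ["bacterial"], index=q.index)
        with pytest.raises(AlgorithmError):
            normfinder_stability(q, groups=groups)


class TestBestkeeper:
    def test_constant_gene_ranks_first(self):
        ct = pd.DataFrame({"A": [25.0, 25.0, 25.0], "B": [30.0, 31.0, 29.0]})
        report = bestkeeper_stats(ct)
        assert report.scores["A"] == 0.0
        assert report.extras["descriptives"].loc["A", "cv_pct"] == 0.0
        assert report.ranks["A"] == 1.0

    def test_hand_computed_index_and_correlation(self):
        ct = pd.DataFrame({"A": [20.0, 21.0, 22.0], "B": [24.0, 26.0, 28.0]})
        report = bestkeeper_stats(ct)
        index = report.extras["index"]
        expected_index = [np.sqrt(20 * 24), np.sqrt(21 * 26), np.sqrt(22 * 28)]
        np.testing.assert_allclose(index.to_numpy(), expected_index, atol=1e-12)
        # MAD about the mean: A deviations (1, 0, 1) -> 2/3
        assert report.scores["A"] == pytest.approx(2.0 / 3.0)
        assert report.scores["B"] == pytest.approx(4.0 / 3.0)
        r = report.extras["index_correlation"]
        a = np.corrcoef(ct["A"], expected_index)[0, 1]
        assert r["A"] == pytest.approx(a, abs=1e-12)

    def test_engineered_sd_ladder_ordering(self, rng):
        # five genes scaled to exact sample SDs matching the reference ladder
        targets = {"PGK1": 0.843, "GUSB": 0.907, "TBP": 0.997,
                   "GAPDH": 1.200, "ACTB": 1.483}
        cols = {}
        for gene, sd in targets.items():
            x = rng.normal(0, 1, 30)
            x = (x - x.mean()) / x.std(ddof=1) * sd + 25.0
            cols[gene] = x
        report = bestkeeper_stats(pd.DataFrame(cols), sd_mode="sample")
        assert report.ordered_genes() == ["PGK1", "GUSB", "TBP", "GAPDH", "ACTB"]

    def test_nonpositive_ct_rejected(self):
        with pytest.raises(ValueError):
            bestkeeper_stats(pd.DataFrame({"A": [-1.0, 2.0], "B": [3.0, 4.0]}))


def brute_force_delta_ct(ct: pd.DataFrame) -> pd.Series:
    out = {}
    for j in ct.columns:
        sds = [np.std(ct[j] - ct[k], ddof=1) for k in ct.columns if k != j]
        out[j] = np.mean(sds)
    return pd.Series(out)


class TestDeltaCtMethod:
    def test_matches_brute_force(self):
        report = delta_ct_stability(TOY)
        expected = brute_force_delta_ct(TOY)
        pd.testing.assert_series_equal(
            report.scores.sort_index(), expected.sort_index(),
            check_names=False, atol=1e-12,
        )

    def test_duplicated_gene_lowers_scores(self, rng):
        base = pd.DataFrame(rng.normal(25, 1, size=(10, 3)),
                            columns=["A", "B", "C"])
        dup = base.copy()
        dup["D"] = dup["A"]
        uncorr = base.copy()
        uncorr["D"] = rng.normal(25, 1, 10)
        s_dup = delta_ct_stability(dup).scores
        s_unc = delta_ct_stability(uncorr).scores
        assert s_dup["A"] < s_unc["A"]
        assert s_dup["D"] < s_unc["D"]

    def test_global_sample_offset_invariance(self, rng):
        offsets = rng.normal(0, 2, size=len(TOY))
        shifted = TOY.add(offsets, axis=0)
        a = delta_ct_stability(TOY).scores
        b = delta_ct_stability(shifted).scores
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy(), atol=1e-10)


class TestComprehensive:
    def test_unanimous_first(self):
        ranks = [pd.Series({"A": 1, "B": 2, "C": 3})] * 4
        report = comprehensive_ranking(ranks)
        assert report.scores["A"] == pytest.approx(1.0)

    def test_unanimous_last_scores_five(self):
        genes = ["A", "B", "C", "D", "E"]
        ranks = [pd.Series(dict(zip(genes, [1, 2, 3, 4, 5])))] * 4
        report = comprehensive_ranking(ranks)
        assert report.scores["E"] == pytest.approx(5.0)
        assert report.ranks["E"] == 5.0

    def test_geometric_mean_closed_form(self):
        ranks = [pd.Series({"A": r, "B": 1, "C": 2}) for r in (1, 2, 4, 8)]
        report = comprehensive_ranking(ranks)
        assert report.scores["A"] == pytest.approx(64 ** 0.25)

    def test_score_bounded_by_rank_extremes(self, rng):
        genes = list("ABCDE")
        ranks = [
            pd.Series(rng.permutation([1, 2, 3, 4, 5]), index=genes)
            for _ in range(4)
        ]
        report = comprehensive_ranking(ranks)
        mat = pd.concat(ranks, axis=1)
        assert (report.scores >= mat.min(axis=1) - 1e-12).all()
        assert (report.scores <= mat.max(axis=1) + 1e-12).all()

    def test_mismatched_gene_sets_rejected(self):
        with pytest.raises(ValueError):
            comprehensive_ranking(
                [pd.Series({"A": 1, "B": 2}), pd.Series({"A": 1, "C": 2})]
            )


class TestRankingCorrelation:
    def test_self_correlation(self):
        v = pd.Series([1.0, 2.0, 3.0, 4.0, 5.0])
        r, r2 = ranking_correlation({"a": v, "b": v})
        assert r.loc["a", "b"] == pytest.approx(1.0)
        assert r2.loc["a", "b"] == pytest.approx(1.0)

    def test_reversal(self):
        v = pd.Series([1.0, 2.0, 3.0, 4.0, 5.0])
        r, _ = ranking_correlation({"a": v, "b": v[::-1].reset_index(drop=True)})
        assert r.loc["a", "b"] == pytest.approx(-1.0)

    def test_hand_computed_pearson(self):
        a = pd.Series([1.0, 2.0, 3.0, 4.0, 5.0])
        b = pd.Series([2.0, 1.0, 4.0, 3.0, 5.0])
        r, _ = ranking_correlation({"a": a, "b": b})
        expected = np.corrcoef(a, b)[0, 1]
        assert r.loc["a", "b"] == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_is_missing(self):
        r, _ = ranking_correlation(
            {"a": pd.Series([1.0, 1.0, 1.0]), "b": pd.Series([1.0, 2.0, 3.0])}
        )
        assert np.isnan(r.loc["a", "b"])


class TestPerGeneOffsetInvariance:
    """Per-gene additive Ct offsets must not change any method's ranking."""

    @pytest.fixture()
    def tables(self, rng):
        ct = pd.DataFrame(
            rng.normal(0, 1, size=(12, 4)) * np.array([0.5, 0.8, 1.2, 2.0])
            + 26.0,
            columns=["A", "B", "C", "D"],
            index=[f"S{i}" for i in range(12)],
        )
        groups = pd.Series(["viral"] * 4 + ["bacterial"] * 4 + ["control"] * 4,
                           index=ct.index)
        shifted = ct + pd.Series({"A": 2.0, "B": -1.5, "C": 0.7, "D": 3.0})
        return ct, shifted, groups

    def test_all_methods(self, tables):
        ct, shifted, groups = tables
        for fn in (
            lambda t: genorm_stability(relative_quantities(t)),
            lambda t: normfinder_stability(relative_quantities(t), groups=groups),
            lambda t: bestkeeper_stats(t),
            lambda t: delta_ct_stability(t),
        ):
            a, b = fn(ct), fn(shifted)
            pd.testing.assert_series_equal(a.ranks, b.ranks, atol=1e-9)
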