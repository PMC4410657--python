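"""Differential, survival and correlation screens against exact oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from nettracks.cohort import (
    CohortError,
    GeneStatsTable,
    GroupLabels,
    SurvivalData,
    bh_adjust,
    call_significant,
    correlate,
    cox_univariate,
    differential,
    survival_assoc,
)
from nettracks.tracks import CompositeTrack
from nettracks.synth import simulate_cohort, simulate_survival


def _track(mat, genes, samples, kind="continuous"):
    return CompositeTrack("t", pd.DataFrame(mat, index=genes, columns=samples),
                          kind=kind)


class TestBhAdjust:
    def test_worked_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04]
        )

    def test_all_equal(self):
        np.testing.assert_allclose(bh_adjust([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    def test_single(self):
        np.testing.assert_allclose(bh_adjust([0.37]), [0.37])

    def test_missing_preserved(self):
        q = bh_adjust([0.01, np.nan, 0.04])
        assert np.isnan(q[1])
        # family excludes the NaN: m = 2
        np.testing.assert_allclose(q[[0, 2]], [0.02, 0.04])

    def test_matches_brute_force_definition(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            m = int(rng.integers(1, 30))
            p = np.round(rng.random(m), 3)
            q = bh_adjust(p)
            order = np.argsort(p, kind="stable")
            for i_sorted, idx in enumerate(order):
                expected = min(
                    p[order[j]] * m / (j + 1) for j in range(i_sorted, m)
                )
                assert math.isclose(q[idx], min(expected, 1.0), rel_tol=1e-12)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(1)
        p = rng.random(100)
        np.testing.assert_allclose(
            bh_adjust(p), multipletests(p, method="fdr_bh")[1]
        )


class TestDifferential:
    def _two_group(self, g1, g2, n_genes=1, rng=None):
        n1, n2 = len(g1), len(g2)
        samples = [f"s{i}" for i in range(n1 + n2)]
        labels = GroupLabels(
            {s: ("a" if i < n1 else "b") for i, s in enumerate(samples)}
        )
        mat = np.array([list(g1) + list(g2)] * n_genes, dtype=float)
        return _track(mat, [f"g{i}" for i in range(n_genes)], samples), labels

    def test_label_swap_antisymmetry(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(size=12)
        samples = [f"s{i}" for i in range(12)]
        track = _track([vals], ["g"], samples)
        lab = {s: ("a" if i < 6 else "b") for i, s in enumerate(samples)}
        swapped = {s: ("b" if v == "a" else "a") for s, v in lab.items()}
        for method in ("t", "wilcoxon"):
            r1 = differential(track, GroupLabels(lab), method).table.loc["g"]
            r2 = differential(track, GroupLabels(swapped), method).table.loc["g"]
            assert math.isclose(r1["stat"], -r2["stat"], abs_tol=1e-12)
            assert math.isclose(r1["effect"], -r2["effect"], abs_tol=1e-12)
            assert math.isclose(r1["p"], r2["p"], rel_tol=1e-12)

    def test_wilcoxon_exact_small(self):
        # group1={1,2}, group2={3,4}: the most extreme of C(4,2)=6 rank
        # splits, two-sided p = 2/6.
        track, labels = self._two_group([1, 2], [3, 4])
        res = differential(track, labels, "wilcoxon")
        assert math.isclose(res.table.loc["g0", "p"], 2 / 6, rel_tol=1e-12)

    def test_wilcoxon_exact_matches_enumeration(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            n1, n2 = int(rng.integers(2, 6)), int(rng.integers(2, 6))
            vals = rng.permutation(np.arange(1.0, n1 + n2 + 1))  # no ties
            g1, g2 = vals[:n1], vals[n1:]
            track, labels = self._two_group(g1, g2)
            p_impl = differential(track, labels, "wilcoxon").table.loc["g0", "p"]
            # enumerate all C(n1+n2, n1) assignments of the pooled values
            pooled = np.concatenate([g1, g2])
            obs = abs(g2.sum() - n2 * (n1 + n2 + 1) / 2)
            count = total = 0
            for combo in itertools.combinations(range(n1 + n2), n2):
                s = abs(pooled[list(combo)].sum() - n2 * (n1 + n2 + 1) / 2)
                total += 1
                if s >= obs - 1e-9:
                    count += 1
            assert math.isclose(p_impl, count / total, rel_tol=1e-9)

    def test_degenerate_gene_missing_p(self):
        track, labels = self._two_group([5, 5, 5], [5, 5, 5])
        res = differential(track, labels, "t")
        assert np.isnan(res.table.loc["g0", "p"])

    def test_group_validation(self):
        track, _ = self._two_group([1, 2], [3, 4])
        with pytest.raises(CohortError):
            differential(track, GroupLabels({"s0": "a", "s1": "a",
                                             "s2": "a", "s3": "a"}))


class TestCox:
    def test_score_test_equals_hand_logrank(self):
        # Two groups of two, all events: hand-computed log-rank gives
        # U = -1.16667, V = 0.47222, chi2 = 2.882.
        x = np.array([0.0, 0.0, 1.0, 1.0])
        t = np.array([1.0, 2.0, 3.0, 4.0])
        e = np.array([1, 1, 1, 1])
        fit = cox_univariate(x, t, e)
        assert math.isclose(fit["score_chi2"], 1.16667**2 / 0.47222,
                            rel_tol=1e-4)

    def test_score_equals_logrank_random(self):
        # Cox score test at beta=0 with a binary covariate is the log-rank
        # test; lifelines provides the independent log-rank oracle.
        from lifelines.statistics import logrank_test

        rng = np.random.default_rng(4)
        for _ in range(10):
            n = 30
            x = rng.integers(0, 2, n).astype(float)
            if x.std() == 0:
                continue
            t = rng.exponential(1.0, n) + 0.01
            e = rng.integers(0, 2, n)
            if e.sum() < 2:
                continue
            fit = cox_univariate(x, t, e)
            lr = logrank_test(t[x == 0], t[x == 1], e[x == 0], e[x == 1])
            assert math.isclose(fit["score_chi2"], lr.test_statistic,
                                rel_tol=1e-6)

    def test_negation_antisymmetry(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=40)
        t = rng.exponential(np.exp(-0.5 * x))
        e = np.ones(40, dtype=int)
        f1, f2 = cox_univariate(x, t, e), cox_univariate(-x, t, e)
        assert math.isclose(f1["beta"], -f2["beta"], abs_tol=1e-8)
        assert math.isclose(f1["p"], f2["p"], rel_tol=1e-8)

    def test_matches_lifelines_tie_free(self):
        # On tie-free data Breslow, Efron and exact partial likelihoods
        # coincide, so lifelines is a full independent oracle.
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(6)
        x = rng.normal(size=60)
        t = rng.exponential(np.exp(-0.8 * x))
        e = (rng.random(60) < 0.8).astype(int)
        fit = cox_univariate(x, t, e)
        cph = CoxPHFitter().fit(
            pd.DataFrame({"T": t, "E": e, "x": x}),
            duration_col="T", event_col="E",
        )
        assert math.isclose(fit["beta"], cph.params_["x"], rel_tol=1e-5)
        assert math.isclose(fit["se"], cph.standard_errors_["x"], rel_tol=1e-4)

    def test_survival_assoc_constant_covariate_missing(self):
        samples = [f"s{i}" for i in range(12)]
        surv = SurvivalData(
            times={s: float(i + 1) for i, s in enumerate(samples)},
            events={s: 1 for s in samples},
        )
        track = _track([np.ones(12)], ["flat"], samples)
        res = survival_assoc(track, surv)
        assert np.isnan(res.table.loc["flat", "p"])

    def test_survival_assoc_no_events_error(self):
        samples = ["s0", "s1"]
        with pytest.raises(CohortError, match="event"):
            SurvivalData(times={s: 1.0 for s in samples},
                         events={s: 0 for s in samples})

    def test_beta_recovery(self):
        track, surv, truth = simulate_survival(
            n_genes=1, n_samples=400, n_prognostic=1, beta=0.8,
            censor_rate=0.2, seed=11,
        )
        res = survival_assoc(track, surv)
        assert abs(res.table.iloc[0]["effect"] - 0.8) < 0.2


class TestCorrelate:
    def _pair(self, x, y):
        samples = [f"s{i}" for i in range(len(x))]
        a = _track([x], ["g"], samples)
        b = _track([y], ["g"], samples)
        return a, b

    def test_identical_rows_rho_one(self):
        a, b = self._pair([1, 2, 3, 4, 5], [1, 2, 3, 4, 5])
        assert math.isclose(correlate(a, b).table.loc["g", "stat"], 1.0)

    def test_reversed_rho_minus_one(self):
        a, b = self._pair([1, 2, 3, 4, 5], [5, 4, 3, 2, 1])
        assert math.isclose(correlate(a, b).table.loc["g", "stat"], -1.0)

    def test_exact_permutation_small_n(self):
        a, b = self._pair([1, 2, 3, 4, 5], [1, 3, 2, 5, 4])
        row = correlate(a, b).table.loc["g"]
        assert math.isclose(row["stat"], 0.8, rel_tol=1e-12)
        # independent full enumeration over all 120 permutations
        x = np.array([1, 2, 3, 4, 5], dtype=float)
        obs = 0.8
        count = 0
        for perm in itertools.permutations([1, 3, 2, 5, 4]):
            d = x - np.array(perm)
            rho = 1 - 6 * (d**2).sum() / (5 * 24)
            if abs(rho) >= obs - 1e-12:
                count += 1
        assert math.isclose(row["p"], count / 120, rel_tol=1e-12)

    @pytest.mark.parametrize("n", [5, 6, 7])
    def test_permutation_p_matches_enumeration(self, n):
        rng = np.random.default_rng(n)
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        a, b = self._pair(x, y)
        row = correlate(a, b).table.loc["g"]
        from scipy.stats import rankdata

        xr, yr = rankdata(x), rankdata(y)
        def rho_of(u, v):
            u, v = u - u.mean(), v - v.mean()
            return float(u @ v / math.sqrt((u @ u) * (v @ v)))
        obs = rho_of(xr, yr)
        vals = [rho_of(xr, np.array(p)) for p in itertools.permutations(yr)]
        p_exact = np.mean([abs(v) >= abs(obs) - 1e-12 for v in vals])
        assert math.isclose(row["p"], p_exact, rel_tol=1e-12)

    def test_per_sample_vector(self):
        samples = [f"s{i}" for i in range(12)]
        rng = np.random.default_rng(8)
        mat = rng.normal(size=(3, 12))
        a = _track(mat, ["g0", "g1", "g2"], samples)
        drug = pd.Series(mat[1] + rng.normal(0, 0.01, 12), index=samples)
        res = correlate(a, drug)
        assert res.table.loc["g1", "stat"] > 0.9

    def test_no_shared_samples_error(self):
        a = _track([[1, 2, 3, 4, 5]], ["g"], list("abcde"))
        b = _track([[1, 2, 3, 4, 5]], ["g"], list("vwxyz"))
        with pytest.raises(CohortError):
            correlate(a, b)


class TestCallSignificant:
    def _stats(self, rows):
        df = pd.DataFrame(rows, columns=["stat", "effect", "p", "fdr", "n_used"])
        df.index = [f"g{i}" for i in range(len(rows))]
        return GeneStatsTable(df)

    def test_fdr_and_fold_thresholds(self):
        stats = self._stats([[3.0, 1.4, 0.001, 0.005, 20]])
        assert call_significant(stats, 0.01, 2.0).genes == {"g0"}

    def test_fdr_only(self):
        stats = self._stats([[3.0, 0.1, 0.001, 0.005, 20]])
        assert call_significant(stats, 0.01, None).genes == {"g0"}
        assert call_significant(stats, 0.01, 2.0).genes == set()

    def test_direction_up_excludes_negative(self):
        stats = self._stats([[-4.0, -2.0, 1e-6, 1e-5, 20]])
        assert call_significant(stats, 0.01, None, "up").genes == set()
        assert call_significant(stats, 0.01, None, "down").genes == {"g0"}

    def test_round_trip_tsv(self, tmp_path):
        stats = self._stats([[1.5, 0.7, 0.04, 0.08, 18],
                             [np.nan, np.nan, np.nan, np.nan, 3]])
        p = tmp_path / "stats.tsv"
        stats.write_tsv(p)
        back = GeneStatsTable.read_tsv(p)
        pd.testing.assert_frame_equal(
            stats.table.astype(float), back.table.astype(float)
        )


class TestCalibration:
    def test_null_type_i_error(self):
        track, labels, _ = simulate_cohort(
            n_genes=600, n_group1=20, n_group2=20, n_de=0, effect_sd=0.0,
            seed=21,
        )
        for method in ("t", "wilcoxon"):
            res = differential(track, labels, method)
            frac = float((res.table["p"] < 0.05).mean())
            assert 0.03 <= frac <= 0.07, (method, frac)

    def test_planted_recall_and_fdp(self):
        track, labels, truth = simulate_cohort(
            n_genes=1000, n_group1=30, n_group2=30, n_de=50, effect_sd=2.0,
            seed=22,
        )
        res = differential(track, labels, "t")
        called = call_significant(res, fdr_max=0.01).genes
        planted = truth.effect_genes
        recall = len(called & planted) / len(planted)
        fdp = len(called - planted) / max(len(called), 1)
        assert recall >= 0.9
        assert fdp <= 0.05
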