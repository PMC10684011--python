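"""The statistical engine against independent oracles.

Cluster permutation is checked against full sign-flip enumeration with a
separately coded clustering routine; the Wilcoxon distribution against
scipy and direct enumeration; the repeated-measures ANOVA against both a
hand-computed sums-of-squares table and pingouin; the single-participant
LME reduction against closed-form OLS.
"""

import itertools

import numpy as np
import pytest
from scipy import stats as st

from cardiomotor import stats
from cardiomotor.exceptions import CardioMotorError, ParameterError
from cardiomotor.stats import (
    Adjacency,
    binned_mep_profile,
    cluster_perm_test,
    cohens_d_paired,
    lme_distance_models,
    montage_adjacency,
    paired_t_power,
    power_n_paired,
    rm_anova_2way,
    wilcoxon_signed_rank,
)


# ---------------------------------------------------------------------------
# independent cluster-mass oracle (1-D chain along the last axis, optional
# channel adjacency): used to cross-check the implementation
# ---------------------------------------------------------------------------

def _oracle_masses(diff, thresh, adj=None):
    n = diff.shape[0]
    t = diff.mean(0) / (diff.std(0, ddof=1) / np.sqrt(n))
    masses = []
    for sign in (1, -1):
        supra = (sign * t) > thresh
        seen = np.zeros_like(supra)
        for idx in np.argwhere(supra):
            idx = tuple(idx)
            if seen[idx]:
                continue
            stack, members = [idx], []
            seen[idx] = True
            while stack:
                node = stack.pop()
                members.append(node)
                s, ti = node
                for nb in [(s, ti - 1), (s, ti + 1)]:
                    if 0 <= nb[1] < t.shape[1] and supra[nb] and not seen[nb]:
                        seen[nb] = True
                        stack.append(nb)
                if adj is not None:
                    for s2 in np.flatnonzero(adj[s]):
                        nb = (s2, ti)
                        if supra[nb] and not seen[nb]:
                            seen[nb] = True
                            stack.append(nb)
            masses.append(sum(t[m] for m in members))
    return masses


def _oracle_pvalues(diff, adj=None, alpha=0.05):
    n = diff.shape[0]
    thresh = st.t.ppf(1 - alpha / 2, n - 1)
    obs = _oracle_masses(diff, thresh, adj)
    null = []
    for signs in itertools.product((1.0, -1.0), repeat=n):
        m = _oracle_masses(diff * np.array(signs)[:, None, None], thresh, adj)
        null.append(max((abs(v) for v in m), default=0.0))
    null = np.array(null)
    return sorted((abs(m), float(np.mean(null >= abs(m)))) for m in obs)


class TestClusterPermutation:
    def test_identical_conditions_give_empty_result(self):
        a = np.random.default_rng(0).normal(size=(6, 2, 5))
        res = cluster_perm_test(a, a.copy())
        assert res.clusters == []
        assert not res.mask.any()

    @pytest.mark.parametrize("n,shape,seed", [
        (5, (1, 4), 1), (8, (2, 6), 2), (10, (3, 4), 3), (12, (1, 8), 4),
    ])
    def test_matches_exhaustive_enumeration(self, n, shape, seed):
        rng = np.random.default_rng(seed)
        diff = rng.normal(1.0, 1.0, size=(n,) + shape)
        adj = np.zeros((shape[0], shape[0]), dtype=bool)
        for i in range(shape[0] - 1):  # chain of channels
            adj[i, i + 1] = adj[i + 1, i] = True
        res = cluster_perm_test(diff, np.zeros_like(diff), adjacency=adj)
        assert res.method == "exact"
        got = sorted((abs(c.mass), c.p) for c in res.clusters)
        expect = _oracle_pvalues(diff, adj)
        assert len(got) == len(expect)
        for (m1, p1), (m2, p2) in zip(got, expect):
            assert m1 == pytest.approx(m2, rel=1e-9)
            assert p1 == pytest.approx(p2, abs=1e-12)

    def test_montecarlo_p_is_plus_one_corrected(self):
        rng = np.random.default_rng(5)
        diff = rng.normal(2.0, 1.0, size=(14, 1, 4))
        res = cluster_perm_test(diff, np.zeros_like(diff), n_perm=200,
                                seed=3, max_exhaustive=2)
        assert res.method == "montecarlo"
        for c in res.clusters:
            assert c.p >= 1 / 201

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ParameterError):
            cluster_perm_test(np.zeros((4, 2, 3)), np.zeros((4, 2, 4)))

    def test_familywise_error_calibrated(self):
        # null Gaussian data: the probability of any significant cluster
        # should match the nominal two-tailed 5 % level.  With exhaustive
        # enumeration over 2^10 sign patterns the attainable p values are
        # even multiples of 1/1024, so the exact null rejection probability
        # is P(p < 0.05) = 48/1024.
        rng = np.random.default_rng(99)
        n_datasets, n_subj = 500, 10
        adj = np.array([[False, True], [True, False]])
        hits = 0
        for _ in range(n_datasets):
            diff = rng.standard_normal((n_subj, 2, 6))
            res = cluster_perm_test(diff, np.zeros_like(diff), adjacency=adj)
            hits += bool(res.significant)
        p0 = 48 / 1024
        lo = st.binom.ppf(0.005, n_datasets, p0) / n_datasets
        hi = st.binom.ppf(0.995, n_datasets, p0) / n_datasets
        assert lo <= hits / n_datasets <= hi


class TestWilcoxon:
    def test_all_positive_three(self):
        res = wilcoxon_signed_rank(np.array([1.0, 2.0, 3.0]))
        assert res.V == 6.0
        assert res.p == pytest.approx(0.25)

    def test_one_negative_smallest(self):
        res = wilcoxon_signed_rank(np.array([-0.5, 2.0, 3.0]))
        assert res.V == 5.0

    def test_all_zero_rejected(self):
        with pytest.raises(CardioMotorError):
            wilcoxon_signed_rank(np.zeros(5))

    def test_exact_distribution_sums_to_one(self):
        # enumerate all sign patterns for n <= 12 and compare tail masses
        rng = np.random.default_rng(1)
        d = rng.normal(0.5, 1.0, size=10)
        ranks = st.rankdata(np.abs(d))
        vs = []
        for signs in itertools.product((1, -1), repeat=10):
            vs.append(ranks[np.array(signs) > 0].sum())
        vs = np.array(vs)
        res = wilcoxon_signed_rank(d)
        p_enum = min(1.0, 2 * min(np.mean(vs <= res.V), np.mean(vs >= res.V)))
        assert res.p == pytest.approx(p_enum, abs=1e-12)

    def test_matches_scipy_exact(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            d = rng.normal(0.3, 1.0, size=15)
            mine = wilcoxon_signed_rank(d)
            ref = st.wilcoxon(d, method="exact")
            assert mine.p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_null_p_uniform(self):
        rng = np.random.default_rng(3)
        ps = [wilcoxon_signed_rank(rng.standard_normal(36)).p
              for _ in range(300)]
        ks = st.kstest(ps, "uniform")
        assert ks.pvalue > 0.01


class TestRmAnova:
    def test_all_cells_equal_flat(self):
        res = rm_anova_2way(np.full((5, 3, 2), 4.0))
        assert res["time"]["F"] == 0.0
        assert res["time"]["flat"]

    def test_hand_computed_table(self):
        # 4 subjects x 3 x 2, hand-verifiable sums of squares
        x = np.array([
            [[3.0, 4.0], [5.0, 6.0], [7.0, 8.0]],
            [[2.0, 3.0], [4.0, 5.0], [6.0, 7.0]],
            [[4.0, 5.0], [6.0, 8.0], [8.0, 9.0]],
            [[3.0, 3.0], [5.0, 6.0], [7.0, 8.0]],
        ])
        res = rm_anova_2way(x)
        # independent oracle via pingouin
        import pandas as pd
        import pingouin as pg
        df = pd.DataFrame([
            {"s": s, "time": a, "phase": b, "y": x[s, a, b]}
            for s in range(4) for a in range(3) for b in range(2)])
        ref = pg.rm_anova(dv="y", within=["time", "phase"], subject="s",
                          data=df, detailed=True, effsize="ng2")
        for name, row in (("time", 0), ("phase", 1), ("time:phase", 2)):
            assert res[name]["F"] == pytest.approx(ref.loc[row, "F"], rel=1e-6)
            assert res[name]["ges"] == pytest.approx(ref.loc[row, "ng2"],
                                                     rel=1e-6)

    def test_two_level_factor_never_corrected(self):
        rng = np.random.default_rng(4)
        res = rm_anova_2way(rng.normal(size=(8, 3, 2)))
        assert res["phase"]["epsilon"] == 1.0
        assert not res["phase"]["gg_applied"]

    def test_gg_correction_reduces_df_when_sphericity_violated(self):
        # heavily correlated pair of levels forces a Mauchly violation
        rng = np.random.default_rng(8)
        n = 25
        base = rng.standard_normal((n, 1))
        lvl1 = base + 0.01 * rng.standard_normal((n, 1))
        lvl2 = base + 0.01 * rng.standard_normal((n, 1))
        lvl3 = rng.standard_normal((n, 1)) * 3
        x = np.stack([np.concatenate([lvl1, lvl2, lvl3], axis=1)] * 2,
                     axis=2)
        x = x + 0.001 * rng.standard_normal(x.shape)
        res = rm_anova_2way(x)
        assert res["time"]["mauchly_p"] < 0.05
        assert res["time"]["gg_applied"]
        assert res["time"]["df1"] < 2.0


class TestLme:
    def test_single_participant_matches_ols_lrt(self):
        rng = np.random.default_rng(6)
        n = 80
        dist = rng.uniform(10, 900, n)
        y = 6.0 - 0.0004 * dist + 0.4 * rng.standard_normal(n)
        cmp_ = lme_distance_models(np.exp(y), dist, np.zeros(n, dtype=int))
        # closed-form nested OLS LRT: chi2 = n * ln(RSS0 / RSS1)
        X0 = np.ones((n, 1))
        X1 = np.column_stack([np.ones(n), dist / 1000.0])
        rss0 = np.sum((y - X0 @ np.linalg.lstsq(X0, y, rcond=None)[0]) ** 2)
        rss1 = np.sum((y - X1 @ np.linalg.lstsq(X1, y, rcond=None)[0]) ** 2)
        chi2_ref = n * np.log(rss0 / rss1)
        assert cmp_.lrt["linear_vs_null"][0] == pytest.approx(chi2_ref,
                                                              rel=1e-8)

    def test_positive_amplitudes_required(self):
        with pytest.raises(ParameterError):
            lme_distance_models(np.array([-1.0, 2.0]), np.array([1.0, 2.0]),
                                np.array([0, 0]))

    def test_linear_effect_detected_quadratic_not(self):
        rng = np.random.default_rng(7)
        n_p, n_t = 10, 60
        pid = np.repeat(np.arange(n_p), n_t)
        dist = rng.uniform(10, 900, n_p * n_t)
        y = (np.log(500) - 4e-4 * dist + 0.3 * rng.standard_normal(n_p)[pid]
             + 0.5 * rng.standard_normal(n_p * n_t))
        cmp_ = lme_distance_models(np.exp(y), dist, pid)
        assert cmp_.lrt["linear_vs_null"][2] < 0.01
        assert cmp_.lrt["quadratic_vs_linear"][2] > 0.05


class TestPowerAndEffectSize:
    def test_reported_sample_size_at_small_effect(self):
        assert power_n_paired(0.48, 0.8, 0.05) == 36

    def test_ceil_convention_guarantees_power(self):
        n = power_n_paired(0.48, 0.8, 0.05, rounding="ceil")
        assert paired_t_power(n, 0.48) >= 0.8 > paired_t_power(n - 1, 0.48)

    def test_monotone_in_effect_and_power(self):
        ns = [power_n_paired(d) for d in (0.2, 0.4, 0.8, 1.6, 3.0)]
        assert ns == sorted(ns, reverse=True)
        np_ = [power_n_paired(0.5, power=p) for p in (0.5, 0.8, 0.95)]
        assert np_ == sorted(np_)

    def test_invalid_effect_rejected(self):
        with pytest.raises(ParameterError):
            power_n_paired(-1.0)

    def test_cohens_d_degenerate_cases(self):
        assert cohens_d_paired(np.array([1.0, -1.0])) == 0.0
        assert np.isinf(cohens_d_paired(np.array([2.0, 2.0])))
        with pytest.raises(ParameterError):
            cohens_d_paired(np.array([1.0]))


class TestProfileAndAdjacency:
    def test_binned_profile_means(self):
        amp = np.array([10.0, 20.0, 30.0, 40.0])
        dist = np.array([10.0, 40.0, 60.0, 90.0])
        prof = binned_mep_profile(amp, dist, width_ms=50.0, max_ms=100.0)
        np.testing.assert_allclose(prof["mean_uv"], [15.0, 35.0])
        np.testing.assert_allclose(prof["count"], [2, 2])

    def test_profile_monotone_for_declining_generator(self, session_effects):
        truth = session_effects["truth"]
        ev = truth.events_for("tms")
        amp = np.array([e["mep_uv"] for e in ev if e["distance_ms"] is not None])
        dist = np.array([e["distance_ms"] for e in ev
                         if e["distance_ms"] is not None])
        prof = binned_mep_profile(amp, dist, width_ms=150.0, max_ms=750.0)
        ok = np.isfinite(prof["mean_uv"])
        sl = np.polyfit(prof["center_ms"][ok], np.log(prof["mean_uv"][ok]), 1)[0]
        assert sl < 0

    def test_montage_adjacency_symmetric_no_self_edges(self):
        adj = montage_adjacency(["C4", "CP4", "C6", "CP6", "Cz"])
        for a, nbrs in adj.neighbors.items():
            assert a not in nbrs
            for b in nbrs:
                assert a in adj.neighbors[b]
        assert "CP4" in adj.neighbors["C4"]
        assert "Cz" not in adj.neighbors["C6"]

    def test_adjacency_rejects_asymmetry(self):
        with pytest.raises(ParameterError):
            Adjacency(["a", "b"], {"a": {"b"}, "b": set()})
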