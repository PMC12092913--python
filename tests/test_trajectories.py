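"""Polarization, slope fits, fixation scoring, and the folded SFS."""

import numpy as np
import pytest
from scipy import stats

from lousescan import trajectories as traj
from lousescan.trajectories import (TrajectorySeries, compare_slopes_tukey,
                                    cumulative_fixations, fit_slope_glm,
                                    fit_slope_ols, folded_sfs,
                                    greatest_change_interval, polarize,
                                    score_fixation)


def series(gens, counts, totals, **kw):
    return TrajectorySeries("s", "p", np.array(gens, float),
                            np.array(counts), np.array(totals), **kw)


class TestPolarize:
    def test_tracks_allele_more_common_in_experimental(self):
        assert polarize(0.8, 0.3) == "alt"
        assert polarize(0.2, 0.6) == "ref"

    def test_tie_breaks_toward_alt(self):
        assert polarize(0.5, 0.5) == "alt"

    def test_missing_reference_data_rejected(self):
        with pytest.raises(ValueError):
            polarize(np.nan, 0.5)

    def test_polarized_selected_sites_have_positive_mean_slope(self, small_sim):
        """With the tracked allele chosen at the final reference point,
        selected-site trajectories in selected populations slope upward."""
        sel = small_sim.truth.selected_indices
        slopes = []
        gens = np.arange(46, dtype=float)
        for pop in small_sim.design.populations:
            if not pop.under_selection:
                continue
            t = small_sim.trajectories[pop.pop_id][:46]
            ctrl = small_sim.trajectories[f"gray_{pop.preening}_{pop.pop_id.split('_')[-1]}"][:46]
            for i in sel:
                pol = polarize(t[-1, i], ctrl[-1, i])
                y = t[:, i] if pol == "alt" else 1 - t[:, i]
                slopes.append(np.polyfit(gens, y, 1)[0])
        assert np.mean(slopes) > 0.005


class TestOlsSlope:
    def test_constant_series_zero_slope(self):
        fit = fit_slope_ols(series([0, 10, 20], [5, 5, 5], [10, 10, 10]))
        assert fit.slope == 0.0

    def test_hand_normal_equations(self):
        # 0.2, 0.4, 0.6 at generations 0, 10, 20 -> slope 0.02/gen
        fit = fit_slope_ols(series([0, 10, 20], [2, 4, 6], [10, 10, 10]))
        assert fit.slope == pytest.approx(0.02)
        assert fit.intercept == pytest.approx(0.2)

    def test_fewer_than_two_points_rejected(self):
        with pytest.raises(ValueError):
            fit_slope_ols(series([0.0], [1], [10]))

    def test_zero_depth_timepoints_dropped_not_imputed(self):
        fit = fit_slope_ols(series([0, 10, 20], [2, 0, 6], [10, 0, 10]))
        assert fit.slope == pytest.approx(0.02)


def grid_glm_oracle(gens, counts, totals):
    """2-D log-likelihood grid maximization for the logit-binomial slope."""
    b0 = np.linspace(-4, 4, 400)
    b1 = np.linspace(-1, 1, 400)
    best = (-np.inf, None)
    for _ in range(3):  # coarse-to-fine refinement
        B0, B1 = np.meshgrid(b0, b1, indexing="ij")
        ll = np.zeros_like(B0)
        for g, c, t in zip(gens, counts, totals):
            eta = B0 + B1 * g
            ll += c * eta - t * np.logaddexp(0, eta)
        i, j = np.unravel_index(np.argmax(ll), ll.shape)
        best = (ll[i, j], (b0[i], b1[j]))
        w0, w1 = b0[1] - b0[0], b1[1] - b1[0]
        b0 = np.linspace(b0[i] - 2 * w0, b0[i] + 2 * w0, 200)
        b1 = np.linspace(b1[j] - 2 * w1, b1[j] + 2 * w1, 200)
    return best[1]


class TestGlmSlope:
    def test_symmetric_counts_zero_slope(self):
        fit = fit_slope_glm(series([0, 10, 20], [5, 5, 5], [10, 10, 10]))
        assert fit.slope == pytest.approx(0.0, abs=1e-8)

    def test_matches_likelihood_grid_oracle(self):
        s = series([0, 10, 20], [2, 5, 8], [10, 10, 10])
        fit = fit_slope_glm(s)
        _, b1 = grid_glm_oracle([0, 10, 20], [2, 5, 8], [10, 10, 10])
        assert fit.slope == pytest.approx(b1, abs=1e-4)

    def test_coverage_scales_evidence_not_slope(self):
        s1 = series([0, 10, 20], [2, 5, 8], [10, 10, 10])
        s2 = series([0, 10, 20], [4, 10, 16], [20, 20, 20])
        f1, f2 = fit_slope_glm(s1), fit_slope_glm(s2)
        assert f2.slope == pytest.approx(f1.slope, rel=1e-6)
        assert f2.p_value < f1.p_value

    def test_complete_separation_flagged(self):
        fit = fit_slope_glm(series([0, 10], [0, 10], [10, 10]))
        assert fit.separated
        assert np.isnan(fit.p_value)

    def test_ols_and_glm_slopes_agree_in_sign(self, rng):
        """Balanced-coverage simulated trajectories with |slope|>0.005/gen."""
        agree = 0
        n = 200
        for _ in range(n):
            slope = rng.choice([-1, 1]) * rng.uniform(0.006, 0.02)
            gens = np.arange(0, 60, 8, dtype=float)
            p = np.clip(0.5 + slope * gens + rng.normal(0, 0.02, gens.size),
                        0.01, 0.99)
            tot = np.full(gens.size, 85)
            cnt = rng.binomial(tot, p)
            s = series(gens, cnt, tot)
            try:
                g, o = fit_slope_glm(s), fit_slope_ols(s)
            except ValueError:
                continue
            if g.separated or o.slope == 0:
                continue
            agree += (np.sign(g.slope) == np.sign(o.slope))
        assert agree / n >= 0.99

    def test_neutral_glm_pvalues_uniform(self):
        """Under pure binomial read noise at constant frequency the Wald p
        of the generation coefficient is ~Uniform (10^3 trajectories)."""
        r = np.random.default_rng(7)
        pvals = []
        gens = np.arange(0, 60, 8, dtype=float)
        for _ in range(1000):
            p = r.uniform(0.2, 0.8)
            tot = r.poisson(85, gens.size)
            cnt = r.binomial(tot, p)
            fit = fit_slope_glm(series(gens, cnt, np.maximum(tot, 1)))
            if not fit.separated:
                pvals.append(fit.p_value)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestFixation:
    @pytest.mark.parametrize("freqs,expected,idx", [
        ([0.5, 0.9, 1.0, 1.0], "fixed", 2),
        ([0.5, 1.0, 0.8, 1.0], "segregating", None),
        ([0.4, 0.1, 0.0, 0.0], "lost", 2),
        ([0.3, 0.4, 0.5, 0.6], "segregating", None),
    ])
    def test_reach_and_remain_rule(self, freqs, expected, idx):
        tot = 10
        s = series(range(len(freqs)), [round(f * tot) for f in freqs],
                   [tot] * len(freqs))
        state, first = score_fixation(s)
        assert state == expected and first == idx

    def test_tolerance_flag_off_by_default(self):
        s = series([0, 1, 2], [9, 10, 10], [10, 10, 10])
        assert score_fixation(s)[0] == "fixed"
        s2 = series([0, 1, 2], [9, 9, 9], [10, 10, 10])
        assert score_fixation(s2)[0] == "segregating"
        assert score_fixation(s2, tolerance=0.1)[0] == "fixed"

    def test_cumulative_curve_non_decreasing(self, rng):
        results = [score_fixation(series(range(5),
                                         rng.integers(0, 11, 5).tolist(),
                                         [10] * 5)) for _ in range(50)]
        curve = cumulative_fixations(results, 5)
        assert np.all(np.diff(curve) >= 0)

    def test_selection_increases_fixation_rate(self, small_sim):
        """The tracked (selected) allele fixes more often in selected than
        in matched impaired populations (the cumulative-fixation contrast)."""
        sel = small_sim.truth.selected_indices
        gens = np.arange(0, 61, 7)
        counts = {"preen": 0, "impaired": 0}
        totals = {"preen": 0, "impaired": 0}
        for pop in small_sim.design.populations:
            if pop.is_control:
                continue
            traj_arr = small_sim.trajectories[pop.pop_id]
            for i in sel:
                f = traj_arr[gens, i]
                tot = 200
                s = series(gens, np.round(f * tot).astype(int), [tot] * len(gens))
                state, _ = score_fixation(s)
                counts[pop.preening] += state == "fixed"
                totals[pop.preening] += 1
        table = [[counts["preen"], totals["preen"] - counts["preen"]],
                 [counts["impaired"], totals["impaired"] - counts["impaired"]]]
        p = stats.fisher_exact(table, alternative="greater")[1]
        assert p < 0.01


class TestTukey:
    def test_null_groups_not_significant(self, rng):
        a = rng.normal(0, 1, 20).tolist()
        b = rng.normal(0, 1, 20).tolist()
        res = compare_slopes_tukey({"a": a, "b": b})
        assert res["p_adj"].iloc[0] > 0.05

    def test_matches_studentized_range_oracle(self):
        groups = {"g1": [1.0, 1.2, 0.9, 1.1], "g2": [2.0, 2.1, 1.9, 2.2],
                  "g3": [1.4, 1.6, 1.5, 1.3]}
        res = compare_slopes_tukey(groups)
        # independent oracle: studentized-range distribution on hand-computed
        # group means and pooled MSE
        all_vals = [v for vals in groups.values() for v in vals]
        k, n = 3, len(all_vals)
        means = {g: np.mean(v) for g, v in groups.items()}
        mse = sum((x - means[g]) ** 2 for g, v in groups.items() for x in v) / (n - k)
        for _, row in res.iterrows():
            g1, g2 = row["group1"], row["group2"]
            q = abs(means[g1] - means[g2]) / np.sqrt(mse / 4)
            p_expect = stats.studentized_range.sf(q, k, n - k)
            assert float(row["p_adj"]) == pytest.approx(p_expect, abs=1e-3)

    def test_singleton_group_rejected(self):
        with pytest.raises(ValueError):
            compare_slopes_tukey({"a": [1.0], "b": [1.0, 2.0]})

    def test_selected_vs_impaired_contrast_significant(self, small_sim):
        gens = np.arange(0, 61, 7, dtype=float)
        sel = small_sim.truth.selected_indices
        groups = {"preen": [], "impaired": []}
        for pop in small_sim.design.populations:
            if pop.is_control:
                continue
            t = small_sim.trajectories[pop.pop_id]
            ctrl = small_sim.trajectories[
                f"gray_{pop.preening}_r{pop.replicate}"]
            for i in sel:
                pol = polarize(t[45, i], ctrl[45, i])
                y = t[gens.astype(int), i]
                y = y if pol == "alt" else 1 - y
                groups[pop.preening].append(np.polyfit(gens, y, 1)[0])
        res = compare_slopes_tukey(groups)
        assert float(res["p_adj"].iloc[0]) < 0.01
        assert np.mean(groups["preen"]) > np.mean(groups["impaired"])


class TestFoldedSfs:
    def test_all_half_frequency_mass_in_top_bin(self):
        hist = folded_sfs(np.full(50, 10), np.full(50, 10), n_bins=5)
        assert hist[-1] == 50 and hist[:-1].sum() == 0

    def test_sums_to_sites_with_data(self, rng):
        ref = rng.integers(0, 40, 200)
        alt = rng.integers(0, 40, 200)
        hist = folded_sfs(ref, alt, 10)
        assert hist.sum() == ((ref + alt) > 0).sum()

    def test_neutral_spectrum_matches_one_over_i_shape(self):
        """Goodness-of-fit of sampled founder MAFs against the folded
        neutral expectation ~ 1/i + 1/(2n-i)."""
        from lousescan import simulate_founders
        two_n = 200
        f = simulate_founders(30_000, two_n // 2, "neutral", rng=5)
        counts = np.rint(f * two_n).astype(int)
        maf_counts = np.minimum(counts, two_n - counts)
        edges = np.array([1, 10, 25, 50, 75, 101])
        obs = np.histogram(maf_counts, bins=edges)[0]
        i = np.arange(1, two_n)
        w = 1.0 / i
        folded = np.minimum(i, two_n - i)
        expect = np.array([w[(folded >= lo) & (folded < hi)].sum()
                           for lo, hi in zip(edges[:-1], edges[1:])])
        expect = expect / expect.sum() * obs.sum()
        chi2 = ((obs - expect) ** 2 / expect).sum()
        assert stats.chi2.sf(chi2, len(obs) - 1) > 0.01

    def test_selected_sites_start_from_commoner_variants(self, small_sim, small_seq):
        """Sites that respond to selection segregate at higher starting
        frequency than the rare-allele-skewed genomic background (measured
        from the first sequenced timepoint)."""
        sel = small_sim.truth.selected_indices
        pop = next(p.pop_id for p in small_sim.design.populations
                   if p.under_selection)
        a, d = small_seq.pooled[(pop, 6)]
        maf = np.minimum(a, d - a) / np.maximum(d, 1)
        neutral = np.setdiff1d(np.arange(small_sim.n_sites), sel)
        p = stats.mannwhitneyu(maf[sel], maf[neutral],
                               alternative="greater").pvalue
        assert p < 0.05


class TestGreatestChange:
    def test_linear_scan_example(self):
        s = series([0, 1, 2, 3], [1, 2, 7, 8], [10, 10, 10, 10])
        i, j, d = greatest_change_interval(s)
        assert (i, j) == (1, 2) and d == pytest.approx(0.5)

    def test_constant_series_first_interval(self):
        s = series([0, 1, 2], [5, 5, 5], [10, 10, 10])
        assert greatest_change_interval(s)[:2] == (0, 1)

    def test_matches_exhaustive_pair_scan(self, rng):
        tot = 50
        cnt = rng.integers(0, tot + 1, 8)
        s = series(range(8), cnt, [tot] * 8)
        i, j, d = greatest_change_interval(s)
        f = cnt / tot
        diffs = [abs(f[k + 1] - f[k]) for k in range(7)]
        assert abs(d) == pytest.approx(max(diffs))
        assert i == int(np.argmax(diffs))
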