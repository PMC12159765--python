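"""Normality screening, mixed ANOVA, bootstrap post-hoc, FDR, correlation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from crossfreq.stats import (
    bootstrap_posthoc,
    fdr_bh,
    normality_screen,
    pac_thi_correlation,
    rm_anova,
)


def _pac_table(rng, n_per_group=10, rois=("r1", "r2", "r3", "r4"),
               group_shift=0.0, roi_shift=None, dv="theta_gamma_mi"):
    rows = []
    for g, n in (("BT", n_per_group), ("HC", n_per_group)):
        for s in range(n):
            sid = f"{g}{s}"
            for roi in rois:
                v = rng.normal(0.1, 0.02)
                if g == "BT":
                    v += group_shift
                    if roi_shift and roi in roi_shift:
                        v += roi_shift[roi]
                rows.append(
                    {"subject_id": sid, "group": g, "roi": roi, dv: v}
                )
    return pd.DataFrame(rows)


class TestNormalityScreen:
    def test_normal_sample_passes(self):
        passes = sum(
            normality_screen(np.random.default_rng(s).normal(size=500))[2]
            for s in range(100)
        )
        assert passes >= 90

    def test_exponential_sample_fails(self):
        fails = sum(
            not normality_screen(
                np.random.default_rng(s).exponential(size=500)
            )[2]
            for s in range(100)
        )
        assert fails >= 95

    def test_w_in_unit_interval(self, rng):
        w, p, _ = normality_screen(rng.normal(size=50))
        assert 0 < w <= 1 and 0 <= p <= 1

    def test_too_small_sample(self):
        with pytest.raises(ValueError, match="3 ≤ n"):
            normality_screen(np.array([1.0, 2.0]))

    def test_constant_sample(self):
        with pytest.raises(ValueError, match="constant"):
            normality_screen(np.ones(20))


class TestRmAnova:
    def test_all_equal_gives_zero_f(self, rng):
        tab = _pac_table(rng)
        tab["theta_gamma_mi"] = 0.5
        for res in rm_anova(tab):
            assert res.F == 0.0

    def test_hand_computed_mixed_anova(self):
        """2 groups × 2 ROIs, n=4: F-ratios recomputed from the textbook
        sum-of-squares decomposition (independent of the implementation)."""
        rng = np.random.default_rng(42)
        y = rng.normal(0.2, 0.05, size=(2, 4, 2))  # group × subject × roi
        y[0, :, 1] += 0.1  # group 0 elevated in roi 1 → interaction
        rows = []
        for g in range(2):
            for s in range(4):
                for r in range(2):
                    rows.append(
                        {"subject_id": f"g{g}s{s}", "group": f"G{g}",
                         "roi": f"R{r}", "theta_gamma_mi": y[g, s, r]}
                    )
        tab = pd.DataFrame(rows)

        # oracle: balanced mixed-design decomposition
        gm = y.mean()
        a_g = y.mean(axis=(1, 2))
        b_r = y.mean(axis=(0, 1))
        ab = y.mean(axis=1)
        subj = y.mean(axis=2)
        nb, nn = 2, 4
        ss_group = nb * nn * np.sum((a_g - gm) ** 2)
        ss_subj = nb * np.sum((subj - a_g[:, None]) ** 2)
        ss_roi = 2 * nn * np.sum((b_r - gm) ** 2)
        ss_int = nn * np.sum((ab - a_g[:, None] - b_r[None, :] + gm) ** 2)
        ss_total = np.sum((y - gm) ** 2)
        ss_err = ss_total - ss_group - ss_subj - ss_roi - ss_int
        f_group = (ss_group / 1) / (ss_subj / (8 - 2))
        f_roi = (ss_roi / 1) / (ss_err / 6)
        f_int = (ss_int / 1) / (ss_err / 6)

        got = {r.effect: r for r in rm_anova(tab)}
        assert got["Group"].F == pytest.approx(f_group, rel=1e-6)
        assert got["ROI"].F == pytest.approx(f_roi, rel=1e-6)
        assert got["ROI×Group"].F == pytest.approx(f_int, rel=1e-6)
        assert got["ROI×Group"].p_bonferroni >= got["ROI×Group"].p

    def test_requires_two_groups(self, rng):
        tab = _pac_table(rng)
        with pytest.raises(ValueError, match="two groups"):
            rm_anova(tab[tab.group == "BT"])

    def test_missing_cells_rejected(self, rng):
        tab = _pac_table(rng).iloc[:-1]
        with pytest.raises(ValueError, match="unbalanced"):
            rm_anova(tab)

    def test_planted_interaction_detected(self, rng):
        tab = _pac_table(
            rng, n_per_group=20, roi_shift={"r1": 0.06, "r2": 0.06}
        )
        got = {r.effect: r for r in rm_anova(tab)}
        assert got["ROI×Group"].p < 0.05


class TestBootstrapPosthoc:
    def test_deterministic_given_seed(self, rng):
        tab = _pac_table(rng, group_shift=0.05)
        a = bootstrap_posthoc(tab, seed=5)
        b = bootstrap_posthoc(tab, seed=5)
        assert a == b

    def test_planted_shift_significant(self, rng):
        tab = _pac_table(rng, group_shift=0.0, roi_shift={"r2": 0.08})
        res = {r.roi_label: r for r in bootstrap_posthoc(tab, seed=1)}
        assert res["r2"].q < 0.05
        assert res["r2"].observed_diff > 0

    def test_q_at_least_p(self, rng):
        tab = _pac_table(rng, group_shift=0.02)
        for r in bootstrap_posthoc(tab, seed=2):
            assert r.q >= r.p - 1e-12

    def test_small_n_boot_rejected(self, rng):
        with pytest.raises(ValueError, match="n_boot"):
            bootstrap_posthoc(_pac_table(rng), n_boot=50)

    def test_needs_five_per_group(self, rng):
        tab = _pac_table(rng, n_per_group=3)
        with pytest.raises(ValueError, match="≥5 subjects"):
            bootstrap_posthoc(tab)


class TestFdrBh:
    @staticmethod
    def _bruteforce(p):
        """Exhaustive step-up: q_i = min over j≥rank(i) of p_(j)·m/j, capped."""
        p = np.asarray(p, float)
        m = p.size
        order = np.argsort(p)
        q = np.empty(m)
        sorted_q = np.minimum.accumulate(
            (p[order] * m / np.arange(1, m + 1))[::-1]
        )[::-1]
        q[order] = np.minimum(sorted_q, 1.0)
        return q

    def test_worked_example(self):
        q = fdr_bh(np.array([0.01, 0.02, 0.03, 0.04]))
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p(self):
        np.testing.assert_allclose(fdr_bh(np.array([0.3])), [0.3])

    def test_all_ones(self):
        np.testing.assert_allclose(fdr_bh(np.ones(5)), np.ones(5))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_bh(np.array([0.5, 1.2]))

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        hst.lists(
            hst.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=12
        )
    )
    def test_matches_bruteforce_stepup(self, pvals):
        p = np.array(pvals)
        np.testing.assert_allclose(fdr_bh(p), self._bruteforce(p), atol=1e-12)


class TestPacThiCorrelation:
    def _table(self, rng, n=12):
        thi = pd.Series(
            rng.uniform(10, 90, n), index=[f"s{i}" for i in range(n)]
        )
        rows = []
        for sid in thi.index:
            rows.append(
                {"subject_id": sid, "group": "NBT", "roi": "ORBsup_L",
                 "theta_beta_mi": rng.normal(0.1, 0.02),
                 "theta_gamma_mi": 0.5 - 0.004 * thi[sid]}
            )
        return pd.DataFrame(rows), thi

    def test_perfect_negative_linear(self, rng):
        tab, thi = self._table(rng)
        res = {
            (r.roi_label, r.band): r for r in pac_thi_correlation(tab, thi)
        }
        r = res[("ORBsup_L", "theta_gamma_mi")]
        assert r.r == pytest.approx(-1.0)
        assert r.n == 12

    def test_missing_thi_dropped(self, rng):
        tab, thi = self._table(rng)
        thi.iloc[0] = np.nan
        res = pac_thi_correlation(tab, thi, bands=("theta_gamma_mi",))
        assert res[0].n == 11

    def test_too_few_subjects(self, rng):
        tab, thi = self._table(rng, n=3)
        with pytest.raises(ValueError, match="≥4"):
            pac_thi_correlation(tab, thi)

    def test_spearman_option(self, rng):
        tab, thi = self._table(rng)
        res = pac_thi_correlation(
            tab, thi, bands=("theta_gamma_mi",), method="spearman"
        )
        assert res[0].r == pytest.approx(-1.0)
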