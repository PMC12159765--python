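"""The KL modulation index and its filter-bank machinery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from crossfreq.pac import (
    Comodulogram,
    PhaseBinning,
    band_pac,
    band_pac_direct,
    comodulogram,
    fir_band,
    hilbert_phase_amp,
    kl_mi,
    surrogate_max_mi,
    surrogate_mi,
)
from crossfreq.synthetic import CouplingSpec, generate_coupled_signal

FS = 500.0


def _dense_phase(n=100_000):
    """Uniform dense phase covering the circle."""
    return np.angle(np.exp(1j * np.linspace(-np.pi, np.pi, n, endpoint=False)))


def _oracle_mi(m, n_bins=18, n_quad=20_000):
    """Quadrature oracle: bin A(φ)=1+m·cos φ over 18 bins, entropy formula."""
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    p = np.empty(n_bins)
    for j in range(n_bins):
        phi = np.linspace(edges[j], edges[j + 1], n_quad)
        p[j] = np.trapezoid(1 + m * np.cos(phi), phi)
    p /= p.sum()
    h = -np.sum(p * np.log(p))
    return (np.log(n_bins) - h) / np.log(n_bins)


class TestKlMi:
    def test_uniform_amplitude_is_zero(self):
        phase = _dense_phase()
        assert kl_mi(phase, np.ones_like(phase)) == 0.0

    def test_single_bin_indicator_is_one(self):
        phase = _dense_phase()
        # all amplitude mass inside the single bin (0°, 20°)
        amp = ((phase > 0.01) & (phase < np.pi / 18 * 0.99)).astype(float)
        assert kl_mi(phase, amp) == pytest.approx(1.0, abs=1e-12)

    def test_bounds_on_random_inputs(self, rng):
        for _ in range(1000):
            n = rng.integers(200, 400)
            phase = rng.uniform(-np.pi, np.pi, n)
            amp = rng.random(n)
            mi = kl_mi(phase, amp)
            assert 0.0 <= mi <= 1.0

    def test_amplitude_scale_invariance(self, rng):
        phase = rng.uniform(-np.pi, np.pi, 5000)
        amp = rng.random(5000)
        assert kl_mi(phase, amp) == pytest.approx(
            kl_mi(phase, 7.3e4 * amp), abs=1e-14
        )

    def test_circular_relabeling_invariance(self, rng):
        # phases drawn strictly inside bins so the ±2-bin relabeling is an
        # exact permutation of the binned distribution
        width = 2 * np.pi / 18
        bins = rng.integers(0, 18, 40_000)
        phase = -np.pi + (bins + rng.uniform(0.1, 0.9, bins.size)) * width
        amp = 1 + 0.5 * np.cos(phase)
        shifted = np.angle(np.exp(1j * (phase + 2 * width)))
        assert kl_mi(shifted, amp) == pytest.approx(kl_mi(phase, amp),
                                                    rel=1e-9)

    @pytest.mark.parametrize("m", [0.2, 0.5, 0.8])
    def test_quadrature_oracle(self, m):
        """A(φ)=1+m·cos φ on a dense uniform phase matches the 18-bin
        quadrature oracle within 2% relative."""
        t = np.arange(int(300 * FS)) / FS
        phase = np.angle(np.exp(1j * 2 * np.pi * 6.0 * t))
        amp = 1 + m * np.cos(phase)
        assert kl_mi(phase, amp) == pytest.approx(_oracle_mi(m), rel=0.02)

    def test_empty_bin_error(self):
        phase = np.full(100, 0.1)
        with pytest.raises(ValueError, match="empty phase bin"):
            kl_mi(phase, np.ones(100))

    def test_zero_amplitude_error(self):
        phase = _dense_phase(3600)
        with pytest.raises(ValueError, match="all-zero amplitude"):
            kl_mi(phase, np.zeros_like(phase))

    def test_negative_amplitude_error(self):
        phase = _dense_phase(3600)
        with pytest.raises(ValueError, match="non-negative"):
            kl_mi(phase, -np.ones_like(phase))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(hst.integers(min_value=0, max_value=2**31 - 1))
    def test_bounds_property(self, seed):
        r = np.random.default_rng(seed)
        phase = r.uniform(-np.pi, np.pi, 500)
        amp = r.random(500) + 1e-9
        assert 0.0 <= kl_mi(phase, amp) <= 1.0


class TestFirBand:
    def test_tone_at_center_passes(self):
        t = np.arange(int(20 * FS)) / FS
        x = np.sin(2 * np.pi * 6.0 * t)
        y = fir_band(x, FS, center=6.0)
        core = slice(int(5 * FS), -int(5 * FS))
        assert np.std(y[core]) >= 0.9 * np.std(x[core])

    def test_tone_off_band_attenuated(self):
        t = np.arange(int(20 * FS)) / FS
        x = np.sin(2 * np.pi * 12.0 * t)  # center + 3·bandwidth
        y = fir_band(x, FS, center=6.0)
        core = slice(int(5 * FS), -int(5 * FS))
        assert np.std(y[core]) <= 0.1 * np.std(x[core])

    def test_zero_signal(self):
        assert np.allclose(fir_band(np.zeros(10_000), FS, 10.0), 0.0)

    def test_band_exceeding_nyquist(self):
        with pytest.raises(ValueError, match="Nyquist"):
            fir_band(np.zeros(10_000), FS, center=249.5)

    def test_signal_too_short_for_order(self):
        with pytest.raises(ValueError, match="filter order"):
            fir_band(np.zeros(100), FS, center=6.0)


class TestHilbert:
    def test_tone_amplitude(self):
        t = np.arange(int(10 * FS)) / FS
        _, amp = hilbert_phase_amp(np.sin(2 * np.pi * 6.0 * t))
        interior = amp[500:-500]
        assert np.all(np.abs(interior - 1.0) < 0.01)

    def test_phase_slope_recovers_frequency(self):
        t = np.arange(int(10 * FS)) / FS
        phase, _ = hilbert_phase_amp(np.sin(2 * np.pi * 6.0 * t))
        unwrapped = np.unwrap(phase[500:-500])
        slope = np.polyfit(t[500:-500], unwrapped, 1)[0] / (2 * np.pi)
        assert slope == pytest.approx(6.0, abs=0.01)

    def test_scaling(self, rng):
        x = rng.standard_normal(5000)
        p1, a1 = hilbert_phase_amp(x)
        p3, a3 = hilbert_phase_amp(3.0 * x)
        np.testing.assert_allclose(a3, 3.0 * a1, rtol=1e-12)
        np.testing.assert_allclose(p3, p1, atol=1e-12)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            hilbert_phase_amp(np.array([1.0, np.inf]))


class TestComodulogram:
    def test_planted_pair_is_global_argmax(self, coupled_signal):
        com = comodulogram(coupled_signal, FS)
        pc, ac = com.argmax()
        assert abs(pc - 6.0) <= 2.0
        assert abs(ac - 40.0) <= 2.0

    def test_pure_tone_below_surrogates(self):
        """A lone oscillation with no coupling partner stays within the
        surrogate null everywhere."""
        t = np.arange(int(40 * FS)) / FS
        x = np.sin(2 * np.pi * 9.0 * t) + 0.5 * np.random.default_rng(
            3
        ).standard_normal(t.size)
        obs, null = surrogate_max_mi(x, FS, n_surrogates=100, rng=4)
        assert obs < np.percentile(null, 95)

    def test_too_short_signal(self):
        with pytest.raises(ValueError, match="10 cycles"):
            comodulogram(np.zeros(int(2 * FS)), FS)

    def test_grid_geometry(self, coupled_signal):
        com = comodulogram(coupled_signal, FS)
        assert np.allclose(np.diff(com.phase_centers), 2.0)
        assert np.allclose(np.diff(com.amp_centers), 2.0)
        assert com.phase_centers[0] == 2.0 and com.phase_centers[-1] == 8.0
        finite = com.mi[np.isfinite(com.mi)]
        assert finite.size > 0
        assert np.all((finite >= 0) & (finite <= 1))


class TestBandPac:
    def _com(self, fill):
        pc = np.array([4.0, 6.0, 8.0])
        ac = np.array([32.0, 40.0])
        return Comodulogram(pc, ac, np.full((3, 2), fill))

    def test_constant_box(self):
        assert band_pac(self._com(0.25), (4, 8), (30, 70)) == pytest.approx(0.25)

    def test_two_cell_mean(self):
        com = self._com(np.nan)
        com.mi[0, 0], com.mi[0, 1] = 0.1, 0.3
        assert band_pac(com, (4, 8), (30, 70)) == pytest.approx(0.2)

    def test_empty_selection(self):
        with pytest.raises(ValueError, match="no admissible"):
            band_pac(self._com(np.nan), (4, 8), (30, 70))

    def test_planted_gamma_beats_beta(self):
        sig = generate_coupled_signal(
            CouplingSpec(phase_freq=6, amp_freq=45, modulation_depth=0.8),
            40.0, FS, seed=21,
        )
        tg = band_pac_direct(sig, FS, amp_band=(30.0, 70.0))
        tb = band_pac_direct(sig, FS, amp_band=(13.0, 30.0))
        assert tg > tb


class TestSurrogates:
    def test_surrogate_rank_uniform_on_uncoupled_noise(self):
        """On uncoupled noise the observed MI is an ordinary draw from the
        surrogate null: its rank is uniform (KS test over 60 runs)."""
        from scipy import stats as spstats

        from crossfreq.pac import _cell_series

        ranks = []
        for seed in range(60):
            r = np.random.default_rng(1000 + seed)
            x = r.standard_normal(int(12 * FS))
            phase, amp = _cell_series(x, FS, 6.0, 40.0, 2.0)
            obs = kl_mi(phase, amp)
            null = surrogate_mi(phase, amp, n_surrogates=99, rng=seed)
            ranks.append((np.sum(null < obs) + 0.5) / 100)
        _, p = spstats.kstest(ranks, "uniform")
        assert p > 0.01


class TestPacPipelineTable:
    def test_shape_and_determinism(self, rng):
        from crossfreq.inverse import ROISeries
        from crossfreq.pac import pac_pipeline

        data = rng.standard_normal((10, 3, 1000))  # 20 s of 2-s epochs
        series = ROISeries(data=data, fs=FS, roi_labels=("a", "b", "c"))
        table = pac_pipeline(
            {"s1": (series, "BT"), "s2": (series, "BT"), "s3": (series, "HC")}
        )
        assert len(table) == 9  # 3 subjects x 3 ROIs
        assert set(table.columns) >= {
            "subject_id", "group", "roi", "theta_beta_mi", "theta_gamma_mi"
        }
        s1 = table[table.subject_id == "s1"].drop(columns="subject_id")
        s2 = table[table.subject_id == "s2"].drop(columns="subject_id")
        np.testing.assert_allclose(
            s1[["theta_beta_mi", "theta_gamma_mi"]].to_numpy(),
            s2[["theta_beta_mi", "theta_gamma_mi"]].to_numpy(),
        )
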