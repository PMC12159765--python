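"""Ground-truth properties of the synthetic cohort generator."""

import numpy as np
import pytest

from crossfreq.pac import _cell_series, kl_mi
from crossfreq.spectral import psd
from crossfreq.synthetic import (
    CohortSpec,
    CouplingSpec,
    RoiProfile,
    THI_THRESHOLD,
    generate_cohort,
    generate_coupled_signal,
    generate_leadfield,
    generate_subject,
    pink_noise,
)

FS = 500.0


class TestCoupledSignal:
    def test_length_and_determinism(self):
        spec = CouplingSpec(modulation_depth=0.5)
        a = generate_coupled_signal(spec, 20.0, FS, seed=3)
        b = generate_coupled_signal(spec, 20.0, FS, seed=3)
        assert a.shape == (10_000,)
        np.testing.assert_array_equal(a, b)

    def test_aliasing_rejected(self):
        spec = CouplingSpec(phase_freq=6, amp_freq=45)
        with pytest.raises(ValueError, match="alias"):
            generate_coupled_signal(spec, 10.0, fs=80.0, seed=0)

    def test_depth_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            CouplingSpec(modulation_depth=1.2)
        with pytest.raises(ValueError):
            CouplingSpec(phase_freq=50, amp_freq=40)

    def test_psd_peaks_at_planted_frequencies(self):
        """Spectral sanity: oscillator lines at f_p and f_a within one bin."""
        sig = generate_coupled_signal(
            CouplingSpec(phase_freq=6, amp_freq=40, modulation_depth=0.5,
                         noise_sd=0.5),
            60.0, FS, seed=4,
        )
        spec = psd(sig.reshape(30, -1), FS)
        df = spec.freqs[1] - spec.freqs[0]
        for f0 in (6.0, 40.0):
            near = np.abs(spec.freqs - f0) <= 1.5 * df
            far = (np.abs(spec.freqs - f0) > 3 * df) & (
                np.abs(spec.freqs - f0) < 10 * df
            )
            assert spec.power[near].max() > 3 * spec.power[far].max()

    def test_mi_monotone_in_modulation_depth(self):
        """Estimated MI at the planted cell is non-decreasing in depth
        (majority ordering over 5 seeds)."""
        depths = [0.0, 0.25, 0.5, 0.75, 1.0]
        votes = 0
        for seed in range(5):
            mis = []
            for m in depths:
                sig = generate_coupled_signal(
                    CouplingSpec(phase_freq=6, amp_freq=40, modulation_depth=m),
                    30.0, FS, seed=100 + seed,
                )
                ph, am = _cell_series(sig, FS, 6.0, 40.0, 2.0)
                mis.append(kl_mi(ph, am))
            if all(b >= a for a, b in zip(mis, mis[1:])):
                votes += 1
        assert votes >= 3


class TestPinkNoise:
    def test_one_over_f_slope(self, rng):
        x = pink_noise(2**16, rng, sd=1.0)
        assert abs(x.std() - 1.0) < 1e-9
        spec = np.abs(np.fft.rfft(x)) ** 2
        freqs = np.fft.rfftfreq(2**16)
        lo = spec[(freqs > 0.001) & (freqs < 0.01)].mean()
        hi = spec[(freqs > 0.1) & (freqs < 0.5)].mean()
        assert lo > 10 * hi  # power falls with frequency


class TestSubject:
    def test_identity_leadfield_zero_noise(self):
        """With identity mixing, one source per ROI and no noise, sensor
        rows equal the ground-truth ROI series."""
        from crossfreq.synthetic import Leadfield

        labels = ["A", "B", "C"]
        lf = Leadfield(gain=np.eye(3), roi_map=tuple(labels))
        profs = [RoiProfile(r, 0.3, 0.3) for r in labels]
        sens, truth = generate_subject(
            profs, lf, 10.0, FS, seed=1,
            sensor_snr_db=np.inf, source_noise_sd=0.0,
        )
        np.testing.assert_allclose(sens, truth, rtol=1e-12)

    def test_determinism(self, small_leadfield):
        profs = [RoiProfile(r, 0.2, 0.5) for r in small_leadfield.roi_labels]
        a = generate_subject(profs, small_leadfield, 4.0, FS, seed=7)
        b = generate_subject(profs, small_leadfield, 4.0, FS, seed=7)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_unknown_roi_rejected(self, small_leadfield):
        profs = [RoiProfile("nowhere", 0.2, 0.2)]
        with pytest.raises(ValueError, match="nowhere"):
            generate_subject(profs, small_leadfield, 4.0, FS, seed=0)

    def test_planted_roi_ordering_recovered(self, small_leadfield):
        """Heschl-vs-orbitofrontal depth contrast survives the sensor level:
        stronger planted theta–gamma coupling gives larger band PAC."""
        from crossfreq.pac import band_pac_direct

        labels = list(small_leadfield.roi_labels)
        depths = {labels[0]: 0.8, labels[1]: 0.1}
        profs = [
            RoiProfile(r, 0.1, depths.get(r, 0.2)) for r in labels
        ]
        _, truth = generate_subject(profs, small_leadfield, 30.0, FS, seed=2)
        hi = band_pac_direct(truth[0], FS, amp_band=(30.0, 70.0))
        lo = band_pac_direct(truth[1], FS, amp_band=(30.0, 70.0))
        assert hi > lo


class TestCohort:
    def test_group_counts_and_thi_threshold(self):
        spec = CohortSpec(n_bt=21, n_nbt=27, n_hc=21, duration_s=4.0, seed=9)
        cohort = generate_cohort(spec)
        assert cohort.group_counts() == {"BT": 21, "NBT": 27, "HC": 21}
        meta = cohort.metadata
        assert len(meta) == 69
        bt = meta[meta.group == "BT"]["thi"]
        nbt = meta[meta.group == "NBT"]["thi"]
        hc = meta[meta.group == "HC"]["thi"]
        assert (bt > THI_THRESHOLD).all()
        assert (nbt <= THI_THRESHOLD).all()
        assert hc.isna().all()

    def test_inconsistent_thi_model_rejected(self):
        with pytest.raises(ValueError, match="threshold"):
            CohortSpec(thi_model={"BT": (30.0, 0.0), "NBT": (18.5, 11.2)})

    def test_no_controls_is_valid(self):
        spec = CohortSpec(n_bt=3, n_nbt=3, n_hc=0, duration_s=4.0, seed=1)
        cohort = generate_cohort(spec)
        assert cohort.group_counts() == {"BT": 3, "NBT": 3, "HC": 0}

    def test_realize_deterministic(self):
        spec = CohortSpec(n_bt=2, n_nbt=2, n_hc=2, duration_s=4.0, seed=3)
        cohort = generate_cohort(spec)
        sid = cohort.subjects[0].subject_id
        a, _ = cohort.realize(sid)
        b, _ = cohort.realize(sid)
        np.testing.assert_array_equal(a, b)

    def test_non_whole_epoch_duration_rejected(self):
        with pytest.raises(ValueError, match="whole epochs"):
            CohortSpec(duration_s=5.0)


class TestLeadfield:
    def test_full_rank_and_roi_coverage(self):
        lf = generate_leadfield(32, 52, 26, seed=0)
        assert np.linalg.matrix_rank(lf.gain) == 32
        assert len(lf.roi_labels) == 26
        for roi in lf.roi_labels:
            assert len(lf.sources_of(roi)) >= 1

    def test_determinism(self):
        a = generate_leadfield(8, 12, 4, seed=3)
        b = generate_leadfield(8, 12, 4, seed=3)
        np.testing.assert_array_equal(a.gain, b.gain)

    def test_more_rois_than_sources_rejected(self):
        with pytest.raises(ValueError, match="ROIs"):
            generate_leadfield(8, 4, 6, seed=0)

    def test_square_invertible(self):
        lf = generate_leadfield(4, 4, 4, seed=1)
        assert abs(np.linalg.det(lf.gain)) > 0
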