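"""Synthetic call and colony generator: acoustics, signatures, determinism."""

import numpy as np
import pytest
from scipy import signal as sps
from scipy import stats

import hievox as hv
from hievox.synth import CALL_NOMINALS

from conftest import TEST_RATE


def _flat_profile(sex="F", f0_offset=0.0, fm_depth_scale=1.0,
                  jitter=0.0):
    """A hand-built profile with no jitter and controlled parameters."""
    base = {ct: {"f0_offset_hz": f0_offset, "duration_scale": 1.0,
                 "fm_rate_offset_hz": 0.0, "fm_depth_scale": fm_depth_scale,
                 "sweep_rate_scale": 1.0} for ct in hv.CALL_TYPES}
    jit = {k: jitter for k in ("f0_offset_hz", "duration_scale",
                               "fm_rate_offset_hz", "fm_depth_scale",
                               "sweep_rate_scale")}
    return hv.IndividualProfile(individual_id="x", sex=sex,
                                base_offsets=base, jitter_sd=jit)


class TestProfiles:
    def test_deterministic_under_fixed_seed(self):
        p1 = hv.make_profile("F", 0)
        p2 = hv.make_profile("F", 0)
        assert p1 == p2

    def test_invalid_sex_rejected(self):
        with pytest.raises(ValueError, match="sex"):
            hv.make_profile("X", 0)

    def test_zero_effect_size_removes_dimorphism(self):
        """With sex effect 0, F and M distributions coincide: the same seed
        yields identical parameters regardless of the sex label."""
        f = hv.make_profile("F", 7, sex_effect_hz=0.0)
        m = hv.make_profile("M", 7, sex_effect_hz=0.0)
        assert f.base_offsets == m.base_offsets

    def test_sex_difference_detectable_at_stated_effect(self):
        """1000 profiles per sex with a 2-sd f0 shift: two-sample t-test
        on the drawn f0 offsets is significant far below p = 0.001."""
        sd = 150.0  # between-individual f0 sd used by the generator
        rng_f = np.random.default_rng(10)
        rng_m = np.random.default_rng(11)
        f0_f = [hv.make_profile("F", rng_f, sex_effect_hz=2 * sd)
                .base_offsets["trill"]["f0_offset_hz"] for _ in range(1000)]
        f0_m = [hv.make_profile("M", rng_m, sex_effect_hz=2 * sd)
                .base_offsets["trill"]["f0_offset_hz"] for _ in range(1000)]
        t = stats.ttest_ind(f0_f, f0_m)
        assert t.pvalue < 1e-3
        assert np.mean(f0_f) > np.mean(f0_m)


class TestSynthCall:
    def test_unknown_call_type_rejected(self):
        with pytest.raises(ValueError, match="call_type"):
            hv.synth_call("bark", _flat_profile(), 0)

    def test_food_call_duration_and_downsweep(self):
        """Food calls last ~0.05 s (times the caller's duration scale) and
        their spectral centroid falls over the call."""
        for scale in (1.0, 1.3):
            p = _flat_profile()
            p.base_offsets["food_call"]["duration_scale"] = scale
            w = hv.synth_call("food_call", p, 3, rate_hz=62_500,
                              noise_snr_db=np.inf)
            assert w.duration_s == pytest.approx(0.05 * scale, rel=0.02)
            # centroid trajectory oracle on spectrogram halves
            half = w.samples.size // 2
            for seg, expect_hi in ((w.samples[:half], True),
                                   (w.samples[half:], False)):
                f, pxx = sps.periodogram(seg, fs=w.rate_hz)
                cen = np.sum(f * pxx) / np.sum(pxx)
                if expect_hi:
                    first = cen
                else:
                    assert cen < first

    def test_degenerate_fm_is_pure_tone(self):
        """fm depth -> 0 and no noise: the dominant DFT bin sits at the
        carrier frequency."""
        p = _flat_profile(fm_depth_scale=1e-9)
        w = hv.synth_call("trill", p, 5, rate_hz=62_500, noise_snr_db=np.inf)
        spec = np.abs(np.fft.rfft(w.samples))
        freqs = np.fft.rfftfreq(w.samples.size, 1 / w.rate_hz)
        carrier = CALL_NOMINALS["trill"]["f0_hz"]
        assert abs(freqs[np.argmax(spec)] - carrier) < 2 * freqs[1]

    def test_trill_fm_rate_recovered_by_analytic_signal(self):
        """Hilbert-transform instantaneous frequency of a noiseless trill
        oscillates at the profile's FM rate (+/- 5%)."""
        p = _flat_profile()
        p.base_offsets["trill"]["fm_rate_offset_hz"] = 4.0
        expected_rate = CALL_NOMINALS["trill"]["fm_rate_hz"] + 4.0
        w = hv.synth_call("trill", p, 8, rate_hz=62_500, noise_snr_db=np.inf)
        analytic = sps.hilbert(w.samples)
        inst_freq = np.diff(np.unwrap(np.angle(analytic))) * w.rate_hz / (2 * np.pi)
        # drop envelope edges, then find the modulation frequency
        core = inst_freq[w.samples.size // 10: -w.samples.size // 10]
        core = core - core.mean()
        f, pxx = sps.periodogram(core, fs=w.rate_hz)
        got = f[np.argmax(pxx)]
        assert got == pytest.approx(expected_rate, rel=0.05)

    @pytest.mark.parametrize("call_type", hv.CALL_TYPES)
    def test_energy_concentrated_in_call_band(self, call_type):
        """At SNR >= 20 dB, >60% of spectral power lies in the call band."""
        p = _flat_profile(jitter=0.0)
        w = hv.synth_call(call_type, p, 9, rate_hz=62_500, noise_snr_db=20.0)
        f, pxx = sps.periodogram(w.samples, fs=w.rate_hz)
        lo, hi = CALL_NOMINALS[call_type]["band_hz"]
        band = (f >= lo - 500) & (f <= hi + 500)
        assert pxx[band].sum() / pxx.sum() > 0.6

    def test_waveform_invariants(self):
        p = hv.make_profile("M", 3)
        for ct in hv.CALL_TYPES:
            w = hv.synth_call(ct, p, 4, rate_hz=TEST_RATE)
            assert np.all(np.isfinite(w.samples))
            assert np.max(np.abs(w.samples)) <= 1.0


class TestColony:
    def test_bookkeeping(self):
        spec = hv.ColonySpec(2, 2, calls_per_type={ct: 10 for ct in hv.CALL_TYPES},
                             sample_rate_hz=TEST_RATE, seed=0)
        waveforms, records = hv.generate_colony(spec)
        assert len(records) == 120 and len(waveforms) == 120
        assert len({r.individual_id for r in records}) == 4
        # counts match the spec exactly, per individual and type
        for ct in hv.CALL_TYPES:
            for ind in spec.individual_ids:
                n = sum(1 for r in records
                        if r.call_type == ct and r.individual_id == ind)
                assert n == 10

    def test_imbalanced_counts_respected(self):
        spec = hv.ColonySpec(2, 1, calls_per_type={"trill": [5, 2, 7]},
                             sample_rate_hz=TEST_RATE, seed=1)
        _, records = hv.generate_colony(spec)
        counts = {ind: sum(r.individual_id == ind for r in records)
                  for ind in spec.individual_ids}
        assert counts == {"F01": 5, "F02": 2, "M01": 7}

    def test_fixed_seed_bit_identical(self):
        spec = hv.ColonySpec(1, 1, calls_per_type={"food_call": 3},
                             sample_rate_hz=TEST_RATE, seed=9)
        w1, r1 = hv.generate_colony(spec)
        w2, r2 = hv.generate_colony(spec)
        assert r1 == r2
        assert all(np.array_equal(a.samples, b.samples) for a, b in zip(w1, w2))

    def test_twin_similarity_one_makes_signatures_identical(self):
        spec = hv.ColonySpec(3, 0, calls_per_type={"trill": 1},
                             twin_pairs=[("F01", "F02", 1.0)],
                             sample_rate_hz=TEST_RATE, seed=2)
        prof = hv.colony_profiles(spec)
        assert prof["F01"].base_offsets == prof["F02"].base_offsets

    def test_cross_sex_twins_rejected(self):
        spec = hv.ColonySpec(1, 1, calls_per_type={"trill": 1},
                             twin_pairs=[("F01", "M01", 0.5)],
                             sample_rate_hz=TEST_RATE, seed=2)
        with pytest.raises(ValueError, match="same-sex"):
            hv.generate_colony(spec)

    def test_twins_closer_in_feature_space_than_unrelated(self):
        """Similarity 0.9 twins have a smaller inter-centroid feature
        distance than unrelated same-sex pairs."""
        spec = hv.ColonySpec(4, 0, calls_per_type={"trill": 12},
                             twin_pairs=[("F01", "F02", 0.9)],
                             sample_rate_hz=TEST_RATE, seed=5)
        waveforms, records = hv.generate_colony(spec)
        fm = hv.build_feature_matrix(waveforms, records,
                                     bank=hv.get_bank("reduced"))
        filt = hv.filter_common_features(fm)
        X = filt.values.to_numpy()
        X = (X - X.mean(0)) / np.where(X.std(0) > 0, X.std(0), 1.0)
        cent = {ind: X[(filt.labels["individual_id"] == ind).to_numpy()].mean(0)
                for ind in spec.individual_ids}

        def d(a, b):
            return float(np.linalg.norm(cent[a] - cent[b]))

        unrelated = [d(a, b) for a, b in
                     [("F01", "F03"), ("F01", "F04"), ("F02", "F03"),
                      ("F02", "F04"), ("F03", "F04")]]
        assert d("F01", "F02") < np.mean(unrelated)
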