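"""Tests for artifact removal and partial-sum t-test denoising."""

import numpy as np
import pytest
from scipy import signal as sps

from fhrscreen import FhrGenConfig, generate_trace
from fhrscreen.core import Signal
from fhrscreen.emd import ImfDecomposition, decompose
from fhrscreen.errors import EmptyRetentionError, InvalidInputError
from fhrscreen.preprocess import (NOISE_ORDER_CAP, CleanTraceReport,
                                  NoiseOrder, clean_trace, denoise, despike,
                                  estimate_noise_order, remove_missing_beats)


def _trace(values):
    return Signal(np.asarray(values, dtype=float), 4.0, "t")


class TestRemoveMissingBeats:
    def test_clean_trace_unchanged(self):
        x = 140 + 5 * np.sin(np.arange(100) / 3)
        out, rep = remove_missing_beats(_trace(x))
        assert np.array_equal(out.values, x)
        assert rep.n_missing_removed == 0
        assert rep.usable

    def test_zero_run_excised(self):
        x = np.full(4800, 140.0)
        x[1000:1480] = 0.0
        out, rep = remove_missing_beats(_trace(x))
        assert len(out) == 4320
        assert rep.fraction_missing == pytest.approx(0.1)
        assert rep.n_missing_removed == 480

    def test_out_of_range_counts_as_missing(self):
        x = np.full(200, 140.0)
        x[50:60] = 300.0   # above physiological range
        x[80:85] = 30.0    # below
        out, rep = remove_missing_beats(_trace(x))
        assert len(out) == 185
        assert np.all((out.values >= 50) & (out.values <= 220))

    def test_heavy_dropout_flagged_unusable(self):
        cfg = FhrGenConfig(seed=5, duration_s=300.0, missing_fraction=0.45)
        trace, _ = generate_trace(cfg)
        _, rep = remove_missing_beats(trace)
        assert rep.fraction_missing == pytest.approx(0.45, abs=0.02)
        assert not rep.usable

    def test_short_gap_interpolation_mode(self):
        x = np.full(100, 120.0)
        x[40:44] = 0.0  # 1 s gap at 4 Hz
        out, rep = remove_missing_beats(_trace(x), interpolate_below_s=2.0)
        assert len(out) == 100
        assert rep.n_missing_removed == 0
        assert np.allclose(out.values, 120.0)


class TestDespike:
    def test_smooth_trace_untouched(self):
        x = 140 + 3 * np.sin(np.arange(200) / 5)
        out, n = despike(_trace(x))
        assert n == 0
        assert np.array_equal(out.values, x)

    def test_single_spike_replaced_by_neighbour_mean(self):
        x = np.full(50, 140.0)
        x[25] = 200.0  # 60 bpm jump
        out, n = despike(_trace(x))
        assert n == 1
        assert out.values[25] == pytest.approx(140.0)

    def test_injected_spike_count_recovered(self, rng):
        x = 140 + 2 * np.sin(np.arange(2000) / 7)
        pos = rng.choice(np.arange(10, 1990, 20), size=10, replace=False)
        for p in pos:
            x[p] += 60.0
        out, n = despike(_trace(x))
        assert n == 10

    def test_invalid_threshold(self):
        with pytest.raises(InvalidInputError):
            despike(_trace(np.zeros(10) + 100), jump_bpm=0)


class TestNoiseOrder:
    def test_cap_applied(self):
        with pytest.raises(InvalidInputError):
            NoiseOrder(p_t=5, p_f=5, alpha=0.05)
        no = NoiseOrder(p_t=5, p_f=3, alpha=0.05)
        assert no.p_f == 3
        assert NoiseOrder(p_t=2, p_f=2, alpha=0.05).p_f == 2

    def test_estimate_respects_cap(self, clean_fhr_trace):
        dec = decompose(clean_fhr_trace)
        order = estimate_noise_order(dec)
        assert order.p_f <= NOISE_ORDER_CAP
        assert order.p_f == min(order.p_t, NOISE_ORDER_CAP)

    def test_first_rejection_sets_pt(self):
        # c1 zero-mean noise, c2 strongly offset: partial sum c1 accepts,
        # c1+c2 rejects, so P_t = 1.
        r = np.random.default_rng(3)
        c1 = r.normal(0, 1, 2000)
        c1 -= c1.mean()
        c2 = np.full(2000, 5.0)
        dec = ImfDecomposition(imfs=[c1, c2], residue=np.zeros(2000))
        order = estimate_noise_order(dec)
        assert order.p_t == 1
        assert order.p_f == 1

    def test_immediate_rejection_gives_zero(self):
        dec = ImfDecomposition(imfs=[np.full(500, 2.0)],
                               residue=np.zeros(500))
        order = estimate_noise_order(dec)
        assert order.p_t == 0

    def test_invalid_alpha(self, clean_fhr_trace):
        dec = decompose(clean_fhr_trace, max_imfs=2)
        with pytest.raises(InvalidInputError):
            estimate_noise_order(dec, alpha=0.7)

    def test_noise_imfs_rarely_rejected_monte_carlo(self):
        # Zero-mean white noise on a strong slow trend: the partial sums of
        # the first (noise) IMFs should fail to reject H0 in >= 90% of
        # replicates.
        ok = 0
        for seed in range(50):
            r = np.random.default_rng(seed)
            t = np.arange(1024) / 4.0
            x = 140 + 20 * np.sin(2 * np.pi * 0.01 * t) + r.normal(0, 1, 1024)
            dec = decompose(Signal(x, 4.0, f"mc{seed}"))
            order = estimate_noise_order(dec, alpha=0.05)
            ok += int(order.p_t >= 1)
        assert ok >= 45


class TestDenoise:
    def test_pf_zero_keeps_everything(self, clean_fhr_trace):
        dec = decompose(clean_fhr_trace)
        den, retained = denoise(dec, NoiseOrder(0, 0, 0.05))
        assert len(retained) == dec.n_imfs_total
        assert np.allclose(den, dec.reconstruct(), rtol=1e-10)

    def test_partition_identity(self, clean_fhr_trace):
        dec = decompose(clean_fhr_trace)
        order = estimate_noise_order(dec)
        den, retained = denoise(dec, order)
        removed = dec.components[:order.p_f]
        total = den + (np.sum(removed, axis=0) if removed else 0.0)
        x = clean_fhr_trace.values
        assert np.max(np.abs(total - x)) <= 1e-8 * np.max(np.abs(x))

    def test_retained_is_contiguous_suffix(self, clean_fhr_trace):
        dec = decompose(clean_fhr_trace)
        order = estimate_noise_order(dec)
        _, retained = denoise(dec, order)
        comps = dec.components
        assert len(retained) == len(comps) - order.p_f
        for a, b in zip(retained, comps[order.p_f:]):
            assert a is b

    def test_pf_two_on_twelve_components(self):
        r = np.random.default_rng(1)
        comps = [r.normal(size=256) for _ in range(11)]
        dec = ImfDecomposition(imfs=comps, residue=r.normal(size=256))
        _, retained = denoise(dec, NoiseOrder(2, 2, 0.05))
        assert dec.n_imfs_total == 12
        assert len(retained) == 10

    def test_discarding_everything_rejected(self):
        dec = ImfDecomposition(imfs=[np.zeros(64), np.zeros(64)],
                               residue=np.zeros(64))
        with pytest.raises(EmptyRetentionError):
            denoise(dec, NoiseOrder(3, 3, 0.05))

    def test_denoising_improves_correlation_with_clean_signal(self):
        # Smooth (low-variability) traces plus high-frequency noise at
        # SNR 10 dB: stripping the noise IMFs should move the trace closer
        # to the clean signal in nearly every replicate.
        wins = 0
        b, a = sps.butter(4, 1.2 / 2.0, btype="high")
        for seed in range(20):
            r = np.random.default_rng(seed)
            cfg = FhrGenConfig(seed=seed, duration_s=300.0,
                               missing_fraction=0.0, spike_rate_per_min=0.0,
                               variability_bpm=3.0, n_decelerations=2,
                               n_accelerations=1)
            clean, _ = generate_trace(cfg)
            x = clean.values
            power = np.mean((x - x.mean()) ** 2)
            noise = sps.filtfilt(b, a, r.normal(0, 1, x.size))
            noise *= np.sqrt(power / 10) / noise.std()
            noisy = x + noise
            dec = decompose(Signal(noisy, 4.0, f"snr{seed}"))
            den, _ = denoise(dec, estimate_noise_order(dec))
            wins += int(np.corrcoef(den, x)[0, 1]
                        > np.corrcoef(noisy, x)[0, 1])
        assert wins >= 18


class TestCleanTrace:
    def test_despike_then_excise(self):
        x = np.full(400, 150.0)
        x[100] = 210.0        # spike, within range
        x[200:240] = 0.0      # dropout run
        out, rep = clean_trace(_trace(x))
        assert rep.n_spikes_corrected == 1
        assert rep.n_missing_removed == 40
        assert len(out) == 360
        assert rep.usable

    def test_usability_report_round_trip_dict(self):
        rep = CleanTraceReport(10, 0.1, 2, True)
        d = rep.to_dict()
        assert d["usable"] and d["n_missing_removed"] == 10
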