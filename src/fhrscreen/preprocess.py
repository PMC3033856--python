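"""FHR artifact removal and EMD-domain denoising.

Doppler-derived FHR traces suffer two characteristic artifacts: *missing
beats* (dropouts, recorded as 0 bpm or physiologically impossible values)
caused by transducer displacement, and single-sample *spikes* from
autocorrelation errors.  Dropouts can reach 20-40% of the samples; a trace
losing more than the usability cutoff is rejected outright.

After artifact removal the trace is decomposed by EMD and the lowest-order
(fastest) IMFs, which carry high-frequency noise and have zero mean, are
identified with a one-sample t-test on partial sums: for M = 1, 2, ... the
mean of c_1 + ... + c_M is tested against zero until the first significant
deviation.  P_t is the largest M before that rejection, and the number of
components actually dropped is capped, P_f = min(P_t, 3), to avoid
over-smoothing.  The denoised trace is the partial reconstruction over the
retained components c_{P_f+1}..c_{N_f} (residue included).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import BPM_MAX, BPM_MIN, Signal
from .emd import ImfDecomposition
from .errors import EmptyRetentionError, InvalidInputError

#: Traces losing more than this fraction to dropouts are unusable.
DEFAULT_USABILITY_CUTOFF = 0.4

#: Spike detection threshold: a sample deviating from both neighbours by
#: more than this many bpm is an artifact.
DEFAULT_JUMP_BPM = 25.0

#: Significance level of the noise-order t-test.
DEFAULT_ALPHA = 0.05

#: Hard cap on the number of IMFs discarded as noise.
NOISE_ORDER_CAP = 3


@dataclass
class CleanTraceReport:
    """Disposition of one trace after artifact removal."""

    n_missing_removed: int
    fraction_missing: float
    n_spikes_corrected: int
    usable: bool

    def to_dict(self) -> dict:
        return {
            "n_missing_removed": self.n_missing_removed,
            "fraction_missing": round(self.fraction_missing, 6),
            "n_spikes_corrected": self.n_spikes_corrected,
            "usable": self.usable,
        }


@dataclass
class NoiseOrder:
    """t-test noise order P_t and the capped final order P_f = min(P_t, 3)."""

    p_t: int
    p_f: int
    alpha: float

    def __post_init__(self) -> None:
        if self.p_f > min(self.p_t, NOISE_ORDER_CAP):
            raise InvalidInputError("p_f must equal min(p_t, 3)")


def missing_mask(values, bpm_min: float = BPM_MIN,
                 bpm_max: float = BPM_MAX) -> np.ndarray:
    """True where a sample is a missing-beat sentinel (0 bpm or out of the
    physiological range)."""
    x = np.asarray(values, dtype=float)
    return (x == 0) | (x < bpm_min) | (x > bpm_max) | ~np.isfinite(x)


def remove_missing_beats(raw: Signal, bpm_min: float = BPM_MIN,
                         bpm_max: float = BPM_MAX,
                         usability_cutoff: float = DEFAULT_USABILITY_CUTOFF,
                         interpolate_below_s: float = 0.0,
                         ) -> tuple[Signal, CleanTraceReport]:
    """Excise missing-beat runs and report the trace's usability.

    Maximal runs of missing/out-of-range samples are removed recursively
    (the first bad run is excised and the procedure recurses on the
    concatenated remainder) so the output holds only in-range samples.
    With ``interpolate_below_s`` > 0, runs no longer than that many seconds
    are bridged by linear interpolation instead of excision.

    The report flags the trace unusable when the missing fraction exceeds
    ``usability_cutoff`` (default 0.4, beyond the regime dropout normally
    reaches); callers should not analyse unusable traces further.
    """
    x = raw.values.copy()
    n_total = x.size
    if n_total == 0:
        raise InvalidInputError("empty trace")
    if interpolate_below_s > 0:
        x = _bridge_short_runs(x, raw.sampling_rate, interpolate_below_s,
                               bpm_min, bpm_max)
    cleaned = _excise(x, bpm_min, bpm_max)
    n_removed = n_total - cleaned.size
    fraction = n_removed / n_total
    report = CleanTraceReport(
        n_missing_removed=n_removed,
        fraction_missing=fraction,
        n_spikes_corrected=0,
        usable=fraction <= usability_cutoff,
    )
    return raw.replace_values(cleaned), report


def _excise(x: np.ndarray, bpm_min: float, bpm_max: float) -> np.ndarray:
    """Recursively remove the first maximal missing run and concatenate."""
    bad = missing_mask(x, bpm_min, bpm_max)
    if not bad.any():
        return x
    start = int(np.argmax(bad))
    after = bad[start:]
    run_end = start + (int(np.argmin(after)) if not after.all() else after.size)
    return _excise(np.concatenate([x[:start], x[run_end:]]), bpm_min, bpm_max)


def _bridge_short_runs(x, fs, max_gap_s, bpm_min, bpm_max):
    bad = missing_mask(x, bpm_min, bpm_max)
    if not bad.any() or bad.all():
        return x
    out = x.copy()
    idx = np.arange(x.size)
    edges = np.flatnonzero(np.diff(np.concatenate([[0], bad.view(np.int8), [0]])))
    for start, stop in zip(edges[::2], edges[1::2]):
        if (stop - start) / fs <= max_gap_s and start > 0 and stop < x.size:
            out[start:stop] = np.interp(idx[start:stop],
                                        [start - 1, stop], [x[start - 1], x[stop]])
    return out


def despike(trace: Signal, jump_bpm: float = DEFAULT_JUMP_BPM,
            ) -> tuple[Signal, int]:
    """Replace single-sample spikes by the mean of their neighbours.

    A sample is a spike when it deviates from *both* neighbours, in the
    same direction, by more than ``jump_bpm``.  Endpoints are left alone.
    """
    if not jump_bpm > 0:
        raise InvalidInputError("jump_bpm must be positive")
    x = trace.values
    if x.size < 3:
        return trace.replace_values(x.copy()), 0
    left = x[1:-1] - x[:-2]
    right = x[1:-1] - x[2:]
    spikes = ((left > jump_bpm) & (right > jump_bpm)) | (
        (left < -jump_bpm) & (right < -jump_bpm))
    out = x.copy()
    pos = np.flatnonzero(spikes) + 1
    out[pos] = 0.5 * (x[pos - 1] + x[pos + 1])
    return trace.replace_values(out), int(pos.size)


def estimate_noise_order(dec: ImfDecomposition,
                         alpha: float = DEFAULT_ALPHA) -> NoiseOrder:
    """Noise order of a decomposition via the partial-sum t-test.

    For M = 1, 2, ... a two-sided one-sample t-test asks whether the mean
    of the partial sum c_1 + ... + c_M (over samples, treated as
    independent) deviates from zero.  P_t is the largest M before the
    first rejection at level ``alpha``; if even M = 1 rejects, P_t = 0,
    and if no partial sum rejects, P_t equals the number of IMFs.  The
    final order is capped: P_f = min(P_t, 3).
    """
    if not 0 < alpha < 0.5:
        raise InvalidInputError("alpha must lie in (0, 0.5)")
    if dec.n_imfs < 1:
        p_t = 0
    else:
        p_t = dec.n_imfs
        partial = np.zeros_like(dec.residue)
        for m, c in enumerate(dec.imfs, start=1):
            partial = partial + c
            res = stats.ttest_1samp(partial, popmean=0.0)
            if np.isfinite(res.pvalue) and res.pvalue < alpha:
                p_t = m - 1
                break
    return NoiseOrder(p_t=p_t, p_f=min(p_t, NOISE_ORDER_CAP), alpha=alpha)


def denoise(dec: ImfDecomposition, order: NoiseOrder,
            ) -> tuple[np.ndarray, list[np.ndarray]]:
    """Partial reconstruction over the retained components.

    Drops the first P_f components (the fastest IMFs) and sums the rest,
    residue included.

    Returns
    -------
    (denoised, retained) : the denoised sample array and the list of
    retained components, still ordered fast to slow.
    """
    components = dec.components
    if order.p_f >= len(components):
        raise EmptyRetentionError(
            f"P_f={order.p_f} would discard all {len(components)} components"
        )
    retained = components[order.p_f:]
    denoised = np.sum(retained, axis=0)
    return denoised, retained


def clean_trace(raw: Signal, jump_bpm: float = DEFAULT_JUMP_BPM,
                bpm_min: float = BPM_MIN, bpm_max: float = BPM_MAX,
                usability_cutoff: float = DEFAULT_USABILITY_CUTOFF,
                interpolate_below_s: float = 0.0,
                ) -> tuple[Signal, CleanTraceReport]:
    """Despike then remove missing beats, merging the two reports."""
    despiked, n_spikes = despike(raw, jump_bpm=jump_bpm)
    cleaned, report = remove_missing_beats(
        despiked, bpm_min=bpm_min, bpm_max=bpm_max,
        usability_cutoff=usability_cutoff,
        interpolate_below_s=interpolate_below_s)
    report.n_spikes_corrected = n_spikes
    return cleaned, report
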