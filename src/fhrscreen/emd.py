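"""Empirical mode decomposition by sifting.

EMD decomposes a nonlinear, non-stationary series x(t) into a small number
of intrinsic mode functions (IMFs) c_1..c_N plus a residue r_N,

    x(t) = sum_i c_i(t) + r_N(t),

without a prescribed basis.  One IMF is extracted by *sifting*: the local
maxima and minima of the current iterate are joined by cubic-spline
envelopes, the envelope mean is subtracted, and the step repeats until the
sum-of-difference between successive iterates,

    S_D = sum_t |q_{k-1}(t) - q_k(t)|^2 / q_{k-1}(t)^2,

falls below a threshold (conventionally 0.2-0.3) and the iterate satisfies
the IMF condition (extrema and zero-crossing counts differ by at most one).
Lower-order IMFs carry the fastest oscillations; each successive IMF is
slower, and the final residue is the trend.

Boundary handling mirrors the two extrema nearest each end about the end
point before spline fitting, which suppresses envelope end swings; splines
use natural end conditions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import solveh_banded

from .core import Signal
from .errors import InvalidInputError, MonotonicSignalError

#: Default sum-of-difference stopping threshold (conservative end of the
#: conventional 0.2-0.3 range).
DEFAULT_SD_THRESHOLD = 0.2

#: Safety cap on sifting passes per IMF.  On long traces the per-sample
#: sum-of-difference is dominated by near-zero denominators and rarely
#: crosses the threshold, so this cap is frequently the binding stop.
DEFAULT_MAX_ITER = 100

#: Guard against division by ~0 in the S_D denominator.
_SD_DENOM_GUARD = 1e-12


def find_extrema(values) -> tuple[np.ndarray, np.ndarray]:
    """Locate interior local maxima and minima.

    A sample is a maximum (minimum) when it exceeds (is below) both
    neighbours; a plateau of equal values flanked by opposite slopes yields
    a single extremum at the plateau midpoint (floor).  Endpoints are never
    extrema.

    Returns
    -------
    (maxima, minima) : pair of int arrays of sample indices.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise InvalidInputError("find_extrema requires at least 3 samples")
    d = np.diff(x)
    nz = np.flatnonzero(d)
    if nz.size < 2:
        return np.array([], dtype=int), np.array([], dtype=int)
    s = np.sign(d[nz])
    turns = np.flatnonzero(s[:-1] != s[1:])
    if turns.size == 0:
        return np.array([], dtype=int), np.array([], dtype=int)
    # Plateau spans from the sample after the last nonzero step to the
    # sample where the next nonzero step starts; midpoint floors ties.
    starts = nz[turns] + 1
    ends = nz[turns + 1]
    idx = (starts + ends) // 2
    is_max = s[turns] > 0
    return idx[is_max], idx[~is_max]


def zero_crossings(values) -> int:
    """Count sign changes, ignoring exact zeros."""
    s = np.sign(np.asarray(values, dtype=float))
    s = s[s != 0]
    if s.size < 2:
        return 0
    return int(np.count_nonzero(s[:-1] != s[1:]))


def is_imf(values) -> bool:
    """IMF condition: |#extrema - #zero-crossings| <= 1."""
    try:
        maxima, minima = find_extrema(values)
    except InvalidInputError:
        return False
    n_ext = maxima.size + minima.size
    return abs(n_ext - zero_crossings(values)) <= 1


def _mirror_knots(idx: np.ndarray, vals: np.ndarray, n: int):
    """Extend extrema knots by mirroring the two nearest about each end."""
    left_k = idx[: min(2, idx.size)]
    right_k = idx[-min(2, idx.size):]
    ext_idx = np.concatenate([-left_k[::-1], idx, 2 * (n - 1) - right_k[::-1]])
    ext_val = np.concatenate(
        [vals[: left_k.size][::-1], vals, vals[-right_k.size:][::-1]]
    )
    # Mirroring an extremum sitting exactly on an endpoint duplicates its
    # abscissa; keep one knot per position.
    ext_idx, keep = np.unique(ext_idx, return_index=True)
    return ext_idx, ext_val[keep]


try:
    from numba import njit as _njit
    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard dependency
    _HAVE_NUMBA = False

    def _njit(*args, **kwargs):
        def deco(f):
            return f
        return deco


@_njit(cache=True)
def _natural_spline_grid(xk, yk, n):  # pragma: no cover - exercised via wrapper
    """Natural cubic spline through (xk, yk) sampled at t = 0..n-1.

    Thomas solve for the interior second derivatives followed by a linear
    walk over the (sorted) sample grid; both O(len(xk) + n).
    """
    k = xk.size
    out = np.empty(n)
    if k == 2:
        s = (yk[1] - yk[0]) / (xk[1] - xk[0])
        for j in range(n):
            out[j] = yk[0] + s * (j - xk[0])
        return out
    m = np.zeros(k)
    if k > 2:
        # Tridiagonal system, natural end conditions M_0 = M_{k-1} = 0.
        a = np.empty(k - 2)
        b = np.empty(k - 2)
        c = np.empty(k - 2)
        d = np.empty(k - 2)
        for i in range(k - 2):
            h0 = xk[i + 1] - xk[i]
            h1 = xk[i + 2] - xk[i + 1]
            a[i] = h0
            b[i] = 2.0 * (h0 + h1)
            c[i] = h1
            d[i] = 6.0 * ((yk[i + 2] - yk[i + 1]) / h1 - (yk[i + 1] - yk[i]) / h0)
        for i in range(1, k - 2):
            w = a[i] / b[i - 1]
            b[i] -= w * c[i - 1]
            d[i] -= w * d[i - 1]
        m[k - 2] = d[k - 3] / b[k - 3]
        for i in range(k - 4, -1, -1):
            m[i + 1] = (d[i] - c[i] * m[i + 2]) / b[i]
    i = 0
    for j in range(n):
        t = float(j)
        while i < k - 2 and xk[i + 1] <= t:
            i += 1
        h = xk[i + 1] - xk[i]
        aa = xk[i + 1] - t
        bb = t - xk[i]
        out[j] = (m[i] * aa ** 3 + m[i + 1] * bb ** 3) / (6.0 * h) + \
            (yk[i] / h - m[i] * h / 6.0) * aa + \
            (yk[i + 1] / h - m[i + 1] * h / 6.0) * bb
    return out


def _natural_spline(xk: np.ndarray, yk: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Natural cubic spline through (xk, yk) evaluated at t.

    Equivalent to ``CubicSpline(xk, yk, bc_type="natural")(t)`` but without
    the constructor overhead; sifting calls this thousands of times per
    trace.  ``t`` must lie inside [xk[0], xk[-1]].
    """
    n = xk.size
    if n == 2:
        return np.interp(t, xk, yk)
    h = np.diff(xk).astype(float)
    slope = np.diff(yk) / h
    # Tridiagonal system for interior second derivatives (M_0 = M_{n-1} = 0).
    diag = 2.0 * (h[:-1] + h[1:])
    off = h[1:-1]
    rhs = 6.0 * np.diff(slope)
    ab = np.zeros((2, n - 2))
    ab[0, 1:] = off
    ab[1] = diag
    m = np.zeros(n)
    m[1:-1] = solveh_banded(ab, rhs, lower=False)
    i = np.clip(np.searchsorted(xk, t, side="right") - 1, 0, n - 2)
    hi = h[i]
    a = xk[i + 1] - t
    b = t - xk[i]
    return (m[i] * a ** 3 + m[i + 1] * b ** 3) / (6.0 * hi) + \
        (yk[i] / hi - m[i] * hi / 6.0) * a + \
        (yk[i + 1] / hi - m[i + 1] * hi / 6.0) * b


def build_envelopes(values, maxima, minima):
    """Upper/lower cubic-spline envelopes and their pointwise mean.

    The envelopes interpolate the (boundary-mirrored) maxima and minima with
    natural cubic splines, evaluated at every sample.

    Returns
    -------
    (e_up, e_low, m) : three arrays the length of ``values``.
    """
    x = np.asarray(values, dtype=float)
    maxima = np.asarray(maxima, dtype=int)
    minima = np.asarray(minima, dtype=int)
    if maxima.size < 2 or minima.size < 2:
        raise MonotonicSignalError(
            "fewer than two maxima or minima: monotonic component"
        )
    n = x.size
    t = np.arange(n, dtype=float)
    up_i, up_v = _mirror_knots(maxima, x[maxima], n)
    lo_i, lo_v = _mirror_knots(minima, x[minima], n)
    if _HAVE_NUMBA:
        e_up = _natural_spline_grid(up_i.astype(float), up_v, n)
        e_low = _natural_spline_grid(lo_i.astype(float), lo_v, n)
    else:
        e_up = _natural_spline(up_i.astype(float), up_v, t)
        e_low = _natural_spline(lo_i.astype(float), lo_v, t)
    return e_up, e_low, 0.5 * (e_up + e_low)


def sd_criterion(q_prev, q_curr) -> float:
    """Sum-of-difference between successive sifting iterates.

    Terms whose denominator q_{k-1}(t)^2 falls below 1e-12 are excluded;
    if every term is excluded the sentinel +inf is returned.
    """
    a = np.asarray(q_prev, dtype=float)
    b = np.asarray(q_curr, dtype=float)
    if a.shape != b.shape:
        raise InvalidInputError("sd_criterion requires equal-length iterates")
    denom = a * a
    keep = denom >= _SD_DENOM_GUARD
    if not keep.any():
        return math.inf
    diff = a[keep] - b[keep]
    return float(np.sum(diff * diff / denom[keep]))


def sift_imf(values, threshold: float = DEFAULT_SD_THRESHOLD,
             max_iter: int = DEFAULT_MAX_ITER):
    """Extract one IMF from ``values`` by iterative envelope-mean removal.

    Iterates q <- q - m(q) until the sum-of-difference drops below
    ``threshold`` and the iterate satisfies the IMF condition, or
    ``max_iter`` sifting passes have run.

    Returns
    -------
    (imf, residual) : the accepted IMF and ``values - imf``.

    Raises
    ------
    MonotonicSignalError
        If the input has fewer than two maxima or two minima.
    """
    if not 0 < threshold <= 1:
        raise InvalidInputError("threshold must lie in (0, 1]")
    if max_iter < 1:
        raise InvalidInputError("max_iter must be >= 1")
    x = np.asarray(values, dtype=float)
    q = x.copy()
    maxima, minima = find_extrema(q)
    if maxima.size < 2 or minima.size < 2:
        raise MonotonicSignalError("no IMF extractable from monotonic input")
    # Over-sifting can re-break the extrema/zero-crossing condition
    # (envelope overshoot spawns extrema without sign changes), so the
    # last condition-satisfying iterate is remembered and restored if the
    # budget runs out on an invalid one.
    last_valid = None
    for _ in range(max_iter):
        _, _, m = build_envelopes(q, maxima, minima)
        q_next = q - m
        sd = sd_criterion(q, q_next)
        q = q_next
        try:
            maxima, minima = find_extrema(q)
        except InvalidInputError:
            break
        if maxima.size < 2 or minima.size < 2:
            # Over-sifted into a monotonic iterate; accept what we have.
            break
        if abs(maxima.size + minima.size - zero_crossings(q)) <= 1:
            last_valid = q
            if sd < threshold:
                break
    if last_valid is not None:
        q = last_valid
    return q, x - q


@dataclass
class ImfDecomposition:
    """Ordered IMFs plus the final residue of one signal.

    ``components`` (IMFs followed by the residue) is the N_f-element list
    that denoising and feature extraction index into; the residue counts as
    the slowest component.
    """

    imfs: list[np.ndarray]
    residue: np.ndarray
    sifting_threshold: float = DEFAULT_SD_THRESHOLD
    signal_id: str = ""

    @property
    def n_imfs(self) -> int:
        """Number of proper IMFs, excluding the residue."""
        return len(self.imfs)

    @property
    def n_imfs_total(self) -> int:
        """Total components including the residue (N_f)."""
        return len(self.imfs) + 1

    @property
    def components(self) -> list[np.ndarray]:
        """IMFs ordered fast to slow, with the residue last."""
        return [*self.imfs, self.residue]

    def reconstruct(self) -> np.ndarray:
        """Element-wise sum of every IMF and the residue."""
        out = self.residue.copy()
        for c in self.imfs:
            out += c
        return out

    def to_frame(self) -> pd.DataFrame:
        cols = {f"imf_{i + 1}": c for i, c in enumerate(self.imfs)}
        cols["residue"] = self.residue
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        """Delimited-text export, one column per IMF plus the residue."""
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, sifting_threshold: float = DEFAULT_SD_THRESHOLD,
                 signal_id: str = "") -> "ImfDecomposition":
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
        if "residue" not in df.columns:
            raise InvalidInputError("decomposition file lacks a residue column")
        imf_cols = [c for c in df.columns if c.startswith("imf_")]
        imf_cols.sort(key=lambda c: int(c.split("_")[1]))
        return cls(
            imfs=[df[c].to_numpy(dtype=float) for c in imf_cols],
            residue=df["residue"].to_numpy(dtype=float),
            sifting_threshold=sifting_threshold,
            signal_id=signal_id,
        )


def default_max_imfs(n_samples: int) -> int:
    return max(1, int(math.floor(math.log2(n_samples))))


def decompose(signal: Signal, threshold: float = DEFAULT_SD_THRESHOLD,
              max_imfs: int | None = None,
              max_iter: int = DEFAULT_MAX_ITER) -> ImfDecomposition:
    """Full EMD of a signal into IMFs and a residue.

    IMFs are peeled off successive residuals until the residual has fewer
    than two maxima or two minima (it is then the final residue), or
    ``max_imfs`` have been extracted.  The reconstruction identity
    x = sum(IMFs) + residue holds to floating-point round-off because each
    residual is formed by exact subtraction.
    """
    signal.validate_for_decomposition()
    if max_imfs is None:
        max_imfs = default_max_imfs(len(signal))
    residual = signal.values.copy()
    imfs: list[np.ndarray] = []
    while len(imfs) < max_imfs:
        try:
            maxima, minima = find_extrema(residual)
        except InvalidInputError:
            break
        if maxima.size < 2 or minima.size < 2:
            break
        imf, residual = sift_imf(residual, threshold=threshold,
                                 max_iter=max_iter)
        imfs.append(imf)
    return ImfDecomposition(imfs=imfs, residue=residual,
                            sifting_threshold=threshold,
                            signal_id=signal.id)
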