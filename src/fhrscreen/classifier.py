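"""Class-weighted soft-margin SVM with an RBF kernel.

The screening problem is imbalanced (twice as many at-risk as normal
records in the reference design), so the soft-margin penalty is split per
class: errors on class +1 (normal) cost C+ and errors on class -1
(at risk) cost C-, with the ratio C+/C- set to the inverse ratio of the
class cardinalities, C+/C- = n-/n+.  Features are affinely scaled to
[-1, +1] using training-set minima/maxima before fitting, and the same
transform is applied at prediction time.

The dual quadratic programme is solved by scikit-learn's SVC; the fitted
support vectors, dual coefficients alpha_i*d_i and bias b are extracted and
the decision function

    f(x) = sign( sum_i d_i alpha_i K(x_i, x) + b ),   K = exp(-gamma ||a-b||^2)

is evaluated by this module's own kernel path, so a model serialised to
text and reloaded reproduces predictions bit-identically.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .errors import InvalidInputError

logger = logging.getLogger(__name__)

#: Operating point found by grid search in the reference design.
DEFAULT_C = 4.0
DEFAULT_GAMMA = 2.0

#: QP solver tolerance.
DEFAULT_TOL = 1e-3


def rbf_kernel(a, b, gamma: float) -> float:
    """Radial basis function kernel K(a, b) = exp(-gamma * ||a - b||^2)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise InvalidInputError("kernel arguments must share dimensionality")
    if not gamma > 0:
        raise InvalidInputError("gamma must be positive")
    d = a - b
    return float(np.exp(-gamma * np.dot(d, d)))


def rbf_gram(A, B, gamma: float) -> np.ndarray:
    """Kernel matrix K[i, j] = exp(-gamma * ||A_i - B_j||^2)."""
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    if A.shape[1] != B.shape[1]:
        raise InvalidInputError("kernel arguments must share dimensionality")
    sq = (np.sum(A * A, axis=1)[:, None] + np.sum(B * B, axis=1)[None, :]
          - 2.0 * A @ B.T)
    np.maximum(sq, 0.0, out=sq)
    return np.exp(-gamma * sq)


@dataclass
class ScalingTransform:
    """Per-feature affine map of training min/max onto [lo, hi].

    Degenerate features (min == max on the training set) map to the
    interval midpoint.  The same transform must be applied to training and
    test data.
    """

    mins: np.ndarray
    maxs: np.ndarray
    lo: float = -1.0
    hi: float = 1.0

    @classmethod
    def fit(cls, X, lo: float = -1.0, hi: float = 1.0) -> "ScalingTransform":
        X = np.asarray(X, dtype=float)
        return cls(mins=X.min(axis=0), maxs=X.max(axis=0), lo=lo, hi=hi)

    def transform(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        span = self.maxs - self.mins
        mid = 0.5 * (self.lo + self.hi)
        out = np.full_like(X, mid)
        ok = span > 0
        out[:, ok] = self.lo + (X[:, ok] - self.mins[ok]) * (
            (self.hi - self.lo) / span[ok])
        return out


def class_weights(labels) -> dict[int, float]:
    """Per-class penalty multipliers with C+/C- = n-/n+.

    Weights are n_total / (2 * n_class), so a 20 normal / 40 at-risk
    training set yields C+/C- = 1.5/0.75 = 2, the inverse cardinality
    ratio.
    """
    y = np.asarray(labels, dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    n = y.size
    return {int(c): n / (2.0 * cnt) for c, cnt in zip(classes, counts)}


@dataclass
class SvmModel:
    """A trained class-weighted RBF-SVM decision function."""

    support_vectors: np.ndarray      # scaled feature space
    dual_coef: np.ndarray            # alpha_i * d_i
    bias: float
    gamma: float
    C: float
    weights: dict[int, float]        # per-class penalty multipliers
    scaling: ScalingTransform
    support_labels: np.ndarray = field(default=None)

    def decision_function(self, X) -> np.ndarray:
        """sum_i d_i alpha_i K(x_i, x) + b on raw (unscaled) inputs."""
        Z = self.scaling.transform(X)
        # Test points may extrapolate slightly past [-1, 1]; only inputs
        # that look unscaled altogether warrant a warning.
        if np.mean(np.abs(Z) > 3.0) > 0.5:
            logger.warning(
                "most inputs fall far outside the training range after "
                "scaling; were unscaled features passed?")
        K = rbf_gram(self.support_vectors, Z, self.gamma)
        return self.dual_coef @ K + self.bias

    def predict(self, X) -> np.ndarray:
        """Class labels in {+1, -1}; a decision value of exactly 0 maps
        to +1 (normal)."""
        f = self.decision_function(X)
        return np.where(f >= 0, 1, -1)

    # -- persistence ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "support_vectors": self.support_vectors.tolist(),
            "dual_coef": self.dual_coef.tolist(),
            "bias": self.bias,
            "gamma": self.gamma,
            "C": self.C,
            "weights": {str(k): v for k, v in self.weights.items()},
            "scaling": {
                "mins": self.scaling.mins.tolist(),
                "maxs": self.scaling.maxs.tolist(),
                "lo": self.scaling.lo,
                "hi": self.scaling.hi,
            },
            "support_labels": (self.support_labels.tolist()
                               if self.support_labels is not None else None),
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "SvmModel":
        sc = d["scaling"]
        return cls(
            support_vectors=np.asarray(d["support_vectors"], dtype=float),
            dual_coef=np.asarray(d["dual_coef"], dtype=float),
            bias=float(d["bias"]),
            gamma=float(d["gamma"]),
            C=float(d["C"]),
            weights={int(k): float(v) for k, v in d["weights"].items()},
            scaling=ScalingTransform(
                mins=np.asarray(sc["mins"], dtype=float),
                maxs=np.asarray(sc["maxs"], dtype=float),
                lo=float(sc["lo"]), hi=float(sc["hi"])),
            support_labels=(np.asarray(d["support_labels"], dtype=int)
                            if d.get("support_labels") is not None else None),
        )

    @classmethod
    def load(cls, path) -> "SvmModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def fit(X, y, C: float = DEFAULT_C, gamma: float = DEFAULT_GAMMA,
        weighted: bool = True, tol: float = DEFAULT_TOL,
        scaling: ScalingTransform | None = None) -> SvmModel:
    """Train the class-weighted RBF SVM.

    The feature scaling is fitted on ``X`` unless an existing transform is
    supplied (cross-validation fits it on each training portion).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    classes = np.unique(y)
    if classes.size < 2:
        raise InvalidInputError("training data must contain both classes")
    if not (C > 0 and gamma > 0):
        raise InvalidInputError("C and gamma must be positive")
    if scaling is None:
        scaling = ScalingTransform.fit(X)
    Z = scaling.transform(X)
    weights = class_weights(y) if weighted else {int(c): 1.0 for c in classes}
    svc = SVC(C=C, kernel="rbf", gamma=gamma, class_weight=weights, tol=tol)
    svc.fit(Z, y)
    return SvmModel(
        support_vectors=svc.support_vectors_.copy(),
        dual_coef=svc.dual_coef_[0].copy(),
        bias=float(svc.intercept_[0]),
        gamma=gamma,
        C=C,
        weights=weights,
        scaling=scaling,
        support_labels=y[svc.support_],
    )


def predict(model: SvmModel, X) -> np.ndarray:
    return model.predict(X)


def _cv_accuracy(X, y, C, gamma, n_folds, seed, weighted=True) -> float:
    """Pooled stratified-CV accuracy with per-fold scaling and weights."""
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    correct = 0
    for tr, te in skf.split(X, y):
        model = fit(X[tr], y[tr], C=C, gamma=gamma, weighted=weighted)
        correct += int(np.sum(model.predict(X[te]) == y[te]))
    return correct / len(y)


def grid_search(X, y, C_grid=None, gamma_grid=None, n_folds: int = 5,
                seed: int = 0, weighted: bool = True, refine: bool = True):
    """Two-pass grid search over (C, gamma) by stratified CV accuracy.

    A coarse pass over exponentially spaced grids (default C = 2^-5..2^15,
    gamma = 2^-15..2^3, two-octave steps) is followed by a half-octave
    refinement around the best cell.  Ties break towards smaller C, then
    smaller gamma.

    Returns
    -------
    (best_C, best_gamma, table) where ``table`` lists
    (C, gamma, cv_accuracy) for every cell evaluated.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if n_folds < 2:
        raise InvalidInputError("n_folds must be >= 2")
    if C_grid is None:
        C_grid = [2.0 ** e for e in range(-5, 16, 2)]
    if gamma_grid is None:
        gamma_grid = [2.0 ** e for e in range(-15, 4, 2)]
    if len(C_grid) == 0 or len(gamma_grid) == 0:
        raise InvalidInputError("grids must be non-empty")

    table: list[tuple[float, float, float]] = []

    def best_over(cs, gs):
        best = None
        for C in sorted(cs):
            for g in sorted(gs):
                acc = _cv_accuracy(X, y, C, g, n_folds, seed, weighted)
                table.append((C, g, acc))
                if best is None or acc > best[2] + 1e-12:
                    best = (C, g, acc)
        return best

    bC, bg, _ = best_over(C_grid, gamma_grid)
    if refine and (len(C_grid) > 1 or len(gamma_grid) > 1):
        ec, eg = np.log2(bC), np.log2(bg)
        fine_C = [2.0 ** e for e in np.arange(ec - 2, ec + 2.01, 0.5)]
        fine_g = [2.0 ** e for e in np.arange(eg - 2, eg + 2.01, 0.5)]
        bC, bg, _ = best_over(fine_C, fine_g)
    return bC, bg, table
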