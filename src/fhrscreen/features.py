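"""Statistical features: standard deviations of retained EMD components.

After denoising, each retained component c_i (i = P_f+1 .. N_f, fast to
slow, residue last) is summarised by its sample standard deviation

    SD(C_i) = sqrt( 1/(N-1) * sum_j (C_{i,j} - mean(C_i))^2 ),

and the vector of these SDs is the trace's feature vector.  The premise is
clinical: at-risk traces show reduced beat-to-beat variability, which
shrinks the SD of the fast retained components.  Because the number of
retained components varies per trace (typically 7-10), the vector has a
fixed width of 10 slots, indexed by *post-cut position* (slot k = k-th
retained component regardless of each trace's P_f); unused slots carry a
pad value and components beyond 10 are dropped from the slow tail.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import Signal
from .errors import InvalidInputError
from . import emd as _emd
from . import preprocess as _pp

logger = logging.getLogger(__name__)

#: Fixed feature-vector width.
MAX_FEATURES = 10

#: Fill for slots beyond the number of retained components.
DEFAULT_PAD = 0.0

LABEL_NORMAL = 1
LABEL_AT_RISK = -1

FEATURE_COLUMNS = [f"sd_{k}" for k in range(1, MAX_FEATURES + 1)]


def component_sd(component) -> float:
    """Sample standard deviation (N-1 denominator) of one component."""
    c = np.asarray(component, dtype=float)
    if c.size < 2:
        raise InvalidInputError("component_sd requires at least 2 samples")
    return float(np.std(c, ddof=1))


@dataclass
class FeatureVector:
    """Up to 10 component SDs plus an optional class label."""

    sds: np.ndarray
    n_components: int
    label: int | None = None

    def __post_init__(self) -> None:
        self.sds = np.asarray(self.sds, dtype=float)
        if self.sds.size != MAX_FEATURES:
            raise InvalidInputError(f"feature vector must have {MAX_FEATURES} slots")
        if not 1 <= self.n_components <= MAX_FEATURES:
            raise InvalidInputError("n_components must lie in [1, 10]")
        if self.label not in (None, LABEL_NORMAL, LABEL_AT_RISK):
            raise InvalidInputError("label must be +1, -1 or None")


def extract_features(retained, label: int | None = None,
                     pad: float = DEFAULT_PAD) -> FeatureVector:
    """Feature vector from the retained components of one trace.

    ``retained`` is the fast-to-slow component list produced by denoising;
    slot k holds SD of the k-th retained component, later slots hold the
    pad value, and components beyond the 10th are dropped.
    """
    if len(retained) == 0:
        raise InvalidInputError("no retained components to featurise")
    kept = retained[:MAX_FEATURES]
    sds = np.full(MAX_FEATURES, pad, dtype=float)
    for k, comp in enumerate(kept):
        sds[k] = component_sd(comp)
    return FeatureVector(sds=sds, n_components=len(kept), label=label)


def process_trace(raw: Signal, label: int | None = None, *,
                  sd_threshold: float = _emd.DEFAULT_SD_THRESHOLD,
                  max_imfs: int | None = None,
                  max_iter: int = _emd.DEFAULT_MAX_ITER,
                  alpha: float = _pp.DEFAULT_ALPHA,
                  jump_bpm: float = _pp.DEFAULT_JUMP_BPM,
                  usability_cutoff: float = _pp.DEFAULT_USABILITY_CUTOFF,
                  pad: float = DEFAULT_PAD):
    """Run one raw trace through the whole chain: despike, dropout removal,
    EMD, noise-order estimation, denoising, feature extraction.

    Returns
    -------
    (FeatureVector | None, CleanTraceReport, NoiseOrder | None)
        The feature vector is None when the trace is unusable.
    """
    cleaned, report = _pp.clean_trace(
        raw, jump_bpm=jump_bpm, usability_cutoff=usability_cutoff)
    if not report.usable:
        return None, report, None
    dec = _emd.decompose(cleaned, threshold=sd_threshold,
                         max_imfs=max_imfs, max_iter=max_iter)
    order = _pp.estimate_noise_order(dec, alpha=alpha)
    _, retained = _pp.denoise(dec, order)
    fv = extract_features(retained, label=label, pad=pad)
    return fv, report, order


def build_dataset(traces, labels=None, **process_kwargs) -> pd.DataFrame:
    """Feature matrix for a collection of traces.

    One row per usable trace, in input order, with columns
    ``sd_1..sd_10, n_components, label`` plus the trace id.  Unusable
    traces are excluded and logged with the reason.
    """
    if labels is None:
        labels = [None] * len(traces)
    if len(labels) != len(traces):
        raise InvalidInputError("labels must match traces in length")
    rows = []
    for trace, label in zip(traces, labels):
        fv, report, _ = process_trace(trace, label=label, **process_kwargs)
        if fv is None:
            logger.warning(
                "trace %s excluded: %.0f%% missing exceeds the usability cutoff",
                trace.id, 100 * report.fraction_missing)
            continue
        row = {"trace_id": trace.id}
        row.update({col: fv.sds[k] for k, col in enumerate(FEATURE_COLUMNS)})
        row["n_components"] = fv.n_components
        row["label"] = fv.label
        rows.append(row)
    columns = ["trace_id", *FEATURE_COLUMNS, "n_components", "label"]
    return pd.DataFrame(rows, columns=columns)


def write_feature_table(df: pd.DataFrame, path, header_comment: str = "") -> None:
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)


def read_feature_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    missing = [c for c in FEATURE_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidInputError(f"feature table lacks columns: {missing}")
    return df


def feature_matrix(df: pd.DataFrame):
    """(X, y) arrays from a feature table; y is None when unlabelled."""
    X = df[FEATURE_COLUMNS].to_numpy(dtype=float)
    y = None
    if "label" in df.columns and df["label"].notna().all() and len(df):
        y = df["label"].to_numpy(dtype=int)
    return X, y
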