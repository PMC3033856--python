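"""Core containers for fetal-heart-rate traces.

An antepartum cardiotocograph records the fetal heart rate (FHR) in beats
per minute, derived by Doppler autocorrelation and emitted by the bedside
monitor as a uniformly sampled series, conventionally at 4 Hz.  The
:class:`Signal` container carries those samples together with the sampling
rate and a provenance label; every stage of the pipeline consumes and
produces this type.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError

#: Default cardiotocograph sampling rate in Hz.
DEFAULT_FS = 4.0

#: Physiological FHR range in bpm; samples outside it are treated as
#: missing-beat dropouts by the preprocessing stage.
BPM_MIN = 50.0
BPM_MAX = 220.0


@dataclass
class Signal:
    """A uniformly sampled real-valued time series.

    Parameters
    ----------
    values : ndarray
        Sample values (bpm for FHR traces, arbitrary units otherwise).
    sampling_rate : float
        Sampling frequency in Hz; must be positive.
    id : str
        Provenance label carried through the pipeline.
    """

    values: np.ndarray
    sampling_rate: float = DEFAULT_FS
    id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise InvalidInputError("signal values must be one-dimensional")
        if not self.sampling_rate > 0:
            raise InvalidInputError("sampling_rate must be positive")

    def __len__(self) -> int:
        return self.values.size

    @property
    def duration_s(self) -> float:
        return self.values.size / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds, starting at 0."""
        return np.arange(self.values.size) / self.sampling_rate

    def replace_values(self, values: np.ndarray, suffix: str = "") -> "Signal":
        """A copy of this signal with new sample values."""
        new_id = f"{self.id}{suffix}" if suffix else self.id
        return Signal(np.asarray(values, dtype=float), self.sampling_rate, new_id)

    def validate_for_decomposition(self) -> None:
        """Check the invariants required before EMD may run."""
        if self.values.size < 8:
            raise InvalidInputError(
                f"signal '{self.id}' has {self.values.size} samples; "
                "decomposition requires at least 8"
            )
        if not np.all(np.isfinite(self.values)):
            raise InvalidInputError(
                f"signal '{self.id}' contains non-finite samples"
            )


#: Alias used where the bpm semantics matter.
FhrTrace = Signal
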