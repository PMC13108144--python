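"""Core trace containers shared across the pipeline.

A :class:`RawTrace` is an uninterpreted PMT time series: alternating
peak segments (cell inside the detection window, so intracellular DNR
fluorescence rides on top of the extracellular background) and valley
segments (background alone).  A :class:`ProcessedTrace` is the
background-subtracted, despiked, normalized intracellular uptake signal
f(t) that the kinetic models are fitted to.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = ["RawTrace", "ProcessedTrace", "TraceValidationError"]


class TraceValidationError(ValueError):
    """A trace violates its structural invariants."""


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise TraceValidationError(f"{name} must be one-dimensional, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        bad = int(np.flatnonzero(~np.isfinite(arr))[0])
        raise TraceValidationError(f"{name} contains a non-finite value at index {bad}")
    return arr


@dataclass
class RawTrace:
    """Time-stamped PMT intensity trace with acquisition metadata.

    Parameters
    ----------
    times
        Sample times in seconds, strictly increasing.
    intensities
        Detector intensities in arbitrary units, finite.
    metadata
        Free-form acquisition metadata.  Recognised keys include
        ``cell_id``, ``condition``, ``t_switch`` (SASCA phase-switch
        time, s), ``normalization_constant`` (a.u.), ``seed`` and
        ``ground_truth`` (present for synthetic traces).
    """

    times: np.ndarray
    intensities: np.ndarray
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = _as_float_array(self.times, "times")
        self.intensities = _as_float_array(self.intensities, "intensities")
        if self.times.size != self.intensities.size:
            raise TraceValidationError(
                f"times ({self.times.size}) and intensities ({self.intensities.size}) "
                "must have equal length"
            )
        if self.times.size >= 2 and not np.all(np.diff(self.times) > 0):
            bad = int(np.flatnonzero(np.diff(self.times) <= 0)[0]) + 1
            raise TraceValidationError(f"times must be strictly increasing (violated at sample {bad})")

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass
class ProcessedTrace:
    """Normalized intracellular uptake signal f(t) after background removal.

    ``times`` are a subset of the raw times (valley-only samples are
    dropped), ``baseline`` is the estimated background at those times,
    and ``f`` is (F_total - F_background) / normalization_constant.
    """

    times: np.ndarray
    f: np.ndarray
    baseline: np.ndarray | None = None
    n_spikes_removed: int = 0
    normalization_constant: float = 1.0
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = _as_float_array(self.times, "times")
        self.f = _as_float_array(self.f, "f")
        if self.times.size != self.f.size:
            raise TraceValidationError("times and f must have equal length")
        if self.baseline is not None:
            self.baseline = _as_float_array(self.baseline, "baseline")
            if self.baseline.size != self.times.size:
                raise TraceValidationError("baseline must align with times")
        if not self.normalization_constant > 0:
            raise TraceValidationError("normalization_constant must be positive")

    def __len__(self) -> int:
        return int(self.times.size)
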