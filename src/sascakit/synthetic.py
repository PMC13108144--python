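"""Synthetic PMT-trace generator with known ground truth.

Emulates the raw signal of a single-cell perfusion uptake experiment:
the retained cell drifts periodically through the detection window, so
the trace alternates between peak segments (background plus scaled
intracellular uptake signal) and valley segments (extracellular
background alone).  Optional additive Gaussian noise, a slow linear
background drift, and isolated single-sample positive spikes complete
the picture.  Every generator is deterministic for a fixed seed, and
the drawn ground truth travels with each trace so downstream stages can
be tested by round trip without any experimental data.

Defaults describe the stated world of the experiments being emulated:
1 s sampling over 3000 s (the fitted rate constants put the uptake
plateau within ~2000-3000 s), a 60 s window-crossing period with 50%
duty, and uptake parameters on the scale of the published single-cell
fits.  They are conventions where the acquisition was not reported, not
measured facts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping

import numpy as np

from .kinetics import eval_one_exp, eval_two_exp
from .trace import RawTrace

__all__ = [
    "GroundTruth",
    "AcquisitionConfig",
    "PhaseSchedule",
    "PopulationSpec",
    "simulate_raw_trace",
    "simulate_sasca_trace",
    "simulate_cohort",
]


@dataclass(frozen=True)
class GroundTruth:
    """True uptake kinetics behind a synthetic trace.

    ``params`` is (P, Q) for ``model_kind='one_exp'`` or (A, B, C, D)
    for ``'two_exp'`` with the fast rate stored first (B >= D).
    Amplitudes are dimensionless normalized fluorescence; rates are 1/s.
    """

    model_kind: str
    params: tuple[float, ...]
    label: str | None = None

    def __post_init__(self) -> None:
        if self.model_kind not in ("one_exp", "two_exp"):
            raise ValueError(f"unknown model kind {self.model_kind!r}")
        n = 2 if self.model_kind == "one_exp" else 4
        if len(self.params) != n:
            raise ValueError(f"{self.model_kind} needs {n} parameters, got {len(self.params)}")
        for name, v in zip("PQ" if n == 2 else "ABCD", self.params):
            if not np.isfinite(v):
                raise ValueError(f"parameter {name} is not finite: {v}")
        amps = self.params[0::2]
        rates = self.params[1::2]
        if any(a < 0 for a in amps):
            raise ValueError(f"amplitudes must be >= 0, got {amps}")
        if any(r <= 0 for r in rates):
            raise ValueError(f"rates must be > 0, got {rates}")
        if self.model_kind == "two_exp" and self.params[1] < self.params[3]:
            raise ValueError("two_exp ground truth must be ordered fast-rate-first (B >= D)")

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        if self.model_kind == "one_exp":
            return eval_one_exp(*self.params, t)
        return eval_two_exp(*self.params, t)

    @property
    def plateau(self) -> float:
        return sum(self.params[0::2])

    def to_dict(self) -> dict:
        return {"model_kind": self.model_kind, "params": list(self.params), "label": self.label}


@dataclass(frozen=True)
class AcquisitionConfig:
    """Acquisition and nuisance-signal parameters for the generator.

    ``window_period``/``window_duty`` control the peak/valley square
    alternation standing in for the cell crossing the detection window;
    ``normalization_constant`` is the extracellular DNR fluorescence
    step (a.u.) that scales the dimensionless uptake signal f(t) onto
    the detector scale.
    """

    duration: float = 3000.0          # s
    sample_interval: float = 1.0      # s
    background_level: float = 100.0   # a.u.
    background_drift_slope: float = 0.0  # a.u./s
    window_period: float = 60.0       # s
    window_duty: float = 0.5          # fraction of period with cell in window
    spike_rate: float = 0.0           # events/s
    spike_amplitude: float = 0.0      # a.u.
    noise_sd: float = 0.0             # a.u.
    normalization_constant: float = 100.0  # a.u.
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.duration > 0:
            raise ValueError("duration must be > 0")
        if not (0 < self.sample_interval < self.duration):
            raise ValueError("sample_interval must be in (0, duration)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (0 < self.window_duty < 1):
            raise ValueError("window_duty must be in (0, 1)")
        if self.spike_rate < 0 or self.spike_amplitude < 0:
            raise ValueError("spike_rate and spike_amplitude must be >= 0")
        if not self.normalization_constant > 0:
            raise ValueError("normalization_constant must be > 0")
        for name in ("duration", "sample_interval", "background_level",
                     "background_drift_slope", "noise_sd"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} is not finite")

    @property
    def times(self) -> np.ndarray:
        return np.arange(0.0, self.duration + 0.5 * self.sample_interval, self.sample_interval)

    def in_window(self, t: np.ndarray) -> np.ndarray:
        """Boolean mask: cell inside the detection window (peak samples)."""
        return np.mod(t, self.window_period) < self.window_duty * self.window_period


@dataclass(frozen=True)
class PhaseSchedule:
    """Two-phase SASCA design: control uptake, then inhibitor uptake.

    After ``t_switch`` the perfusion switches to drug plus inhibitor;
    the clean signal becomes ``phase2_offset + phase2(t - t_switch)``.
    Choosing ``phase2_offset = phase1(t_switch)`` (see
    :meth:`continuous`) makes the trace continuous at the switch.
    """

    t_switch: float
    phase1: GroundTruth
    phase2: GroundTruth
    phase2_offset: float = 0.0

    def __post_init__(self) -> None:
        if not self.t_switch > 0:
            raise ValueError("t_switch must be > 0")
        if self.phase2_offset < 0:
            raise ValueError("phase2_offset must be >= 0")

    @classmethod
    def continuous(cls, t_switch: float, phase1: GroundTruth, phase2: GroundTruth) -> "PhaseSchedule":
        offset = float(phase1.evaluate(np.array([t_switch]))[0])
        return cls(t_switch, phase1, phase2, offset)

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.where(
            t < self.t_switch,
            self.phase1.evaluate(np.maximum(t, 0.0)),
            self.phase2_offset + self.phase2.evaluate(np.maximum(t - self.t_switch, 0.0)),
        )
        return out


@dataclass(frozen=True)
class PopulationSpec:
    """Heterogeneous cohort description.

    Per-parameter spreads are lognormal, specified as (median,
    geometric CV); draws use sigma = ln(1 + gcv), so gcv = 0 collapses
    to identical cells.  Lognormality reflects the positivity and
    right skew of observed single-cell uptake parameters.
    """

    n_cells: int
    model_kind: str
    param_distributions: Mapping[str, tuple[float, float]]
    condition_label: str = ""
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        names = "PQ" if self.model_kind == "one_exp" else "ABCD"
        missing = [n for n in names if n not in self.param_distributions]
        if missing:
            raise ValueError(f"missing distributions for parameters {missing}")
        for name, (median, gcv) in self.param_distributions.items():
            if not median > 0:
                raise ValueError(f"median for {name} must be > 0")
            if gcv < 0:
                raise ValueError(f"geometric CV for {name} must be >= 0")


def _synthesize(clean: Callable[[np.ndarray], np.ndarray], acq: AcquisitionConfig,
                metadata: dict) -> RawTrace:
    """Assemble background + windowed signal + noise + spikes."""
    rng = np.random.default_rng(acq.seed)
    t = acq.times
    background = acq.background_level + acq.background_drift_slope * t
    intensity = background.copy()
    peak = acq.in_window(t)
    intensity[peak] += acq.normalization_constant * clean(t[peak])
    if acq.noise_sd > 0:
        intensity += rng.normal(0.0, acq.noise_sd, size=t.size)
    n_spikes = rng.poisson(acq.spike_rate * acq.duration) if acq.spike_rate > 0 else 0
    if n_spikes > 0:
        idx = rng.choice(t.size, size=min(n_spikes, t.size), replace=False)
        intensity[idx] += acq.spike_amplitude
    meta = {
        "seed": acq.seed,
        "sample_interval_s": acq.sample_interval,
        "window_period_s": acq.window_period,
        "window_duty": acq.window_duty,
        "normalization_constant": acq.normalization_constant,
        "background_level": acq.background_level,
        "background_drift_slope": acq.background_drift_slope,
        "n_spikes_injected": int(n_spikes),
        **metadata,
    }
    return RawTrace(t, intensity, meta)


def simulate_raw_trace(truth: GroundTruth, acq: AcquisitionConfig, *,
                       cell_id: str = "synthetic", condition: str = "") -> RawTrace:
    """Generate one raw PMT-style uptake trace from known kinetics."""
    return _synthesize(
        truth.evaluate, acq,
        {"cell_id": cell_id, "condition": condition, "ground_truth": truth.to_dict()},
    )


def simulate_sasca_trace(schedule: PhaseSchedule, acq: AcquisitionConfig, *,
                         cell_id: str = "synthetic-sasca", condition: str = "sasca") -> RawTrace:
    """Generate a two-phase (control then inhibitor) SASCA trace.

    Requires ``t_switch`` to lie on the sampling grid and strictly
    inside the acquisition window.
    """
    t = acq.times
    if not (0 < schedule.t_switch < acq.duration):
        raise ValueError(
            f"t_switch={schedule.t_switch} must lie strictly inside (0, {acq.duration})"
        )
    on_grid = np.isclose(np.mod(schedule.t_switch, acq.sample_interval), 0.0) or np.isclose(
        np.mod(schedule.t_switch, acq.sample_interval), acq.sample_interval
    )
    if not on_grid:
        raise ValueError(f"t_switch={schedule.t_switch} is not on the sampling grid")
    return _synthesize(
        schedule.evaluate, acq,
        {
            "cell_id": cell_id,
            "condition": condition,
            "t_switch": schedule.t_switch,
            "ground_truth_phase1": schedule.phase1.to_dict(),
            "ground_truth_phase2": schedule.phase2.to_dict(),
            "phase2_offset": schedule.phase2_offset,
        },
    )


def _draw_truth(spec: PopulationSpec, rng: np.random.Generator) -> GroundTruth:
    names = "PQ" if spec.model_kind == "one_exp" else "ABCD"
    params = []
    for name in names:
        median, gcv = spec.param_distributions[name]
        sigma = np.log1p(gcv)
        params.append(float(median * np.exp(sigma * rng.standard_normal())))
    if spec.model_kind == "two_exp" and params[1] < params[3]:
        params = [params[2], params[3], params[0], params[1]]
    return GroundTruth(spec.model_kind, tuple(params))


def simulate_cohort(spec: PopulationSpec, acq: AcquisitionConfig) -> list[tuple[RawTrace, GroundTruth]]:
    """Draw a heterogeneous cohort of cells with recorded ground truth.

    Each cell gets an independent child seed via ``SeedSequence.spawn``,
    so the multiset of drawn parameters depends only on ``spec.seed``
    and the acquisition noise of cell *i* is decoupled from the other
    cells.
    """
    seq = np.random.SeedSequence(spec.seed)
    children = seq.spawn(spec.n_cells)
    out: list[tuple[RawTrace, GroundTruth]] = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        truth = _draw_truth(spec, rng)
        cell_acq = replace(acq, seed=int(rng.integers(0, 2**31 - 1)))
        trace = simulate_raw_trace(
            truth, cell_acq,
            cell_id=f"{spec.condition_label or 'cell'}-{i:03d}",
            condition=spec.condition_label,
        )
        out.append((trace, truth))
    return out
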