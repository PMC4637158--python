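"""Shared monodomain scaffolding: parameters, stimuli and run results.

Both tissue models advance with Godunov operator splitting: the
membrane reaction ODEs are integrated with explicit Euler substeps
``dt_o`` (N_o of them per macro step), then the diffusive coupling is
advanced by one unconditionally stable implicit-Euler step ``dt_p``.

Unit system: μm, ms, mV, μS, nF.  The membrane capacitance per unit
area C_m = 1 μF/cm² = 1e-5 nF/μm² (the single-cell model's value); the
surface-to-volume ratio β = 0.17 μm⁻¹ is the calibrated value at which
the homogeneous tissue conducts at 410 μm/ms along and 130 μm/ms across
the fibers with the frozen gap-junction placement.  Neither parameter
enters the single-cell kinetics (which are per-capacitance); together
they set the ratio between membrane charging and intercellular current,
i.e. the conduction-velocity scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = ["MonodomainParams", "Stimulus", "StimulusProtocol", "SimulationResult",
           "ActivityTracker", "V_ACT_DEFAULT"]

V_ACT_DEFAULT = -60.0   # mV: "activity" / activation-map threshold
AP_UP_DEFAULT = -30.0   # mV: AP counted on upward crossing
AP_REARM_DEFAULT = -60.0  # mV: counter re-arms below this


@dataclass(frozen=True)
class MonodomainParams:
    """Bulk monodomain constants and the split time steps."""

    beta: float = 0.17          # surface-to-volume ratio, μm^-1 (calibrated)
    C_m: float = 1.0e-5         # membrane capacitance, nF/μm^2 (= 1 μF/cm^2)
    dt_o: float = 1e-4          # reaction substep, ms
    dt_p: float = 0.01          # diffusion (macro) step, ms

    def __post_init__(self) -> None:
        if self.beta <= 0 or self.C_m <= 0:
            raise ValueError("beta and C_m must be positive")
        if self.dt_o <= 0 or self.dt_p < self.dt_o:
            raise ValueError("need 0 < dt_o <= dt_p")
        if abs(self.dt_p / self.dt_o - round(self.dt_p / self.dt_o)) > 1e-9:
            raise ValueError("dt_p must be an integer multiple of dt_o")

    @property
    def N_o(self) -> int:
        return int(round(self.dt_p / self.dt_o))

    def alpha(self, h: float) -> float:
        """Per-volume implicit-Euler coefficient βC_m h²/Δt_p (μS/μm)."""
        return self.beta * self.C_m * h * h / self.dt_p


@dataclass
class Stimulus:
    """One rectangular current pulse applied to a set of units."""

    mask: np.ndarray            # boolean over volumes/cells
    start: float                # ms
    duration: float             # ms
    amplitude: float            # pA/pF, depolarizing > 0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("stimulus duration must be positive")
        if not np.any(self.mask):
            raise ValueError("stimulus region is empty")


@dataclass
class StimulusProtocol:
    """A list of pulses; fills the I_stim vector for any time."""

    pulses: list[Stimulus] = field(default_factory=list)
    name: str = "custom"

    def current(self, t: float, out: np.ndarray) -> np.ndarray:
        out[:] = 0.0
        for p in self.pulses:
            if p.start <= t < p.start + p.duration:
                out[p.mask] += p.amplitude
        return out

    @property
    def t_last(self) -> float:
        return max((p.start + p.duration) for p in self.pulses) if self.pulses else 0.0


class ActivityTracker:
    """Online activation map and AP counting with hysteresis.

    Counts one action potential per upward crossing of ``ap_up``
    (default -30 mV), re-armed once the unit falls back below
    ``ap_rearm`` (-60 mV), which prevents double counts on notched
    upstrokes.  Also records the first crossing of the activation
    threshold ``v_act`` per unit and the tissue-wide activity series.
    """

    def __init__(self, n: int, v_act: float = V_ACT_DEFAULT,
                 ap_up: float = AP_UP_DEFAULT, ap_rearm: float = AP_REARM_DEFAULT):
        self.v_act = v_act
        self.ap_up = ap_up
        self.ap_rearm = ap_rearm
        self.activation_time = np.full(n, np.nan)
        self.ap_count = np.zeros(n, dtype=np.int32)
        self.armed = np.ones(n, dtype=bool)
        self.last_active_time = -np.inf
        self.n_active_series: list[int] = []
        self.times: list[float] = []

    def update(self, t: float, V: np.ndarray) -> None:
        act = V >= self.v_act
        newly = act & np.isnan(self.activation_time)
        self.activation_time[newly] = t
        fire = self.armed & (V >= self.ap_up)
        self.ap_count[fire] += 1
        self.armed = np.where(fire, False, self.armed | (V <= self.ap_rearm))
        n_act = int(act.sum())
        if n_act:
            self.last_active_time = t
        self.times.append(t)
        self.n_active_series.append(n_act)


@dataclass
class SimulationResult:
    """Time-stamped voltage output of one tissue run.

    ``probe_traces`` holds full-Δt_p-resolution voltages at the probe
    units; snapshots are optional coarser V fields.  The activity
    tracker summarises activation times, AP counts and the tissue-wide
    active-unit series used by reentry detection and classification.
    """

    times: np.ndarray                   # macro-step times, ms
    probe_idx: np.ndarray
    probe_traces: np.ndarray            # (n_probes, n_times)
    tracker: ActivityTracker
    snapshot_times: np.ndarray
    snapshots: list[np.ndarray]
    T_end: float
    metadata: dict

    @property
    def activation_map(self) -> np.ndarray:
        return self.tracker.activation_time

    @property
    def n_active_series(self) -> np.ndarray:
        return np.asarray(self.tracker.n_active_series)

    def active_at(self, t: float) -> bool:
        """Any unit above the activity threshold at (the step nearest) t."""
        times = np.asarray(self.tracker.times)
        if t > times[-1] + 1e-9:
            if self.metadata.get("stopped_quiet_at") is not None:
                return False  # run ended early because the tissue was at rest
            raise ValueError(f"simulation ended at {times[-1]} ms, before {t} ms")
        i = int(np.argmin(np.abs(times - t)))
        return self.tracker.n_active_series[i] > 0

    def final_V(self) -> np.ndarray:
        return self.metadata["V_final"]


def run_split_loop(
    V: np.ndarray,
    eta: np.ndarray,
    stepper: Callable,
    diffusion_solve: Callable[[np.ndarray], np.ndarray],
    params: MonodomainParams,
    protocol: StimulusProtocol,
    T_end: float,
    probe_idx: Sequence[int],
    tracker: ActivityTracker,
    snapshot_every: float | None = None,
    metadata: dict | None = None,
    stop_when_quiet: float | None = None,
) -> SimulationResult:
    """Godunov-split time loop shared by the two tissue models.

    ``stop_when_quiet``: end the run early once no unit has been above
    the activity threshold for that many ms (and all stimuli are over).
    A tissue that is quiescent and subthreshold everywhere can only
    relax to rest, so reentry queries after the stop time are False.
    """
    n_steps = int(round(T_end / params.dt_p))
    if abs(n_steps * params.dt_p - T_end) > 1e-9:
        raise ValueError("T_end must be a multiple of dt_p")
    probe_idx = np.asarray(probe_idx, dtype=np.int64)
    traces = np.empty((probe_idx.size, n_steps + 1))
    traces[:, 0] = V[probe_idx]
    times = np.linspace(0.0, T_end, n_steps + 1)
    snap_times: list[float] = []
    snaps: list[np.ndarray] = []
    stim = np.zeros_like(V)
    tracker.update(0.0, V)
    nan_check_every = max(1, int(round(1.0 / params.dt_p)))
    for k in range(n_steps):
        t = k * params.dt_p
        protocol.current(t, stim)
        stepper(V, eta, stim, params.dt_o, params.N_o)
        V[:] = diffusion_solve(V)
        t_next = t + params.dt_p
        tracker.update(t_next, V)
        traces[:, k + 1] = V[probe_idx]
        if snapshot_every is not None and (k + 1) % int(round(snapshot_every / params.dt_p)) == 0:
            snap_times.append(t_next)
            snaps.append(V.copy())
        if (k + 1) % nan_check_every == 0 and not np.isfinite(V).all():
            raise FloatingPointError(f"non-finite V at t={t_next} ms")
        if (
            stop_when_quiet is not None
            and t_next > protocol.t_last
            and tracker.n_active_series[-1] == 0
            and t_next - max(tracker.last_active_time, protocol.t_last) >= stop_when_quiet
        ):
            traces = traces[:, : k + 2]
            times = times[: k + 2]
            md_quiet = t_next
            break
    else:
        md_quiet = None
    if not np.isfinite(V).all():
        raise FloatingPointError("non-finite V at end of run")
    md = dict(metadata or {})
    md["V_final"] = V.copy()
    md["stopped_quiet_at"] = md_quiet
    return SimulationResult(
        times=times,
        probe_idx=probe_idx,
        probe_traces=traces,
        tracker=tracker,
        snapshot_times=np.asarray(snap_times),
        snapshots=snaps,
        T_end=T_end,
        metadata=md,
    )
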