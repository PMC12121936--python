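"""Synthetic two-channel calcium-imaging sessions with known ground truth.

Every pipeline stage can be tested against planted truth without any real
recording. A simulated session emulates the statistics of subcellular
(axon/bouton) GCaMP6s imaging:

* **Transients** — a Poisson event train per active ROI convolved with a
  double-exponential indicator kernel ``(1 − e^(−t/τ_rise)) e^(−t/τ_decay)``
  (slow rise ~0.2 s, slower decay ~1.5 s), with log-normal event
  amplitudes. The kernel's spectral power concentrates in the same
  low-frequency band the selection stage looks for.
* **Noise ROIs** — the large majority of upstream segmentation output
  (default 90%) carries no events at all: white shot-like noise on a
  bleaching baseline.
* **Bleaching** — a multiplicative exponential decay of the baseline
  (default time constant 1800 s), giving the percentile-baseline stage a
  realistic slow drift to remove.
* **z-shifts** — synchronous level steps added to *both* channels over an
  interval, with per-ROI random sign and magnitude (uniform 0.5–1.5x the
  stated size, in units of that ROI's temporal sd): different ROIs move in
  different directions, but simultaneously.
* **Axon groups** — sets of active ROIs sharing one event train, scaled by
  a per-member gain, emulating boutons of a single axon.

The static channel is a flat baseline plus noise (an activity-independent
fluorophore) that receives the same z-shift steps.

What this generator does **not** emulate: within-frame/nonrigid motion,
rhythmic (breathing/heartbeat) artifacts, neuropil contamination, or
pixel-level structure — the pipeline explicitly does not address those.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .io import Channel, SamplingInfo, TraceMatrix

__all__ = [
    "ZShiftSpec",
    "SimConfig",
    "PlantedTruth",
    "SimulatedSession",
    "transient_kernel",
    "simulate_session",
    "simulate_paired_environments",
]


@dataclass(frozen=True)
class ZShiftSpec:
    """One planted z-shift: when, for how long, how big, how widespread."""

    start_s: float
    duration_s: float
    magnitude_sd: float = 3.0  # step size in units of each ROI's temporal sd
    affected_fraction: float = 0.8

    def __post_init__(self) -> None:
        if self.start_s < 0 or self.duration_s <= 0:
            raise ValueError("z-shift must have start_s >= 0 and duration_s > 0")
        if not 0 < self.affected_fraction <= 1:
            raise ValueError("affected_fraction must be in (0, 1]")


@dataclass(frozen=True)
class SimConfig:
    """Full description of a synthetic session.

    Defaults reflect a typical axon-GCaMP6s recording: ~6.5 min at
    15.49 Hz, 90% noise-only ROIs, sparse events (0.03 Hz) with large
    bouton transients (log-normal, mean 1.0 ΔF/F), shot noise of
    0.03 ΔF/F per frame and slow bleaching.
    """

    n_rois: int = 100
    n_frames: int = 6000
    frame_rate_hz: float = 15.49
    fraction_noise_rois: float = 0.9
    event_rate_hz: float = 0.03
    tau_rise_s: float = 0.2
    tau_decay_s: float = 1.5
    amplitude_dff_mean: float = 1.0
    amplitude_dff_sd: float = 0.5
    noise_sd: float = 0.03  # per-frame Gaussian noise, ΔF/F units
    bleach_tau_s: float = 1800.0
    z_shifts: tuple[ZShiftSpec, ...] = ()
    groups: tuple[int, ...] = ()  # sizes of same-axon ROI groups
    gain_range: tuple[float, float] = (0.5, 1.5)
    f0_range: tuple[float, float] = (100.0, 300.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.fraction_noise_rois <= 1:
            raise ValueError("fraction_noise_rois must be in [0, 1]")
        for name in ("event_rate_hz", "tau_rise_s", "tau_decay_s", "bleach_tau_s", "noise_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if sum(self.groups) > self.n_active:
            raise ValueError(
                f"group sizes sum to {sum(self.groups)} but only "
                f"{self.n_active} active ROIs are available"
            )

    @property
    def n_noise(self) -> int:
        return int(round(self.fraction_noise_rois * self.n_rois))

    @property
    def n_active(self) -> int:
        return self.n_rois - self.n_noise

    @property
    def sampling(self) -> SamplingInfo:
        return SamplingInfo(self.frame_rate_hz, self.n_frames, self.n_rois)

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate_hz


@dataclass
class PlantedTruth:
    """Everything the generator knows that the pipeline must recover."""

    roi_ids: list[str]
    active: np.ndarray  # bool per ROI
    event_times_s: dict[str, list[float]]
    event_amplitudes: dict[str, list[float]]
    groups: list[list[str]]  # multi-ROI same-axon groups only
    artifact_intervals: list[tuple[int, int]]  # half-open frames
    f0: np.ndarray
    bleach: np.ndarray  # shared drift curve, multiplicative

    def full_partition(self) -> list[list[str]]:
        """Groups plus every ungrouped ROI as its own singleton group."""
        grouped = {r for g in self.groups for r in g}
        return self.groups + [[r] for r in self.roi_ids if r not in grouped]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "roi_ids": self.roi_ids,
            "active": self.active.astype(int).tolist(),
            "event_times_s": self.event_times_s,
            "event_amplitudes": self.event_amplitudes,
            "groups": self.groups,
            "artifact_intervals": [list(iv) for iv in self.artifact_intervals],
            "f0": self.f0.tolist(),
            "bleach": self.bleach.tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "PlantedTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            roi_ids=d["roi_ids"],
            active=np.array(d["active"], dtype=bool),
            event_times_s=d["event_times_s"],
            event_amplitudes=d["event_amplitudes"],
            groups=d["groups"],
            artifact_intervals=[tuple(iv) for iv in d["artifact_intervals"]],
            f0=np.array(d["f0"]),
            bleach=np.array(d["bleach"]),
        )


@dataclass
class SimulatedSession:
    activity: TraceMatrix
    static: TraceMatrix
    truth: PlantedTruth
    config: SimConfig


def transient_kernel(
    tau_rise_s: float,
    tau_decay_s: float,
    sampling: SamplingInfo,
    max_duration_s: float = 60.0,
) -> np.ndarray:
    """Unit-peak double-exponential indicator kernel, sampled at the frame
    rate and truncated once it falls below 1% of peak (or at
    ``max_duration_s`` for extremely slow decays)."""
    if tau_rise_s >= tau_decay_s:
        raise ValueError(
            f"tau_rise_s ({tau_rise_s}) must be < tau_decay_s ({tau_decay_s})"
        )
    dt = 1.0 / sampling.frame_rate_hz
    # the kernel decays below 1% of peak by ~5 decay constants
    horizon = min(6.0 * tau_decay_s, max_duration_s)
    t = np.arange(0, horizon, dt)
    k = (1.0 - np.exp(-t / tau_rise_s)) * np.exp(-t / tau_decay_s)
    k /= k.max()
    peak = int(np.argmax(k))
    below = np.flatnonzero(k[peak:] < 0.01)
    if below.size:
        k = k[: peak + below[0]]
    return k


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    sigma2 = np.log1p((sd / mean) ** 2)
    return np.log(mean) - sigma2 / 2.0, np.sqrt(sigma2)


def _event_train(
    rng: np.random.Generator, config: SimConfig, mu: float, sigma: float
) -> tuple[np.ndarray, np.ndarray]:
    n_events = rng.poisson(config.event_rate_hz * config.duration_s)
    times = np.sort(rng.uniform(0, config.duration_s, size=n_events))
    amps = rng.lognormal(mu, sigma, size=n_events)
    return times, amps


def _signal_from_events(
    times: np.ndarray, amps: np.ndarray, kernel: np.ndarray, config: SimConfig
) -> np.ndarray:
    impulses = np.zeros(config.n_frames)
    frames = np.round(times * config.frame_rate_hz).astype(int)
    frames = np.clip(frames, 0, config.n_frames - 1)
    np.add.at(impulses, frames, amps)
    return np.convolve(impulses, kernel)[: config.n_frames]


def simulate_session(config: SimConfig | None = None) -> SimulatedSession:
    """Generate one two-channel session plus its planted truth.

    Active ROI model (ΔF/F-multiplicative, then additive shot noise)::

        F[t] = F0 * (1 + Σ_i a_i k(t - t_i)) * bleach(t) + F0 * σ * N(0,1)

    Group members share one event train, scaled by a per-member gain drawn
    uniformly from ``gain_range``. Noise ROIs have no events. Each planted
    z-shift adds a constant step over its interval to both channels of
    every affected ROI, with random sign and per-ROI magnitude
    ``U(0.5, 1.5) x magnitude_sd`` x that ROI's pre-shift temporal sd.
    Fully reproducible from ``config.seed``.
    """
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed)
    return _simulate(config, rng_struct=rng, rng_session=rng)


def simulate_paired_environments(
    config: SimConfig | None = None,
) -> tuple[SimulatedSession, SimulatedSession]:
    """Two sessions of the same ROIs in two environments.

    ROI identity, group membership, baselines and per-member gains are
    shared; event trains, noise and artifacts are drawn independently —
    emulating place-field remapping, where the same axons fire different
    patterns in different environments. Used to build ground-truth
    groupings from cross-environment correlation consistency.
    """
    config = config or SimConfig()
    sessions = []
    for env in (0, 1):
        rng_struct = np.random.default_rng(config.seed)  # identical structure
        rng_session = np.random.default_rng((config.seed, 1 + env))
        sessions.append(_simulate(config, rng_struct, rng_session))
    return sessions[0], sessions[1]


def _simulate(
    config: SimConfig,
    rng_struct: np.random.Generator,
    rng_session: np.random.Generator,
) -> SimulatedSession:
    n, T = config.n_rois, config.n_frames
    sampling = config.sampling
    roi_ids = [f"roi{i:04d}" for i in range(n)]
    kernel = transient_kernel(config.tau_rise_s, config.tau_decay_s, sampling)
    mu, sigma = _lognormal_params(config.amplitude_dff_mean, config.amplitude_dff_sd)

    # --- structural draws (shared across paired environments) ---
    active = np.zeros(n, dtype=bool)
    active_idx = rng_struct.choice(n, size=config.n_active, replace=False)
    active[active_idx] = True
    f0 = rng_struct.uniform(*config.f0_range, size=n)
    f0_static = rng_struct.uniform(*config.f0_range, size=n) * 0.5
    group_members: list[list[int]] = []
    pool = list(active_idx)
    for size in config.groups:
        group_members.append([pool.pop(0) for _ in range(size)])
    gains = {
        i: rng_struct.uniform(*config.gain_range)
        for g in group_members
        for i in g
    }

    # --- per-session draws ---
    t_s = np.arange(T) / config.frame_rate_hz
    bleach = np.exp(-t_s / config.bleach_tau_s)
    signal = np.zeros((n, T))
    event_times: dict[str, list[float]] = {r: [] for r in roi_ids}
    event_amps: dict[str, list[float]] = {r: [] for r in roi_ids}

    for members in group_members:
        times, amps = _event_train(rng_session, config, mu, sigma)
        base = _signal_from_events(times, amps, kernel, config)
        for i in members:
            g = gains[i]
            signal[i] = g * base
            event_times[roi_ids[i]] = list(times)
            event_amps[roi_ids[i]] = list(g * amps)
    grouped = {i for g in group_members for i in g}
    for i in active_idx:
        if i in grouped:
            continue
        times, amps = _event_train(rng_session, config, mu, sigma)
        signal[i] = _signal_from_events(times, amps, kernel, config)
        event_times[roi_ids[i]] = list(times)
        event_amps[roi_ids[i]] = list(amps)

    noise = rng_session.standard_normal((n, T))
    activity = f0[:, None] * (1.0 + signal) * bleach[None, :] + (
        f0[:, None] * config.noise_sd * noise
    )
    static = f0_static[:, None] + f0_static[:, None] * config.noise_sd * (
        rng_session.standard_normal((n, T))
    )

    # --- planted z-shifts: synchronous steps on both channels ---
    artifact_intervals: list[tuple[int, int]] = []
    for shift in config.z_shifts:
        s = int(round(shift.start_s * config.frame_rate_hz))
        e = min(T, s + max(1, int(round(shift.duration_s * config.frame_rate_hz))))
        if s >= T:
            raise ValueError(f"z-shift at {shift.start_s}s starts beyond the session")
        n_aff = max(1, int(round(shift.affected_fraction * n)))
        affected = rng_session.choice(n, size=n_aff, replace=False)
        signs = rng_session.choice([-1.0, 1.0], size=n_aff)
        scale = rng_session.uniform(0.5, 1.5, size=n_aff) * shift.magnitude_sd
        step_act = signs * scale * activity[affected].std(axis=1)
        step_stat = signs * scale * static[affected].std(axis=1)
        activity[affected, s:e] += step_act[:, None]
        static[affected, s:e] += step_stat[:, None]
        artifact_intervals.append((s, e))
    artifact_intervals.sort()

    truth = PlantedTruth(
        roi_ids=roi_ids,
        active=active,
        event_times_s=event_times,
        event_amplitudes=event_amps,
        groups=[[roi_ids[i] for i in g] for g in group_members],
        artifact_intervals=artifact_intervals,
        f0=f0,
        bleach=bleach,
    )
    return SimulatedSession(
        activity=TraceMatrix(activity, Channel.ACTIVITY, roi_ids, sampling),
        static=TraceMatrix(static, Channel.STATIC, roi_ids, sampling),
        truth=truth,
        config=config,
    )
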