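"""Synthetic capacitive-ECG lead signals with acquisition-chain effects.

The forward model gives the lead voltage for any dipole moment; a
cardiac cycle is modelled as a sum of Gaussian moment components (P,
Q, R, S, T), each with its own phase, width, magnitude and direction,
with the R component carrying the full equivalent-dipole magnitude of
2.0×10⁻⁵ A·m along the reference heart axis.  The acquisition chain is
emulated by sampling at 2.3 kHz, adding gap-modulation motion
artifacts and white amplifier noise, and averaging-downsampling to
72 Hz.  All randomness is seeded; traces carry their ground-truth
R-wave times.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import json

import numpy as np

from .electrode_model import EPSILON_0, ElectrodeCoupling, electrode_potential
from .forward_solver import LeadFieldBasis, angles_to_moment

__all__ = [
    "WaveComponent",
    "CardiacCycleModel",
    "MotionEventModel",
    "SignalTrace",
    "dipole_trajectory",
    "lead_transfer",
    "simulate_lead_signal",
    "add_motion_artifact",
    "add_noise",
    "downsample_averaging",
    "calibrated_noise_sigma",
    "write_trace_csv",
    "read_trace_csv",
]

REFERENCE_AZIMUTH = 5.0 * np.pi / 6.0
REFERENCE_ELEVATION = 3.0 * np.pi / 4.0
R_MOMENT = 2.0e-5  # A·m — equivalent dipole magnitude at the R instant


@dataclass(frozen=True)
class WaveComponent:
    """One Gaussian component of the dipole-moment loop.

    ``center`` and ``width`` are in seconds on a nominal 1 s cycle and
    scale linearly with the actual cycle length.
    """

    name: str
    center: float
    width: float
    amplitude: float       # A·m
    direction: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError(f"{self.name}: width must be > 0")
        d = np.linalg.norm(self.direction)
        if not np.isclose(d, 1.0, rtol=1e-6):
            raise ValueError(f"{self.name}: direction must be a unit vector")


def _default_waves(r_direction: np.ndarray,
                   r_amplitude: float) -> tuple[WaveComponent, ...]:
    d = tuple(r_direction)
    neg = tuple(-r_direction)
    return (
        WaveComponent("P", 0.21, 0.025, 0.12 * r_amplitude, d),
        WaveComponent("Q", 0.300, 0.009, 0.15 * r_amplitude, neg),
        WaveComponent("R", 0.330, 0.012, r_amplitude, d),
        WaveComponent("S", 0.360, 0.009, 0.18 * r_amplitude, neg),
        WaveComponent("T", 0.600, 0.040, 0.35 * r_amplitude, d),
    )


@dataclass(frozen=True)
class CardiacCycleModel:
    """Sum-of-Gaussians dipole trajectory over a cardiac cycle.

    The default wave set produces a physiological-looking trace whose
    R-instant moment equals ``R_MOMENT`` along the reference heart axis
    (azimuth 5π/6, elevation 3π/4); P/Q/S/T magnitudes and timings are
    generic textbook-like values — the shape model is package plumbing,
    only the R instant is anchored to measured data.
    """

    heart_rate: float = 60.0
    waves: tuple[WaveComponent, ...] = ()

    def __post_init__(self) -> None:
        if self.heart_rate <= 0:
            raise ValueError("heart rate must be > 0")
        if not self.waves:
            object.__setattr__(
                self, "waves",
                _default_waves(angles_to_moment(1.0, REFERENCE_AZIMUTH,
                                                REFERENCE_ELEVATION), R_MOMENT))
        centers = [w.center for w in self.waves]
        if sorted(centers) != centers:
            raise ValueError("wave components must be ordered in phase")
        qrs = [w for w in self.waves if w.name in ("Q", "R", "S")]
        r = [w for w in self.waves if w.name == "R"]
        if r and qrs and max(w.amplitude for w in qrs) > r[0].amplitude:
            raise ValueError("R must be the largest QRS component")

    @classmethod
    def default(cls, heart_rate: float = 60.0,
                azimuth: float = REFERENCE_AZIMUTH,
                elevation: float = REFERENCE_ELEVATION,
                r_amplitude: float = R_MOMENT) -> "CardiacCycleModel":
        d = angles_to_moment(1.0, azimuth, elevation)
        return cls(heart_rate, _default_waves(d, r_amplitude))

    @property
    def cycle_length(self) -> float:
        return 60.0 / self.heart_rate

    @property
    def r_phase(self) -> float:
        """R-wave instant within the cycle, in seconds."""
        for w in self.waves:
            if w.name == "R":
                return w.center * self.cycle_length
        raise ValueError("model has no R component")

    def r_times(self, duration: float) -> np.ndarray:
        cl = self.cycle_length
        n = int(np.floor((duration - self.r_phase) / cl)) + 1
        return self.r_phase + cl * np.arange(max(n, 0))

    def r_moment(self) -> np.ndarray:
        return dipole_trajectory(self, np.array([self.r_phase]))[0]


def dipole_trajectory(model: CardiacCycleModel, t) -> np.ndarray:
    """Moment vector (A·m) at times ``t``; periodic in the cycle length."""
    t = np.asarray(t, float)
    cl = model.cycle_length
    phase = np.mod(t, cl)
    out = np.zeros(t.shape + (3,))
    for w in model.waves:
        c, s = w.center * cl, w.width * cl
        g = w.amplitude * np.exp(-0.5 * ((phase - c) / s) ** 2)
        # wrap-around tails keep the trajectory exactly periodic
        g = g + w.amplitude * np.exp(-0.5 * ((phase - c - cl) / s) ** 2)
        g = g + w.amplitude * np.exp(-0.5 * ((phase - c + cl) / s) ** 2)
        out += g[..., None] * np.asarray(w.direction)
    return out


@dataclass(frozen=True)
class MotionEventModel:
    """Moderate-movement events modulating the electrode gap.

    Each event rigidly displaces the plate away from the body along a
    raised-cosine excursion; contact is never reversed (the excursion
    may not push the plate through the surface).
    """

    rate_per_min: float = 2.0
    excursion: float = 5.0e-4     # m, peak gap change (positive = away)
    duration: float = 0.5         # s
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rate_per_min < 0 or self.duration <= 0:
            raise ValueError("invalid motion event parameters")

    def event_starts(self, total: float) -> np.ndarray:
        """Poisson event start times in [0, total), non-overlapping."""
        rng = np.random.default_rng(self.seed)
        n = rng.poisson(self.rate_per_min * total / 60.0)
        starts = np.sort(rng.uniform(0.0, max(total - self.duration, 0.0), n))
        kept: list[float] = []
        for s in starts:
            if not kept or s - kept[-1] >= self.duration:
                kept.append(float(s))
        return np.asarray(kept)


@dataclass
class SignalTrace:
    """Sampled lead voltage with ground-truth beat annotations."""

    fs: float                      # Hz
    samples: np.ndarray            # V
    annotations: np.ndarray        # true R times, s
    start_time: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, float)
        self.annotations = np.asarray(self.annotations, float)
        if np.any(np.diff(self.annotations) <= 0):
            raise ValueError("annotations must be strictly increasing")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.fs

    def times(self) -> np.ndarray:
        return self.start_time + np.arange(len(self.samples)) / self.fs

    def copy_with(self, **kw) -> "SignalTrace":
        base = dict(fs=self.fs, samples=self.samples.copy(),
                    annotations=self.annotations.copy(),
                    start_time=self.start_time, meta=dict(self.meta))
        base.update(kw)
        return SignalTrace(**base)


def lead_transfer(basis: LeadFieldBasis, coupling_a: ElectrodeCoupling,
                  coupling_b: ElectrodeCoupling) -> np.ndarray:
    """Per-axis lead gain ℓ (V per A·m): signal = ℓ · m(t)."""
    return np.array([
        electrode_potential(f, coupling_a) - electrode_potential(f, coupling_b)
        for f in basis.field_maps])


def simulate_lead_signal(basis: LeadFieldBasis,
                         coupling_a: ElectrodeCoupling,
                         coupling_b: ElectrodeCoupling,
                         model: CardiacCycleModel,
                         duration: float,
                         fs: float = 2300.0) -> SignalTrace:
    """Noise-free cECG lead trace sampled at ``fs``.

    Sample k at t = k/fs carries (Ve_A − Ve_B) for the instantaneous
    dipole moment, obtained from the lead-field basis by superposition.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    t = np.arange(int(round(duration * fs))) / fs
    moments = dipole_trajectory(model, t)
    ell = lead_transfer(basis, coupling_a, coupling_b)
    samples = moments @ ell
    ann = model.r_times(duration)
    return SignalTrace(fs, samples, ann,
                       meta={"model": model, "fs_native": fs})


def add_motion_artifact(trace: SignalTrace, basis: LeadFieldBasis,
                        model: CardiacCycleModel,
                        coupling: ElectrodeCoupling,
                        events: MotionEventModel,
                        sign: float = 1.0) -> SignalTrace:
    """Inject gap-modulation motion artifacts on one electrode.

    During each event the plate–body gap follows a raised-cosine
    excursion; the electrode potential is recomputed per sample from
    the Ve formula with the perturbed specific capacitance while the
    surface potential distribution keeps evolving with the heart.
    Outside events the trace is untouched.  ``sign`` is +1 for the
    lead's A electrode, −1 for B.
    """
    out = trace.copy_with()
    starts = events.event_starts(trace.duration)
    if starts.size == 0 or events.excursion == 0.0:
        out.meta["motion_events"] = starts
        return out
    if np.any(coupling.gap_profile + min(events.excursion, 0.0) <= 0):
        raise ValueError("excursion would push the electrode through the body")
    idx_all = np.arange(len(trace.samples))
    t_all = trace.times()
    patch = coupling.patch
    w = patch.weights
    eps = EPSILON_0 * coupling.electrode.eps_r
    for s in starts:
        win = idx_all[(t_all >= s) & (t_all < s + events.duration)]
        if win.size == 0:
            continue
        tw = t_all[win]
        delta = events.excursion * 0.5 * (
            1.0 - np.cos(2.0 * np.pi * (tw - s) / events.duration))
        vw = basis.boundary_potential_series(
            dipole_trajectory(model, tw), patch.vertex_idx)  # (n, k)
        w0 = coupling.ce * w
        ve0 = vw @ w0 / w0.sum()
        ce_t = eps / (coupling.gap_profile[None, :] + delta[:, None])
        wt = ce_t * w[None, :]
        ve1 = (vw * wt).sum(axis=1) / wt.sum(axis=1)
        out.samples[win] += sign * (ve1 - ve0)
    out.meta["motion_events"] = starts
    return out


def add_noise(trace: SignalTrace, sigma: float, seed: int = 0) -> SignalTrace:
    """Add zero-mean white Gaussian noise of standard deviation ``sigma``."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    out = trace.copy_with()
    if sigma > 0:
        rng = np.random.default_rng(seed)
        out.samples = out.samples + rng.normal(0.0, sigma, len(out.samples))
    out.meta["noise_sigma"] = sigma
    out.meta["noise_seed"] = seed
    return out


def downsample_averaging(trace: SignalTrace, target_rate: float) -> SignalTrace:
    """Averaging-filter downsample: each output sample is the arithmetic
    mean of the input samples falling in its half-open output interval
    [k/target, (k+1)/target).  Annotations are carried over unchanged.
    """
    if target_rate >= trace.fs:
        raise ValueError("target rate must be below the trace rate")
    n = len(trace.samples)
    bins = np.floor(np.arange(n) * target_rate / trace.fs).astype(int)
    n_out = int(np.floor(n * target_rate / trace.fs))
    keep = bins < n_out
    sums = np.bincount(bins[keep], weights=trace.samples[keep], minlength=n_out)
    counts = np.bincount(bins[keep], minlength=n_out)
    out = trace.copy_with(fs=target_rate, samples=sums / counts)
    out.meta["downsampled_from"] = trace.fs
    return out


def calibrated_noise_sigma(trace: SignalTrace, target_snr_db: float,
                           window: float = 0.08) -> float:
    """Noise SD achieving a target SNR = 20·log10(VR/σ) on this trace.

    VR is the mean over annotated beats of the peak |value| within
    ±``window`` s of each R time, matching the SNR estimator's
    definition of the R amplitude.
    """
    if trace.annotations.size == 0:
        raise ValueError("trace has no beat annotations")
    half = max(1, int(round(window * trace.fs)))
    peaks = []
    for r in trace.annotations:
        k = int(round((r - trace.start_time) * trace.fs))
        lo, hi = max(0, k - half), min(len(trace.samples), k + half + 1)
        if hi > lo:
            peaks.append(np.abs(trace.samples[lo:hi]).max())
    vr = float(np.mean(peaks))
    return vr * 10.0 ** (-target_snr_db / 20.0)


# --------------------------------------------------------------------------
# plain-text trace I/O (CSV + JSON sidecar)
# --------------------------------------------------------------------------

def write_trace_csv(trace: SignalTrace, path: str) -> None:
    """Write (time, value) CSV plus a JSON sidecar with rate, annotations
    and scalar generator metadata."""
    t = trace.times()
    with open(path, "w") as f:
        f.write("time_s,value_V\n")
        for ti, v in zip(t, trace.samples):
            f.write(f"{ti:.9g},{v:.9g}\n")
    meta = {k: v for k, v in trace.meta.items()
            if isinstance(v, (int, float, str, bool))}
    sidecar = {
        "fs_hz": trace.fs,
        "start_time_s": trace.start_time,
        "n_samples": len(trace.samples),
        "r_times_s": trace.annotations.tolist(),
        "meta": meta,
    }
    with open(str(path) + ".json", "w") as f:
        json.dump(sidecar, f)


def read_trace_csv(path: str) -> SignalTrace:
    data = np.loadtxt(path, delimiter=",", skiprows=1)
    with open(str(path) + ".json") as f:
        sidecar = json.load(f)
    return SignalTrace(sidecar["fs_hz"], data[:, 1],
                       np.asarray(sidecar["r_times_s"]),
                       start_time=sidecar.get("start_time_s", 0.0),
                       meta=sidecar.get("meta", {}))
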