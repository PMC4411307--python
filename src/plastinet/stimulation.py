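"""Stochastic stimulation paradigm and stimulus pattern generators.

In the absence of a stimulus every input unit fires Poisson at a fixed
background rate (10 Hz).  A stimulus is an activation map zeta in [0, 1]
over the input grid (binary for the geometric shapes, graded for Gaussian
profiles); while it is on, an active unit's rate is raised by
zeta * 35 Hz.  Stimulus identity is drawn uniformly at random; stimulus
durations and interstimulus intervals are i.i.d. exponential with means
T_on and T_off, which switch between a learning phase (1 s / 2 s) and a
recall phase (0.2 s / 20 s).  No stimulus is presented during an initial
burn-in period.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StimulusPattern",
    "ParadigmConfig",
    "ScheduledStimulus",
    "schedule_stimuli",
    "pattern_rate",
    "rate_segments",
    "occlude",
    "make_shape_patterns",
    "make_gaussian_profile_stimuli",
]


@dataclass
class StimulusPattern:
    """Activation map over the input units: zeta in [0, 1] per unit."""

    activation: np.ndarray
    id: str = ""

    def __post_init__(self):
        self.activation = np.asarray(self.activation, dtype=np.float64)
        if self.activation.min() < 0 or self.activation.max() > 1:
            raise ValueError("pattern activation values must lie in [0, 1]")

    @property
    def is_binary(self) -> bool:
        return bool(np.isin(self.activation, (0.0, 1.0)).all())


@dataclass
class ParadigmConfig:
    """Timing and intensity of the stochastic stimulation paradigm."""

    T_on: float = 1.0
    T_off: float = 2.0
    background_rate: float = 10.0
    stim_increment: float = 35.0
    burn_in: float = 50.0
    pattern_probs: np.ndarray | None = None

    def validate(self) -> None:
        for name in ("T_on", "T_off"):
            if getattr(self, name) <= 0:
                raise ValueError(f"stimulation.{name} must be positive")
        if self.background_rate < 0 or self.stim_increment < 0:
            raise ValueError("stimulation rates must be non-negative")
        if self.burn_in < 0:
            raise ValueError("stimulation.burn_in must be non-negative")


@dataclass
class ScheduledStimulus:
    pattern_id: int
    t_start: float
    t_end: float


def schedule_stimuli(
    config: ParadigmConfig,
    total_T: float,
    rng: np.random.Generator,
    n_patterns: int = 1,
    phases: list[tuple[float, float, float]] | None = None,
) -> list[ScheduledStimulus]:
    """Draw the alternating off/on schedule over [0, total_T).

    ``phases`` optionally lists (t_start, T_on, T_off) triples taking effect
    from t_start onward (e.g. switching from the learning to the recall
    paradigm mid-run); the base config supplies the values before the first
    phase entry.  Epochs are truncated at total_T; nothing is scheduled
    before the burn-in ends.
    """
    config.validate()
    probs = config.pattern_probs
    if probs is not None:
        probs = np.asarray(probs, dtype=float)
        probs = probs / probs.sum()
    phase_list = sorted(phases) if phases else []

    def timing(t: float) -> tuple[float, float]:
        T_on, T_off = config.T_on, config.T_off
        for t0, on, off in phase_list:
            if t >= t0:
                T_on, T_off = on, off
        return T_on, T_off

    out: list[ScheduledStimulus] = []
    t = config.burn_in
    while t < total_T:
        T_on, T_off = timing(t)
        t = t + rng.exponential(T_off)
        if t >= total_T:
            break
        dur = rng.exponential(T_on)
        pid = int(rng.choice(n_patterns, p=probs))
        out.append(ScheduledStimulus(pid, t, min(t + dur, total_T)))
        t += dur
    return out


def pattern_rate(pattern: StimulusPattern | None, config: ParadigmConfig) -> np.ndarray | float:
    """Per-unit firing rate while ``pattern`` is active (or background if None)."""
    if pattern is None:
        return config.background_rate
    return config.background_rate + pattern.activation * config.stim_increment


def rate_segments(
    schedule: list[ScheduledStimulus],
    patterns: list[StimulusPattern],
    config: ParadigmConfig,
    t0: float,
    t1: float,
) -> list[tuple[float, float, np.ndarray | float]]:
    """Piecewise-constant rate segments covering [t0, t1) for Network.run."""
    segs: list[tuple[float, float, np.ndarray | float]] = []
    t = t0
    for st in schedule:
        if st.t_end <= t0 or st.t_start >= t1:
            continue
        a, b = max(st.t_start, t0), min(st.t_end, t1)
        if a > t:
            segs.append((t, a, config.background_rate))
        segs.append((a, b, pattern_rate(patterns[st.pattern_id], config)))
        t = b
    if t < t1:
        segs.append((t, t1, config.background_rate))
    return segs


def occlude(pattern: StimulusPattern, grid: tuple[int, int], keep_fraction: float = 0.25) -> StimulusPattern:
    """Zero the activation outside the first ``keep_fraction`` of the grid rows.

    Models partial cues: up to three quarters of the input field occluded.
    """
    if not (0.0 < keep_fraction <= 1.0):
        raise ValueError("keep_fraction must lie in (0, 1]")
    gx, gy = grid
    act = pattern.activation.reshape(gx, gy).copy()
    act[int(round(gx * keep_fraction)):, :] = 0.0
    return StimulusPattern(act.ravel(), id=f"{pattern.id}|occluded{keep_fraction:g}")


def _disc(xs, ys, cx, cy, r):
    return (xs - cx) ** 2 + (ys - cy) ** 2 <= r * r


def make_shape_patterns(
    grid: tuple[int, int] = (64, 64), n_patterns: int = 4, seed: int = 0
) -> list[StimulusPattern]:
    """Binary masks of overlapping geometric shapes (disc, square, triangle, cross).

    Shape centres are jittered around the grid centre under the seed;
    placement is retried until every pair of masks overlaps in at least one
    unit, since only the overlap structure matters downstream.
    """
    if n_patterns < 1:
        raise ValueError("n_patterns must be >= 1")
    gx, gy = grid
    xs, ys = np.meshgrid(np.arange(gx), np.arange(gy), indexing="ij")
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence([seed, 0x5A9E])))
    names = ["disc", "square", "triangle", "cross"]

    def make(kind: str, cx: float, cy: float, size: float) -> np.ndarray:
        if kind == "disc":
            return _disc(xs, ys, cx, cy, size)
        if kind == "square":
            return (np.abs(xs - cx) <= size) & (np.abs(ys - cy) <= size)
        if kind == "triangle":  # upward triangle: half-plane cuts
            return (xs >= cx - size) & (np.abs(ys - cy) <= (xs - (cx - size)) * 0.5)
        # cross: union of horizontal and vertical bars
        bar = size / 3.0
        return ((np.abs(xs - cx) <= bar) & (np.abs(ys - cy) <= size)) | (
            (np.abs(ys - cy) <= bar) & (np.abs(xs - cx) <= size)
        )

    for _attempt in range(100):
        masks = []
        for k in range(n_patterns):
            kind = names[k % len(names)]
            size = min(gx, gy) * rng.uniform(0.15, 0.25)
            cx = gx / 2 + rng.uniform(-gx / 8, gx / 8)
            cy = gy / 2 + rng.uniform(-gy / 8, gy / 8)
            masks.append(make(kind, cx, cy, size))
        ok = all(
            (masks[a] & masks[b]).sum() >= 1
            for a in range(n_patterns)
            for b in range(a + 1, n_patterns)
        )
        if ok and all(m.sum() >= 4 for m in masks):
            return [
                StimulusPattern(m.astype(np.float64).ravel(), id=names[k % len(names)])
                for k, m in enumerate(masks)
            ]
    raise RuntimeError("could not place overlapping shapes; grid too small?")


def make_gaussian_profile_stimuli(
    n_inputs: int = 1000, sigma: float = 50.0, n_stimuli: int = 10, seed: int = 0
) -> list[StimulusPattern]:
    """Graded Gaussian zeta-profiles over the presynaptic index, peak 1 at the centre."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence([seed, 0x6A55])))
    idx = np.arange(n_inputs)
    out = []
    for k in range(n_stimuli):
        c = rng.uniform(0, n_inputs)
        out.append(StimulusPattern(np.exp(-0.5 * ((idx - c) / sigma) ** 2), id=f"gauss{k}@{c:.0f}"))
    return out
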