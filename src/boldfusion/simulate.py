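"""Synthetic task-fMRI signal generation.

Emulates the block/phase structure of the four acquisition paradigms the
classifier is built for, so the whole pipeline can be exercised end-to-end
without scanner data:

* **resting** — 180 samples at TR=3 s, spontaneous fluctuations only (no
  stimulus blocks).
* **motor** — 200 samples at TR=2 s: ten repeats of 20 s rest followed by
  20 s of finger tapping.
* **emotion** — 600 samples at TR=3 s: three equal sequential social-support
  phases (high, medium, low) whose game rounds are modelled as periodic
  stimulus blocks with phase-specific response amplitude, monotonically
  decreasing high > medium > low.
* **memory** — 600 samples at TR=3 s: rest / encode / rest / recall blocks,
  with encode and recall carrying distinct stimulus amplitudes and block
  periods (hence distinct spectral signatures).

Each signal is a boxcar stimulus train convolved with a canonical
double-gamma haemodynamic response function, plus AR(1)-correlated Gaussian
noise and a slow polynomial drift. Everything is reproducible from a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special

from .signals import BoldSignal, DesignSegment, SignalPool

__all__ = [
    "NoiseSpec",
    "StimulusBlock",
    "TaskDesignSpec",
    "canonical_hrf",
    "generate_signal",
    "generate_pool",
    "default_class_specs",
]


@dataclass(frozen=True)
class NoiseSpec:
    """Additive noise model: white + AR(1) + slow drift."""

    white_sd: float = 0.5
    drift_amplitude: float = 0.3
    ar1_coefficient: float = 0.3

    def __post_init__(self) -> None:
        if self.white_sd < 0 or self.drift_amplitude < 0:
            raise ValueError("noise magnitudes must be non-negative")
        if not 0 <= self.ar1_coefficient < 1:
            raise ValueError("ar1_coefficient must lie in [0, 1)")


@dataclass(frozen=True)
class StimulusBlock:
    """One stimulus boxcar: label, onset and duration in samples, amplitude."""

    label: str
    onset: int
    duration: int
    amplitude: float = 1.0


@dataclass(frozen=True)
class TaskDesignSpec:
    """Complete recipe for one synthetic signal class."""

    task: str
    tr_seconds: float
    n_samples: int
    blocks: tuple[StimulusBlock, ...] = ()
    #: coarse labeled phases recorded as design metadata on the signal
    phases: tuple[DesignSegment, ...] = ()
    noise: NoiseSpec = field(default_factory=NoiseSpec)

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.tr_seconds <= 0:
            raise ValueError("n_samples and tr_seconds must be positive")
        for b in self.blocks:
            if b.onset < 0 or b.onset + b.duration > self.n_samples:
                raise ValueError(f"stimulus block {b} outside [0, {self.n_samples})")
        if self.task != "resting" and not self.blocks:
            raise ValueError(f"{self.task} design requires stimulus blocks")


def canonical_hrf(
    tr_seconds: float,
    duration_seconds: float = 32.0,
    peak_shape: float = 6.0,
    undershoot_shape: float = 16.0,
    scale: float = 1.0,
    undershoot_ratio: float = 1.0 / 6.0,
) -> np.ndarray:
    """Sample the canonical double-gamma HRF at the TR grid.

    ``h(t) = g(t; a1, s) - r * g(t; a2, s)`` with gamma densities ``g``;
    defaults (shapes 6 and 16, scale 1 s, ratio 1/6) peak near 5 s. The
    kernel is normalised so its maximum is 1.
    """
    if tr_seconds <= 0 or duration_seconds <= 0:
        raise ValueError("tr_seconds and duration_seconds must be positive")
    if peak_shape <= 0 or undershoot_shape <= 0 or scale <= 0:
        raise ValueError("gamma shape/scale parameters must be positive")
    t = np.arange(0.0, duration_seconds, tr_seconds)

    def gamma_pdf(x, shape):
        out = np.zeros_like(x)
        pos = x > 0
        xs = x[pos] / scale
        out[pos] = (
            xs ** (shape - 1.0) * np.exp(-xs) / (special.gamma(shape) * scale)
        )
        return out

    h = gamma_pdf(t, peak_shape) - undershoot_ratio * gamma_pdf(t, undershoot_shape)
    peak = np.abs(h).max()
    if peak > 0:
        h = h / peak
    return h


def _boxcar(spec: TaskDesignSpec) -> np.ndarray:
    box = np.zeros(spec.n_samples)
    for b in spec.blocks:
        box[b.onset : b.onset + b.duration] += b.amplitude
    return box


def _noise(spec: TaskDesignSpec, rng: np.random.Generator) -> np.ndarray:
    n, ns = spec.n_samples, spec.noise
    eps = rng.normal(0.0, ns.white_sd, size=n) if ns.white_sd > 0 else np.zeros(n)
    out = np.empty(n)
    prev = 0.0
    for i in range(n):  # AR(1) recursion
        prev = ns.ar1_coefficient * prev + eps[i]
        out[i] = prev
    if ns.drift_amplitude > 0:
        t = np.linspace(-1.0, 1.0, n)
        coef = rng.normal(0.0, 1.0, size=3)
        drift = coef[0] * t + coef[1] * (t**2 - 1 / 3) + coef[2] * np.cos(np.pi * t)
        out = out + ns.drift_amplitude * drift
    return out


def generate_signal(
    spec: TaskDesignSpec, seed: int | np.random.Generator = 0, gain: float = 1.0
) -> BoldSignal:
    """Simulate one BOLD signal: HRF-convolved boxcar plus structured noise.

    ``gain`` scales the stimulus response only (used for between-subject
    variability). Deterministic for a fixed seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    hrf = canonical_hrf(spec.tr_seconds)
    clean = np.convolve(_boxcar(spec), hrf)[: spec.n_samples]
    values = gain * clean + _noise(spec, rng)
    return BoldSignal(
        values=values,
        tr_seconds=spec.tr_seconds,
        task_label=spec.task,
        design=list(spec.phases) if spec.phases else None,
    )


def _cyclic_blocks(label, start, end, period, duty, amplitude):
    """Periodic stimulus blocks of ``duty`` on-samples every ``period`` samples."""
    return tuple(
        StimulusBlock(label, onset, min(duty, end - onset), amplitude)
        for onset in range(start, end, period)
    )


def default_class_specs(noise: NoiseSpec | None = None) -> dict[str, TaskDesignSpec]:
    """The four default task designs (see module docstring)."""
    ns = noise or NoiseSpec()
    specs: dict[str, TaskDesignSpec] = {}
    specs["resting"] = TaskDesignSpec("resting", 3.0, 180, noise=ns)
    specs["motor"] = TaskDesignSpec(
        "motor",
        2.0,
        200,
        # 10 cycles of 20 s rest then 20 s tapping (10 samples each at TR=2 s)
        blocks=_cyclic_blocks("tap", 10, 200, 20, 10, 1.0),
        noise=ns,
    )
    emotion_blocks = (
        _cyclic_blocks("high", 0, 200, 20, 10, 1.0)
        + _cyclic_blocks("medium", 200, 400, 20, 10, 0.6)
        + _cyclic_blocks("low", 400, 600, 20, 10, 0.3)
    )
    specs["emotion"] = TaskDesignSpec(
        "emotion",
        3.0,
        600,
        blocks=emotion_blocks,
        phases=(
            DesignSegment("high", 0, 200),
            DesignSegment("medium", 200, 400),
            DesignSegment("low", 400, 600),
        ),
        noise=ns,
    )
    memory_blocks = (
        # encode: 5 slow face-name presentation cycles, strong response
        _cyclic_blocks("encode", 150, 300, 30, 15, 1.0)
        # recall: faster decision cycles, weaker response
        + _cyclic_blocks("recall", 450, 600, 20, 10, 0.7)
    )
    specs["memory"] = TaskDesignSpec(
        "memory",
        3.0,
        600,
        blocks=memory_blocks,
        phases=(
            DesignSegment("rest", 0, 150),
            DesignSegment("encode", 150, 300),
            DesignSegment("rest", 300, 450),
            DesignSegment("recall", 450, 600),
        ),
        noise=ns,
    )
    return specs


def generate_pool(
    n_per_class: int = 150,
    n_subjects: int = 12,
    class_specs: dict[str, TaskDesignSpec] | None = None,
    seed: int = 0,
    target_length: int = 600,
    subject_gain_sd: float = 0.15,
) -> SignalPool:
    """Generate a balanced labeled pool across the four task classes.

    Subjects are assigned round-robin within each class so every subject
    contributes to every class; each subject carries a fixed multiplicative
    response gain drawn once (lognormal-ish, sd ``subject_gain_sd``) to mimic
    between-participant variability.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    if n_subjects < 2:
        raise ValueError("n_subjects must be >= 2")
    specs = class_specs if class_specs is not None else default_class_specs()
    for key in specs:
        if key not in ("emotion", "memory", "motor", "resting"):
            raise ValueError(f"unknown class key {key!r}")
    rng = np.random.default_rng(seed)
    subjects = [f"sub-{i + 1:02d}" for i in range(n_subjects)]
    gains = np.exp(rng.normal(0.0, subject_gain_sd, size=n_subjects))
    signals = []
    for task in sorted(specs):
        spec = specs[task]
        for i in range(n_per_class):
            j = i % n_subjects
            sig = generate_signal(spec, seed=rng, gain=float(gains[j]))
            sig.subject_id = subjects[j]
            signals.append(sig)
    return SignalPool(
        signals,
        target_length=target_length,
        provenance=f"synthetic(seed={seed}, n_per_class={n_per_class})",
    )
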