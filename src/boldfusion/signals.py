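"""Data model and conditioning for ROI-averaged BOLD time series.

A :class:`BoldSignal` is one labeled 1-D time series (one sample per TR).
A :class:`SignalPool` is a collection of such signals sharing a target padded
length. Pools are read and written as delimited text: one row per signal with
``subject_id, task_label, subphase_spec, tr_seconds, s0..s{T-1}`` columns,
where ``subphase_spec`` is a semicolon-separated list of ``label:start:end``
sample-index triples describing the block design (empty when there is none).

Conditioning follows standard practice for extracted ROI signals: each series
is normalised to zero mean and linearly detrended, then zero-padded at the
tail to the pool's target length so heterogeneous acquisitions (180-sample
resting runs, 200-sample motor runs, 600-sample emotion/memory runs) share a
common input dimension while task onsets stay temporally aligned.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "TASK_LABELS",
    "SUBPHASE_LABELS",
    "DesignSegment",
    "BoldSignal",
    "SignalPool",
    "PoolFormatError",
    "load_pool",
    "save_pool",
    "zero_mean_detrend",
    "pad_to_length",
    "split_into_phases",
    "extract_design_segments",
]

TASK_LABELS = ("emotion", "memory", "motor", "resting")
SUBPHASE_LABELS = ("high", "medium", "low", "encode", "recall")
#: Design-segment labels that do not name a classifiable sub-phase.
REST_LABELS = ("rest",)

DEFAULT_TARGET_LENGTH = 600


class PoolFormatError(ValueError):
    """Raised when a pool file does not conform to the delimited-text schema."""


@dataclass(frozen=True)
class DesignSegment:
    """One labeled block of a signal's experimental design, in sample indices.

    ``start`` is inclusive, ``end`` exclusive, both in samples (not seconds).
    """

    label: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.label:
            raise ValueError("design segment label must be non-empty")
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"invalid design segment bounds [{self.start}, {self.end})"
            )


@dataclass
class BoldSignal:
    """A single labeled BOLD time series with acquisition metadata."""

    values: np.ndarray
    tr_seconds: float
    task_label: str = "unknown"
    subject_id: str = ""
    design: list[DesignSegment] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1 or self.values.size < 1:
            raise ValueError("values must be a non-empty 1-D sequence")
        if not np.isfinite(self.values).all():
            raise ValueError("values must be finite")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if self.task_label not in TASK_LABELS + ("unknown",):
            raise ValueError(f"unknown task label {self.task_label!r}")
        if self.design is not None:
            for seg in self.design:
                if seg.end > len(self.values):
                    raise ValueError(
                        f"design segment {seg} exceeds signal length {len(self.values)}"
                    )
            labeled = self.labeled_segments()
            for a, b in zip(labeled, labeled[1:]):
                if b.start < a.end:
                    raise ValueError("labeled design segments overlap")

    def __len__(self) -> int:
        return len(self.values)

    def labeled_segments(self) -> list[DesignSegment]:
        """Design segments carrying a sub-phase label, in temporal order."""
        if self.design is None:
            return []
        segs = [s for s in self.design if s.label not in REST_LABELS]
        return sorted(segs, key=lambda s: s.start)

    @property
    def subphase_labels(self) -> list[str]:
        return [s.label for s in self.labeled_segments()]


@dataclass
class SignalPool:
    """A collection of BOLD signals with a uniform post-padding length."""

    signals: list[BoldSignal]
    target_length: int = DEFAULT_TARGET_LENGTH
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.target_length < 1:
            raise ValueError("target_length must be positive")
        for s in self.signals:
            if not s.subject_id:
                raise ValueError("every pooled signal needs a subject_id")

    def __len__(self) -> int:
        return len(self.signals)

    def __iter__(self):
        return iter(self.signals)

    def conditioned(self) -> "SignalPool":
        """Zero-mean/detrend then pad every signal to ``target_length``."""
        out = [
            pad_to_length(zero_mean_detrend(s), self.target_length)
            for s in self.signals
        ]
        return SignalPool(out, self.target_length, self.provenance)

    def task_labels(self) -> np.ndarray:
        return np.asarray([s.task_label for s in self.signals])

    def subject_ids(self) -> np.ndarray:
        return np.asarray([s.subject_id for s in self.signals])

    def to_matrix(self) -> np.ndarray:
        """Stack signal values row-wise; requires uniform lengths."""
        lengths = {len(s) for s in self.signals}
        if len(lengths) != 1:
            raise ValueError(
                f"pool has mixed signal lengths {sorted(lengths)}; condition it first"
            )
        return np.stack([s.values for s in self.signals])


# ---------------------------------------------------------------------------
# conditioning operations
# ---------------------------------------------------------------------------

def zero_mean_detrend(signal: BoldSignal) -> BoldSignal:
    """Remove the least-squares straight line (slope and mean) from a signal.

    Idempotent up to floating-point error; the output has zero mean and a
    zero best-fit slope.
    """
    x = signal.values
    if x.size < 2:
        raise ValueError("zero_mean_detrend needs at least 2 samples")
    t = np.arange(x.size, dtype=np.float64)
    t = t - t.mean()
    slope = (t @ (x - x.mean())) / (t @ t)
    out = x - x.mean() - slope * t
    return replace(signal, values=out)


def pad_to_length(signal: BoldSignal, target: int) -> BoldSignal:
    """Zero-pad a signal's tail to ``target`` samples; never truncates."""
    if target < 1:
        raise ValueError("target length must be positive")
    n = len(signal)
    if n > target:
        raise ValueError(f"signal length {n} exceeds target {target}; refusing to truncate")
    if n == target:
        return replace(signal, values=signal.values.copy())
    out = np.zeros(target, dtype=np.float64)
    out[:n] = signal.values
    return replace(signal, values=out)


def split_into_phases(signal: BoldSignal, n_segments: int) -> list[BoldSignal]:
    """Split into ``n_segments`` equal contiguous segments, temporal order.

    The emotion task interleaves its three support phases sequentially and
    equally spaced, so a padded 600-sample run splits into three 200-sample
    phase signals. Lengths that do not divide evenly are a hard error.
    """
    if n_segments < 1:
        raise ValueError("n_segments must be positive")
    n = len(signal)
    if n % n_segments:
        raise ValueError(
            f"signal length {n} not divisible by {n_segments}; refusing to truncate"
        )
    width = n // n_segments
    return [
        replace(signal, values=signal.values[i * width : (i + 1) * width].copy(),
                design=None)
        for i in range(n_segments)
    ]


def extract_design_segments(signal: BoldSignal) -> list[tuple[BoldSignal, str]]:
    """Cut out each labeled non-rest design block with its sub-phase label.

    The memory task's encode and recall blocks have no fixed grid, so they
    are recovered from the design metadata rather than by equal division.
    """
    if signal.design is None:
        raise ValueError("signal carries no design metadata")
    out = []
    for seg in signal.labeled_segments():
        piece = replace(
            signal, values=signal.values[seg.start : seg.end].copy(), design=None
        )
        out.append((piece, seg.label))
    return out


# ---------------------------------------------------------------------------
# pool I/O
# ---------------------------------------------------------------------------

_FIXED_COLS = ("subject_id", "task_label", "subphase_spec", "tr_seconds")


def _format_design(design: list[DesignSegment] | None) -> str:
    if not design:
        return ""
    return ";".join(f"{s.label}:{s.start}:{s.end}" for s in design)


def _parse_design(spec: str, line_no: int) -> list[DesignSegment] | None:
    if not spec:
        return None
    segs = []
    for part in spec.split(";"):
        bits = part.split(":")
        if len(bits) != 3:
            raise PoolFormatError(
                f"line {line_no}: malformed subphase_spec entry {part!r}"
            )
        try:
            segs.append(DesignSegment(bits[0], int(bits[1]), int(bits[2])))
        except ValueError as exc:
            raise PoolFormatError(f"line {line_no}: {exc}") from exc
    return segs


def save_pool(pool: SignalPool, path) -> None:
    """Write a pool as delimited text; requires uniform signal lengths.

    Floats are rendered with 17 significant digits so a round-trip reproduces
    the binary values exactly.
    """
    lengths = {len(s) for s in pool.signals}
    if len(lengths) > 1:
        raise ValueError("cannot save a pool with mixed signal lengths; pad first")
    t = lengths.pop() if lengths else pool.target_length
    buf = io.StringIO()
    header = list(_FIXED_COLS) + [f"s{i}" for i in range(t)]
    buf.write(",".join(header) + "\n")
    for s in pool.signals:
        row = [
            s.subject_id,
            s.task_label,
            _format_design(s.design),
            format(s.tr_seconds, ".17g"),
        ]
        row.extend(format(v, ".17g") for v in s.values)
        buf.write(",".join(row) + "\n")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(buf.getvalue())


def load_pool(path, target_length: int | None = None) -> SignalPool:
    """Read a pool file, validating the schema row by row.

    Malformed headers, non-numeric samples and inconsistent column counts
    raise :class:`PoolFormatError` naming the offending line.
    """
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise PoolFormatError("line 1: empty pool file")
    header = lines[0].split(",")
    if tuple(header[:4]) != _FIXED_COLS:
        raise PoolFormatError(
            f"line 1: header must start with {','.join(_FIXED_COLS)}"
        )
    n_samples = len(header) - 4
    if n_samples < 1 or header[4:] != [f"s{i}" for i in range(n_samples)]:
        raise PoolFormatError("line 1: sample columns must be s0..s{T-1}")
    signals = []
    for idx, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        cols = line.split(",")
        if len(cols) != 4 + n_samples:
            raise PoolFormatError(
                f"line {idx}: expected {4 + n_samples} columns, found {len(cols)}"
            )
        try:
            tr = float(cols[3])
            values = np.array(cols[4:], dtype=np.float64)
        except ValueError as exc:
            raise PoolFormatError(f"line {idx}: non-numeric field ({exc})") from exc
        signals.append(
            BoldSignal(
                values=values,
                tr_seconds=tr,
                task_label=cols[1],
                subject_id=cols[0],
                design=_parse_design(cols[2], idx),
            )
        )
    return SignalPool(
        signals,
        target_length=target_length or n_samples,
        provenance=str(path),
    )
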