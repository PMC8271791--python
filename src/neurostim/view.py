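"""Visualization-side signal processing (everything but the drawing).

The live display cannot render 10^7 samples per half second, so channel
traces are reduced with min–max decimation, which keeps single-sample spikes
visible at any reduction factor.  The remaining operations mirror the online
analysis toolbox: trigger-aligned averaging of evoked responses, Butterworth
band splitting (low-pass view for LFPs, high-pass for spikes) and one-sided
magnitude spectra.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.signal

from .errors import AlignmentError
from .protocol import SAMPLE_RATE


@dataclass(frozen=True)
class ViewConfig:
    """Display-pipeline settings for a subset of channels."""

    channels: tuple[int, ...] = ()
    decimation: int = 1
    window_seconds: float = 10.0       # at most the last 10 s are drawn
    voltage_range: tuple[float, float] = (-1.8, 1.8)
    trigger_sources: tuple[int, ...] = ()  # 1-8; multiple lines OR together
    averaging_count: int = 1
    filter_kind: str | None = None     # "low" | "high"
    filter_cutoff: float = 300.0
    filter_order: int = 4

    def __post_init__(self):
        if self.decimation < 1:
            raise ValueError("decimation factor must be >= 1")
        if self.window_seconds > 10.0:
            raise ValueError("display window is limited to 10 s")


def minmax_decimate(x: np.ndarray, factor: int) -> np.ndarray:
    """Min–max decimation: each block of ``factor`` samples contributes its
    minimum and maximum, in temporal order, so rapid single-sample events
    survive any reduction factor and the global extrema are preserved
    exactly.  ``factor=1`` is the identity."""
    if factor < 1:
        raise ValueError("decimation factor must be >= 1")
    x = np.asarray(x)
    if factor == 1 or x.size == 0:
        return x.copy()
    n_full = x.size // factor
    out = []
    if n_full:
        blocks = x[: n_full * factor].reshape(n_full, factor)
        imin = blocks.argmin(axis=1)
        imax = blocks.argmax(axis=1)
        first = np.where(imin <= imax, blocks[np.arange(n_full), imin],
                         blocks[np.arange(n_full), imax])
        second = np.where(imin <= imax, blocks[np.arange(n_full), imax],
                          blocks[np.arange(n_full), imin])
        out.append(np.stack([first, second], axis=1).reshape(-1))
    rest = x[n_full * factor:]
    if rest.size:
        lo, hi = rest.argmin(), rest.argmax()
        pair = [rest[min(lo, hi)], rest[max(lo, hi)]] if lo != hi else [rest[lo], rest[lo]]
        out.append(np.asarray(pair, dtype=x.dtype))
    return np.concatenate(out)


def combine_triggers(triggers: np.ndarray, sources: tuple[int, ...]) -> np.ndarray:
    """Logical OR of the selected trigger lines (1-based) into one virtual
    trigger trace."""
    triggers = np.asarray(triggers, dtype=bool)
    if not sources:
        raise ValueError("at least one trigger source is required")
    out = np.zeros(triggers.shape[-1], dtype=bool)
    for s in sources:
        out |= triggers[s - 1]
    return out


def trigger_align_average(
    data: np.ndarray,
    trigger: np.ndarray,
    window: tuple[int, int],
    n_events: int | None = None,
) -> np.ndarray:
    """Average windows aligned on the trigger's rising edges.

    ``window = (pre, post)`` in samples around each edge (the output is
    ``pre + post`` samples long, the edge at index ``pre``); only events
    whose full window lies inside the data are used.  Raises
    :class:`AlignmentError` when fewer than ``n_events`` usable edges exist.
    """
    data = np.asarray(data, dtype=np.float64)
    trig = np.asarray(trigger, dtype=bool).astype(np.int8)
    pre, post = window
    edges = np.flatnonzero(np.diff(trig) == 1) + 1
    edges = edges[(edges >= pre) & (edges + post <= data.size)]
    if n_events is None:
        n_events = edges.size
    if edges.size < n_events or n_events == 0:
        raise AlignmentError(
            f"need {n_events} trigger events with full windows, found {edges.size}"
        )
    edges = edges[:n_events]
    windows = np.stack([data[e - pre: e + post] for e in edges])
    return windows.mean(axis=0)


def bandsplit_filter(
    x: np.ndarray,
    kind: str,
    fc: float,
    order: int = 4,
    fs: float = SAMPLE_RATE,
) -> np.ndarray:
    """Causal digital Butterworth filter (single pass, -3 dB at ``fc``).

    ``kind`` is ``"low"`` for the LFP view or ``"high"`` for the spike
    view.  The single-pass filter has the textbook magnitude response at the
    cut-off; its (nonlinear) phase delay is the price of causality.
    """
    if kind not in ("low", "high"):
        raise ValueError(f"filter kind must be 'low' or 'high', got {kind!r}")
    if not 0 < fc < fs / 2:
        raise ValueError(f"cut-off must lie in (0, {fs / 2:.0f}) Hz, got {fc}")
    if order < 1:
        raise ValueError("filter order must be >= 1")
    sos = scipy.signal.butter(order, fc, btype=kind, fs=fs, output="sos")
    return scipy.signal.sosfilt(sos, np.asarray(x, dtype=np.float64))


def spectrum(x: np.ndarray, fs: float = SAMPLE_RATE) -> tuple[np.ndarray, np.ndarray]:
    """One-sided magnitude spectrum ``(frequencies, |X(f)|)``.

    Plain rFFT magnitude; Parseval's identity holds in the form
    ``sum x^2 = (|X|^2, doubled off the DC/Nyquist bins) / N``.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.size == 0:
        raise ValueError("empty trace")
    mag = np.abs(np.fft.rfft(x))
    freqs = np.fft.rfftfreq(x.size, d=1.0 / fs)
    return freqs, mag


def clip_and_scale(
    x: np.ndarray, voltage_range: tuple[float, float]
) -> np.ndarray:
    """Clip a trace into the display voltage range (applied before
    decimation, so off-range excursions decimate like rails)."""
    lo, hi = voltage_range
    return np.clip(np.asarray(x, dtype=np.float64), lo, hi)


@dataclass
class ProbeLayout:
    """Channel -> (x, y) canvas positions, loadable from a JSON layout file."""

    positions: dict[int, tuple[float, float]] = field(default_factory=dict)

    @classmethod
    def load(cls, path: str | Path) -> "ProbeLayout":
        raw = json.loads(Path(path).read_text())
        return cls({int(k): (float(v[0]), float(v[1])) for k, v in raw.items()})

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(
            json.dumps({str(k): list(v) for k, v in self.positions.items()}, indent=1)
        )
        return path
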