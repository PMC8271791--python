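"""Demultiplexing of input chunks into per-channel sample matrices.

The input stream interleaves, per 25 µs sampling period, the 12-bit ADC
codes of all 512 channels (64 per chip line) plus eight binary trigger
lines.  :func:`demultiplex` recovers the canonical ``(512 + 8) x samples``
matrix — 520 x 20,000 two-byte values (19.84 MiB) for a standard 0.5 s
chunk.  :func:`sync_filter` implements the sync-queue contract: chunks the
generator re-sent to keep the hardware alive are tagged ``sync_id = -1`` and
must be dropped before any further processing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np

from . import protocol
from .asic import ADC_RAIL
from .errors import SequencingError
from .protocol import N_CHANNELS, N_TRIGGER_LINES, InputChunk

N_ROWS = N_CHANNELS + N_TRIGGER_LINES  # 512 data + 8 trigger rows


@dataclass
class PerChannelData:
    """Demultiplexed sample matrix for one chunk.

    Rows 0–511 hold 12-bit ADC codes (as ``uint16``), rows 512–519 the eight
    trigger lines as 0/1.
    """

    codes: np.ndarray          # (520, n_samples) uint16
    chunk_index: int = 0
    duration: float = protocol.CHUNK_SECONDS

    def __post_init__(self):
        self.codes = np.ascontiguousarray(self.codes, dtype=np.uint16)
        if self.codes.ndim != 2 or self.codes.shape[0] != N_ROWS:
            raise ValueError(
                f"per-channel data must have {N_ROWS} rows, got {self.codes.shape}"
            )
        if self.codes[:N_CHANNELS].max(initial=0) > protocol.ADC_MAX_CODE:
            raise ValueError("data rows exceed the 12-bit ADC code range")
        if not np.isin(self.codes[N_CHANNELS:], (0, 1)).all():
            raise ValueError("trigger rows must be 0/1")

    @property
    def n_samples(self) -> int:
        return self.codes.shape[1]

    @property
    def data(self) -> np.ndarray:
        return self.codes[:N_CHANNELS]

    @property
    def triggers(self) -> np.ndarray:
        return self.codes[N_CHANNELS:].astype(bool)

    @property
    def nbytes(self) -> int:
        return self.codes.size * 2

    @property
    def size_mib(self) -> float:
        return self.nbytes / 2**20


def demultiplex(chunk: InputChunk) -> PerChannelData:
    """Exact inverse of the simulator's multiplexing.

    Vacant chip slots arrive as the constant mid-rail idle code and pass
    through unchanged.
    """
    if chunk.sync_id < 0:
        raise SequencingError(
            "refusing to demultiplex a repeated (sync_id = -1) chunk; "
            "apply sync_filter first"
        )
    codes, triggers = protocol.unpack_samples(chunk)
    matrix = np.empty((N_ROWS, chunk.n_periods), dtype=np.uint16)
    matrix[:N_CHANNELS] = codes.T
    matrix[N_CHANNELS:] = triggers.T
    return PerChannelData(matrix, chunk_index=chunk.sync_id, duration=chunk.duration)


def sync_filter(
    stream: Iterable[tuple[InputChunk, int] | InputChunk],
) -> Iterator[InputChunk]:
    """Drop repeated chunks (sync_id -1), enforce strictly increasing ids.

    Accepts either ``(chunk, sync_id)`` pairs or chunks carrying their own
    ``sync_id``; order of surviving chunks is preserved.
    """
    last = -1
    for item in stream:
        if isinstance(item, tuple):
            chunk, sync_id = item
        else:
            chunk, sync_id = item, item.sync_id
        if sync_id == -1:
            continue
        if sync_id <= last:
            raise SequencingError(
                f"sync ids must be strictly increasing, got {sync_id} after {last}"
            )
        last = sync_id
        yield chunk


def codes_to_volts(data: PerChannelData | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Affine inverse of the ADC map: code 0 -> -1.8 V, 4095 -> +1.8 V.

    Returns ``(volts (512, n), triggers (8, n) bool)``; when given a bare
    code array of data rows, returns volts with an empty trigger array.
    """
    if isinstance(data, PerChannelData):
        codes = data.data
        triggers = data.triggers
    else:
        codes = np.asarray(data)
        triggers = np.zeros((0, codes.shape[-1]), dtype=bool)
    if codes.max(initial=0) > protocol.ADC_MAX_CODE:
        raise ValueError("codes exceed the 12-bit ADC range")
    volts = codes.astype(np.float64) / protocol.ADC_MAX_CODE * (2 * ADC_RAIL) - ADC_RAIL
    return volts, triggers
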