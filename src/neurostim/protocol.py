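"""Bit-packed command protocol for the stimulation/recording ASIC stream.

The acquisition hardware exchanges two continuous streams with up to eight
64-channel stimulation/recording ASICs:

* the **output bitstream** carries commands *to* the chips — rare register
  (state-change) commands plus one *real-time data command* per 25 µs
  sampling period and per chip, holding a stimulation control word for every
  channel;
* the **input bitstream** carries the multiplexed 12-bit ADC samples *from*
  the chips, plus eight external trigger lines.

Both streams are driven over a 16-line digital interface clocked at 50 MHz:
one 16-bit word per clock tick, bit ``i`` of each word being the level of
line ``i`` at that tick.  Lines 0–7 each belong to one ASIC; lines 8–15 are
trigger lines.  One second of stream is therefore 5x10^7 16-bit words
(95.37 MiB), and the stream is handled in 0.5 s chunks of 2.5x10^7 words.

Wire dialect
------------
The original silicon's framing is proprietary; the layout implemented here
is a documented stand-in that reproduces the interface rates exactly.  Each
ASIC line carries one 1250-bit frame per sampling period
(50 MHz / 40 kHz = 1250 ticks), all fields most-significant-bit first:

====================  ==========================================================
bits                  output-frame content
====================  ==========================================================
``[0, 8)``            opcode byte: ``0x00`` no-op frame, ``0x02`` real-time data
``[8, 776)``          64 channel control words, 12 bits each:
                      ``polarity<<11 | dac4bit<<7 | dac7bit``
``[776, 1248)``       state-record region: up to 14 records of 32 bits
                      (``register_id:8 | channel:8 | value:16``); register id 0
                      terminates the list; channel ``0xFF`` addresses the chip
                      globally (or every channel, for per-channel registers)
====================  ==========================================================

State records may only occupy the record regions of the *leading* frames of
a chunk (region of frame ``k`` may be used only when regions of frames
``0..k-1`` are full).  Logically all state commands therefore precede every
real-time command of the chunk, which is exactly the ordering the hardware
requires and the simulator assumes.

Input frames are simpler: bits ``[0, 768)`` are the 64 channels' 12-bit ADC
codes of that sampling period, the rest of the frame idles at zero.  Trigger
lines (8–15) hold their binary level for all 1250 ticks of a period in both
directions.

Serialized chunks are flat little-endian ``uint16`` arrays; chunk metadata
(duration, sync id, direction) travels in a JSON sidecar header.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple, Sequence

import numpy as np

from .errors import (
    CapacityError,
    DecodeError,
    ProtocolOrderError,
    RegisterRangeError,
)

# --- interface constants -----------------------------------------------------

LINE_RATE = 50_000_000          # ticks (bits per line) per second
SAMPLE_RATE = 40_000            # Hz, fixed channel sampling rate
BITS_PER_PERIOD = LINE_RATE // SAMPLE_RATE  # 1250 ticks per sampling period
N_DATA_LINES = 8                # lines 0-7, one per ASIC
N_TRIGGER_LINES = 8             # lines 8-15
CHANNELS_PER_ASIC = 64
N_CHANNELS = N_DATA_LINES * CHANNELS_PER_ASIC  # 512
CHUNK_SECONDS = 0.5             # canonical chunk duration
WORDS_PER_SECOND = LINE_RATE    # one 16-bit word per tick

ADC_BITS = 12
ADC_MAX_CODE = 2 ** ADC_BITS - 1  # 4095

GAIN_LEVELS = (100, 150, 200, 250, 300, 400, 500)

OP_NOP = 0x00
OP_RT = 0x02

_RT_PAYLOAD_START = 8
_RT_PAYLOAD_BITS = CHANNELS_PER_ASIC * 12  # 768
_STATE_REGION_START = _RT_PAYLOAD_START + _RT_PAYLOAD_BITS  # 776
_RECORD_BITS = 32
RECORDS_PER_FRAME = (BITS_PER_PERIOD - _STATE_REGION_START) // _RECORD_BITS  # 14
_GLOBAL_CHANNEL = 0xFF

# register name -> (wire id, lo, hi, per_channel)
_REGISTERS = {
    "dac10bit": (1, 0, 1023, False),
    "hp_reg": (2, 0, 31, False),
    "lp_reg": (3, 0, 31, False),
    "gain": (4, min(GAIN_LEVELS), max(GAIN_LEVELS), True),
    "stim_enable": (5, 0, 1, True),
}
_REGISTER_BY_ID = {v[0]: k for k, v in _REGISTERS.items()}


def chunk_word_count(duration: float) -> int:
    """Number of 16-bit words in a chunk of ``duration`` seconds."""
    n = duration * WORDS_PER_SECOND
    if abs(n - round(n)) > 1e-6 or round(n) % BITS_PER_PERIOD:
        raise ValueError(
            f"duration {duration} s is not a whole number of sampling periods"
        )
    return int(round(n))


def chunk_period_count(duration: float) -> int:
    """Number of 25 µs sampling periods in a chunk of ``duration`` seconds."""
    return chunk_word_count(duration) // BITS_PER_PERIOD


# --- command model -----------------------------------------------------------


@dataclass(frozen=True)
class StateCommand:
    """One register assignment (chip- or channel-level state change)."""

    register: str
    value: int
    channel: int | None = None  # None = global / all channels
    asic: int = 0

    def __post_init__(self):
        _validate_register(self.register, self.value, self.channel)
        if not 0 <= self.asic < N_DATA_LINES:
            raise RegisterRangeError("asic", self.asic, 0, N_DATA_LINES - 1)


def _validate_register(register: str, value: int, channel: int | None) -> None:
    if register not in _REGISTERS:
        raise RegisterRangeError(register, value, "-", "-")
    _, lo, hi, per_channel = _REGISTERS[register]
    if register == "gain":
        if value not in GAIN_LEVELS:
            raise RegisterRangeError("gain", value, GAIN_LEVELS, GAIN_LEVELS)
    elif not (isinstance(value, (int, np.integer)) and lo <= value <= hi):
        raise RegisterRangeError(register, value, lo, hi)
    if channel is not None:
        if not per_channel:
            raise RegisterRangeError(register, channel, "global register", "")
        if not 0 <= channel < CHANNELS_PER_ASIC:
            raise RegisterRangeError("channel", channel, 0, CHANNELS_PER_ASIC - 1)


def encode_state_command(
    register: str, value: int, channel: int | None = None, asic: int = 0
) -> StateCommand:
    """Validate and build a self-delimiting state-change command record."""
    return StateCommand(register, int(value), channel, asic)


@dataclass(frozen=True)
class RtChannelWord:
    """Per-channel, per-period stimulation control word."""

    dac7bit: int
    dac4bit: int
    polarity: int

    def __post_init__(self):
        if not 0 <= self.dac7bit <= 127:
            raise RegisterRangeError("dac7bit", self.dac7bit, 0, 127)
        if not 0 <= self.dac4bit <= 15:
            raise RegisterRangeError("dac4bit", self.dac4bit, 0, 15)
        if self.polarity not in (0, 1):
            raise RegisterRangeError("polarity", self.polarity, 0, 1)


class RealTimeDataCommand:
    """One sampling period's stimulation control: 64 channel words + triggers.

    Channel codes are stored as small numpy arrays; :attr:`words` exposes the
    per-channel :class:`RtChannelWord` view.
    """

    __slots__ = ("dac7bit", "dac4bit", "polarity", "trigger_bits", "asic")

    def __init__(self, dac7bit, dac4bit, polarity, trigger_bits=None, asic: int = 0):
        self.dac7bit = np.broadcast_to(
            np.asarray(dac7bit, dtype=np.uint8), (CHANNELS_PER_ASIC,)
        ).copy()
        self.dac4bit = np.broadcast_to(
            np.asarray(dac4bit, dtype=np.uint8), (CHANNELS_PER_ASIC,)
        ).copy()
        self.polarity = np.broadcast_to(
            np.asarray(polarity, dtype=np.uint8), (CHANNELS_PER_ASIC,)
        ).copy()
        if self.dac7bit.max(initial=0) > 127:
            raise RegisterRangeError("dac7bit", int(self.dac7bit.max()), 0, 127)
        if self.dac4bit.max(initial=0) > 15:
            raise RegisterRangeError("dac4bit", int(self.dac4bit.max()), 0, 15)
        if self.polarity.max(initial=0) > 1:
            raise RegisterRangeError("polarity", int(self.polarity.max()), 0, 1)
        if trigger_bits is None:
            trigger_bits = np.zeros(N_TRIGGER_LINES, dtype=bool)
        self.trigger_bits = np.broadcast_to(
            np.asarray(trigger_bits, dtype=bool), (N_TRIGGER_LINES,)
        ).copy()
        self.asic = int(asic)

    @classmethod
    def idle(cls, asic: int = 0) -> "RealTimeDataCommand":
        return cls(0, 0, 1, asic=asic)

    @classmethod
    def from_words(
        cls, words: Sequence[RtChannelWord], trigger_bits=None, asic: int = 0
    ) -> "RealTimeDataCommand":
        if len(words) != CHANNELS_PER_ASIC:
            raise ValueError(f"expected {CHANNELS_PER_ASIC} channel words, got {len(words)}")
        return cls(
            [w.dac7bit for w in words],
            [w.dac4bit for w in words],
            [w.polarity for w in words],
            trigger_bits,
            asic,
        )

    @property
    def words(self) -> list[RtChannelWord]:
        return [
            RtChannelWord(int(d7), int(d4), int(p))
            for d7, d4, p in zip(self.dac7bit, self.dac4bit, self.polarity)
        ]

    def __eq__(self, other) -> bool:
        if not isinstance(other, RealTimeDataCommand):
            return NotImplemented
        return (
            self.asic == other.asic
            and np.array_equal(self.dac7bit, other.dac7bit)
            and np.array_equal(self.dac4bit, other.dac4bit)
            and np.array_equal(self.polarity, other.polarity)
            and np.array_equal(self.trigger_bits, other.trigger_bits)
        )

    def __repr__(self) -> str:
        active = int(np.count_nonzero(self.dac7bit))
        return f"<RealTimeDataCommand asic={self.asic} active_channels={active}>"


class RealTimeStream:
    """Array-backed sequence of real-time commands parsed from one line."""

    def __init__(self, dac7bit, dac4bit, polarity, triggers, periods, asic: int = 0):
        self.dac7bit = np.asarray(dac7bit, dtype=np.uint8)    # (k, 64)
        self.dac4bit = np.asarray(dac4bit, dtype=np.uint8)    # (k, 64)
        self.polarity = np.asarray(polarity, dtype=np.uint8)  # (k, 64)
        self.triggers = np.asarray(triggers, dtype=bool)      # (k, 8)
        self.periods = np.asarray(periods, dtype=np.int64)    # (k,) frame indices
        self.asic = int(asic)

    def __len__(self) -> int:
        return self.dac7bit.shape[0]

    def __getitem__(self, i: int) -> RealTimeDataCommand:
        return RealTimeDataCommand(
            self.dac7bit[i], self.dac4bit[i], self.polarity[i],
            self.triggers[i], self.asic,
        )

    def __iter__(self) -> Iterator[RealTimeDataCommand]:
        for i in range(len(self)):
            yield self[i]

    def __eq__(self, other) -> bool:
        if not isinstance(other, RealTimeStream):
            return NotImplemented
        return (
            self.asic == other.asic
            and np.array_equal(self.periods, other.periods)
            and np.array_equal(self.dac7bit, other.dac7bit)
            and np.array_equal(self.dac4bit, other.dac4bit)
            and np.array_equal(self.polarity, other.polarity)
            and np.array_equal(self.triggers, other.triggers)
        )


# --- chunk containers --------------------------------------------------------


@dataclass
class _Chunk:
    words: np.ndarray
    duration: float = CHUNK_SECONDS
    sync_id: int = 0

    def __post_init__(self):
        self.words = np.ascontiguousarray(self.words, dtype=np.uint16)
        expected = chunk_word_count(self.duration)
        if self.words.shape != (expected,):
            raise ValueError(
                f"chunk of {self.duration} s must hold {expected} words, "
                f"got shape {self.words.shape}"
            )

    @property
    def n_periods(self) -> int:
        return self.words.size // BITS_PER_PERIOD

    @property
    def nbytes(self) -> int:
        return self.words.size * 2

    @property
    def size_mib(self) -> float:
        """Serialized size in binary mebibytes."""
        return self.nbytes / 2**20

    def tobytes(self) -> bytes:
        return self.words.astype("<u2").tobytes()


@dataclass
class BitstreamChunk(_Chunk):
    """0.5 s (by default) of packed output-stream words (commands)."""


@dataclass
class InputChunk(_Chunk):
    """0.5 s (by default) of multiplexed ADC samples and trigger lines."""


class ParsedChunk(NamedTuple):
    state_commands: list[StateCommand]
    realtime: dict[int, RealTimeStream]   # keyed by ASIC line
    triggers: np.ndarray                  # (n_periods, 8) bool


# --- bit helpers -------------------------------------------------------------


def _to_bits(values: np.ndarray, nbits: int) -> np.ndarray:
    """uint array (...,) -> bit array (..., nbits), MSB first."""
    shifts = np.arange(nbits - 1, -1, -1)
    return ((values[..., None].astype(np.int64) >> shifts) & 1).astype(np.uint8)


def _from_bits(bits: np.ndarray) -> np.ndarray:
    """bit array (..., nbits) MSB first -> int64 values (...,)."""
    nbits = bits.shape[-1]
    weights = 1 << np.arange(nbits - 1, -1, -1, dtype=np.int64)
    return bits.astype(np.int64) @ weights


def _pack12(values: np.ndarray) -> np.ndarray:
    """(m, k) 12-bit values -> (m, k*12) bit array, MSB first (fast path)."""
    m, k = values.shape
    be = np.ascontiguousarray(values, dtype=">u2").view(np.uint8).reshape(m, k, 2)
    bits16 = np.unpackbits(be, axis=2)           # (m, k, 16)
    return np.ascontiguousarray(bits16[:, :, 4:]).reshape(m, k * 12)


def _unpack12(bits: np.ndarray) -> np.ndarray:
    """(m, k*12) bit array MSB first -> (m, k) uint16 values (fast path)."""
    m = bits.shape[0]
    k = bits.shape[1] // 12
    padded = np.zeros((m, k, 16), dtype=np.uint8)
    padded[:, :, 4:] = bits.reshape(m, k, 12)
    by = np.packbits(padded, axis=2)             # (m, k, 2)
    return (
        np.ascontiguousarray(by).reshape(m, 2 * k).view(">u2").astype(np.uint16)
    )


# --- packing -----------------------------------------------------------------


@dataclass
class RtBlock:
    """Dense per-line real-time payload used by the fast packing path.

    ``mask[i]`` says whether period ``i`` carries a real-time command; code
    arrays hold one row per period (rows where ``mask`` is False are ignored).
    """

    mask: np.ndarray     # (n_periods,) bool
    dac7bit: np.ndarray  # (n_periods, 64) uint8
    dac4bit: np.ndarray  # (n_periods, 64) uint8
    polarity: np.ndarray  # (n_periods, 64) uint8

    @classmethod
    def idle(cls, n_periods: int) -> "RtBlock":
        return cls(
            mask=np.ones(n_periods, dtype=bool),
            dac7bit=np.zeros((n_periods, CHANNELS_PER_ASIC), dtype=np.uint8),
            dac4bit=np.zeros((n_periods, CHANNELS_PER_ASIC), dtype=np.uint8),
            polarity=np.ones((n_periods, CHANNELS_PER_ASIC), dtype=np.uint8),
        )


def pack_chunk_arrays(
    rt: dict[int, RtBlock],
    state_commands: Sequence[StateCommand] = (),
    triggers: np.ndarray | None = None,
    duration: float = CHUNK_SECONDS,
    sync_id: int = 0,
) -> BitstreamChunk:
    """Pack dense per-line arrays into an output chunk (vectorized path)."""
    n_periods = chunk_period_count(duration)
    words = np.zeros(n_periods * BITS_PER_PERIOD, dtype=np.uint16)

    states_by_line: dict[int, list[StateCommand]] = {}
    for cmd in state_commands:
        states_by_line.setdefault(cmd.asic, []).append(cmd)

    for line in sorted(set(rt) | set(states_by_line)):
        if not 0 <= line < N_DATA_LINES:
            raise RegisterRangeError("asic", line, 0, N_DATA_LINES - 1)
        bits = np.zeros((n_periods, BITS_PER_PERIOD), dtype=np.uint8)
        block = rt.get(line)
        if block is not None:
            if block.mask.shape != (n_periods,):
                raise CapacityError(
                    f"real-time block for line {line} has {block.mask.shape[0]} "
                    f"periods, chunk holds {n_periods}"
                )
            idx = np.flatnonzero(block.mask)
            bits[idx, 6] = 1  # opcode byte 0x02
            cw = (
                (block.polarity[idx].astype(np.uint16) << 11)
                | (block.dac4bit[idx].astype(np.uint16) << 7)
                | block.dac7bit[idx].astype(np.uint16)
            )
            bits[idx, _RT_PAYLOAD_START:_STATE_REGION_START] = _pack12(cw)
        records = states_by_line.get(line, [])
        if len(records) > RECORDS_PER_FRAME * n_periods:
            raise CapacityError(
                f"{len(records)} state records exceed chunk capacity of "
                f"{RECORDS_PER_FRAME * n_periods}"
            )
        for j, cmd in enumerate(records):
            frame, slot = divmod(j, RECORDS_PER_FRAME)
            start = _STATE_REGION_START + slot * _RECORD_BITS
            reg_id = _REGISTERS[cmd.register][0]
            chan = _GLOBAL_CHANNEL if cmd.channel is None else cmd.channel
            bits[frame, start:start + 8] = _to_bits(np.asarray(reg_id), 8)
            bits[frame, start + 8:start + 16] = _to_bits(np.asarray(chan), 8)
            bits[frame, start + 16:start + 32] = _to_bits(np.asarray(cmd.value), 16)
        words |= bits.reshape(-1).astype(np.uint16) << line

    if triggers is not None:
        triggers = np.asarray(triggers, dtype=bool)
        if triggers.shape != (n_periods, N_TRIGGER_LINES):
            raise ValueError(
                f"trigger array must be (n_periods, 8), got {triggers.shape}"
            )
        for j in range(N_TRIGGER_LINES):
            if triggers[:, j].any():
                words |= np.repeat(
                    triggers[:, j].astype(np.uint16), BITS_PER_PERIOD
                ) << (N_DATA_LINES + j)

    return BitstreamChunk(words, duration, sync_id)


def pack_chunk(
    commands: Iterable[StateCommand | RealTimeDataCommand],
    duration: float = CHUNK_SECONDS,
    sync_id: int = 0,
) -> BitstreamChunk:
    """Pack an ordered command list into an output chunk.

    State commands must all precede the first real-time command (per line);
    real-time commands occupy consecutive sampling periods from the start of
    the chunk, remaining periods are padded with no-op frames.
    """
    n_periods = chunk_period_count(duration)
    states: list[StateCommand] = []
    rt_cmds: dict[int, list[RealTimeDataCommand]] = {}
    seen_rt: set[int] = set()
    n_rt = 0
    triggers = np.zeros((n_periods, N_TRIGGER_LINES), dtype=bool)
    for cmd in commands:
        if isinstance(cmd, StateCommand):
            if cmd.asic in seen_rt:
                raise ProtocolOrderError(
                    f"state command {cmd.register!r} after the first real-time "
                    f"command on line {cmd.asic}"
                )
            states.append(cmd)
        elif isinstance(cmd, RealTimeDataCommand):
            seen_rt.add(cmd.asic)
            lst = rt_cmds.setdefault(cmd.asic, [])
            if len(lst) >= n_periods:
                raise CapacityError(
                    f"more than {n_periods} real-time commands for line "
                    f"{cmd.asic} in a {duration} s chunk"
                )
            triggers[len(lst)] |= cmd.trigger_bits
            lst.append(cmd)
            n_rt += 1
        else:
            raise TypeError(f"not a command: {cmd!r}")

    rt_blocks: dict[int, RtBlock] = {}
    for line, cmds in rt_cmds.items():
        mask = np.zeros(n_periods, dtype=bool)
        mask[: len(cmds)] = True
        arrays = []
        for attr in ("dac7bit", "dac4bit", "polarity"):
            a = np.zeros((n_periods, CHANNELS_PER_ASIC), dtype=np.uint8)
            a[: len(cmds)] = np.stack([getattr(c, attr) for c in cmds])
            arrays.append(a)
        rt_blocks[line] = RtBlock(mask, *arrays)

    return pack_chunk_arrays(rt_blocks, states, triggers, duration, sync_id)


# --- parsing -----------------------------------------------------------------


def _parse_state_region(bits: np.ndarray, line: int) -> list[StateCommand]:
    """Decode state records from the leading frames' record regions."""
    n_periods = bits.shape[0]
    region = bits[:, _STATE_REGION_START:
                  _STATE_REGION_START + RECORDS_PER_FRAME * _RECORD_BITS]
    recs = region.reshape(n_periods, RECORDS_PER_FRAME, _RECORD_BITS)
    reg_ids = _from_bits(recs[:, :, :8])          # (n_periods, 14)
    has_any = reg_ids.any(axis=1)
    frames = np.flatnonzero(has_any)
    if frames.size == 0:
        return []
    last = int(frames[-1])
    if not np.array_equal(frames, np.arange(last + 1)):
        raise ProtocolOrderError(
            f"state records after the real-time region on line {line}"
        )
    commands: list[StateCommand] = []
    for f in range(last + 1):
        row = reg_ids[f]
        stop = np.flatnonzero(row == 0)
        count = int(stop[0]) if stop.size else RECORDS_PER_FRAME
        if f < last and count < RECORDS_PER_FRAME:
            raise ProtocolOrderError(
                f"state records resume after a gap on line {line} "
                f"(frame {f} not full)"
            )
        for slot in range(count):
            reg_id = int(row[slot])
            if reg_id not in _REGISTER_BY_ID:
                raise DecodeError(
                    f"unknown register id {reg_id}",
                    line=line,
                    word_offset=f * BITS_PER_PERIOD,
                )
            chan = int(_from_bits(recs[f, slot, 8:16][None])[0])
            value = int(_from_bits(recs[f, slot, 16:32][None])[0])
            commands.append(
                StateCommand(
                    _REGISTER_BY_ID[reg_id],
                    value,
                    None if chan == _GLOBAL_CHANNEL else chan,
                    asic=line,
                )
            )
    return commands


def parse_chunk(chunk: BitstreamChunk) -> ParsedChunk:
    """Decode an output chunk back into state and real-time commands.

    Enforces the protocol ordering (state changes only before the first
    real-time command) and raises :class:`DecodeError` with the word offset
    of any unknown opcode.
    """
    n_periods = chunk.n_periods
    frames16 = chunk.words.reshape(n_periods, BITS_PER_PERIOD)
    trig_shifts = np.arange(N_DATA_LINES, 16)
    triggers = ((frames16[:, 0:1].astype(np.int64) >> trig_shifts) & 1).astype(bool)

    state_commands: list[StateCommand] = []
    realtime: dict[int, RealTimeStream] = {}
    used_lines = int(np.bitwise_or.reduce(chunk.words))
    for line in range(N_DATA_LINES):
        if not (used_lines >> line) & 1:
            continue  # vacant line, never driven
        bits = ((frames16 >> line) & 1).astype(np.uint8)
        opcodes = _from_bits(bits[:, :_RT_PAYLOAD_START])
        bad = ~np.isin(opcodes, (OP_NOP, OP_RT))
        if bad.any():
            period = int(np.flatnonzero(bad)[0])
            raise DecodeError(
                f"unknown opcode 0x{int(opcodes[period]):02x}",
                line=line,
                word_offset=period * BITS_PER_PERIOD,
            )
        state_commands.extend(_parse_state_region(bits, line))
        rt_mask = opcodes == OP_RT
        if rt_mask.any():
            idx = np.flatnonzero(rt_mask)
            payload = bits[idx, _RT_PAYLOAD_START:_STATE_REGION_START]
            cw = _unpack12(payload)
            realtime[line] = RealTimeStream(
                dac7bit=cw & 0x7F,
                dac4bit=(cw >> 7) & 0xF,
                polarity=(cw >> 11) & 1,
                triggers=triggers[idx],
                periods=idx,
                asic=line,
            )
    return ParsedChunk(state_commands, realtime, triggers)


# --- input-stream multiplexing ----------------------------------------------


def pack_samples(
    codes: np.ndarray,
    triggers: np.ndarray | None = None,
    duration: float = CHUNK_SECONDS,
    sync_id: int = 0,
) -> InputChunk:
    """Multiplex per-channel ADC codes into an input chunk.

    ``codes`` is ``(n_periods, 512)`` with 12-bit values; channel ``c`` lives
    on line ``c // 64`` at slot ``c % 64``.
    """
    n_periods = chunk_period_count(duration)
    codes = np.asarray(codes)
    if codes.shape != (n_periods, N_CHANNELS):
        raise ValueError(
            f"codes must be (n_periods, {N_CHANNELS}) = ({n_periods}, {N_CHANNELS}), "
            f"got {codes.shape}"
        )
    if codes.max(initial=0) > ADC_MAX_CODE:
        raise ValueError(f"sample codes exceed {ADC_MAX_CODE}")
    # lines whose codes never change (idle/vacant chips) contribute one
    # repeating 1250-tick pattern; build it once and tile
    base = np.zeros(BITS_PER_PERIOD, dtype=np.uint16)
    varying: list[int] = []
    for line in range(N_DATA_LINES):
        chan_codes = codes[:, line * CHANNELS_PER_ASIC:(line + 1) * CHANNELS_PER_ASIC]
        if (chan_codes == chan_codes[0]).all():
            frame = np.zeros(BITS_PER_PERIOD, dtype=np.uint16)
            frame[:_RT_PAYLOAD_BITS] = _pack12(chan_codes[0][None])[0]
            base |= frame << line
        else:
            varying.append(line)
    words = (
        np.tile(base, n_periods)
        if base.any()
        else np.zeros(n_periods * BITS_PER_PERIOD, dtype=np.uint16)
    )
    for line in varying:
        chan_codes = codes[:, line * CHANNELS_PER_ASIC:(line + 1) * CHANNELS_PER_ASIC]
        bits = np.zeros((n_periods, BITS_PER_PERIOD), dtype=np.uint8)
        bits[:, :_RT_PAYLOAD_BITS] = _pack12(chan_codes)
        words |= bits.reshape(-1).astype(np.uint16) << line
    if triggers is not None:
        triggers = np.asarray(triggers, dtype=bool)
        if triggers.shape != (n_periods, N_TRIGGER_LINES):
            raise ValueError(f"trigger array must be (n_periods, 8), got {triggers.shape}")
        for j in range(N_TRIGGER_LINES):
            if triggers[:, j].any():
                words |= np.repeat(
                    triggers[:, j].astype(np.uint16), BITS_PER_PERIOD
                ) << (N_DATA_LINES + j)
    return InputChunk(words, duration, sync_id)


def unpack_samples(chunk: InputChunk) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`pack_samples`: ``(codes (n, 512), triggers (n, 8))``."""
    n_periods = chunk.n_periods
    frames16 = chunk.words.reshape(n_periods, BITS_PER_PERIOD)
    payload = frames16[:, :_RT_PAYLOAD_BITS]
    codes = np.empty((n_periods, N_CHANNELS), dtype=np.uint16)
    for line in range(N_DATA_LINES):
        sl = slice(line * CHANNELS_PER_ASIC, (line + 1) * CHANNELS_PER_ASIC)
        mask = np.uint16(1 << line)
        if not ((payload ^ payload[0]) & mask).any():
            # constant line (idle/vacant chip): decode one period, broadcast
            row = _unpack12(((payload[0:1] >> line) & 1).astype(np.uint8))
            codes[:, sl] = row[0]
        else:
            bits = ((payload >> line) & 1).astype(np.uint8)
            codes[:, sl] = _unpack12(bits)
    trig_shifts = np.arange(N_DATA_LINES, 16)
    triggers = ((frames16[:, 0:1].astype(np.int64) >> trig_shifts) & 1).astype(bool)
    return codes, triggers


# --- chunk file I/O ----------------------------------------------------------


def write_chunk(chunk: _Chunk, path: str | Path) -> Path:
    """Serialize a chunk as raw little-endian words plus a JSON sidecar."""
    path = Path(path)
    path.write_bytes(chunk.tobytes())
    header = {
        "duration": chunk.duration,
        "sync_id": chunk.sync_id,
        "direction": "input" if isinstance(chunk, InputChunk) else "output",
        "dtype": "<u2",
    }
    Path(str(path) + ".hdr.json").write_text(json.dumps(header))
    return path


def read_chunk(path: str | Path) -> _Chunk:
    path = Path(path)
    header = json.loads(Path(str(path) + ".hdr.json").read_text())
    words = np.frombuffer(path.read_bytes(), dtype="<u2").astype(np.uint16)
    cls = InputChunk if header["direction"] == "input" else BitstreamChunk
    return cls(words, header["duration"], header["sync_id"])
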