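"""Dataset persistence and replay.

Every run is archived as one HDF5 file holding the demultiplexed
per-channel chunks, the simulated stimulation waveforms, and the setup data
(register images plus the experiment-protocol JSON), with optional gzip
compression — worthwhile when few chip slots are populated, since vacant
channels carry constant data.  The Data Player re-emits stored chunks over
any time window so downstream consumers cannot tell replay from a live run.

File layout (format version 1):

========================  =====================================================
path                      content
========================  =====================================================
``/meta``                 attrs: ``version``, ``sample_rate``, ``chunk_seconds``
``/setup/protocol``       experiment JSON (UTF-8 string dataset)
``/setup/asic_states``    JSON of ``{asic: register image}``
``/data``                 ``(n_chunks, 520, samples_per_chunk)`` uint16
``/simulation``           optional ``(n_chunks, channels, samples)`` float32
``/simulation_channels``  system channel index of each simulation row
========================  =====================================================
"""

from __future__ import annotations

import json
import threading
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import h5py
import numpy as np

from . import stim
from .asic import AsicState
from .demux import N_ROWS, PerChannelData
from .errors import ReplayBusyError
from .protocol import CHUNK_SECONDS, SAMPLE_RATE

FORMAT_VERSION = 1

_replay_lock = threading.Lock()
_active = False


def write_dataset(
    path: str | Path,
    chunks: Sequence[PerChannelData],
    setup: Mapping[int, AsicState] | AsicState,
    protocol_json: Mapping | str | None = None,
    simulation: Sequence[np.ndarray] | None = None,
    simulation_channels: Sequence[int] | None = None,
    compress: bool = False,
) -> Path:
    """Archive demultiplexed chunks with the run's setup data.

    ``setup`` (the register images) is mandatory — a dataset without its
    configuration cannot be interpreted.  ``simulation`` optionally stores
    the per-chunk ideal stimulation waveforms for the channels listed in
    ``simulation_channels``.
    """
    if setup is None:
        raise ValueError("setup data is required to archive a dataset")
    if isinstance(setup, AsicState):
        setup = {0: setup}
    if not chunks:
        raise ValueError("nothing to archive: no chunks")
    n_samples = chunks[0].n_samples
    for c in chunks:
        if c.n_samples != n_samples:
            raise ValueError("all chunks must have the same length")
    path = Path(path)
    opts = {"compression": "gzip", "compression_opts": 4} if compress else {}
    with h5py.File(path, "w") as f:
        meta = f.create_group("meta")
        meta.attrs["version"] = FORMAT_VERSION
        meta.attrs["sample_rate"] = SAMPLE_RATE
        meta.attrs["chunk_seconds"] = chunks[0].duration
        grp = f.create_group("setup")
        if protocol_json is None:
            protocol_json = {}
        if not isinstance(protocol_json, str):
            protocol_json = json.dumps(protocol_json)
        grp.create_dataset("protocol", data=protocol_json)
        grp.create_dataset(
            "asic_states",
            data=json.dumps({str(a): stim._state_to_dict(s) for a, s in setup.items()}),
        )
        data = f.create_dataset(
            "data",
            shape=(len(chunks), N_ROWS, n_samples),
            dtype=np.uint16,
            chunks=(1, N_ROWS, n_samples),
            **opts,
        )
        for i, c in enumerate(chunks):
            data[i] = c.codes
        if simulation is not None:
            sim = np.stack([np.asarray(s, dtype=np.float32) for s in simulation])
            f.create_dataset("simulation", data=sim, **opts)
            if simulation_channels is not None:
                f.create_dataset(
                    "simulation_channels",
                    data=np.asarray(simulation_channels, dtype=np.int64),
                )
    return path


@dataclass
class Dataset:
    """In-memory view of an archived run."""

    chunks: list[PerChannelData]
    setup: dict[int, AsicState]
    protocol: dict
    simulation: np.ndarray | None = None
    simulation_channels: np.ndarray | None = None
    chunk_seconds: float = CHUNK_SECONDS

    @property
    def duration(self) -> float:
        return len(self.chunks) * self.chunk_seconds

    def channel_trace(self, channel: int) -> np.ndarray:
        """Concatenated uint16 codes of one channel across all chunks."""
        return np.concatenate([c.codes[channel] for c in self.chunks])


def read_dataset(path: str | Path) -> Dataset:
    with h5py.File(path, "r") as f:
        version = int(f["meta"].attrs["version"])
        if version != FORMAT_VERSION:
            raise ValueError(f"unsupported dataset format version {version}")
        chunk_seconds = float(f["meta"].attrs["chunk_seconds"])
        states_raw = json.loads(f["setup/asic_states"][()].decode())
        setup = {int(a): stim._state_from_dict(d) for a, d in states_raw.items()}
        protocol = json.loads(f["setup/protocol"][()].decode())
        data = f["data"][:]
        simulation = f["simulation"][:] if "simulation" in f else None
        sim_channels = (
            f["simulation_channels"][:] if "simulation_channels" in f else None
        )
    chunks = [
        PerChannelData(data[i], chunk_index=i, duration=chunk_seconds)
        for i in range(data.shape[0])
    ]
    return Dataset(chunks, setup, protocol, simulation, sim_channels, chunk_seconds)


def replay(
    path: str | Path, t_start: float = 0.0, t_end: float | None = None
) -> Iterator[PerChannelData]:
    """Re-emit the stored chunks overlapping ``[t_start, t_end)`` in order.

    Only one replay (and no live run) may be active at a time — a second
    request raises :class:`ReplayBusyError`.  The generator must be consumed
    (or closed) to release the player.
    """
    global _active
    with _replay_lock:
        if _active:
            raise ReplayBusyError("another replay or experiment is running")
        _active = True
    try:
        with h5py.File(path, "r") as f:
            chunk_seconds = float(f["meta"].attrs["chunk_seconds"])
            n_chunks = f["data"].shape[0]
            length = n_chunks * chunk_seconds
            if t_end is None:
                t_end = length
            if not 0 <= t_start < t_end or t_start >= length or t_end > length + 1e-9:
                raise ValueError(
                    f"replay window [{t_start}, {t_end}) outside the "
                    f"{length} s recording"
                )
            first = int(np.floor(t_start / chunk_seconds + 1e-9))
            last = int(np.ceil(t_end / chunk_seconds - 1e-9))
            for i in range(first, last):
                yield PerChannelData(
                    f["data"][i], chunk_index=i, duration=chunk_seconds
                )
    finally:
        with _replay_lock:
            _active = False
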