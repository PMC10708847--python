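"""Offline emulation of the client-server acquisition transport.

The live platform pairs each headset (a Bluetooth client) with a server
that forwards raw samples in IP packets to a signal processor, which cuts
the stream into 2-s epochs.  One server instance multiplexes at most four
clients.  Here the transport is replayed offline: traces are packetized,
packet streams are reassembled, and contiguous 1024-sample epochs are
emitted on an absolute sample grid.  A sequence gap invalidates the
partially filled window (dropping it is preferred to zero-filling, which
would silently bias the PSD downward).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import DuplicatePacketError, Epoch, RawTrace

__all__ = [
    "SamplePacket",
    "ClientAdmission",
    "AssemblyLog",
    "packetize",
    "depacketize",
    "accept_clients",
    "assemble_epochs",
]

DEFAULT_PACKET_SIZE = 512  # one second of samples
SERVER_CAPACITY = 4


@dataclass
class SamplePacket:
    """One transport unit: a run of consecutive vendor-unit samples."""

    subject_id: str
    seq: int
    samples: np.ndarray

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples)
        if self.seq < 0:
            raise ValueError("seq must be non-negative")
        if len(self.samples) == 0:
            raise ValueError("packet must carry at least one sample")


@dataclass
class ClientAdmission:
    """Outcome of a batch of connection attempts against one server."""

    accepted: list[int]
    refused: list[int]
    capacity: int

    @property
    def n_accepted(self) -> int:
        return len(self.accepted)


@dataclass
class AssemblyLog:
    """Per-subject epoch assembly accounting."""

    subject_id: str
    n_packets: int = 0
    n_epochs: int = 0
    n_discarded_windows: int = 0
    n_pending: int = 0
    gap_events: list[tuple[int, int]] = field(default_factory=list)  # (prev_seq, seq)


def packetize(trace: RawTrace, subject_id: str | None = None,
              packet_size: int = DEFAULT_PACKET_SIZE) -> list[SamplePacket]:
    """Split a trace into consecutive packets; the last may be short."""
    if packet_size < 1:
        raise ValueError("packet_size must be >= 1")
    sid = subject_id or trace.subject_id
    samples = trace.samples
    return [
        SamplePacket(sid, seq, samples[start:start + packet_size])
        for seq, start in enumerate(range(0, len(samples), packet_size))
    ]


def depacketize(packets: list[SamplePacket]) -> np.ndarray:
    """Concatenate packet payloads in sequence order."""
    if not packets:
        return np.array([], dtype=np.int32)
    ordered = sorted(packets, key=lambda p: p.seq)
    return np.concatenate([p.samples for p in ordered])


def accept_clients(requested: int, capacity: int = SERVER_CAPACITY) -> ClientAdmission:
    """Admit up to ``capacity`` clients; surplus attempts are refused.

    Refusal is a normal outcome (the physical server simply stops pairing
    new headsets), so no exception is raised.
    """
    if requested < 0:
        raise ValueError("requested must be non-negative")
    n_ok = min(requested, capacity)
    return ClientAdmission(
        accepted=list(range(n_ok)),
        refused=list(range(n_ok, requested)),
        capacity=capacity,
    )


def assemble_epochs(packets: list[SamplePacket], epoch_len: int = 1024,
                    fs: float = 512.0) -> tuple[list[Epoch], AssemblyLog]:
    """Reassemble a single subject's packet stream into contiguous epochs.

    Epochs live on an absolute sample grid: epoch k covers samples
    [k*epoch_len, (k+1)*epoch_len).  On a sequence gap the partially
    filled window is discarded (logged) and assembly resumes at the next
    epoch boundary at or after the gap.  Missing spans are inferred from
    the nominal packet size (the size of the first packet), which is exact
    for the fixed-size transport emulated here.

    Raises
    ------
    DuplicatePacketError
        If two packets share a sequence number.
    """
    sid = packets[0].subject_id if packets else "unknown"
    log = AssemblyLog(subject_id=sid, n_packets=len(packets))
    if not packets:
        return [], log
    ordered = sorted(packets, key=lambda p: p.seq)
    for a, b in zip(ordered, ordered[1:]):
        if a.seq == b.seq:
            raise DuplicatePacketError(f"duplicate packet seq={a.seq} for {sid}")
    nominal = len(ordered[0].samples)

    epochs: list[Epoch] = []
    pending: list[np.ndarray] = []
    pending_len = 0
    pos = 0  # absolute index of the next sample to buffer
    prev_seq: int | None = None

    def flush_full() -> None:
        nonlocal pending, pending_len, pos
        while pending_len >= epoch_len:
            buf = np.concatenate(pending) if len(pending) > 1 else pending[0]
            epoch_start = pos - pending_len
            epochs.append(Epoch(
                subject_id=sid,
                index=epoch_start // epoch_len,
                start_s=epoch_start / fs,
                raw=buf[:epoch_len].copy(),
            ))
            log.n_epochs += 1
            rest = buf[epoch_len:]
            pending = [rest] if len(rest) else []
            pending_len = len(rest)

    for pkt in ordered:
        expected_seq = 0 if prev_seq is None else prev_seq + 1
        if pkt.seq != expected_seq:
            # gap: drop the window in progress, realign to the epoch grid
            if pending_len > 0:
                log.n_discarded_windows += 1
            log.gap_events.append((expected_seq - 1, pkt.seq))
            pending, pending_len = [], 0
            pos = pkt.seq * nominal
            boundary = -(-pos // epoch_len) * epoch_len  # ceil to next boundary
            skip = boundary - pos
            if skip >= len(pkt.samples):
                pos += len(pkt.samples)
                prev_seq = pkt.seq
                continue
            pending = [pkt.samples[skip:]]
            pending_len = len(pkt.samples) - skip
            pos = boundary + pending_len
        else:
            pending.append(pkt.samples)
            pending_len += len(pkt.samples)
            pos += len(pkt.samples)
        prev_seq = pkt.seq
        flush_full()

    log.n_pending = pending_len
    return epochs, log
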