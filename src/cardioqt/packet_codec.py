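"""Bit-exact codec for the device's fixed-length 40-byte data packets.

Wire layout (little-endian throughout)::

    offset  size  field
    0       3     sync header, fixed AA FF F1
    3       1     payload length, fixed 0x22 (= 34)
    4       32    eight channel samples, int32 LE, order I, II, V1..V6
    36      2     lead-off flag bytes (byte 0: bit i <-> channel i off;
                  byte 1 reserved, carried verbatim)
    38      1     checksum1 = sum(bytes[0..37]) mod 256
    39      1     checksum2 = running mod-256 sum of every checksum1
                  emitted since stream start

Decoding never raises on bad data: a corrupted window yields a typed
reject value so the stream resynchronizer can skip forward byte by byte.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

SYNC_WORD = b"\xaa\xff\xf1"
PACKET_LEN = 40
PAYLOAD_LEN = 34  # 32 data bytes + 2 flag bytes
N_CHANNELS = 8
CHANNEL_ORDER = ("I", "II", "V1", "V2", "V3", "V4", "V5", "V6")

_INT32_MIN = -(2**31)
_INT32_MAX = 2**31 - 1
_PAYLOAD_STRUCT = struct.Struct("<8i")


class RejectReason(Enum):
    BAD_HEADER = "bad_header"
    BAD_LENGTH = "bad_length"
    BAD_CHECKSUM = "bad_checksum"


@dataclass(frozen=True)
class Packet:
    """One decoded 40-byte frame."""

    channel_samples: tuple[int, ...]
    leadoff_flags: int  # 16-bit; low byte = channel bits, high byte opaque
    checksum1: int
    checksum2: int

    def channel_off(self, i: int) -> bool:
        """True when the lead-off bit for transmitted channel *i* is set."""
        return bool((self.leadoff_flags >> i) & 1)


@dataclass
class StreamState:
    """Running checksum2 accumulator; reset at session start."""

    checksum2_acc: int = 0

    def advance(self, checksum1: int) -> int:
        self.checksum2_acc = (self.checksum2_acc + checksum1) % 256
        return self.checksum2_acc


@dataclass
class RawFrameStream:
    frames: list[Packet] = field(default_factory=list)
    byte_offset_log: list[int] = field(default_factory=list)
    discard_count: int = 0

    def __len__(self) -> int:
        return len(self.frames)

    def sample_matrix(self) -> np.ndarray:
        """(n_frames, 8) int32 array of raw counts."""
        return np.array([p.channel_samples for p in self.frames], dtype=np.int32).reshape(-1, N_CHANNELS)

    def leadoff_matrix(self) -> np.ndarray:
        """(n_frames, 8) boolean array, True where the channel was flagged off."""
        flags = np.array([p.leadoff_flags for p in self.frames], dtype=np.uint16).reshape(-1, 1)
        bits = (flags >> np.arange(N_CHANNELS)) & 1
        return bits.astype(bool)


def encode_packet(
    channel_samples: Sequence[int],
    leadoff_flags: int = 0,
    stream_state: StreamState | None = None,
) -> bytes:
    """Encode one frame; updates *stream_state*'s cumulative checksum."""
    if len(channel_samples) != N_CHANNELS:
        raise ValueError(f"expected {N_CHANNELS} channel samples, got {len(channel_samples)}")
    samples = [int(s) for s in channel_samples]
    for s in samples:
        if not _INT32_MIN <= s <= _INT32_MAX:
            raise ValueError(f"sample {s} outside int32 range")
    if not 0 <= leadoff_flags <= 0xFFFF:
        raise ValueError("leadoff_flags must fit in 16 bits")

    body = bytearray(SYNC_WORD)
    body.append(PAYLOAD_LEN)
    body += _PAYLOAD_STRUCT.pack(*samples)
    body.append(leadoff_flags & 0xFF)
    body.append((leadoff_flags >> 8) & 0xFF)
    checksum1 = sum(body) % 256
    body.append(checksum1)
    if stream_state is None:
        checksum2 = checksum1
    else:
        checksum2 = stream_state.advance(checksum1)
    body.append(checksum2)
    assert len(body) == PACKET_LEN
    return bytes(body)


def decode_packet(window: bytes | bytearray | memoryview) -> Packet | RejectReason:
    """Decode a 40-byte window, or return the reject reason.

    checksum2 is cumulative over the stream and cannot be verified from a
    single frame; it is surfaced on the Packet for stream-level checks.
    """
    if len(window) != PACKET_LEN:
        raise ValueError(f"decode_packet needs a {PACKET_LEN}-byte window")
    window = bytes(window)
    if window[:3] != SYNC_WORD:
        return RejectReason.BAD_HEADER
    if window[3] != PAYLOAD_LEN:
        return RejectReason.BAD_LENGTH
    checksum1 = sum(window[:38]) % 256
    if window[38] != checksum1:
        return RejectReason.BAD_CHECKSUM
    samples = _PAYLOAD_STRUCT.unpack_from(window, 4)
    flags = window[36] | (window[37] << 8)
    return Packet(
        channel_samples=samples,
        leadoff_flags=flags,
        checksum1=checksum1,
        checksum2=window[39],
    )


def resync_stream(data: bytes | bytearray) -> RawFrameStream:
    """Scan an arbitrary byte sequence, recovering every decodable frame.

    On a successful decode the cursor advances 40 bytes; on any reject it
    advances a single byte, so a spurious sync word inside junk cannot mask
    a later true frame.
    """
    data = bytes(data)
    out = RawFrameStream()
    pos = 0
    n = len(data)
    expected = 0  # next aligned position; divergence is logged as a resync
    while pos + PACKET_LEN <= n:
        if data[pos : pos + 3] != SYNC_WORD:
            pos += 1
            continue
        result = decode_packet(data[pos : pos + PACKET_LEN])
        if isinstance(result, Packet):
            if pos != expected:
                out.byte_offset_log.append(pos)
            out.frames.append(result)
            pos += PACKET_LEN
            expected = pos
        else:
            pos += 1
    out.discard_count = n - PACKET_LEN * len(out.frames)
    return out


def encode_stream(
    sample_matrix: np.ndarray,
    leadoff_flags: Iterable[int] | None = None,
    stream_state: StreamState | None = None,
) -> bytes:
    """Encode an (n, 8) raw-count matrix as a flat packet stream."""
    sample_matrix = np.asarray(sample_matrix)
    if sample_matrix.ndim != 2 or sample_matrix.shape[1] != N_CHANNELS:
        raise ValueError("sample_matrix must be (n_frames, 8)")
    if leadoff_flags is None:
        leadoff_flags = [0] * len(sample_matrix)
    else:
        leadoff_flags = list(leadoff_flags)
        if len(leadoff_flags) != len(sample_matrix):
            raise ValueError("leadoff_flags length must match frame count")
    state = stream_state if stream_state is not None else StreamState()
    chunks = [
        encode_packet(row.tolist(), flags, state)
        for row, flags in zip(sample_matrix, leadoff_flags)
    ]
    return b"".join(chunks)


def read_stream_file(path) -> RawFrameStream:
    with open(path, "rb") as fh:
        return resync_stream(fh.read())


def write_stream_file(path, data: bytes) -> None:
    with open(path, "wb") as fh:
        fh.write(data)


def frames_to_csv(stream: RawFrameStream, path) -> None:
    """Debug export: one row per frame with raw counts and flag bits."""
    import pandas as pd

    mat = stream.sample_matrix()
    df = pd.DataFrame(mat, columns=[f"raw_{c}" for c in CHANNEL_ORDER])
    df.insert(0, "frame", np.arange(len(df)))
    df["leadoff_flags"] = [p.leadoff_flags for p in stream.frames]
    df.to_csv(path, index=False)
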