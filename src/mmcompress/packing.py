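"""Packing: map 32-bit encoded integers onto compact byte streams.

Two schemes, both bijective over the full int32 range:

* **Recursive indexing** to 16-bit (default) or 8-bit integers: a value
  strictly inside the target interval represents itself; anything else is
  stored as a run of interval endpoints plus an in-range remainder that the
  decoder accumulates.  A value equal to an endpoint is stored as the
  endpoint followed by an explicit 0 so the decoder terminates.
* **Variable-length quantity** (VLQ): each value's 32-bit two's-complement
  pattern in big-endian base-128 bytes, 7 payload bits + 1 continuation bit
  per byte (negative values occupy five bytes).

Packed 16-bit streams are serialized little-endian.
"""

from __future__ import annotations

import enum

import numpy as np

_BOUNDS = {16: (-32768, 32767), 8: (-128, 127)}
_DTYPES = {16: np.int16, 8: np.int8}


class PackerId(str, enum.Enum):
    RECURSIVE_INDEX_16 = "recursive_index_16"
    RECURSIVE_INDEX_8 = "recursive_index_8"
    VLQ = "vlq"
    RAW_INT32 = "raw_int32"


class TruncatedStreamError(ValueError):
    """A packed stream ended in the middle of a value."""


def recursive_index_pack(x: np.ndarray, width: int = 16) -> np.ndarray:
    """Pack int32 values into ``width``-bit integers by recursive indexing.

    Out-of-interval values emit ``k`` copies of the relevant endpoint (max
    for positive, min for negative) followed by the remainder; exact
    endpoint multiples are followed by a 0 remainder.
    """
    lo, hi = _BOUNDS[width]
    x = np.asarray(x, dtype=np.int64)
    pos = x >= 0
    k = np.where(pos, x // hi, (-x) // (-lo))
    rem = x - k * np.where(pos, hi, lo)
    counts = k + 1  # k endpoints then one remainder per value
    total = int(counts.sum())
    out = np.empty(total, dtype=np.int64)
    ends = np.cumsum(counts)
    rem_pos = ends - 1
    mask = np.ones(total, dtype=bool)
    mask[rem_pos] = False
    out[mask] = np.repeat(np.where(pos, hi, lo), k)
    out[rem_pos] = rem
    return out.astype(_DTYPES[width])


def recursive_index_unpack(p: np.ndarray, width: int = 16) -> np.ndarray:
    """Exact inverse of :func:`recursive_index_pack`."""
    lo, hi = _BOUNDS[width]
    p = np.asarray(p, dtype=np.int64)
    if len(p) == 0:
        return np.empty(0, dtype=np.int32)
    is_term = (p != lo) & (p != hi)
    if not is_term[-1]:
        raise TruncatedStreamError(
            "recursive-index stream ends with an interval endpoint"
        )
    starts = np.flatnonzero(is_term)
    starts = np.concatenate([[0], starts[:-1] + 1])
    sums = np.add.reduceat(p, starts)
    if np.any((sums < -(2**31)) | (sums > 2**31 - 1)):
        raise OverflowError("recursive-index stream decodes outside int32")
    return sums.astype(np.int32)


def vlq_pack(x: np.ndarray) -> bytes:
    """Variable-length-quantity byte stream for 32-bit integers.

    Each value's 32-bit two's-complement pattern is split into big-endian
    base-128 groups with the continuation bit on every byte but the last --
    the classic unsigned VLQ applied to the raw bit pattern.  Small positive
    values stay short; negative values sign-extend to five bytes, which is
    exactly why recursive indexing packs difference streams tighter.
    """
    x = np.asarray(x, dtype=np.int64)
    if len(x) == 0:
        return b""
    u = x.astype(np.int32).astype(np.uint32).astype(np.uint64)
    # bytes needed: ceil(bitlength / 7), at least 1
    nbytes = np.maximum(1, (_bitlen64(u) + 6) // 7)
    total = int(nbytes.sum())
    ends = np.cumsum(nbytes)
    starts = ends - nbytes
    idx = np.arange(total) - np.repeat(starts, nbytes)
    shifts = ((np.repeat(nbytes, nbytes) - 1 - idx) * 7).astype(np.uint64)
    payload = (np.repeat(u, nbytes) >> shifts) & np.uint64(0x7F)
    cont = np.ones(total, dtype=np.uint64)
    cont[ends - 1] = 0
    return ((cont << np.uint64(7)) | payload).astype(np.uint8).tobytes()


def _bitlen64(u: np.ndarray) -> np.ndarray:
    """Bit length of each uint64 element (0 maps to 0); float64 conversion is
    unsafe above 2^53, so use a halving reduction."""
    u = u.copy()
    n = np.zeros(u.shape, dtype=np.int64)
    for width in (32, 16, 8, 4, 2, 1):
        w = np.uint64(width)
        big = u >= (np.uint64(1) << w)
        n = np.where(big, n + width, n)
        u = np.where(big, u >> w, u)
    return n + (u != 0).astype(np.int64)


def vlq_unpack(b: bytes) -> np.ndarray:
    """Exact inverse of :func:`vlq_pack`."""
    raw = np.frombuffer(b, dtype=np.uint8)
    if len(raw) == 0:
        return np.empty(0, dtype=np.int32)
    cont = (raw & 0x80) != 0
    if cont[-1]:
        raise TruncatedStreamError("VLQ stream ends with a continuation bit set")
    term = np.flatnonzero(~cont)
    starts = np.concatenate([[0], term[:-1] + 1])
    lengths = term - starts + 1
    if np.any(lengths > 5):
        raise ValueError("VLQ value longer than 5 bytes cannot be a 32-bit integer")
    payload = (raw & 0x7F).astype(np.uint64)
    values = np.zeros(len(term), dtype=np.uint64)
    max_len = int(lengths.max())
    for off in range(max_len):
        active = lengths > off
        values[active] = (values[active] << np.uint64(7)) | payload[starts[active] + off]
    if np.any(values > 0xFFFFFFFF):
        raise OverflowError("VLQ stream decodes outside the 32-bit range")
    return values.astype(np.uint32).astype(np.int32)


def pack_to_bytes(x: np.ndarray, packer: PackerId) -> bytes:
    """Serialize int32 values with the chosen packer (multi-byte integers
    little-endian)."""
    x = np.asarray(x, dtype=np.int32)
    if packer is PackerId.RECURSIVE_INDEX_16:
        return recursive_index_pack(x, 16).astype("<i2").tobytes()
    if packer is PackerId.RECURSIVE_INDEX_8:
        return recursive_index_pack(x, 8).astype("i1").tobytes()
    if packer is PackerId.VLQ:
        return vlq_pack(x)
    if packer is PackerId.RAW_INT32:
        return x.astype("<i4").tobytes()
    raise ValueError(f"unknown packer {packer}")


def unpack_from_bytes(b: bytes, packer: PackerId) -> np.ndarray:
    if packer is PackerId.RECURSIVE_INDEX_16:
        return recursive_index_unpack(np.frombuffer(b, dtype="<i2"), 16)
    if packer is PackerId.RECURSIVE_INDEX_8:
        return recursive_index_unpack(np.frombuffer(b, dtype="i1"), 8)
    if packer is PackerId.VLQ:
        return vlq_unpack(b)
    if packer is PackerId.RAW_INT32:
        return np.frombuffer(b, dtype="<i4").astype(np.int32)
    raise ValueError(f"unknown packer {packer}")
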