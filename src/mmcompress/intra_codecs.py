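"""Quantization and the four intramolecular coordinate encoders.

All encoders transform the quantized integer coordinate array into a
representation whose values concentrate near zero, so that the packing and
entropy stages downstream can shrink them.  Every encoder here has an exact
inverse on the integer domain: losslessness is defined relative to the
quantized grid (0.001 A at factor 1000, 0.1 A at factor 10).

Encoders
--------
delta
    Successive differences ``s_i = c_i - c_{i-1}``; bond-length geometry makes
    these small.
predictive
    Second-order differences: the error against the linear extrapolation
    ``p_i = 2 c_{i-1} - c_{i-2}`` (equivalently delta applied twice).
wavelet
    One level of the integer-to-integer CDF 5/3 (Le Gall) lifting transform,
    applied after delta encoding.
unit-vector (uv16/uv32)
    Consecutive-atom bond vectors split into a quantized direction code, a
    length residual against the molecule's mean bond length, and per-axis
    integer corrections that make reconstruction bitwise exact.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from .structure_model import CoordinateArrays, flatten_axis_major

INT32_MIN = -(2**31)
INT32_MAX = 2**31 - 1

LOSSLESS_FACTOR = 1000
LOSSY_FACTOR = 10
VALID_FACTORS = (LOSSLESS_FACTOR, LOSSY_FACTOR)


class CodecId(str, enum.Enum):
    INTEGER = "integer"
    DELTA = "delta"
    PREDICTIVE = "predictive"
    WAVELET = "wavelet"
    UV16 = "uv16"
    UV32 = "uv32"


@dataclass
class QuantizedCoords:
    """Axis-major integer coordinates: ``round(coord * factor)``."""

    values: np.ndarray  # int32, length 3N
    factor: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int32)

    @property
    def n_atoms(self) -> int:
        return len(self.values) // 3


@dataclass
class EncodedPayload:
    """Output of an intramolecular encoder, sufficient for exact inversion."""

    codec_id: CodecId
    main: np.ndarray  # int32
    n_atoms: int
    factor: int
    aux: dict[str, np.ndarray] = field(default_factory=dict)


class QuantizationOverflowError(OverflowError):
    pass


def round_half_away(x: np.ndarray) -> np.ndarray:
    """Round to nearest integer, ties away from zero.

    numpy's ``round`` ties to even; coordinate quantization uses the
    away-from-zero rule so that e.g. 0.0005 A and -0.0005 A quantize
    symmetrically at factor 1000.
    """
    x = np.asarray(x, dtype=np.float64)
    return np.trunc(x + np.copysign(0.5, x))


def quantize(coords: CoordinateArrays, factor: int) -> QuantizedCoords:
    """Scale coordinates to integers: factor 1000 preserves 3-decimal input
    exactly (lossless); factor 10 keeps one decimal (lossy, 0.1 A grid)."""
    if factor not in VALID_FACTORS:
        raise ValueError(f"factor must be one of {VALID_FACTORS}, got {factor}")
    flat = flatten_axis_major(coords)
    scaled = round_half_away(flat * factor)
    bad = (scaled < INT32_MIN) | (scaled > INT32_MAX)
    if np.any(bad):
        i = int(np.argmax(bad))
        raise QuantizationOverflowError(
            f"coordinate {flat[i]:.3f} A at flat index {i} does not fit a "
            f"32-bit integer at factor {factor}"
        )
    return QuantizedCoords(scaled.astype(np.int32), factor)


def dequantize(q: QuantizedCoords) -> CoordinateArrays:
    """Inverse of :func:`quantize` onto the quantized grid."""
    flat = q.values.astype(np.float64) / q.factor
    n = q.n_atoms
    return CoordinateArrays(flat[:n], flat[n : 2 * n], flat[2 * n :])


def _check_int32(a: np.ndarray, what: str) -> np.ndarray:
    if np.any((a < INT32_MIN) | (a > INT32_MAX)):
        raise OverflowError(f"{what} exceeds the 32-bit signed range")
    return a.astype(np.int32)


# ---------------------------------------------------------------------------
# delta / predictive


def delta_encode(q: np.ndarray) -> np.ndarray:
    """``s_0 = c_0; s_i = c_i - c_{i-1}`` over one continuous pass.

    The axis-major array is treated as a single sequence; the two values at
    axis seams are ordinary differences.
    """
    q = np.asarray(q, dtype=np.int64)
    if len(q) == 0:
        raise ValueError("delta_encode requires length >= 1")
    out = np.empty_like(q)
    out[0] = q[0]
    out[1:] = np.diff(q)
    return _check_int32(out, "delta difference")


def delta_decode(s: np.ndarray) -> np.ndarray:
    s = np.asarray(s, dtype=np.int64)
    return _check_int32(np.cumsum(s), "delta prefix sum")


def predictive_encode(q: np.ndarray) -> np.ndarray:
    """Store the error against the linear prediction ``2 c_{i-1} - c_{i-2}``.

    ``s_0 = c_0`` and ``s_1 = c_1 - c_0``; from i = 2 on this coincides with
    delta encoding applied twice.
    """
    q = np.asarray(q, dtype=np.int64)
    if len(q) == 0:
        raise ValueError("predictive_encode requires length >= 1")
    out = np.empty_like(q)
    out[0] = q[0]
    if len(q) > 1:
        out[1] = q[1] - q[0]
    if len(q) > 2:
        out[2:] = q[2:] - (2 * q[1:-1] - q[:-2])
    return _check_int32(out, "prediction error")


def predictive_decode(s: np.ndarray) -> np.ndarray:
    s = np.asarray(s, dtype=np.int64)
    if len(s) == 1:
        return _check_int32(s.copy(), "predictive reconstruction")
    # first cumsum rebuilds the first differences (s_1 seeds them), the
    # second rebuilds the values from c_0 = s_0
    d = np.cumsum(s[1:])
    out = np.empty(len(s), dtype=np.int64)
    out[0] = s[0]
    out[1:] = s[0] + np.cumsum(d)
    return _check_int32(out, "predictive reconstruction")


# ---------------------------------------------------------------------------
# CDF 5/3 integer lifting wavelet


def _reflect(i: int, n: int) -> int:
    """Whole-point symmetric index extension: ...2 1 0 1 2... n-2 n-1 n-2..."""
    if n == 1:
        return 0
    period = 2 * (n - 1)
    i = i % period
    if i < 0:
        i += period
    return i if i < n else period - i


def wavelet_forward(q: np.ndarray) -> np.ndarray:
    """Single-level CDF 5/3 (Le Gall) integer lifting transform.

    Odd samples become detail coefficients
    ``d[i] = x[2i+1] - floor((x[2i] + x[2i+2]) / 2)`` and even samples the
    smoothed approximation ``s[i] = x[2i] + floor((d[i-1] + d[i] + 2) / 4)``,
    with whole-point symmetric extension at the boundaries.  Output is
    ``[approx | detail]`` of the same total length.  Inputs shorter than two
    samples pass through unchanged.
    """
    x = np.asarray(q, dtype=np.int64)
    n = len(x)
    if n < 2:
        return x.astype(np.int32).copy()
    n_d = n // 2  # details at odd indices 1, 3, ...
    n_s = n - n_d

    def xe(i: int) -> int:
        return int(x[_reflect(i, n)])

    d = np.empty(n_d, dtype=np.int64)
    for i in range(n_d):
        d[i] = x[2 * i + 1] - ((xe(2 * i) + xe(2 * i + 2)) >> 1)

    def de(i: int) -> int:
        # detail sequence extended symmetrically about its own ends
        if n_d == 0:
            return 0
        return int(d[_reflect(i, n_d)])

    s = np.empty(n_s, dtype=np.int64)
    for i in range(n_s):
        s[i] = x[2 * i] + ((de(i - 1) + de(i) + 2) >> 2)
    out = np.concatenate([s, d])
    return _check_int32(out, "wavelet coefficient")


def wavelet_inverse(w: np.ndarray) -> np.ndarray:
    """Exact inverse of :func:`wavelet_forward` (undo lifting steps in reverse)."""
    w = np.asarray(w, dtype=np.int64)
    n = len(w)
    if n < 2:
        return w.astype(np.int32).copy()
    n_d = n // 2
    n_s = n - n_d
    s = w[:n_s]
    d = w[n_s:]

    def de(i: int) -> int:
        if n_d == 0:
            return 0
        return int(d[_reflect(i, n_d)])

    x = np.empty(n, dtype=np.int64)
    for i in range(n_s):
        x[2 * i] = s[i] - ((de(i - 1) + de(i) + 2) >> 2)

    def xe(i: int) -> int:
        return int(x[_reflect(i, n)])  # even entries already restored

    for i in range(n_d):
        x[2 * i + 1] = d[i] + ((xe(2 * i) + xe(2 * i + 2)) >> 1)
    return _check_int32(x, "wavelet reconstruction")


# ---------------------------------------------------------------------------
# unit-vector encoding

#: Per-axis quantization levels of the folded-octahedron grid (half the code
#: bits per axis).
UV_GRID_N = {16: 2**8 - 1, 32: 2**16 - 1}
#: Code layout version for the container header: the direction is projected
#: onto the L1 sphere |x|+|y|+|z| = 1 (one triangular face per octant), the
#: lower hemisphere is folded outward to unfold the octahedron into a square,
#: and the two square coordinates are quantized to half the code bits each;
#: the signed code is that unsigned grid index shifted by 2**(bits-1).
UV_LAYOUT_VERSION = 1


def _uv_quantize_dirs(v: np.ndarray, bits: int) -> np.ndarray:
    """Map unit-length rows of ``v`` to one signed integer code each
    (octahedral unit-vector quantization)."""
    n_grid = UV_GRID_N[bits]
    half_bits = bits // 2
    s = np.abs(v).sum(axis=1)
    s[s == 0] = 1.0
    px, py, pz = v[:, 0] / s, v[:, 1] / s, v[:, 2] / s
    sx = np.where(px >= 0, 1.0, -1.0)
    sy = np.where(py >= 0, 1.0, -1.0)
    u = np.where(pz < 0, (1.0 - np.abs(py)) * sx, px)
    w = np.where(pz < 0, (1.0 - np.abs(px)) * sy, py)
    i = np.floor((u + 1.0) / 2.0 * n_grid + 0.5).astype(np.int64)
    j = np.floor((w + 1.0) / 2.0 * n_grid + 0.5).astype(np.int64)
    return (i << half_bits) + j - 2 ** (bits - 1)


def _uv_dequantize_dirs(codes: np.ndarray, bits: int) -> np.ndarray:
    """Inverse of :func:`_uv_quantize_dirs` up to quantization error."""
    n_grid = UV_GRID_N[bits]
    half_bits = bits // 2
    raw = np.asarray(codes, dtype=np.int64) + 2 ** (bits - 1)
    i, j = raw >> half_bits, raw & ((1 << half_bits) - 1)
    u = i / n_grid * 2.0 - 1.0
    w = j / n_grid * 2.0 - 1.0
    z = 1.0 - np.abs(u) - np.abs(w)
    su = np.where(u >= 0, 1.0, -1.0)
    sw = np.where(w >= 0, 1.0, -1.0)
    x = np.where(z < 0, (1.0 - np.abs(w)) * su, u)
    y = np.where(z < 0, (1.0 - np.abs(u)) * sw, w)
    m = np.column_stack([x, y, z])
    norm = np.linalg.norm(m, axis=1)
    norm[norm == 0] = 1.0
    return m / norm[:, None]


def uv_encode(coords: CoordinateArrays, bits: int, factor: int) -> EncodedPayload:
    """Encode consecutive-atom bond vectors as direction codes + lengths.

    Each vector between consecutive atoms is split into (a) a unit direction
    quantized to a single signed 16- or 32-bit code, (b) its length stored as
    an integer residual against the molecule's mean bond length (the mean is
    stored once), and (c) per-axis integer corrections between the true
    quantized step and the step rebuilt from code and length, so decoding is
    bitwise exact.  A zero-length step gets the +x direction code with the
    full step in the corrections (pathological but well-defined).
    """
    if bits not in (16, 32):
        raise ValueError("bits must be 16 or 32")
    n = len(coords)
    if n < 2:
        raise ValueError("unit-vector encoding requires at least 2 atoms")
    q = quantize(coords, factor)
    pts = q.values.reshape(3, n).T.astype(np.int64)  # (N, 3) integer grid
    steps = np.diff(pts, axis=0).astype(np.float64)  # factor units
    lengths = np.linalg.norm(steps, axis=1)
    nonzero = lengths > 0
    dirs = np.zeros_like(steps)
    dirs[nonzero] = steps[nonzero] / lengths[nonzero, None]
    dirs[~nonzero] = (1.0, 0.0, 0.0)

    mean_len = int(round_half_away(np.array(lengths.mean()))[()])
    len_resid = round_half_away(lengths - mean_len).astype(np.int64)
    codes = _uv_quantize_dirs(dirs, bits)

    rec = _uv_reconstruct_steps(codes, len_resid, mean_len, bits)
    corrections = (np.diff(pts, axis=0) - rec).reshape(-1)

    return EncodedPayload(
        codec_id=CodecId.UV16 if bits == 16 else CodecId.UV32,
        main=_check_int32(codes, "unit-vector code"),
        n_atoms=n,
        factor=factor,
        aux={
            "first": pts[0].astype(np.int32),
            "mean_len": np.array([mean_len], dtype=np.int32),
            "len_resid": _check_int32(len_resid, "length residual"),
            "corrections": _check_int32(corrections, "uv correction"),
        },
    )


def _uv_reconstruct_steps(
    codes: np.ndarray, len_resid: np.ndarray, mean_len: int, bits: int
) -> np.ndarray:
    """Integer steps predicted from direction codes and reconstructed lengths
    (shared by encoder and decoder so corrections cancel exactly)."""
    dirs = _uv_dequantize_dirs(codes, bits)
    lengths = (mean_len + np.asarray(len_resid, dtype=np.float64))[:, None]
    return round_half_away(dirs * lengths).astype(np.int64)


def uv_decode(p: EncodedPayload) -> QuantizedCoords:
    """Exact inverse of :func:`uv_encode` onto the quantized grid."""
    if p.codec_id not in (CodecId.UV16, CodecId.UV32):
        raise ValueError(f"not a unit-vector payload: {p.codec_id}")
    bits = 16 if p.codec_id is CodecId.UV16 else 32
    n = p.n_atoms
    codes = np.asarray(p.main, dtype=np.int64)
    len_resid = np.asarray(p.aux["len_resid"], dtype=np.int64)
    corrections = np.asarray(p.aux["corrections"], dtype=np.int64).reshape(-1, 3)
    if not (len(codes) == len(len_resid) == len(corrections) == n - 1):
        raise ValueError("inconsistent unit-vector payload array lengths")
    mean_len = int(p.aux["mean_len"][0])
    steps = _uv_reconstruct_steps(codes, len_resid, mean_len, bits) + corrections
    pts = np.empty((n, 3), dtype=np.int64)
    pts[0] = np.asarray(p.aux["first"], dtype=np.int64)
    pts[1:] = pts[0] + np.cumsum(steps, axis=0)
    values = _check_int32(pts.T.reshape(-1), "uv coordinate")
    return QuantizedCoords(values, p.factor)
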