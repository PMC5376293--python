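"""Entropy back-ends (gzip, optionally brotli) and compression metrics."""

from __future__ import annotations

import enum
import gzip
import math
import zlib
from collections import Counter
from dataclasses import dataclass

#: gzip level fixed at maximum so compressed sizes are reproducible run to run.
GZIP_LEVEL = 9
BROTLI_QUALITY = 11

try:  # brotli is optional
    import brotli as _brotli
except ImportError:  # pragma: no cover
    _brotli = None


class EntropyBackend(str, enum.Enum):
    GZIP = "gzip"
    BROTLI = "brotli"


class BackendUnavailableError(RuntimeError):
    pass


def brotli_available() -> bool:
    return _brotli is not None


def entropy_compress(b: bytes, backend: EntropyBackend = EntropyBackend.GZIP) -> bytes:
    """Compress a byte stream with the chosen standard back-end (RFC 1952
    gzip or RFC 7932 brotli)."""
    if backend is EntropyBackend.GZIP:
        # mtime pinned to 0 so output is byte-identical across runs
        return gzip.compress(b, compresslevel=GZIP_LEVEL, mtime=0)
    if backend is EntropyBackend.BROTLI:
        if _brotli is None:
            raise BackendUnavailableError(
                "brotli backend requested but the 'brotli' package is not installed"
            )
        return _brotli.compress(b, quality=BROTLI_QUALITY)
    raise ValueError(f"unknown backend {backend}")


def entropy_decompress(b: bytes, backend: EntropyBackend = EntropyBackend.GZIP) -> bytes:
    if backend is EntropyBackend.GZIP:
        try:
            return gzip.decompress(b)
        except (OSError, zlib.error) as e:
            raise ValueError(f"corrupt gzip stream: {e}") from e
    if backend is EntropyBackend.BROTLI:
        if _brotli is None:
            raise BackendUnavailableError(
                "brotli backend requested but the 'brotli' package is not installed"
            )
        try:
            return _brotli.decompress(b)
        except _brotli.error as e:
            raise ValueError(f"corrupt brotli stream: {e}") from e
    raise ValueError(f"unknown backend {backend}")


def shannon_entropy(b: bytes) -> float:
    """Shannon entropy of the byte-value distribution, in bits per byte.

    0 for a constant stream, 8 for uniformly random bytes; an upper bound on
    what a memoryless entropy coder could achieve on the stream.
    """
    if len(b) == 0:
        raise ValueError("Shannon entropy is undefined for an empty stream")
    n = len(b)
    return -sum(
        (c / n) * math.log2(c / n) for c in Counter(b).values()
    )


@dataclass(frozen=True)
class CompressionMetrics:
    """Size accounting for one compressed stream."""

    original_bytes: int
    compressed_bytes: int

    @property
    def ratio(self) -> float:
        return self.original_bytes / self.compressed_bytes

    @staticmethod
    def measure(original: bytes, compressed: bytes) -> "CompressionMetrics":
        return CompressionMetrics(len(original), len(compressed))
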