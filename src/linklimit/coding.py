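"""Adaptive arithmetic coding.

A standard 32-bit integer arithmetic coder (Witten-Neal-Cleary style) driven
by adaptive models:

* :class:`AdaptiveModel` -- Dirichlet(1/2) (Krichevsky-Trofimov) estimator
  over a fixed finite alphabet, used for the single-bit stream.
* :class:`BetaBinomialModel` -- codes an integer count ``k`` out of a known
  cell size ``m`` under a beta-binomial law whose pseudo-counts are shared
  across symbols.  This is what turns per-cell neighbour *counts* (rather
  than per-vertex bits) into actual savings.

Both models expose exact closed-form ideal codelengths, used by the fast
length-only compression path.
"""
from __future__ import annotations

import math
from typing import Sequence

import numpy as np
from scipy.special import gammaln

__all__ = [
    "BitWriter",
    "BitReader",
    "ArithmeticEncoder",
    "ArithmeticDecoder",
    "AdaptiveModel",
    "BetaBinomialModel",
    "DecodeError",
    "entropy_code",
    "entropy_decode",
    "kt_cost_bits",
    "log2_binomial",
]

_LN2 = math.log(2.0)

_PREC = 32
_MASK = (1 << _PREC) - 1
_HALF = 1 << (_PREC - 1)
_QTR = 1 << (_PREC - 2)
_3QTR = _HALF + _QTR


class DecodeError(ValueError):
    """Raised when a bit stream is truncated or inconsistent."""


class BitWriter:
    def __init__(self) -> None:
        self._buf = bytearray()
        self._acc = 0
        self._nacc = 0
        self.nbits = 0

    def write(self, bit: int) -> None:
        self._acc = (self._acc << 1) | (bit & 1)
        self._nacc += 1
        self.nbits += 1
        if self._nacc == 8:
            self._buf.append(self._acc)
            self._acc = 0
            self._nacc = 0

    def getvalue(self) -> bytes:
        buf = bytearray(self._buf)
        if self._nacc:
            buf.append(self._acc << (8 - self._nacc))
        return bytes(buf)


class BitReader:
    """Reads bits from ``data``; up to 64 zero padding bits may be consumed
    past the declared length (arithmetic decoders read ahead), anything more
    raises :class:`DecodeError`."""

    def __init__(self, data: bytes, nbits: int, slack: int = 64) -> None:
        self._data = data
        self._nbits = nbits
        self._limit = nbits + slack
        self._pos = 0

    def read(self) -> int:
        if self._pos >= self._limit:
            raise DecodeError("bit stream exhausted (truncated or corrupt input)")
        p = self._pos
        self._pos += 1
        if p >= self._nbits:
            return 0
        byte = self._data[p >> 3]
        return (byte >> (7 - (p & 7))) & 1


class ArithmeticEncoder:
    def __init__(self, writer: BitWriter) -> None:
        self._w = writer
        self._low = 0
        self._high = _MASK
        self._pending = 0
        self._any = False

    def _emit(self, bit: int) -> None:
        self._w.write(bit)
        inv = bit ^ 1
        while self._pending:
            self._w.write(inv)
            self._pending -= 1

    def encode(self, cum_lo: int, cum_hi: int, total: int) -> None:
        if not (0 <= cum_lo < cum_hi <= total):
            raise ValueError("invalid cumulative frequencies")
        self._any = True
        span = self._high - self._low + 1
        self._high = self._low + span * cum_hi // total - 1
        self._low = self._low + span * cum_lo // total
        while True:
            if self._high < _HALF:
                self._emit(0)
            elif self._low >= _HALF:
                self._emit(1)
                self._low -= _HALF
                self._high -= _HALF
            elif self._low >= _QTR and self._high < _3QTR:
                self._pending += 1
                self._low -= _QTR
                self._high -= _QTR
            else:
                break
            self._low <<= 1
            self._high = (self._high << 1) | 1

    def finish(self) -> None:
        if not self._any:
            return
        self._pending += 1
        if self._low < _QTR:
            self._emit(0)
        else:
            self._emit(1)


class ArithmeticDecoder:
    def __init__(self, reader: BitReader) -> None:
        self._r = reader
        self._low = 0
        self._high = _MASK
        self._code = 0
        for _ in range(_PREC):
            self._code = (self._code << 1) | reader.read()

    def target(self, total: int) -> int:
        span = self._high - self._low + 1
        return ((self._code - self._low + 1) * total - 1) // span

    def consume(self, cum_lo: int, cum_hi: int, total: int) -> None:
        span = self._high - self._low + 1
        self._high = self._low + span * cum_hi // total - 1
        self._low = self._low + span * cum_lo // total
        while True:
            if self._high < _HALF:
                pass
            elif self._low >= _HALF:
                self._low -= _HALF
                self._high -= _HALF
                self._code -= _HALF
            elif self._low >= _QTR and self._high < _3QTR:
                self._low -= _QTR
                self._high -= _QTR
                self._code -= _QTR
            else:
                break
            self._low <<= 1
            self._high = (self._high << 1) | 1
            self._code = (self._code << 1) | self._r.read()


def kt_cost_bits(n0: float, n1: float) -> float:
    """Exact ideal codelength (bits) of a binary sequence with ``n0`` zeros
    and ``n1`` ones under the KT (Dirichlet-1/2) adaptive estimator."""
    if n0 == 0 and n1 == 0:
        return 0.0
    logp = (
        gammaln(n0 + 0.5)
        + gammaln(n1 + 0.5)
        - 2.0 * gammaln(0.5)
        + gammaln(1.0)
        - gammaln(n0 + n1 + 1.0)
    )
    return -logp / _LN2


def log2_binomial(m, k):
    """Vectorized ``log2 C(m, k)``."""
    m = np.asarray(m, dtype=np.float64)
    k = np.asarray(k, dtype=np.float64)
    return (gammaln(m + 1) - gammaln(k + 1) - gammaln(m - k + 1)) / _LN2


class AdaptiveModel:
    """Adaptive Dirichlet(1/2) model over the alphabet ``0..size-1``.

    Integer symbol weights ``2c+1`` keep the arithmetic coder exact (no
    frequency quantization for this model).
    """

    def __init__(self, size: int) -> None:
        if size < 2:
            raise ValueError("alphabet must have at least 2 symbols")
        self.size = size
        self.counts = [0] * size

    def _weights(self) -> tuple[list[int], int]:
        w = [2 * c + 1 for c in self.counts]
        return w, 2 * sum(self.counts) + self.size

    def encode(self, enc: ArithmeticEncoder, s: int) -> None:
        w, total = self._weights()
        lo = sum(w[:s])
        enc.encode(lo, lo + w[s], total)
        self.counts[s] += 1

    def decode(self, dec: ArithmeticDecoder) -> int:
        w, total = self._weights()
        t = dec.target(total)
        lo = 0
        for s, ws in enumerate(w):
            if t < lo + ws:
                dec.consume(lo, lo + ws, total)
                self.counts[s] += 1
                return s
            lo += ws
        raise DecodeError("decoder target out of range")

    def ideal_cost_bits(self) -> float:
        """Closed-form ideal codelength of everything encoded so far."""
        n = sum(self.counts)
        if n == 0:
            return 0.0
        a = self.size / 2.0
        logp = (
            sum(gammaln(c + 0.5) - gammaln(0.5) for c in self.counts)
            + gammaln(a)
            - gammaln(n + a)
        )
        return -logp / _LN2


class BetaBinomialModel:
    """Codes counts ``k`` of successes in cells of known size ``m`` with a
    beta-binomial whose pseudo-counts (KT style, +1/2) accumulate across
    symbols.  Frequencies are quantized to ``2^16`` for the coder; the ideal
    codelength is tracked in closed form separately."""

    SCALE = 1 << 16

    def __init__(self) -> None:
        self.c0 = 0
        self.c1 = 0

    def _pmf(self, m: int) -> np.ndarray:
        k = np.arange(m + 1, dtype=np.float64)
        a = self.c1 + 0.5
        b = self.c0 + 0.5
        logp = (
            gammaln(m + 1) - gammaln(k + 1) - gammaln(m - k + 1)
            + gammaln(a + k) + gammaln(b + m - k) - gammaln(a + b + m)
            - (gammaln(a) + gammaln(b) - gammaln(a + b))
        )
        return np.exp(logp)

    def _freqs(self, m: int) -> np.ndarray:
        p = self._pmf(m)
        f = np.floor(p * self.SCALE).astype(np.int64) + 1
        return f

    def encode(self, enc: ArithmeticEncoder, m: int, k: int) -> None:
        if not 0 <= k <= m:
            raise ValueError("count exceeds cell size")
        f = self._freqs(m)
        cum = np.cumsum(f)
        total = int(cum[-1])
        lo = int(cum[k - 1]) if k else 0
        enc.encode(lo, int(cum[k]), total)
        self.c1 += k
        self.c0 += m - k

    def decode(self, dec: ArithmeticDecoder, m: int) -> int:
        f = self._freqs(m)
        cum = np.cumsum(f)
        total = int(cum[-1])
        t = dec.target(total)
        k = int(np.searchsorted(cum, t, side="right"))
        if k > m:
            raise DecodeError("decoded count exceeds cell size")
        lo = int(cum[k - 1]) if k else 0
        dec.consume(lo, int(cum[k]), total)
        self.c1 += k
        self.c0 += m - k
        return k


# ---------------------------------------------------------------------------
# generic entropy coding of a symbol sequence (the public coding contract)
# ---------------------------------------------------------------------------

def entropy_code(symbols: Sequence[int], alphabet_size: int | None = None) -> tuple[bytes, int]:
    """Losslessly code a sequence over a finite integer alphabet.

    Returns ``(payload, nbits)``.  The codelength is within the adaptive-coder
    redundancy bound ``n*H_emp + O(log n)`` of the empirical entropy.
    """
    symbols = list(symbols)
    if alphabet_size is None:
        alphabet_size = max(symbols) + 1 if symbols else 2
    alphabet_size = max(alphabet_size, 2)
    if symbols and (min(symbols) < 0 or max(symbols) >= alphabet_size):
        raise ValueError("symbol out of alphabet range")
    if not symbols:
        return b"", 0
    writer = BitWriter()
    enc = ArithmeticEncoder(writer)
    model = AdaptiveModel(alphabet_size)
    for s in symbols:
        model.encode(enc, s)
    enc.finish()
    return writer.getvalue(), writer.nbits


def entropy_decode(payload: bytes, nbits: int, n_symbols: int, alphabet_size: int) -> list[int]:
    """Inverse of :func:`entropy_code`."""
    if n_symbols == 0:
        return []
    dec = ArithmeticDecoder(BitReader(payload, nbits))
    model = AdaptiveModel(max(alphabet_size, 2))
    return [model.decode(dec) for _ in range(n_symbols)]
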