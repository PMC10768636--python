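"""Quasi-succinct (Elias-Fano) representation of monotone integer lists.

A sorted list of ``n`` non-negative integers bounded by a universe ``u`` is
split into fixed-width low bits and a unary-coded high-bit vector.  Each value
``y_i`` contributes its ``low_width = floor(log2(u/n))`` least significant bits
to a packed array ``L`` and its remaining high part ``h_i`` to a bit vector
``H`` that concatenates the inverted-unary codes of the gaps ``h_i - h_{i-1}``
(equivalently: the i-th element sets bit ``h_i + i``).  The payload never
exceeds ``2n + n*ceil(log2(u/n))`` bits, less than half a bit per element away
from the information-theoretic optimum.

``rank``/``select`` queries are answered by locating set/unset bits in ``H``.
Position indexes ``O_1`` and ``O_0`` sample the position of every ``quantum``-th
one and zero so a query only scans a bounded window of ``H`` instead of the
whole vector; with the default quantum of 1024 and 32-bit index entries the
index costs 32/1024 = 3.125% of the indexed bits and an average select scan
touches 1024/64 = 16 machine words.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "EliasFanoSet",
    "DEFAULT_QUANTUM",
    "INDEX_ENTRY_BITS",
    "WORD_BITS",
    "index_overhead_fraction",
    "select_scan_window_words",
]

DEFAULT_QUANTUM = 1024
INDEX_ENTRY_BITS = 32
WORD_BITS = 64

_ONE = np.uint64(1)


def index_overhead_fraction(quantum: int = DEFAULT_QUANTUM,
                            entry_bits: int = INDEX_ENTRY_BITS) -> float:
    """Memory overhead of a position index relative to the bits it indexes.

    One ``entry_bits``-wide position is stored per ``quantum`` indexed bits,
    so the overhead is ``entry_bits / quantum`` (3.125% at the defaults).
    """
    if quantum <= 0:
        raise ValueError("quantum must be positive")
    return entry_bits / quantum


def select_scan_window_words(quantum: int = DEFAULT_QUANTUM,
                             word_bits: int = WORD_BITS) -> float:
    """Average number of machine words scanned per select query.

    A select starts from the nearest indexed position and scans at most the
    ``quantum`` bits up to the next one, i.e. ``quantum / word_bits`` words
    (16 at the defaults).
    """
    return quantum / word_bits


def _low_width(n: int, u: int) -> int:
    # floor(log2(u/n)), clamped to >= 0; floor(log2(u//n)) is identical for
    # u >= n because integer division cannot cross a power of two downward.
    if n == 0 or u <= n:
        return 0
    return (u // n).bit_length() - 1


class EliasFanoSet:
    """Elias-Fano encoded monotone list with rank/select support.

    Parameters
    ----------
    values
        Monotone non-decreasing sequence of integers, each ``< u``.
    u
        Universe bound (exclusive).
    quantum
        Sampling period of the one/zero position indexes.
    """

    __slots__ = ("n", "u", "quantum", "low_width", "_L", "_H", "_nbits",
                 "_O0", "_O1", "_n_zeros")

    def __init__(self, values, u: int, quantum: int = DEFAULT_QUANTUM):
        values = np.asarray(values, dtype=np.uint64)
        n = int(values.size)
        u = int(u)
        if u < 1:
            raise ValueError("universe bound u must be >= 1")
        if quantum < 1:
            raise ValueError("quantum must be >= 1")
        if n:
            if not np.all(values[1:] >= values[:-1]):
                raise ValueError("values must be monotone non-decreasing")
            if int(values[-1]) >= u:
                raise ValueError(
                    f"value {int(values[-1])} outside universe [0, {u})")

        self.n = n
        self.u = u
        self.quantum = int(quantum)
        lw = _low_width(n, u)
        self.low_width = lw

        if n == 0:
            self._L = np.zeros(0, dtype=np.uint64)
            self._H = np.zeros(0, dtype=np.uint64)
            self._nbits = 0
            self._O0 = np.zeros(0, dtype=np.uint32)
            self._O1 = np.zeros(0, dtype=np.uint32)
            self._n_zeros = 0
            return

        highs = (values >> np.uint64(lw)).astype(np.uint64)
        self._L = self._pack_lows(values, lw)

        # one for element i at bit position highs[i] + i; the zeros in
        # between are the inverted-unary gap codes of consecutive highs
        pos = highs + np.arange(n, dtype=np.uint64)
        nbits = int(pos[-1]) + 1
        self._nbits = nbits
        H = np.zeros((nbits + WORD_BITS - 1) // WORD_BITS, dtype=np.uint64)
        np.bitwise_or.at(H, (pos >> np.uint64(6)).astype(np.intp),
                         _ONE << (pos & np.uint64(63)))
        self._H = H
        self._n_zeros = nbits - n

        # ones index: bit position of the one with 0-based rank j*quantum
        self._O1 = pos[::self.quantum].astype(np.uint32)
        # zeros index: likewise for unset bits
        if self._n_zeros:
            all_pos = np.arange(nbits, dtype=np.int64)
            is_one = np.zeros(nbits, dtype=bool)
            is_one[pos.astype(np.int64)] = True
            zero_pos = all_pos[~is_one]
            self._O0 = zero_pos[::self.quantum].astype(np.uint32)
        else:
            self._O0 = np.zeros(0, dtype=np.uint32)

    # -- construction helpers -------------------------------------------

    @staticmethod
    def _pack_lows(values: np.ndarray, lw: int) -> np.ndarray:
        n = values.size
        if lw == 0:
            return np.zeros(0, dtype=np.uint64)
        lows = values & np.uint64((1 << lw) - 1)
        total = n * lw
        L = np.zeros((total + WORD_BITS - 1) // WORD_BITS, dtype=np.uint64)
        start = np.arange(n, dtype=np.uint64) * np.uint64(lw)
        word = (start >> np.uint64(6)).astype(np.intp)
        off = start & np.uint64(63)
        np.bitwise_or.at(L, word, lows << off)
        spill = off.astype(np.int64) + lw > WORD_BITS
        if np.any(spill):
            sh = np.uint64(WORD_BITS) - off[spill]
            np.bitwise_or.at(L, word[spill] + 1, lows[spill] >> sh)
        return L

    def _read_low(self, i: int) -> int:
        lw = self.low_width
        if lw == 0:
            return 0
        start = i * lw
        word, off = divmod(start, WORD_BITS)
        val = int(self._L[word]) >> off
        if off + lw > WORD_BITS:
            val |= int(self._L[word + 1]) << (WORD_BITS - off)
        return val & ((1 << lw) - 1)

    def _read_lows(self, idx: np.ndarray) -> np.ndarray:
        lw = self.low_width
        if lw == 0:
            return np.zeros(len(idx), dtype=np.uint64)
        start = idx.astype(np.uint64) * np.uint64(lw)
        word = (start >> np.uint64(6)).astype(np.intp)
        off = start & np.uint64(63)
        val = self._L[word] >> off
        spill = off.astype(np.int64) + lw > WORD_BITS
        if np.any(spill):
            sh = np.uint64(WORD_BITS) - off[spill]
            val[spill] |= self._L[word[spill] + 1] << sh
        return val & np.uint64((1 << lw) - 1)

    # -- bit-vector scans -----------------------------------------------

    def _bit(self, pos: int) -> int:
        return (int(self._H[pos >> 6]) >> (pos & 63)) & 1

    def _select_bit(self, i: int, ones: bool) -> int:
        """Position of the i-th (0-based) set/unset bit of H.

        Starts from the quantum-index sample at or before rank ``i`` and
        scans whole words, so at most ``quantum`` bits are examined.
        """
        index = self._O1 if ones else self._O0
        j = i // self.quantum
        start = int(index[j])
        need = i - j * self.quantum  # set/unset bits to skip at/after start
        word_idx = start >> 6
        w = int(self._H[word_idx]) >> (start & 63)
        if not ones:
            w = ~w & ((1 << (WORD_BITS - (start & 63))) - 1)
        base = start
        while True:
            c = w.bit_count()
            if need < c:
                # need-th set bit within w
                while need:
                    w &= w - 1
                    need -= 1
                return base + ((w & -w).bit_length() - 1)
            need -= c
            word_idx += 1
            base = word_idx << 6
            w = int(self._H[word_idx])
            if not ones:
                w = ~w & 0xFFFFFFFFFFFFFFFF

    # -- public queries --------------------------------------------------

    def select(self, i: int) -> int:
        """Return the (i+1)-th smallest stored value (0-based index)."""
        if not 0 <= i < self.n:
            raise IndexError(f"select index {i} out of range [0, {self.n})")
        pos = self._select_bit(i, ones=True)
        high = pos - i
        return (high << self.low_width) | self._read_low(i)

    def rank(self, m: int) -> int:
        """Number of stored elements strictly lower than ``m``."""
        if m < 0:
            raise ValueError("rank bound must be non-negative")
        if self.n == 0 or m == 0:
            return 0
        lw = self.low_width
        hm = m >> lw
        lm = m & ((1 << lw) - 1)
        if hm > self._n_zeros:
            return self.n
        if hm == 0:
            i = 0
            pos = 0
        else:
            # ones before the hm-th zero are exactly the elements with
            # high part < hm; the bucket for high part hm starts just after
            z = self._select_bit(hm - 1, ones=False)
            i = z - (hm - 1)
            pos = z + 1
        # lows within a bucket are sorted, so stop at the first >= lm
        while pos < self._nbits and self._bit(pos):
            if self._read_low(i) >= lm:
                break
            i += 1
            pos += 1
        return i

    def to_array(self) -> np.ndarray:
        """Decode the full stored list (vectorized)."""
        if self.n == 0:
            return np.zeros(0, dtype=np.uint64)
        bits = np.unpackbits(self._H.view(np.uint8), bitorder="little")
        pos = np.flatnonzero(bits[: self._nbits]).astype(np.uint64)
        highs = pos - np.arange(self.n, dtype=np.uint64)
        lows = self._read_lows(np.arange(self.n))
        return (highs << np.uint64(self.low_width)) | lows

    def size_in_bits(self) -> tuple[int, int]:
        """(payload_bits, index_bits): L+H payload and O_0+O_1 index cost."""
        payload = self.n * self.low_width + self._nbits
        index = INDEX_ENTRY_BITS * (len(self._O0) + len(self._O1))
        return payload, index

    # -- dunders ----------------------------------------------------------

    def __len__(self) -> int:
        return self.n

    def __iter__(self):
        return iter(self.to_array().tolist())

    def __contains__(self, value: int) -> bool:
        if value < 0 or value >= self.u:
            return False
        r = self.rank(value)
        return r < self.n and self.select(r) == value

    def __repr__(self) -> str:  # pragma: no cover
        return (f"EliasFanoSet(n={self.n}, u={self.u}, "
                f"low_width={self.low_width})")
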