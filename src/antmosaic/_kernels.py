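"""Numba kernels for fixed-fixed randomization and checkerboard counting.

Matrices are bit-packed: each species row is an array of uint64 words over
the sample columns.  All kernels are deterministic given the integer seed
passed in (numba's per-thread legacy RNG is seeded explicitly at the top of
every seeded kernel).
"""

from __future__ import annotations

import numpy as np
from numba import njit

_M1 = np.uint64(0x5555555555555555)
_M2 = np.uint64(0x3333333333333333)
_M4 = np.uint64(0x0F0F0F0F0F0F0F0F)
_H01 = np.uint64(0x0101010101010101)

CURVEBALL = 0
TRIAL_SWAP = 1


@njit(cache=True, inline="always")
def _popcount(x):
    x = x - ((x >> np.uint64(1)) & _M1)
    x = (x & _M2) + ((x >> np.uint64(2)) & _M2)
    x = (x + (x >> np.uint64(4))) & _M4
    return np.int64((x * _H01) >> np.uint64(56))


@njit(cache=True)
def _cu_from_masks(words, n_rows, n_words):
    """Summed (r_i - S_ij)(r_j - S_ij) over unordered row pairs."""
    r = np.empty(n_rows, dtype=np.int64)
    for i in range(n_rows):
        acc = np.int64(0)
        for w in range(n_words):
            acc += _popcount(words[i, w])
        r[i] = acc
    total = np.int64(0)
    for i in range(n_rows):
        for j in range(i + 1, n_rows):
            s = np.int64(0)
            for w in range(n_words):
                s += _popcount(words[i, w] & words[j, w])
            total += (r[i] - s) * (r[j] - s)
    return total


@njit(cache=True)
def _curveball_sweep(words, n_rows, n_words, n_cols, n_trades, pool, owner):
    """In-place curveball trades: random row pairs exchange random subsets
    of the columns where exactly one of them is present."""
    one = np.uint64(1)
    for _ in range(n_trades):
        i = np.random.randint(0, n_rows)
        j = np.random.randint(0, n_rows)
        if i == j:
            continue
        k = 0
        k1 = 0
        for w in range(n_words):
            lo = w << 6
            width = n_cols - lo
            if width > 64:
                width = 64
            diff = words[i, w] ^ words[j, w]
            if diff == np.uint64(0):
                continue
            for b in range(width):
                if (diff >> np.uint64(b)) & one:
                    pool[k] = lo + b
                    owned = np.int64((words[i, w] >> np.uint64(b)) & one)
                    owner[k] = owned
                    k1 += owned
                    k += 1
        if k1 == 0 or k1 == k:
            continue
        # choose which k1 of the k differing columns row i keeps
        for t in range(k1):
            r = t + np.random.randint(0, k - t)
            tmp = pool[t]
            pool[t] = pool[r]
            pool[r] = tmp
        for t in range(k):
            pos = pool[t]
            w = pos >> 6
            bit = one << np.uint64(pos & 63)
            if t < k1:
                words[i, w] |= bit
                words[j, w] &= ~bit
            else:
                words[j, w] |= bit
                words[i, w] &= ~bit


@njit(cache=True)
def _trial_swap_sweep(words, n_rows, n_words, n_cols, n_attempts):
    """In-place trial swaps: flip a random 2x2 checkerboard submatrix when
    one is hit; attempts that miss count as steps (classic trial-swap)."""
    one = np.uint64(1)
    for _ in range(n_attempts):
        i = np.random.randint(0, n_rows)
        j = np.random.randint(0, n_rows)
        if i == j:
            continue
        a = np.random.randint(0, n_cols)
        b = np.random.randint(0, n_cols)
        if a == b:
            continue
        wa, ba = a >> 6, np.uint64(a & 63)
        wb, bb = b >> 6, np.uint64(b & 63)
        ia = (words[i, wa] >> ba) & one
        ib = (words[i, wb] >> bb) & one
        ja = (words[j, wa] >> ba) & one
        jb = (words[j, wb] >> bb) & one
        if ia != ja and ib != jb and ia != ib:
            words[i, wa] ^= one << ba
            words[i, wb] ^= one << bb
            words[j, wa] ^= one << ba
            words[j, wb] ^= one << bb


@njit(cache=True)
def _sweep(words, n_rows, n_words, n_cols, n_steps, algorithm, pool, owner):
    if algorithm == CURVEBALL:
        _curveball_sweep(words, n_rows, n_words, n_cols, n_steps, pool, owner)
    else:
        _trial_swap_sweep(words, n_rows, n_words, n_cols, n_steps)


@njit(cache=True)
def randomize_masks(base, n_rows, n_words, n_cols, n_steps, burn_in, algorithm, seed):
    """One fixed-fixed draw starting from ``base``; returns a new array."""
    np.random.seed(seed)
    words = base.copy()
    pool = np.empty(n_cols, dtype=np.int64)
    owner = np.empty(n_cols, dtype=np.int64)
    _sweep(words, n_rows, n_words, n_cols, burn_in + n_steps, algorithm, pool, owner)
    return words


@njit(cache=True)
def null_cu_distribution(
    base, n_rows, n_words, n_cols, n_null, n_steps, burn_in, algorithm, independent, seed
):
    """Checkerboard-unit counts for ``n_null`` fixed-fixed randomizations.

    independent=True restarts every draw from ``base``; otherwise a single
    chain is advanced ``n_steps`` between consecutive draws after an
    initial ``burn_in``.
    """
    np.random.seed(seed)
    out = np.empty(n_null, dtype=np.int64)
    pool = np.empty(n_cols, dtype=np.int64)
    owner = np.empty(n_cols, dtype=np.int64)
    if independent:
        for d in range(n_null):
            words = base.copy()
            _sweep(words, n_rows, n_words, n_cols, burn_in + n_steps, algorithm, pool, owner)
            out[d] = _cu_from_masks(words, n_rows, n_words)
    else:
        words = base.copy()
        _sweep(words, n_rows, n_words, n_cols, burn_in, algorithm, pool, owner)
        for d in range(n_null):
            _sweep(words, n_rows, n_words, n_cols, n_steps, algorithm, pool, owner)
            out[d] = _cu_from_masks(words, n_rows, n_words)
    return out


@njit(cache=True)
def null_draws(
    base, n_rows, n_words, n_cols, n_null, n_steps, burn_in, algorithm, independent, seed
):
    """As :func:`null_cu_distribution` but returning the drawn matrices."""
    np.random.seed(seed)
    out = np.empty((n_null, n_rows, n_words), dtype=np.uint64)
    pool = np.empty(n_cols, dtype=np.int64)
    owner = np.empty(n_cols, dtype=np.int64)
    if independent:
        for d in range(n_null):
            words = base.copy()
            _sweep(words, n_rows, n_words, n_cols, burn_in + n_steps, algorithm, pool, owner)
            out[d] = words
    else:
        words = base.copy()
        _sweep(words, n_rows, n_words, n_cols, burn_in, algorithm, pool, owner)
        for d in range(n_null):
            _sweep(words, n_rows, n_words, n_cols, n_steps, algorithm, pool, owner)
            out[d] = words
    return out


def pack_rows(cells: np.ndarray) -> np.ndarray:
    """Bit-pack a binary (rows x cols) array into uint64 words per row."""
    cells = np.ascontiguousarray(cells, dtype=np.uint8)
    n_rows, n_cols = cells.shape
    n_words = max(1, (n_cols + 63) // 64)
    padded = np.zeros((n_rows, n_words * 64), dtype=np.uint8)
    padded[:, :n_cols] = cells
    bits = padded.reshape(n_rows, n_words, 8, 8)
    # packbits uses MSB-first within bytes; build LSB-first uint64 manually
    weights = (np.uint64(1) << np.arange(64, dtype=np.uint64)).reshape(8, 8)
    return (bits.astype(np.uint64) * weights[None, None]).sum(axis=(2, 3)).astype(np.uint64)


def unpack_rows(words: np.ndarray, n_cols: int) -> np.ndarray:
    """Inverse of :func:`pack_rows`."""
    n_rows, n_words = words.shape
    out = np.zeros((n_rows, n_words * 64), dtype=np.uint8)
    for w in range(n_words):
        for b in range(64):
            out[:, w * 64 + b] = (words[:, w] >> np.uint64(b)) & np.uint64(1)
    return out[:, :n_cols]
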