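"""Numba kernels shared by the object-level API and the population engine.

Encoding convention used throughout the package: an rDNA locus is a 1-D
``int64`` array of unit codes, where ``0`` is an uninserted unit, a positive
value ``k`` is a unit carrying full-length R2 of lineage ``k``, and a negative
value ``-k`` is a unit carrying a 5'-truncated copy of lineage ``k``.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def largest_run(codes, L):
    """Leftmost maximal run of consecutive uninserted units in ``codes[:L]``.

    Returns ``(start, length)``; ``(0, 0)`` when every unit is inserted.
    """
    best_start = 0
    best_len = 0
    cur_start = 0
    cur_len = 0
    for i in range(L):
        if codes[i] == 0:
            if cur_len == 0:
                cur_start = i
            cur_len += 1
            if cur_len > best_len:
                best_len = cur_len
                best_start = cur_start
        else:
            cur_len = 0
    return best_start, best_len


@njit(cache=True)
def place_domain_kernel(codes, L, domain_size):
    """Place the transcription domain of ``domain_size`` units on a locus.

    The domain is centered on the largest contiguous R2-free block (leftmost
    on ties), its midpoint rounded to the nearest unit with exact halves
    resolved toward the lower index, and the window clamped inside the locus.
    A fully inserted locus centers the domain on the locus midpoint.
    Returns ``(start, effective_size)`` with the half-open window
    ``[start, start + effective_size)``.
    """
    d_eff = domain_size if domain_size < L else L
    run_start, run_len = largest_run(codes, L)
    if run_len == 0:
        center = (L - 1) / 2.0
    else:
        center = run_start + (run_len - 1) / 2.0
    start = int(np.ceil(center - (d_eff - 1) / 2.0 - 0.5))
    if start < 0:
        start = 0
    if start > L - d_eff:
        start = L - d_eff
    return start, d_eff


@njit(cache=True)
def domain_counts(codes, start, size):
    """Count (full-length, truncated, uninserted) units in the domain window."""
    n_full = 0
    n_trunc = 0
    n_un = 0
    for i in range(start, start + size):
        c = codes[i]
        if c > 0:
            n_full += 1
        elif c < 0:
            n_trunc += 1
        else:
            n_un += 1
    return n_full, n_trunc, n_un


@njit(cache=True)
def crossover_fill(a, La, b, Lb, cut_a, cut_b, out1, out2):
    """Write the two unequal-crossover products into ``out1`` / ``out2``.

    ``out1 = a[:cut_a] + b[cut_b:]`` and ``out2 = b[:cut_b] + a[cut_a:]``;
    returns their lengths. Buffers must be large enough.
    """
    l1 = cut_a + (Lb - cut_b)
    l2 = cut_b + (La - cut_a)
    for i in range(cut_a):
        out1[i] = a[i]
    for i in range(Lb - cut_b):
        out1[cut_a + i] = b[cut_b + i]
    for i in range(cut_b):
        out2[i] = b[i]
    for i in range(La - cut_a):
        out2[cut_b + i] = a[cut_a + i]
    return l1, l2
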