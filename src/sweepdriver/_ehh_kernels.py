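"""Compiled inner loops for EHH walks.

The EHH recursion splits carrier haplotypes into identity groups one site at
a time; these kernels carry the group labels and sizes through the walk so a
whole arm costs O(extent * n_carriers). The arithmetic is identical to the
all-pairs definition sum_h C(k_h,2)/C(n,2), which the test suite verifies
against an O(n^2) oracle.
"""

from __future__ import annotations

import numpy as np
from numba import njit

STATUS_CUTOFF = 0
STATUS_EDGE = 1
STATUS_GAP = 2


@njit(cache=True)
def walk(entries, positions, carriers, core, cutoff, max_gap, step, out_pos, out_ehh):
    """Extend EHH from ``core`` in one direction until it drops below
    ``cutoff`` (status 0), the chromosome edge (1) or a gap > max_gap (2).

    Writes (position, EHH) per extent into out_pos/out_ehh; returns
    (number of extents written, status). The core itself (EHH = 1 by the
    zero-length convention) is not written; every extent's identity span
    includes the core column, so a pooled walk separates the two core
    alleles from its first step. ``max_gap`` <= 0 disables the gap rule.
    """
    n = carriers.size
    n_sites = entries.shape[1]
    labels = np.zeros(n, dtype=np.int64)
    for i in range(n):
        labels[i] = entries[carriers[i], core]
    sizes = np.zeros(n, dtype=np.int64)
    n_groups = 2
    denom = n * (n - 1)
    j = core
    last = positions[core]
    count = 0
    while True:
        j += step
        if j < 0 or j >= n_sites:
            return count, STATUS_EDGE
        gap = positions[j] - last
        if gap < 0:
            gap = -gap
        if max_gap > 0 and gap > max_gap:
            return count, STATUS_GAP
        last = positions[j]

        scratch = np.full(2 * n_groups, -1, dtype=np.int64)
        k = 0
        for g in range(n):
            sizes[g] = 0
        for i in range(n):
            nl = 2 * labels[i] + entries[carriers[i], j]
            if scratch[nl] < 0:
                scratch[nl] = k
                k += 1
            labels[i] = scratch[nl]
            sizes[labels[i]] += 1
        n_groups = k
        s = 0
        for g in range(k):
            s += sizes[g] * (sizes[g] - 1)
        e = s / denom
        out_pos[count] = positions[j]
        out_ehh[count] = e
        count += 1
        if e < cutoff:
            return count, STATUS_CUTOFF


@njit(cache=True)
def walk_fixed(entries, positions, carriers, core, n_steps, step, out_pos, out_ehh):
    """EHH at exactly ``n_steps`` extents from the core (no stop rule);
    the identity span includes the core column."""
    n = carriers.size
    labels = np.zeros(n, dtype=np.int64)
    for i in range(n):
        labels[i] = entries[carriers[i], core]
    sizes = np.zeros(n, dtype=np.int64)
    n_groups = 2
    denom = n * (n - 1)
    j = core
    for t in range(n_steps):
        j += step
        scratch = np.full(2 * n_groups, -1, dtype=np.int64)
        k = 0
        for g in range(n):
            sizes[g] = 0
        for i in range(n):
            nl = 2 * labels[i] + entries[carriers[i], j]
            if scratch[nl] < 0:
                scratch[nl] = k
                k += 1
            labels[i] = scratch[nl]
            sizes[labels[i]] += 1
        n_groups = k
        s = 0
        for g in range(k):
            s += sizes[g] * (sizes[g] - 1)
        out_pos[t] = positions[j]
        out_ehh[t] = s / denom


@njit(cache=True)
def wf_children(
    M, S, positions, hap_idx, other_idx, breaks_flat, breaks_off, children
):
    """One generation of non-migrant gamete formation.

    Child i copies row ``hap_idx[i]`` of ``M`` over the live columns [:S],
    switching to row ``other_idx[i]`` wherever an odd number of its
    crossover breakpoints (``breaks_flat[breaks_off[i]:breaks_off[i+1]]``)
    lie below the column's position. Columns at and beyond S are untouched.
    """
    n = children.shape[0]
    for i in range(n):
        b0, b1 = breaks_off[i], breaks_off[i + 1]
        a_row = hap_idx[i]
        if b1 == b0:
            for j in range(S):
                children[i, j] = M[a_row, j]
        else:
            b_row = other_idx[i]
            for j in range(S):
                parity = 0
                p = positions[j]
                for b in range(b0, b1):
                    if breaks_flat[b] < p:
                        parity += 1
                if parity % 2 == 1:
                    children[i, j] = M[b_row, j]
                else:
                    children[i, j] = M[a_row, j]
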