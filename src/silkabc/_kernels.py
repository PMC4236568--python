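"""Numba kernels for the two-population structured coalescent.

Time is in units of 4*N1 generations; population sizes are relative to
N1.  With that scaling a pair of lineages in a population of relative
size s coalesces at rate 2/s, and a lineage in population i moves to
population j at the epoch's scaled backward rate M_ij = 4*N1*m_ij.

Epochs are passed as parallel arrays (start time, dom size, wild size,
backward movement rate out of dom, out of wild); the last epoch is the
ancestral single population, at whose start all lineages are pooled.

Node numbering: leaves 0 .. n-1 (dom first, then wild); internal nodes
n .. 2n-2 created in increasing time order, so every child id is smaller
than its parent id.  The root's parent is -1.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["simulate_genealogy_arrays", "genealogy_stats", "simulate_locus_stats_batch"]


@njit(cache=True)
def simulate_genealogy_arrays(n_dom, n_wild, starts, size_dom, size_wild,
                              m_dom, m_wild, seed):
    """Simulate one genealogy; returns (parent, time, pop, lchild, rchild).

    ``pop`` records the population (0=dom, 1=wild, 0 after the merge) in
    which each node was created.
    """
    np.random.seed(seed)
    n = n_dom + n_wild
    n_nodes = 2 * n - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    lchild = np.full(n_nodes, -1, dtype=np.int64)
    rchild = np.full(n_nodes, -1, dtype=np.int64)
    time = np.zeros(n_nodes, dtype=np.float64)
    popl = np.zeros(n_nodes, dtype=np.int64)

    act = np.empty((2, n), dtype=np.int64)  # active lineage ids per pop
    k = np.zeros(2, dtype=np.int64)
    for i in range(n_dom):
        act[0, i] = i
        popl[i] = 0
    for i in range(n_wild):
        act[1, i] = n_dom + i
        popl[n_dom + i] = 1
    k[0] = n_dom
    k[1] = n_wild

    n_epochs = starts.shape[0]
    last = n_epochs - 1
    t = 0.0
    e = 0
    nxt = n
    while k[0] + k[1] > 1:
        if e == last and k[1] > 0:
            # split reached: pool everything into population 0
            for i in range(k[1]):
                act[0, k[0] + i] = act[1, i]
            k[0] += k[1]
            k[1] = 0
        sd = size_dom[e]
        sw = size_wild[e]
        r_cd = k[0] * (k[0] - 1) / sd
        r_cw = k[1] * (k[1] - 1) / sw
        r_md = k[0] * m_dom[e]
        r_mw = k[1] * m_wild[e]
        tot = r_cd + r_cw + r_md + r_mw
        if tot <= 0.0:
            t = starts[e + 1]
            e += 1
            continue
        dt = np.random.exponential(1.0 / tot)
        if e < last and t + dt >= starts[e + 1]:
            # epoch boundary: rates change; memoryless, so just re-draw
            t = starts[e + 1]
            e += 1
            continue
        t += dt
        u = np.random.random() * tot
        if u < r_cd + r_cw:
            pop = 0 if u < r_cd else 1
            kk = k[pop]
            i = np.random.randint(kk)
            j = np.random.randint(kk - 1)
            if j >= i:
                j += 1
            a = act[pop, i]
            b = act[pop, j]
            parent[a] = nxt
            parent[b] = nxt
            lchild[nxt] = a
            rchild[nxt] = b
            time[nxt] = t
            popl[nxt] = pop
            # replace the two children by the new node
            lo = i if i < j else j
            hi = j if i < j else i
            act[pop, lo] = nxt
            act[pop, hi] = act[pop, kk - 1]
            k[pop] = kk - 1
            nxt += 1
        elif u < r_cd + r_cw + r_md:
            i = np.random.randint(k[0])
            lin = act[0, i]
            act[0, i] = act[0, k[0] - 1]
            k[0] -= 1
            act[1, k[1]] = lin
            k[1] += 1
        else:
            i = np.random.randint(k[1])
            lin = act[1, i]
            act[1, i] = act[1, k[1] - 1]
            k[1] -= 1
            act[0, k[0]] = lin
            k[0] += 1
    return parent, time, popl, lchild, rchild


@njit(cache=True)
def genealogy_stats(parent, time, lchild, rchild, n_dom, n_wild, theta_locus):
    """Drop infinite-sites mutations and return per-population (S, pi).

    Mutation counts per branch are Poisson(theta_locus * len), with
    branch lengths in units of 4*N1 generations (so E[pi] = theta and
    E[S] = theta * a_{n-1} in a constant-size population); a
    mutation carried by d of the n_dom dom samples contributes to S_dom
    when 0 < d < n_dom and adds d*(n_dom-d) differing pairs to pi_dom.
    Site positions are irrelevant to S and pi and are not drawn here.
    """
    n = n_dom + n_wild
    n_nodes = parent.shape[0]
    ndesc_d = np.zeros(n_nodes, dtype=np.int64)
    ndesc_w = np.zeros(n_nodes, dtype=np.int64)
    s_dom = 0.0
    s_wild = 0.0
    pi_dom = 0.0
    pi_wild = 0.0
    for v in range(n_nodes):
        if v < n_dom:
            ndesc_d[v] = 1
        elif v < n:
            ndesc_w[v] = 1
        else:
            ndesc_d[v] = ndesc_d[lchild[v]] + ndesc_d[rchild[v]]
            ndesc_w[v] = ndesc_w[lchild[v]] + ndesc_w[rchild[v]]
        pa = parent[v]
        if pa < 0:
            continue
        blen = time[pa] - time[v]
        mv = np.random.poisson(theta_locus * blen)
        if mv == 0:
            continue
        d = ndesc_d[v]
        w = ndesc_w[v]
        if 0 < d < n_dom:
            s_dom += mv
            pi_dom += mv * d * (n_dom - d)
        if 0 < w < n_wild:
            s_wild += mv
            pi_wild += mv * w * (n_wild - w)
    if n_dom > 1:
        pi_dom *= 2.0 / (n_dom * (n_dom - 1))
    if n_wild > 1:
        pi_wild *= 2.0 / (n_wild * (n_wild - 1))
    return s_dom, s_wild, pi_dom, pi_wild


@njit(cache=True)
def simulate_locus_stats_batch(n_dom, n_wild, starts, size_dom, size_wild,
                               m_dom, m_wild, theta_loci, seeds):
    """Per-locus (S_dom, S_wild, pi_dom, pi_wild) for independent loci.

    ``n_dom``/``n_wild`` give per-locus sample sizes, ``theta_loci`` one
    per-locus theta (per-site theta times locus length) and ``seeds``
    one RNG seed per locus, so locus i is reproducible regardless of
    how many loci are simulated.
    """
    n_loci = theta_loci.shape[0]
    out = np.empty((n_loci, 4), dtype=np.float64)
    for i in range(n_loci):
        parent, time, popl, lc, rc = simulate_genealogy_arrays(
            n_dom[i], n_wild[i], starts, size_dom, size_wild, m_dom,
            m_wild, seeds[i])
        s_d, s_w, p_d, p_w = genealogy_stats(
            parent, time, lc, rc, n_dom[i], n_wild[i], theta_loci[i])
        out[i, 0] = s_d
        out[i, 1] = s_w
        out[i, 2] = p_d
        out[i, 3] = p_w
    return out
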