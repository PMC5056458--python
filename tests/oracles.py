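"""Independent brute-force reference implementations used only by tests.

Everything here is deliberately scalar / enumerative and shares no code
with the package implementations it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def hp_oracle(major, minor) -> float:
    """Direct one-line pooled-heterozygosity formula."""
    smaj = sum(int(x) for x in major)
    smin = sum(int(x) for x in minor)
    return 2.0 * smaj * smin / (smaj + smin) ** 2


def tajima_oracle(haplotypes) -> float:
    """Tajima's D from explicit all-pairs haplotype differences."""
    h = np.asarray(haplotypes)
    n, length = h.shape
    s = 0
    for j in range(length):
        c = int(h[:, j].sum())
        if 0 < c < n:
            s += 1
    total = 0
    pairs = 0
    for i in range(n):
        for k in range(i + 1, n):
            total += int((h[i] != h[k]).sum())
            pairs += 1
    pi = total / pairs
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * s + e2 * s * (s - 1)
    num = pi - s / a1
    if var <= 0:
        return 0.0 if abs(num) < 1e-12 else float("nan")
    return num / math.sqrt(var)


def wc_diploid_site_oracle(g1, g2):
    """Weir-Cockerham (a, b, c) for one site, two diploid samples, scalar."""
    r = 2
    n = [len(g1), len(g2)]
    p = [sum(g1) / (2.0 * n[0]), sum(g2) / (2.0 * n[1])]
    h = [sum(1 for g in g1 if g == 1) / n[0],
         sum(1 for g in g2 if g == 1) / n[1]]
    nbar = sum(n) / r
    nc = (r * nbar - sum(ni * ni for ni in n) / (r * nbar)) / (r - 1)
    pbar = sum(ni * pi for ni, pi in zip(n, p)) / (r * nbar)
    s2 = sum(ni * (pi - pbar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * nbar)
    hbar = sum(ni * hi for ni, hi in zip(n, h)) / (r * nbar)
    a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4)
                       / (nbar - 1))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                               - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    return a, b, c


def wc_haploid_site_oracle(ref1, alt1, ref2, alt2):
    """Haploid-sample Weir-Cockerham (a, a + MSG) for one site, scalar."""
    n1, n2 = ref1 + alt1, ref2 + alt2
    p1, p2 = alt1 / n1, alt2 / n2
    ntot = n1 + n2
    pbar = (alt1 + alt2) / ntot
    nc = ntot - (n1 * n1 + n2 * n2) / ntot
    msp = n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2
    msg = (n1 * p1 * (1 - p1) + n2 * p2 * (1 - p2)) / (ntot - 2)
    a = (msp - msg) / nc
    return a, a + msg


def enumerate_paint(recipient, donors, ne, mut, recomb_rate=1e-8):
    """Full path enumeration of the copying HMM for one recipient.

    Returns (site_group_posterior (L, G), expected group entries (G,),
    log-likelihood, group name list).  Exponential in K**L: tiny cases only.
    """
    alleles = np.asarray(donors.alleles)
    K, L = alleles.shape
    positions = np.asarray(donors.positions, dtype=float)
    rho = [1.0 - math.exp(-ne * recomb_rate * (positions[t + 1] - positions[t]))
           for t in range(L - 1)]
    groups = []
    for g in donors.groups:
        if g not in groups:
            groups.append(g)
    gidx = [groups.index(g) for g in donors.groups]
    n_groups = len(groups)

    def emit(t, k):
        d, r = alleles[k, t], recipient[t]
        if d < 0 or r < 0:
            return 1.0
        return 1.0 - mut if d == r else mut

    total = 0.0
    post = np.zeros((L, n_groups))
    entries = np.zeros(n_groups)
    for path in itertools.product(range(K), repeat=L):
        p = (1.0 / K) * emit(0, path[0])
        for t in range(1, L):
            trans = rho[t - 1] / K
            if path[t] == path[t - 1]:
                trans += 1.0 - rho[t - 1]
            p *= trans * emit(t, path[t])
        total += p
        ent = np.zeros(n_groups)
        ent[gidx[path[0]]] += 1
        for t in range(L):
            post[t, gidx[path[t]]] += p
            if t and gidx[path[t]] != gidx[path[t - 1]]:
                ent[gidx[path[t]]] += 1
        entries += ent * p
    return post / total, entries / total, math.log(total), groups
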