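"""Haplotype-copying (chromosome painting) under a Li-Stephens HMM.

Each recipient haplotype is modelled as a mosaic of donor haplotypes: the
hidden state at a site is the donor currently being copied.  Between
adjacent sites the chain switches with probability ``1 - exp(-Ne * g)``
(``g`` the inter-site genetic distance in Morgans, or a uniform per-base
rate surrogate), the new donor drawn uniformly; emissions match the donor
allele with probability ``1 - Mut`` and miscopy with probability ``Mut``.

The forward-backward posterior yields, per recipient and donor group, the
expected copying fraction and the expected chunk count (expected number of
entries into that group's states along the sequence) - the "number of
inferred haplotype segments" similarity summary.  A Viterbi mode counting
segments on the single best path is available for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class PainterParams:
    """Copying-model parameters.

    ``ne`` scales the switch (recombination) rate and ``mut`` the miscopy
    probability; the defaults are the fixed values used genome-wide after a
    single estimation pass in the original analysis.  ``recomb_rate`` is the
    uniform Morgans-per-base surrogate used when no genetic map is supplied
    (1 cM/Mb); pass per-site map positions (cM) to ``paint`` to override.
    """

    ne: float = 3166.0
    mut: float = 0.0287574
    recomb_rate: float = 1e-8

    def __post_init__(self):
        if self.ne <= 0:
            raise ValueError("ne must be positive")
        if not 0 < self.mut < 0.5:
            raise ValueError("mut must be in (0, 0.5)")
        if self.recomb_rate < 0:
            raise ValueError("recomb_rate must be >= 0")


@dataclass
class HaplotypePanel:
    """Phased haplotypes over a shared site list, labelled by donor group."""

    alleles: np.ndarray            # (n_haplotypes, n_sites) int8, -1 missing
    groups: np.ndarray             # (n_haplotypes,) group label per haplotype
    positions: np.ndarray          # (n_sites,) 0-based base positions
    map_cm: np.ndarray | None = None  # optional genetic-map positions (cM)

    def __post_init__(self):
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        self.groups = np.asarray(self.groups)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be (n_haplotypes, n_sites)")
        if self.alleles.shape != (len(self.groups), len(self.positions)):
            raise ValueError("alleles shape inconsistent with groups/positions")

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    def group_names(self) -> list[str]:
        seen: list[str] = []
        for g in self.groups:
            if g not in seen:
                seen.append(g)
        return seen


@dataclass
class PaintingResult:
    """Per-recipient copying summaries by donor group."""

    groups: list[str]
    chunk_counts: np.ndarray     # (n_recipients, n_groups) expected entries
    copy_fractions: np.ndarray   # (n_recipients, n_groups), rows sum to 1
    group_sizes: np.ndarray      # haplotypes per donor group
    log_likelihood: np.ndarray   # (n_recipients,)
    site_posterior: np.ndarray | None = None  # (n_rec, n_sites, n_groups)

    def normalized_chunk_counts(self) -> np.ndarray:
        """Chunk counts divided by donor-group size (per-haplotype sharing)."""
        return self.chunk_counts / self.group_sizes[None, :]

    def mean_copy_fraction(self) -> dict[str, float]:
        return {g: float(self.copy_fractions[:, i].mean())
                for i, g in enumerate(self.groups)}


def _switch_probs(positions: np.ndarray, params: PainterParams,
                  map_cm: np.ndarray | None) -> np.ndarray:
    """Per-gap switch probability 1 - exp(-Ne * g)."""
    if map_cm is not None:
        g = np.diff(np.asarray(map_cm, dtype=float)) / 100.0
        g = np.maximum(g, 0.0)
    else:
        g = np.diff(positions.astype(float)) * params.recomb_rate
    return -np.expm1(-params.ne * g)


def _emissions(recipients: np.ndarray, donors: np.ndarray,
               mut: float) -> np.ndarray:
    """Emission table, shape (n_rec, n_sites, n_donors).

    Missing alleles (recipient or donor) emit 1 for every state, so the
    site is informationally skipped.
    """
    rec = recipients[:, :, None]      # (R, L, 1)
    don = donors.T[None, :, :]        # (1, L, K)
    match = rec == don
    e = np.where(match, 1.0 - mut, mut)
    e[np.broadcast_to(rec < 0, e.shape)] = 1.0
    e[np.broadcast_to(don < 0, e.shape)] = 1.0
    return e


def paint(recipients: np.ndarray, donors: HaplotypePanel,
          params: PainterParams | None = None,
          return_posterior: bool = False) -> PaintingResult:
    """Forward-backward painting of recipient haplotypes against a donor panel.

    ``recipients`` is (n_recipients, n_sites) over the donor panel's site
    list (alleles {0,1}, -1 missing).  Returns expected chunk counts and
    copying fractions per donor group; optionally the dense per-site group
    posterior.
    """
    params = params or PainterParams()
    rec = np.atleast_2d(np.asarray(recipients, dtype=np.int8))
    K = donors.n_haplotypes
    L = donors.n_sites
    if K < 1:
        raise ValueError("need at least one donor haplotype")
    if L < 2:
        raise ValueError("need at least two sites to paint")
    if rec.shape[1] != L:
        raise ValueError("recipients and donors disagree on site count")
    if (rec < 0).all(axis=1).any():
        raise ValueError("recipient with all alleles missing")
    R = rec.shape[0]

    groups = donors.group_names()
    G = len(groups)
    gidx = np.array([groups.index(g) for g in donors.groups])
    member = np.zeros((K, G))
    member[np.arange(K), gidx] = 1.0

    rho = _switch_probs(donors.positions, params, donors.map_cm)
    E = _emissions(rec, donors.alleles, params.mut)

    # scaled forward pass
    alpha = np.empty((L, R, K))
    scale = np.empty((L, R))
    a = E[:, 0, :] / K
    scale[0] = a.sum(axis=1)
    alpha[0] = a / scale[0][:, None]
    for t in range(1, L):
        prior = (1.0 - rho[t - 1]) * alpha[t - 1] + rho[t - 1] / K
        a = prior * E[:, t, :]
        scale[t] = a.sum(axis=1)
        alpha[t] = a / scale[t][:, None]

    # scaled backward pass, accumulating posteriors and group entries
    beta = np.ones((R, K))
    gamma_sum = np.zeros((R, G))
    chunks = np.zeros((R, G))
    posterior = np.empty((R, L, G)) if return_posterior else None

    gamma = alpha[L - 1] * beta
    gamma_sum += gamma @ member
    if posterior is not None:
        posterior[:, L - 1, :] = gamma @ member
    for t in range(L - 2, -1, -1):
        w = E[:, t + 1, :] * beta / scale[t + 1][:, None]  # (R, K)
        a_g = alpha[t] @ member                            # (R, G)
        w_g = w @ member
        chunks += (rho[t] / K) * (1.0 - a_g) * w_g
        beta = (1.0 - rho[t]) * w + (rho[t] / K) * w.sum(axis=1)[:, None]
        gamma = alpha[t] * beta
        g_g = gamma @ member
        gamma_sum += g_g
        if posterior is not None:
            posterior[:, t, :] = g_g
    chunks += gamma @ member  # entry at the first site

    group_sizes = member.sum(axis=0)
    return PaintingResult(
        groups=groups,
        chunk_counts=chunks,
        copy_fractions=gamma_sum / L,
        group_sizes=group_sizes,
        log_likelihood=np.log(scale).sum(axis=0),
        site_posterior=posterior,
    )


def viterbi_paint(recipients: np.ndarray, donors: HaplotypePanel,
                  params: PainterParams | None = None):
    """Best-path painting: per-recipient donor-state path and group chunk counts.

    Returns ``(paths, chunk_counts, groups)`` where ``paths`` is
    (n_recipients, n_sites) donor indices and chunk counts tally entries
    into each group along the single most probable path.
    """
    params = params or PainterParams()
    rec = np.atleast_2d(np.asarray(recipients, dtype=np.int8))
    K, L = donors.n_haplotypes, donors.n_sites
    groups = donors.group_names()
    gidx = np.array([groups.index(g) for g in donors.groups])
    rho = _switch_probs(donors.positions, params, donors.map_cm)
    with np.errstate(divide="ignore"):
        logE = np.log(_emissions(rec, donors.alleles, params.mut))
        log_stay = np.log(np.maximum((1.0 - rho) + rho / K, 1e-300))
        log_move = np.log(np.maximum(rho / K, 1e-300))
    R = rec.shape[0]
    paths = np.empty((R, L), dtype=np.int64)
    chunk_counts = np.zeros((R, len(groups)))
    for r in range(R):
        v = -np.log(K) + logE[r, 0]
        back = np.empty((L, K), dtype=np.int64)
        for t in range(1, L):
            stay = v + log_stay[t - 1]
            best = int(np.argmax(v))
            move = v[best] + log_move[t - 1]
            take_stay = stay >= move
            vt = np.where(take_stay, stay, move)
            back[t] = np.where(take_stay, np.arange(K), best)
            v = vt + logE[r, t]
        s = int(np.argmax(v))
        path = np.empty(L, dtype=np.int64)
        path[L - 1] = s
        for t in range(L - 1, 0, -1):
            s = back[t, s]
            path[t - 1] = s
        paths[r] = path
        gpath = gidx[path]
        chunk_counts[r, gpath[0]] += 1
        for t in range(1, L):
            if gpath[t] != gpath[t - 1]:
                chunk_counts[r, gpath[t]] += 1
    return paths, chunk_counts, groups
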