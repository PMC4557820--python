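"""Likelihood mapping: quartet ML under GTR+Gamma and simplex-region tallies.

Each sampled quartet of taxa is evaluated under its three unrooted
topologies; branch lengths are optimized numerically and the three
log-likelihoods are turned into posterior weights on the 2-simplex.  The
simplex is divided into seven regions — three corners (fully resolved
quartets), three edge regions (partly resolved) and a central star-like
region — and the tally of quartets per region summarizes the phylogenetic
signal of an alignment.  In cluster mode one taxon is drawn per cluster and
corner identities are fixed by the cluster pairings, so corner fractions
answer which grouping hypothesis the data support.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize

from .alignment import Alignment
from .gtr import GTRModel, LEAF_PARTIALS, discrete_gamma_rates

log = logging.getLogger(__name__)

REGIONS = ("T1", "T2", "T3", "E12", "E13", "E23", "C")

#: quartet topologies as leaf pairings: T1 = (0,1)|(2,3) etc.
TOPOLOGIES = (((0, 1), (2, 3)), ((0, 2), (1, 3)), ((0, 3), (1, 2)))


@dataclass
class QuartetMapConfig:
    model: GTRModel = field(default_factory=GTRModel)
    gamma_shape: Optional[float] = None  # None -> rate homogeneity
    n_categories: int = 4
    n_quartets: int | str = 10_000
    clusters: Optional[list[list[str]]] = None
    seed: int = 0
    exhaustive_limit: int = 50_000

    def __post_init__(self) -> None:
        if self.clusters is not None:
            if len(self.clusters) != 4 or any(not c for c in self.clusters):
                raise ValueError("need exactly 4 non-empty clusters")
            flat = [t for c in self.clusters for t in c]
            if len(set(flat)) != len(flat):
                raise ValueError("clusters must be disjoint")


@dataclass
class QuartetMapResult:
    counts: dict[str, int]
    total: int

    @property
    def fractions(self) -> dict[str, float]:
        return {k: v / self.total for k, v in self.counts.items()}

    @property
    def resolved_fraction(self) -> float:
        return sum(self.counts[k] for k in ("T1", "T2", "T3")) / self.total

    @property
    def star_fraction(self) -> float:
        return self.counts["C"] / self.total


def _pattern_partials(seqs: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    """Compress columns to unique site patterns.

    Returns (partials, counts): partials has shape (4 leaves, n_patterns, 4
    states); columns with no shared unambiguous information still enter (gap
    columns are uninformative but harmless).
    """
    L = len(seqs[0])
    patterns: dict[tuple[str, ...], int] = {}
    counts: list[int] = []
    for j in range(L):
        col = tuple(s[j] for s in seqs)
        if col in patterns:
            counts[patterns[col]] += 1
        else:
            patterns[col] = len(counts)
            counts.append(1)
    P = np.empty((4, len(counts), 4))
    for col, k in patterns.items():
        for leaf in range(4):
            P[leaf, k] = LEAF_PARTIALS[col[leaf]]
    return P, np.asarray(counts, dtype=float)


def _loglik(
    partials: np.ndarray,
    counts: np.ndarray,
    model: GTRModel,
    topology: int,
    branch_lengths: np.ndarray,
    rates: np.ndarray,
) -> float:
    """Pruning likelihood of one quartet topology.

    ``branch_lengths`` are the four terminal branches (in leaf order) plus
    the internal branch; rates are the discrete-gamma category rates.
    """
    (a, b), (c, d) = TOPOLOGIES[topology]
    pi = model.frequencies
    site = np.zeros(counts.size)
    for r in rates:
        Pa = model.transition_matrix(branch_lengths[0] * r)
        Pb = model.transition_matrix(branch_lengths[1] * r)
        Pc = model.transition_matrix(branch_lengths[2] * r)
        Pd = model.transition_matrix(branch_lengths[3] * r)
        Pe = model.transition_matrix(branch_lengths[4] * r)
        u = (partials[a] @ Pa.T) * (partials[b] @ Pb.T)
        v = (partials[c] @ Pc.T) * (partials[d] @ Pd.T)
        site += np.einsum("k,nk,kl,nl->n", pi, u, Pe, v)
    site /= rates.size
    if np.any(site <= 0):
        return -np.inf
    return float(np.dot(counts, np.log(site)))


_BL_FLOOR = 1e-8
_BL_CEIL = 20.0


def quartet_likelihoods(
    seqs: Sequence[str],
    model: GTRModel,
    gamma_shape: Optional[float] = None,
    n_categories: int = 4,
    tol: float = 1e-6,
    max_sweeps: int = 10,
) -> np.ndarray:
    """Maximized log-likelihoods of the three quartet topologies.

    Branch lengths (4 terminal + 1 internal) are optimized by coordinate
    descent with bounded Brent line searches.  Gaps and ambiguity codes are
    marginalized per site.
    """
    if len(seqs) != 4 or len({len(s) for s in seqs}) != 1:
        raise ValueError("need 4 equal-length sequences")
    partials, counts = _pattern_partials(seqs)
    informative = np.all(partials.sum(axis=2) < 4.0, axis=0)
    if not np.any(informative):
        raise ValueError("no column shared by all four sequences")
    rates = (
        discrete_gamma_rates(gamma_shape, n_categories)
        if gamma_shape is not None
        else np.array([1.0])
    )
    out = np.empty(3)
    for topo in range(3):
        bl = np.full(5, 0.1)
        best = _loglik(partials, counts, model, topo, bl, rates)
        for _ in range(max_sweeps):
            prev = best
            for k in range(5):
                def f(x: float, k=k) -> float:
                    trial = bl.copy()
                    trial[k] = x
                    return -_loglik(partials, counts, model, topo, trial, rates)

                res = optimize.minimize_scalar(
                    f, bounds=(_BL_FLOOR, _BL_CEIL), method="bounded",
                    options={"xatol": tol},
                )
                if -res.fun >= best:
                    bl[k] = float(res.x)
                    best = -res.fun
            if abs(best - prev) < tol:
                break
        out[topo] = best
    return out


def posterior_weights(lnls: Sequence[float]) -> np.ndarray:
    """Normalized likelihood weights of the three topologies."""
    l = np.asarray(lnls, dtype=float)
    w = np.exp(l - np.max(l))
    return w / w.sum()


#: attractors of the seven-region Voronoi geometry, in region order.
_ATTRACTORS = {
    "T1": np.array([1.0, 0.0, 0.0]),
    "T2": np.array([0.0, 1.0, 0.0]),
    "T3": np.array([0.0, 0.0, 1.0]),
    "E12": np.array([0.5, 0.5, 0.0]),
    "E13": np.array([0.5, 0.0, 0.5]),
    "E23": np.array([0.0, 0.5, 0.5]),
    "C": np.array([1 / 3, 1 / 3, 1 / 3]),
}


def simplex_region(weights: Sequence[float]) -> str:
    """Classify a weight vector into one of the seven mapping regions.

    Regions are the Voronoi cells of the seven canonical points of the
    simplex (corners, edge midpoints, centroid); boundary ties resolve to
    the lowest region id in the order T1..T3, E12..E23, C.
    """
    w = np.asarray(weights, dtype=float)
    if w.shape != (3,) or np.any(w < -1e-12) or abs(w.sum() - 1) > 1e-9:
        raise ValueError("not a simplex point")
    dists = {k: float(np.sum((w - v) ** 2)) for k, v in _ATTRACTORS.items()}
    best = min(dists.values())
    for k in REGIONS:
        if dists[k] <= best + 1e-12:
            return k
    raise AssertionError


def likelihood_mapping(aln: Alignment, config: QuartetMapConfig) -> QuartetMapResult:
    """Tally sampled (or exhaustive) quartets into the seven regions.

    Unconstrained mode samples quartets uniformly; cluster mode draws one
    taxon per cluster and labels the corners by cluster pairings, so T1 is
    the (c1,c2)|(c3,c4) grouping and so on.
    """
    if aln.n_taxa < 4:
        raise ValueError("need at least 4 taxa")
    rng = np.random.default_rng(config.seed)
    idx_of = {t: i for i, t in enumerate(aln.taxa)}
    if config.clusters is not None:
        for c in config.clusters:
            for t in c:
                if t not in idx_of:
                    raise ValueError(f"cluster taxon {t!r} not in alignment")
        cluster_idx = [[idx_of[t] for t in c] for c in config.clusters]
        all_combos = None
        n_possible = math.prod(len(c) for c in cluster_idx)
    else:
        cluster_idx = None
        n_possible = math.comb(aln.n_taxa, 4)
    exhaustive = (
        config.n_quartets == "all"
        or (isinstance(config.n_quartets, int) and n_possible <= min(config.n_quartets, config.exhaustive_limit))
    )
    if exhaustive and n_possible > config.exhaustive_limit:
        raise ValueError("too many quartets for exhaustive mode")
    quartets: list[tuple[int, int, int, int]]
    if cluster_idx is not None:
        if exhaustive:
            quartets = list(itertools.product(*cluster_idx))
        else:
            quartets = [
                tuple(int(rng.choice(c)) for c in cluster_idx)
                for _ in range(int(config.n_quartets))
            ]
    else:
        if exhaustive:
            quartets = list(itertools.combinations(range(aln.n_taxa), 4))
        else:
            quartets = [
                tuple(sorted(rng.choice(aln.n_taxa, size=4, replace=False)))
                for _ in range(int(config.n_quartets))
            ]
    counts = {k: 0 for k in REGIONS}
    failed = 0
    for q in quartets:
        seqs = [aln.rows[i] for i in q]
        try:
            lnls = quartet_likelihoods(
                seqs, config.model, config.gamma_shape, config.n_categories
            )
        except Exception as e:  # optimization failure: skip with log entry
            failed += 1
            log.warning("quartet %s failed: %s", q, e)
            continue
        counts[simplex_region(posterior_weights(lnls))] += 1
    if failed:
        log.warning("%d quartet(s) excluded after optimization failure", failed)
    total = sum(counts.values())
    if total == 0:
        raise RuntimeError("no quartet could be evaluated")
    return QuartetMapResult(counts, total)
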