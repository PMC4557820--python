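"""Bayesian relative-rates test and MCMC-trace model comparison.

The relative-rates test takes a posterior tree sample, recomputes per tree
the root-to-tip path length from a reference clade's MRCA to each terminal,
and flags terminals whose credible interval of path lengths does not overlap
the envelope of the remaining terminals' intervals — those are the
fast-evolving lineages pruned before long-branch-sensitive analyses.

Model comparison works on sampled log-likelihood traces: the (stabilized)
log harmonic mean of likelihoods and AICM, an AIC analogue whose penalty is
the trace's lnL variance:

    AICM = 2 * var(lnL) - 2 * mean(lnL)

(sample variance; a zero-variance trace at c gives -2c).  The AICM standard
deviation is estimated by a seeded bootstrap over trace samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy.special import logsumexp

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# relative rates
# ---------------------------------------------------------------------------

def pathlength_profiles(
    trees: Sequence[dendropy.Tree],
    clade: Sequence[str],
    terminals: Optional[Sequence[str]] = None,
) -> dict[str, np.ndarray]:
    """Per-terminal distribution of MRCA-to-tip path lengths over a sample.

    The clade's MRCA is recomputed per tree (the clade need not be
    monophyletic).  ``terminals`` defaults to the clade members.  Every
    requested tip must be present in every tree.
    """
    clade = list(clade)
    if len(clade) < 2:
        raise ValueError("clade must contain at least 2 taxa")
    terminals = list(terminals) if terminals is not None else clade
    depths: dict[str, list[float]] = {t: [] for t in terminals}
    for k, tree in enumerate(trees):
        # MRCA of the clade is taken on the tree as stored (seed node = root)
        tree.is_rooted = True
        by_label = {
            lf.taxon.label: lf for lf in tree.leaf_node_iter() if lf.taxon
        }
        missing = [t for t in set(clade) | set(terminals) if t not in by_label]
        if missing:
            raise ValueError(f"tree {k}: tip(s) absent: {sorted(missing)}")
        mrca = tree.mrca(taxa=[by_label[t].taxon for t in clade])
        for t in terminals:
            node = by_label[t]
            d = 0.0
            while node is not mrca:
                d += node.edge.length or 0.0
                node = node.parent_node
                if node is None:
                    raise ValueError(f"tip {t} not below the clade MRCA")
            depths[t].append(d)
    return {t: np.asarray(v) for t, v in depths.items()}


@dataclass
class RateProfile:
    taxon: str
    mean: float
    lo: float
    hi: float
    min: float
    max: float
    fast: bool


def relative_rates_test(
    profiles: dict[str, np.ndarray],
    mass: float = 0.95,
    pairwise: bool = False,
) -> list[RateProfile]:
    """Flag rate-outlier terminals from path-length distributions.

    Equal-tailed credible intervals at ``mass``.  Default rule: a terminal is
    fast-evolving iff its interval does not overlap the leave-one-out
    envelope [min of the others' lower bounds, max of the others' upper
    bounds].  ``pairwise`` instead requires no overlap with any single other
    terminal's interval.
    """
    if not 0 < mass < 1:
        raise ValueError("mass must be in (0, 1)")
    if len(profiles) < 2:
        raise ValueError("need at least 2 terminals")
    q_lo, q_hi = (1 - mass) / 2, 1 - (1 - mass) / 2
    stats = {}
    for t, d in profiles.items():
        stats[t] = (
            float(np.mean(d)),
            float(np.quantile(d, q_lo)),
            float(np.quantile(d, q_hi)),
            float(np.min(d)),
            float(np.max(d)),
        )
    out = []
    for t, (mean, lo, hi, dmin, dmax) in stats.items():
        others = [v for u, v in stats.items() if u != t]
        if pairwise:
            fast = all(hi < o[1] or lo > o[2] for o in others)
        else:
            env_lo = min(o[1] for o in others)
            env_hi = max(o[2] for o in others)
            fast = hi < env_lo or lo > env_hi
        out.append(RateProfile(t, mean, lo, hi, dmin, dmax, fast))
    return out


# ---------------------------------------------------------------------------
# traces
# ---------------------------------------------------------------------------

@dataclass
class TraceSeries:
    """Post-burn-in sampled log-likelihood values."""

    values: np.ndarray
    burnin: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("trace must be one-dimensional")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace contains non-finite values")

    @property
    def n(self) -> int:
        return self.values.size


def read_trace(
    path: str | Path,
    column: str = "LnL",
    burnin: float = 0.1,
) -> TraceSeries:
    """Read a sampled-lnL table (MrBayes .p dialect accepted: a bracketed
    first line is skipped; tab-separated with named columns).  The leading
    ``burnin`` fraction of rows is discarded."""
    lines = Path(path).read_text().splitlines()
    if lines and lines[0].lstrip().startswith("["):
        lines = lines[1:]
    from io import StringIO

    df = pd.read_csv(StringIO("\n".join(lines)), sep="\t")
    if column not in df.columns:
        raise ValueError(f"no column {column!r}; have {list(df.columns)}")
    vals = df[column].to_numpy(dtype=float)
    cut = int(round(burnin * len(vals)))
    return TraceSeries(vals[cut:], burnin)


def harmonic_mean_lnl(trace: TraceSeries) -> float:
    """Log of the harmonic mean of sampled likelihoods, in log space.

    log HM = -(logsumexp(-lnL) - log n); a constant trace at c returns c.
    """
    if trace.n < 1:
        raise ValueError("empty trace")
    x = trace.values
    return float(-(logsumexp(-x) - np.log(x.size)))


def aicm(
    trace: TraceSeries, boot_reps: int = 1000, seed: int = 0
) -> tuple[float, float]:
    """AICM = 2 var(lnL) - 2 mean(lnL), with a bootstrap SD (seeded)."""
    if trace.n < 2:
        raise ValueError("need at least 2 samples")
    x = trace.values

    def _aicm(v: np.ndarray) -> float:
        return float(2.0 * np.var(v, ddof=1) - 2.0 * np.mean(v))

    rng = np.random.default_rng(seed)
    boots = np.empty(boot_reps)
    for r in range(boot_reps):
        boots[r] = _aicm(rng.choice(x, size=x.size, replace=True))
    return _aicm(x), float(np.std(boots, ddof=1))


@dataclass
class ModelComparison:
    """Positive deltas favor the second model (B)."""

    hm_a: float
    hm_b: float
    delta_hm: float
    aicm_a: float
    aicm_sd_a: float
    aicm_b: float
    aicm_sd_b: float
    delta_aicm: float


def compare_partition_models(
    trace_a: TraceSeries,
    trace_b: TraceSeries,
    boot_reps: int = 1000,
    seed: int = 0,
) -> ModelComparison:
    """Harmonic-mean and AICM comparison of two analyses' lnL traces.

    delta_hm = hm_b - hm_a (positive: B fits better); delta_aicm =
    aicm_a - aicm_b (positive: B preferred, lower AICM is better).
    """
    hm_a = harmonic_mean_lnl(trace_a)
    hm_b = harmonic_mean_lnl(trace_b)
    a_a, sd_a = aicm(trace_a, boot_reps, seed)
    a_b, sd_b = aicm(trace_b, boot_reps, seed + 1)
    return ModelComparison(
        hm_a, hm_b, hm_b - hm_a, a_a, sd_a, a_b, sd_b, a_a - a_b
    )
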