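"""Entropy-based index of substitution saturation (Iss) and its test.

A saturated alignment has lost most historical signal: site states approach
independent draws from the base composition, and per-site entropy approaches
its full-saturation expectation.  Iss is the ratio of mean observed site
entropy to that expectation; it is compared against simulation-derived
critical values (Iss.c) for a symmetric or asymmetric four-group topology —
an Iss well below both critical values means phylogenetic analysis is not
yet expected to fail from saturation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .alignment import Alignment, BASES

log = logging.getLogger(__name__)


def site_entropy(aln: Alignment) -> np.ndarray:
    """Per-column Shannon entropy in bits over observed A,C,G,T states.

    Gaps and ambiguity codes are excluded per column; columns with no
    unambiguous residue are excluded (NaN) with a warning.
    """
    H = np.full(aln.n_columns, np.nan)
    dropped = 0
    for j, col in enumerate(aln.columns()):
        counts = np.array([col.count(b) for b in BASES], dtype=float)
        n = counts.sum()
        if n == 0:
            dropped += 1
            continue
        p = counts[counts > 0] / n
        H[j] = -np.sum(p * np.log2(p))
    if dropped:
        log.warning("%d column(s) with no unambiguous residue excluded", dropped)
    return H


def _global_frequencies(aln: Alignment) -> np.ndarray:
    counts = np.zeros(4)
    for row in aln.rows:
        for k, b in enumerate(BASES):
            counts[k] += row.count(b)
    if counts.sum() == 0:
        raise ValueError("alignment contains no unambiguous residues")
    return counts / counts.sum()


def full_saturation_entropy(
    freqs: np.ndarray, n_otu: int, reps: int = 10_000, seed: int = 0
) -> float:
    """Monte-Carlo expectation of site entropy at full saturation.

    Draw ``reps`` columns of ``n_otu`` states i.i.d. from ``freqs`` and
    average their entropies.  This finite-sample expectation is below
    -sum(p log2 p) for small taxon counts and converges to it as n grows.
    """
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_otu, freqs, size=reps).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = counts / n_otu
        terms = np.where(counts > 0, p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
    return float(-terms.sum(axis=1).mean())


def iss(aln: Alignment, reps: int = 10_000, seed: int = 0) -> float:
    """Index of substitution saturation: mean site entropy over its
    full-saturation expectation.  0 for identical sequences; approaches 1 as
    sites randomize.  Ambiguous positions are excluded."""
    if aln.n_taxa < 4:
        raise ValueError("need at least 4 taxa")
    H = site_entropy(aln)
    Hobs = float(np.nanmean(H)) if np.any(~np.isnan(H)) else 0.0
    if Hobs == 0.0:
        return 0.0
    Hfss = full_saturation_entropy(_global_frequencies(aln), aln.n_taxa, reps, seed)
    return Hobs / Hfss


# ---------------------------------------------------------------------------
# critical-value simulation
# ---------------------------------------------------------------------------

def _evolve_jc(rng: np.random.Generator, parent: np.ndarray, t: float) -> np.ndarray:
    """Jukes-Cantor evolution of a state vector over branch length t."""
    p_change = 0.75 * (1.0 - np.exp(-4.0 * t / 3.0))
    flip = rng.random(parent.size) < p_change
    out = parent.copy()
    out[flip] = (parent[flip] + rng.integers(1, 4, flip.sum())) % 4
    return out


def _states_to_alignment(states: np.ndarray) -> Alignment:
    rows = ["".join(BASES[s] for s in row) for row in states]
    return Alignment([f"t{i}" for i in range(len(rows))], rows)


def _four_group_recovery(
    rng: np.random.Generator, n_otu: int, aln_len: int, depth: float, shape: str
) -> tuple[float, bool]:
    """Simulate one alignment on a four-group topology at the given depth.

    Returns (Iss of the alignment, whether mean JC distances between groups
    satisfy the four-point condition for the true topology).  ``sym`` is a
    balanced quartet of clades; ``asym`` a ladder.
    """
    m = max(1, n_otu // 4)
    root = rng.integers(0, 4, aln_len)
    if shape == "sym":
        # ((G0,G1),(G2,G3)) with all stem branches = depth, internal = depth
        u = _evolve_jc(rng, root, depth)
        v = _evolve_jc(rng, root, depth)
        anc = [_evolve_jc(rng, u, depth), _evolve_jc(rng, u, depth),
               _evolve_jc(rng, v, depth), _evolve_jc(rng, v, depth)]
    elif shape == "asym":
        # ladder (G0,(G1,(G2,G3)))
        a1 = _evolve_jc(rng, root, depth)
        a2 = _evolve_jc(rng, a1, depth)
        anc = [_evolve_jc(rng, root, depth), _evolve_jc(rng, a1, depth),
               _evolve_jc(rng, a2, depth), _evolve_jc(rng, a2, depth)]
    else:
        raise ValueError("shape must be 'sym' or 'asym'")
    groups = [
        [_evolve_jc(rng, anc[g], depth * 0.5) for _ in range(m)] for g in range(4)
    ]
    states = np.array([s for g in groups for s in g])
    aln = _states_to_alignment(states)

    def jc_dist(a: np.ndarray, b: np.ndarray) -> float:
        p = float(np.mean(a != b))
        p = min(p, 0.74)
        return -0.75 * np.log(1.0 - 4.0 * p / 3.0)

    # mean inter-group distances; true topology groups (0,1)|(2,3)
    centro = [np.array([states[g * m + i] for i in range(m)]) for g in range(4)]
    D = np.zeros((4, 4))
    for a in range(4):
        for b in range(a + 1, 4):
            d = np.mean(
                [jc_dist(x, y) for x in centro[a] for y in centro[b]]
            )
            D[a, b] = D[b, a] = d
    s_true = D[0, 1] + D[2, 3]
    s_alt1 = D[0, 2] + D[1, 3]
    s_alt2 = D[0, 3] + D[1, 2]
    recovered = s_true < s_alt1 and s_true < s_alt2
    val = iss(aln, reps=2_000, seed=int(rng.integers(2**31)))
    return val, recovered


def iss_critical(
    n_otu: int,
    aln_len: int,
    shape: str = "sym",
    reps: int = 50,
    seed: int = 0,
    recovery_threshold: float = 0.95,
    depths: Optional[np.ndarray] = None,
) -> float:
    """Simulation estimate of the critical saturation index Iss.c.

    Evolve alignments on the four-group topology over a ladder of divergence
    depths, record mean Iss and topology-recovery probability (four-point
    condition on mean JC distances) at each depth, and interpolate the Iss at
    which recovery drops to ``recovery_threshold``.  Seeded and reproducible.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    if depths is None:
        depths = np.geomspace(0.01, 4.0, 12)
    mean_iss = []
    recov = []
    for d in depths:
        vals, hits = [], 0
        for _ in range(reps):
            v, ok = _four_group_recovery(rng, n_otu, aln_len, float(d), shape)
            vals.append(v)
            hits += ok
        mean_iss.append(float(np.mean(vals)))
        recov.append(hits / reps)
    mean_iss = np.array(mean_iss)
    recov = np.array(recov)
    # enforce monotone-decreasing recovery vs depth before interpolating
    recov_mono = np.minimum.accumulate(recov)
    below = np.where(recov_mono < recovery_threshold)[0]
    if below.size == 0:
        raise RuntimeError(
            "recovery never dropped below threshold; extend the depth ladder "
            "or increase reps"
        )
    k = below[0]
    if k == 0:
        return float(mean_iss[0])
    r0, r1 = recov_mono[k - 1], recov_mono[k]
    w = 0.0 if r0 == r1 else (r0 - recovery_threshold) / (r0 - r1)
    return float(mean_iss[k - 1] + w * (mean_iss[k] - mean_iss[k - 1]))


@dataclass
class SaturationResult:
    iss: float
    iss_c_sym: Optional[float]
    iss_c_asym: Optional[float]
    t_sym: Optional[float]
    p_sym: Optional[float]
    t_asym: Optional[float]
    p_asym: Optional[float]
    n_otu: int
    aln_len: int
    saturated: Optional[bool]


def saturation_test(
    aln: Alignment,
    iss_c_sym: Optional[float] = None,
    iss_c_asym: Optional[float] = None,
    simulate_critical: bool = False,
    reps: int = 50,
    seed: int = 0,
) -> SaturationResult:
    """Iss with two-sided t-tests against the sym/asym critical values.

    Critical values may be supplied (e.g. from an external table) or
    simulated.  The standard error of Iss uses the among-site variance of
    site entropy.  Verdict ``saturated`` is True when Iss is not
    significantly below either critical value.
    """
    val = iss(aln, seed=seed)
    H = site_entropy(aln)
    H = H[~np.isnan(H)]
    n = H.size
    if simulate_critical:
        iss_c_sym = iss_critical(aln.n_taxa, aln.n_columns, "sym", reps, seed)
        iss_c_asym = iss_critical(aln.n_taxa, aln.n_columns, "asym", reps, seed + 1)
    if val == 0.0 or n < 2:
        se = 0.0
    else:
        Hfss = full_saturation_entropy(
            _global_frequencies(aln), aln.n_taxa, seed=seed
        )
        se = float(np.std(H, ddof=1) / (Hfss * np.sqrt(n)))

    def _test(crit: Optional[float]):
        if crit is None:
            return None, None
        if se == 0.0:
            return float("inf"), 0.0
        t = (val - crit) / se
        p = float(2.0 * stats.t.sf(abs(t), df=n - 1))
        return float(t), p

    t_s, p_s = _test(iss_c_sym)
    t_a, p_a = _test(iss_c_asym)
    verdict: Optional[bool] = None
    if iss_c_sym is not None and iss_c_asym is not None:
        below_both = val < iss_c_sym and val < iss_c_asym
        significant = (p_s is None or p_s < 0.05) and (p_a is None or p_a < 0.05)
        verdict = not (below_both and significant)
    return SaturationResult(
        val, iss_c_sym, iss_c_asym, t_s, p_s, t_a, p_a, aln.n_taxa, aln.n_columns, verdict
    )
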