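"""Per-taxon nucleotide composition diagnostics.

Covers the standard pre-inference data exploration for rDNA partitions:
base composition per taxon (loops in these genes are typically adenine rich),
the tetrahedral simplex embedding used for compositional plots, the
GC-content vs sequence-length rank correlation, and a chi-squared test of
compositional stationarity (each taxon against the pooled composition).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .alignment import Alignment, BASES

log = logging.getLogger(__name__)


@dataclass
class CompositionProfile:
    """Ungapped base counts per taxon for one partition."""

    taxa: list[str]
    counts: np.ndarray  # (n_taxa, 4) counts of A,C,G,T
    lengths: np.ndarray  # ungapped length incl. ambiguity positions

    @property
    def frequencies(self) -> np.ndarray:
        tot = self.counts.sum(axis=1, keepdims=True).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(tot > 0, self.counts / tot, np.nan)

    @property
    def gc(self) -> np.ndarray:
        tot = self.counts.sum(axis=1).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(tot > 0, (self.counts[:, 1] + self.counts[:, 2]) / tot, np.nan)


def base_composition(aln: Alignment) -> CompositionProfile:
    """Count A,C,G,T per taxon over ungapped positions.

    Ambiguity codes contribute to the ungapped length but not to the base
    counts.  An all-gap row yields a zero-length profile (warned).
    """
    if aln.n_taxa == 0:
        raise ValueError("empty alignment")
    counts = np.zeros((aln.n_taxa, 4), dtype=int)
    lengths = np.zeros(aln.n_taxa, dtype=int)
    for i, row in enumerate(aln.rows):
        for c in row:
            if c == "-":
                continue
            lengths[i] += 1
            k = BASES.find(c)
            if k >= 0:
                counts[i, k] += 1
        if lengths[i] == 0:
            log.warning("taxon %s is all-gap in this partition", aln.taxa[i])
    return CompositionProfile(list(aln.taxa), counts, lengths)


#: Regular tetrahedron vertices (centered at origin) for A, C, G, T.
_TETRA_VERTICES = np.array(
    [[1.0, 1.0, 1.0], [1.0, -1.0, -1.0], [-1.0, 1.0, -1.0], [-1.0, -1.0, 1.0]]
) / np.sqrt(3.0)


def tetrahedral_coords(freqs: np.ndarray) -> np.ndarray:
    """Affine embedding of a base-frequency vector into 3-space.

    The four unit compositions map to the vertices of a regular tetrahedron
    centered at the origin; the uniform composition maps to the origin.  The
    map is affine, so convex combinations of compositions map to the same
    convex combinations of their images.
    """
    f = np.asarray(freqs, dtype=float)
    if f.shape[-1] != 4:
        raise ValueError("expected 4 base frequencies")
    if np.any(f < 0):
        raise ValueError("negative frequency")
    if np.any(np.abs(f.sum(axis=-1) - 1.0) > 1e-9):
        raise ValueError("frequencies must sum to 1")
    return f @ _TETRA_VERTICES


def gc_length_correlation(profile: CompositionProfile) -> tuple[float, float]:
    """Spearman rank correlation of GC content against ungapped length.

    Returns (rho, two-sided p).  Constant input yields (nan, nan) with a
    warning rather than an error.
    """
    gc = profile.gc
    lengths = profile.lengths.astype(float)
    ok = ~np.isnan(gc) & (lengths > 0)
    if ok.sum() < 3:
        raise ValueError("need at least 3 taxa with positive length")
    if np.all(gc[ok] == gc[ok][0]) or np.all(lengths[ok] == lengths[ok][0]):
        log.warning("constant GC or length vector: rho undefined")
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(gc[ok], lengths[ok])
    return float(rho), float(p)


@dataclass
class StationarityResult:
    taxa: list[str]
    chi2: np.ndarray
    p_values: np.ndarray
    deviates: np.ndarray  # bool flags at the 5 % level
    n_deviating: int
    alpha: float = 0.05


def stationarity_chisq(
    profile: CompositionProfile,
    alpha: float = 0.05,
    leave_one_out: bool = False,
    pseudocount: float = 0.0,
) -> StationarityResult:
    """Chi-squared test of each taxon's composition against the average.

    Expected counts for taxon t are its ungapped base total times the pooled
    base frequencies over all taxa (or all *other* taxa with
    ``leave_one_out``).  df = 3; a taxon deviates when p < ``alpha``.  A base
    present in some taxon but absent from the pool makes the expectation
    zero — pass ``pseudocount`` (e.g. 0.5 per pooled cell) in that case.
    """
    if profile.counts.shape[0] < 2:
        raise ValueError("need at least 2 taxa")
    counts = profile.counts.astype(float)
    total = counts.sum(axis=0)
    chi2 = np.zeros(len(profile.taxa))
    for i in range(len(profile.taxa)):
        pool = (total - counts[i]) if leave_one_out else total
        pool = pool + pseudocount
        if pool.sum() == 0:
            raise ValueError("empty pooled composition")
        expected_freq = pool / pool.sum()
        obs = counts[i]
        exp = obs.sum() * expected_freq
        bad = (exp == 0) & (obs > 0)
        if np.any(bad):
            raise ValueError(
                "zero expected count for an observed base; "
                "use a pseudocount (e.g. pseudocount=0.5)"
            )
        nz = exp > 0
        chi2[i] = np.sum((obs[nz] - exp[nz]) ** 2 / exp[nz])
    p = stats.chi2.sf(chi2, df=3)
    flags = p < alpha
    return StationarityResult(
        list(profile.taxa), chi2, p, flags, int(flags.sum()), alpha
    )
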