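"""Rescue of regions of ambiguous alignment (RAAs).

Ambiguously aligned rDNA regions are cut out of the structure-consensus
matrix, realigned independently per block with a progressive affine-gap
aligner following a guide tree (gap opening four times the equally weighted
gap extension and substitution costs), concatenated, and filtered by a
Monte-Carlo random-similarity mask: sliding-window pairwise scores are
compared against a null distribution from composition-preserving shuffles,
and only columns whose consensus profile is positive are retained.

Cost convention: a gap of length k costs ``gap_open + k * gap_extend``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import dendropy
import numpy as np

from .alignment import GAP, Alignment
from .structure import ColumnClass, StructuredAlignment

log = logging.getLogger(__name__)


@dataclass
class AlignmentCosts:
    """Affine alignment cost regime (all costs non-negative)."""

    gap_open: float = 4.0
    gap_extend: float = 1.0
    substitution: float = 1.0

    def __post_init__(self) -> None:
        if min(self.gap_open, self.gap_extend, self.substitution) < 0:
            raise ValueError("costs must be non-negative")
        if self.gap_open < self.gap_extend:
            raise ValueError("gap_open must be >= gap_extend")


@dataclass
class RaaBlock:
    """One ambiguous region: ungapped per-taxon subsequences plus the master
    span they came from."""

    block_id: str
    span: tuple[int, int]
    sequences: dict[str, str]  # taxon -> ungapped subsequence (may be empty)

    def __post_init__(self) -> None:
        for t, s in self.sequences.items():
            if GAP in s:
                raise ValueError(f"block {self.block_id}: taxon {t} subsequence has gaps")


@dataclass
class AlignedBlock:
    block_id: str
    alignment: Alignment
    cost: float
    guide_costs: list[float] = field(default_factory=list)


def extract_raa_blocks(saln: StructuredAlignment) -> list[RaaBlock]:
    """One block per annotated RAA span; each taxon contributes its non-gap
    characters within the span (possibly the empty string)."""
    blocks = []
    for span in saln.raa_spans:
        seqs = {
            t: row[span.start : span.end].replace(GAP, "")
            for t, row in zip(saln.taxa, saln.alignment.rows)
        }
        blocks.append(RaaBlock(span.block_id, (span.start, span.end), seqs))
    log.info("extracted %d RAA block(s)", len(blocks))
    return blocks


# ---------------------------------------------------------------------------
# progressive affine-gap alignment
# ---------------------------------------------------------------------------

def _column_cost(col_a: str, col_b: str, costs: AlignmentCosts) -> float:
    """Mean pairwise cost of stacking two profile columns."""
    tot = 0.0
    n = 0
    for x in col_a:
        for y in col_b:
            n += 1
            if x == GAP or y == GAP:
                if not (x == GAP and y == GAP):
                    tot += costs.gap_extend
            elif x != y:
                tot += costs.substitution
    return tot / n if n else 0.0


def _gotoh(prof_a: list[str], prof_b: list[str], costs: AlignmentCosts) -> list[str]:
    """Align two profiles; returns the merged profile (rows of A then B)."""
    n = len(prof_a[0])
    m = len(prof_b[0])
    cols_a = ["".join(r[i] for r in prof_a) for i in range(n)]
    cols_b = ["".join(r[j] for r in prof_b) for j in range(m)]
    INF = float("inf")
    go, ge = costs.gap_open, costs.gap_extend
    M = np.full((n + 1, m + 1), INF)
    X = np.full((n + 1, m + 1), INF)  # gap in A, consume B
    Y = np.full((n + 1, m + 1), INF)  # gap in B, consume A
    M[0, 0] = 0.0
    for j in range(1, m + 1):
        X[0, j] = go + ge * j
    for i in range(1, n + 1):
        Y[i, 0] = go + ge * i
    sub = np.empty((n, m))
    for i in range(n):
        for j in range(m):
            sub[i, j] = _column_cost(cols_a[i], cols_b[j], costs)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            M[i, j] = sub[i - 1, j - 1] + min(
                M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]
            )
            X[i, j] = min(
                M[i, j - 1] + go + ge, X[i, j - 1] + ge, Y[i, j - 1] + go + ge
            )
            Y[i, j] = min(
                M[i - 1, j] + go + ge, Y[i - 1, j] + ge, X[i - 1, j] + go + ge
            )
    i, j = n, m
    order = ("M", "X", "Y")
    mats = {"M": M, "X": X, "Y": Y}
    state = min(order, key=lambda s: (mats[s][i, j], order.index(s)))
    steps: list[str] = []
    eps = 1e-9
    while i > 0 or j > 0:
        steps.append(state)
        if state == "M":
            prev = M[i, j] - sub[i - 1, j - 1]
            i, j = i - 1, j - 1
            for s in order:
                if abs(mats[s][i, j] - prev) < eps:
                    state = s
                    break
        elif state == "X":
            val = X[i, j]
            j -= 1
            if j == 0 and i == 0:
                break
            if abs(X[i, j] + ge - val) < eps and j > 0:
                state = "X"
            elif abs(M[i, j] + go + ge - val) < eps:
                state = "M"
            elif abs(Y[i, j] + go + ge - val) < eps:
                state = "Y"
            else:
                state = "X"
        else:  # Y
            val = Y[i, j]
            i -= 1
            if i == 0 and j == 0:
                break
            if abs(Y[i, j] + ge - val) < eps and i > 0:
                state = "Y"
            elif abs(M[i, j] + go + ge - val) < eps:
                state = "M"
            elif abs(X[i, j] + go + ge - val) < eps:
                state = "X"
            else:
                state = "Y"
    steps.reverse()
    rows_a = ["" for _ in prof_a]
    rows_b = ["" for _ in prof_b]
    ia = ib = 0
    for s in steps:
        if s == "M":
            for k, r in enumerate(prof_a):
                rows_a[k] += r[ia]
            for k, r in enumerate(prof_b):
                rows_b[k] += r[ib]
            ia += 1
            ib += 1
        elif s == "X":
            for k in range(len(prof_a)):
                rows_a[k] += GAP
            for k, r in enumerate(prof_b):
                rows_b[k] += r[ib]
            ib += 1
        else:
            for k, r in enumerate(prof_a):
                rows_a[k] += r[ia]
            for k in range(len(prof_b)):
                rows_b[k] += GAP
            ia += 1
    assert ia == n and ib == m, "backtrace did not consume both profiles"
    return rows_a + rows_b


def pairwise_align_cost(a: str, b: str, costs: AlignmentCosts) -> float:
    """Optimal affine-gap cost of aligning two sequences (no traceback)."""
    merged = _gotoh([a], [b], costs)
    return alignment_cost(merged, costs)


def alignment_cost(rows: Sequence[str], costs: AlignmentCosts) -> float:
    """Sum-of-pairs cost of a finished alignment under the affine regime.

    Per pair: columns where both are gaps are skipped; mismatches cost
    ``substitution``; each maximal run of k residue-vs-gap columns costs
    ``gap_open + k * gap_extend``.
    """
    total = 0.0
    nrows = len(rows)
    for i in range(nrows):
        for j in range(i + 1, nrows):
            a, b = rows[i], rows[j]
            in_gap = False
            for x, y in zip(a, b):
                if x == GAP and y == GAP:
                    continue
                if x == GAP or y == GAP:
                    if not in_gap:
                        total += costs.gap_open
                        in_gap = True
                    total += costs.gap_extend
                else:
                    in_gap = False
                    if x != y:
                        total += costs.substitution
    return total


def _merge_order(guide: dendropy.Tree, taxa: set[str]) -> list:
    """Postorder merge plan over the guide tree restricted to ``taxa``.

    Returns a nested-tuple topology whose leaves are taxon labels.
    """
    def build(node):
        if node.is_leaf():
            lbl = node.taxon.label if node.taxon else None
            return lbl if lbl in taxa else None
        parts = [build(c) for c in node.child_nodes()]
        parts = [p for p in parts if p is not None]
        if not parts:
            return None
        plan = parts[0]
        for p in parts[1:]:
            plan = (plan, p)
        return plan

    plan = build(guide.seed_node)
    if plan is None:
        raise ValueError("guide tree shares no taxa with the block")
    return plan


def align_block(
    block: RaaBlock,
    guide: dendropy.Tree,
    costs: Optional[AlignmentCosts] = None,
    master_taxa: Optional[list[str]] = None,
) -> AlignedBlock:
    """Progressively align one RAA block following a guide tree.

    Profiles are merged in the guide tree's postorder; each merge is an exact
    affine-gap profile alignment with columns scored by mean pairwise cost.
    Taxa with empty subsequences are excluded from the alignment and appended
    afterwards as all-gap rows.  Reported cost is the sum-of-pairs cost of
    the final alignment.
    """
    costs = costs or AlignmentCosts()
    present = {t for t, s in block.sequences.items() if s}
    guide_labels = {lf.taxon.label for lf in guide.leaf_node_iter() if lf.taxon}
    missing = present - guide_labels
    if missing:
        raise ValueError(f"taxa missing from guide tree: {sorted(missing)}")
    order = master_taxa if master_taxa is not None else sorted(block.sequences)
    if not present:
        return AlignedBlock(block.block_id, Alignment(list(order), ["" for _ in order]), 0.0)

    def run(plan) -> tuple[list[str], list[str]]:
        if isinstance(plan, str):
            return [plan], [block.sequences[plan]]
        (left, right) = plan
        ta, pa = run(left)
        tb, pb = run(right)
        if not pa[0] and not pb[0]:
            return ta + tb, pa + pb
        if not pa[0]:
            # zero-length profile: all-gap rows at the other profile's width
            return ta + tb, [GAP * len(pb[0]) for _ in ta] + pb
        if not pb[0]:
            return ta + tb, pa + [GAP * len(pa[0]) for _ in tb]
        merged = _gotoh(pa, pb, costs)
        return ta + tb, merged

    plan = _merge_order(guide, present)
    taxa_done, rows_done = run(plan)
    width = len(rows_done[0]) if rows_done else 0
    by_taxon = dict(zip(taxa_done, rows_done))
    taxa_out = [t for t in order]
    rows_out = [by_taxon.get(t, GAP * width) for t in taxa_out]
    cost = alignment_cost([by_taxon[t] for t in taxa_done], costs)
    return AlignedBlock(block.block_id, Alignment(taxa_out, rows_out), cost)


def align_block_multi(
    block: RaaBlock,
    guides: Sequence[dendropy.Tree],
    costs: Optional[AlignmentCosts] = None,
    master_taxa: Optional[list[str]] = None,
) -> AlignedBlock:
    """Align under every guide tree; keep the minimum-total-cost alignment
    (ties broken by input order).  All candidate costs are recorded in
    ``guide_costs``."""
    if not guides:
        raise ValueError("need at least one guide tree")
    best: Optional[AlignedBlock] = None
    all_costs = []
    for g in guides:
        cand = align_block(block, g, costs, master_taxa)
        all_costs.append(cand.cost)
        if best is None or cand.cost < best.cost:
            best = cand
    assert best is not None
    best.guide_costs = all_costs
    return best


@dataclass
class ConcatenatedBlocks:
    alignment: Alignment
    provenance: list[tuple[str, int]]  # per column: (block id, offset)


def concatenate_blocks(blocks: Sequence[AlignedBlock]) -> ConcatenatedBlocks:
    """Concatenate aligned blocks column-wise over a shared taxon list.

    Taxa absent from a block are padded with gaps.  Provenance maps each
    output column to (block id, column offset within the block).
    """
    ids = [b.block_id for b in blocks]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate block id")
    taxa: list[str] = []
    for b in blocks:
        for t in b.alignment.taxa:
            if t not in taxa:
                taxa.append(t)
    rows = {t: [] for t in taxa}
    prov: list[tuple[str, int]] = []
    for b in blocks:
        width = b.alignment.n_columns
        for t in taxa:
            if t in b.alignment.taxa:
                rows[t].append(b.alignment.row(t))
            else:
                rows[t].append(GAP * width)
        prov.extend((b.block_id, k) for k in range(width))
    aln = Alignment(taxa, ["".join(rows[t]) for t in taxa])
    return ConcatenatedBlocks(aln, prov)


# ---------------------------------------------------------------------------
# random-similarity masking
# ---------------------------------------------------------------------------

@dataclass
class MaskProfile:
    consensus: np.ndarray  # per-column mean pair profile in [-1, 1]
    keep: np.ndarray  # bool; keep <=> consensus > 0
    window: int
    reps: int
    quantile: float
    seed: int


def _pair_scores(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Per-column scores for one taxon pair: +1 match, -1 mismatch or any gap."""
    gap = (a == GAP) | (b == GAP)
    return np.where(~gap & (a == b), 1.0, -1.0)


def _window_sums(scores: np.ndarray, w: int) -> np.ndarray:
    c = np.concatenate([[0.0], np.cumsum(scores)])
    return c[w:] - c[:-w]


def random_similarity_mask(
    aln: Alignment,
    window: int = 7,
    reps: int = 500,
    quantile: float = 0.95,
    seed: int = 0,
) -> MaskProfile:
    """Monte-Carlo sliding-window mask for random similarity.

    For every taxon pair, window scores (+1 match, -1 mismatch or gap) are
    compared against a null distribution obtained by shuffling both rows
    (composition preserved).  A window is non-random when its observed score
    exceeds the null's ``quantile``; a site's pair profile is +1 when the
    majority of windows covering it are non-random.  The consensus profile is
    the mean over pairs; columns with positive consensus are kept.
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    if reps < 100:
        raise ValueError("reps must be >= 100")
    if aln.n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    L = aln.n_columns
    w = min(window, L)
    rng = np.random.default_rng(seed)
    arr = aln.to_array()
    n = aln.n_taxa
    pair_profiles = []
    for i in range(n):
        for j in range(i + 1, n):
            a, b = arr[i], arr[j]
            obs = _window_sums(_pair_scores(a, b), w)
            null = np.empty((reps, obs.size))
            for r in range(reps):
                pa = rng.permutation(a)
                pb = rng.permutation(b)
                null[r] = _window_sums(_pair_scores(pa, pb), w)
            thresh = np.quantile(null.ravel(), quantile)
            nonrandom = obs > thresh
            # majority vote of covering windows per site
            cover = np.zeros(L)
            hits = np.zeros(L)
            for k in range(obs.size):
                cover[k : k + w] += 1
                if nonrandom[k]:
                    hits[k : k + w] += 1
            profile = np.where(hits * 2 > cover, 1.0, -1.0)
            pair_profiles.append(profile)
    consensus = np.mean(pair_profiles, axis=0)
    return MaskProfile(consensus, consensus > 0, w, reps, quantile, seed)


def apply_mask(aln: Alignment, profile: MaskProfile) -> Alignment:
    """Retain exactly the keep-flagged columns, order preserved."""
    if profile.keep.size != aln.n_columns:
        raise ValueError("mask length does not match alignment")
    idx = [j for j in range(aln.n_columns) if profile.keep[j]]
    if not idx:
        log.warning("mask drops every column")
    return aln.take_columns(idx)


def raa_pipeline(
    saln: StructuredAlignment,
    guides: Sequence[dendropy.Tree],
    costs: Optional[AlignmentCosts] = None,
    window: int = 7,
    reps: int = 500,
    quantile: float = 0.95,
    seed: int = 0,
) -> tuple[ConcatenatedBlocks, MaskProfile, Alignment]:
    """Full RAA rescue: extract -> per-block multi-guide alignment ->
    concatenation -> random-similarity mask -> filtered alignment."""
    blocks = extract_raa_blocks(saln)
    aligned = [
        align_block_multi(b, guides, costs, master_taxa=saln.taxa) for b in blocks
    ]
    concat = concatenate_blocks(aligned)
    profile = random_similarity_mask(concat.alignment, window, reps, quantile, seed)
    return concat, profile, apply_mask(concat.alignment, profile)
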