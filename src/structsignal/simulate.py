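"""Synthetic data with known ground truth for every pipeline stage.

The generator emulates the salient features of structure-annotated rDNA
matrices: helix (stem) columns evolved as complementary doublets maintained
by compensatory substitutions, adenine-rich loop columns under GTR+Gamma,
indel-rich length-variable RAA blocks, per-lineage substitution-rate
multipliers, posterior-like tree samples with branch-length jitter, and
bootstrap-like tree sets with controlled frequencies of conflicting
bipartitions.  Every generator is deterministic under a fixed seed and
returns a truth record sufficient to recompute the planted quantities.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Optional, Sequence

import dendropy
import numpy as np

from .alignment import BASES, GAP, Alignment
from .bayesrates import TraceSeries
from .gtr import GTRModel, discrete_gamma_rates
from .structure import RaaSpan, StructuredAlignment

#: Watson-Crick partner used for stem doublets.
COMPLEMENT = {0: 3, 3: 0, 1: 2, 2: 1}


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic rDNA generator.

    Defaults mirror the kind of matrix the pipeline targets, at desk scale:
    A-rich loops (pi_A = 0.4), stem doublets with compensation probability
    q = 0.9, and a handful of indel-rich RAA blocks that carry most of the
    length variation.
    """

    n_taxa: int = 32
    birth_rate: float = 1.0
    death_rate: float = 0.0
    tree_depth: float = 0.5  # mean root-to-tip path, substitutions/site
    # stems
    n_stem_pairs: int = 60
    stem_frequencies: tuple[float, ...] = (0.2, 0.3, 0.3, 0.2)
    compensation_q: float = 0.9
    # loops
    n_loop_columns: int = 120
    loop_frequencies: tuple[float, ...] = (0.4, 0.2, 0.2, 0.2)
    gamma_shape: float = 0.5
    # RAAs
    n_raa_blocks: int = 3
    raa_base_length: int = 30
    indel_rate: float = 0.5  # events per unit branch length per block
    indel_length_p: float = 0.4  # geometric length parameter
    deletion_multipliers: dict[str, float] = field(default_factory=dict)
    raa_freq_overrides: dict[str, tuple[float, ...]] = field(default_factory=dict)
    # lineage rates
    rate_multipliers: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        for f in (self.stem_frequencies, self.loop_frequencies):
            arr = np.asarray(f)
            if arr.shape != (4,) or np.any(arr < 0) or abs(arr.sum() - 1) > 1e-9:
                raise ValueError("frequencies must be a 4-simplex point")
        if not 0 <= self.compensation_q <= 1:
            raise ValueError("compensation probability must be in [0, 1]")
        if min(self.indel_rate, self.birth_rate) < 0 or self.death_rate < 0:
            raise ValueError("rates must be non-negative")
        if any(m <= 0 for m in self.rate_multipliers.values()):
            raise ValueError("rate multipliers must be positive")


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

def simulate_tree(
    n_taxa: int,
    birth_rate: float = 1.0,
    death_rate: float = 0.0,
    seed: int = 0,
    rate_multipliers: Optional[dict[str, float]] = None,
    scale_depth: Optional[float] = None,
    max_attempts: int = 100,
) -> dendropy.Tree:
    """Seeded birth-death tree with ``n_taxa`` extant tips labelled t1..tn.

    ``scale_depth`` rescales all branch lengths so the mean root-to-tip path
    equals the given value (in expected substitutions per site) — the knob
    that keeps simulated matrices at a realistic overall divergence.
    Per-lineage rate multipliers scale the terminal branch of the named tip.
    Extinct simulations are retried up to ``max_attempts``.
    """
    if n_taxa < 4:
        raise ValueError("need at least 4 taxa")
    from dendropy.simulate import treesim

    rng = random.Random(seed)
    tree = None
    for _ in range(max_attempts):
        try:
            tree = treesim.birth_death_tree(
                birth_rate=birth_rate,
                death_rate=death_rate,
                num_extant_tips=n_taxa,
                rng=rng,
                repeat_until_success=False,
            )
            break
        except Exception:
            continue
    if tree is None:
        raise RuntimeError(f"birth-death simulation failed {max_attempts} times")
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon.label = f"t{i}"
    if scale_depth is not None:
        tip_depths = []
        for lf in tree.leaf_node_iter():
            d, node = 0.0, lf
            while node.parent_node is not None:
                d += node.edge.length or 0.0
                node = node.parent_node
            tip_depths.append(d)
        mean_depth = sum(tip_depths) / len(tip_depths)
        if mean_depth > 0:
            factor = scale_depth / mean_depth
            for e in tree.preorder_edge_iter():
                if e.length is not None:
                    e.length *= factor
    if rate_multipliers:
        apply_rate_multipliers(tree, rate_multipliers)
    return tree


def apply_rate_multipliers(tree: dendropy.Tree, multipliers: dict[str, float]) -> None:
    for leaf in tree.leaf_node_iter():
        m = multipliers.get(leaf.taxon.label if leaf.taxon else "")
        if m is not None and leaf.edge.length is not None:
            leaf.edge.length *= m


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------

def _draw_state(rng: np.random.Generator, P: np.ndarray, state: int) -> int:
    return int(rng.choice(4, p=P[state] / P[state].sum()))


def _evolve_column(
    rng: np.random.Generator,
    tree: dendropy.Tree,
    model: GTRModel,
    rate: float,
) -> dict[str, int]:
    """One independently evolving column; returns tip label -> state."""
    root_state = int(rng.choice(4, p=model.frequencies))
    states = {tree.seed_node: root_state}
    out = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        t = (node.edge.length or 0.0) * rate
        P = model.transition_matrix(t)
        states[node] = _draw_state(rng, P, states[node.parent_node])
        if node.is_leaf():
            out[node.taxon.label] = states[node]
    return out


def _evolve_stem_pair(
    rng: np.random.Generator,
    tree: dendropy.Tree,
    model: GTRModel,
    q: float,
) -> tuple[dict[str, tuple[int, int]], int, int]:
    """One stem doublet.  On each branch the pair is fully coupled with
    probability q (the partner compensates every substitution, keeping the
    doublet complementary); otherwise both sides evolve independently.

    Returns (tip -> (left, right) states, n_changed_branches,
    n_pair_preserving_changes).
    """
    left0 = int(rng.choice(4, p=model.frequencies))
    states = {tree.seed_node: (left0, COMPLEMENT[left0])}
    out = {}
    changed = preserved = 0
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        t = node.edge.length or 0.0
        P = model.transition_matrix(t)
        l_par, r_par = states[node.parent_node]
        l_child = _draw_state(rng, P, l_par)
        if rng.random() < q:
            r_child = COMPLEMENT[l_child]
        else:
            r_child = _draw_state(rng, P, r_par)
        if (l_child, r_child) != (l_par, r_par):
            changed += 1
            if r_child == COMPLEMENT[l_child]:
                preserved += 1
        states[node] = (l_child, r_child)
        if node.is_leaf():
            out[node.taxon.label] = (l_child, r_child)
    return out, changed, preserved


def _evolve_raa_block(
    rng: np.random.Generator,
    tree: dendropy.Tree,
    model: GTRModel,
    config: SimulationConfig,
) -> dict[str, str]:
    """Substitution + indel evolution of one unconstrained block.

    Indels arrive as a Poisson process along each branch (rate per unit
    branch length), insertion or deletion with equal probability, geometric
    lengths, uniform positions.  Deletion rates on terminal branches can be
    scaled per taxon; terminal-branch substitution frequencies can be
    overridden per taxon (both hooks exist to plant composition-length
    covariation).
    """
    L0 = config.raa_base_length
    root = list(rng.choice(4, size=L0, p=model.frequencies))
    seqs = {tree.seed_node: root}
    out = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        t = node.edge.length or 0.0
        label = node.taxon.label if (node.is_leaf() and node.taxon) else None
        sub_model = model
        if label and label in config.raa_freq_overrides:
            sub_model = GTRModel(frequencies=np.asarray(config.raa_freq_overrides[label]))
        P = sub_model.transition_matrix(t)
        seq = [_draw_state(rng, P, s) for s in seqs[node.parent_node]]
        del_mult = config.deletion_multipliers.get(label, 1.0) if label else 1.0
        p_del = min(0.5 * del_mult, 0.95)
        n_events = rng.poisson(config.indel_rate * t)
        for _ in range(n_events):
            length = int(rng.geometric(config.indel_length_p))
            if rng.random() < p_del and seq:
                pos = int(rng.integers(0, len(seq)))
                del seq[pos : pos + length]
            else:
                pos = int(rng.integers(0, len(seq) + 1))
                ins = [int(s) for s in rng.choice(4, size=length, p=sub_model.frequencies)]
                seq[pos:pos] = ins
        seqs[node] = seq
        if node.is_leaf():
            out[node.taxon.label] = "".join(BASES[s] for s in seq)
    return out


def simulate_structured_alignment(
    tree: dendropy.Tree,
    config: SimulationConfig,
    seed: Optional[int] = None,
) -> tuple[StructuredAlignment, dict]:
    """Structured alignment on a tree plus a truth record.

    Layout: P left stem columns, loop columns, the RAA blocks (right-padded
    with gaps to the block's widest taxon), then P right stem columns in
    reverse pairing order; the mask is '('*P + '.'*middle + ')'*P so stack
    matching recovers the planted pairing exactly.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    taxa = sorted(
        (lf.taxon.label for lf in tree.leaf_node_iter() if lf.taxon),
        key=lambda s: (len(s), s),
    )
    stem_model = GTRModel(frequencies=np.asarray(config.stem_frequencies))
    loop_model = GTRModel(frequencies=np.asarray(config.loop_frequencies))
    # stems
    left_cols: list[dict[str, int]] = []
    right_cols: list[dict[str, int]] = []
    changed = preserved = 0
    for _ in range(config.n_stem_pairs):
        pair, c, p = _evolve_stem_pair(rng, tree, stem_model, config.compensation_q)
        left_cols.append({t: s[0] for t, s in pair.items()})
        right_cols.append({t: s[1] for t, s in pair.items()})
        changed += c
        preserved += p
    # loops
    rates = discrete_gamma_rates(config.gamma_shape) if config.n_loop_columns else None
    loop_cols = []
    for _ in range(config.n_loop_columns):
        r = float(rng.choice(rates))
        loop_cols.append(_evolve_column(rng, tree, loop_model, r))
    # RAAs
    blocks = []
    for _ in range(config.n_raa_blocks):
        blocks.append(_evolve_raa_block(rng, tree, loop_model, config))
    widths = [max(len(s) for s in b.values()) for b in blocks]
    P = config.n_stem_pairs
    middle = config.n_loop_columns + sum(widths)
    rows = []
    for t in taxa:
        left = "".join(BASES[c[t]] for c in left_cols)
        right = "".join(BASES[c[t]] for c in reversed(right_cols))
        loops = "".join(BASES[c[t]] for c in loop_cols)
        raa = "".join(
            b[t] + GAP * (w - len(b[t])) for b, w in zip(blocks, widths)
        )
        rows.append(left + loops + raa + right)
    mask = "(" * P + "." * middle + ")" * P
    spans = []
    offset = P + config.n_loop_columns
    for k, w in enumerate(widths, start=1):
        spans.append(RaaSpan(f"RAA{k}", offset, offset + w))
        offset += w
    saln = StructuredAlignment(Alignment(taxa, rows), mask, spans)
    truth = {
        "config": config,
        "taxa": taxa,
        "n_stem_pairs": P,
        "stem_changes": changed,
        "stem_changes_pair_preserving": preserved,
        "realized_compensation": preserved / changed if changed else float("nan"),
        "raa_widths": widths,
        "raa_ungapped_lengths": {
            t: [len(b[t]) for b in blocks] for t in taxa
        },
    }
    return saln, truth


# ---------------------------------------------------------------------------
# tree sets
# ---------------------------------------------------------------------------

@dataclass
class EdgeConflict:
    """A planted conflict at one internal edge of the true topology.

    ``clade`` identifies the edge (leaf labels below it); ``alt_clade`` is
    the conflicting resolution to plant (one of the two nearest-neighbour
    alternatives); the edge appears with frequency ~f1, the alternative with
    ~f2, and the third resolution with the remainder.
    """

    clade: frozenset
    alt_clade: frozenset
    f1: float
    f2: float

    def __post_init__(self) -> None:
        if self.f1 < 0 or self.f2 < 0 or self.f1 + self.f2 > 1 + 1e-12:
            raise ValueError("need f1, f2 >= 0 and f1 + f2 <= 1")


def _leafset(node) -> frozenset:
    return frozenset(lf.taxon.label for lf in node.leaf_iter() if lf.taxon)


def _apply_resolution(tree: dendropy.Tree, clade: frozenset, target: frozenset) -> None:
    """Nearest-neighbour rearrangement turning the edge ``clade`` into
    ``target`` (``target == clade`` is a no-op)."""
    if target == clade:
        return
    node = next(
        (n for n in tree.preorder_node_iter() if not n.is_leaf() and _leafset(n) == clade),
        None,
    )
    if node is None or node.parent_node is None:
        raise ValueError(f"no internal edge with clade {sorted(clade)}")
    parent = node.parent_node
    siblings = [c for c in parent.child_nodes() if c is not node]
    kids = node.child_nodes()
    if len(kids) != 2:
        raise ValueError("conflict edge must be binary")
    for sib in siblings:
        sib_set = _leafset(sib)
        for kid in kids:
            if _leafset(kid) | sib_set == target:
                move = next(k for k in kids if k is not kid)
                node.remove_child(move)
                parent.remove_child(sib)
                node.add_child(sib)
                parent.add_child(move)
                return
    raise ValueError(
        f"{sorted(target)} is not a nearest-neighbour alternative of {sorted(clade)}"
    )


def _nni_alternatives(tree: dendropy.Tree, clade: frozenset) -> list[frozenset]:
    """The conflicting resolutions reachable by one swap around ``clade``."""
    node = next(
        (n for n in tree.preorder_node_iter() if not n.is_leaf() and _leafset(n) == clade),
        None,
    )
    if node is None or node.parent_node is None:
        raise ValueError(f"no internal edge with clade {sorted(clade)}")
    out = []
    kid_sets = [_leafset(k) for k in node.child_nodes()]
    for sib in (c for c in node.parent_node.child_nodes() if c is not node):
        for ks in kid_sets:
            alt = ks | _leafset(sib)
            if alt != clade:
                out.append(alt)
    return out


def simulate_bootstrap_tree_set(
    true_tree: dendropy.Tree,
    conflicts: Sequence[EdgeConflict],
    n_trees: int,
    seed: int = 0,
) -> list[dendropy.Tree]:
    """Tree set in which each conflicted internode appears with frequency
    ~f1 and its planted alternative with ~f2 (seeded multinomial draws;
    unconflicted edges appear in every tree)."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_trees):
        tree = true_tree.clone(depth=1)
        for cf in conflicts:
            u = rng.random()
            if u < cf.f1:
                continue
            if u < cf.f1 + cf.f2:
                _apply_resolution(tree, cf.clade, cf.alt_clade)
            else:
                # remaining mass: another one-swap alternative, drawn uniformly
                alts = [
                    a for a in _nni_alternatives(tree, cf.clade) if a != cf.alt_clade
                ]
                _apply_resolution(
                    tree, cf.clade, alts[int(rng.integers(len(alts)))]
                )
        out.append(tree)
    return out


def simulate_posterior_sample(
    tree: dendropy.Tree,
    multipliers: Optional[dict[str, float]] = None,
    jitter_sd: float = 0.1,
    n: int = 500,
    seed: int = 0,
) -> list[dendropy.Tree]:
    """Fixed-topology posterior-like sample: branch lengths are the true
    lengths times the lineage multiplier (terminal branches of named tips)
    times a lognormal jitter of the given log-sd."""
    if multipliers and any(m <= 0 for m in multipliers.values()):
        raise ValueError("multipliers must be positive")
    if jitter_sd < 0:
        raise ValueError("jitter sd must be non-negative")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        t = tree.clone(depth=1)
        if multipliers:
            apply_rate_multipliers(t, multipliers)
        if jitter_sd > 0:
            for edge in t.preorder_edge_iter():
                if edge.length is not None:
                    edge.length *= float(np.exp(rng.normal(0.0, jitter_sd)))
        out.append(t)
    return out


def simulate_trace(mean: float, sd: float, n: int, seed: int = 0) -> TraceSeries:
    """i.i.d. normal sampled-lnL trace."""
    if sd < 0 or n < 1:
        raise ValueError("need sd >= 0 and n >= 1")
    rng = np.random.default_rng(seed)
    return TraceSeries(rng.normal(mean, sd, size=n))
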