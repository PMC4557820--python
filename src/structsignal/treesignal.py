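"""Split systems, consensus-network export, and internode-certainty indices.

A set of trees (bootstrap replicates or an MCMC posterior sample) over one
leaf set induces a split system: every nontrivial bipartition with its
observed frequency.  Filtered at a frequency threshold (0.1 by default for
consensus networks) the system can be exported as a NEXUS SPLITS block for
splits-graph viewers.  Against a reference topology, internode certainty
quantifies conflict per internal edge:

    IC  = 1 + sum_{i in {1,2}} p_i log2 p_i,   p_i = f_i / (f1 + f2)

with f1 the reference edge's split frequency and f2 the most frequent
incompatible split (IC = 1 when there is no conflict; 0 when f1 = f2; the
sign is flipped negative when the conflicting split is the more frequent).
ICA generalizes to all incompatible splits above a threshold with a log base
equal to the size of that split set.  TC/TCA are the tree-wide sums, and the
relative versions divide by the number of internal edges of a fully resolved
unrooted tree, n - 3.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import dendropy

log = logging.getLogger(__name__)

Split = frozenset  # canonical side: the side NOT containing the first taxon


@dataclass
class SplitSystem:
    taxa: list[str]
    frequencies: dict[frozenset, float]
    n_trees: int

    def nontrivial(self) -> dict[frozenset, float]:
        n = len(self.taxa)
        return {
            s: f for s, f in self.frequencies.items() if 2 <= len(s) <= n - 2
        }


def _canonical_split(side: set[str], taxa: Sequence[str]) -> frozenset:
    if taxa[0] in side:
        return frozenset(t for t in taxa if t not in side)
    return frozenset(side)


def tree_splits(tree: dendropy.Tree, taxa: Sequence[str]) -> set[frozenset]:
    """Nontrivial canonical splits of one (rooted or unrooted) tree."""
    n = len(taxa)
    taxa_set = set(taxa)
    out = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        below = {
            lf.taxon.label for lf in node.leaf_iter() if lf.taxon is not None
        }
        if 2 <= len(below) <= n - 2 and below < taxa_set:
            out.add(_canonical_split(below, taxa))
    return out


def split_frequencies(trees: Sequence[dendropy.Tree]) -> SplitSystem:
    """Observed frequency of every nontrivial bipartition across a tree set.

    All trees must share one leaf set; a mismatch reports the symmetric
    difference.
    """
    if not trees:
        raise ValueError("empty tree set")
    ref_taxa = sorted(
        lf.taxon.label for lf in trees[0].leaf_node_iter() if lf.taxon
    )
    counts: dict[frozenset, int] = {}
    for k, tr in enumerate(trees):
        labels = sorted(lf.taxon.label for lf in tr.leaf_node_iter() if lf.taxon)
        if labels != ref_taxa:
            diff = set(labels) ^ set(ref_taxa)
            raise ValueError(f"tree {k} leaf set differs: {sorted(diff)}")
        for s in tree_splits(tr, ref_taxa):
            counts[s] = counts.get(s, 0) + 1
    n = len(trees)
    return SplitSystem(ref_taxa, {s: c / n for s, c in counts.items()}, n)


def filter_splits(system: SplitSystem, threshold: float = 0.1) -> SplitSystem:
    """Retain splits with frequency >= threshold (consensus-network cut)."""
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must be in [0, 1]")
    kept = {s: f for s, f in system.frequencies.items() if f >= threshold}
    return SplitSystem(list(system.taxa), kept, system.n_trees)


def splits_compatible(a: frozenset, b: frozenset, taxa: Sequence[str]) -> bool:
    """Two splits are compatible iff one of the four side-intersections is
    empty (then they can coexist in a single tree)."""
    ta = set(taxa)
    a1, a2 = set(a), ta - set(a)
    b1, b2 = set(b), ta - set(b)
    return (
        not (a1 & b1) or not (a1 & b2) or not (a2 & b1) or not (a2 & b2)
    )


# ---------------------------------------------------------------------------
# NEXUS SPLITS export
# ---------------------------------------------------------------------------

def export_splits_nexus(system: SplitSystem, path: str | Path) -> None:
    """Write a TAXA + SPLITS NEXUS file (weights = frequencies) readable by
    splits-graph viewers; round-trips with :func:`read_splits_nexus`."""
    taxa = system.taxa
    index = {t: i + 1 for i, t in enumerate(taxa)}
    lines = [
        "#NEXUS",
        "",
        "BEGIN Taxa;",
        f"DIMENSIONS ntax={len(taxa)};",
        "TAXLABELS",
    ]
    lines += [f"[{i + 1}] '{t}'" for i, t in enumerate(taxa)]
    lines += [";", "END;", "", "BEGIN Splits;"]
    splits = sorted(system.frequencies.items(), key=lambda kv: (-kv[1], sorted(kv[0])))
    lines.append(f"DIMENSIONS ntax={len(taxa)} nsplits={len(splits)};")
    lines.append("FORMAT labels=no weights=yes confidences=no intervals=no;")
    lines.append("MATRIX")
    for k, (s, f) in enumerate(splits, start=1):
        members = " ".join(str(index[t]) for t in sorted(s, key=taxa.index))
        lines.append(f"[{k}, size={len(s)}]\t{f:.10g}\t{members},")
    lines += [";", "END;", ""]
    Path(path).write_text("\n".join(lines))


def read_splits_nexus(path: str | Path) -> SplitSystem:
    """Parse the SPLITS dialect written by :func:`export_splits_nexus`."""
    text = Path(path).read_text()
    taxlabels = re.search(r"TAXLABELS(.*?);", text, re.S)
    if not taxlabels:
        raise ValueError("no TAXLABELS block")
    taxa = re.findall(r"'([^']*)'", taxlabels.group(1))
    freqs: dict[frozenset, float] = {}
    matrix = re.search(r"MATRIX(.*?);", text[text.index("BEGIN Splits"):], re.S)
    if matrix:
        for line in matrix.group(1).splitlines():
            line = line.strip().rstrip(",")
            if not line:
                continue
            line = re.sub(r"\[[^\]]*\]", "", line).strip()
            if not line:
                continue
            parts = line.split()
            weight = float(parts[0])
            members = frozenset(taxa[int(i) - 1] for i in parts[1:])
            freqs[members] = weight
    return SplitSystem(taxa, freqs, n_trees=0)


# ---------------------------------------------------------------------------
# internode certainty
# ---------------------------------------------------------------------------

@dataclass
class EdgeCertainty:
    split: frozenset
    frequency: float
    max_conflict: float
    ic: float
    ica: float
    n_conflicts: int


@dataclass
class CertaintyAnnotatedTree:
    tree: dendropy.Tree
    edges: list[EdgeCertainty]
    tc: float
    tca: float
    relative_tc: float
    relative_tca: float


def _ic_pair(f1: float, f2: float) -> float:
    """IC from the reference-split and strongest-conflict frequencies."""
    if f2 == 0:
        return 1.0
    p1 = f1 / (f1 + f2)
    p2 = f2 / (f1 + f2)
    h = 0.0
    for p in (p1, p2):
        if p > 0:
            h += p * math.log2(p)
    val = 1.0 + h
    return -val if f2 > f1 else val


def _ica(f1: float, conflicts: list[float], threshold: float) -> float:
    fs = [f1] + [f for f in conflicts if f >= threshold]
    k = len(fs)
    if k == 1:
        return 1.0
    tot = sum(fs)
    h = sum((f / tot) * math.log(f / tot, k) for f in fs if f > 0)
    val = 1.0 + h
    return -val if max(conflicts) > f1 else val


def internode_certainty(
    ref: dendropy.Tree,
    trees: Sequence[dendropy.Tree],
    ica_threshold: float = 0.05,
) -> CertaintyAnnotatedTree:
    """IC/ICA per internal edge of ``ref`` against a tree set, plus TC/TCA.

    The reference tree's leaves must equal the tree set's.  An edge never
    observed and never contradicted is degenerate and scored 1 with a
    warning.  Scores are attached to the reference tree's nodes as
    ``node.ic`` / ``node.ica``.
    """
    system = split_frequencies(list(trees))
    taxa = system.taxa
    ref_labels = sorted(lf.taxon.label for lf in ref.leaf_node_iter() if lf.taxon)
    if ref_labels != taxa:
        diff = set(ref_labels) ^ set(taxa)
        raise ValueError(f"reference leaf set differs from tree set: {sorted(diff)}")
    nontrivial = system.nontrivial()
    edges: list[EdgeCertainty] = []
    n = len(taxa)
    taxa_set = set(taxa)
    for node in ref.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            node.ic = None
            node.ica = None
            continue
        below = {lf.taxon.label for lf in node.leaf_iter() if lf.taxon}
        if not (2 <= len(below) <= n - 2) or not below < taxa_set:
            node.ic = None
            node.ica = None
            continue
        split = _canonical_split(below, taxa)
        f1 = nontrivial.get(split, 0.0)
        conflicts = [
            f for s, f in nontrivial.items()
            if s != split and not splits_compatible(split, s, taxa)
        ]
        if f1 == 0.0 and not conflicts:
            log.warning(
                "reference edge %s never observed and never conflicted; IC=1",
                sorted(below),
            )
            ic = ica = 1.0
            f2 = 0.0
        else:
            f2 = max(conflicts, default=0.0)
            ic = _ic_pair(f1, f2)
            ica = _ica(f1, conflicts, ica_threshold) if conflicts else 1.0
        node.ic = ic
        node.ica = ica
        edges.append(EdgeCertainty(split, f1, f2, ic, ica, len(conflicts)))
    tc = sum(e.ic for e in edges)
    tca = sum(e.ica for e in edges)
    denom = n - 3
    return CertaintyAnnotatedTree(
        ref, edges, tc, tca, tc / denom if denom else float("nan"),
        tca / denom if denom else float("nan"),
    )


def annotate_tree(result: CertaintyAnnotatedTree) -> str:
    """Newick string with 'IC/ICA' internal-node labels (6 decimals)."""
    tree = result.tree
    for node in tree.preorder_node_iter():
        if getattr(node, "ic", None) is not None:
            node.label = f"{node.ic:.6f}/{node.ica:.6f}"
    return tree.as_string(schema="newick", suppress_rooting=True)


def read_annotated_tree(newick: str) -> dendropy.Tree:
    """Re-parse an annotated Newick; IC/ICA recovered onto ``node.ic``/``.ica``."""
    tree = dendropy.Tree.get(
        data=newick, schema="newick", suppress_internal_node_taxa=True
    )
    for node in tree.preorder_node_iter():
        if node.label and "/" in node.label:
            ic, ica = node.label.split("/")
            node.ic = float(ic)
            node.ica = float(ica)
        else:
            node.ic = None
            node.ica = None
    return tree
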