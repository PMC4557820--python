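"""RAA pipeline: block extraction, progressive aligner vs brute force,
concatenation, random-similarity masking."""

import itertools

import dendropy
import numpy as np
import pytest

from structsignal import (
    Alignment,
    AlignmentCosts,
    RaaBlock,
    StructuredAlignment,
    align_block,
    align_block_multi,
    alignment_cost,
    apply_mask,
    concatenate_blocks,
    extract_raa_blocks,
    random_similarity_mask,
)
from structsignal.raa import AlignedBlock, pairwise_align_cost
from structsignal.structure import RaaSpan


# ---------------------------------------------------------------------------
# independent oracle: exhaustive enumeration of pairwise affine alignments
# ---------------------------------------------------------------------------

def brute_force_affine(a: str, b: str, costs: AlignmentCosts) -> float:
    """Minimum affine cost by exhaustive enumeration of all alignments.

    Gap runs scored open + k * extend; completely independent of the DP.
    """
    best = [float("inf")]

    def score(pairs) -> float:
        total = 0.0
        in_gap = False
        for x, y in pairs:
            if x == "-" or y == "-":
                if not in_gap:
                    total += costs.gap_open
                    in_gap = True
                total += costs.gap_extend
            else:
                in_gap = False
                if x != y:
                    total += costs.substitution
        return total

    def rec(i, j, pairs):
        if i == len(a) and j == len(b):
            best[0] = min(best[0], score(pairs))
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, pairs + [(a[i], b[j])])
        if i < len(a):
            rec(i + 1, j, pairs + [(a[i], "-")])
        if j < len(b):
            rec(i, j + 1, pairs + [("-", b[j])])

    rec(0, 0, [])
    return best[0]


def star_guide(taxa) -> dendropy.Tree:
    nwk = "(" + ",".join(f"{t}:1" for t in taxa) + ");"
    return dendropy.Tree.get(data=nwk, schema="newick")


class TestBlockExtraction:
    def test_span_degaps(self):
        saln = StructuredAlignment(
            Alignment(["a"], ["AC--GTAC"]), "........", [RaaSpan("B", 2, 6)]
        )
        blocks = extract_raa_blocks(saln)
        assert blocks[0].sequences["a"] == "GT"

    def test_no_spans_empty_list(self, toy_structured):
        assert extract_raa_blocks(toy_structured) == []

    def test_gapped_subsequence_rejected(self):
        with pytest.raises(ValueError, match="gaps"):
            RaaBlock("B", (0, 4), {"a": "A-C"})


class TestAligner:
    def test_identical_subsequences_cost_zero(self):
        block = RaaBlock("B", (0, 5), {t: "ACGTT" for t in "abcd"})
        out = align_block(block, star_guide("abcd"))
        assert out.cost == 0.0
        assert all(r == "ACGTT" for r in out.alignment.rows)

    @pytest.mark.parametrize("seed", range(8))
    def test_pairwise_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        a = "".join(rng.choice(list("ACGT"), size=rng.integers(1, 6)))
        b = "".join(rng.choice(list("ACGT"), size=rng.integers(1, 6)))
        costs = AlignmentCosts()
        assert pairwise_align_cost(a, b, costs) == pytest.approx(
            brute_force_affine(a, b, costs)
        )

    def test_pairwise_block_equals_oracle(self):
        costs = AlignmentCosts()
        block = RaaBlock("B", (0, 9), {"a": "ACGTACG", "b": "ACTTAG"})
        out = align_block(block, star_guide("ab"), costs)
        assert out.cost == pytest.approx(
            brute_force_affine("ACGTACG", "ACTTAG", costs)
        )

    def test_three_identical_sequences_match_pair_oracle(self):
        # degenerate case: identical inputs must still yield zero total cost
        block = RaaBlock("B", (0, 6), {"a": "ACGT", "b": "ACGT", "c": "ACGT"})
        out = align_block(block, star_guide("abc"))
        assert out.cost == 0.0

    def test_degapping_recovers_input(self):
        rng = np.random.default_rng(3)
        seqs = {
            t: "".join(rng.choice(list("ACGT"), size=rng.integers(0, 12)))
            for t in "abcdef"
        }
        block = RaaBlock("B", (0, 20), seqs)
        out = align_block(block, star_guide("abcdef"))
        for t in "abcdef":
            assert out.alignment.row(t).replace("-", "") == seqs[t]

    def test_absent_taxon_padded_after(self):
        block = RaaBlock("B", (0, 5), {"a": "ACGT", "b": "ACG", "c": ""})
        out = align_block(block, star_guide("ab"), master_taxa=["a", "b", "c"])
        assert set(out.alignment.row("c")) == {"-"}

    def test_missing_taxon_errors(self):
        block = RaaBlock("B", (0, 5), {"a": "ACGT", "b": "ACG"})
        with pytest.raises(ValueError, match="missing"):
            align_block(block, star_guide("a"))

    def test_cost_invariant_under_relabeling(self):
        rng = np.random.default_rng(6)
        seqs = [
            "".join(rng.choice(list("ACGT"), size=8)) for _ in range(4)
        ]
        b1 = RaaBlock("B", (0, 9), dict(zip("abcd", seqs)))
        b2 = RaaBlock("B", (0, 9), dict(zip("wxyz", seqs)))
        g1 = dendropy.Tree.get(data="((a:1,b:1):1,(c:1,d:1):1);", schema="newick")
        g2 = dendropy.Tree.get(data="((w:1,x:1):1,(y:1,z:1):1);", schema="newick")
        assert align_block(b1, g1).cost == align_block(b2, g2).cost


class TestMultiGuide:
    def test_single_guide_identity(self):
        block = RaaBlock("B", (0, 9), {"a": "ACGTA", "b": "ACTA", "c": "AGTA"})
        g = star_guide("abc")
        assert align_block_multi(block, [g]).cost == align_block(block, g).cost

    def test_min_cost_selected(self):
        rng = np.random.default_rng(8)
        seqs = {t: "".join(rng.choice(list("ACGT"), size=10)) for t in "abcde"}
        block = RaaBlock("B", (0, 11), seqs)
        guides = [
            dendropy.Tree.get(data="(((a:1,b:1):1,c:1):1,(d:1,e:1):1);", schema="newick"),
            dendropy.Tree.get(data="(((a:1,d:1):1,e:1):1,(b:1,c:1):1);", schema="newick"),
            star_guide("abcde"),
        ]
        out = align_block_multi(block, guides)
        assert len(out.guide_costs) == 3
        assert out.cost == min(out.guide_costs)


class TestConcatenation:
    def _blk(self, bid, taxa, width, rng):
        rows = ["".join(rng.choice(list("ACGT"), size=width)) for _ in taxa]
        return AlignedBlock(bid, Alignment(list(taxa), rows), 0.0)

    def test_widths_and_provenance_tile(self):
        rng = np.random.default_rng(0)
        blocks = [self._blk("B1", "abc", 5, rng), self._blk("B2", "abc", 7, rng)]
        cat = concatenate_blocks(blocks)
        assert cat.alignment.n_columns == 12
        assert [b for b, _ in cat.provenance] == ["B1"] * 5 + ["B2"] * 7
        assert [k for _, k in cat.provenance] == list(range(5)) + list(range(7))

    def test_provenance_round_trip(self):
        rng = np.random.default_rng(1)
        blocks = [self._blk(f"B{i}", "abcd", int(rng.integers(2, 8)), rng) for i in range(4)]
        cat = concatenate_blocks(blocks)
        for b in blocks:
            idx = [k for k, (bid, _) in enumerate(cat.provenance) if bid == b.block_id]
            assert cat.alignment.take_columns(idx).rows == b.alignment.rows

    def test_absent_taxon_gap_padded(self):
        rng = np.random.default_rng(2)
        blocks = [self._blk("B1", "ab", 4, rng), self._blk("B2", "bc", 3, rng)]
        cat = concatenate_blocks(blocks)
        assert cat.alignment.row("c")[:4] == "----"
        assert cat.alignment.row("a")[4:] == "---"

    def test_duplicate_id_rejected(self):
        rng = np.random.default_rng(3)
        with pytest.raises(ValueError, match="duplicate"):
            concatenate_blocks([self._blk("B", "ab", 3, rng)] * 2)


class TestMasking:
    def test_identical_sequences_all_kept(self):
        rows = ["ACGTTGCAACGTGGCA"] * 4
        aln = Alignment(list("abcd"), rows)
        prof = random_similarity_mask(aln, reps=100, seed=0)
        assert prof.keep.all()

    def test_shuffled_unrelated_mostly_dropped(self):
        rng = np.random.default_rng(5)
        rows = ["".join(rng.choice(list("ACGT"), size=120)) for _ in range(4)]
        aln = Alignment(list("abcd"), rows)
        prof = random_similarity_mask(aln, reps=200, seed=5)
        assert prof.keep.mean() <= 0.10

    def test_conserved_core_kept_random_tails_dropped(self):
        rng = np.random.default_rng(6)
        core = "".join(rng.choice(list("ACGT"), size=40))
        rows = []
        for _ in range(5):
            left = "".join(rng.choice(list("ACGT"), size=30))
            right = "".join(rng.choice(list("ACGT"), size=30))
            rows.append(left + core + right)
        aln = Alignment([f"t{i}" for i in range(5)], rows)
        prof = random_similarity_mask(aln, reps=200, seed=6)
        core_cols = prof.keep[30:70]
        tail_cols = np.concatenate([prof.keep[:30], prof.keep[70:]])
        assert core_cols.mean() >= 0.9
        assert tail_cols.mean() <= 0.2

    def test_determinism(self):
        rng = np.random.default_rng(7)
        rows = ["".join(rng.choice(list("ACGT"), size=50)) for _ in range(3)]
        aln = Alignment(list("abc"), rows)
        p1 = random_similarity_mask(aln, reps=150, seed=42)
        p2 = random_similarity_mask(aln, reps=150, seed=42)
        assert np.array_equal(p1.consensus, p2.consensus)

    def test_apply_mask_counts(self):
        rng = np.random.default_rng(8)
        aln = Alignment(list("ab"), ["ACGTACGT", "ACGTACGT"])
        prof = random_similarity_mask(aln, window=4, reps=100, seed=1)
        keep = rng.random(8) > 0.5
        prof.keep = keep
        assert apply_mask(aln, prof).n_columns == int(keep.sum())

    def test_parameter_validation(self):
        aln = Alignment(list("ab"), ["ACGT", "ACGT"])
        with pytest.raises(ValueError):
            random_similarity_mask(aln, window=1)
        with pytest.raises(ValueError):
            random_similarity_mask(aln, reps=10)
        with pytest.raises(ValueError):
            random_similarity_mask(Alignment(["a"], ["ACGT"]))
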