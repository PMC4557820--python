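"""Structure-annotated alignment IO, bracket matching, partitioning, counting."""

import numpy as np
import pytest

from structsignal import (
    Alignment,
    ColumnClass,
    StructuredAlignment,
    count_site_patterns,
    extract_partition,
    read_structured_fasta,
    write_partition_files,
)
from structsignal.structure import (
    FormatError,
    RaaSpan,
    match_brackets,
    read_phylip,
    write_raa_annotation,
    write_structured_fasta,
)


def random_structured(rng: np.random.Generator, n_taxa=6, pairs=4, loops=6, raa=5):
    bases = "ACGT"
    L = 2 * pairs + loops + raa
    rows = ["".join(rng.choice(list(bases), size=L)) for _ in range(n_taxa)]
    mask = "(" * pairs + "." * (loops + raa) + ")" * pairs
    spans = [RaaSpan("B1", pairs + loops, pairs + loops + raa)] if raa else []
    return StructuredAlignment(
        Alignment([f"t{i}" for i in range(n_taxa)], rows), mask, spans
    )


class TestBracketMatching:
    def test_nesting_forced(self, toy_structured):
        assert toy_structured.pairing == {0: 7, 7: 0, 1: 6, 6: 1}
        classes = toy_structured.column_classes()
        assert [c == ColumnClass.STEM for c in classes] == [
            True, True, False, False, False, False, True, True,
        ]

    def test_all_dots(self):
        pairing, orphans = match_brackets("........")
        assert pairing == {} and orphans == set()

    def test_orphans_from_unsequenced_strand(self):
        # a '(' without partner is legal: recorded as orphan, still counted paired
        saln = StructuredAlignment(Alignment(["a"], ["ACGTA"]), "((.).")
        assert saln.orphan_paired == {0}
        assert saln.pairing == {1: 3, 3: 1}
        assert saln.n_paired() == 3  # odd paired count is representable

    def test_mirror_property(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            pairs = int(rng.integers(1, 5))
            loops = int(rng.integers(0, 6))
            mask = "(" * pairs + "." * loops + ")" * pairs
            fwd, _ = match_brackets(mask)
            swapped = mask[::-1].translate(str.maketrans("()", ")("))
            rev, _ = match_brackets(swapped)
            L = len(mask)
            assert rev == {L - 1 - i: L - 1 - j for i, j in fwd.items()}

    def test_length_mismatch_names_record(self):
        with pytest.raises(FormatError, match="mask length"):
            StructuredAlignment(Alignment(["a"], ["ACGT"]), "((.....))")

    def test_duplicate_taxon_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            Alignment(["a", "a"], ["ACGT", "ACGT"])


class TestPartitionExtraction:
    def test_stem_extraction(self, toy_structured):
        sub, prov = extract_partition(toy_structured, "STEM")
        assert prov == [0, 1, 6, 7]
        assert sub.rows == ["ACGT", "ACGT"]

    def test_union_is_identity_without_raa(self, toy_structured):
        sub, prov = extract_partition(toy_structured, "STEM+LOOP")
        assert sub == toy_structured.alignment
        assert prov == list(range(8))

    def test_empty_class_is_empty_alignment(self, toy_structured):
        sub, prov = extract_partition(toy_structured, ColumnClass.RAA)
        assert sub.n_columns == 0 and prov == []

    def test_three_classes_tile_master(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            saln = random_structured(rng)
            cover = []
            for cls in (ColumnClass.STEM, ColumnClass.LOOP, ColumnClass.RAA):
                _, prov = extract_partition(saln, cls)
                cover.extend(prov)
            assert sorted(cover) == list(range(saln.n_columns))


def brute_force_pattern_class(col: str) -> str:
    """Independent per-column classifier straight from the definitions."""
    states = [c for c in col if c in "ACGT"]
    from collections import Counter

    counts = Counter(states)
    if len(counts) <= 1:
        return "constant"
    if sum(1 for v in counts.values() if v >= 2) >= 2:
        return "informative"
    return "uninformative"


class TestSitePatterns:
    def test_identical_rows_all_constant(self):
        aln = Alignment([f"t{i}" for i in range(5)], ["ACGTACGTAC"] * 5)
        c = count_site_patterns(aln)
        assert (c.n_constant, c.n_parsimony_informative) == (10, 0)

    @pytest.mark.parametrize(
        "col,expected",
        [("AACCG", "informative"), ("AAAAC", "uninformative"), ("AAAAA", "constant"),
         ("AA--A", "constant"), ("AC---", "uninformative"), ("AACC-", "informative"),
         ("NNNNN", "constant")],
    )
    def test_single_column_classes(self, col, expected):
        aln = Alignment([f"t{i}" for i in range(5)], [c for c in col])
        counts = count_site_patterns(aln)
        got = {
            "constant": counts.n_constant,
            "uninformative": counts.n_variable_uninformative,
            "informative": counts.n_parsimony_informative,
        }
        assert got[expected] == 1 and sum(got.values()) == 1

    def test_counts_match_enumeration_oracle(self):
        rng = np.random.default_rng(7)
        chars = list("ACGT-N")
        for _ in range(10):
            n, L = int(rng.integers(2, 7)), int(rng.integers(5, 30))
            rows = ["".join(rng.choice(chars, size=L)) for _ in range(n)]
            aln = Alignment([f"t{i}" for i in range(n)], rows)
            counts = count_site_patterns(aln)
            from collections import Counter

            want = Counter(brute_force_pattern_class(col) for col in aln.columns())
            assert counts.n_constant == want["constant"]
            assert counts.n_variable_uninformative == want["uninformative"]
            assert counts.n_parsimony_informative == want["informative"]
            assert (
                counts.n_constant
                + counts.n_variable_uninformative
                + counts.n_parsimony_informative
                == counts.n_columns
            )

    def test_zero_taxa_errors(self):
        with pytest.raises(ValueError):
            count_site_patterns(Alignment([], []))


class TestRoundTrips:
    def test_partition_files_round_trip(self, tmp_path, toy_structured):
        written = write_partition_files(toy_structured, tmp_path)
        again = read_structured_fasta(written["fasta"])
        assert again.alignment == toy_structured.alignment
        assert again.mask == toy_structured.mask
        stem = read_phylip(written["stem"])
        sub, _ = extract_partition(toy_structured, "STEM")
        assert stem == sub

    def test_partition_definition_tiles(self, tmp_path):
        rng = np.random.default_rng(3)
        saln = random_structured(rng)
        written = write_partition_files(saln, tmp_path)
        text = written["partitions"].read_text()
        cols = []
        for line in text.splitlines():
            _, _, ranges = line.partition("=")
            for chunk in ranges.split(","):
                chunk = chunk.strip()
                if chunk:
                    a, b = chunk.split("-")
                    cols.extend(range(int(a), int(b) + 1))
        assert sorted(cols) == list(range(1, saln.n_columns + 1))

    def test_orphan_demoted_in_structure_file(self, tmp_path, caplog):
        saln = StructuredAlignment(Alignment(["a", "b"], ["ACGTA", "ACGTA"]), "((.).")
        import logging

        with caplog.at_level(logging.WARNING):
            written = write_partition_files(saln, tmp_path)
        assert written["structure"].read_text().strip() == ".(.)."
        assert any("orphan" in r.message for r in caplog.records)

    def test_raa_sidecar_round_trip(self, tmp_path):
        rng = np.random.default_rng(5)
        saln = random_structured(rng)
        fasta = tmp_path / "aln.fasta"
        sidecar = tmp_path / "raa.tsv"
        write_structured_fasta(saln, fasta)
        write_raa_annotation(saln.raa_spans, sidecar)
        again = read_structured_fasta(fasta, sidecar)
        assert again.alignment == saln.alignment
        assert [(s.block_id, s.start, s.end) for s in again.raa_spans] == [
            (s.block_id, s.start, s.end) for s in saln.raa_spans
        ]

    def test_lowercase_raa_convention(self, tmp_path):
        fasta = tmp_path / "aln.fasta"
        fasta.write_text(
            ">#structure\n........\n>a\nACGTacGT\n>b\nACGTtgGT\n"
        )
        # all-lowercase columns 4-5 mark the ambiguous block
        saln = read_structured_fasta(fasta)
        assert [(s.start, s.end) for s in saln.raa_spans] == [(4, 6)]
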