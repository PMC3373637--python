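"""Codon arithmetic, translation, labels, block padding and matrix assembly."""

import pytest
from hypothesis import given, settings, strategies as st

from Bio.Seq import Seq

from seqvault import (BuildError, DatasetSpec, VoucherRecord, build_gene_block,
                      build_supermatrix, extract_codon_positions,
                      make_taxon_label, site_class, translate_dna)

# Independent per-site oracle: for frame f the class sequence over sites
# 1, 2, 3, ... is the [1, 2, 3] cycle started at offset (1 - f) mod 3.
_CLASS_CYCLE = {1: (1, 2, 3), 2: (3, 1, 2), 3: (2, 3, 1)}


def oracle_classes(n, frame):
    cycle = _CLASS_CYCLE[frame]
    return [cycle[i % 3] for i in range(n)]


def oracle_extract(seq, frame, positions):
    classes = oracle_classes(len(seq), frame)
    return "".join(ch for ch, c in zip(seq, classes) if c in positions)


class TestSiteClass:
    @pytest.mark.parametrize("site,frame,expected", [
        (1, 1, 1), (4, 1, 1), (5, 1, 2), (6, 1, 3),
        (1, 2, 3),  # leading base before the first full codon, cyclic class
        (2, 2, 1), (1, 3, 2), (3, 3, 1),
    ])
    def test_matches_hand_computed_classes(self, site, frame, expected):
        assert site_class(site, frame) == expected

    def test_agrees_with_cycle_oracle(self):
        for frame in (1, 2, 3):
            got = [site_class(i, frame) for i in range(1, 31)]
            assert got == oracle_classes(30, frame)


class TestExtractCodonPositions:
    @pytest.mark.parametrize("seq,frame,positions,expected", [
        ("ATGAAACCC", 1, {1, 2, 3}, "ATGAAACCC"),
        ("ATGAAACCC", 1, {1}, "AAC"),
        ("CATGAAACC", 2, {3}, "CGA"),
        ("AT-G?", 1, {2}, "T?"),  # gap/missing carried through by site index
    ])
    def test_worked_examples(self, seq, frame, positions, expected):
        assert extract_codon_positions(seq, frame, positions) == expected

    def test_empty_positions_rejected(self):
        with pytest.raises(ValueError):
            extract_codon_positions("ACGT", 1, set())

    @given(seq=st.text(alphabet="ACGTN-?", max_size=60),
           frame=st.sampled_from([1, 2, 3]))
    @settings(max_examples=200, deadline=None)
    def test_length_conservation_and_interleave(self, seq, frame):
        parts = {k: extract_codon_positions(seq, frame, {k}) for k in (1, 2, 3)}
        assert sum(len(p) for p in parts.values()) == len(seq)
        # re-interleave by walking the class cycle
        iters = {k: iter(parts[k]) for k in (1, 2, 3)}
        rebuilt = "".join(next(iters[c]) for c in oracle_classes(len(seq), frame))
        assert rebuilt == seq

    @given(seq=st.text(alphabet="ACGTRYN-?", max_size=60),
           frame=st.sampled_from([1, 2, 3]))
    @settings(max_examples=100, deadline=None)
    def test_full_position_set_is_identity(self, seq, frame):
        assert extract_codon_positions(seq, frame, {1, 2, 3}) == seq


class TestTranslateDna:
    @pytest.mark.parametrize("seq,frame,table,expected", [
        ("ATGAAACCC", 1, 1, "MKP"),
        ("", 1, 1, ""),
        ("ATGA", 1, 1, "M"),       # trailing partial codon dropped
        ("CCN", 1, 1, "P"),        # all CCx codons are proline
        ("---ATG", 1, 1, "-M"),    # all-gap codon
        ("A?GATG", 1, 1, "XM"),    # missing data in codon
        ("A-GATG", 1, 1, "XM"),    # gap mixed with bases
        ("RTG", 1, 1, "X"),        # ATG=M vs GTG=V disagree
        ("TAA", 1, 1, "*"),        # stop
        ("AGA", 1, 2, "*"),        # vertebrate-mito stop
        ("AGA", 1, 5, "S"),        # invertebrate-mito serine
        ("CATG", 2, 1, "M"),       # bases before the frame start dropped
        ("TTGATG", 1, 1, "LM"),
        ("ATGUUU", 1, 1, "MF"),    # RNA U treated as T
    ])
    def test_codon_conventions(self, seq, frame, table, expected):
        assert translate_dna(seq, frame, table) == expected

    def test_unsupported_table_rejected(self):
        with pytest.raises(BuildError):
            translate_dna("ATG", 1, 99)

    @given(seq=st.text(alphabet="ACGT", max_size=60),
           frame=st.sampled_from([1, 2, 3]),
           table=st.sampled_from([1, 2, 5]))
    @settings(max_examples=200, deadline=None)
    def test_agrees_with_biopython_on_unambiguous_dna(self, seq, frame, table):
        sub = seq[frame - 1:]
        sub = sub[:len(sub) // 3 * 3]
        assert translate_dna(seq, frame, table) == str(Seq(sub).translate(table=table))


class TestMakeTaxonLabel:
    @pytest.mark.parametrize("code,genus,species,expected", [
        ("CP01", "Papilio", "machaon", "CP01_Papilio_machaon"),
        ("CP 2", "Pieris", "napi-adalwinda", "CP_2_Pieris_napi_adalwinda"),
        ("X", "", "", "X__"),
    ])
    def test_join_and_sanitize(self, code, genus, species, expected):
        v = VoucherRecord(code, genus, species, unidentified=not (genus or species))
        assert make_taxon_label(v) == expected


class TestBuildGeneBlock:
    def test_missing_taxon_gets_all_missing_row_and_warning(self, store):
        gene = store.get_gene("COI")
        rows, length, warnings = build_gene_block(
            store, gene, ["CP01", "CP02", "CP03"])
        assert length == 12  # longest stored COI
        assert rows[1] == "ATGAAACCC???"  # CP02 right-padded
        assert not warnings
        rows, length, warnings = build_gene_block(
            store, store.get_gene("EF1a"), ["CP01", "CP03"])
        assert rows[1] == "?" * 6
        assert warnings == ["taxon CP03 has no sequence for gene EF1a"]

    def test_position_filter_then_pad(self, store):
        rows, length, _ = build_gene_block(
            store, store.get_gene("COI"), ["CP01", "CP02"], frozenset({3}))
        assert length == 4  # 12 bp / 3
        assert rows == ["GACG", "GAC?"]

    def test_gene_absent_everywhere_contributes_zero_length(self, store):
        rows, length, warnings = build_gene_block(
            store, store.get_gene("EF1a"), ["CP03", "OG1"])
        assert length == 0 and rows == ["", ""]
        assert any("no sequence in any selected taxon" in w for w in warnings)

    def test_position_filter_requires_reading_frame(self, store):
        with pytest.raises(BuildError):
            build_gene_block(store, store.get_gene("ITS2"), ["CP01"],
                             frozenset({1}))

    def test_strict_mode_rejects_unequal_lengths(self, store):
        with pytest.raises(BuildError):
            build_gene_block(store, store.get_gene("COI"),
                             ["CP01", "CP02"], strict=True)


class TestBuildSupermatrix:
    def test_by_gene_partitions_use_cumulative_offsets(self, store):
        spec = DatasetSpec(ingroup=["CP01", "CP02"], genes=["COI", "EF1a"])
        m = build_supermatrix(spec, store)
        assert m.partitions == [("COI", 1, 12), ("EF1a", 13, 18)]
        assert m.nchar == 18

    def test_by_codon_reorders_sites_into_contiguous_blocks(self, store):
        spec = DatasetSpec(ingroup=["CP01"], genes=["COI"],
                           partition_scheme="by_codon")
        m = build_supermatrix(spec, store)
        assert m.partitions == [("COI_pos1", 1, 4), ("COI_pos2", 5, 8),
                                ("COI_pos3", 9, 12)]
        seq = store.get_sequence("CP01", "COI").sequence
        expected = "".join(extract_codon_positions(seq, 1, {k}) for k in (1, 2, 3))
        assert m.rows[0] == expected

    def test_pos12_pos3_groups_first_two_positions(self, store):
        spec = DatasetSpec(ingroup=["CP01"], genes=["COI"],
                           partition_scheme="pos12_pos3")
        m = build_supermatrix(spec, store)
        assert m.partitions == [("COI_pos12", 1, 8), ("COI_pos3", 9, 12)]
        seq = store.get_sequence("CP01", "COI").sequence
        assert m.rows[0] == (extract_codon_positions(seq, 1, {1, 2})
                             + extract_codon_positions(seq, 1, {3}))

    def test_outgroup_rows_come_first(self, store):
        spec = DatasetSpec(ingroup=["CP01", "CP02"], outgroup=["OG1"],
                           genes=["COI"])
        m = build_supermatrix(spec, store)
        assert m.taxon_labels[0] == "OG1_Zygaena_filipendulae"
        assert m.ntax == 3

    def test_taxonset_name_resolves_ingroup(self, store):
        store.create_taxonset("ms1", ["CP02", "CP01"])
        m = build_supermatrix(DatasetSpec(ingroup="ms1", genes=["COI"]), store)
        assert m.taxon_labels == ["CP02_Pieris_napi", "CP01_Papilio_machaon"]

    def test_aminoacid_translation_on_the_fly(self, store):
        spec = DatasetSpec(ingroup=["CP01", "CP02"], genes=["COI"],
                           datatype="aminoacid")
        m = build_supermatrix(spec, store)
        assert m.rows[0] == "MKPG"     # ATG AAA CCC GGG under table 5
        assert m.rows[1] == "MKP?"     # shorter sequence padded
        assert m.datatype == "aminoacid"

    def test_partition_scheme_none_yields_single_block(self, store):
        spec = DatasetSpec(ingroup=["CP01"], genes=["COI", "EF1a"],
                           partition_scheme="none")
        m = build_supermatrix(spec, store)
        assert m.partitions == [("all", 1, 18)]

    @pytest.mark.parametrize("bad_spec_kwargs", [
        {"datatype": "aminoacid", "partition_scheme": "by_codon"},
        {"datatype": "aminoacid", "partition_scheme": "pos12_pos3"},
        {"datatype": "aminoacid", "positions": frozenset({1, 2})},
        {"positions": frozenset()},
        {"partition_scheme": "bogus"},
    ])
    def test_conflicting_specs_rejected(self, store, bad_spec_kwargs):
        spec = DatasetSpec(ingroup=["CP01"], genes=["COI"], **bad_spec_kwargs)
        with pytest.raises(BuildError):
            build_supermatrix(spec, store)

    def test_overlapping_outgroup_and_ingroup_rejected(self, store):
        spec = DatasetSpec(ingroup=["CP01"], outgroup=["CP01"], genes=["COI"])
        with pytest.raises(BuildError):
            build_supermatrix(spec, store)

    def test_deterministic_rebuild(self, store):
        spec = DatasetSpec(ingroup=["CP01", "CP02", "CP03"], outgroup=["OG1"],
                           genes=["COI", "EF1a", "ITS2"])
        a = build_supermatrix(spec, store)
        b = build_supermatrix(spec, store)
        assert a == b
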