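import pytest

from seqvault import GeneDefinition, SequenceRecord, Store, VoucherRecord


@pytest.fixture
def store():
    """Small hand-built store: 4 vouchers, 3 genes, mixed sequence coverage."""
    s = Store()
    s.add_gene(GeneDefinition("COI", description="cytochrome c oxidase subunit I",
                              reading_frame_start=1, genetic_code=5,
                              expected_length=658))
    s.add_gene(GeneDefinition("EF1a", reading_frame_start=1, genetic_code=1))
    s.add_gene(GeneDefinition("ITS2"))  # non-coding spacer

    s.add_voucher(VoucherRecord("CP01", "Papilio", "machaon", country="Finland",
                                latitude=61.5, longitude=23.8))
    s.add_voucher(VoucherRecord("CP02", "Pieris", "napi", country="Finland"))
    s.add_voucher(VoucherRecord("CP03", "Papilio", "xuthus", country="Japan"))
    s.add_voucher(VoucherRecord("OG1", "Zygaena", "filipendulae", country="Spain"))

    s.add_sequence(SequenceRecord("CP01", "COI", "ATGAAACCCGGG", accession="AB1"))
    s.add_sequence(SequenceRecord("CP02", "COI", "ATGAAACCC"))
    s.add_sequence(SequenceRecord("CP03", "COI", "ATGTTTCCCGGG", accession="AB2"))
    s.add_sequence(SequenceRecord("OG1", "COI", "ATGCCCAAAGGG", accession="AB3"))
    s.add_sequence(SequenceRecord("CP01", "EF1a", "ATGGGG"))
    s.add_sequence(SequenceRecord("CP02", "EF1a", "ATGCCC"))
    s.add_sequence(SequenceRecord("CP01", "ITS2", "ACGT-ACG"))
    yield s
    s.close()
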