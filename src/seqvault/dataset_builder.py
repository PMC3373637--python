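"""Assemble concatenated character matrices for phylogenetic analysis.

Given a store and a dataset request (:class:`DatasetSpec`), this module
builds a :class:`Supermatrix`: one row per taxon (outgroup first), genes
concatenated in the requested order, with codon-position filtering,
optional translation to amino acids, ``?``-padding for missing data, and a
partition table in 1-based inclusive coordinates.

Codon positions are assigned purely by site index relative to the gene's
declared reading frame: site ``i`` (1-based) has class
``((i - reading_frame_start) mod 3) + 1``, with the mathematical
(non-negative) modulus, so bases before the first complete codon receive
cyclically extended classes rather than being discarded.  Gap, ambiguity
and missing characters occupy sites like any base and are carried through
filtering unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio.Data import CodonTable
from Bio.Data.IUPACData import ambiguous_dna_values

from .datastore import GeneDefinition, Store, StoreError, VoucherRecord

MISSING = "?"
GAP = "-"

PARTITION_SCHEMES = ("none", "by_gene", "by_codon", "pos12_pos3")
DATATYPES = ("nucleotide", "aminoacid")


class BuildError(StoreError):
    """A dataset request cannot be satisfied."""


# ---------------------------------------------------------------------------
# Codon-position arithmetic
# ---------------------------------------------------------------------------

def site_class(site_index: int, reading_frame_start: int) -> int:
    """Codon position (1, 2 or 3) of a 1-based alignment site."""
    if site_index < 1:
        raise ValueError(f"site_index must be >= 1, got {site_index}")
    if reading_frame_start not in (1, 2, 3):
        raise ValueError(f"reading_frame_start must be 1, 2 or 3, got {reading_frame_start}")
    return (site_index - reading_frame_start) % 3 + 1


def extract_codon_positions(sequence: str, reading_frame_start: int,
                            positions: Iterable[int]) -> str:
    """Keep only the sites whose codon position is in ``positions``.

    Order is preserved; non-base characters (``-``, ``?``, ambiguity
    codes) are classified by their site index and carried through.
    """
    wanted = frozenset(positions)
    if not wanted:
        raise ValueError("positions must be a non-empty subset of {1, 2, 3}")
    if not wanted <= {1, 2, 3}:
        raise ValueError(f"positions must be within {{1, 2, 3}}, got {sorted(wanted)}")
    return "".join(
        ch for i, ch in enumerate(sequence, start=1)
        if site_class(i, reading_frame_start) in wanted)


# ---------------------------------------------------------------------------
# Translation
# ---------------------------------------------------------------------------

def _codon_table(genetic_code: int) -> CodonTable.CodonTable:
    try:
        return CodonTable.unambiguous_dna_by_id[genetic_code]
    except KeyError:
        raise BuildError(f"unsupported genetic code table {genetic_code}") from None


def translate_dna(sequence: str, reading_frame_start: int = 1,
                  genetic_code: int = 1) -> str:
    """Translate a nucleotide string to amino acids.

    Translation starts at ``reading_frame_start`` (bases before it and any
    trailing partial codon are dropped).  Conventions for non-standard
    codons: ``---`` gives ``-``; a codon containing ``?``, or mixing gaps
    with bases, gives ``X``; IUPAC ambiguity codes are expanded and give
    the amino acid if every expansion agrees, else ``X``; stops give ``*``.
    """
    table = _codon_table(genetic_code)
    seq = sequence.upper().replace("U", "T")
    out: list[str] = []
    for i in range(reading_frame_start - 1, len(seq) - 2, 3):
        out.append(_translate_codon(seq[i:i + 3], table))
    return "".join(out)


def _translate_codon(codon: str, table: CodonTable.CodonTable) -> str:
    if codon == "---":
        return GAP
    if "?" in codon or "-" in codon:
        return "X"
    try:
        expansions = ["".join(bases) for bases in _expand_ambiguity(codon)]
    except KeyError:
        return "X"
    amino_acids = set()
    for exp in expansions:
        if exp in table.stop_codons:
            amino_acids.add("*")
        else:
            aa = table.forward_table.get(exp)
            if aa is None:
                return "X"
            amino_acids.add(aa)
    return amino_acids.pop() if len(amino_acids) == 1 else "X"


def _expand_ambiguity(codon: str):
    from itertools import product
    return product(*(ambiguous_dna_values[ch] for ch in codon))


# ---------------------------------------------------------------------------
# Taxon labels
# ---------------------------------------------------------------------------

def make_taxon_label(voucher: VoucherRecord) -> str:
    """``code_Genus_species`` with every non-word character replaced by ``_``."""
    raw = "_".join((voucher.code, voucher.genus, voucher.species))
    return "".join(ch if ch.isascii() and (ch.isalnum() or ch == "_") else "_"
                   for ch in raw)


# ---------------------------------------------------------------------------
# Dataset specification and result
# ---------------------------------------------------------------------------

@dataclass
class DatasetSpec:
    """A user's dataset request.

    ``ingroup`` is either a taxon-set name or an explicit ordered list of
    voucher codes; ``positions`` applies to protein-coding genes and
    defaults to all three codon positions.
    """

    ingroup: str | Sequence[str]
    genes: Sequence[str]
    outgroup: Sequence[str] = ()
    positions: frozenset[int] = frozenset({1, 2, 3})
    datatype: str = "nucleotide"
    partition_scheme: str = "by_gene"
    missing_char: str = MISSING

    def __post_init__(self) -> None:
        self.positions = frozenset(self.positions)

    def validate(self) -> None:
        if not self.genes:
            raise BuildError("dataset must select at least one gene")
        if not self.ingroup:
            raise BuildError("ingroup must be non-empty")
        if self.datatype not in DATATYPES:
            raise BuildError(f"unknown datatype {self.datatype!r}")
        if self.partition_scheme not in PARTITION_SCHEMES:
            raise BuildError(f"unknown partition scheme {self.partition_scheme!r}")
        if not self.positions or not self.positions <= {1, 2, 3}:
            raise BuildError("positions must be a non-empty subset of {1, 2, 3}")
        if self.datatype == "aminoacid":
            if self.partition_scheme in ("by_codon", "pos12_pos3"):
                raise BuildError(
                    "codon-position partition schemes are meaningless for "
                    "amino-acid datasets")
            if self.positions != {1, 2, 3}:
                raise BuildError(
                    "codon-position filtering cannot be combined with "
                    "amino-acid translation")
        if not isinstance(self.ingroup, str):
            overlap = set(self.ingroup) & set(self.outgroup)
            if overlap:
                raise BuildError(
                    f"outgroup and ingroup overlap: {sorted(overlap)}")


@dataclass
class Supermatrix:
    """A concatenated character matrix with a partition table.

    ``partitions`` are ``(name, start, end)`` in 1-based inclusive
    coordinates; they are contiguous, non-overlapping and tile
    ``1..nchar`` exactly.
    """

    taxon_labels: list[str]
    rows: list[str]
    partitions: list[tuple[str, int, int]]
    datatype: str
    warnings: list[str] = field(default_factory=list)

    @property
    def ntax(self) -> int:
        return len(self.taxon_labels)

    @property
    def nchar(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def validate(self) -> None:
        if len(self.rows) != len(self.taxon_labels):
            raise BuildError("row count does not match taxon count")
        if len(set(self.taxon_labels)) != len(self.taxon_labels):
            raise BuildError("taxon labels are not unique")
        nchar = self.nchar
        if any(len(r) != nchar for r in self.rows):
            raise BuildError("rows have unequal lengths")
        expected_start = 1
        for name, start, end in self.partitions:
            if start != expected_start or end < start:
                raise BuildError(f"partition {name!r} ({start}-{end}) breaks tiling")
            expected_start = end + 1
        if self.partitions and self.partitions[-1][2] != nchar:
            raise BuildError("partitions do not cover 1..nchar")


# ---------------------------------------------------------------------------
# Block and matrix assembly
# ---------------------------------------------------------------------------

def _prepare_sequence(seq: str, gene: GeneDefinition, positions: frozenset[int],
                      datatype: str) -> str:
    """Filter/translate one stored sequence for inclusion in a gene block."""
    if datatype == "aminoacid":
        if not gene.is_coding:
            raise BuildError(
                f"gene {gene.name!r} has no reading frame; cannot translate")
        return translate_dna(seq, gene.reading_frame_start, gene.genetic_code)
    if positions != frozenset({1, 2, 3}):
        if not gene.is_coding:
            raise BuildError(
                f"codon-position filtering requires a reading frame, but gene "
                f"{gene.name!r} is non-coding")
        return extract_codon_positions(seq, gene.reading_frame_start, positions)
    return seq


def _pad_chunk(chunks: dict[str, str | None], taxa: Sequence[str],
               missing_char: str, strict: bool, gene_name: str) -> tuple[list[str], int]:
    """Right-pad per-taxon strings to a common block length."""
    lengths = {len(s) for s in chunks.values() if s is not None}
    block_len = max(lengths, default=0)
    if strict and len(lengths) > 1:
        raise BuildError(
            f"unequal sequence lengths for gene {gene_name!r} in strict mode: "
            f"{sorted(lengths)}")
    rows = []
    for t in taxa:
        s = chunks[t]
        if s is None:
            rows.append(missing_char * block_len)
        else:
            rows.append(s + missing_char * (block_len - len(s)))
    return rows, block_len


def build_gene_block(store: Store, gene: GeneDefinition, taxa: Sequence[str],
                     positions: frozenset[int] = frozenset({1, 2, 3}),
                     datatype: str = "nucleotide", *,
                     missing_char: str = MISSING,
                     strict: bool = False) -> tuple[list[str], int, list[str]]:
    """Build one gene's column block over an ordered list of voucher codes.

    Returns ``(rows, block_length, warnings)``.  The block length is that
    of the longest filtered/translated sequence; shorter sequences are
    right-padded with the missing character, and taxa lacking the gene get
    an all-missing row plus a warning.
    """
    if not taxa:
        raise BuildError("taxa list must be non-empty")
    chunks: dict[str, str | None] = {}
    warnings: list[str] = []
    for code in taxa:
        if store.has_sequence(code, gene.name):
            raw = store.get_sequence(code, gene.name).sequence
            chunks[code] = _prepare_sequence(raw, gene, positions, datatype)
        else:
            chunks[code] = None
            warnings.append(f"taxon {code} has no sequence for gene {gene.name}")
    rows, block_len = _pad_chunk(chunks, taxa, missing_char, strict, gene.name)
    if block_len == 0:
        warnings.append(f"gene {gene.name} has no sequence in any selected taxon")
    return rows, block_len, warnings


def _resolve_taxa(spec: DatasetSpec, store: Store) -> list[str]:
    if isinstance(spec.ingroup, str):
        ingroup = list(store.get_taxonset(spec.ingroup).voucher_codes)
    else:
        ingroup = list(spec.ingroup)
    outgroup = list(spec.outgroup)
    overlap = set(outgroup) & set(ingroup)
    if overlap:
        raise BuildError(f"outgroup and ingroup overlap: {sorted(overlap)}")
    taxa = outgroup + ingroup
    if not taxa:
        raise BuildError("dataset resolves to zero taxa")
    for code in taxa:
        store.get_voucher(code)  # raises UnknownRecordError
    return taxa


def build_supermatrix(spec: DatasetSpec, store: Store, *,
                      strict: bool = False) -> Supermatrix:
    """Assemble the full concatenated matrix for a dataset request.

    Taxon order is outgroup codes first, then the ingroup in its given (or
    taxon-set) order.  Genes are concatenated in request order.  Under the
    ``by_codon`` scheme the sites of each gene are reordered so that each
    selected codon position forms a contiguous partition; ``pos12_pos3``
    groups positions 1+2 (original relative order) apart from position 3.
    """
    spec.validate()
    taxa = _resolve_taxa(spec, store)
    genes = [store.get_gene(name) for name in spec.genes]

    labels = [make_taxon_label(store.get_voucher(code)) for code in taxa]
    columns: list[list[str]] = [[] for _ in taxa]
    partitions: list[tuple[str, int, int]] = []
    warnings: list[str] = []
    offset = 0

    for gene in genes:
        # one sub-block per partition unit of this gene under the scheme
        if spec.partition_scheme == "by_codon":
            if not gene.is_coding:
                raise BuildError(
                    f"by_codon partitioning requires a reading frame, but gene "
                    f"{gene.name!r} is non-coding")
            units = [(f"{gene.name}_pos{k}", frozenset({k}))
                     for k in sorted(spec.positions)]
        elif spec.partition_scheme == "pos12_pos3":
            if not gene.is_coding:
                raise BuildError(
                    f"pos12_pos3 partitioning requires a reading frame, but gene "
                    f"{gene.name!r} is non-coding")
            units = []
            p12 = spec.positions & {1, 2}
            if p12:
                units.append((f"{gene.name}_pos12", frozenset(p12)))
            if 3 in spec.positions:
                units.append((f"{gene.name}_pos3", frozenset({3})))
        else:
            units = [(gene.name, spec.positions)]

        gene_missing_warned = False
        for unit_name, unit_positions in units:
            rows, length, block_warnings = build_gene_block(
                store, gene, taxa, unit_positions, spec.datatype,
                missing_char=spec.missing_char, strict=strict)
            if not gene_missing_warned:
                warnings.extend(block_warnings)
                gene_missing_warned = True
            if length == 0:
                continue
            for col, row in zip(columns, rows):
                col.append(row)
            partitions.append((unit_name, offset + 1, offset + length))
            offset += length

    if spec.partition_scheme == "none" and partitions:
        partitions = [("all", 1, offset)]

    matrix = Supermatrix(
        taxon_labels=labels,
        rows=["".join(col) for col in columns],
        partitions=partitions,
        datatype=spec.datatype,
        warnings=warnings)
    matrix.validate()
    return matrix
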