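"""Serialize supermatrices and store slices into analysis-ready files.

Formats produced:

* NEXUS with DATA + SETS blocks and an optional MRBAYES block (charsets,
  partition command, outgroup, mcmc line);
* relaxed PHYLIP plus a RAxML-style partition file;
* TNT ``xread``;
* plain FASTA (80-column wrapped);
* GenBank/Sequin submission FASTA with bracketed source modifiers;
* CSV voucher/accession tables for publication.

Writers are pure functions: the same matrix and options always produce
byte-identical text.  Partition ranges are printed exactly as stored on
the matrix (1-based, inclusive).
"""

from __future__ import annotations

import csv
import io
import re
from dataclasses import dataclass
from typing import Sequence

from .dataset_builder import BuildError, Supermatrix
from .datastore import GeneDefinition, Store

_SAFE_LABEL_RE = re.compile(r"^[A-Za-z0-9_]+$")
FASTA_WIDTH = 80


@dataclass
class MrBayesOptions:
    """Controls the optional MRBAYES block appended to NEXUS output."""

    include_block: bool = False
    outgroup_label: str | None = None
    ngen: int = 1_000_000
    samplefreq: int = 1000

    def validate(self) -> None:
        if self.ngen <= 0 or self.samplefreq <= 0:
            raise ValueError("ngen and samplefreq must be positive")


def _require_nonempty(matrix: Supermatrix) -> None:
    if matrix.ntax == 0 or matrix.nchar == 0:
        raise BuildError("cannot serialize an empty matrix")


def _nexus_label(label: str) -> str:
    """Single-quote a taxon label when it contains unsafe characters."""
    if _SAFE_LABEL_RE.match(label):
        return label
    return "'" + label.replace("'", "''") + "'"


# ---------------------------------------------------------------------------
# NEXUS
# ---------------------------------------------------------------------------

def write_nexus(matrix: Supermatrix, options: MrBayesOptions | None = None) -> str:
    """Render a matrix as a non-interleaved NEXUS file.

    The DATA block carries the matrix, the SETS block one CHARSET per
    partition; with ``options.include_block`` a MRBAYES block repeats the
    charsets, declares the partition scheme and an mcmc line.
    """
    _require_nonempty(matrix)
    options = options or MrBayesOptions()
    options.validate()
    datatype = "DNA" if matrix.datatype == "nucleotide" else "PROTEIN"
    width = max(len(_nexus_label(l)) for l in matrix.taxon_labels)
    lines = [
        "#NEXUS",
        "",
        "BEGIN DATA;",
        f"DIMENSIONS NTAX={matrix.ntax} NCHAR={matrix.nchar};",
        f"FORMAT DATATYPE={datatype} MISSING=? GAP=- INTERLEAVE=NO;",
        "MATRIX",
    ]
    for label, row in zip(matrix.taxon_labels, matrix.rows):
        lines.append(f"{_nexus_label(label):<{width}}  {row}")
    lines += [";", "END;", ""]

    charsets = [f"CHARSET {name} = {start}-{end};"
                for name, start, end in matrix.partitions]
    lines += ["BEGIN SETS;", *charsets, "END;", ""]

    if options.include_block:
        names = [name for name, _, _ in matrix.partitions]
        lines.append("BEGIN MRBAYES;")
        lines += [cs.replace("CHARSET", "charset", 1) for cs in charsets]
        lines.append(f"partition scheme = {len(names)}: {', '.join(names)};")
        lines.append("set partition = scheme;")
        if options.outgroup_label:
            lines.append(f"outgroup {_nexus_label(options.outgroup_label)};")
        lines.append(f"mcmc ngen={options.ngen} samplefreq={options.samplefreq};")
        lines += ["END;", ""]
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# PHYLIP + RAxML partitions
# ---------------------------------------------------------------------------

def write_phylip(matrix: Supermatrix) -> tuple[str, str]:
    """Render relaxed PHYLIP plus a RAxML partition file.

    Relaxed dialect: labels of any length, separated from the row by
    whitespace.  Partition lines are ``DNA, name = start-end`` for
    nucleotide data and ``WAG, name = start-end`` for amino acids.
    """
    _require_nonempty(matrix)
    width = max(len(l) for l in matrix.taxon_labels)
    lines = [f"{matrix.ntax} {matrix.nchar}"]
    for label, row in zip(matrix.taxon_labels, matrix.rows):
        lines.append(f"{label:<{width}}  {row}")
    alignment = "\n".join(lines) + "\n"
    model = "DNA" if matrix.datatype == "nucleotide" else "WAG"
    partition = "".join(f"{model}, {name} = {start}-{end}\n"
                        for name, start, end in matrix.partitions)
    return alignment, partition


# ---------------------------------------------------------------------------
# TNT
# ---------------------------------------------------------------------------

def write_tnt(matrix: Supermatrix) -> str:
    """Render a TNT ``xread`` block (note nchar before ntax)."""
    _require_nonempty(matrix)
    nstates = "nstates dna;" if matrix.datatype == "nucleotide" else "nstates prot;"
    width = max(len(l) for l in matrix.taxon_labels)
    lines = [nstates, "xread", f"{matrix.nchar} {matrix.ntax}"]
    for label, row in zip(matrix.taxon_labels, matrix.rows):
        lines.append(f"{label:<{width}}  {row}")
    lines += [";", ""]
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def _wrap(seq: str, width: int = FASTA_WIDTH) -> list[str]:
    return [seq[i:i + width] for i in range(0, len(seq), width)] or [""]


def write_fasta(records: Supermatrix | Sequence[tuple[str, str]]) -> str:
    """Render label/sequence pairs (or a whole matrix) as 80-column FASTA."""
    if isinstance(records, Supermatrix):
        _require_nonempty(records)
        pairs: Sequence[tuple[str, str]] = list(
            zip(records.taxon_labels, records.rows))
    else:
        pairs = list(records)
    if not pairs:
        raise BuildError("cannot write FASTA for an empty selection")
    out: list[str] = []
    for label, seq in pairs:
        out.append(f">{label}")
        out.extend(_wrap(seq))
    return "\n".join(out) + "\n"


def write_gene_fasta(store: Store, taxa: Sequence[str], gene_name: str) -> str:
    """FASTA of one gene's stored sequences over an ordered taxon list.

    Taxa without the gene are omitted; headers are the voucher codes.
    """
    pairs = [(code, store.get_sequence(code, gene_name).sequence)
             for code in taxa if store.has_sequence(code, gene_name)]
    if not pairs:
        raise BuildError(f"no selected taxon has a sequence for {gene_name!r}")
    return write_fasta(pairs)


# ---------------------------------------------------------------------------
# GenBank submission FASTA
# ---------------------------------------------------------------------------

def write_genbank_submission_fasta(
        store: Store, taxa: Sequence[str], gene: GeneDefinition,
) -> tuple[str, list[str]]:
    """FASTA with Sequin source modifiers for GenBank submission.

    One record per selected taxon that has the gene; headers carry
    ``[organism=...]`` (omitted when genus and species are both empty),
    ``[specimen-voucher=...]`` and, when the gene has a description,
    ``[note=...]``.  Returns ``(text, skipped)`` where ``skipped`` lists
    taxa lacking the gene.
    """
    records: list[tuple[str, str]] = []
    skipped: list[str] = []
    for code in taxa:
        if not store.has_sequence(code, gene.name):
            skipped.append(code)
            continue
        voucher = store.get_voucher(code)
        organism = " ".join(p for p in (voucher.genus, voucher.species) if p)
        header = code
        if organism:
            header += f" [organism={organism}]"
        header += f" [specimen-voucher={code}]"
        if gene.description:
            header += f" [note={gene.description}]"
        records.append((header, store.get_sequence(code, gene.name).sequence))
    if not records:
        raise BuildError(f"no selected taxon has a sequence for {gene.name!r}")
    return write_fasta(records), skipped


# ---------------------------------------------------------------------------
# Publication tables
# ---------------------------------------------------------------------------

def write_voucher_table(store: Store, taxa: Sequence[str],
                        genes: Sequence[str]) -> str:
    """CSV overview table: one row per voucher, one column per gene.

    A gene cell holds the accession if present, else ``"<n> bp"`` when a
    sequence exists without accession, else it is empty.
    """
    if not taxa or not genes:
        raise BuildError("voucher table needs at least one taxon and one gene")
    for g in genes:
        store.get_gene(g)  # raises UnknownRecordError
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(["code", "genus", "species", "country", *genes])
    for code in taxa:
        voucher = store.get_voucher(code)
        cells = [code, voucher.genus, voucher.species, voucher.country or ""]
        for gene in genes:
            if not store.has_sequence(code, gene):
                cells.append("")
                continue
            seq = store.get_sequence(code, gene)
            cells.append(seq.accession if seq.accession else f"{len(seq)} bp")
        writer.writerow(cells)
    return buf.getvalue()


def write_voucher_table_xlsx(store: Store, taxa: Sequence[str],
                             genes: Sequence[str], path: str) -> None:
    """Spreadsheet flavour of :func:`write_voucher_table`."""
    from openpyxl import Workbook

    text = write_voucher_table(store, taxa, genes)
    wb = Workbook()
    ws = wb.active
    ws.title = "vouchers"
    for row in csv.reader(io.StringIO(text)):
        ws.append(row)
    wb.save(path)
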