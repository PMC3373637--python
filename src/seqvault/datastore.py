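"""Persistent store for voucher specimens, gene sequences and taxon sets.

The store is a single SQLite file holding four kinds of records:

* :class:`VoucherRecord` — one physical specimen, identified by a unique
  voucher code, with taxonomy and collection data;
* :class:`GeneDefinition` — per-marker metadata (reading frame, genetic
  code, expected alignment length);
* :class:`SequenceRecord` — one DNA sequence for one (voucher, gene) pair,
  optionally with a GenBank accession and PCR primers;
* :class:`TaxonSet` — a named, ordered list of voucher codes defining the
  taxa of a phylogenetic project.

All writes are committed before the operation returns; the store is
single-writer.  Every mutation goes through validating operations, so a
store on disk always satisfies the domain invariants.
"""

from __future__ import annotations

import csv
import io
import json
import re
import sqlite3
from dataclasses import dataclass, field, fields, replace
from typing import Iterable, Mapping, Sequence

# IUPAC nucleotide one-letter codes, plus alignment gap and missing data.
IUPAC_NUCLEOTIDES = frozenset("ACGTURYSWKMBDHVN")
SEQUENCE_ALPHABET = IUPAC_NUCLEOTIDES | frozenset("-?")

_GENE_NAME_RE = re.compile(r"^\S+$")
_ISO_DATE_RE = re.compile(r"^\d{4}-\d{2}-\d{2}$")


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class StoreError(Exception):
    """Base class for all datastore errors."""


class DuplicateCodeError(StoreError):
    """An identifier (voucher code, gene name, taxon-set name) already exists."""


class UnknownRecordError(StoreError):
    """A referenced voucher, gene, taxon set or search field does not exist."""


class ValidationError(StoreError):
    """A record violates a domain invariant."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VoucherRecord:
    """One physical specimen.  ``code`` is the unique anchor identifier."""

    code: str
    genus: str = ""
    species: str = ""
    subspecies: str | None = None
    order: str | None = None
    family: str | None = None
    subfamily: str | None = None
    tribe: str | None = None
    country: str | None = None
    specific_locality: str | None = None
    latitude: float | None = None
    longitude: float | None = None
    collector: str | None = None
    collection_date: str | None = None
    notes: str | None = None
    unidentified: bool = False

    def validate(self) -> None:
        if not self.code:
            raise ValidationError("voucher code must be non-empty")
        if self.latitude is not None and not -90.0 <= self.latitude <= 90.0:
            raise ValidationError(
                f"latitude {self.latitude} outside [-90, 90] for voucher {self.code!r}")
        if self.longitude is not None and not -180.0 <= self.longitude <= 180.0:
            raise ValidationError(
                f"longitude {self.longitude} outside [-180, 180] for voucher {self.code!r}")
        if not self.genus and not self.species and not self.unidentified:
            raise ValidationError(
                f"voucher {self.code!r} has empty genus and species but is not "
                "flagged as unidentified")
        if self.collection_date is not None and not _ISO_DATE_RE.match(self.collection_date):
            raise ValidationError(
                f"collection_date {self.collection_date!r} is not ISO-8601 (YYYY-MM-DD)")


#: Voucher fields that may appear as batch-import columns and search keys.
VOUCHER_FIELDS: tuple[str, ...] = tuple(
    f.name for f in fields(VoucherRecord) if f.name != "unidentified")


@dataclass(frozen=True)
class GeneDefinition:
    """Per-marker metadata.

    ``reading_frame_start`` is the 1-based site index of the first complete
    codon; absent means the marker is non-coding.  ``genetic_code`` is an
    NCBI translation-table number (1 = standard, 2 = vertebrate mito,
    5 = invertebrate mito, ...).
    """

    name: str
    description: str | None = None
    reading_frame_start: int | None = None
    genetic_code: int = 1
    expected_length: int | None = None

    def validate(self) -> None:
        if not self.name or not _GENE_NAME_RE.match(self.name):
            raise ValidationError(
                f"gene name {self.name!r} must be non-empty and contain no whitespace")
        if self.reading_frame_start is not None and self.reading_frame_start not in (1, 2, 3):
            raise ValidationError(
                f"reading_frame_start must be 1, 2 or 3, got {self.reading_frame_start}")

    @property
    def is_coding(self) -> bool:
        return self.reading_frame_start is not None


@dataclass(frozen=True)
class PrimerPair:
    forward_name: str
    forward_seq: str
    reverse_name: str
    reverse_seq: str

    def validate(self) -> None:
        for label, seq in (("forward", self.forward_seq), ("reverse", self.reverse_seq)):
            bad = set(seq.upper()) - IUPAC_NUCLEOTIDES
            if bad:
                raise ValidationError(
                    f"{label} primer {seq!r} contains non-IUPAC characters {sorted(bad)}")


@dataclass(frozen=True)
class SequenceRecord:
    """One gene sequence attached to one voucher.

    The sequence is stored upper-cased over the IUPAC nucleotide alphabet
    plus ``-`` (gap) and ``?`` (missing).  Length is always derived from the
    stored string, never stored separately.
    """

    voucher_code: str
    gene_name: str
    sequence: str
    accession: str | None = None
    lab_notes: str | None = None
    primers: tuple[PrimerPair, ...] = ()

    def normalized(self) -> "SequenceRecord":
        return replace(self, sequence=self.sequence.upper())

    def validate(self) -> None:
        bad = set(self.sequence.upper()) - SEQUENCE_ALPHABET
        if bad:
            raise ValidationError(
                f"sequence for ({self.voucher_code}, {self.gene_name}) contains "
                f"invalid characters {sorted(bad)}")
        for p in self.primers:
            p.validate()

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class TaxonSet:
    name: str
    voucher_codes: tuple[str, ...]


@dataclass
class ImportReport:
    """Outcome of one batch import.

    ``rejected_rows`` holds ``(line_number, reason)`` for rows skipped
    whole; ``rejected_cells`` holds ``(line_number, gene, reason)`` for
    sequence cells rejected within otherwise accepted rows.
    """

    vouchers_created: int = 0
    vouchers_updated: int = 0
    sequences_created: int = 0
    rejected_rows: list[tuple[int, str]] = field(default_factory=list)
    rejected_cells: list[tuple[int, str, str]] = field(default_factory=list)

    @property
    def rejected(self) -> int:
        return len(self.rejected_rows)


# ---------------------------------------------------------------------------
# The store
# ---------------------------------------------------------------------------

_SCHEMA = """
CREATE TABLE IF NOT EXISTS vouchers (
    code TEXT PRIMARY KEY,
    genus TEXT NOT NULL DEFAULT '',
    species TEXT NOT NULL DEFAULT '',
    subspecies TEXT,
    "order" TEXT, family TEXT, subfamily TEXT, tribe TEXT,
    country TEXT, specific_locality TEXT,
    latitude REAL, longitude REAL,
    collector TEXT, collection_date TEXT, notes TEXT,
    unidentified INTEGER NOT NULL DEFAULT 0
);
CREATE TABLE IF NOT EXISTS genes (
    name TEXT PRIMARY KEY,
    description TEXT,
    reading_frame_start INTEGER,
    genetic_code INTEGER NOT NULL DEFAULT 1,
    expected_length INTEGER
);
CREATE TABLE IF NOT EXISTS sequences (
    voucher_code TEXT NOT NULL REFERENCES vouchers(code),
    gene_name TEXT NOT NULL REFERENCES genes(name),
    sequence TEXT NOT NULL,
    accession TEXT, lab_notes TEXT,
    primers TEXT NOT NULL DEFAULT '[]',
    PRIMARY KEY (voucher_code, gene_name)
);
CREATE TABLE IF NOT EXISTS taxon_sets (
    name TEXT PRIMARY KEY
);
CREATE TABLE IF NOT EXISTS taxon_set_members (
    set_name TEXT NOT NULL REFERENCES taxon_sets(name),
    position INTEGER NOT NULL,
    voucher_code TEXT NOT NULL REFERENCES vouchers(code),
    PRIMARY KEY (set_name, position)
);
"""


class Store:
    """Single-file voucher/sequence store.

    Parameters
    ----------
    path
        SQLite file path, or ``":memory:"`` for a transient store.
    """

    def __init__(self, path: str = ":memory:"):
        self.path = path
        self._conn = sqlite3.connect(path)
        self._conn.row_factory = sqlite3.Row
        self._conn.executescript(_SCHEMA)
        self._conn.commit()

    # -- lifecycle ---------------------------------------------------------

    def close(self) -> None:
        self._conn.close()

    def __enter__(self) -> "Store":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    # -- vouchers ----------------------------------------------------------

    def add_voucher(self, record: VoucherRecord) -> VoucherRecord:
        record.validate()
        if self._voucher_exists(record.code):
            raise DuplicateCodeError(
                f"voucher code {record.code!r} already exists and cannot be overwritten")
        self._insert_voucher(record)
        self._conn.commit()
        return record

    def get_voucher(self, code: str) -> VoucherRecord:
        row = self._conn.execute(
            "SELECT * FROM vouchers WHERE code = ?", (code,)).fetchone()
        if row is None:
            raise UnknownRecordError(f"unknown voucher code {code!r}")
        return _voucher_from_row(row)

    def list_vouchers(self) -> list[VoucherRecord]:
        rows = self._conn.execute("SELECT * FROM vouchers ORDER BY code").fetchall()
        return [_voucher_from_row(r) for r in rows]

    def update_voucher(self, record: VoucherRecord) -> VoucherRecord:
        """Replace the stored record with the same code."""
        record.validate()
        if not self._voucher_exists(record.code):
            raise UnknownRecordError(f"unknown voucher code {record.code!r}")
        self._conn.execute("DELETE FROM vouchers WHERE code = ?", (record.code,))
        self._insert_voucher(record)
        self._conn.commit()
        return record

    def rename_voucher(self, old_code: str, new_code: str) -> VoucherRecord:
        """Change a voucher code, cascading to sequences and taxon sets."""
        if not new_code:
            raise ValidationError("new voucher code must be non-empty")
        if not self._voucher_exists(old_code):
            raise UnknownRecordError(f"unknown voucher code {old_code!r}")
        if self._voucher_exists(new_code):
            raise DuplicateCodeError(f"voucher code {new_code!r} already exists")
        cur = self._conn
        cur.execute("UPDATE vouchers SET code = ? WHERE code = ?", (new_code, old_code))
        cur.execute("UPDATE sequences SET voucher_code = ? WHERE voucher_code = ?",
                    (new_code, old_code))
        cur.execute("UPDATE taxon_set_members SET voucher_code = ? WHERE voucher_code = ?",
                    (new_code, old_code))
        cur.commit()
        return self.get_voucher(new_code)

    def delete_voucher(self, code: str, cascade: bool = False) -> None:
        """Delete a voucher; refused while sequences reference it unless
        ``cascade`` is set.  Taxon-set memberships are always removed."""
        if not self._voucher_exists(code):
            raise UnknownRecordError(f"unknown voucher code {code!r}")
        n_seq = self._conn.execute(
            "SELECT COUNT(*) FROM sequences WHERE voucher_code = ?", (code,)).fetchone()[0]
        if n_seq and not cascade:
            raise ValidationError(
                f"voucher {code!r} has {n_seq} sequence(s); delete them first or "
                "pass cascade=True")
        self._conn.execute("DELETE FROM sequences WHERE voucher_code = ?", (code,))
        self._conn.execute("DELETE FROM taxon_set_members WHERE voucher_code = ?", (code,))
        self._conn.execute("DELETE FROM vouchers WHERE code = ?", (code,))
        self._conn.commit()

    # -- genes -------------------------------------------------------------

    def add_gene(self, gene: GeneDefinition) -> GeneDefinition:
        gene.validate()
        if self._conn.execute(
                "SELECT 1 FROM genes WHERE name = ?", (gene.name,)).fetchone():
            raise DuplicateCodeError(f"gene {gene.name!r} already defined")
        self._conn.execute(
            "INSERT INTO genes VALUES (?,?,?,?,?)",
            (gene.name, gene.description, gene.reading_frame_start,
             gene.genetic_code, gene.expected_length))
        self._conn.commit()
        return gene

    def get_gene(self, name: str) -> GeneDefinition:
        row = self._conn.execute("SELECT * FROM genes WHERE name = ?", (name,)).fetchone()
        if row is None:
            raise UnknownRecordError(f"unknown gene {name!r}")
        return GeneDefinition(
            name=row["name"], description=row["description"],
            reading_frame_start=row["reading_frame_start"],
            genetic_code=row["genetic_code"], expected_length=row["expected_length"])

    def list_genes(self) -> list[GeneDefinition]:
        names = [r["name"] for r in
                 self._conn.execute("SELECT name FROM genes ORDER BY name")]
        return [self.get_gene(n) for n in names]

    # -- sequences ---------------------------------------------------------

    def add_sequence(self, record: SequenceRecord) -> SequenceRecord:
        record = record.normalized()
        record.validate()
        if not self._voucher_exists(record.voucher_code):
            raise UnknownRecordError(f"unknown voucher code {record.voucher_code!r}")
        self.get_gene(record.gene_name)  # raises UnknownRecordError
        if self._conn.execute(
                "SELECT 1 FROM sequences WHERE voucher_code = ? AND gene_name = ?",
                (record.voucher_code, record.gene_name)).fetchone():
            raise DuplicateCodeError(
                f"a sequence for ({record.voucher_code}, {record.gene_name}) "
                "already exists")
        self._conn.execute(
            "INSERT INTO sequences VALUES (?,?,?,?,?,?)",
            (record.voucher_code, record.gene_name, record.sequence,
             record.accession, record.lab_notes,
             json.dumps([vars(p) for p in record.primers])))
        self._conn.commit()
        return record

    def get_sequence(self, voucher_code: str, gene_name: str) -> SequenceRecord:
        row = self._conn.execute(
            "SELECT * FROM sequences WHERE voucher_code = ? AND gene_name = ?",
            (voucher_code, gene_name)).fetchone()
        if row is None:
            raise UnknownRecordError(
                f"no sequence for ({voucher_code!r}, {gene_name!r})")
        return _sequence_from_row(row)

    def has_sequence(self, voucher_code: str, gene_name: str) -> bool:
        return self._conn.execute(
            "SELECT 1 FROM sequences WHERE voucher_code = ? AND gene_name = ?",
            (voucher_code, gene_name)).fetchone() is not None

    def sequences_for_voucher(self, voucher_code: str) -> list[SequenceRecord]:
        rows = self._conn.execute(
            "SELECT * FROM sequences WHERE voucher_code = ? ORDER BY gene_name",
            (voucher_code,)).fetchall()
        return [_sequence_from_row(r) for r in rows]

    def delete_sequence(self, voucher_code: str, gene_name: str) -> None:
        self.get_sequence(voucher_code, gene_name)
        self._conn.execute(
            "DELETE FROM sequences WHERE voucher_code = ? AND gene_name = ?",
            (voucher_code, gene_name))
        self._conn.commit()

    # -- search ------------------------------------------------------------

    def search_vouchers(self, criteria: Mapping[str, str]) -> list[VoucherRecord]:
        """Conjunctive multi-field search.

        Every criterion is a case-insensitive substring match against the
        named voucher field; the special key ``"gene"`` matches vouchers
        that have a stored sequence for a gene whose name contains the
        query.  Results are ordered by voucher code.
        """
        for key in criteria:
            if key != "gene" and key not in VOUCHER_FIELDS:
                raise UnknownRecordError(f"unknown search field {key!r}")
        clauses: list[str] = []
        params: list[str] = []
        for key, query in criteria.items():
            pat = "%" + _escape_like(str(query)) + "%"
            if key == "gene":
                clauses.append(
                    "EXISTS (SELECT 1 FROM sequences s WHERE s.voucher_code = "
                    "vouchers.code AND s.gene_name LIKE ? ESCAPE '\\' COLLATE NOCASE)")
            else:
                col = f'"{key}"' if key == "order" else key
                clauses.append(
                    f"COALESCE(CAST({col} AS TEXT), '') LIKE ? ESCAPE '\\' COLLATE NOCASE")
            params.append(pat)
        sql = "SELECT * FROM vouchers"
        if clauses:
            sql += " WHERE " + " AND ".join(clauses)
        sql += " ORDER BY code"
        return [_voucher_from_row(r) for r in self._conn.execute(sql, params)]

    # -- batch import ------------------------------------------------------

    def batch_import(self, table_text: str) -> ImportReport:
        """Import a tab-delimited table with a header row.

        Header columns must be voucher field names or defined gene names
        (gene columns hold sequences).  Rows failing validation are
        rejected individually and never abort the batch.  For an existing
        voucher only empty fields are filled in; non-empty stored fields
        are never overwritten.  A sequence cell colliding with a stored
        (voucher, gene) pair is rejected for that cell only.
        """
        if not table_text.strip():
            raise ValidationError("empty import table")
        reader = csv.reader(io.StringIO(table_text), delimiter="\t")
        rows = list(reader)
        header = [h.strip() for h in rows[0]]
        gene_names = {g.name for g in self.list_genes()}
        gene_cols: list[tuple[int, str]] = []
        field_cols: list[tuple[int, str]] = []
        for i, col in enumerate(header):
            if col in VOUCHER_FIELDS:
                field_cols.append((i, col))
            elif col in gene_names:
                gene_cols.append((i, col))
            else:
                raise ValidationError(
                    f"header column {col!r} is neither a voucher field nor a defined gene")
        if "code" not in (c for _, c in field_cols):
            raise ValidationError("import table must have a 'code' column")

        report = ImportReport()
        for line_no, row in enumerate(rows[1:], start=2):
            if not any(cell.strip() for cell in row):
                continue
            values = {col: (row[i].strip() if i < len(row) else "")
                      for i, col in field_cols}
            code = values.get("code", "")
            if not code:
                report.rejected_rows.append((line_no, "missing voucher code"))
                continue
            try:
                voucher = _voucher_from_strings(values)
            except ValidationError as exc:
                report.rejected_rows.append((line_no, str(exc)))
                continue
            try:
                if self._voucher_exists(code):
                    merged = _merge_empty_fields(self.get_voucher(code), voucher)
                    if merged != self.get_voucher(code):
                        self.update_voucher(merged)
                        report.vouchers_updated += 1
                else:
                    self.add_voucher(voucher)
                    report.vouchers_created += 1
            except StoreError as exc:
                report.rejected_rows.append((line_no, str(exc)))
                continue
            for i, gene in gene_cols:
                seq = row[i].strip() if i < len(row) else ""
                if not seq:
                    continue
                try:
                    self.add_sequence(SequenceRecord(code, gene, seq))
                    report.sequences_created += 1
                except StoreError as exc:
                    report.rejected_cells.append((line_no, gene, str(exc)))
        return report

    # -- taxon sets --------------------------------------------------------

    def create_taxonset(self, name: str, codes: Sequence[str]) -> TaxonSet:
        """Create a named ordered taxon set; duplicates keep first occurrence."""
        if not name:
            raise ValidationError("taxon-set name must be non-empty")
        if self._conn.execute(
                "SELECT 1 FROM taxon_sets WHERE name = ?", (name,)).fetchone():
            raise DuplicateCodeError(f"taxon set {name!r} already exists")
        ordered = _dedup_keep_first(codes)
        for code in ordered:
            if not self._voucher_exists(code):
                raise UnknownRecordError(f"unknown voucher code {code!r}")
        self._conn.execute("INSERT INTO taxon_sets VALUES (?)", (name,))
        self._conn.executemany(
            "INSERT INTO taxon_set_members VALUES (?,?,?)",
            [(name, i, c) for i, c in enumerate(ordered)])
        self._conn.commit()
        return TaxonSet(name, tuple(ordered))

    def append_to_taxonset(self, name: str, codes: Sequence[str]) -> TaxonSet:
        existing = self.get_taxonset(name)
        for code in codes:
            if not self._voucher_exists(code):
                raise UnknownRecordError(f"unknown voucher code {code!r}")
        merged = _dedup_keep_first(list(existing.voucher_codes) + list(codes))
        self._conn.execute("DELETE FROM taxon_set_members WHERE set_name = ?", (name,))
        self._conn.executemany(
            "INSERT INTO taxon_set_members VALUES (?,?,?)",
            [(name, i, c) for i, c in enumerate(merged)])
        self._conn.commit()
        return TaxonSet(name, tuple(merged))

    def get_taxonset(self, name: str) -> TaxonSet:
        if not self._conn.execute(
                "SELECT 1 FROM taxon_sets WHERE name = ?", (name,)).fetchone():
            raise UnknownRecordError(f"unknown taxon set {name!r}")
        rows = self._conn.execute(
            "SELECT voucher_code FROM taxon_set_members WHERE set_name = ? "
            "ORDER BY position", (name,)).fetchall()
        return TaxonSet(name, tuple(r["voucher_code"] for r in rows))

    def list_taxonsets(self) -> list[TaxonSet]:
        names = [r["name"] for r in
                 self._conn.execute("SELECT name FROM taxon_sets ORDER BY name")]
        return [self.get_taxonset(n) for n in names]

    # -- internals ---------------------------------------------------------

    def _voucher_exists(self, code: str) -> bool:
        return self._conn.execute(
            "SELECT 1 FROM vouchers WHERE code = ?", (code,)).fetchone() is not None

    def _insert_voucher(self, record: VoucherRecord) -> None:
        self._conn.execute(
            "INSERT INTO vouchers VALUES (?,?,?,?,?,?,?,?,?,?,?,?,?,?,?,?)",
            (record.code, record.genus, record.species, record.subspecies,
             record.order, record.family, record.subfamily, record.tribe,
             record.country, record.specific_locality,
             record.latitude, record.longitude,
             record.collector, record.collection_date, record.notes,
             int(record.unidentified)))


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _escape_like(text: str) -> str:
    return text.replace("\\", "\\\\").replace("%", "\\%").replace("_", "\\_")


def _dedup_keep_first(codes: Iterable[str]) -> list[str]:
    seen: set[str] = set()
    out: list[str] = []
    for c in codes:
        if c not in seen:
            seen.add(c)
            out.append(c)
    return out


def _voucher_from_row(row: sqlite3.Row) -> VoucherRecord:
    d = dict(row)
    d["unidentified"] = bool(d["unidentified"])
    return VoucherRecord(**d)


def _sequence_from_row(row: sqlite3.Row) -> SequenceRecord:
    primers = tuple(PrimerPair(**p) for p in json.loads(row["primers"]))
    return SequenceRecord(
        voucher_code=row["voucher_code"], gene_name=row["gene_name"],
        sequence=row["sequence"], accession=row["accession"],
        lab_notes=row["lab_notes"], primers=primers)


def _voucher_from_strings(values: Mapping[str, str]) -> VoucherRecord:
    """Build a VoucherRecord from string-valued import cells."""
    kwargs: dict[str, object] = {}
    for key, raw in values.items():
        if raw == "":
            continue
        if key in ("latitude", "longitude"):
            try:
                kwargs[key] = float(raw)
            except ValueError:
                raise ValidationError(f"{key} {raw!r} is not a number") from None
        else:
            kwargs[key] = raw
    record = VoucherRecord(**kwargs)  # type: ignore[arg-type]
    if not record.genus and not record.species:
        record = replace(record, unidentified=True)
    record.validate()
    return record


def _merge_empty_fields(stored: VoucherRecord, incoming: VoucherRecord) -> VoucherRecord:
    """Fill empty fields of ``stored`` from ``incoming``; never overwrite."""
    updates: dict[str, object] = {}
    for f in fields(VoucherRecord):
        if f.name in ("code", "unidentified"):
            continue
        current = getattr(stored, f.name)
        new = getattr(incoming, f.name)
        if (current is None or current == "") and new not in (None, ""):
            updates[f.name] = new
    if not updates:
        return stored
    merged = replace(stored, **updates)
    if merged.genus or merged.species:
        merged = replace(merged, unidentified=False)
    return merged
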