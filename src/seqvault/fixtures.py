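"""Deterministic synthetic stores for tests, demos and benchmarking.

The generator emulates a single-lab molecular-systematics project: a few
dozen voucher specimens with toy Lepidoptera taxonomy and collection data,
and per-marker sequences with realistic missing-data patterns.  Sequences
carry no phylogenetic signal — they are i.i.d. random nucleotides, except
that protein-coding markers are built codon-wise from non-stop codons so
translation under the declared genetic code is stop-free.

Everything is inserted through the public :class:`~seqvault.datastore.Store`
operations, so generated stores always satisfy the domain invariants.
"""

from __future__ import annotations

import itertools
import random
from dataclasses import dataclass, field
from typing import Sequence

from Bio.Data import CodonTable

from .datastore import (GeneDefinition, SequenceRecord, Store, ValidationError,
                        VoucherRecord)

# Toy taxonomy: butterfly and moth genera, enough to label a few dozen taxa.
TOY_TAXA: tuple[tuple[str, str], ...] = (
    ("Papilio", "machaon"), ("Pieris", "napi"), ("Pieris", "brassicae"),
    ("Colias", "croceus"), ("Lycaena", "phlaeas"), ("Polyommatus", "icarus"),
    ("Vanessa", "atalanta"), ("Vanessa", "cardui"), ("Aglais", "urticae"),
    ("Nymphalis", "antiopa"), ("Argynnis", "paphia"), ("Melitaea", "cinxia"),
    ("Pararge", "aegeria"), ("Maniola", "jurtina"), ("Coenonympha", "pamphilus"),
    ("Erebia", "ligea"), ("Hesperia", "comma"), ("Thymelicus", "lineola"),
    ("Zygaena", "filipendulae"), ("Autographa", "gamma"), ("Noctua", "pronuba"),
    ("Biston", "betularia"), ("Operophtera", "brumata"), ("Tortrix", "viridana"),
)

_COUNTRIES = ("Finland", "Sweden", "Estonia", "Norway", "Germany", "Spain")
_COLLECTORS = ("A. Aurivillius", "B. Wahlberg", "C. Nylund", "D. Kaila")


@dataclass(frozen=True)
class GeneFixture:
    """One marker to simulate: name, alignment length, frame, genetic code."""

    name: str
    length: int
    reading_frame_start: int | None = 1
    genetic_code: int = 1


#: Default marker panel: mitochondrial barcode plus two nuclear coding
#: markers and one non-coding spacer, at their customary lengths.
DEFAULT_GENES: tuple[GeneFixture, ...] = (
    GeneFixture("COI", 658, 1, 5),
    GeneFixture("EF1a", 1240, 1, 1),
    GeneFixture("wingless", 412, 1, 1),
    GeneFixture("ITS2", 480, None, 1),
)


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic store.

    ``missing_rate`` is the probability that a (taxon, gene) pair has no
    sequence; ``accession_rate`` the probability a stored sequence carries
    a synthetic accession.  The same seed always yields a byte-identical
    store.
    """

    n_taxa: int = 20
    genes: tuple[GeneFixture, ...] = DEFAULT_GENES
    missing_rate: float = 0.15
    accession_rate: float = 0.7
    seed: int = 0

    def validate(self) -> None:
        if self.n_taxa < 1:
            raise ValidationError("n_taxa must be >= 1")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValidationError("missing_rate must be in [0, 1)")
        if not 0.0 <= self.accession_rate <= 1.0:
            raise ValidationError("accession_rate must be in [0, 1]")
        if not self.genes:
            raise ValidationError("at least one gene is required")
        for g in self.genes:
            if g.length < 3:
                raise ValidationError(f"gene {g.name!r} length must be >= 3")


def _random_coding_sequence(rng: random.Random, length: int, frame: int,
                            genetic_code: int) -> str:
    """Random nucleotides of ``length`` whose complete codons are non-stop."""
    table = CodonTable.unambiguous_dna_by_id[genetic_code]
    sense_codons = sorted(table.forward_table)
    bases = "ACGT"
    leading = "".join(rng.choice(bases) for _ in range(frame - 1))
    n_codons, n_tail = divmod(length - len(leading), 3)
    body = "".join(rng.choice(sense_codons) for _ in range(n_codons))
    tail = "".join(rng.choice(bases) for _ in range(n_tail))
    return leading + body + tail


def _random_sequence(rng: random.Random, length: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(length))


def generate_store(spec: FixtureSpec = FixtureSpec(),
                   path: str = ":memory:") -> Store:
    """Create and populate a store according to ``spec``.

    Vouchers are coded ``T001..``, taxonomy cycles through the built-in
    toy list, and coordinates stay within valid ranges.
    """
    spec.validate()
    rng = random.Random(spec.seed)
    store = Store(path)
    for g in spec.genes:
        store.add_gene(GeneDefinition(
            name=g.name,
            description=f"{g.name} marker (synthetic)",
            reading_frame_start=g.reading_frame_start,
            genetic_code=g.genetic_code,
            expected_length=g.length))

    taxa = itertools.cycle(TOY_TAXA)
    accession_counter = itertools.count(1)
    for i in range(1, spec.n_taxa + 1):
        genus, species = next(taxa)
        code = f"T{i:03d}"
        store.add_voucher(VoucherRecord(
            code=code, genus=genus, species=species,
            order="Lepidoptera",
            country=rng.choice(_COUNTRIES),
            latitude=round(rng.uniform(35.0, 69.0), 4),
            longitude=round(rng.uniform(-9.0, 31.0), 4),
            collector=rng.choice(_COLLECTORS),
            collection_date=f"{rng.randrange(1995, 2012)}-"
                            f"{rng.randrange(1, 13):02d}-{rng.randrange(1, 29):02d}"))
        for g in spec.genes:
            if rng.random() < spec.missing_rate:
                continue
            if g.reading_frame_start is not None:
                seq = _random_coding_sequence(
                    rng, g.length, g.reading_frame_start, g.genetic_code)
            else:
                seq = _random_sequence(rng, g.length)
            accession = None
            if rng.random() < spec.accession_rate:
                accession = f"SYN{next(accession_counter):04d}"
            store.add_sequence(SequenceRecord(
                voucher_code=code, gene_name=g.name,
                sequence=seq, accession=accession))
    return store
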