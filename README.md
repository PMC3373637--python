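# seqvault

Voucher-and-sequence management for molecular systematics, as a Python
library and CLI. seqvault keeps the working data of a phylogenetics
project — voucher specimens, per-marker DNA sequences, gene definitions
and taxon sets — in a single SQLite file, and turns any selection of taxa
and markers into ready-to-run datasets: NEXUS (with CHARSET and MrBayes
blocks), relaxed PHYLIP with a RAxML partition file, TNT `xread`, FASTA,
GenBank/Sequin submission FASTA, and CSV/XLSX publication tables.

It is aimed at researchers who sequence a handful of markers across tens
to hundreds of specimens and repeatedly need the same bookkeeping:
unique, renameable voucher codes with rename cascading to sequences and
taxon sets; batch import of tab-delimited spreadsheets; conjunctive
multi-field search; and supermatrix assembly with codon-position
filtering, amino-acid translation and partition schemes.

## The core constructions

**Codon positions.** A gene's reading frame start `f ∈ {1,2,3}` is the
1-based index of its first complete codon; site `i` has codon position
`((i − f) mod 3) + 1` (non-negative modulus, so leading bases before the
first codon are classified cyclically). Position filtering keeps exactly
the sites of the requested classes, in order, carrying gaps (`-`),
missing data (`?`) and ambiguity codes through unchanged.

**Supermatrix.** Taxa are ordered outgroup first, then ingroup; genes are
concatenated in request order. Per gene the block length is the longest
filtered (or translated) sequence; shorter sequences are right-padded
with `?`, and taxa lacking the gene get an all-`?` block plus a warning.
Partition schemes: `none`, `by_gene`, `by_codon` (sites reordered so each
codon position is a contiguous CHARSET range) and `pos12_pos3`
(positions 1+2 vs 3). Partitions are 1-based, inclusive, and always tile
`1..nchar`.

**Translation.** Amino-acid datasets are translated on the fly under any
NCBI genetic code shipped with Biopython (`---` → `-`; codons with `?` or
gap/base mixtures → `X`; ambiguity codes resolved when all expansions
agree; stops → `*`).

## Worked example

```
$ seqvault --store project.db init
initialized store at project.db
$ seqvault --store project.db fixtures --n-taxa 12 --seed 7
populated store project.db with 12 taxa, 4 genes (seed 7)
$ seqvault --store project.db taxonset create ms1 T003,T004,T005,T006,T007,T008
taxon set ms1: 6 members
$ seqvault --store project.db dataset --taxonset ms1 --outgroup T001 \
    --genes COI,EF1a --partition by_codon --format nexus,phylip --mrbayes
warning: taxon T003 has no sequence for gene COI
warning: taxon T004 has no sequence for gene COI
7 taxa x 1898 characters, 6 partition(s)
ms1_nucleotide.nex
ms1_nucleotide.partitions
ms1_nucleotide.phy
```

The 7 taxa are the outgroup voucher T001 followed by the six `ms1`
members; 1898 characters are COI (658 bp) + EF1a (1240 bp). Under
`by_codon` each gene is split into three contiguous codon-position
partitions, so `ms1_nucleotide.partitions` reads:

```
DNA, COI_pos1 = 1-220
DNA, COI_pos2 = 221-439
DNA, COI_pos3 = 440-658
DNA, EF1a_pos1 = 659-1072
DNA, EF1a_pos2 = 1073-1485
DNA, EF1a_pos3 = 1486-1898
```

The warnings (T003 and T004 lack COI in this synthetic project) go to
standard error only; in the matrix those blocks are filled with `?`. The
same pipeline is available as library calls:

```python
from seqvault import DatasetSpec, Store, build_supermatrix, write_nexus

store = Store("project.db")
spec = DatasetSpec(ingroup="ms1", outgroup=["T001"], genes=["COI", "EF1a"],
                   partition_scheme="by_codon")
matrix = build_supermatrix(spec, store)
print(matrix.ntax, matrix.nchar)        # 7 1898
open("ms1.nex", "w").write(write_nexus(matrix))
```

See `docs/methods.md` for the full account of conventions (reading
frames, padding, translation edge cases, the synthetic-data generator)
and `seqvault --help` for the remaining subcommands (`import`, `search`,
`table`, `genbank-fasta`, ...).

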