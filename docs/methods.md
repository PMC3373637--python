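# Methods

## What seqvault models

seqvault is the data-management layer of a molecular-systematics project:
a single-file relational store of voucher specimens (the physical animals
or plants DNA was extracted from), per-marker DNA sequences, gene
definitions and named taxon sets, plus a builder that turns a selection of
taxa and markers into a concatenated character matrix ("supermatrix")
ready to run in MrBayes, RAxML or TNT.

The anchor record is the voucher code: it is unique, can never be
silently overwritten, but can be renamed, in which case the rename
cascades to every sequence and taxon-set membership that references it.
One sequence is stored per (voucher, gene) pair, upper-cased over the
IUPAC nucleotide alphabet plus `-` (alignment gap) and `?` (missing
data); sequence length is always derived, never stored.

## Codon-position arithmetic

Each gene definition may carry a reading frame start `f ∈ {1, 2, 3}` —
the 1-based index of the first complete codon in the stored alignment.
Site `i` is assigned codon position

    class(i) = ((i − f) mod 3) + 1

with the non-negative mathematical modulus. Bases *before* the first
complete codon therefore receive cyclically extended classes (for `f = 2`,
site 1 has class 3) rather than being discarded; either convention is
defensible, this one is total and keeps position filtering a pure
per-site operation. Classification is purely positional: gaps, `?` and
ambiguity codes occupy sites like any base and are carried through
filtering unchanged.

Position filtering preserves site order, so for any sequence the three
single-position extracts partition it exactly (length conservation), and
the full set `{1,2,3}` is the identity. Both are enforced as property
tests.

## Translation

Amino-acid datasets are translated on the fly (sequences are stored as
DNA only). Translation starts at the reading frame start — bases before
it and any trailing partial codon are dropped — and uses the NCBI
translation tables as shipped by Biopython (`Bio.Data.CodonTable`); any
table Biopython knows is supported, and tables 1 (standard), 2
(vertebrate mitochondrial) and 5 (invertebrate mitochondrial) are
exercised in the tests. Conventions for non-standard codons, chosen so
that translation is total over the stored alphabet:

* `---` → `-` (an all-gap codon stays a gap);
* any codon containing `?`, or mixing `-` with bases, → `X`;
* IUPAC ambiguity codes are expanded; if every expansion agrees on one
  amino acid (or all are stops) that residue is emitted, otherwise `X`;
* stop codons → `*`;
* `U` is accepted and treated as `T`.

## Supermatrix assembly

Taxon order is the outgroup codes in their given order, then the ingroup
in its given (or taxon-set) order; outgroup-first matters because the
MrBayes block names the first outgroup taxon. Row labels are
`code_Genus_species` with every character outside `[A-Za-z0-9_]`
replaced by `_`; uniqueness follows from code uniqueness.

Per gene, the block length is the length of the longest
filtered/translated sequence among the selected taxa; shorter sequences
are right-padded with `?`. This is deliberately permissive — the store
does not require sequences to be pre-aligned — and a `strict=True` flag
turns unequal lengths into an error for users who guarantee aligned
input. A taxon lacking a gene receives an all-`?` block and a warning
naming taxon and gene; a gene absent from every selected taxon
contributes zero columns, a warning, and no partition entry, so the
partition table always tiles `1..nchar` exactly.

Partition schemes:

* `none` — one block `all`;
* `by_gene` — one block per gene, in request order;
* `by_codon` — per gene × selected codon position, named `gene_posK`.
  Sites are **reordered** so each partition is a contiguous range (the
  form CHARSET and RAxML partition files consume); the original order is
  recoverable from the partition metadata and the frame;
* `pos12_pos3` — per gene, positions 1+2 in original relative order,
  then position 3; the canonical protein-coding scheme.

The codon-based schemes and any position subset other than `{1,2,3}`
require every selected gene to have a reading frame. Amino-acid datasets
exclude the codon-based schemes (codon positions do not exist after
translation) and, by the same logic, exclude position filtering — a
constraint this package enforces at spec validation even though only the
scheme exclusion is strictly forced by the data model.

## Output formats

* **NEXUS** — non-interleaved DATA block (`MISSING=? GAP=-`), SETS block
  with one CHARSET per partition (1-based inclusive ranges), optional
  MRBAYES block repeating the charsets, declaring
  `partition scheme = N: ...; set partition = scheme;`, the first
  outgroup taxon, and an `mcmc ngen=... samplefreq=...` line
  (defaults 1 000 000 / 1000 — minimal, valid, overridable). Labels are
  single-quoted only when they contain unsafe characters.
* **PHYLIP** — the relaxed dialect (labels of any length, whitespace
  separated), because strict 10-character PHYLIP destroys voucher-code
  labels and the intended consumer, RAxML, accepts relaxed. A companion
  RAxML partition file uses `DNA, name = a-b` (or `WAG,` for amino
  acids).
* **TNT** — `nstates dna;` (or `prot`), `xread`, then `nchar ntax` (TNT
  order), label/row pairs, `;`.
* **FASTA** — 80-column wrapped; matrix rows or raw per-gene store
  slices.
* **GenBank submission FASTA** — one record per taxon having the gene,
  with Sequin source modifiers `[organism=Genus species]` (omitted when
  empty), `[specimen-voucher=code]` and `[note=gene description]`; taxa
  lacking the gene are skipped and returned in a skip list.
* **Publication table** — CSV with code/genus/species/country plus one
  column per gene holding the accession, else `"<n> bp"` when a sequence
  exists without accession, else empty; an XLSX flavour is available
  from the CLI.

Writers are pure functions; byte-identical output for identical input is
asserted in the tests. Round-trips are verified with independent readers
(Biopython's NEXUS, relaxed-PHYLIP and FASTA parsers; a minimal xread
parser written only as a test oracle).

## The synthetic-data generator

`seqvault.fixtures.generate_store` emulates a single-lab project:
vouchers `T001..` cycling through a built-in list of 24 Lepidoptera
genus/species pairs, European collection metadata with valid
coordinates, and per-marker sequences. The default panel is the
mitochondrial barcode COI (658 bp, frame 1, translation table 5) plus
nuclear EF1a (1240 bp) and wingless (412 bp, both table 1) and the
non-coding spacer ITS2 (480 bp) — markers and lengths a lepidopterist
would recognise. Defaults of 20 taxa, 15 % missing (taxon, gene) pairs
and 70 % of sequences carrying a synthetic `SYNnnnn` accession reflect a
realistic part-finished project; the acceptance script scales the same
panel to 60 taxa. Protein-coding sequences are generated codon-wise from
sense codons so translation is stop-free under the declared table.

What the generator does **not** emulate: phylogenetic signal (sequences
are i.i.d. random), alignment structure (no indels), rate variation, or
contamination. Passing tests therefore demonstrate data-management
correctness — storage, filtering, concatenation, serialization — not
anything about inference on real data.

Everything is inserted through the public store operations, so a
generator bug cannot bypass validation.

## Numerical and design choices

* Backing store: SQLite via the standard library; every operation
  commits before returning; single writer assumed.
* Voucher deletion is refused while sequences reference the voucher
  (`cascade=True` overrides); taxon-set memberships are always removed
  on successful deletion so sets never hold dangling codes.
* Batch import fills only empty fields of an existing voucher and never
  overwrites non-empty ones; a sequence cell colliding with a stored
  (voucher, gene) pair is rejected for that cell only, the row survives.
* Search is conjunctive case-insensitive substring matching (SQL `LIKE`
  with escaping), checked in tests against a brute-force Python scan.
* Dates are ISO-8601 `YYYY-MM-DD`, validated for syntax only.
* Taxon-set creation silently drops duplicate codes, keeping the first
  occurrence.

## Known limitations

* No alignment is computed; unequal sequence lengths are padded, which
  only makes biological sense for pre-aligned input (use `strict` mode
  otherwise).
* Concurrent writers are not supported.
* The MrBayes block sets no substitution model or priors beyond the
  partition; it is a valid starting point, not an analysis
  recommendation.
* NEXUS/PHYLIP/TNT files are written, never read back into the store.
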