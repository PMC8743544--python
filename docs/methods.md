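# Methods

This note documents the models, conventions and numerical choices behind
`prokannot`, what the synthetic test bed does and does not emulate, and the
known limitations.

## Coordinates, sequences, genetic code

All coordinates are 0-based half-open on the forward strand; writers alone
convert to 1-based inclusive (GFF3). A feature spanning the origin of a
circular, complete replicon is one internal feature with `edge=True` and an
unwrapped `stop` greater than the replicon length; the GFF3 writer splits
it into two location lines sharing one `ID`, and the GFF3 reader re-joins
such pairs when the replicon's metadata permits origin spanning.

Translation uses the bacterial/archaeal code (table 11) exclusively, with
ATG/GTG/TTG accepted as initiators and rendered as methionine at position 1
(not for 5'-truncated features, which have no initiator). Codons containing
N translate to X. A stop codon anywhere but the final position raises an
error carrying its nucleotide offset.

Protein canonicalization (uppercase, strip one terminal `*`, reject
internal stops) precedes every digest computation. Rare and ambiguity
residues (X, B, Z, J, U, O) are accepted and digested verbatim: digests
must be reproducible from the reference FASTA bytes, so no rewriting of
selenocysteine/pyrrolysine is attempted.

## Alignment-free sequence identification (AFSI)

A protein is identified exactly when the MD5 digest of its canonical
sequence matches a stored unique-protein-sequence (UPS) record *and* the
stored sequence length equals the query length. The length equality is the
collision guard: a digest match with a differing length is treated as
unidentified and logged, never resolved to the wrong record. At database
build time the digest-uniqueness invariant is enforced outright — two
distinct sequences mapping to one digest abort the build naming both
record ids. (The digest function is injectable precisely so that this
abort path can be exercised in tests; MD5 collisions cannot otherwise be
manufactured at test scale.)

An AFSI hit inherits the IPS (UniRef100-level) gene/product and, when the
IPS record lacks a product, fills the gap from the linked UniRef90/UniRef50
records — still without any alignment. The identification tier remains
`ips` because the identification itself was exact.

## Homology routing

AFSI misses are aligned against UniRef90 cluster representative sequences.
A hit is considered only with query coverage ≥ 0.80 AND subject coverage
≥ 0.80. Among surviving hits, identity ≥ 0.90 routes to the PSC tier;
0.50 ≤ identity < 0.90 routes to the PSCC tier through the cluster's
UniRef50 parent; below 0.50 the protein stays unannotated by this stage.
All thresholds are inclusive on the accepting side (0.90 exactly is PSC,
0.50 exactly is PSCC) and configurable. The best hit is chosen by score,
then identity, then subject id — a total, deterministic order.

The built-in aligner is global pairwise alignment with free end gaps
(match +1, mismatch −1, gap open −2, extend −1, end gaps 0), implemented on
Biopython's `PairwiseAligner`. Identity is identical columns divided by
alignment columns over the aligned core (terminal overhangs excluded);
coverage is the aligned span over the full sequence length. The aligner
sits behind a one-method interface so an external seeded search engine can
replace it. Because exhaustive alignment against every representative is
wasteful, a shared 5-mer counting index shortlists the top 50 candidates
(ties broken by id) before alignment; a representative sharing no 5-mer
with the query cannot pass the 80 % coverage gate at these sequence
lengths, so the shortlist is a performance device, not an accuracy trade.

## Expert rules and concluding annotation

Expert rules are curated reference proteins with per-rule minimum
identity, query coverage and subject coverage, plus an integer priority
rank. Every eligible rule competes; the highest rank wins (ties: higher
identity, then rule id). The expert tier outranks even exact
identification: expert sources exist precisely to discriminate alleles
that sequence clusters cannot, so their curated product is preferred. This
ordering is a configuration default, not hard-wired.

The concluding step takes the highest tier present as the annotation tier,
takes gene and product from the most specific tier providing them (lower
tiers fill gaps), unions dbxrefs across all tiers (each dbxref keeps its
prefix namespace), and applies the product-refinement chain: whitespace
collapse, quote stripping, dropping trailing "homolog"/"-like protein"
tokens after a named protein, and "uncharacterised" → "uncharacterized".
Products equal (case-insensitively) to any of {hypothetical protein,
uncharacterized protein, putative protein, conserved predicted protein}
count as *no* product; a feature with no informative product from any tier
becomes `hypothetical protein` at the hypothetical tier, keeping whatever
dbxrefs were gathered.

Hypothetical proteins are characterized by molecular mass — the sum of
average residue masses plus one water (18.0153 Da), EMBOSS-style constants
shipped in `annotate.AVERAGE_RESIDUE_MASS`; X contributes the mean residue
mass — and isoelectric point, found by bisecting the Henderson–Hasselbalch
net-charge function on pH 0–14 to an interval of 1e−9 (side-chain pKa: C
8.5, D 3.9, E 4.1, H 6.5, K 10.8, R 12.5, Y 10.1; termini 8.6/3.6; the
whole constant set is one swappable object). The charge function is
strictly decreasing in pH, so bisection converges unconditionally; a
peptide with no ionizable side chains has its pI exactly at the terminal
pKa midpoint.

## Structural stage

`naive_orf_call` is a deliberately simple fallback, not a statistical gene
model: it reports, per stop codon, the longest ORF (earliest in-frame
start after the previous stop) on both strands, wrapping across the origin
of circular complete replicons but never exceeding one full lap. Its false
positive rate on real sequence is that of random ORF occurrence; external
predictions should be supplied (`--cds`) when available. sORF extraction
enumerates *every* start-to-stop ORF in the 7–29 aa window (nested
candidates included, duplicates by locus removed). The upper bound is
strict (< 30 aa) and the lower default of 7 aa exists because an unbounded
minimum floods the candidate set; both are configuration knobs. sORF
extraction crosses the origin on circular complete replicons for
consistency with CDS handling.

Origin-spanning merge: a pair of partial CDSs on the same strand of a
circular complete replicon, one ending exactly at the sequence end and one
starting exactly at base 0, is replaced by one edge feature whose
nucleotide sequence concatenates across the origin. The merge must
translate cleanly (frame-consistent, no internal stop) or it is abandoned
with both partials kept. If several candidates exist on one strand, only
the pair exactly at the edges merges; the rest are logged.

The spurious-sequence filter is a pluggable predicate `aa → reason|None`;
the default backend is the reference database's digest blocklist of known
false-positive sequences. A backend failure aborts the run — silently
skipping the filter would leak known false positives.

Overlap filtering: exact duplicate loci are collapsed, and an sORF
overlapping a retained CDS by more than 10 bp (either strand) is removed
unless it was identified at the expert or ips tier. These rules are
declared configuration of this package, not a fidelity claim about any
external tool's (unpublished) rule set.

## Reference store

The store is one SQLite file, written once at build time and opened
read-only at annotation time. Identifier prefixes (`UniRef100_`,
`UniRef90_`, `UniRef50_`, `WP_`, `UPI`) are stripped before storage and
restored at query time; unregistered prefixes pass verbatim and are
flagged in the audit log. Cluster representative sequences are stored in
the PSC table so the homology stage is self-contained in one file.

Builds apply functional annotation sources in a declared
specificity order (most specific first); a field set by a more specific
source is never overwritten, and each skipped supersession is logged. The
audit log is a TSV (`event, record_type, key, source, field, old, new`)
with no timestamps, so identical inputs yield byte-identical logs — build
determinism is a tested invariant. The schema version is `<major>.<minor>`;
readers accept any minor under their supported major and refuse other
majors before any output is produced.

## Synthetic test bed

`fixtures.gen_reference` builds a toy proteome: per cluster one
representative (60–400 aa, uniform residues, always starting with M) and
members derived by point substitutions to declared identity levels
(default 0.95 and 0.70, ±2 % as measured by alignment); adjacent cluster
pairs share a UniRef50-level parent; two annotation sources with planted
conflicts exercise supersession; expert rules use dedicated proteins
outside the clusters; a blocklist carries digests of dedicated "spurious"
proteins.

`fixtures.gen_genome` plants, by default, 50 exact copies of reference
proteins, 20 fresh ~95 %-identity and 20 fresh ~70 %-identity mutants of
cluster representatives (checked to be absent from the reference set), 5
random sORFs of 8–29 aa, and one 249 nt gene (82 aa protein) spanning the
origin (99 bp before it, 150 bp after). Every planted feature is preceded
by a stop-codon cassette (`TTAATTAATTAA`) that terminates all six reading
frames and contains no start codon, so the naive caller recovers planted
coordinates exactly and no ORF can span two features. sORF segments are
additionally resampled until no ≥ 30 aa ORF exists on either strand of
their padded neighbourhood, so no planted sORF is shadowed by a spurious
CDS call. These guarantees are properties of the generator: real genomes
have none of them, so passing tests demonstrate correctness of the
mechanics, not annotation accuracy on biological data. There is no codon
usage realism, no sequencing error, no assembly fragmentation and no
taxonomy.

Problem sizes in the automated checks — ~1,000 reference proteins with
10,000 mixed identification queries, 100 corrupted-length records, random
10 kb replicons for the ORF-enumeration oracle, and the 90-gene planted
genome — were chosen as the smallest scales at which every code path
(dedup, supersession, both homology routes, origin wrap, collision guard)
is exercised with non-trivial multiplicity.

## Known limitations

* The naive ORF caller over-predicts on both strands of coding regions;
  it exists so the engine runs without an external predictor, and its
  extra calls surface as hypothetical features.
* Pairwise alignment is exhaustive over the k-mer shortlist; for reference
  sets far beyond the desk scale an external seeded aligner should be
  plugged in.
* Only GFF3/JSON/FASTA/TSV writers are provided; no flat-file
  (EMBL/GenBank) output and no INSDC compliance filtering.
* Non-coding features (tRNA, rRNA, ncRNA, CRISPR, origins) are out of
  scope; the pipeline annotates CDSs and sORFs.
* The expert-over-ips precedence and the overlap rules are package
  defaults; both are configurable and other orderings are defensible.
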