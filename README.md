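# prokannot

Bacterial CDS annotation via **alignment-free sequence identification
(AFSI)** over a hierarchical, hash-keyed protein reference store — plus the
compiler that builds that store from flat files.

## The problem

Functional annotation of bacterial genomes usually means aligning every
predicted protein against a large reference collection. Most proteins in a
newly sequenced isolate, however, are *exactly identical* to a protein that
is already known. `prokannot` exploits this: a protein is first identified
by the 16-byte MD5 digest of its full-length amino-acid sequence, checked
against a read-only embedded SQLite store. A digest hit whose stored
sequence length equals the query length identifies the protein exactly —
no alignment performed — and carries stable database cross-references
(UniRef100/90/50-style identifiers) with it. Only the remaining unknown
proteins fall through to pairwise alignment against cluster representative
sequences.

The reference store is a four-tier hierarchy:

| tier | key | granularity | carries |
|------|-----|-------------|---------|
| UPS  | MD5 digest + length | unique sequence | external ids |
| IPS  | UniRef100 id | identical proteins | gene, product, parent cluster |
| PSC  | UniRef90 id  | ~90 % identity cluster | gene, product, COG/EC/GO, representative sequence |
| PSCC | UniRef50 id  | ~50 % identity cluster | coarse product |

Routing for AFSI misses follows the standard thresholds: alignment hits
need mutual (query *and* subject) coverage ≥ 80 %; identity ≥ 90 % assigns
the protein to the PSC tier, identity in [50 %, 90 %) to the PSCC tier.
Curated **expert rules** (reference proteins with per-rule identity and
coverage thresholds and priority ranks) can override cluster annotation,
and a concluding step merges all evidence by tier precedence
(expert > ips > psc > pscc), unions the dbxrefs, normalizes product names,
and marks proteins of unknown function as *hypothetical protein* with
molecular mass and isoelectric point computed from the sequence.

Structural handling includes ingestion of pre-predicted CDS (GFF3) or a
built-in naive ORF caller, merging of partial CDS pairs that run off both
edges of a complete circular replicon (origin-spanning genes), extraction
of short ORFs (sORFs, proteins of 7–29 aa) that de-novo predictors skip,
a pluggable spurious-sequence filter (digest blocklist by default), and
overlap-based filtering of unidentified sORFs.

## Worked example

```sh
# 1. generate a synthetic reference proteome (20 clusters x 3 members)
#    and a toy genome with 96 planted features
python - <<'EOF'
from prokannot import fixtures
manifest = fixtures.gen_reference(42, "toy/ref")
fixtures.gen_genome(42, manifest, "toy/genome")
EOF

# 2. compile the reference database
prokannot build-db \
    --proteins toy/ref/proteins.faa --membership toy/ref/membership.tsv \
    --annotations toy/ref/annotations --expert toy/ref/expert.tsv \
    --expert-fasta toy/ref/expert.faa --blocklist toy/ref/blocklist.txt \
    --version 1.0 --output toy/db.sqlite

# 3. annotate the genome
prokannot annotate --db toy/db.sqlite --output toy/run --prefix TOY \
    --replicons toy/genome/replicons.tsv toy/genome/genome.fasta
```

The build step prints

```
database toy/db.sqlite built (schema 1.0): ups=60, ips=60, psc=20, pscc=10, expert=2, blocklist=2
```

— 60 unique protein sequences in 20 UniRef90-style clusters under 10
UniRef50-style parents, two expert rules and two blocklisted digests. The
annotation step prints

```
annotated 718 CDS and 14 sORF features; tiers: expert=0, ips=50, psc=20, pscc=20, hypothetical=642
```

All 50 planted exact-copy genes were identified alignment-free at the ips
tier, the twenty ~95 %-identity mutants routed to their UniRef90 cluster
(psc) and the twenty ~70 %-identity mutants to the UniRef50 parent (pscc);
the origin-spanning planted gene is reported as one feature wrapped across
the origin. The hypothetical features are background ORFs of the naive
caller plus the planted random sORFs; each carries its computed molecular
mass and isoelectric point in `toy/run/TOY.hypotheticals.tsv`. Outputs:
GFF3, JSON (full model, round-trippable), protein/nucleotide FASTA,
feature-summary TSV and a machine-readable run summary.

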