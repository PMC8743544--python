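"""Functional annotation engine.

The engine resolves each protein in three escalating stages:

1. **AFSI** — alignment-free sequence identification: an MD5 digest of the
   full-length protein is looked up in the reference store; a hit whose
   stored length equals the query length identifies the protein exactly and
   skips all alignments.
2. **Cluster homology** — AFSI misses are aligned against UniRef90 cluster
   representative sequences. Hits need mutual (query and subject) coverage
   of at least 80%; identity >= 90% assigns the protein to the cluster
   (PSC), identity in [50%, 90%) falls back to the coarser UniRef50 tier
   (PSCC) via the cluster's parent link.
3. **Expert rules** — curated reference proteins with per-rule identity and
   coverage thresholds and priority ranks refine or override cluster-level
   annotation.

A concluding step merges the stages by tier precedence
(expert > ips > psc > pscc), normalizes product names, marks products of
unknown function as hypothetical proteins and characterizes them by
molecular mass and isoelectric point, and filters overlapping features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

from . import structural
from .model import (
    AlignmentHit,
    Annotation,
    CdsFeature,
    ExpertRule,
    FeatureClass,
    Genome,
    Tier,
)
from .refdb import RefDb, compute_digest

logger = logging.getLogger(__name__)

# Homology-routing thresholds (fractions). All are inclusive on the
# accepting side: identity exactly 0.90 routes to PSC, exactly 0.50 to PSCC.
MIN_COVERAGE = 0.80
MIN_PSC_IDENTITY = 0.90
MIN_PSCC_IDENTITY = 0.50

HYPOTHETICAL_PRODUCT = "hypothetical protein"

#: Product strings that denote an unknown function and normalize to
#: "hypothetical protein" at tier-assignment time.
UNKNOWN_FUNCTION_PRODUCTS = frozenset({
    "hypothetical protein",
    "uncharacterized protein",
    "putative protein",
    "conserved predicted protein",
})


class AlignerError(Exception):
    """The pairwise aligner failed; the affected feature is not annotated."""


# ---------------------------------------------------------------------------
# Pairwise alignment
# ---------------------------------------------------------------------------

class PairwiseProteinAligner:
    """Global protein alignment with free end gaps and unit scoring.

    identity = identical columns / alignment columns over the aligned core
    (terminal overhangs excluded); coverage = aligned span / full length.
    The class is the default implementation of the aligner interface used
    by the engine; an external seeded aligner can be swapped in as long as
    it returns :class:`AlignmentHit` objects.
    """

    def __init__(self):
        from Bio.Align import PairwiseAligner

        a = PairwiseAligner()
        a.mode = "global"
        a.match_score = 1.0
        a.mismatch_score = -1.0
        a.open_gap_score = -2.0
        a.extend_gap_score = -1.0
        try:
            a.end_insertion_score = 0.0
            a.end_deletion_score = 0.0
        except AttributeError:  # older Biopython naming
            a.target_end_gap_score = 0.0
            a.query_end_gap_score = 0.0
        self._aligner = a

    def align(self, query: str, query_id: str, subject: str,
              subject_id: str) -> Optional[AlignmentHit]:
        try:
            aln = self._aligner.align(query, subject)[0]
            blocks_q, blocks_s = aln.aligned
        except Exception as exc:  # pragma: no cover - defensive
            raise AlignerError(f"alignment of {query_id!r} vs {subject_id!r} "
                               f"failed: {exc}") from exc
        if len(blocks_q) == 0:
            return None
        matches = 0
        aligned_len = 0
        for (qs, qe), (ss, se) in zip(blocks_q, blocks_s):
            aligned_len += qe - qs
            for i in range(qe - qs):
                if query[qs + i] == subject[ss + i]:
                    matches += 1
        q_span = int(blocks_q[-1][1] - blocks_q[0][0])
        s_span = int(blocks_s[-1][1] - blocks_s[0][0])
        columns = q_span + s_span - aligned_len
        if columns == 0:
            return None
        return AlignmentHit(
            query_id=query_id, subject_id=subject_id,
            identity=matches / columns,
            query_cov=min(1.0, q_span / len(query)),
            subject_cov=min(1.0, s_span / len(subject)),
            score=float(aln.score))


def _kmers(seq: str, k: int = 5) -> set:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


class KmerPreselector:
    """Shared 5-mer counting to shortlist cluster representatives before the
    expensive alignments; stands in for a seeded external search engine."""

    def __init__(self, refdb: RefDb, k: int = 5):
        self.k = k
        self._index: Dict[str, set] = {}
        self._reps: Dict[str, str] = {}
        for u90, rep in refdb.iter_psc_reps():
            self._reps[u90] = rep
            for kmer in _kmers(rep, k):
                self._index.setdefault(kmer, set()).add(u90)

    def candidates(self, aa: str, top_n: int = 50) -> List[Tuple[str, str]]:
        counts: Dict[str, int] = {}
        for kmer in _kmers(aa, self.k):
            for u90 in self._index.get(kmer, ()):
                counts[u90] = counts.get(u90, 0) + 1
        ranked = sorted(counts, key=lambda u: (-counts[u], u))[:top_n]
        return [(u90, self._reps[u90]) for u90 in ranked]


# ---------------------------------------------------------------------------
# Identification stages
# ---------------------------------------------------------------------------

def identify_afsi(aa: str, refdb: RefDb) -> Optional[Annotation]:
    """Exact identification by digest + length; no alignment performed."""
    hit = refdb.lookup_ups(compute_digest(aa), len(aa))
    if hit is None:
        return None
    ups, ips = hit
    dbxrefs = {f"UniRef:{ups.uniref100_id}"}
    if ups.uniparc_id:
        dbxrefs.add(f"UniParc:{ups.uniparc_id}")
    gene = product = None
    if ips is not None:
        gene, product = ips.gene, ips.product
        if ips.uniref90_id:
            dbxrefs.add(f"UniRef:{ips.uniref90_id}")
    return Annotation(product=product or HYPOTHETICAL_PRODUCT, gene=gene,
                      dbxrefs=dbxrefs, tier=Tier.IPS)


def route_hit(hit: AlignmentHit,
              min_coverage: float = MIN_COVERAGE,
              min_psc_identity: float = MIN_PSC_IDENTITY,
              min_pscc_identity: float = MIN_PSCC_IDENTITY) -> Optional[str]:
    """Coverage gate, then identity partition into {psc, pscc, None}."""
    if hit.query_cov < min_coverage or hit.subject_cov < min_coverage:
        return None
    if hit.identity >= min_psc_identity:
        return "psc"
    if hit.identity >= min_pscc_identity:
        return "pscc"
    return None


def search_clusters(aa: str, query_id: str, refdb: RefDb,
                    aligner: PairwiseProteinAligner,
                    preselector: Optional[KmerPreselector] = None,
                    top_n: int = 50,
                    alignment_counter: Optional[list] = None,
                    min_coverage: float = MIN_COVERAGE,
                    min_psc_identity: float = MIN_PSC_IDENTITY,
                    min_pscc_identity: float = MIN_PSCC_IDENTITY,
                    ) -> Optional[Tuple[AlignmentHit, str]]:
    """Align a query against cluster representatives and route the best hit.

    Returns ``(hit, route)`` where route is ``"psc"`` or ``"pscc"``, or
    ``None`` when no hit survives the coverage/identity thresholds. The
    best hit is chosen by score, then identity, then subject id.
    """
    if preselector is not None:
        candidates = preselector.candidates(aa, top_n)
    else:
        candidates = list(refdb.iter_psc_reps())
    routed = []
    for u90, rep in candidates:
        hit = aligner.align(aa, query_id, rep, u90)
        if alignment_counter is not None:
            alignment_counter.append(query_id)
        if hit is None:
            continue
        route = route_hit(hit, min_coverage, min_psc_identity,
                          min_pscc_identity)
        if route is not None:
            routed.append((hit, route))
    if not routed:
        return None
    routed.sort(key=lambda hr: (-hr[0].score, -hr[0].identity, hr[0].subject_id))
    return routed[0]


def cluster_annotation(hit: AlignmentHit, route: str,
                       refdb: RefDb) -> Optional[Annotation]:
    """Turn a routed cluster hit into a tier-psc or tier-pscc annotation."""
    psc = refdb.lookup_psc(hit.subject_id)
    if psc is None:
        return None
    if route == "psc":
        dbxrefs = {f"UniRef:{psc.uniref90_id}"}
        if psc.uniref50_id:
            dbxrefs.add(f"UniRef:{psc.uniref50_id}")
        if psc.cog_id:
            dbxrefs.add(f"COG:{psc.cog_id}")
        dbxrefs.update(f"EC:{e}" for e in psc.ec)
        dbxrefs.update(psc.go)
        return Annotation(product=psc.product or HYPOTHETICAL_PRODUCT,
                          gene=psc.gene, dbxrefs=dbxrefs, tier=Tier.PSC)
    # pscc route: the annotation comes from the cluster's parent UniRef50
    if not psc.uniref50_id:
        return None
    pscc = refdb.lookup_pscc(psc.uniref50_id)
    if pscc is None:
        return None
    return Annotation(product=pscc.product or HYPOTHETICAL_PRODUCT,
                      dbxrefs={f"UniRef:{pscc.uniref50_id}"}, tier=Tier.PSCC)


def linked_cluster_annotations(refdb: RefDb,
                               uniref90_id: Optional[str]) -> List[Annotation]:
    """Cluster-tier annotations reached through an IPS's parent links.

    An AFSI-identified protein whose IPS record lacks a product inherits
    one from its linked UniRef90 cluster (and, failing that, the UniRef50
    parent) without any alignment being performed.
    """
    if not uniref90_id:
        return []
    psc = refdb.lookup_psc(uniref90_id)
    if psc is None:
        return []
    out = [cluster_annotation(
        AlignmentHit(query_id="", subject_id=psc.uniref90_id, identity=1.0,
                     query_cov=1.0, subject_cov=1.0), "psc", refdb)]
    if psc.uniref50_id:
        pscc = refdb.lookup_pscc(psc.uniref50_id)
        if pscc is not None and pscc.product:
            out.append(Annotation(product=pscc.product,
                                  dbxrefs={f"UniRef:{pscc.uniref50_id}"},
                                  tier=Tier.PSCC))
    return [a for a in out if a is not None]


def apply_expert(aa: str, query_id: str, rules: Iterable[ExpertRule],
                 aligner: PairwiseProteinAligner) -> Optional[Annotation]:
    """Match curated expert rules; among eligible rules the highest rank
    wins (ties: higher identity, then rule id)."""
    eligible = []
    for rule in rules:
        hit = aligner.align(aa, query_id, rule.seq, rule.rule_id)
        if hit is None:
            continue
        if (hit.identity >= rule.min_identity
                and hit.query_cov >= rule.min_query_cov
                and hit.subject_cov >= rule.min_subject_cov):
            eligible.append((rule, hit))
    if not eligible:
        return None
    eligible.sort(key=lambda rh: (-rh[0].rank, -rh[1].identity, rh[0].rule_id))
    rule = eligible[0][0]
    return Annotation(product=rule.product, gene=rule.gene,
                      dbxrefs=set(rule.dbxrefs), tier=Tier.EXPERT,
                      rule_rank=rule.rank)


# ---------------------------------------------------------------------------
# Concluding annotation
# ---------------------------------------------------------------------------

def refine_product(product: str) -> str:
    """Deterministic product-name cleanup toward nomenclature guidelines."""
    p = " ".join(product.split())
    if len(p) >= 2 and p[0] == p[-1] and p[0] in "\"'":
        p = p[1:-1].strip()
    if p.lower().endswith("-like protein") and len(p) > len("-like protein"):
        p = p[: -len("-like protein")].strip()
    elif p.lower().endswith(" homolog"):
        head = p[: -len(" homolog")].strip()
        if head:
            p = head
    p = p.replace("uncharacterised", "uncharacterized").replace(
        "Uncharacterised", "Uncharacterized")
    return p


def _effective_product(product: Optional[str]) -> Optional[str]:
    """Refined product, or None when it denotes an unknown function."""
    if not product:
        return None
    refined = refine_product(product)
    if refined.lower() in UNKNOWN_FUNCTION_PRODUCTS:
        return None
    return refined


def conclude(afsi_result: Optional[Annotation],
             cluster_result: Optional[Annotation],
             expert_result: Optional[Annotation]) -> Annotation:
    """Merge stage results into the concluding annotation.

    Tier precedence is expert > ips > psc > pscc. Gene and product come
    from the most specific tier providing them; lower tiers fill gaps.
    Dbxrefs are the union across all tiers. When no tier provides an
    informative product the feature is a hypothetical protein.
    """
    order = [Tier.EXPERT, Tier.IPS, Tier.PSC, Tier.PSCC]
    flat = [afsi_result, expert_result]
    if isinstance(cluster_result, (list, tuple)):
        flat.extend(cluster_result)
    else:
        flat.append(cluster_result)
    results = {}
    for res in flat:
        if res is not None and res.tier not in results:
            results[res.tier] = res
    present = [t for t in order if t in results]
    dbxrefs = set()
    for res in results.values():
        dbxrefs |= res.dbxrefs
    gene = product = None
    rule_rank = None
    for t in present:
        res = results[t]
        if gene is None and res.gene:
            gene = res.gene
        if product is None:
            eff = _effective_product(res.product)
            if eff is not None:
                product = eff
        if t is Tier.EXPERT:
            rule_rank = res.rule_rank
    if product is None:
        return Annotation(product=HYPOTHETICAL_PRODUCT, gene=gene,
                          dbxrefs=dbxrefs, tier=Tier.HYPOTHETICAL)
    return Annotation(product=product, gene=gene, dbxrefs=dbxrefs,
                      tier=present[0], rule_rank=rule_rank)


# ---------------------------------------------------------------------------
# Sequence-based characterization (mass, isoelectric point)
# ---------------------------------------------------------------------------

#: Average residue masses in Dalton (monomer minus water). B/Z/J are means
#: of the residues they stand for; X is the mean over the 20 standard ones.
AVERAGE_RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "E": 129.1155, "Q": 128.1307, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
    "U": 150.0388, "O": 237.3018,
}
AVERAGE_RESIDUE_MASS["B"] = (AVERAGE_RESIDUE_MASS["N"] + AVERAGE_RESIDUE_MASS["D"]) / 2
AVERAGE_RESIDUE_MASS["Z"] = (AVERAGE_RESIDUE_MASS["Q"] + AVERAGE_RESIDUE_MASS["E"]) / 2
AVERAGE_RESIDUE_MASS["J"] = AVERAGE_RESIDUE_MASS["I"]
AVERAGE_RESIDUE_MASS["X"] = sum(
    AVERAGE_RESIDUE_MASS[r] for r in "ACDEFGHIKLMNPQRSTVWY") / 20

WATER_MASS = 18.0153


@dataclass(frozen=True)
class PkaSet:
    """Side-chain and terminal pKa constants for net-charge computation
    (EMBOSS-style values); swappable as one unit."""

    positive: Dict[str, float] = field(default_factory=lambda: {
        "K": 10.8, "R": 12.5, "H": 6.5})
    negative: Dict[str, float] = field(default_factory=lambda: {
        "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1})
    n_term: float = 8.6
    c_term: float = 3.6


DEFAULT_PKA = PkaSet()


def net_charge(aa: str, ph: float, pka: PkaSet = DEFAULT_PKA) -> float:
    """Henderson–Hasselbalch net charge of a peptide at a given pH."""
    charge = 1.0 / (1.0 + 10 ** (ph - pka.n_term))
    charge -= 1.0 / (1.0 + 10 ** (pka.c_term - ph))
    for res, value in pka.positive.items():
        n = aa.count(res)
        if n:
            charge += n / (1.0 + 10 ** (ph - value))
    for res, value in pka.negative.items():
        n = aa.count(res)
        if n:
            charge -= n / (1.0 + 10 ** (value - ph))
    return charge


def characterize(aa: str, pka: PkaSet = DEFAULT_PKA,
                 mass_table: Dict[str, float] = AVERAGE_RESIDUE_MASS,
                 ) -> Tuple[float, float]:
    """Molecular mass (Da, average masses + one water) and isoelectric
    point (bisection of the monotone net-charge function on pH 0..14)."""
    if not aa:
        raise ValueError("cannot characterize an empty protein")
    mass = WATER_MASS + sum(mass_table[r] for r in aa)
    lo, hi = 0.0, 14.0
    while hi - lo > 1e-9:
        mid = (lo + hi) / 2.0
        if net_charge(aa, mid, pka) > 0:
            lo = mid
        else:
            hi = mid
    return mass, (lo + hi) / 2.0


# ---------------------------------------------------------------------------
# Overlap filtering
# ---------------------------------------------------------------------------

def _overlap_bp(a: CdsFeature, b: CdsFeature, replicon_len: int) -> int:
    if a.replicon_id != b.replicon_id:
        return 0

    def segments(f):
        if f.stop <= replicon_len:
            return [(f.start, f.stop)]
        return [(f.start, replicon_len), (0, f.stop - replicon_len)]

    total = 0
    for s1, e1 in segments(a):
        for s2, e2 in segments(b):
            total += max(0, min(e1, e2) - max(s1, s2))
    return total


def overlap_filter(features: Iterable[CdsFeature], genome: Genome,
                   max_sorf_overlap: int = 10,
                   log: Optional[list] = None) -> List[CdsFeature]:
    """Resolve conflicting features.

    Rules: (1) an sORF overlapping a retained CDS by more than
    ``max_sorf_overlap`` bp on either strand is removed, unless it was
    identified at the expert or ips tier; (2) exact duplicate loci are
    collapsed. Removals are logged with the conflicting feature's id.
    """
    log = log if log is not None else []
    seen_loci = set()
    deduped = []
    for feat in features:
        key = feat.locus_key()
        if key in seen_loci:
            log.append(f"removed duplicate {feat.id} at locus {key}")
            continue
        seen_loci.add(key)
        deduped.append(feat)

    lengths = {rep.id: rep.length for rep in genome.replicons}
    cds = [f for f in deduped if f.feature_class is FeatureClass.CDS]
    retained = list(cds)
    for feat in deduped:
        if feat.feature_class is not FeatureClass.SORF:
            continue
        tier = feat.annotation.tier if feat.annotation else Tier.HYPOTHETICAL
        if tier in (Tier.EXPERT, Tier.IPS):
            retained.append(feat)
            continue
        clash = next(
            (c for c in cds
             if _overlap_bp(feat, c, lengths[feat.replicon_id]) > max_sorf_overlap),
            None)
        if clash is not None:
            log.append(f"removed sORF {feat.id}: overlaps CDS {clash.id}")
        else:
            retained.append(feat)
    retained.sort(key=lambda f: (f.replicon_id, f.start, f.stop, f.strand))
    return retained


# ---------------------------------------------------------------------------
# Whole-genome driver
# ---------------------------------------------------------------------------

@dataclass
class AnnotateConfig:
    """Engine configuration; defaults mirror the engine's published
    behaviour and are exposed for experimentation."""

    min_cds_aa: int = structural.DEFAULT_MIN_CDS_AA
    min_sorf_aa: int = structural.DEFAULT_MIN_SORF_AA
    max_sorf_aa: int = structural.DEFAULT_MAX_SORF_AA
    min_coverage: float = MIN_COVERAGE
    min_psc_identity: float = MIN_PSC_IDENTITY
    min_pscc_identity: float = MIN_PSCC_IDENTITY
    top_n_candidates: int = 50
    max_sorf_overlap: int = 10
    locus_prefix: str = "P"


@dataclass
class RunSummary:
    """Machine-readable account of one annotation run."""

    tier_counts: Dict[str, int] = field(default_factory=dict)
    resolved_without_alignment: int = 0
    alignments_performed: int = 0
    expert_alignments: int = 0
    cds_count: int = 0
    sorf_count: int = 0
    log: List[str] = field(default_factory=list)
    db_version: str = ""
    config: Dict[str, object] = field(default_factory=dict)


def annotate_genome(genome: Genome, refdb: RefDb,
                    config: Optional[AnnotateConfig] = None,
                    precomputed_cds: Optional[List[CdsFeature]] = None,
                    aligner: Optional[PairwiseProteinAligner] = None,
                    ) -> Tuple[List[CdsFeature], RunSummary]:
    """Run the full CDS/sORF annotation pipeline over a genome.

    Stage order: CDS calling/ingestion -> origin-spanning merge -> sORF
    extraction -> spurious filter -> AFSI -> cluster homology for AFSI
    misses -> expert rules -> concluding annotation -> product refinement
    and characterization of hypotheticals -> overlap filter -> locus tags.
    """
    config = config or AnnotateConfig()
    refdb.check_version()
    aligner = aligner or PairwiseProteinAligner()
    preselector = KmerPreselector(refdb)
    rules = refdb.expert_rules()
    summary = RunSummary(db_version=refdb.meta.version,
                         config={k: getattr(config, k)
                                 for k in vars(config)})

    features: List[CdsFeature] = []
    for replicon in genome.replicons:
        if precomputed_cds is not None:
            cds = [f for f in precomputed_cds if f.replicon_id == replicon.id]
        else:
            cds = structural.naive_orf_call(replicon, config.min_cds_aa)
        cds = structural.merge_edge_cds(cds, replicon, log=summary.log)
        sorfs = structural.extract_sorfs(
            replicon, config.max_sorf_aa, config.min_sorf_aa)
        features.extend(cds)
        features.extend(sorfs)

    features = structural.filter_spurious(
        features, structural.blocklist_backend(refdb), log=summary.log)

    alignment_counter: List[str] = []
    for feat in features:
        afsi = identify_afsi(feat.aa, refdb)
        cluster = None
        if afsi is not None:
            u90 = next((x.split(":", 1)[1] for x in afsi.dbxrefs
                        if x.startswith("UniRef:UniRef90_")), None)
            cluster = linked_cluster_annotations(refdb, u90)
        else:
            routed = search_clusters(
                feat.aa, feat.id, refdb, aligner, preselector,
                config.top_n_candidates, alignment_counter,
                config.min_coverage, config.min_psc_identity,
                config.min_pscc_identity)
            if routed is not None:
                cluster = cluster_annotation(routed[0], routed[1], refdb)
        expert = None
        if rules:
            expert = apply_expert(feat.aa, feat.id, rules, aligner)
            summary.expert_alignments += len(rules)
        feat.annotation = conclude(afsi, cluster, expert)
        if feat.annotation.tier is Tier.HYPOTHETICAL:
            feat.mass, feat.pi = characterize(feat.aa)
        if afsi is not None:
            summary.resolved_without_alignment += 1

    features = overlap_filter(features, genome, config.max_sorf_overlap,
                              log=summary.log)

    # locus tags: prefix + zero-padded counter, ordered by replicon then start
    order = {rep.id: i for i, rep in enumerate(genome.replicons)}
    features.sort(key=lambda f: (order[f.replicon_id], f.start, f.stop, f.strand))
    for i, feat in enumerate(features, start=1):
        feat.id = f"{config.locus_prefix}_{i:05d}"

    summary.alignments_performed = len(alignment_counter)
    summary.cds_count = sum(
        1 for f in features if f.feature_class is FeatureClass.CDS)
    summary.sorf_count = sum(
        1 for f in features if f.feature_class is FeatureClass.SORF)
    counts = {t.value: 0 for t in Tier}
    for feat in features:
        counts[feat.annotation.tier.value] += 1
    summary.tier_counts = counts
    return features, summary
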