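"""Annotation engine: AFSI, homology routing, expert rules, conclusion,
product refinement, characterization, overlap filtering."""

import itertools
import random

import pytest

from prokannot.annotate import (
    HYPOTHETICAL_PRODUCT,
    AVERAGE_RESIDUE_MASS,
    DEFAULT_PKA,
    WATER_MASS,
    Annotation,
    PairwiseProteinAligner,
    apply_expert,
    characterize,
    cluster_annotation,
    conclude,
    identify_afsi,
    net_charge,
    overlap_filter,
    refine_product,
    route_hit,
    search_clusters,
)
from prokannot.fixtures import STOPPER, make_replicon, _mutate
from prokannot.model import (
    AlignmentHit,
    CdsFeature,
    ExpertRule,
    FeatureClass,
    Genome,
    Tier,
)


@pytest.fixture(scope="module")
def aligner():
    return PairwiseProteinAligner()


class TestAfsi:
    def test_stored_protein_identified(self, ref_manifest, ref_db):
        member = ref_manifest["clusters"][0]["members"][0]
        ann = identify_afsi(member["seq"], ref_db)
        assert ann is not None
        assert ann.tier is Tier.IPS
        assert f"UniRef:{member['uniref100_id']}" in ann.dbxrefs

    def test_single_substitution_misses(self, ref_manifest, ref_db):
        seq = ref_manifest["clusters"][0]["members"][0]["seq"]
        mutated = ("A" if seq[5] != "A" else "C").join((seq[:5], seq[6:]))
        assert len(mutated) == len(seq)
        assert identify_afsi(mutated, ref_db) is None

    def test_absent_protein_misses(self, ref_db):
        assert identify_afsi("MAAAAAAAAAAAAAAAQQQ", ref_db) is None

    def test_equivalence_with_exact_string_matching(self, ref_manifest,
                                                    ref_db):
        rng = random.Random(4)
        stored = {m["seq"] for cl in ref_manifest["clusters"]
                  for m in cl["members"]}
        queries = list(stored)[:30]
        queries += [_mutate(rng, s, 0.98) for s in queries[:15]]
        queries += ["M" + "".join(rng.choice("ACDEFGHIKLMNPQRSTVWY")
                                  for _ in range(50)) for _ in range(15)]
        for q in queries:
            assert (identify_afsi(q, ref_db) is not None) == (q in stored)


class TestRouting:
    # identity grid x coverage grid; routing depends only on the 0.50/0.90
    # identity cuts once mutual coverage >= 0.80 holds
    @pytest.mark.parametrize("identity,expected", [
        (0.49, None), (0.50, "pscc"), (0.899, "pscc"), (0.90, "psc"),
        (0.95, "psc"),
    ])
    @pytest.mark.parametrize("cov", [0.79, 0.80, 1.00])
    def test_grid(self, identity, expected, cov):
        hit = AlignmentHit(query_id="q", subject_id="s", identity=identity,
                           query_cov=cov, subject_cov=cov, score=10)
        assert route_hit(hit) == (expected if cov >= 0.80 else None)

    def test_one_sided_coverage_rejected(self):
        hit = AlignmentHit(query_id="q", subject_id="s", identity=0.95,
                           query_cov=0.79, subject_cov=1.0)
        assert route_hit(hit) is None

    def test_mutant95_routes_to_psc(self, ref_manifest, ref_db, aligner):
        rng = random.Random(21)
        cl = ref_manifest["clusters"][1]
        query = _mutate(rng, cl["rep_seq"], 0.95)
        routed = search_clusters(query, "q", ref_db, aligner)
        assert routed is not None
        hit, route = routed
        assert route == "psc"
        assert hit.subject_id == cl["uniref90_id"]
        ann = cluster_annotation(hit, route, ref_db)
        assert ann.tier is Tier.PSC
        assert ann.product == cl["psc_product"]

    def test_mutant70_routes_to_pscc(self, ref_manifest, ref_db, aligner):
        rng = random.Random(22)
        cl = ref_manifest["clusters"][2]
        query = _mutate(rng, cl["rep_seq"], 0.70)
        routed = search_clusters(query, "q", ref_db, aligner)
        assert routed is not None
        hit, route = routed
        assert route == "pscc"
        ann = cluster_annotation(hit, route, ref_db)
        assert ann.tier is Tier.PSCC
        assert ann.product == cl["pscc_product"]

    def test_unrelated_query_finds_nothing(self, ref_db, aligner):
        rng = random.Random(23)
        query = "M" + "".join(rng.choice("ACDEFGHIKLMNPQRSTVWY")
                              for _ in range(120))
        assert search_clusters(query, "q", ref_db, aligner) is None

    def test_alignment_count_monotone_under_enrichment(self, ref_manifest,
                                                       ref_db, aligner):
        # a query whose exact sequence is stored resolves alignment-free;
        # the same query without its record needs >= 0 alignments, so adding
        # the record never increases the alignment count
        def alignments_for(query):
            counter = []
            if identify_afsi(query, ref_db) is None:
                search_clusters(query, "q", ref_db, aligner,
                                alignment_counter=counter)
            return len(counter)

        member = ref_manifest["clusters"][3]["members"][1]
        assert alignments_for(member["seq"]) == 0
        rng = random.Random(41)
        novel = _mutate(rng, member["seq"], 0.95)
        assert alignments_for(novel) >= 1


class TestExpert:
    def _rules(self):
        seq_a = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"
        seq_b = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVA"
        return [
            ExpertRule(rule_id="r10", source="s", rank=10, product="low-rank",
                       seq=seq_a, min_identity=0.9, min_query_cov=0.9,
                       min_subject_cov=0.9),
            ExpertRule(rule_id="r20", source="s", rank=20, product="high-rank",
                       seq=seq_b, min_identity=0.9, min_query_cov=0.9,
                       min_subject_cov=0.9),
        ]

    def test_self_alignment_matches(self, aligner):
        rules = self._rules()[:1]
        ann = apply_expert(rules[0].seq, "q", rules, aligner)
        assert ann is not None
        assert ann.tier is Tier.EXPERT
        assert ann.product == "low-rank"

    def test_highest_rank_wins(self, aligner):
        rules = self._rules()
        ann = apply_expert(rules[0].seq, "q", rules, aligner)
        assert ann.product == "high-rank"
        assert ann.rule_rank == 20

    def test_subject_coverage_threshold(self, aligner):
        rule = ExpertRule(rule_id="r", source="s", rank=1, product="p",
                          seq="MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ" * 3,
                          min_identity=0.9, min_query_cov=0.5,
                          min_subject_cov=0.9)
        # query identical to a third of the rule protein: subject_cov ~ 0.33
        assert apply_expert(rule.seq[:33], "q", [rule], aligner) is None


class TestConclude:
    RESULTS = {
        Tier.EXPERT: Annotation(product="expert product", gene="exg",
                                dbxrefs={"Expert:R1"}, tier=Tier.EXPERT,
                                rule_rank=5),
        Tier.IPS: Annotation(product="ips product", gene="ipg",
                             dbxrefs={"UniRef:UniRef100_A"}, tier=Tier.IPS),
        Tier.PSC: Annotation(product="psc product", gene="pcg",
                             dbxrefs={"UniRef:UniRef90_A"}, tier=Tier.PSC),
        Tier.PSCC: Annotation(product="pscc product",
                              dbxrefs={"UniRef:UniRef50_A"}, tier=Tier.PSCC),
    }

    @pytest.mark.parametrize("combo", list(itertools.product(
        [False, True], repeat=4)))
    def test_all_16_presence_combinations(self, combo):
        has_expert, has_ips, has_psc, has_pscc = combo
        afsi = self.RESULTS[Tier.IPS] if has_ips else None
        expert = self.RESULTS[Tier.EXPERT] if has_expert else None
        clusters = [self.RESULTS[t]
                    for t, h in ((Tier.PSC, has_psc), (Tier.PSCC, has_pscc))
                    if h]
        ann = conclude(afsi, clusters, expert)
        order = [(Tier.EXPERT, has_expert), (Tier.IPS, has_ips),
                 (Tier.PSC, has_psc), (Tier.PSCC, has_pscc)]
        present = [t for t, h in order if h]
        if not present:
            assert ann.tier is Tier.HYPOTHETICAL
            assert ann.product == HYPOTHETICAL_PRODUCT
        else:
            assert ann.tier is present[0]
            assert ann.product == self.RESULTS[present[0]].product
            expected_dbx = set()
            for t in present:
                expected_dbx |= self.RESULTS[t].dbxrefs
            assert ann.dbxrefs == expected_dbx

    def test_lower_tier_fills_product_gap(self):
        ips = Annotation(product=HYPOTHETICAL_PRODUCT,
                         dbxrefs={"UniRef:UniRef100_A"}, tier=Tier.IPS)
        psc = self.RESULTS[Tier.PSC]
        ann = conclude(ips, [psc], None)
        assert ann.tier is Tier.IPS  # identification is still exact
        assert ann.product == "psc product"

    def test_unknown_function_synonym_becomes_hypothetical(self):
        ips = Annotation(product="Uncharacterised protein",
                         dbxrefs={"UniRef:UniRef100_A"}, tier=Tier.IPS)
        ann = conclude(ips, None, None)
        assert ann.product == HYPOTHETICAL_PRODUCT
        assert ann.tier is Tier.HYPOTHETICAL
        assert "UniRef:UniRef100_A" in ann.dbxrefs


class TestRefineProduct:
    @pytest.mark.parametrize("raw,expected", [
        ("  DNA   polymerase III ", "DNA polymerase III"),
        ('"ferredoxin"', "ferredoxin"),
        ("recA homolog", "recA"),
        ("ferritin-like protein", "ferritin"),
        ("uncharacterised conserved domain", "uncharacterized conserved domain"),
        ("ATP synthase", "ATP synthase"),
    ])
    def test_rewrites(self, raw, expected):
        assert refine_product(raw) == expected


class TestCharacterize:
    def test_glycine_mass(self):
        mass, _ = characterize("G")
        assert mass == pytest.approx(75.07, abs=0.01)

    def test_mass_matches_residue_summation_oracle(self):
        rng = random.Random(6)
        for _ in range(200):
            aa = "".join(rng.choice("ACDEFGHIKLMNPQRSTVWY")
                         for _ in range(rng.randint(1, 300)))
            expected = WATER_MASS + sum(AVERAGE_RESIDUE_MASS[r] for r in aa)
            mass, _ = characterize(aa)
            assert mass == pytest.approx(expected, abs=1e-9)

    def test_no_ionizable_side_chains_closed_form(self):
        # only termini ionize: charge crosses zero at the pKa midpoint
        _, pi = characterize("GGGAGLVITP")
        assert pi == pytest.approx((DEFAULT_PKA.n_term + DEFAULT_PKA.c_term) / 2,
                                   abs=1e-4)

    def test_net_charge_at_pi_is_zero(self):
        rng = random.Random(9)
        for _ in range(50):
            aa = "".join(rng.choice("ACDEFGHIKLMNPQRSTVWY")
                         for _ in range(rng.randint(5, 100)))
            _, pi = characterize(aa)
            assert abs(net_charge(aa, pi)) < 1e-4

    def test_arginine_raises_pi_aspartate_lowers(self):
        base = "MGKLVITA"
        _, pi = characterize(base)
        assert characterize(base + "R")[1] > pi
        assert characterize(base + "D")[1] < pi


class TestOverlapFilter:
    def _setup(self):
        rep = make_replicon(STOPPER * 100, replicon_id="r1")
        genome = Genome(replicons=[rep])

        def feat(fid, start, stop, cls, tier):
            f = CdsFeature(id=fid, replicon_id="r1", start=start, stop=stop,
                           strand="+", feature_class=cls, nt="A" * (stop - start),
                           aa="M")
            f.annotation = Annotation(product="x", tier=tier)
            return f

        return genome, feat

    def test_unidentified_sorf_inside_cds_removed(self):
        genome, feat = self._setup()
        cds = feat("c", 100, 400, FeatureClass.CDS, Tier.PSC)
        sorf = feat("s", 150, 210, FeatureClass.SORF, Tier.HYPOTHETICAL)
        log = []
        kept = overlap_filter([cds, sorf], genome, log=log)
        assert [f.id for f in kept] == ["c"]
        assert any("s" in line and "c" in line for line in log)

    def test_identified_sorf_retained(self):
        genome, feat = self._setup()
        cds = feat("c", 100, 400, FeatureClass.CDS, Tier.PSC)
        sorf = feat("s", 150, 210, FeatureClass.SORF, Tier.IPS)
        kept = overlap_filter([cds, sorf], genome)
        assert sorted(f.id for f in kept) == ["c", "s"]

    def test_small_overlap_tolerated(self):
        genome, feat = self._setup()
        cds = feat("c", 100, 400, FeatureClass.CDS, Tier.PSC)
        sorf = feat("s", 391, 460, FeatureClass.SORF, Tier.HYPOTHETICAL)
        kept = overlap_filter([cds, sorf], genome)  # 9 bp overlap <= 10
        assert sorted(f.id for f in kept) == ["c", "s"]

    def test_exact_duplicates_collapsed(self):
        genome, feat = self._setup()
        a = feat("a", 100, 400, FeatureClass.CDS, Tier.PSC)
        b = feat("b", 100, 400, FeatureClass.CDS, Tier.PSC)
        kept = overlap_filter([a, b], genome)
        assert len(kept) == 1
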