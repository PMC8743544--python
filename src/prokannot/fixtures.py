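"""Deterministic synthetic test bed.

Generates (a) a toy reference proteome with a known UniRef-style cluster
hierarchy plus all flat-file inputs the database compiler consumes, and
(b) a toy genome with planted genes, sORFs and (optionally) one
origin-spanning gene, plus a ground-truth record of every planted feature.

The intergenic background is actively ORF-suppressed: a stop-codon cassette
covering all six reading frames is inserted before every planted feature,
so the naive ORF caller recovers planted coordinates exactly and background
false positives stay short. That is a property of this generator, not of
real genomes: there is no codon-usage realism, no sequencing error and no
assembly fragmentation here.
"""

from __future__ import annotations

import json
import random
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

from Bio.Data.CodonTable import unambiguous_dna_by_id

from .model import Replicon, Topology, Completeness, RepliconType, reverse_complement
from .refdb import compute_digest
from . import structural

RESIDUES = "ACDEFGHIKLMNPQRSTVWY"

#: Stop-codon cassette: contains TAA in all three forward frames and, being
#: its own reverse complement, in all three reverse frames; contains no
#: ATG/GTG/TTG start codon.
STOPPER = "TTAATTAATTAA"

# codon choices per residue (translation table 11), initiator always ATG
_CODONS: Dict[str, List[str]] = {}
for _codon, _res in unambiguous_dna_by_id[11].forward_table.items():
    _CODONS.setdefault(_res, []).append(_codon)


def _random_protein(rng: random.Random, length: int) -> str:
    return "M" + "".join(rng.choice(RESIDUES) for _ in range(length - 1))


def _mutate(rng: random.Random, seq: str, identity: float) -> str:
    """Point-substitute to the target identity; the initiator M is kept."""
    n_sub = round(len(seq) * (1.0 - identity))
    positions = rng.sample(range(1, len(seq)), n_sub)
    chars = list(seq)
    for pos in positions:
        chars[pos] = rng.choice([r for r in RESIDUES if r != chars[pos]])
    return "".join(chars)


def _reverse_translate(rng: random.Random, aa: str,
                       stop: str = "TAA") -> str:
    codons = ["ATG"]
    for res in aa[1:]:
        codons.append(rng.choice(sorted(_CODONS[res])))
    codons.append(stop)
    return "".join(codons)


def _write_fasta(path: Path, records: Sequence[Tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# Reference proteome + database build inputs
# ---------------------------------------------------------------------------

def gen_reference(seed: int, out_dir, n_clusters: int = 20,
                  members_per_cluster: int = 3,
                  identity_levels: Sequence[float] = (0.95, 0.70),
                  n_expert_rules: int = 2,
                  n_spurious: int = 2) -> dict:
    """Generate the reference proteome and every database build input.

    Each cluster has one representative protein (60-400 aa, uniform random
    residues) and ``members_per_cluster - 1`` members derived by point
    substitutions cycling through ``identity_levels``. Pairs of adjacent
    clusters share a UniRef50-level parent. Two annotation sources are
    emitted ("curated" is more specific than "cluster-derived" and wins
    conflicts). Returns the ground-truth manifest, also written as JSON.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = random.Random(seed)

    clusters = []
    proteins: List[Tuple[str, str]] = []
    membership_rows = []
    distinct_seqs = set()
    for i in range(n_clusters):
        acc = f"C{i:05d}"
        u90 = f"UniRef90_{acc}"
        u50 = f"UniRef50_F{i // 2:05d}"
        rep_seq = _random_protein(rng, rng.randint(60, 400))
        members = []
        for j in range(members_per_cluster):
            if j == 0:
                seq, level = rep_seq, 1.0
                u100 = f"UniRef100_{acc}"
            else:
                level = identity_levels[(j - 1) % len(identity_levels)]
                seq = rep_seq if level >= 1.0 else _mutate(rng, rep_seq, level)
                u100 = f"UniRef100_{acc}M{j}"
            pid = f"P{i:05d}_{j}"
            proteins.append((pid, seq))
            distinct_seqs.add(seq)
            membership_rows.append((pid, u100, u90, u50))
            members.append({"protein_id": pid, "uniref100_id": u100,
                            "seq": seq, "identity_level": level})
        clusters.append({
            "accession": acc, "uniref90_id": u90, "uniref50_id": u50,
            "rep_seq": rep_seq, "members": members,
            "gene": f"syg{i}", "psc_product": f"synthetic cluster {i} protein",
            "pscc_product": f"synthetic family {i // 2} protein",
            "ips_product": f"synthetic protein {i}" if i % 2 == 0 else None,
        })

    _write_fasta(out_dir / "proteins.faa", proteins)
    with open(out_dir / "membership.tsv", "w") as fh:
        for row in membership_rows:
            fh.write("\t".join(row) + "\n")

    # annotation sources, most specific first
    ann_dir = out_dir / "annotations"
    ann_dir.mkdir(exist_ok=True)
    with open(ann_dir / "curated.tsv", "w") as fh:
        for i, cl in enumerate(clusters):
            if cl["ips_product"]:
                fh.write("\t".join((f"UniRef100_{cl['accession']}",
                                    cl["gene"], cl["ips_product"])) + "\n")
            fh.write("\t".join((
                cl["uniref90_id"], cl["gene"], cl["psc_product"],
                f"COG{1000 + i}", "S",
                "1.1.1.1" if i % 3 == 0 else "",
                "GO:0008150" if i % 3 == 1 else "")) + "\n")
    with open(ann_dir / "cluster.tsv", "w") as fh:
        for i, cl in enumerate(clusters):
            # deliberate conflict with the curated product on every cluster
            fh.write("\t".join((cl["uniref90_id"], "",
                                f"cluster-derived product {i}")) + "\n")
            if i % 2 == 0:
                fh.write("\t".join((cl["uniref50_id"], "",
                                    cl["pscc_product"])) + "\n")
    annotation_tables = [("curated", ann_dir / "curated.tsv"),
                         ("cluster-derived", ann_dir / "cluster.tsv")]

    # expert rules over dedicated proteins absent from the clusters
    expert_rules = []
    expert_proteins = []
    for r in range(n_expert_rules):
        seq = _random_protein(rng, rng.randint(80, 200))
        rule_id = f"RULE{r:03d}"
        expert_proteins.append((rule_id, seq))
        expert_rules.append((rule_id, "synthetic-expert", str(10 * (r + 1)),
                             f"exg{r}", f"expert product {r}",
                             "0.9", "0.9", "0.9", f"Expert:{rule_id}"))
    _write_fasta(out_dir / "expert.faa", expert_proteins)
    with open(out_dir / "expert.tsv", "w") as fh:
        for row in expert_rules:
            fh.write("\t".join(row) + "\n")

    spurious = [_random_protein(rng, rng.randint(40, 80))
                for _ in range(n_spurious)]
    with open(out_dir / "blocklist.txt", "w") as fh:
        for seq in spurious:
            fh.write(compute_digest(seq).hex() + "\n")

    manifest = {
        "seed": seed,
        "clusters": clusters,
        "spurious": spurious,
        "expert": [{"rule_id": rid, "seq": seq}
                   for rid, seq in expert_proteins],
        "counts": {
            "proteins": len(proteins),
            "ups": len(distinct_seqs),
            "ips": len({r[1] for r in membership_rows}),
            "psc": n_clusters,
            "pscc": len({r[3] for r in membership_rows}),
            "expert": n_expert_rules,
            "blocklist": n_spurious,
        },
        "paths": {
            "proteins": str(out_dir / "proteins.faa"),
            "membership": str(out_dir / "membership.tsv"),
            "annotations": [(s, str(p)) for s, p in annotation_tables],
            "expert_tsv": str(out_dir / "expert.tsv"),
            "expert_fasta": str(out_dir / "expert.faa"),
            "blocklist": str(out_dir / "blocklist.txt"),
        },
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1) + "\n")
    return manifest


# ---------------------------------------------------------------------------
# Genome with planted features
# ---------------------------------------------------------------------------

def _no_long_orf(segment: str, min_aa: int) -> bool:
    """No ORF of CDS-calling length on either strand of the segment; keeps
    planted sORFs from being shadowed by a spurious overlapping CDS call."""
    for s in (segment, reverse_complement(segment)):
        if structural._walk_orfs(s, False, min_aa, None):
            return False
    return True


def gen_genome(seed: int, manifest: dict, out_dir,
               n_exact: int = 50, n_psc_mutants: int = 20,
               n_pscc_mutants: int = 20, n_sorfs: int = 5,
               with_edge_gene: bool = True,
               replicon_id: str = "chr1") -> dict:
    """Assemble a circular toy replicon with planted features.

    Exact copies of reference proteins are expected to resolve
    alignment-free at the ips tier; fresh ~95%-identity mutants of cluster
    representatives at the psc tier; fresh ~70%-identity mutants at the
    pscc tier; random sORFs and the optional origin-spanning gene are not
    in the reference set and come out hypothetical. Writes genome FASTA,
    replicon TSV, a truth GFF3 (the origin-spanning gene as a partial CDS
    pair) and returns the truth manifest.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = random.Random(seed + 1)
    clusters = manifest["clusters"]
    db_seqs = {m["seq"] for cl in clusters for m in cl["members"]}

    # pick planted proteins
    planted: List[dict] = []  # {aa, nt, tier, kind, cluster}
    member_pool = [m for cl in clusters for m in cl["members"]]
    seen = set()
    exact_members = []
    for m in member_pool:
        if m["seq"] not in seen:
            seen.add(m["seq"])
            exact_members.append(m)
    if n_exact > len(exact_members):
        raise ValueError("not enough distinct reference proteins to plant")
    member_cluster = {m["uniref100_id"]: cl["accession"] for cl in clusters
                      for m in cl["members"]}
    for m in exact_members[:n_exact]:
        planted.append({"aa": m["seq"], "tier": "ips", "kind": "exact",
                        "ref": m["uniref100_id"],
                        "cluster": member_cluster[m["uniref100_id"]]})

    def fresh_mutant(cl, level):
        for _ in range(20):
            seq = _mutate(rng, cl["rep_seq"], level)
            if seq not in db_seqs:
                return seq
        raise RuntimeError("could not derive a novel mutant sequence")

    for k in range(n_psc_mutants):
        cl = clusters[k % len(clusters)]
        planted.append({"aa": fresh_mutant(cl, 0.95), "tier": "psc",
                        "kind": "mutant95", "ref": cl["uniref90_id"],
                        "cluster": cl["accession"]})
    for k in range(n_pscc_mutants):
        cl = clusters[k % len(clusters)]
        planted.append({"aa": fresh_mutant(cl, 0.70), "tier": "pscc",
                        "kind": "mutant70", "ref": cl["uniref50_id"],
                        "cluster": cl["accession"]})

    for s in range(n_sorfs):
        length = rng.randint(8, 29)
        for _ in range(50):
            aa = _random_protein(rng, length)
            nt = _reverse_translate(rng, aa)
            if aa not in db_seqs and _no_long_orf(
                    STOPPER + nt + STOPPER, structural.DEFAULT_MIN_CDS_AA):
                break
        else:
            raise RuntimeError("could not place an ORF-free sORF segment")
        planted.append({"aa": aa, "nt": nt, "tier": "hypothetical",
                        "kind": "sorf", "ref": None})

    rng.shuffle(planted)

    # assemble: [edge head][stopper features stopper]...[stopper][edge tail]
    truth: List[dict] = []
    parts: List[str] = []
    pos = 0

    edge_gene: Optional[dict] = None
    if with_edge_gene:
        aa = _random_protein(rng, 82)
        nt = _reverse_translate(rng, aa)  # 249 nt
        assert len(nt) == 249
        head, tail = nt[99:], nt[:99]  # 150 nt into the start, 99 at the end
        parts.append(head)
        pos = len(head)
        edge_gene = {"aa": aa, "nt": nt, "tier": "hypothetical",
                     "kind": "edge", "ref": None,
                     "head_len": len(head), "tail_len": len(tail)}

    for item in planted:
        pad = "A" * rng.randint(0, 2)
        parts.append(pad + STOPPER)
        pos += len(pad) + len(STOPPER)
        if item["kind"] == "sorf":
            nt = item["nt"]
        else:
            nt = _reverse_translate(rng, item["aa"])
        parts.append(nt)
        truth.append({
            "start": pos, "stop": pos + len(nt), "strand": "+",
            "class": "sorf" if item["kind"] == "sorf" else "cds",
            "tier": item["tier"], "kind": item["kind"], "ref": item["ref"],
            "cluster": item.get("cluster"), "aa": item["aa"],
        })
        pos += len(nt)

    parts.append(STOPPER)
    pos += len(STOPPER)
    if edge_gene is not None:
        parts.append(edge_gene["nt"][:99])
        pos += 99
    seq = "".join(parts)
    L = len(seq)
    assert pos == L
    if edge_gene is not None:
        truth.append({
            "start": L - 99, "stop": L + 150, "strand": "+", "class": "cds",
            "tier": edge_gene["tier"], "kind": "edge", "ref": None,
            "aa": edge_gene["aa"],
        })

    fasta_path = out_dir / "genome.fasta"
    _write_fasta(fasta_path, [(replicon_id, seq)])
    tsv_path = out_dir / "replicons.tsv"
    tsv_path.write_text(
        f"{replicon_id}\t{replicon_id}\tchromosome\tcircular\ttoy\n")

    gff_path = out_dir / "truth.gff3"
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {replicon_id} 1 {L}\n")
        n = 0
        for t in truth:
            n += 1
            ftype = "sORF" if t["class"] == "sorf" else "CDS"
            if t["stop"] <= L:
                fh.write("\t".join((
                    replicon_id, "fixture", ftype, str(t["start"] + 1),
                    str(t["stop"]), ".", t["strand"], "0",
                    f"ID=truth_{n:04d};expected_tier={t['tier']}")) + "\n")
            else:
                # origin-spanning gene as the partial pair a predictor
                # would emit: 3'-truncated tail, then 5'-truncated head
                fh.write("\t".join((
                    replicon_id, "fixture", ftype, str(t["start"] + 1),
                    str(L), ".", t["strand"], "0",
                    f"ID=truth_{n:04d}a;partial3=true;"
                    f"expected_tier={t['tier']}")) + "\n")
                fh.write("\t".join((
                    replicon_id, "fixture", ftype, "1", str(t["stop"] - L),
                    ".", t["strand"], "0",
                    f"ID=truth_{n:04d}b;partial5=true;"
                    f"expected_tier={t['tier']}")) + "\n")

    genome_truth = {
        "seed": seed,
        "replicon_id": replicon_id,
        "length": L,
        "features": truth,
        "paths": {"fasta": str(fasta_path), "replicons": str(tsv_path),
                  "truth_gff3": str(gff_path)},
        "counts": {"exact": n_exact, "psc_mutants": n_psc_mutants,
                   "pscc_mutants": n_pscc_mutants, "sorfs": n_sorfs,
                   "edge": int(with_edge_gene)},
    }
    (out_dir / "genome_truth.json").write_text(
        json.dumps(genome_truth, indent=1) + "\n")
    return genome_truth


def make_replicon(seq: str, circular: bool = False,
                  replicon_id: str = "rep1") -> Replicon:
    """Convenience wrapper used across the test suite."""
    return Replicon(
        id=replicon_id, seq=seq,
        topology=Topology.CIRCULAR if circular else Topology.LINEAR,
        completeness=(Completeness.COMPLETE if circular
                      else Completeness.INCOMPLETE),
        rep_type=RepliconType.CHROMOSOME if circular else RepliconType.CONTIG)
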