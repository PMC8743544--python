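"""File input/output.

Readers: genome FASTA (optionally gzip-compressed) with an optional
replicon-metadata TSV. Writers: GFF3, nucleotide/protein FASTA, feature
summary TSV, hypothetical-protein TSV, and a versioned JSON result document
that round-trips the full annotation model.

Coordinates are converted from the internal 0-based half-open convention to
1-based inclusive here and nowhere else. Origin-spanning features are
emitted as two GFF3 location lines sharing one ``ID`` attribute so that the
files stay parseable by strict validators.
"""

from __future__ import annotations

import gzip
import json
from pathlib import Path
from typing import Iterable, List, Optional, Tuple

from Bio import SeqIO

from .model import (
    Annotation,
    CdsFeature,
    Completeness,
    FeatureClass,
    Genome,
    Replicon,
    RepliconType,
    Tier,
    Topology,
)

#: Version of the JSON result-document schema written by this package.
JSON_SCHEMA_VERSION = "1.0"


class ResultSchemaError(ValueError):
    """A JSON result document has an unsupported schema version."""


# ---------------------------------------------------------------------------
# Genome reading
# ---------------------------------------------------------------------------

def _open_maybe_gzip(path):
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path)


def read_replicon_tsv(path) -> dict:
    """Replicon metadata rows: original_id, new_id, type, topology, name."""
    meta = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.split("\t")
        cols += [""] * (5 - len(cols))
        original_id, new_id, rep_type, topology, name = cols[:5]
        meta[original_id] = {
            "new_id": new_id or original_id,
            "type": rep_type or "contig",
            "topology": topology or "linear",
            "name": name,
        }
    return meta


def read_genome(fasta_path, replicon_tsv=None, genome_id: str = "genome") -> Genome:
    """Load a genome FASTA (plain or gzipped) plus optional metadata TSV.

    Replicons without a metadata row default to linear, incomplete contigs.
    Circular replicons are treated as complete molecules, which enables
    origin-spanning CDS handling.
    """
    meta = read_replicon_tsv(replicon_tsv) if replicon_tsv else {}
    replicons = []
    seen = set()
    with _open_maybe_gzip(fasta_path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in seen:
                raise ValueError(f"duplicate sequence id {rec.id!r} in FASTA")
            seen.add(rec.id)
            m = meta.pop(rec.id, None)
            if m is None:
                replicons.append(Replicon(id=rec.id, seq=str(rec.seq)))
                continue
            topology = Topology(m["topology"])
            replicons.append(Replicon(
                id=m["new_id"], seq=str(rec.seq), topology=topology,
                completeness=(Completeness.COMPLETE
                              if topology is Topology.CIRCULAR
                              else Completeness.INCOMPLETE),
                rep_type=RepliconType(m["type"]), name=m["name"]))
    if meta:
        raise ValueError(
            f"replicon TSV references unknown sequence ids: {sorted(meta)}")
    return Genome(replicons=replicons, id=genome_id)


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

_GFF3_ESCAPES = {"%": "%25", ";": "%3B", "=": "%3D", "&": "%26", ",": "%2C",
                 "\t": "%09", "\n": "%0A"}


def gff3_escape(value: str) -> str:
    for raw, enc in _GFF3_ESCAPES.items():
        value = value.replace(raw, enc)
    return value


def _feature_attributes(feat: CdsFeature) -> str:
    parts = [f"ID={gff3_escape(feat.id)}"]
    ann = feat.annotation
    if ann is not None:
        if ann.gene:
            parts.append(f"gene={gff3_escape(ann.gene)}")
        parts.append(f"product={gff3_escape(ann.product)}")
        if ann.dbxrefs:
            parts.append("Dbxref=" + ",".join(
                gff3_escape(x) for x in sorted(ann.dbxrefs)))
    if feat.partial5:
        parts.append("partial5=true")
    if feat.partial3:
        parts.append("partial3=true")
    return ";".join(parts)


def write_gff3(features: Iterable[CdsFeature], genome: Genome, path) -> None:
    """Write annotated features as GFF3 (1-based inclusive coordinates).

    An origin-spanning feature on a circular replicon becomes two lines
    sharing one ID: the part up to the sequence end, then the wrapped part
    from base 1.
    """
    source = "prokannot"
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for rep in genome.replicons:
            fh.write(f"##sequence-region {rep.id} 1 {rep.length}\n")
        for feat in features:
            rep = genome.get(feat.replicon_id)
            ftype = "sORF" if feat.feature_class is FeatureClass.SORF else "CDS"
            attrs = _feature_attributes(feat)
            if feat.edge and feat.stop > rep.length:
                spans = [(feat.start + 1, rep.length),
                         (1, feat.stop - rep.length)]
            else:
                spans = [(feat.start + 1, feat.stop)]
            for lo, hi in spans:
                fh.write("\t".join((
                    rep.id, source, ftype, str(lo), str(hi), ".",
                    feat.strand, "0", attrs)) + "\n")


# ---------------------------------------------------------------------------
# JSON result document
# ---------------------------------------------------------------------------

def _annotation_to_dict(ann: Optional[Annotation]):
    if ann is None:
        return None
    return {
        "gene": ann.gene,
        "product": ann.product,
        "dbxrefs": sorted(ann.dbxrefs),
        "tier": ann.tier.value,
        "rule_rank": ann.rule_rank,
    }


def _annotation_from_dict(d) -> Optional[Annotation]:
    if d is None:
        return None
    return Annotation(product=d["product"], gene=d.get("gene"),
                      dbxrefs=set(d.get("dbxrefs", [])),
                      tier=Tier(d["tier"]), rule_rank=d.get("rule_rank"))


def _feature_to_dict(feat: CdsFeature) -> dict:
    return {
        "id": feat.id,
        "replicon_id": feat.replicon_id,
        "start": feat.start,
        "stop": feat.stop,
        "strand": feat.strand,
        "partial5": feat.partial5,
        "partial3": feat.partial3,
        "edge": feat.edge,
        "class": feat.feature_class.value,
        "nt": feat.nt,
        "aa": feat.aa,
        "annotation": _annotation_to_dict(feat.annotation),
        "mass": feat.mass,
        "pi": feat.pi,
    }


def _feature_from_dict(d: dict) -> CdsFeature:
    return CdsFeature(
        id=d["id"], replicon_id=d["replicon_id"], start=d["start"],
        stop=d["stop"], strand=d["strand"], partial5=d["partial5"],
        partial3=d["partial3"], edge=d["edge"],
        feature_class=FeatureClass(d["class"]), nt=d["nt"], aa=d["aa"],
        annotation=_annotation_from_dict(d.get("annotation")),
        mass=d.get("mass"), pi=d.get("pi"))


def write_json(features: Iterable[CdsFeature], genome: Genome,
               run_meta: dict, path) -> None:
    """Write the full result document: genome, features, run metadata."""
    doc = {
        "schema": JSON_SCHEMA_VERSION,
        "genome": {
            "id": genome.id,
            "replicons": [{
                "id": rep.id,
                "seq": rep.seq,
                "topology": rep.topology.value,
                "completeness": rep.completeness.value,
                "type": rep.rep_type.value,
                "name": rep.name,
                "length": rep.length,
            } for rep in genome.replicons],
        },
        "features": [_feature_to_dict(f) for f in features],
        "run": run_meta,
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n")


def read_json(path) -> Tuple[List[CdsFeature], Genome, dict]:
    """Restore a result document written by :func:`write_json`."""
    doc = json.loads(Path(path).read_text())
    schema = doc.get("schema")
    if schema != JSON_SCHEMA_VERSION:
        raise ResultSchemaError(
            f"unsupported result schema {schema!r}; "
            f"this reader supports {JSON_SCHEMA_VERSION}")
    replicons = [Replicon(
        id=r["id"], seq=r["seq"], topology=Topology(r["topology"]),
        completeness=Completeness(r["completeness"]),
        rep_type=RepliconType(r["type"]), name=r.get("name", ""))
        for r in doc["genome"]["replicons"]]
    genome = Genome(replicons=replicons, id=doc["genome"]["id"])
    features = [_feature_from_dict(d) for d in doc["features"]]
    return features, genome, doc["run"]


# ---------------------------------------------------------------------------
# FASTA and TSV outputs
# ---------------------------------------------------------------------------

def _wrap(seq: str, width: int = 60) -> str:
    return "\n".join(seq[i : i + width] for i in range(0, len(seq), width))


def write_fastas(features: Iterable[CdsFeature], genome: Genome,
                 prefix) -> Tuple[Path, Path]:
    """Write feature nucleotide (.ffn) and protein (.faa) FASTA files."""
    features = list(features)
    prefix = Path(prefix)
    ffn, faa = prefix.with_suffix(".ffn"), prefix.with_suffix(".faa")
    with open(ffn, "w") as fh:
        for feat in features:
            fh.write(f">{feat.id} {feat.annotation.product if feat.annotation else ''}\n")
            fh.write(_wrap(feat.nt) + "\n")
    with open(faa, "w") as fh:
        for feat in features:
            if not feat.aa:
                continue
            fh.write(f">{feat.id} {feat.annotation.product if feat.annotation else ''}\n")
            fh.write(_wrap(feat.aa) + "\n")
    return ffn, faa


_SUMMARY_COLS = ("replicon", "class", "start", "stop", "strand", "gene",
                 "product", "dbxref_count", "tier")


def write_summary_tsv(features: Iterable[CdsFeature], path) -> None:
    """Compact human-readable feature table, one row per feature."""
    with open(path, "w") as fh:
        fh.write("\t".join(_SUMMARY_COLS) + "\n")
        for feat in features:
            ann = feat.annotation
            fh.write("\t".join((
                feat.replicon_id, feat.feature_class.value,
                str(feat.start + 1), str(feat.stop), feat.strand,
                (ann.gene or "") if ann else "",
                ann.product if ann else "",
                str(len(ann.dbxrefs)) if ann else "0",
                ann.tier.value if ann else "")) + "\n")


def write_hypotheticals_tsv(features: Iterable[CdsFeature], path) -> None:
    """Hypothetical proteins with their sequence-based characterizations."""
    with open(path, "w") as fh:
        fh.write("\t".join(_SUMMARY_COLS + ("mass_da", "pi")) + "\n")
        for feat in features:
            ann = feat.annotation
            if ann is None or ann.tier is not Tier.HYPOTHETICAL:
                continue
            fh.write("\t".join((
                feat.replicon_id, feat.feature_class.value,
                str(feat.start + 1), str(feat.stop), feat.strand,
                ann.gene or "", ann.product, str(len(ann.dbxrefs)),
                ann.tier.value,
                f"{feat.mass:.2f}" if feat.mass is not None else "",
                f"{feat.pi:.2f}" if feat.pi is not None else "")) + "\n")
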