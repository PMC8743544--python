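"""Hierarchical protein-annotation reference store.

The store is a single-file embedded SQLite database holding four linked
record tiers keyed by protein identity at decreasing resolution:

* UPS  — unique protein sequences, keyed by the 16-byte MD5 digest of the
  full-length amino-acid sequence (plus its length, to guard lookups
  against hash collisions);
* IPS  — UniRef100-level records carrying gene/product and the link to the
  parent UniRef90 cluster;
* PSC  — UniRef90-level clusters with a representative sequence (used by
  the homology search) and functional annotation (COG, EC, GO);
* PSCC — UniRef50-level clusters providing coarse product names.

Identifier prefixes (``UniRef100_`` etc.) are stripped before storage and
restored at query time. The database carries a strict ``<major>.<minor>``
schema version; a major mismatch is a hard incompatibility. Every insert and
every annotation supersession during a build is appended to a TSV audit log.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sqlite3
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Optional

from . import model
from .model import (
    DbMeta,
    ExpertRule,
    IpsRecord,
    PscRecord,
    PsccRecord,
    UpsRecord,
    canonicalize_protein,
)

logger = logging.getLogger(__name__)

#: Schema major version this code reads and writes.
SCHEMA_MAJOR = 1

#: Registered identifier namespaces: namespace -> public prefix.
NAMESPACES = {
    "uniref100": "UniRef100_",
    "uniref90": "UniRef90_",
    "uniref50": "UniRef50_",
    "refseq": "WP_",
    "uniparc": "UPI",
}


class DbBuildError(Exception):
    """A hard failure during database compilation (collision, bad row...)."""


class DbVersionError(Exception):
    """Schema major version of a database is incompatible with this code."""


def compute_digest(aa: str) -> bytes:
    """16-byte MD5 digest of a canonical amino-acid sequence."""
    return hashlib.md5(aa.encode("ascii")).digest()


def namespace_of(public_id: str) -> Optional[str]:
    for ns, prefix in NAMESPACES.items():
        if public_id.startswith(prefix):
            return ns
    return None


def shorten_id(public_id: str) -> str:
    """Strip a registered namespace prefix; unregistered ids pass verbatim."""
    ns = namespace_of(public_id)
    if ns is None:
        return public_id
    return public_id[len(NAMESPACES[ns]) :]


def expand_id(stored_id: str, namespace: str) -> str:
    """Restore the public prefix of a stored identifier."""
    return NAMESPACES[namespace] + stored_id


_SCHEMA = """
CREATE TABLE meta (key TEXT PRIMARY KEY, value TEXT NOT NULL);
CREATE TABLE ups (
    digest BLOB PRIMARY KEY,
    length INTEGER NOT NULL,
    uniref100 TEXT NOT NULL,
    uniparc TEXT
);
CREATE TABLE ips (
    uniref100 TEXT PRIMARY KEY,
    uniref90 TEXT,
    gene TEXT,
    product TEXT
);
CREATE TABLE psc (
    uniref90 TEXT PRIMARY KEY,
    uniref50 TEXT,
    gene TEXT,
    product TEXT,
    cog_id TEXT,
    cog_category TEXT,
    ec TEXT,
    go TEXT,
    rep_seq TEXT NOT NULL
);
CREATE TABLE pscc (uniref50 TEXT PRIMARY KEY, product TEXT);
CREATE TABLE expert (
    rule_id TEXT PRIMARY KEY,
    source TEXT NOT NULL,
    rank INTEGER NOT NULL,
    gene TEXT,
    product TEXT NOT NULL,
    min_identity REAL NOT NULL,
    min_query_cov REAL NOT NULL,
    min_subject_cov REAL NOT NULL,
    seq TEXT NOT NULL,
    dbxrefs TEXT
);
CREATE TABLE blocklist (digest BLOB PRIMARY KEY);
"""


@dataclass
class AuditLog:
    """TSV audit trail of a database build.

    Columns: event, record_type, key, source, field, old, new. Timestamps
    are deliberately absent so that identical builds produce identical logs.
    """

    rows: list = field(default_factory=list)

    def emit(self, event: str, record_type: str, key: str, source: str = "",
             fld: str = "", old: str = "", new: str = "") -> None:
        self.rows.append((event, record_type, key, source, fld, old, new))

    def write(self, path: Path) -> None:
        with open(path, "w") as fh:
            fh.write("event\trecord_type\tkey\tsource\tfield\told\tnew\n")
            for row in self.rows:
                fh.write("\t".join(row) + "\n")


def _read_fasta(path) -> dict:
    from Bio import SeqIO

    seqs = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise DbBuildError(f"duplicate FASTA id {rec.id!r}")
        seqs[rec.id] = canonicalize_protein(str(rec.seq))
    return seqs


def _read_tsv(path) -> list:
    import csv

    with open(path, newline="") as fh:
        return [row for row in csv.reader(fh, delimiter="\t")
                if row and not row[0].startswith("#")]


def _split_multi(value: str) -> tuple:
    return tuple(v for v in (value or "").split(",") if v)


def build_db(
    proteins_fasta,
    membership_tsv,
    annotation_tables: Iterable,
    out_db,
    expert_tsv=None,
    expert_fasta=None,
    blocklist=None,
    version: str = "1.0",
    log_path=None,
    meta_path=None,
    digest_fn: Callable[[str], bytes] = compute_digest,
) -> DbMeta:
    """Compile the reference database from flat-file build inputs.

    ``annotation_tables`` is an ordered sequence of ``(source_name, path)``
    pairs, most specific source first; once a field is set by a more
    specific source, later sources do not overwrite it (the skipped
    supersession is logged). Digest uniqueness across distinct sequences is
    enforced: a collision aborts the build naming both record ids.
    ``digest_fn`` exists as a seam for collision-injection tests.
    """
    out_db = Path(out_db)
    log_path = Path(log_path) if log_path else out_db.with_suffix(".log.tsv")
    meta_path = Path(meta_path) if meta_path else out_db.with_suffix(".meta.json")

    try:
        major_s, minor_s = str(version).split(".")
        major, minor = int(major_s), int(minor_s)
    except ValueError as exc:
        raise DbBuildError(f"version must be <major>.<minor>, got {version!r}") from exc
    if major < 1:
        raise DbBuildError(f"schema major version must be >= 1, got {major}")

    log = AuditLog()
    proteins = _read_fasta(proteins_fasta)

    membership = []  # (protein_id, u100, u90, u50) with prefixes stripped
    seen_proteins = set()
    for lineno, row in enumerate(_read_tsv(membership_tsv), start=1):
        if len(row) < 2 or not row[0] or not row[1]:
            raise DbBuildError(f"membership row {lineno}: malformed: {row!r}")
        pid, u100 = row[0], row[1]
        u90 = row[2] if len(row) > 2 and row[2] else None
        u50 = row[3] if len(row) > 3 and row[3] else None
        if pid not in proteins:
            raise DbBuildError(
                f"membership row {lineno}: unknown protein id {pid!r}")
        seen_proteins.add(pid)
        membership.append((pid, shorten_id(u100), u90 and shorten_id(u90),
                           u50 and shorten_id(u50)))
    missing = sorted(set(proteins) - seen_proteins)
    if missing:
        raise DbBuildError(f"proteins without membership rows: {missing}")

    # UPS: dedup by digest, enforce digest uniqueness across distinct seqs.
    ups: dict = {}  # digest -> [length, uniref100, uniparc, seq, protein_id]
    ips: dict = {}  # uniref100 -> [uniref90, gene, product]
    psc: dict = {}  # uniref90 -> [uniref50, gene, product, cog, cat, ec, go, rep_seq]
    pscc: dict = {}  # uniref50 -> [product]
    for pid, u100, u90, u50 in membership:
        seq = proteins[pid]
        digest = digest_fn(seq)
        if digest in ups:
            if ups[digest][3] != seq:
                raise DbBuildError(
                    "digest collision between distinct sequences: "
                    f"{ups[digest][4]!r} and {pid!r}")
            log.emit("dedup", "ups", digest.hex(), "", "uniref100",
                     ups[digest][1], u100)
        else:
            ups[digest] = [len(seq), u100, None, seq, pid]
            log.emit("insert", "ups", digest.hex(), "", "uniref100", "", u100)
        if u100 in ips:
            if ips[u100][0] != u90:
                raise DbBuildError(
                    f"conflicting cluster assignment for UniRef100 {u100!r}: "
                    f"{ips[u100][0]!r} vs {u90!r}")
        else:
            ips[u100] = [u90, None, None]
            log.emit("insert", "ips", u100, "", "uniref90", "", u90 or "")
        if u90 is not None:
            if u90 not in psc:
                psc[u90] = [u50, None, None, None, None, (), (), None]
                log.emit("insert", "psc", u90, "", "uniref50", "", u50 or "")
            elif psc[u90][0] != u50:
                raise DbBuildError(
                    f"conflicting cluster assignment for UniRef90 {u90!r}: "
                    f"{psc[u90][0]!r} vs {u50!r}")
            # representative: the member whose UniRef100 accession equals the
            # cluster accession; first member otherwise.
            if psc[u90][7] is None or u100 == u90:
                psc[u90][7] = seq
        if u50 is not None and u50 not in pscc:
            pscc[u50] = [None]
            log.emit("insert", "pscc", u50, "", "", "", "")

    # Functional annotation, most specific source first.
    _PSC_FIELDS = {"gene": 1, "product": 2, "cog_id": 3, "cog_category": 4,
                   "ec": 5, "go": 6}
    for source, path in annotation_tables:
        for lineno, row in enumerate(_read_tsv(path), start=1):
            if not row or not row[0]:
                raise DbBuildError(f"{source} row {lineno}: malformed: {row!r}")
            key = row[0]
            cols = row[1:] + [""] * (6 - len(row[1:]))
            gene, product, cog_id, cog_cat, ec, go = cols[:6]
            ns = namespace_of(key)
            short = shorten_id(key)
            if ns == "uniref100" and short in ips:
                rec = ips[short]
                for idx, fld, val in ((1, "gene", gene), (2, "product", product)):
                    if not val:
                        continue
                    if rec[idx] is None:
                        rec[idx] = val
                        log.emit("annotate", "ips", short, source, fld, "", val)
                    elif rec[idx] != val:
                        log.emit("supersede_skip", "ips", short, source, fld,
                                 rec[idx], val)
            elif ns == "uniref90" and short in psc:
                rec = psc[short]
                values = {"gene": gene, "product": product, "cog_id": cog_id,
                          "cog_category": cog_cat, "ec": _split_multi(ec),
                          "go": _split_multi(go)}
                for fld, idx in _PSC_FIELDS.items():
                    val = values[fld]
                    if not val:
                        continue
                    empty = rec[idx] is None or rec[idx] == ()
                    if empty:
                        rec[idx] = val
                        log.emit("annotate", "psc", short, source, fld, "",
                                 str(val))
                    elif rec[idx] != val:
                        log.emit("supersede_skip", "psc", short, source, fld,
                                 str(rec[idx]), str(val))
            elif ns == "uniref50" and short in pscc:
                rec = pscc[short]
                if product:
                    if rec[0] is None:
                        rec[0] = product
                        log.emit("annotate", "pscc", short, source, "product",
                                 "", product)
                    elif rec[0] != product:
                        log.emit("supersede_skip", "pscc", short, source,
                                 "product", rec[0], product)
            else:
                log.emit("dangling", ns or "unknown", key, source)

    for u90, rec in psc.items():
        for ec in rec[5]:
            if not _valid_ec(ec):
                raise DbBuildError(f"PSC {u90!r}: invalid EC number {ec!r}")
        for go in rec[6]:
            if not _valid_go(go):
                raise DbBuildError(f"PSC {u90!r}: invalid GO term {go!r}")

    # Expert rules.
    expert_rows = []
    if expert_tsv is not None:
        rule_seqs = _read_fasta(expert_fasta) if expert_fasta else {}
        for lineno, row in enumerate(_read_tsv(expert_tsv), start=1):
            if len(row) < 8:
                raise DbBuildError(f"expert row {lineno}: malformed: {row!r}")
            rule_id, source, rank, gene, product, mi, mq, ms = row[:8]
            dbx = row[8] if len(row) > 8 else ""
            if rule_id not in rule_seqs:
                raise DbBuildError(
                    f"expert row {lineno}: no sequence for rule {rule_id!r}")
            rule = ExpertRule(
                rule_id=rule_id, source=source, rank=int(rank),
                gene=gene or None, product=product, seq=rule_seqs[rule_id],
                min_identity=float(mi), min_query_cov=float(mq),
                min_subject_cov=float(ms), dbxrefs=_split_multi(dbx))
            expert_rows.append(rule)
            log.emit("insert", "expert", rule_id, source, "product", "", product)

    # Spurious-sequence blocklist.
    block_digests = []
    if blocklist is not None:
        for line in Path(blocklist).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if len(line) != 32:
                raise DbBuildError(f"blocklist digest not 32 hex chars: {line!r}")
            block_digests.append(bytes.fromhex(line))
            log.emit("insert", "blocklist", line, "", "", "", "")

    counts = {"ups": len(ups), "ips": len(ips), "psc": len(psc),
              "pscc": len(pscc), "expert": len(expert_rows),
              "blocklist": len(block_digests)}
    meta = DbMeta(schema_major=major, schema_minor=minor, counts=counts,
                  build_log_path=str(log_path))

    out_db.unlink(missing_ok=True)
    conn = sqlite3.connect(out_db)
    try:
        conn.executescript(_SCHEMA)
        conn.executemany("INSERT INTO meta VALUES (?,?)", [
            ("schema_major", str(major)), ("schema_minor", str(minor)),
            ("counts", json.dumps(counts))])
        conn.executemany(
            "INSERT INTO ups VALUES (?,?,?,?)",
            [(d, r[0], r[1], r[2]) for d, r in ups.items()])
        conn.executemany(
            "INSERT INTO ips VALUES (?,?,?,?)",
            [(k, r[0], r[1], r[2]) for k, r in ips.items()])
        conn.executemany(
            "INSERT INTO psc VALUES (?,?,?,?,?,?,?,?,?)",
            [(k, r[0], r[1], r[2], r[3], r[4], ",".join(r[5]), ",".join(r[6]),
              r[7] or "") for k, r in psc.items()])
        conn.executemany(
            "INSERT INTO pscc VALUES (?,?)",
            [(k, r[0]) for k, r in pscc.items()])
        conn.executemany(
            "INSERT INTO expert VALUES (?,?,?,?,?,?,?,?,?,?)",
            [(r.rule_id, r.source, r.rank, r.gene, r.product, r.min_identity,
              r.min_query_cov, r.min_subject_cov, r.seq, ",".join(r.dbxrefs))
             for r in expert_rows])
        conn.executemany("INSERT INTO blocklist VALUES (?)",
                         [(d,) for d in block_digests])
        conn.commit()
        conn.execute("VACUUM")
    finally:
        conn.close()

    log.write(log_path)
    meta_path.write_text(json.dumps(
        {"schema_version": meta.version, "counts": counts}, indent=2) + "\n")
    return meta


def _valid_ec(ec: str) -> bool:
    parts = ec.split(".")
    return len(parts) == 4 and all(
        p == "-" or p.replace("n", "").isdigit() for p in parts if p)


def _valid_go(go: str) -> bool:
    return go.startswith("GO:") and len(go) == 10 and go[3:].isdigit()


class RefDb:
    """Read-only handle on a compiled reference database."""

    def __init__(self, path):
        self.path = Path(path)
        if not self.path.exists():
            raise FileNotFoundError(f"no reference database at {self.path}")
        self._conn = sqlite3.connect(f"file:{self.path}?mode=ro", uri=True)
        row = dict(self._conn.execute("SELECT key, value FROM meta").fetchall())
        self.meta = DbMeta(
            schema_major=int(row["schema_major"]),
            schema_minor=int(row["schema_minor"]),
            counts=json.loads(row.get("counts", "{}")))
        self.warnings: list = []

    def close(self) -> None:
        self._conn.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()

    # -- version ---------------------------------------------------------
    def check_version(self, supported_major: int = SCHEMA_MAJOR) -> None:
        """Any minor version under a matching major is compatible."""
        if self.meta.schema_major != supported_major:
            raise DbVersionError(
                f"database schema {self.meta.version} incompatible with "
                f"supported major version {supported_major}")

    # -- lookups ---------------------------------------------------------
    def lookup_ups(self, digest: bytes, aa_length: int):
        """AFSI core lookup: digest match AND stored-length equality.

        A digest match whose stored length differs is treated as a potential
        hash collision: nothing is returned and a warning is recorded.
        """
        row = self._conn.execute(
            "SELECT length, uniref100, uniparc FROM ups WHERE digest = ?",
            (digest,)).fetchone()
        if row is None:
            return None
        length, u100, uniparc = row
        if length != aa_length:
            msg = (f"digest {digest.hex()} length mismatch: stored {length}, "
                   f"query {aa_length}; treated as unidentified")
            self.warnings.append(msg)
            logger.warning(msg)
            return None
        ups = UpsRecord(digest=digest, aa_length=length,
                        uniref100_id=expand_id(u100, "uniref100"),
                        uniparc_id=expand_id(uniparc, "uniparc") if uniparc else None)
        return ups, self.lookup_ips(ups.uniref100_id)

    def lookup_ips(self, uniref100_id: str) -> Optional[IpsRecord]:
        row = self._conn.execute(
            "SELECT uniref90, gene, product FROM ips WHERE uniref100 = ?",
            (shorten_id(uniref100_id),)).fetchone()
        if row is None:
            return None
        u90, gene, product = row
        return IpsRecord(
            uniref100_id=expand_id(shorten_id(uniref100_id), "uniref100"),
            uniref90_id=expand_id(u90, "uniref90") if u90 else None,
            gene=gene, product=product)

    def lookup_psc(self, uniref90_id: str) -> Optional[PscRecord]:
        row = self._conn.execute(
            "SELECT uniref50, gene, product, cog_id, cog_category, ec, go, "
            "rep_seq FROM psc WHERE uniref90 = ?",
            (shorten_id(uniref90_id),)).fetchone()
        if row is None:
            return None
        u50, gene, product, cog_id, cog_cat, ec, go, rep_seq = row
        return PscRecord(
            uniref90_id=expand_id(shorten_id(uniref90_id), "uniref90"),
            uniref50_id=expand_id(u50, "uniref50") if u50 else None,
            gene=gene, product=product, cog_id=cog_id, cog_category=cog_cat,
            ec=_split_multi(ec), go=_split_multi(go), rep_seq=rep_seq)

    def lookup_pscc(self, uniref50_id: str) -> Optional[PsccRecord]:
        row = self._conn.execute(
            "SELECT product FROM pscc WHERE uniref50 = ?",
            (shorten_id(uniref50_id),)).fetchone()
        if row is None:
            return None
        return PsccRecord(
            uniref50_id=expand_id(shorten_id(uniref50_id), "uniref50"),
            product=row[0])

    def iter_psc_reps(self):
        """Yield (public uniref90 id, representative sequence) pairs."""
        for u90, rep in self._conn.execute(
                "SELECT uniref90, rep_seq FROM psc ORDER BY uniref90"):
            if rep:
                yield expand_id(u90, "uniref90"), rep

    def expert_rules(self) -> list:
        rules = []
        for row in self._conn.execute(
                "SELECT rule_id, source, rank, gene, product, min_identity, "
                "min_query_cov, min_subject_cov, seq, dbxrefs FROM expert "
                "ORDER BY rule_id"):
            rules.append(ExpertRule(
                rule_id=row[0], source=row[1], rank=row[2], gene=row[3] or None,
                product=row[4], min_identity=row[5], min_query_cov=row[6],
                min_subject_cov=row[7], seq=row[8], dbxrefs=_split_multi(row[9])))
        return rules

    def is_blocked(self, digest: bytes) -> bool:
        return self._conn.execute(
            "SELECT 1 FROM blocklist WHERE digest = ?", (digest,)
        ).fetchone() is not None
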