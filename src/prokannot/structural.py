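"""Structural CDS handling.

Ingests externally predicted CDS coordinates (GFF3), or falls back to a
built-in naive ORF caller, merges origin-spanning partial CDS pairs on
complete circular replicons, extracts short ORFs (sORFs) below the de-novo
length cut-off, and removes known spurious sequences through a pluggable
filter backend.

Origin-spanning features are represented as a single feature with
``edge=True`` and an unwrapped ``stop`` beyond the replicon length; the
wrap back into [0, length) happens in the writers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, List, Optional, Tuple

from . import model
from .model import (
    CdsFeature,
    FeatureClass,
    Genome,
    InternalStopError,
    Replicon,
    SequenceError,
    reverse_complement,
    translate,
)
from .refdb import compute_digest

STOP_CODONS = frozenset(("TAA", "TAG", "TGA"))

#: Default minimum CDS length produced by the naive caller, in amino acids.
DEFAULT_MIN_CDS_AA = 30
#: sORF length window (amino acids): min inclusive, max exclusive.
DEFAULT_MIN_SORF_AA = 7
DEFAULT_MAX_SORF_AA = 30


class SpuriousFilterError(Exception):
    """The spurious-sequence backend failed; filtering must never be skipped
    silently."""


@dataclass
class PartialCdsPair:
    """A candidate origin-spanning pair: one partial CDS touching the
    replicon start (5' sequence edge) and one touching its end."""

    five_prime_partial: CdsFeature
    three_prime_partial: CdsFeature
    strand: str


# ---------------------------------------------------------------------------
# ORF enumeration
# ---------------------------------------------------------------------------

def _walk_orfs(seq: str, circular: bool, min_aa: int,
               max_aa_exclusive: Optional[int]) -> List[Tuple[int, int]]:
    """Enumerate all (start, unwrapped stop) ORF spans on one strand.

    An ORF runs from a start codon (ATG/GTG/TTG) to its nearest in-frame
    stop codon; on circular sequences the walk wraps across the origin but
    never exceeds one full lap. ``min_aa``/``max_aa_exclusive`` bound the
    protein length (stop codon excluded).
    """
    L = len(seq)
    scan = seq + seq if circular else seq
    starts = model.START_CODONS
    spans = []
    max_codons = L // 3  # never more than one lap
    for s in range(L):
        if scan[s : s + 3] not in starts:
            continue
        limit = min(max_codons, (len(scan) - s) // 3)
        for k in range(1, limit):
            codon = scan[s + 3 * k : s + 3 * k + 3]
            if codon in STOP_CODONS:
                aa_len = k
                if aa_len >= min_aa and (
                        max_aa_exclusive is None or aa_len < max_aa_exclusive):
                    spans.append((s, s + 3 * k + 3))
                break
    return spans


def _longest_per_stop(spans: List[Tuple[int, int]],
                      L: int) -> List[Tuple[int, int]]:
    # key stops by circle position: wrapped and unwrapped walks reaching the
    # same physical stop codon are one ORF family
    best = {}
    for s, e in spans:
        key = e % L
        if key not in best or (e - s) > (best[key][1] - best[key][0]):
            best[key] = (s, e)
    return sorted(best.values())


def _spans_to_features(spans, replicon: Replicon, strand: str,
                       feature_class: FeatureClass, id_prefix: str):
    L = replicon.length
    features = []
    for s, e in spans:
        if strand == "+":
            start, stop = s, e
        else:
            # coordinates were computed on the reverse complement
            start = (L - e) % L
            stop = start + (e - s)
        nt = replicon.slice(start, stop)
        if strand == "-":
            nt = reverse_complement(nt)
        aa = translate(nt)
        features.append(CdsFeature(
            id=f"{id_prefix}_{replicon.id}_{start}_{stop}_{strand}",
            replicon_id=replicon.id, start=start, stop=stop, strand=strand,
            nt=nt, aa=aa, edge=stop > L, feature_class=feature_class))
    return features


def naive_orf_call(replicon: Replicon,
                   min_aa: int = DEFAULT_MIN_CDS_AA) -> List[CdsFeature]:
    """Built-in fallback CDS caller: maximal ORFs on both strands.

    Reports the longest ORF per stop codon (i.e. the earliest in-frame
    start after the preceding stop). On circular complete replicons the
    scan continues across the origin. This is a deliberately simple caller,
    not a statistical gene model: it has no coding-potential scoring.
    """
    if min_aa < 1:
        raise ValueError("min_aa must be >= 1")
    circular = replicon.allows_origin_spanning
    features = []
    for strand, seq in (("+", replicon.seq),
                        ("-", reverse_complement(replicon.seq))):
        spans = _longest_per_stop(_walk_orfs(seq, circular, min_aa, None),
                                  replicon.length)
        features.extend(_spans_to_features(
            spans, replicon, strand, FeatureClass.CDS, "cds"))
    features.sort(key=lambda f: (f.start, f.stop, f.strand))
    return features


def extract_sorfs(replicon: Replicon,
                  max_aa_exclusive: int = DEFAULT_MAX_SORF_AA,
                  min_aa: int = DEFAULT_MIN_SORF_AA) -> List[CdsFeature]:
    """Extract all short ORFs encoding proteins of ``min_aa`` up to (but
    excluding) ``max_aa_exclusive`` amino acids, on both strands and across
    the origin of circular complete replicons.

    Unlike the CDS caller, every start codon yields a candidate (nested
    sORFs included); duplicates by exact locus are removed.
    """
    circular = replicon.allows_origin_spanning
    seen = set()
    features = []
    for strand, seq in (("+", replicon.seq),
                        ("-", reverse_complement(replicon.seq))):
        spans = sorted(set(_walk_orfs(seq, circular, min_aa, max_aa_exclusive)))
        for feat in _spans_to_features(spans, replicon, strand,
                                       FeatureClass.SORF, "sorf"):
            key = (feat.replicon_id, feat.start, feat.stop, feat.strand)
            if key not in seen:
                seen.add(key)
                features.append(feat)
    features.sort(key=lambda f: (f.start, f.stop, f.strand))
    return features


# ---------------------------------------------------------------------------
# Ingestion of pre-predicted CDS
# ---------------------------------------------------------------------------

def _populate_sequences(feat: CdsFeature, replicon: Replicon) -> None:
    nt = replicon.slice(feat.start, feat.stop)
    if feat.strand == "-":
        nt = reverse_complement(nt)
    feat.nt = nt
    if feat.is_partial and len(nt) % 3 != 0:
        nt = nt[: len(nt) - len(nt) % 3]
    feat.aa = translate(nt, partial5=feat.partial5)


def ingest_cds(gff_path, genome: Genome) -> Tuple[List[CdsFeature], List[Tuple[str, str]]]:
    """Read pre-predicted CDS records from GFF3 into internal features.

    GFF3 coordinates (1-based inclusive) are converted to the internal
    0-based half-open convention. Two CDS lines sharing one ``ID`` on a
    circular replicon — one ending at the sequence end, one starting at
    base 1 — are re-joined into a single origin-spanning feature.

    Non-partial records failing the frame (length mod 3) or internal-stop
    checks are rejected; the second return value lists ``(id, reason)``
    pairs for every rejected record.
    """
    from gffutils.feature import feature_from_line

    raw = []
    with open(gff_path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = feature_from_line(line)
            if f.featuretype not in ("CDS", "sORF"):
                continue
            raw.append(f)

    by_id: dict = {}
    for f in raw:
        fid = f.attributes.get("ID", [f"{f.seqid}:{f.start}-{f.end}"])[0]
        by_id.setdefault(fid, []).append(f)

    features: List[CdsFeature] = []
    rejects: List[Tuple[str, str]] = []
    for fid, parts in by_id.items():
        try:
            feat = _build_feature(fid, parts, genome)
        except KeyError as exc:
            raise ValueError(f"record {fid!r}: {exc}") from exc
        except (SequenceError, ValueError) as exc:
            rejects.append((fid, str(exc)))
            continue
        features.append(feat)
    features.sort(key=lambda f: (f.replicon_id, f.start, f.stop, f.strand))
    return features, rejects


def _build_feature(fid: str, parts, genome: Genome) -> CdsFeature:
    replicon = genome.get(parts[0].seqid)
    L = replicon.length
    cls = (FeatureClass.SORF if parts[0].featuretype == "sORF"
           else FeatureClass.CDS)

    def flags(f):
        p5 = f.attributes.get("partial5", ["false"])[0] == "true"
        p3 = f.attributes.get("partial3", ["false"])[0] == "true"
        return p5, p3

    if len(parts) == 2 and replicon.allows_origin_spanning:
        # two-line origin-spanning representation: 5' part then 3' part
        tail = next((p for p in parts if p.end == L), None)
        head = next((p for p in parts if p.start == 1), None)
        if tail is None or head is None or tail is head:
            raise ValueError("two-line feature does not touch both sequence edges")
        if tail.strand != head.strand:
            raise ValueError("two-line feature parts on different strands")
        start, stop = tail.start - 1, L + head.end
        p5 = p3 = False
        edge = True
        strand = tail.strand
    elif len(parts) == 1:
        f = parts[0]
        if f.start < 1 or f.end > L:
            raise KeyError(f"coordinates {f.start}..{f.end} out of range for "
                           f"replicon {replicon.id!r} of length {L}")
        start, stop = f.start - 1, f.end
        p5, p3 = flags(f)
        edge = False
        strand = f.strand
    else:
        raise ValueError(f"{len(parts)} lines share ID {fid!r}")

    if strand not in ("+", "-"):
        raise ValueError(f"missing or invalid strand {strand!r}")
    feat = CdsFeature(id=fid, replicon_id=replicon.id, start=start, stop=stop,
                      strand=strand, partial5=p5, partial3=p3, edge=edge,
                      feature_class=cls)
    if not feat.is_partial and feat.length_nt % 3 != 0:
        raise SequenceError(
            f"length {feat.length_nt} not a multiple of 3 for non-partial CDS")
    _populate_sequences(feat, replicon)
    return feat


# ---------------------------------------------------------------------------
# Origin-spanning CDS merging
# ---------------------------------------------------------------------------

def merge_edge_cds(cds_list: Iterable[CdsFeature], replicon: Replicon,
                   log: Optional[list] = None) -> List[CdsFeature]:
    """Merge pairs of partial CDSs running off both sequence edges.

    Only applies on circular, complete replicons. A candidate pair consists
    of a partial CDS ending exactly at the replicon end and a partial CDS
    starting exactly at base 0 on the same strand. The merged feature spans
    the origin (``edge=True``) and must translate cleanly (frame-consistent,
    no internal stop); otherwise the merge is abandoned and both partials
    are kept. Excess candidates beyond the adjacent edge pair are logged.
    """
    cds_list = list(cds_list)
    if not replicon.allows_origin_spanning:
        return cds_list
    log = log if log is not None else []
    L = replicon.length

    for strand in ("+", "-"):
        tails = [f for f in cds_list
                 if f.strand == strand and not f.edge and f.is_partial
                 and f.stop == L and f.replicon_id == replicon.id]
        heads = [f for f in cds_list
                 if f.strand == strand and not f.edge and f.is_partial
                 and f.start == 0 and f.replicon_id == replicon.id]
        if not tails or not heads:
            continue
        if len(tails) > 1 or len(heads) > 1:
            log.append(f"replicon {replicon.id}: multiple edge-partial "
                       f"candidates on strand {strand}; merging only the "
                       "adjacent pair")
        tail, head = tails[0], heads[0]
        nt = tail.nt + head.nt if strand == "+" else head.nt + tail.nt
        try:
            if len(nt) % 3 != 0:
                raise SequenceError("merged length not a multiple of 3")
            aa = translate(nt)
        except SequenceError as exc:
            log.append(f"replicon {replicon.id}: edge merge of {tail.id} + "
                       f"{head.id} abandoned: {exc}")
            continue
        merged = CdsFeature(
            id=f"{tail.id}|{head.id}", replicon_id=replicon.id,
            start=tail.start, stop=L + head.stop, strand=strand,
            nt=nt, aa=aa, edge=True, feature_class=FeatureClass.CDS)
        cds_list = [f for f in cds_list if f is not tail and f is not head]
        cds_list.append(merged)
    cds_list.sort(key=lambda f: (f.start, f.stop, f.strand))
    return cds_list


def find_partial_pairs(cds_list, replicon: Replicon) -> List[PartialCdsPair]:
    """Enumerate candidate origin-spanning pairs without merging them."""
    pairs = []
    if not replicon.allows_origin_spanning:
        return pairs
    L = replicon.length
    for strand in ("+", "-"):
        tails = [f for f in cds_list
                 if f.strand == strand and f.is_partial and f.stop == L]
        heads = [f for f in cds_list
                 if f.strand == strand and f.is_partial and f.start == 0]
        if tails and heads:
            pairs.append(PartialCdsPair(
                five_prime_partial=heads[0], three_prime_partial=tails[0],
                strand=strand))
    return pairs


# ---------------------------------------------------------------------------
# Spurious-sequence filtering
# ---------------------------------------------------------------------------

def blocklist_backend(refdb) -> Callable[[str], Optional[str]]:
    """Default spurious-filter backend: the reference database's digest
    blocklist of known false-positive sequences."""

    def predicate(aa: str) -> Optional[str]:
        if refdb.is_blocked(compute_digest(aa)):
            return "sequence digest on spurious blocklist"
        return None

    return predicate


def filter_spurious(features: Iterable[CdsFeature],
                    backend: Callable[[str], Optional[str]],
                    log: Optional[list] = None) -> List[CdsFeature]:
    """Drop features whose protein the backend flags as spurious.

    The backend is a predicate ``aa -> reason-or-None``. A backend failure
    aborts annotation: silently skipping the filter would leak known
    false positives into the output.
    """
    log = log if log is not None else []
    retained = []
    for feat in features:
        try:
            reason = backend(feat.aa)
        except Exception as exc:
            raise SpuriousFilterError(
                f"spurious-filter backend failed on feature {feat.id!r}: {exc}"
            ) from exc
        if reason:
            log.append(f"removed {feat.id}: {reason}")
        else:
            retained.append(feat)
    return retained
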