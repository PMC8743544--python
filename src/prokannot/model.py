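"""Core domain types and sequence conventions.

All coordinates are 0-based half-open on the forward strand; conversion to
1-based inclusive happens only in file writers. Amino-acid sequences never
carry a terminal stop symbol. The genetic code is the bacterial/archaeal
translation table 11 throughout, with ATG/GTG/TTG accepted as initiators.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

from Bio.Data.CodonTable import unambiguous_dna_by_id

TRANSLATION_TABLE = 11

#: Initiator codons rendered as methionine at position 1.
START_CODONS = ("ATG", "GTG", "TTG")

#: Residues accepted in canonical protein sequences: the 20 standard amino
#: acids plus ambiguity/rare codes (X, B, Z, J) and selenocysteine (U) /
#: pyrrolysine (O). Rare residues participate in digests verbatim so that
#: digests are reproducible from reference FASTA bytes.
VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY" + "XBZJUO")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class Topology(str, enum.Enum):
    CIRCULAR = "circular"
    LINEAR = "linear"


class Completeness(str, enum.Enum):
    COMPLETE = "complete"
    INCOMPLETE = "incomplete"


class RepliconType(str, enum.Enum):
    CHROMOSOME = "chromosome"
    PLASMID = "plasmid"
    CONTIG = "contig"


class FeatureClass(str, enum.Enum):
    CDS = "cds"
    SORF = "sorf"


class Tier(str, enum.Enum):
    """Provenance tier of a concluded annotation, most to least specific."""

    EXPERT = "expert"
    IPS = "ips"
    PSC = "psc"
    PSCC = "pscc"
    HYPOTHETICAL = "hypothetical"


class SequenceError(ValueError):
    """Raised for sequences violating the package's canonical conventions."""


@dataclass
class Replicon:
    """A single assembled sequence with its structural metadata.

    Topology and completeness govern whether coding features may span the
    artificial sequence origin: only circular, complete replicons allow
    origin-spanning features.
    """

    id: str
    seq: str
    topology: Topology = Topology.LINEAR
    completeness: Completeness = Completeness.INCOMPLETE
    rep_type: RepliconType = RepliconType.CONTIG
    name: str = ""

    def __post_init__(self) -> None:
        self.seq = canonicalize_nt(self.seq)
        if not self.seq:
            raise SequenceError(f"replicon {self.id!r}: empty sequence")

    @property
    def length(self) -> int:
        return len(self.seq)

    @property
    def allows_origin_spanning(self) -> bool:
        return (
            self.topology is Topology.CIRCULAR
            and self.completeness is Completeness.COMPLETE
        )

    def slice(self, start: int, stop: int) -> str:
        """Forward-strand slice, wrapping across the origin when stop > length.

        Wrapping is only meaningful on circular replicons; callers enforce
        topology.
        """
        if stop <= self.length:
            return self.seq[start:stop]
        return self.seq[start:] + self.seq[: stop - self.length]


@dataclass
class CdsFeature:
    """A (candidate) protein-coding feature in internal coordinates.

    ``start``/``stop`` are 0-based half-open on the forward strand. An
    origin-spanning feature on a circular replicon has ``edge=True`` and an
    unwrapped ``stop > replicon.length``; writers re-wrap at output time.
    """

    id: str
    replicon_id: str
    start: int
    stop: int
    strand: str  # "+" or "-"
    nt: str = ""
    aa: str = ""
    partial5: bool = False
    partial3: bool = False
    edge: bool = False
    feature_class: FeatureClass = FeatureClass.CDS
    annotation: Optional["Annotation"] = None
    mass: Optional[float] = None
    pi: Optional[float] = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"feature {self.id!r}: strand must be '+' or '-'")
        if self.stop <= self.start:
            raise ValueError(f"feature {self.id!r}: stop must exceed start")

    @property
    def length_nt(self) -> int:
        return self.stop - self.start

    @property
    def is_partial(self) -> bool:
        return self.partial5 or self.partial3

    def locus_key(self) -> tuple:
        return (self.feature_class.value, self.replicon_id, self.start, self.stop, self.strand)


@dataclass(frozen=True)
class UpsRecord:
    """Unique protein sequence: one record per distinct full-length sequence,
    keyed by the 16-byte MD5 digest of the canonical amino-acid string."""

    digest: bytes
    aa_length: int
    uniref100_id: str
    uniparc_id: Optional[str] = None

    def __post_init__(self) -> None:
        if len(self.digest) != 16:
            raise ValueError("UPS digest must be exactly 16 bytes")
        if self.aa_length < 1:
            raise ValueError("UPS aa_length must be >= 1")


@dataclass(frozen=True)
class IpsRecord:
    """Identical protein sequence: UniRef100-level annotation record."""

    uniref100_id: str
    uniref90_id: Optional[str] = None
    gene: Optional[str] = None
    product: Optional[str] = None


@dataclass(frozen=True)
class PscRecord:
    """Protein sequence cluster: UniRef90-level record carrying the cluster
    representative sequence used by the homology search."""

    uniref90_id: str
    uniref50_id: Optional[str] = None
    gene: Optional[str] = None
    product: Optional[str] = None
    cog_id: Optional[str] = None
    cog_category: Optional[str] = None
    ec: tuple = ()
    go: tuple = ()
    rep_seq: str = ""


@dataclass(frozen=True)
class PsccRecord:
    """Protein sequence cluster of clusters: UniRef50-level product record."""

    uniref50_id: str
    product: Optional[str] = None


@dataclass(frozen=True)
class ExpertRule:
    """A curated reference protein with per-rule alignment thresholds and a
    priority rank; higher rank wins among eligible rules."""

    rule_id: str
    source: str
    rank: int
    product: str
    seq: str
    gene: Optional[str] = None
    min_identity: float = 0.9
    min_query_cov: float = 0.9
    min_subject_cov: float = 0.9
    dbxrefs: tuple = ()

    def __post_init__(self) -> None:
        for v in (self.min_identity, self.min_query_cov, self.min_subject_cov):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"rule {self.rule_id!r}: thresholds must lie in [0,1]")
        if self.rank < 0:
            raise ValueError(f"rule {self.rule_id!r}: rank must be >= 0")


@dataclass(frozen=True)
class AlignmentHit:
    """A pairwise protein alignment summary.

    identity = matches / alignment columns over the aligned core;
    query_cov / subject_cov = aligned span / full sequence length.
    """

    query_id: str
    subject_id: str
    identity: float
    query_cov: float
    subject_cov: float
    score: float = 0.0

    def __post_init__(self) -> None:
        for v in (self.identity, self.query_cov, self.subject_cov):
            if not 0.0 <= v <= 1.0:
                raise ValueError("alignment fractions must lie in [0,1]")


@dataclass
class Annotation:
    """Concluding functional annotation of one feature."""

    product: str
    gene: Optional[str] = None
    dbxrefs: set = field(default_factory=set)
    tier: Tier = Tier.HYPOTHETICAL
    rule_rank: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.product:
            raise ValueError("annotation product must be non-empty")


@dataclass
class DbMeta:
    """Reference-database metadata: schema version and record counts."""

    schema_major: int
    schema_minor: int
    counts: dict = field(default_factory=dict)
    build_log_path: str = ""

    def __post_init__(self) -> None:
        if self.schema_major < 1:
            raise ValueError("schema major version must be >= 1")

    @property
    def version(self) -> str:
        return f"{self.schema_major}.{self.schema_minor}"


@dataclass
class Genome:
    """An assembled genome: an ordered collection of replicons."""

    replicons: list
    id: str = "genome"

    def __post_init__(self) -> None:
        seen = set()
        for rep in self.replicons:
            if rep.id in seen:
                raise ValueError(f"duplicate replicon id {rep.id!r}")
            seen.add(rep.id)

    def get(self, replicon_id: str) -> Replicon:
        for rep in self.replicons:
            if rep.id == replicon_id:
                return rep
        raise KeyError(f"unknown replicon id {replicon_id!r}")


def canonicalize_nt(raw: str) -> str:
    """Uppercase a nucleotide string and validate its ACGTN alphabet."""
    seq = "".join(raw.split()).upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise SequenceError(f"invalid nucleotide characters: {sorted(bad)}")
    return seq


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def canonicalize_protein(raw: str) -> str:
    """Normalize a protein sequence to its canonical digestable form.

    Uppercases, strips whitespace, and removes a single terminal stop
    symbol (``*``). Rejects empty results and internal stop symbols.
    Idempotent on its own output.
    """
    aa = "".join(raw.split()).upper()
    if aa.endswith("*"):
        aa = aa[:-1]
    if not aa:
        raise SequenceError("protein sequence empty after canonicalization")
    if "*" in aa:
        raise SequenceError(f"internal stop symbol at position {aa.index('*')}")
    bad = set(aa) - VALID_RESIDUES
    if bad:
        raise SequenceError(f"invalid residue characters: {sorted(bad)}")
    return aa


class InternalStopError(SequenceError):
    """An in-frame stop codon before the final codon; carries its nt offset."""

    def __init__(self, offset: int):
        self.offset = offset
        super().__init__(f"internal stop codon at nucleotide offset {offset}")


_CODON_TABLE = unambiguous_dna_by_id[TRANSLATION_TABLE]


def translate(nt: str, table: int = TRANSLATION_TABLE, partial5: bool = False) -> str:
    """Translate an in-frame coding sequence to its protein.

    The initiator codon (ATG/GTG/TTG) is rendered as M unless the sequence is
    5'-partial; a terminal stop codon is dropped from the output. Codons
    containing N translate to X. Raises :class:`InternalStopError` for a stop
    codon before the final position.
    """
    if table != TRANSLATION_TABLE:
        raise ValueError(f"only translation table {TRANSLATION_TABLE} is supported")
    if len(nt) % 3 != 0:
        raise SequenceError(f"coding sequence length {len(nt)} not a multiple of 3")
    if not nt:
        return ""
    codons = [nt[i : i + 3] for i in range(0, len(nt), 3)]
    residues = []
    stops = _CODON_TABLE.stop_codons
    for i, codon in enumerate(codons):
        if codon in stops:
            if i < len(codons) - 1:
                raise InternalStopError(i * 3)
            break  # terminal stop dropped
        if "N" in codon:
            residues.append("X")
        elif i == 0 and not partial5 and codon in START_CODONS:
            residues.append("M")
        else:
            residues.append(_CODON_TABLE.forward_table[codon])
    return "".join(residues)
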