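"""Core domain types shared across the pipeline.

The pipeline tracks somatic calls from four variant callers through a
consensus/filtering stage into a deduplicated mutation table annotated with
gene, consequence class, and protein change, and relates those mutations to
miRNA expression, isomiR composition, and clinical outcome.
"""
from __future__ import annotations

import bisect
import json
import zlib
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Optional


class MutatlasError(Exception):
    """Base class for all package errors."""


class ConfigError(MutatlasError):
    """Invalid configuration; the message names the offending field."""


class ParseError(MutatlasError):
    """A malformed input record; the message locates the record."""


class ValidationError(MutatlasError):
    """Inputs violate a documented precondition."""


class Caller(str, Enum):
    MUSE = "MuSE"
    MUTECT2 = "MuTect2"
    VARSCAN2 = "VarScan2"
    SOMATICSNIPER = "SomaticSniper"


#: Callers that report a somatic score (SSC) used in reliability filtering.
SSC_CALLERS = frozenset({Caller.VARSCAN2, Caller.SOMATICSNIPER})
#: Callers that report the tumor alt-read base quality (BQ).
BQ_CALLERS = frozenset({Caller.MUSE, Caller.MUTECT2})


class Consequence(str, Enum):
    MISSENSE = "missense"
    SYNONYMOUS = "synonymous"
    NONSENSE = "nonsense"
    FRAMESHIFT = "frameshift"
    INFRAME_INDEL = "inframe_indel"
    SPLICE_SITE = "splice_site"
    START_STOP = "start_stop"
    OTHER = "other"


#: Classes counted as definitively protein-disabling ("deleterious").
DELETERIOUS_CLASSES = frozenset(
    {Consequence.FRAMESHIFT, Consequence.NONSENSE, Consequence.SPLICE_SITE}
)

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def complement(base: str) -> str:
    return base.translate(_COMPLEMENT)


def pseudo_base(chrom: str, pos: int) -> str:
    """Deterministic reference base for positions outside modeled exons.

    Intronic/extension positions have no sequence in the simplified
    transcript model; a CRC-derived base keeps emitted files reproducible
    and self-consistent across callers.
    """
    return "ACGT"[zlib.crc32(f"{chrom}:{pos}".encode()) % 4]


def normalize_variant(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Parsimony-normalize a variant representation.

    Trims the shared suffix, then the shared prefix (advancing ``pos``),
    so equivalent indel representations from different callers collapse to
    one canonical key before deduplication.
    """
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


@dataclass
class CallerVariant:
    """One caller's somatic call for one sample.

    ``ssc`` is present only for VarScan2/SomaticSniper and ``bq`` only for
    MuSE/MuTect2; an absent field is never grounds for rejection.
    Coordinates are 1-based as in the source files.
    """

    caller: Caller
    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    filter_status: str = "PASS"
    t_alt_reads: int = 0
    n_alt_reads: int = 0
    t_alt_freq: float = 0.0
    n_alt_freq: float = 0.0
    ssc: Optional[float] = None
    bq: Optional[float] = None
    # depths are carried for round-tripping through caller files
    t_depth: Optional[int] = None
    n_depth: Optional[int] = None

    def key(self) -> tuple[str, str, int, str, str]:
        pos, ref, alt = normalize_variant(self.pos, self.ref, self.alt)
        return (self.sample_id, self.chrom, pos, ref, alt)


@dataclass
class ConsensusMutation:
    """A deduplicated, filter-passing somatic mutation."""

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    callers: set[Caller]
    cancer_type: Optional[str] = None
    gene: Optional[str] = None
    consequence: Optional[Consequence] = None
    #: (1-based AA position, reference AA, alternate AA or "fs"/"del"/"ins")
    protein_change: Optional[tuple[int, str, str]] = None

    def key(self) -> tuple[str, str, int, str, str]:
        return (self.sample_id, self.chrom, self.pos, self.ref, self.alt)

    @property
    def protein_label(self) -> Optional[str]:
        if self.protein_change is None:
            return None
        aa_pos, ref_aa, alt_aa = self.protein_change
        return f"p.{ref_aa}{aa_pos}{alt_aa}"


@dataclass
class GeneRegion:
    """Analyzed region of one gene: coding exons extended by 2 nt each side.

    ``intervals`` are (chrom, start, end), 0-based half-open, merged and
    non-overlapping; ``coding_length_bp`` is their total length.
    """

    gene: str
    intervals: list[tuple[str, int, int]]
    strand: str = "+"

    def __post_init__(self) -> None:
        merged: list[tuple[str, int, int]] = []
        for chrom, start, end in sorted(self.intervals):
            if end <= start:
                raise ValidationError(f"{self.gene}: empty interval {start}-{end}")
            if merged and merged[-1][0] == chrom and start <= merged[-1][2]:
                prev = merged.pop()
                merged.append((chrom, prev[1], max(prev[2], end)))
            else:
                merged.append((chrom, start, end))
        self.intervals = merged

    @property
    def coding_length_bp(self) -> int:
        return sum(end - start for _, start, end in self.intervals)

    def contains(self, chrom: str, pos0: int) -> bool:
        for c, start, end in self.intervals:
            if c == chrom and start <= pos0 < end:
                return True
        return False


class TranscriptModel:
    """Simplified single-transcript CDS model used for consequence calls.

    ``exons`` are the coding portions of exons as (start, end) 0-based
    half-open genomic intervals in ascending order; ``cds_seq`` is the
    spliced coding sequence (coding-strand orientation, including the stop
    codon). Minus-strand transcripts read the exons in descending order with
    complemented bases.
    """

    def __init__(self, gene: str, chrom: str, strand: str,
                 exons: list[tuple[int, int]], cds_seq: str):
        if strand not in {"+", "-"}:
            raise ValidationError(f"{gene}: strand must be + or -")
        exons = sorted((int(s), int(e)) for s, e in exons)
        if sum(e - s for s, e in exons) != len(cds_seq):
            raise ValidationError(f"{gene}: exon lengths do not match CDS length")
        self.gene = gene
        self.chrom = chrom
        self.strand = strand
        self.exons = exons
        self.cds_seq = cds_seq.upper()
        # cumulative CDS offset of each exon, in transcription order
        order = exons if strand == "+" else list(reversed(exons))
        self._tx_order = order
        offsets = []
        acc = 0
        for s, e in order:
            offsets.append(acc)
            acc += e - s
        self._tx_offsets = offsets
        self._starts = [s for s, _ in exons]

    @property
    def cds_length(self) -> int:
        return len(self.cds_seq)

    def exon_index(self, pos0: int) -> Optional[int]:
        i = bisect.bisect_right(self._starts, pos0) - 1
        if i >= 0 and self.exons[i][0] <= pos0 < self.exons[i][1]:
            return i
        return None

    def genomic_to_cds(self, pos0: int) -> Optional[int]:
        """0-based CDS index of a genomic position, or None if non-exonic."""
        i = self.exon_index(pos0)
        if i is None:
            return None
        s, e = self.exons[i]
        j = self._tx_order.index((s, e))
        if self.strand == "+":
            return self._tx_offsets[j] + (pos0 - s)
        return self._tx_offsets[j] + (e - 1 - pos0)

    def cds_to_genomic(self, idx: int) -> int:
        if not 0 <= idx < len(self.cds_seq):
            raise ValidationError(f"{self.gene}: CDS index {idx} out of range")
        for (s, e), off in zip(self._tx_order, self._tx_offsets):
            if off <= idx < off + (e - s):
                if self.strand == "+":
                    return s + (idx - off)
                return e - 1 - (idx - off)
        raise AssertionError("unreachable")

    def ref_base(self, pos0: int) -> str:
        """Genomic (plus-strand) reference base at an exonic position."""
        idx = self.genomic_to_cds(pos0)
        if idx is None:
            raise ValidationError(f"{self.gene}: {pos0} is not exonic")
        base = self.cds_seq[idx]
        return base if self.strand == "+" else complement(base)

    def splice_windows(self) -> set[int]:
        """Genomic positions within 2 nt of an internal exon junction."""
        window: set[int] = set()
        for i in range(len(self.exons) - 1):
            _, end = self.exons[i]
            nxt_start, _ = self.exons[i + 1]
            window.update({end, end + 1, nxt_start - 2, nxt_start - 1})
        return window

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "gene": self.gene,
            "chrom": self.chrom,
            "strand": self.strand,
            "exons": [list(x) for x in self.exons],
            "cds_seq": self.cds_seq,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TranscriptModel":
        return cls(d["gene"], d["chrom"], d["strand"],
                   [tuple(x) for x in d["exons"]], d["cds_seq"])


def save_transcripts(models: Iterable[TranscriptModel], path) -> None:
    with open(path, "w") as fh:
        json.dump([m.to_dict() for m in models], fh, indent=1)
        fh.write("\n")


def load_transcripts(path) -> dict[str, TranscriptModel]:
    with open(path) as fh:
        raw = json.load(fh)
    return {d["gene"]: TranscriptModel.from_dict(d) for d in raw}
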