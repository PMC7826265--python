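"""Multi-caller somatic-call consensus.

Reads per-sample call sets from four caller dialects, keeps PASS calls,
applies four reliability criteria, merges calls across callers without
duplication, restricts to the analyzed gene regions (coding exons extended
by 2 nt), and assigns a consequence class from a simplified transcript
model.

Reliability criteria (a call is retained iff every applicable criterion
holds):

(i)   >= 2 tumor alt-supporting reads, applied when the matched normal has
      zero alt-supporting reads;
(ii)  tumor alt-read frequency >= 5x the normal alt-read frequency, applied
      when the normal frequency is > 0 (inclusive boundary);
(iii) somatic score SSC > 30 (VarScan2, SomaticSniper);
(iv)  tumor alt-read base quality BQ > 20 (MuSE, MuTect2).
"""
from __future__ import annotations

from collections import defaultdict
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd
from cyvcf2 import VCF
from intervaltree import IntervalTree

from . import dialects
from .types import (
    Caller,
    CallerVariant,
    ConfigError,
    Consequence,
    ConsensusMutation,
    GeneRegion,
    MutatlasError,
    ParseError,
    TranscriptModel,
    ValidationError,
    complement,
)

MIN_T_ALT_READS = 2
MIN_FREQ_RATIO = 5.0
MIN_SSC = 30.0
MIN_BQ = 20.0


def read_caller_file(path, dialect: Caller | str,
                     sample_id: Optional[str] = None) -> list[CallerVariant]:
    """Read one caller's VCF, returning only PASS records.

    ``sample_id`` defaults to the file stem up to the first dot
    (``<sample>.<caller>.vcf`` layout).
    """
    try:
        dialect = Caller(dialect)
    except ValueError:
        raise ConfigError(f"unknown caller dialect: {dialect!r}") from None
    path = Path(path)
    if sample_id is None:
        sample_id = path.name.split(".")[0]
    try:
        vcf = VCF(str(path))
    except Exception as exc:
        raise ParseError(f"{path}: cannot open as VCF ({exc})") from exc
    try:
        samples = list(vcf.samples)
        tumor_idx = samples.index(dialects.TUMOR)
        normal_idx = samples.index(dialects.NORMAL)
    except ValueError:
        raise ParseError(f"{path}: TUMOR/NORMAL sample columns missing")
    out: list[CallerVariant] = []
    for i, variant in enumerate(vcf, start=1):
        try:
            rec = dialects.decode_variant(variant, dialect, sample_id,
                                          tumor_idx, normal_idx)
        except (TypeError, ValueError, ParseError) as exc:
            raise ParseError(f"{path}: record {i}: {exc}") from exc
        if rec.filter_status == "PASS":
            out.append(rec)
    vcf.close()
    return out


def passes_reliability_filters(call: CallerVariant) -> bool:
    """Evaluate the conjunction of the four reliability criteria."""
    if call.n_alt_reads == 0 and call.t_alt_reads < MIN_T_ALT_READS:
        return False
    if call.n_alt_freq > 0 and call.t_alt_freq < MIN_FREQ_RATIO * call.n_alt_freq:
        return False
    if call.ssc is not None and not call.ssc > MIN_SSC:
        return False
    if call.bq is not None and not call.bq > MIN_BQ:
        return False
    return True


def apply_reliability_filters(calls: Iterable[CallerVariant]) -> list[CallerVariant]:
    return [c for c in calls if passes_reliability_filters(c)]


def merge_callers(per_caller: Mapping[Caller, list[CallerVariant]],
                  clinical: pd.DataFrame) -> list[ConsensusMutation]:
    """Merge filter-passing calls across callers without duplication.

    One consensus record per distinct (sample, chrom, pos, ref, alt) after
    parsimony normalization of indel representations; the callers field is
    the union of supporting callers. ``clinical`` must index or contain
    ``sample_id`` and ``cancer_type``.
    """
    if "sample_id" in clinical.columns:
        cancer_of = clinical.set_index("sample_id")["cancer_type"]
    else:
        cancer_of = clinical["cancer_type"]
    merged: dict[tuple, ConsensusMutation] = {}
    for caller, calls in per_caller.items():
        caller = Caller(caller)
        for call in calls:
            key = call.key()
            if key in merged:
                merged[key].callers.add(caller)
                continue
            if call.sample_id not in cancer_of.index:
                raise ValidationError(
                    f"sample {call.sample_id!r} absent from the clinical table"
                )
            _, chrom, pos, ref, alt = key
            merged[key] = ConsensusMutation(
                sample_id=call.sample_id,
                chrom=chrom,
                pos=pos,
                ref=ref,
                alt=alt,
                callers={caller},
                cancer_type=str(cancer_of.loc[call.sample_id]),
            )
    return [merged[k] for k in sorted(merged)]


def load_regions_bed(path) -> list[GeneRegion]:
    """Load gene regions from a BED file (chrom, start, end, gene[, score, strand]).

    Intervals of the same gene are merged; overlap between different genes
    is rejected.
    """
    by_gene: dict[str, list[tuple[str, int, int]]] = defaultdict(list)
    strand_of: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(f"{path}: line {lineno}: expected >=4 BED columns")
            chrom, start, end, gene = fields[0], int(fields[1]), int(fields[2]), fields[3]
            by_gene[gene].append((chrom, start, end))
            if len(fields) >= 6:
                strand_of[gene] = fields[5]
    regions = [GeneRegion(g, ivs, strand_of.get(g, "+"))
               for g, ivs in by_gene.items()]
    validate_regions(regions)
    return regions


def validate_regions(regions: list[GeneRegion]) -> None:
    """Reject overlap between intervals of different genes."""
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for region in regions:
        for chrom, start, end in region.intervals:
            hits = trees[chrom][start:end]
            if hits:
                other = next(iter(hits)).data
                raise ValidationError(
                    f"gene regions overlap: {region.gene} and {other} on {chrom}"
                )
        for chrom, start, end in region.intervals:
            trees[chrom][start:end] = region.gene


def restrict_to_regions(muts: Iterable[ConsensusMutation],
                        regions: list[GeneRegion]) -> list[ConsensusMutation]:
    """Keep mutations whose (0-based) position falls in a gene region."""
    validate_regions(regions)
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for region in regions:
        for chrom, start, end in region.intervals:
            trees[chrom][start:end] = region.gene
    kept: list[ConsensusMutation] = []
    for mut in muts:
        hits = trees.get(mut.chrom, IntervalTree())[mut.pos - 1]
        if hits:
            mut.gene = next(iter(hits)).data
            kept.append(mut)
    return kept


def classify_consequence(
    mut: ConsensusMutation, transcript: TranscriptModel
) -> tuple[Consequence, Optional[tuple[int, str, str]]]:
    """Classify one mutation against a simplified CDS model.

    SNVs are translated through the codon table (missense / synonymous /
    nonsense; start- or stop-codon disruptions are ``start_stop``); indels
    are frameshift when length mod 3 != 0, otherwise in-frame; variants in
    the 2-nt windows flanking internal exon junctions are ``splice_site``.
    Multi-nucleotide substitutions and variants inside the analyzed region
    but outside both the CDS and the splice windows are ``other``.
    """
    from Bio.Seq import Seq

    if transcript.gene != mut.gene:
        raise ValidationError(
            f"transcript model {transcript.gene} does not cover {mut.gene}"
        )
    pos0 = mut.pos - 1
    minus = transcript.strand == "-"
    if pos0 in transcript.splice_windows():
        return Consequence.SPLICE_SITE, None

    if len(mut.ref) == 1 and len(mut.alt) == 1:  # SNV
        idx = transcript.genomic_to_cds(pos0)
        if idx is None:
            return Consequence.OTHER, None
        ref_cds = complement(mut.ref) if minus else mut.ref
        alt_cds = complement(mut.alt) if minus else mut.alt
        if transcript.cds_seq[idx] != ref_cds.upper():
            raise ValidationError(
                f"{mut.gene}:{mut.pos} REF {mut.ref} does not match the model"
            )
        codon_i = idx // 3
        codon = transcript.cds_seq[codon_i * 3: codon_i * 3 + 3]
        alt_codon = list(codon)
        alt_codon[idx % 3] = alt_cds.upper()
        alt_codon = "".join(alt_codon)
        ref_aa = str(Seq(codon).translate())
        alt_aa = str(Seq(alt_codon).translate())
        change = (codon_i + 1, ref_aa, alt_aa)
        if ref_aa == alt_aa:
            return Consequence.SYNONYMOUS, change
        if codon_i == 0 or ref_aa == "*":
            return Consequence.START_STOP, change
        if alt_aa == "*":
            return Consequence.NONSENSE, change
        return Consequence.MISSENSE, change

    if len(mut.ref) != len(mut.alt):  # indel, anchored-base convention
        anchor = pos0 + 1 if not minus else pos0
        idx = transcript.genomic_to_cds(anchor)
        if idx is None:
            idx = transcript.genomic_to_cds(pos0)
        if idx is None:
            return Consequence.OTHER, None
        aa_pos = idx // 3 + 1
        ref_aa = str(Seq(transcript.cds_seq[(aa_pos - 1) * 3: aa_pos * 3]).translate())
        delta = len(mut.alt) - len(mut.ref)
        if delta % 3 != 0:
            return Consequence.FRAMESHIFT, (aa_pos, ref_aa, "fs")
        label = "del" if delta < 0 else "ins"
        return Consequence.INFRAME_INDEL, (aa_pos, ref_aa, label)

    return Consequence.OTHER, None


def annotate_mutations(muts: Iterable[ConsensusMutation],
                       transcripts: Mapping[str, TranscriptModel]) -> list[ConsensusMutation]:
    """Assign consequence and protein change in place; returns the list."""
    muts = list(muts)
    for mut in muts:
        if mut.gene is None or mut.gene not in transcripts:
            raise ValidationError(
                f"no transcript model for mutation at {mut.chrom}:{mut.pos}"
                f" (gene={mut.gene})"
            )
        mut.consequence, mut.protein_change = classify_consequence(
            mut, transcripts[mut.gene]
        )
    return muts


# -- tabular round-trip ---------------------------------------------------

_TSV_COLUMNS = [
    "sample_id", "cancer_type", "gene", "chrom", "pos", "ref", "alt",
    "consequence", "aa_pos", "aa_ref", "aa_alt", "protein_label", "callers",
]


def mutations_to_frame(muts: Iterable[ConsensusMutation]) -> pd.DataFrame:
    rows = []
    for m in muts:
        aa_pos, aa_ref, aa_alt = (m.protein_change or (None, None, None))
        rows.append({
            "sample_id": m.sample_id,
            "cancer_type": m.cancer_type,
            "gene": m.gene,
            "chrom": m.chrom,
            "pos": m.pos,
            "ref": m.ref,
            "alt": m.alt,
            "consequence": m.consequence.value if m.consequence else None,
            "aa_pos": aa_pos,
            "aa_ref": aa_ref,
            "aa_alt": aa_alt,
            "protein_label": m.protein_label,
            "callers": "|".join(sorted(c.value for c in m.callers)),
        })
    df = pd.DataFrame(rows, columns=_TSV_COLUMNS)
    df["aa_pos"] = df["aa_pos"].astype("Int64")
    return df


def write_mutations_tsv(muts: Iterable[ConsensusMutation], path) -> pd.DataFrame:
    df = mutations_to_frame(muts)
    df.to_csv(path, sep="\t", index=False)
    return df


def read_mutations_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"aa_pos": "Int64"})


def run_consensus(vcf_dir, regions_path, clinical: pd.DataFrame,
                  transcripts: Mapping[str, TranscriptModel] | None = None
                  ) -> list[ConsensusMutation]:
    """End-to-end consensus: read every ``<sample>.<caller>.vcf`` in a
    directory, filter, merge, restrict to regions, and (when transcript
    models are given) classify consequences."""
    vcf_dir = Path(vcf_dir)
    per_caller: dict[Caller, list[CallerVariant]] = {c: [] for c in Caller}
    paths = sorted(vcf_dir.glob("*.vcf"))
    if not paths:
        raise MutatlasError(f"no VCF files found under {vcf_dir}")
    for path in paths:
        parts = path.name.split(".")
        if len(parts) < 3:
            raise ParseError(f"{path}: expected <sample>.<caller>.vcf naming")
        caller = Caller(parts[-2])
        calls = read_caller_file(path, caller, sample_id=parts[0])
        per_caller[caller].extend(apply_reliability_filters(calls))
    muts = merge_callers(per_caller, clinical)
    regions = load_regions_bed(regions_path)
    muts = restrict_to_regions(muts, regions)
    if transcripts is not None:
        muts = annotate_mutations(muts, transcripts)
    return muts
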