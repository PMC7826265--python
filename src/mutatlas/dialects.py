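"""Per-caller VCF dialect contract.

The four somatic callers emit VCF 4.2 with PASS/non-PASS FILTER values but
place read support and quality fields differently. This module fixes one
emulation contract per caller (an explicit stand-in for the heterogeneous
field layouts of real call sets) and provides the matching encode/decode
routines. Differences are limited to where alt-read counts, the somatic
score (SSC) and the alt-read base quality (BQ) live:

==============  =======================  ============================
caller          SSC                      BQ
==============  =======================  ============================
MuSE            (absent)                 FORMAT/BQ on the TUMOR column
MuTect2         (absent)                 INFO/MBQ
VarScan2        INFO/SSC                 (absent)
SomaticSniper   FORMAT/SSC on TUMOR      (absent)
==============  =======================  ============================

All callers report per-sample FORMAT/AD as ``ref_reads,alt_reads`` and
FORMAT/DP; allele frequencies are derived as alt/(ref+alt). Sample columns
are TUMOR then NORMAL.
"""
from __future__ import annotations

from typing import Iterable

from .types import Caller, CallerVariant, ConfigError, ParseError

TUMOR, NORMAL = "TUMOR", "NORMAL"

_COMMON_HEADER = [
    '##fileformat=VCFv4.2',
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Ref and alt read counts">',
    '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
    '##FILTER=<ID=REJECT,Description="Rejected by the caller">',
]

_DIALECT_HEADER = {
    Caller.MUSE: [
        '##INFO=<ID=SOMATIC,Number=0,Type=Flag,Description="Somatic event">',
        '##FORMAT=<ID=BQ,Number=1,Type=Integer,Description="Mean base quality of alt reads">',
    ],
    Caller.MUTECT2: [
        '##INFO=<ID=MBQ,Number=1,Type=Integer,Description="Median base quality of alt reads in tumor">',
        '##FORMAT=<ID=AF,Number=1,Type=Float,Description="Alt allele fraction">',
    ],
    Caller.VARSCAN2: [
        '##INFO=<ID=SOMATIC,Number=0,Type=Flag,Description="Somatic event">',
        '##INFO=<ID=SSC,Number=1,Type=Integer,Description="Somatic score">',
    ],
    Caller.SOMATICSNIPER: [
        '##FORMAT=<ID=SSC,Number=1,Type=Integer,Description="Somatic score">',
    ],
}


def vcf_header(caller: Caller, contigs: Iterable[str]) -> list[str]:
    lines = list(_COMMON_HEADER)
    lines += [f"##contig=<ID={c}>" for c in contigs]
    lines += _DIALECT_HEADER[caller]
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        f"{TUMOR}\t{NORMAL}"
    )
    return lines


def encode_record(v: CallerVariant) -> str:
    """Render one CallerVariant as a VCF body line in its caller's dialect."""
    t_dp = v.t_depth if v.t_depth is not None else max(v.t_alt_reads, 1)
    n_dp = v.n_depth if v.n_depth is not None else max(v.n_alt_reads, 1)
    t_ref = t_dp - v.t_alt_reads
    n_ref = n_dp - v.n_alt_reads
    gt_t, gt_n = "0/1", "0/0"
    if v.caller is Caller.MUSE:
        bq = int(round(v.bq))
        info = "SOMATIC"
        fmt = "GT:AD:DP:BQ"
        t = f"{gt_t}:{t_ref},{v.t_alt_reads}:{t_dp}:{bq}"
        n = f"{gt_n}:{n_ref},{v.n_alt_reads}:{n_dp}:{bq}"
    elif v.caller is Caller.MUTECT2:
        info = f"MBQ={int(round(v.bq))}"
        fmt = "GT:AD:AF:DP"
        t = f"{gt_t}:{t_ref},{v.t_alt_reads}:{v.t_alt_freq:.4f}:{t_dp}"
        n = f"{gt_n}:{n_ref},{v.n_alt_reads}:{v.n_alt_freq:.4f}:{n_dp}"
    elif v.caller is Caller.VARSCAN2:
        info = f"SOMATIC;SSC={int(round(v.ssc))}"
        fmt = "GT:AD:DP"
        t = f"{gt_t}:{t_ref},{v.t_alt_reads}:{t_dp}"
        n = f"{gt_n}:{n_ref},{v.n_alt_reads}:{n_dp}"
    elif v.caller is Caller.SOMATICSNIPER:
        ssc = int(round(v.ssc))
        info = "."
        fmt = "GT:AD:DP:SSC"
        t = f"{gt_t}:{t_ref},{v.t_alt_reads}:{t_dp}:{ssc}"
        n = f"{gt_n}:{n_ref},{v.n_alt_reads}:{n_dp}:0"
    else:  # pragma: no cover
        raise ConfigError(f"unknown caller dialect: {v.caller}")
    return "\t".join(
        [v.chrom, str(v.pos), ".", v.ref, v.alt, ".", v.filter_status, info,
         fmt, t, n]
    )


def write_vcf(path, caller: Caller, records: list[CallerVariant],
              contigs: Iterable[str]) -> None:
    records = sorted(records, key=lambda r: (r.chrom, r.pos, r.ref, r.alt))
    with open(path, "w") as fh:
        for line in vcf_header(caller, contigs):
            fh.write(line + "\n")
        for rec in records:
            fh.write(encode_record(rec) + "\n")


def decode_variant(variant, caller: Caller, sample_id: str,
                   tumor_idx: int, normal_idx: int) -> CallerVariant:
    """Build a CallerVariant from one cyvcf2 record."""
    ad = variant.format("AD")
    if ad is None:
        raise ParseError("record lacks FORMAT/AD")
    t_ref, t_alt = int(ad[tumor_idx][0]), int(ad[tumor_idx][1])
    n_ref, n_alt = int(ad[normal_idx][0]), int(ad[normal_idx][1])
    t_dp, n_dp = t_ref + t_alt, n_ref + n_alt
    t_freq = t_alt / t_dp if t_dp > 0 else 0.0
    n_freq = n_alt / n_dp if n_dp > 0 else 0.0
    ssc = bq = None
    if caller is Caller.MUSE:
        arr = variant.format("BQ")
        bq = float(arr[tumor_idx][0])
    elif caller is Caller.MUTECT2:
        bq = float(variant.INFO.get("MBQ"))
    elif caller is Caller.VARSCAN2:
        ssc = float(variant.INFO.get("SSC"))
    elif caller is Caller.SOMATICSNIPER:
        arr = variant.format("SSC")
        ssc = float(arr[tumor_idx][0])
    return CallerVariant(
        caller=caller,
        sample_id=sample_id,
        chrom=variant.CHROM,
        pos=int(variant.POS),
        ref=variant.REF,
        alt=variant.ALT[0],
        filter_status=variant.FILTER or "PASS",
        t_alt_reads=t_alt,
        n_alt_reads=n_alt,
        t_alt_freq=t_freq,
        n_alt_freq=n_freq,
        ssc=ssc,
        bq=bq,
        t_depth=t_dp,
        n_depth=n_dp,
    )
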