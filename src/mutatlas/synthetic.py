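"""Synthetic pan-cancer cohort generator with planted ground truth.

Emulates every input the downstream stages consume: per-sample somatic call
sets in four caller dialects, gene regions (coding exons extended by 2 nt),
sample x miRNA expression matrices in two dialects (additive-noise
"batch-normalized" levels that may dip below zero, and multiplicative-noise
RPM counts), 5'-offset isomiR tables, clinical tables with exponential
survival, and thresholded gene-level copy-number calls.

Planted effects define the ground truth: recurrent hotspot residues,
per-gene deleterious mutation rates, hypermutated samples, an arm-asymmetric
expression shift (5p down / 3p up in carriers of a chosen mutation class)
that spares a reference miRNA matured independently of the affected
nuclease, a reduction of the main 5'-isoform fraction in the same carriers,
a survival hazard ratio, and copy-number deletion enrichment.

All randomness flows from ``config.seed`` through fixed per-family stream
offsets plus per-sample substreams, so the bundle is byte-reproducible and
adding samples does not reshuffle earlier ones.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import dialects
from .types import (
    BQ_CALLERS,
    Caller,
    CallerVariant,
    ConfigError,
    Consequence,
    SSC_CALLERS,
    TranscriptModel,
    complement,
    pseudo_base,
    save_transcripts,
)

# fixed rng stream offsets per file family
_S_GENES, _S_MUT, _S_CALLS, _S_EXPR, _S_ISO, _S_CLIN, _S_CNV = range(1, 8)

HYPERMUTATION_THRESHOLD = 10_000

_BASES = "ACGT"

NOISE_FILTERS = ("alt_reads", "freq_ratio", "ssc", "bq")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneSpec:
    """One synthetic gene: protein length (AA, excl. stop) and exon count."""
    name: str
    n_aa: int
    n_exons: int = 3
    strand: str = "+"


@dataclass(frozen=True)
class HotspotSpec:
    """Plant ``count`` missense carriers at one AA residue of ``gene``,
    drawn from the listed cancer types (all types when None)."""
    gene: str
    residue: int
    count: int
    cancers: Optional[tuple[str, ...]] = None


@dataclass(frozen=True)
class ArmEffect:
    """Additive (normalized scale) / log2-multiplicative (RPM scale) shift
    of 5p- and 3p-annotated miRNAs in carriers of ``mutation_class``
    mutations in ``gene``; the reference miRNA is exempt."""
    gene: str = "DICER1"
    mutation_class: str = "hotspot"
    shift_5p: float = -0.5
    shift_3p: float = 0.5


@dataclass(frozen=True)
class SurvivalEffect:
    gene: str = "SMAD4"
    mutation_class: str = "deleterious"
    hazard_ratio: float = 2.0


@dataclass(frozen=True)
class CnvEffect:
    gene: str = "SMAD4"
    del_prob_mutated: float = 0.6
    del_prob_background: float = 0.1


DEFAULT_GENES: tuple[GeneSpec, ...] = (
    GeneSpec("SMAD4", 552, 4),
    GeneSpec("SMAD2", 467, 4, "-"),
    GeneSpec("DICER1", 1922, 6),
    GeneSpec("PRKRA", 313, 3),
    GeneSpec("TNRC6A", 1962, 5),
    GeneSpec("AGO2", 859, 4),
)

DEFAULT_HOTSPOTS: tuple[HotspotSpec, ...] = (
    HotspotSpec("SMAD4", 361, 12, ("PAAD", "COAD", "READ")),
    HotspotSpec("DICER1", 1709, 6, ("UCEC",)),
    HotspotSpec("PRKRA", 127, 4, ("OV", "COAD")),
)

DEFAULT_CANCERS: tuple[str, ...] = ("PAAD", "COAD", "READ", "UCEC", "OV", "SKCM")


@dataclass(frozen=True)
class CohortConfig:
    """Full specification of one synthetic cohort.

    Defaults model a modest six-cancer cohort with the effect structure of
    interest: recurrent MH2-domain-like and RNase-domain-like hotspots,
    per-gene deleterious mutations, ~1% hypermutated samples, a 5p-down /
    3p-up expression shift in carriers of the nuclease hotspot sparing the
    Dicer-independent reference miRNA, a doubled hazard in carriers of
    deleterious mutations in the transcription-factor gene, and deletion
    enrichment in mutated samples of that same gene.
    """

    n_samples_per_cancer: int = 40
    cancer_types: tuple[str, ...] = DEFAULT_CANCERS
    genes: tuple[GeneSpec, ...] = DEFAULT_GENES
    hotspot_spec: tuple[HotspotSpec, ...] = DEFAULT_HOTSPOTS
    deleterious_rate: float = 0.04
    background_snv_rate: float = 0.3
    noise_call_rate: float = 1.0
    nonpass_rate: float = 0.5
    hypermutated_fraction: float = 0.01
    hyper_burden_multiplier: float = 10.0
    arm_effect: ArmEffect = ArmEffect()
    reference_mirna_id: str = "hsa-miR-451a"
    n_mirna_pairs: int = 60
    n_unpaired_mirnas: int = 8
    n_dropout_mirnas: int = 5
    dropout_rate: float = 0.4
    expr_noise_sd: float = 1.0
    rpm_noise_sigma: float = 0.5
    high_confidence_fraction: float = 0.5
    main_fraction_shift: float = 0.05
    isomir_concentration: float = 300.0
    survival_effect: SurvivalEffect = SurvivalEffect()
    baseline_hazard_per_day: float = 1.0 / 1000.0
    follow_up_days: float = 3000.0
    cnv_effect: CnvEffect = CnvEffect()
    seed: int = 0

    def validate(self) -> None:
        def _prob(name):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")

        if self.n_samples_per_cancer <= 0:
            raise ConfigError("n_samples_per_cancer must be positive")
        if not self.cancer_types:
            raise ConfigError("cancer_types must be non-empty")
        if not self.genes:
            raise ConfigError("genes must be non-empty")
        for name in ("deleterious_rate", "hypermutated_fraction",
                     "dropout_rate", "high_confidence_fraction",
                     "main_fraction_shift"):
            _prob(name)
        for name in ("noise_call_rate", "nonpass_rate", "background_snv_rate"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.survival_effect.hazard_ratio <= 0:
            raise ConfigError("survival_effect.hazard_ratio must be > 0")
        for v, nm in ((self.arm_effect.shift_5p, "arm_effect.shift_5p"),
                      (self.arm_effect.shift_3p, "arm_effect.shift_3p")):
            if not np.isfinite(v):
                raise ConfigError(f"{nm} must be finite")
        gene_names = {g.name for g in self.genes}
        for hs in self.hotspot_spec:
            if hs.gene not in gene_names:
                raise ConfigError(f"hotspot_spec gene {hs.gene!r} not in genes")
            gene = next(g for g in self.genes if g.name == hs.gene)
            if not 2 <= hs.residue <= gene.n_aa:
                raise ConfigError(
                    f"hotspot_spec residue {hs.residue} outside {hs.gene} CDS")
            if hs.cancers is not None:
                unknown = set(hs.cancers) - set(self.cancer_types)
                if unknown:
                    raise ConfigError(
                        f"hotspot_spec cancers {sorted(unknown)} not in cancer_types")
        for eff_gene, nm in ((self.arm_effect.gene, "arm_effect.gene"),
                             (self.survival_effect.gene, "survival_effect.gene"),
                             (self.cnv_effect.gene, "cnv_effect.gene")):
            if eff_gene not in gene_names:
                raise ConfigError(f"{nm} {eff_gene!r} not in genes")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PlannedMutation:
    sample_id: str
    gene: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    consequence: str
    aa_pos: Optional[int]
    aa_ref: Optional[str]
    aa_alt: Optional[str]
    mclass: str  # hotspot | deleterious | background
    callers: list[str] = field(default_factory=list)

    def key(self):
        return (self.sample_id, self.chrom, self.pos, self.ref, self.alt)


@dataclass
class GroundTruth:
    """Everything planted, for exact downstream verification."""

    mutations: list[dict]
    hypermutated: list[str]
    groups: dict[str, list[str]]  # "<gene>|<class>" -> carriers
    shifted_mirnas: dict[str, str]  # miRNA -> down/up
    arm_shifts: dict[str, float]
    expression_mutated: list[str]
    reference_mirna: str
    isomir: dict
    survival: dict
    cnv: dict
    config: dict

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def load(cls, path) -> "GroundTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------

def _codon_tables():
    from Bio.Data.CodonTable import standard_dna_table

    fwd = dict(standard_dna_table.forward_table)
    for c in standard_dna_table.stop_codons:
        fwd[c] = "*"
    by_aa: dict[str, list[str]] = {}
    for codon, aa in fwd.items():
        by_aa.setdefault(aa, []).append(codon)
    for v in by_aa.values():
        v.sort()
    return fwd, by_aa


_CODON_TO_AA, _AA_TO_CODONS = _codon_tables()
_AA20 = sorted(set(_CODON_TO_AA.values()) - {"*"})


def build_gene_models(config: CohortConfig) -> dict[str, TranscriptModel]:
    """Deterministic per-gene CDS sequences and exon layouts."""
    rng = np.random.default_rng([config.seed, _S_GENES])
    models: dict[str, TranscriptModel] = {}
    for gi, spec in enumerate(config.genes):
        aa_seq = ["M"] + [_AA20[i] for i in rng.integers(0, 20, spec.n_aa - 1)]
        codons = []
        for aa in aa_seq:
            opts = _AA_TO_CODONS[aa]
            codons.append(opts[rng.integers(0, len(opts))])
        codons.append("TAA")  # stop
        cds = "".join(codons)
        n_ex = max(1, spec.n_exons)
        # exon lengths >= 30 nt, remainder spread by a Dirichlet draw
        minimum = 30
        extra = len(cds) - minimum * n_ex
        if extra < 0:
            raise ConfigError(f"gene {spec.name}: CDS too short for {n_ex} exons")
        weights = rng.dirichlet(np.ones(n_ex))
        lengths = (minimum + np.floor(weights * extra)).astype(int)
        lengths[-1] += len(cds) - int(lengths.sum())
        chrom = f"chr{gi + 1}"
        exons = []
        cursor = 1000
        for L in lengths:
            exons.append((cursor, cursor + int(L)))
            cursor += int(L) + 300  # 300 bp introns
        models[spec.name] = TranscriptModel(spec.name, chrom, spec.strand,
                                            exons, cds)
    return models


def regions_bed_rows(models: dict[str, TranscriptModel]) -> list[tuple]:
    """Extended (+-2 nt) exon intervals as BED rows."""
    rows = []
    for model in models.values():
        for start, end in model.exons:
            rows.append((model.chrom, start - 2, end + 2, model.gene, 0,
                         model.strand))
    return rows


def write_regions_bed(models: dict[str, TranscriptModel], path) -> None:
    with open(path, "w") as fh:
        for row in regions_bed_rows(models):
            fh.write("\t".join(str(x) for x in row) + "\n")


# ---------------------------------------------------------------------------
# mutation planning
# ---------------------------------------------------------------------------

def _snv_at(model: TranscriptModel, idx: int, alt_cds: str
            ) -> tuple[str, int, str, str]:
    """Genomic (chrom, 1-based pos, ref, alt) for a CDS substitution."""
    pos0 = model.cds_to_genomic(idx)
    ref = model.ref_base(pos0)
    alt = complement(alt_cds) if model.strand == "-" else alt_cds
    return model.chrom, pos0 + 1, ref, alt


def _missense_options(model: TranscriptModel, residue: int
                      ) -> list[tuple[int, str, str, str]]:
    """(cds_idx, alt_cds_base, ref_aa, alt_aa) substitutions that change
    residue ``residue`` (1-based) to a different, non-stop AA."""
    codon = model.cds_seq[(residue - 1) * 3: residue * 3]
    ref_aa = _CODON_TO_AA[codon]
    opts = []
    if ref_aa == "*" or residue == 1:
        return opts
    for k in range(3):
        for b in _BASES:
            if b == codon[k]:
                continue
            alt_codon = codon[:k] + b + codon[k + 1:]
            alt_aa = _CODON_TO_AA[alt_codon]
            if alt_aa not in ("*", ref_aa):
                opts.append(((residue - 1) * 3 + k, b, ref_aa, alt_aa))
    return opts


def _stop_options(model: TranscriptModel) -> list[tuple[int, str, str]]:
    """Single-base substitutions creating a premature stop codon."""
    cached = getattr(model, "_stop_options_cache", None)
    if cached is not None:
        return cached
    opts = []
    n_codons = len(model.cds_seq) // 3
    for ci in range(1, n_codons - 1):  # skip start and the stop itself
        codon = model.cds_seq[ci * 3: ci * 3 + 3]
        ref_aa = _CODON_TO_AA[codon]
        if ref_aa == "*":
            continue
        for k in range(3):
            for b in _BASES:
                if b == codon[k]:
                    continue
                if _CODON_TO_AA[codon[:k] + b + codon[k + 1:]] == "*":
                    opts.append((ci * 3 + k, b, ref_aa))
    model._stop_options_cache = opts
    return opts


def _interior_cds_indices(model: TranscriptModel) -> np.ndarray:
    """CDS indices whose genomic position and successor lie inside the same
    exon, at least 3 nt from its edges (safe anchors for 1-bp indels)."""
    idxs = []
    for s, e in model.exons:
        for pos0 in range(s + 3, e - 4):
            idxs.append(pos0)
    return np.array(idxs)


def _plant_hotspot(model, residue, rng) -> PlannedMutation | None:
    opts = _missense_options(model, residue)
    if not opts:
        raise ConfigError(f"residue {residue} of {model.gene} admits no missense SNV")
    idx, alt_b, ref_aa, alt_aa = opts[rng.integers(0, len(opts))]
    chrom, pos, ref, alt = _snv_at(model, idx, alt_b)
    return PlannedMutation("", model.gene, chrom, pos, ref, alt,
                           Consequence.MISSENSE.value, residue, ref_aa, alt_aa,
                           "hotspot")


def _plant_deleterious(model, rng) -> PlannedMutation:
    kind = rng.choice(["nonsense", "frameshift", "splice"],
                      p=[0.45, 0.45, 0.10])
    if kind == "splice" and len(model.exons) < 2:
        kind = "nonsense"
    if kind == "nonsense":
        opts = _stop_options(model)
        idx, alt_b, ref_aa = opts[rng.integers(0, len(opts))]
        chrom, pos, ref, alt = _snv_at(model, idx, alt_b)
        return PlannedMutation("", model.gene, chrom, pos, ref, alt,
                               Consequence.NONSENSE.value, idx // 3 + 1,
                               ref_aa, "*", "deleterious")
    if kind == "frameshift":
        anchors = _interior_cds_indices(model)
        pos0 = int(anchors[rng.integers(0, len(anchors))])
        anchor_base = model.ref_base(pos0)
        if rng.integers(0, 2) == 0:  # 1-bp deletion of the next base
            ref = anchor_base + model.ref_base(pos0 + 1)
            alt = anchor_base
        else:  # 1-bp insertion after the anchor
            ref = anchor_base
            alt = anchor_base + _BASES[rng.integers(0, 4)]
        fs_anchor = pos0 + 1 if model.strand == "+" else pos0
        idx = model.genomic_to_cds(fs_anchor)
        aa_pos = idx // 3 + 1
        aa_ref = _CODON_TO_AA[model.cds_seq[(aa_pos - 1) * 3: aa_pos * 3]]
        return PlannedMutation("", model.gene, model.chrom, pos0 + 1, ref, alt,
                               Consequence.FRAMESHIFT.value, aa_pos, aa_ref,
                               "fs", "deleterious")
    # splice: one of the 2-nt windows at an internal junction
    junction = rng.integers(0, len(model.exons) - 1)
    _, end = model.exons[junction]
    nxt_start, _ = model.exons[junction + 1]
    pos0 = int(rng.choice([end, end + 1, nxt_start - 2, nxt_start - 1]))
    ref = pseudo_base(model.chrom, pos0 + 1)
    alt = _BASES[(_BASES.index(ref) + 1 + rng.integers(0, 3)) % 4]
    return PlannedMutation("", model.gene, model.chrom, pos0 + 1, ref, alt,
                           Consequence.SPLICE_SITE.value, None, None, None,
                           "deleterious")


def _plant_benign(model, rng) -> PlannedMutation:
    """Random missense or synonymous coding SNV."""
    for _ in range(100):
        idx = int(rng.integers(3, len(model.cds_seq) - 3))
        codon_i = idx // 3
        codon = model.cds_seq[codon_i * 3: codon_i * 3 + 3]
        ref_aa = _CODON_TO_AA[codon]
        if ref_aa == "*":
            continue
        b = _BASES[rng.integers(0, 4)]
        if b == model.cds_seq[idx]:
            continue
        alt_codon = codon[: idx % 3] + b + codon[idx % 3 + 1:]
        alt_aa = _CODON_TO_AA[alt_codon]
        if alt_aa == "*":
            continue
        chrom, pos, ref, alt = _snv_at(model, idx, b)
        cons = (Consequence.SYNONYMOUS if alt_aa == ref_aa
                else Consequence.MISSENSE)
        return PlannedMutation("", model.gene, chrom, pos, ref, alt,
                               cons.value, codon_i + 1, ref_aa, alt_aa,
                               "background")
    raise RuntimeError("could not place a benign SNV")  # pragma: no cover


@dataclass
class CohortPlan:
    samples: pd.DataFrame  # sample_id, cancer_type, hypermutated, exome_mutation_total
    mutations: list[PlannedMutation]
    models: dict[str, TranscriptModel]

    def carriers(self, gene: str, mclass: str) -> set[str]:
        """Samples with >=1 planted mutation of ``mclass`` in ``gene``
        ("any" matches every class)."""
        out = set()
        for m in self.mutations:
            if m.gene == gene and (mclass == "any" or m.mclass == mclass):
                out.add(m.sample_id)
        return out

    def gene_free(self, gene: str) -> set[str]:
        with_any = self.carriers(gene, "any")
        return set(self.samples["sample_id"]) - with_any


def plan_cohort(config: CohortConfig) -> CohortPlan:
    config.validate()
    models = build_gene_models(config)
    rng = np.random.default_rng([config.seed, _S_MUT])

    sample_rows = []
    for cancer in config.cancer_types:
        for i in range(config.n_samples_per_cancer):
            sample_rows.append({"sample_id": f"{cancer}-{i:04d}",
                                "cancer_type": cancer})
    samples = pd.DataFrame(sample_rows)
    n = len(samples)

    n_hyper = int(round(config.hypermutated_fraction * n))
    hyper_idx = set(rng.choice(n, size=n_hyper, replace=False).tolist()) if n_hyper else set()
    samples["hypermutated"] = [i in hyper_idx for i in range(n)]
    totals = rng.integers(20, 5000, size=n)
    hyper_totals = rng.integers(HYPERMUTATION_THRESHOLD + 1, 80_000, size=n)
    samples["exome_mutation_total"] = np.where(samples["hypermutated"],
                                               hyper_totals, totals)

    mutations: list[PlannedMutation] = []
    used: set[tuple] = set()

    def _add(mut: PlannedMutation, sample_id: str) -> bool:
        mut.sample_id = sample_id
        if mut.key() in used:
            return False
        used.add(mut.key())
        mutations.append(mut)
        return True

    # hotspots
    for hs in config.hotspot_spec:
        pool = samples if hs.cancers is None else samples[
            samples["cancer_type"].isin(hs.cancers)]
        if len(pool) < hs.count:
            raise ConfigError(
                f"hotspot_spec {hs.gene}:{hs.residue} needs {hs.count} samples,"
                f" only {len(pool)} available in {hs.cancers}")
        chosen = rng.choice(pool["sample_id"].to_numpy(), size=hs.count,
                            replace=False)
        for sid in chosen:
            for _ in range(20):
                if _add(_plant_hotspot(models[hs.gene], hs.residue, rng), sid):
                    break

    # per-gene deleterious carriers
    for gene in models:
        draws = rng.random(n)
        for i, sid in enumerate(samples["sample_id"]):
            if draws[i] < config.deleterious_rate:
                for _ in range(20):
                    if _add(_plant_deleterious(models[gene], rng), sid):
                        break

    # benign background, inflated in hypermutated samples
    gene_names = list(models)
    for i, sid in enumerate(samples["sample_id"]):
        lam = config.background_snv_rate
        if samples["hypermutated"].iloc[i]:
            lam *= config.hyper_burden_multiplier
        for _ in range(rng.poisson(lam)):
            gene = gene_names[rng.integers(0, len(gene_names))]
            for _ in range(20):
                if _add(_plant_benign(models[gene], rng), sid):
                    break

    # caller support: each planted mutation appears in >=1 caller
    all_callers = [c.value for c in Caller]
    for mut in mutations:
        k = int(rng.integers(1, 5))
        mut.callers = sorted(rng.choice(all_callers, size=k, replace=False))

    return CohortPlan(samples=samples, mutations=mutations, models=models)


# ---------------------------------------------------------------------------
# caller call sets
# ---------------------------------------------------------------------------

def _passing_values(caller: Caller, rng) -> dict:
    t_dp = int(rng.integers(60, 200))
    vaf = rng.uniform(0.15, 0.6)
    t_alt = max(2, int(round(vaf * t_dp)))
    n_dp = int(rng.integers(40, 120))
    vals = dict(t_alt_reads=t_alt, n_alt_reads=0,
                t_alt_freq=t_alt / t_dp, n_alt_freq=0.0,
                t_depth=t_dp, n_depth=n_dp, ssc=None, bq=None)
    if caller in SSC_CALLERS:
        vals["ssc"] = float(rng.integers(31, 121))
    if caller in BQ_CALLERS:
        vals["bq"] = float(rng.integers(21, 41))
    return vals


def emit_noise_call(failing_filter: str, rng, *, caller: Optional[Caller] = None,
                    sample_id: str = "NOISE", chrom: str = "chr1",
                    pos: int = 100, ref: str = "A", alt: str = "C"
                    ) -> CallerVariant:
    """A PASS-annotated call that violates exactly the named reliability
    criterion and satisfies the other three.

    ``failing_filter`` is one of ``alt_reads``, ``freq_ratio``, ``ssc``,
    ``bq``. When ``caller`` is omitted, a caller compatible with the
    criterion is chosen (SSC only exists for VarScan2/SomaticSniper, BQ for
    MuSE/MuTect2).
    """
    if failing_filter not in NOISE_FILTERS:
        raise ConfigError(f"unknown filter id: {failing_filter!r}")
    if caller is None:
        caller = {"ssc": Caller.VARSCAN2, "bq": Caller.MUSE}.get(
            failing_filter, Caller(np.asarray([c.value for c in Caller])[
                rng.integers(0, 4)]))
    caller = Caller(caller)
    if failing_filter == "ssc" and caller not in SSC_CALLERS:
        raise ConfigError(f"{caller.value} does not report SSC")
    if failing_filter == "bq" and caller not in BQ_CALLERS:
        raise ConfigError(f"{caller.value} does not report BQ")

    vals = _passing_values(caller, rng)
    if failing_filter == "alt_reads":
        vals["t_alt_reads"] = 1
        vals["t_alt_freq"] = 1 / vals["t_depth"]
    elif failing_filter == "freq_ratio":
        # normal freq 0.1; tumor freq <= 0.48 < 5 x 0.1
        vals.update(n_depth=40, n_alt_reads=4, n_alt_freq=0.1, t_depth=100)
        vals["t_alt_reads"] = int(rng.integers(2, 49))
        vals["t_alt_freq"] = vals["t_alt_reads"] / 100
    elif failing_filter == "ssc":
        vals["ssc"] = float(rng.integers(0, 31))  # <= 30 fails the > 30 rule
    elif failing_filter == "bq":
        vals["bq"] = float(rng.integers(0, 21))  # <= 20 fails the > 20 rule
    return CallerVariant(caller=caller, sample_id=sample_id, chrom=chrom,
                         pos=pos, ref=ref, alt=alt, filter_status="PASS",
                         **vals)


def _random_exonic_site(models, rng, used: set) -> tuple[str, int, str, str]:
    gene_names = list(models)
    for _ in range(200):
        model = models[gene_names[rng.integers(0, len(gene_names))]]
        idx = int(rng.integers(0, len(model.cds_seq)))
        pos0 = model.cds_to_genomic(idx)
        ref = model.ref_base(pos0)
        alt = _BASES[(_BASES.index(ref) + 1 + rng.integers(0, 3)) % 4]
        if (model.chrom, pos0 + 1, ref, alt) not in used:
            used.add((model.chrom, pos0 + 1, ref, alt))
            return model.chrom, pos0 + 1, ref, alt
    raise RuntimeError("could not place a noise call")  # pragma: no cover


def build_caller_records(plan: CohortPlan, config: CohortConfig
                         ) -> dict[tuple[str, Caller], list[CallerVariant]]:
    """Per (sample, caller) call lists: planted mutations with
    filter-passing values, noise calls each failing one named criterion,
    and non-PASS records."""
    by_sample: dict[str, list[PlannedMutation]] = {}
    for mut in plan.mutations:
        by_sample.setdefault(mut.sample_id, []).append(mut)

    records: dict[tuple[str, Caller], list[CallerVariant]] = {}
    for j, sid in enumerate(plan.samples["sample_id"]):
        rng = np.random.default_rng([config.seed, _S_CALLS, j])
        sample_keys = {(m.chrom, m.pos, m.ref, m.alt)
                       for m in by_sample.get(sid, [])}
        for caller in Caller:
            recs: list[CallerVariant] = []
            for mut in by_sample.get(sid, []):
                if caller.value not in mut.callers:
                    continue
                vals = _passing_values(caller, rng)
                recs.append(CallerVariant(
                    caller=caller, sample_id=sid, chrom=mut.chrom,
                    pos=mut.pos, ref=mut.ref, alt=mut.alt,
                    filter_status="PASS", **vals))
            applicable = ["alt_reads", "freq_ratio"]
            applicable.append("ssc" if caller in SSC_CALLERS else "bq")
            for _ in range(rng.poisson(config.noise_call_rate)):
                filt = applicable[rng.integers(0, len(applicable))]
                chrom, pos, ref, alt = _random_exonic_site(
                    plan.models, rng, sample_keys)
                recs.append(emit_noise_call(filt, rng, caller=caller,
                                            sample_id=sid, chrom=chrom,
                                            pos=pos, ref=ref, alt=alt))
            for _ in range(rng.poisson(config.nonpass_rate)):
                chrom, pos, ref, alt = _random_exonic_site(
                    plan.models, rng, sample_keys)
                vals = _passing_values(caller, rng)
                recs.append(CallerVariant(
                    caller=caller, sample_id=sid, chrom=chrom, pos=pos,
                    ref=ref, alt=alt, filter_status="REJECT", **vals))
            records[(sid, caller)] = recs
    return records


# ---------------------------------------------------------------------------
# expression, isomiRs, clinical, copy number
# ---------------------------------------------------------------------------

def mirna_panel(config: CohortConfig) -> pd.DataFrame:
    """The synthetic miRNA catalog: ID, arm annotation, confidence flag,
    dropout membership."""
    rng = np.random.default_rng([config.seed, _S_EXPR, 0])
    rows = []
    for i in range(config.n_mirna_pairs):
        rows.append((f"sim-miR-{i + 1:03d}-5p", "5p"))
        rows.append((f"sim-miR-{i + 1:03d}-3p", "3p"))
    for i in range(config.n_unpaired_mirnas):
        rows.append((f"sim-miR-u{i + 1:02d}", "unspecified"))
    for i in range(config.n_dropout_mirnas):
        rows.append((f"sim-miR-lo{i + 1:02d}", "unspecified"))
    rows.append((config.reference_mirna_id, "unspecified"))
    df = pd.DataFrame(rows, columns=["mirna", "arm"])
    flags = rng.random(len(df)) < config.high_confidence_fraction
    df["high_confidence"] = flags
    df.loc[df["mirna"] == config.reference_mirna_id, "high_confidence"] = True
    df["dropout"] = df["mirna"].str.startswith("sim-miR-lo")
    return df


def build_expression(plan: CohortPlan, config: CohortConfig
                     ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """(normalized-dialect matrix, RPM-dialect matrix, annotation table).

    Matrices are miRNA x sample. Carriers of the arm-effect mutation class
    receive ``shift_5p``/``shift_3p`` additively on the normalized scale and
    as log2 multipliers on the RPM scale; the reference miRNA is exempt.
    """
    panel = mirna_panel(config)
    mirnas = panel["mirna"].to_numpy()
    arm = panel["arm"].to_numpy()
    M = len(panel)
    shift = np.where(arm == "5p", config.arm_effect.shift_5p,
                     np.where(arm == "3p", config.arm_effect.shift_3p, 0.0))
    shift[mirnas == config.reference_mirna_id] = 0.0

    rng0 = np.random.default_rng([config.seed, _S_EXPR, 0])
    rng0.random(M)  # skip the confidence-flag draw of mirna_panel
    baseline_norm = rng0.normal(0.0, 0.3, size=M)
    log2_rpm_base = rng0.uniform(4.0, 11.0, size=M)
    log2_rpm_base[mirnas == config.reference_mirna_id] = rng0.uniform(8.0, 10.0)

    carriers = plan.carriers(config.arm_effect.gene,
                             config.arm_effect.mutation_class)
    dropout = panel["dropout"].to_numpy()

    sample_ids = plan.samples["sample_id"].to_numpy()
    norm = np.empty((M, len(sample_ids)))
    rpm = np.empty((M, len(sample_ids)))
    for j, sid in enumerate(sample_ids):
        rng = np.random.default_rng([config.seed, _S_EXPR, 1 + j])
        mutated = sid in carriers
        eff = shift if mutated else 0.0
        norm[:, j] = baseline_norm + eff + rng.normal(0, config.expr_noise_sd, M)
        rpm[:, j] = 2.0 ** (log2_rpm_base + eff
                            + rng.normal(0, config.rpm_noise_sigma, M))
        mask = dropout & (rng.random(M) < config.dropout_rate)
        norm[mask, j] = 0.0
        rpm[mask, j] = 0.0
    norm_df = pd.DataFrame(np.round(norm, 4), index=mirnas, columns=sample_ids)
    rpm_df = pd.DataFrame(np.round(rpm, 4), index=mirnas, columns=sample_ids)
    norm_df.index.name = rpm_df.index.name = "mirna"
    return norm_df, rpm_df, panel.drop(columns="dropout")


def isomir_affected_samples(plan: CohortPlan, config: CohortConfig) -> set[str]:
    gene = config.arm_effect.gene
    return plan.carriers(gene, "hotspot") | plan.carriers(gene, "deleterious")


def build_isomirs(plan: CohortPlan, config: CohortConfig,
                  rpm_df: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Long-format isomiR table for the 3p-annotated miRNAs.

    Each (sample, miRNA) distributes its total RPM over 5' offsets
    (-1, 0, +1) with a concentrated main isoform; affected samples have the
    main fraction reduced by ``main_fraction_shift``.
    """
    panel = mirna_panel(config)
    three_p = panel.loc[panel["arm"] == "3p", "mirna"].tolist()
    main_offsets = {m: (-1 if (i % 7) == 6 else 0)
                    for i, m in enumerate(three_p)}
    affected = isomir_affected_samples(plan, config)
    offsets = np.array([-1, 0, 1])
    conc = config.isomir_concentration
    rows = []
    for j, sid in enumerate(plan.samples["sample_id"]):
        rng = np.random.default_rng([config.seed, _S_ISO, 1 + j])
        shifted = sid in affected
        for m in three_p:
            total = float(rpm_df.at[m, sid])
            main = main_offsets[m]
            p_main = 0.96 - (config.main_fraction_shift if shifted else 0.0)
            p_minor = (1.0 - p_main) / 2.0
            probs = np.full(3, p_minor)
            probs[np.where(offsets == main)[0][0]] = p_main
            fracs = rng.dirichlet(probs * conc)
            for off, fr in zip(offsets, fracs):
                rows.append((sid, m, int(off), round(total * fr, 4)))
    df = pd.DataFrame(rows, columns=["sample_id", "mirna", "offset", "rpm"])
    return df, main_offsets


def build_clinical(plan: CohortPlan, config: CohortConfig) -> pd.DataFrame:
    """Clinical table with exponential survival under proportional hazards
    and uniform censoring over the follow-up window."""
    eff = config.survival_effect
    carriers = plan.carriers(eff.gene, eff.mutation_class)
    stages = np.array(["I", "II", "III", "IV"])
    rows = []
    for j, row in enumerate(plan.samples.itertuples()):
        rng = np.random.default_rng([config.seed, _S_CLIN, 1 + j])
        hazard = config.baseline_hazard_per_day
        if row.sample_id in carriers:
            hazard *= eff.hazard_ratio
        t_event = rng.exponential(1.0 / hazard)
        t_cens = rng.uniform(0.0, config.follow_up_days)
        stage = stages[rng.choice(4, p=[0.3, 0.3, 0.25, 0.15])]
        rows.append({
            "sample_id": row.sample_id,
            "cancer_type": row.cancer_type,
            "exome_mutation_total": int(row.exome_mutation_total),
            "stage": stage,
            "os_time": round(min(t_event, t_cens), 1),
            "os_event": bool(t_event <= t_cens),
        })
    return pd.DataFrame(rows)


def build_copy_number(plan: CohortPlan, config: CohortConfig) -> pd.DataFrame:
    """Thresholded gene-level copy-number calls in {-2..2}; deletions are
    enriched in mutated samples of the CNV-effect gene."""
    eff = config.cnv_effect
    carriers = plan.carriers(eff.gene, "any")
    genes = list(plan.models)
    values = np.array([-2, -1, 0, 1, 2])
    base_p = np.array([0.03, 0.07, 0.80, 0.07, 0.03])
    rows = []
    for j, sid in enumerate(plan.samples["sample_id"]):
        rng = np.random.default_rng([config.seed, _S_CNV, 1 + j])
        row = {"sample_id": sid}
        for gene in genes:
            if gene == eff.gene:
                p_del = (eff.del_prob_mutated if sid in carriers
                         else eff.del_prob_background)
                if rng.random() < p_del:
                    row[gene] = int(rng.choice([-1, -2]))
                else:
                    row[gene] = int(values[rng.choice(5, p=base_p)])
                    if row[gene] < 0:
                        row[gene] = 0  # deletion probability fully governed above
            else:
                row[gene] = int(values[rng.choice(5, p=base_p)])
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# bundle assembly
# ---------------------------------------------------------------------------

ALL_COMPONENTS = frozenset({"calls", "expression", "isomir", "clinical", "cnv"})


def build_ground_truth(plan: CohortPlan, config: CohortConfig,
                       main_offsets: dict[str, int] | None) -> GroundTruth:
    panel = mirna_panel(config)
    shifted = {}
    for _, r in panel.iterrows():
        if r["mirna"] == config.reference_mirna_id or r["arm"] == "unspecified":
            continue
        s = (config.arm_effect.shift_5p if r["arm"] == "5p"
             else config.arm_effect.shift_3p)
        if s != 0:
            shifted[r["mirna"]] = "down" if s < 0 else "up"
    groups = {}
    for gene in plan.models:
        for mclass in ("hotspot", "deleterious", "background", "any"):
            members = sorted(plan.carriers(gene, mclass))
            if members:
                groups[f"{gene}|{mclass}"] = members
    eff = config.survival_effect
    return GroundTruth(
        mutations=[dataclasses.asdict(m) for m in plan.mutations],
        hypermutated=sorted(
            plan.samples.loc[plan.samples["hypermutated"], "sample_id"]),
        groups=groups,
        shifted_mirnas=shifted,
        arm_shifts={"5p": config.arm_effect.shift_5p,
                    "3p": config.arm_effect.shift_3p},
        expression_mutated=sorted(plan.carriers(
            config.arm_effect.gene, config.arm_effect.mutation_class)),
        reference_mirna=config.reference_mirna_id,
        isomir={
            "affected": sorted(isomir_affected_samples(plan, config)),
            "main_offsets": main_offsets or {},
            "main_fraction_shift": config.main_fraction_shift,
        },
        survival={"gene": eff.gene, "mutation_class": eff.mutation_class,
                  "hazard_ratio": eff.hazard_ratio,
                  "mutated": sorted(plan.carriers(eff.gene, eff.mutation_class))},
        cnv=dataclasses.asdict(config.cnv_effect),
        config=config.to_dict(),
    )


def generate_cohort(config: CohortConfig, out_dir,
                    components: frozenset = ALL_COMPONENTS
                    ) -> tuple[dict[str, Path], GroundTruth]:
    """Emit the full synthetic file bundle and its ground truth.

    Returns a mapping of logical names to file paths, plus the GroundTruth
    (also saved as ``ground_truth.json``). The same config and seed produce
    a byte-identical bundle.
    """
    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    plan = plan_cohort(config)
    bundle: dict[str, Path] = {}

    bundle["regions"] = out_dir / "regions.bed"
    write_regions_bed(plan.models, bundle["regions"])
    bundle["transcripts"] = out_dir / "transcripts.json"
    save_transcripts(plan.models.values(), bundle["transcripts"])

    main_offsets = None
    rpm_df = None
    if {"expression", "isomir"} & components:
        norm_df, rpm_df, annot = build_expression(plan, config)
        if "expression" in components:
            bundle["expression_normalized"] = out_dir / "expression_normalized.tsv"
            norm_df.to_csv(bundle["expression_normalized"], sep="\t",
                           float_format="%.4f")
            bundle["expression_rpm"] = out_dir / "expression_rpm.tsv"
            rpm_df.to_csv(bundle["expression_rpm"], sep="\t",
                          float_format="%.4f")
            bundle["mirna_annotations"] = out_dir / "mirna_annotations.tsv"
            annot.to_csv(bundle["mirna_annotations"], sep="\t", index=False)
    if "isomir" in components:
        iso_df, main_offsets = build_isomirs(plan, config, rpm_df)
        bundle["isomirs"] = out_dir / "isomirs.tsv"
        iso_df.to_csv(bundle["isomirs"], sep="\t", index=False,
                      float_format="%.4f")
    if "clinical" in components:
        bundle["clinical"] = out_dir / "clinical.tsv"
        build_clinical(plan, config).to_csv(bundle["clinical"], sep="\t",
                                            index=False, float_format="%.1f")
    if "cnv" in components:
        bundle["copy_number"] = out_dir / "copy_number.tsv"
        build_copy_number(plan, config).to_csv(bundle["copy_number"], sep="\t",
                                               index=False)
    if "calls" in components:
        calls_dir = out_dir / "calls"
        calls_dir.mkdir(exist_ok=True)
        contigs = [m.chrom for m in plan.models.values()]
        for (sid, caller), recs in build_caller_records(plan, config).items():
            path = calls_dir / f"{sid}.{caller.value}.vcf"
            dialects.write_vcf(path, caller, recs, contigs)
        bundle["calls_dir"] = calls_dir

    truth = build_ground_truth(plan, config, main_offsets)
    bundle["ground_truth"] = out_dir / "ground_truth.json"
    truth.save(bundle["ground_truth"])
    return bundle, truth
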