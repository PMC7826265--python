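"""Cohort-level mutation statistics.

Hypermutated-sample exclusion, consequence-class summaries, mutation
density, per-gene/per-cancer mutated-sample frequencies, overmutation
enrichment (one-sided Fisher against the pan-cancer background with
Bonferroni control), recurrence-based hotspot detection, and the
hotspot-versus-deleterious composition of a gene's mutation spectrum.

Mutation tables are the MAF-like DataFrames produced by
:mod:`mutatlas.consensus` (columns ``sample_id, cancer_type, gene, ...,
consequence, aa_pos``); sample tables carry ``sample_id, cancer_type,
exome_mutation_total`` and clinical fields.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from .types import Consequence, DELETERIOUS_CLASSES, ValidationError
from .synthetic import HYPERMUTATION_THRESHOLD

DELETERIOUS = sorted(c.value for c in DELETERIOUS_CLASSES)


def round_half_up(x: float, digits: int = 0) -> float:
    """Round with ties away from zero, as printed percentages are."""
    q = Decimal(1).scaleb(-digits)
    v = float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
    return int(v) if digits == 0 else v


def pct(numerator: float, denominator: float, digits: int = 0) -> float:
    if denominator == 0:
        return 0.0
    return round_half_up(100.0 * numerator / denominator, digits)


# ---------------------------------------------------------------------------
# hypermutation
# ---------------------------------------------------------------------------

def flag_hypermutated(samples: pd.DataFrame,
                      threshold: int = HYPERMUTATION_THRESHOLD) -> pd.DataFrame:
    """Flag samples whose exome-wide burden strictly exceeds ``threshold``."""
    out = samples.copy()
    out["hypermutated"] = out["exome_mutation_total"] > threshold
    return out


def exclude_hypermutated(muts: pd.DataFrame, samples: pd.DataFrame
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop flagged samples and their mutations."""
    if "hypermutated" not in samples.columns:
        samples = flag_hypermutated(samples)
    keep = samples.loc[~samples["hypermutated"], "sample_id"]
    return (muts[muts["sample_id"].isin(set(keep))].copy(),
            samples[~samples["hypermutated"]].copy())


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def classification_summary(muts: pd.DataFrame) -> dict:
    """Counts, integer percentages (half-up), and the deleterious total
    (frameshift + nonsense + splice_site)."""
    counts = {c.value: 0 for c in Consequence}
    counts.update(muts["consequence"].value_counts().to_dict())
    total = int(len(muts))
    out = {
        "total": total,
        "counts": {k: int(v) for k, v in counts.items()},
        "percent": {k: pct(v, total) for k, v in counts.items()},
    }
    deleterious = sum(counts[c] for c in DELETERIOUS)
    out["deleterious_total"] = int(deleterious)
    out["deleterious_percent"] = pct(deleterious, total)
    return out


def mutation_density(count: int, coding_length_bp: int) -> float:
    """Mutations per kbp of analyzed coding sequence."""
    if coding_length_bp <= 0:
        raise ValidationError("coding_length_bp must be > 0")
    return 1000.0 * count / coding_length_bp


def sample_mutation_frequency(muts: pd.DataFrame, samples: pd.DataFrame,
                              genes: Optional[Iterable[str]] = None
                              ) -> pd.DataFrame:
    """Percent of samples of each cancer with >=1 mutation in each gene.

    A sample with several mutations in a gene counts once. Returns a
    gene x cancer matrix with a leading ``pan_cancer`` column.
    """
    genes = sorted(genes) if genes is not None else sorted(
        muts["gene"].dropna().unique())
    cancers = sorted(samples["cancer_type"].unique())
    n_by_cancer = samples.groupby("cancer_type")["sample_id"].nunique()
    mutated = muts.drop_duplicates(["sample_id", "gene"])
    table = pd.DataFrame(0.0, index=genes, columns=["pan_cancer"] + cancers)
    for gene in genes:
        carriers = mutated.loc[mutated["gene"] == gene]
        table.loc[gene, "pan_cancer"] = 100.0 * len(carriers) / len(samples)
        per_cancer = carriers.groupby("cancer_type")["sample_id"].nunique()
        for cancer in cancers:
            table.loc[gene, cancer] = (
                100.0 * per_cancer.get(cancer, 0) / n_by_cancer[cancer])
    table.index.name = "gene"
    return table


# ---------------------------------------------------------------------------
# overmutation
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentResult:
    gene: str
    cancer_type: str
    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    p: float
    p_adjusted: float


def overmutation_test(gene: str, cancer: str, muts: pd.DataFrame,
                      n_tests: int = 1, *, count_samples: bool = False,
                      include_self: bool = False) -> EnrichmentResult:
    """One-sided Fisher enrichment of ``gene`` mutations in ``cancer``
    against the pan-cancer background.

    The 2x2 table counts mutations {in gene, in other panel genes} x
    {in cancer, in the rest of the cohort}; with ``count_samples`` it counts
    mutated samples instead, and with ``include_self`` the background
    includes the tested cancer. Bonferroni adjustment multiplies by
    ``n_tests``.
    """
    df = muts
    if count_samples:
        df = muts.drop_duplicates(["sample_id", "gene"])
    in_cancer = df["cancer_type"] == cancer
    in_gene = df["gene"] == gene
    rest = pd.Series(True, index=df.index) if include_self else ~in_cancer
    a = int((in_gene & in_cancer).sum())
    b = int((~in_gene & in_cancer).sum())
    c = int((in_gene & rest).sum())
    d = int((~in_gene & rest).sum())
    table = ((a, b), (c, d))
    if min(a + b, c + d) == 0 or min(a + c, b + d) == 0:
        warnings.warn(f"overmutation_test({gene}, {cancer}): empty margin")
        return EnrichmentResult(gene, cancer, table, float("nan"), 1.0, 1.0)
    odds, p = sps.fisher_exact(np.array(table), alternative="greater")
    return EnrichmentResult(gene, cancer, table, float(odds), float(p),
                            min(1.0, float(p) * n_tests))


def overmutation_scan(muts: pd.DataFrame, samples: pd.DataFrame,
                      genes: Optional[Iterable[str]] = None,
                      **kwargs) -> pd.DataFrame:
    """Fisher enrichment for every gene x cancer pair, Bonferroni-adjusted
    over the full grid."""
    genes = sorted(genes) if genes is not None else sorted(
        muts["gene"].dropna().unique())
    cancers = sorted(samples["cancer_type"].unique())
    n_tests = len(genes) * len(cancers)
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for gene in genes:
            for cancer in cancers:
                r = overmutation_test(gene, cancer, muts, n_tests, **kwargs)
                (a, b), (c, d) = r.table
                rows.append({"gene": gene, "cancer_type": cancer,
                             "gene_in_cancer": a, "other_in_cancer": b,
                             "gene_in_rest": c, "other_in_rest": d,
                             "odds_ratio": r.odds_ratio, "p": r.p,
                             "p_adjusted": r.p_adjusted})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# hotspots
# ---------------------------------------------------------------------------

@dataclass
class HotspotResult:
    gene: str
    aa_position: int
    count: int
    breakdown: dict[str, int]
    cancers: dict[str, int]


def detect_hotspots(muts: pd.DataFrame, min_recurrence: int = 3
                    ) -> list[HotspotResult]:
    """Recurrently mutated AA residues: (gene, AA position) pairs carrying
    at least ``min_recurrence`` protein-changing mutations, sorted by count
    descending, ties by gene then position."""
    df = muts.dropna(subset=["gene", "aa_pos"])
    results = []
    for (gene, aa_pos), grp in df.groupby(["gene", "aa_pos"]):
        if len(grp) >= min_recurrence:
            results.append(HotspotResult(
                gene=gene, aa_position=int(aa_pos), count=int(len(grp)),
                breakdown=grp["consequence"].value_counts().to_dict(),
                cancers=grp["cancer_type"].value_counts().to_dict()))
    results.sort(key=lambda h: (-h.count, h.gene, h.aa_position))
    return results


def hotspots_to_frame(hotspots: list[HotspotResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "gene": h.gene, "aa_position": h.aa_position, "count": h.count,
        "breakdown": ";".join(f"{k}:{v}" for k, v in sorted(h.breakdown.items())),
        "cancers": ";".join(f"{k}:{v}" for k, v in sorted(h.cancers.items())),
    } for h in hotspots])


def hotspot_vs_deleterious_proportions(
    muts: pd.DataFrame, gene: str, hotspot_residues: Iterable[int]
) -> pd.DataFrame:
    """Per-cancer split of a gene's hotspot-missense vs deleterious
    mutations, with a Fisher test of each cancer's split against the rest
    of the cohort. The ``pan_cancer`` row summarizes all cancers."""
    residues = set(int(r) for r in hotspot_residues)
    df = muts[muts["gene"] == gene].copy()
    is_hot = ((df["consequence"] == "missense")
              & df["aa_pos"].isin(residues))
    is_del = df["consequence"].isin(DELETERIOUS)
    df = df[is_hot | is_del]
    df["kind"] = np.where(
        ((df["consequence"] == "missense") & df["aa_pos"].isin(residues)),
        "hotspot", "deleterious")
    total_hot = int((df["kind"] == "hotspot").sum())
    total_del = int((df["kind"] == "deleterious").sum())
    rows = [{
        "cancer_type": "pan_cancer", "hotspot": total_hot,
        "deleterious": total_del,
        "hotspot_pct": pct(total_hot, total_hot + total_del),
        "deleterious_pct": pct(total_del, total_hot + total_del),
        "p": np.nan,
    }]
    for cancer, grp in df.groupby("cancer_type"):
        h = int((grp["kind"] == "hotspot").sum())
        d = int((grp["kind"] == "deleterious").sum())
        if h + d == 0:
            continue
        rest_h, rest_d = total_hot - h, total_del - d
        _, p = sps.fisher_exact([[h, d], [rest_h, rest_d]])
        rows.append({"cancer_type": cancer, "hotspot": h, "deleterious": d,
                     "hotspot_pct": pct(h, h + d),
                     "deleterious_pct": pct(d, h + d), "p": float(p)})
    return pd.DataFrame(rows)
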