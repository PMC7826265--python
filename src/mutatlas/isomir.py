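"""5'-end heterogeneity of 3p-miRNAs.

Quantifies, per sample and miRNA, the fraction of reads carried by the
most abundant 5'-end isoform (the "main" isoform, defined cohort-wide on
the unmutated reference samples) versus upstream/downstream minor isomiRs,
and compares main fractions between mutation groups.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from .types import ValidationError

MIN_INFORMATIVE = 3


def load_isomirs(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "mirna", "offset", "rpm"}
    if not required <= set(df.columns):
        raise ValidationError(f"isomiR table must have columns {sorted(required)}")
    return df


def select_high_expression_3p(isomirs: pd.DataFrame, arm: pd.Series,
                              min_rpm: float = 100.0,
                              stat: str = "median") -> list[str]:
    """3p-annotated miRNAs whose per-sample total RPM has cohort
    median (or mean/min) >= ``min_rpm``."""
    totals = isomirs.groupby(["mirna", "sample_id"])["rpm"].sum()
    agg = {"median": np.median, "mean": np.mean, "min": np.min}[stat]
    keep = []
    for mirna, per_sample in totals.groupby(level="mirna"):
        if arm.get(mirna, "unspecified") != "3p":
            continue
        if agg(per_sample.to_numpy()) >= min_rpm:
            keep.append(mirna)
    return sorted(keep)


@dataclass
class MainFractionResult:
    mirna: str
    main_offset: int
    fractions: pd.DataFrame  # sample_id, main_fraction, upstream, downstream
    n_excluded: int  # all-zero samples


def main_fraction(isomirs: pd.DataFrame, mirna: str,
                  reference_samples: Iterable[str]) -> MainFractionResult:
    """Main-isoform fraction per sample for one miRNA.

    The main offset is the 5' offset with the highest total RPM across the
    reference (unmutated) samples, so group comparisons address the same
    isoform. Upstream (more negative) and downstream minor fractions are
    reported alongside; all-zero samples are excluded and counted.
    """
    df = isomirs[isomirs["mirna"] == mirna]
    if df.empty:
        raise ValidationError(f"no isomiR records for {mirna!r}")
    ref = df[df["sample_id"].isin(set(reference_samples))]
    pool = ref if not ref.empty else df
    by_offset = pool.groupby("offset")["rpm"].sum()
    if float(by_offset.max()) <= 0:
        raise ValidationError(f"{mirna}: no positive RPM in reference samples")
    main_off = int(by_offset.idxmax())
    rows = []
    n_excluded = 0
    for sid, grp in df.groupby("sample_id"):
        total = float(grp["rpm"].sum())
        if total <= 0:
            n_excluded += 1
            continue
        main = float(grp.loc[grp["offset"] == main_off, "rpm"].sum()) / total
        upstream = float(grp.loc[grp["offset"] < main_off, "rpm"].sum()) / total
        downstream = float(grp.loc[grp["offset"] > main_off, "rpm"].sum()) / total
        rows.append({"sample_id": sid, "main_fraction": main,
                     "upstream": upstream, "downstream": downstream})
    return MainFractionResult(mirna, main_off, pd.DataFrame(rows), n_excluded)


def compare_fractions(results: list[MainFractionResult],
                      mutated: Iterable[str], reference: Iterable[str]
                      ) -> pd.DataFrame:
    """Rank-sum comparison of per-sample main fractions between groups.

    One row per miRNA plus a ``pooled`` row over all (miRNA, sample) main
    fractions. Groups with < 3 informative samples yield a missing p with
    a warning.
    """
    mutated, reference = set(mutated), set(reference)
    rows = []
    pooled_mut, pooled_ref = [], []

    def _row(label, x, y):
        if len(x) < MIN_INFORMATIVE or len(y) < MIN_INFORMATIVE:
            warnings.warn(f"{label}: fewer than {MIN_INFORMATIVE} informative "
                          "samples in a group")
            return {"mirna": label, "n_mut": len(x), "n_ref": len(y),
                    "median_mut": np.median(x) if len(x) else np.nan,
                    "median_ref": np.median(y) if len(y) else np.nan,
                    "effect": np.nan, "p": np.nan, "direction": None}
        if np.ptp(np.concatenate([x, y])) == 0:
            p = 1.0
        else:
            p = float(sps.mannwhitneyu(x, y, alternative="two-sided").pvalue)
        eff = float(np.median(x) - np.median(y))
        return {"mirna": label, "n_mut": len(x), "n_ref": len(y),
                "median_mut": float(np.median(x)),
                "median_ref": float(np.median(y)),
                "effect": eff, "p": p,
                "direction": "down" if eff < 0 else "up"}

    for res in results:
        fr = res.fractions.set_index("sample_id")["main_fraction"]
        x = fr[fr.index.isin(mutated)].to_numpy()
        y = fr[fr.index.isin(reference)].to_numpy()
        pooled_mut.append(x)
        pooled_ref.append(y)
        rows.append(_row(res.mirna, x, y))
    rows.append(_row("pooled", np.concatenate(pooled_mut) if pooled_mut else
                     np.array([]), np.concatenate(pooled_ref) if pooled_ref
                     else np.array([])))
    return pd.DataFrame(rows)
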