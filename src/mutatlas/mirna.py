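"""miRNA expression filtering, normalization, and mutation-group
differential analysis with 5p/3p arm-asymmetry statistics.

Two expression dialects flow through this module: ``batch_normalized``
levels (additively comparable, may be negative) on which group effects are
differences of medians, and ``rpm`` counts (reads per million miRNA-mapped,
non-negative) on which effects are log2 fold changes of medians. A third
derived dialect, ``log2_ratio``, results from re-normalizing RPM values
against a reference miRNA whose maturation bypasses the perturbed nuclease;
being already a log scale, it uses difference effects.

The differential test is a two-sided Wilcoxon rank-sum: exact enumeration
when the smaller group has <= 8 samples and the data are tie-free,
otherwise the normal approximation with tie correction.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .types import ValidationError
from .stats import DELETERIOUS

EXACT_MAX_N = 8


@dataclass
class ExpressionMatrix:
    """miRNA x sample expression values with arm/confidence annotations.

    ``dialect`` is ``batch_normalized``, ``rpm``, or ``log2_ratio``;
    RPM values must be non-negative.
    """

    values: pd.DataFrame  # index = miRNA, columns = sample IDs
    dialect: str = "batch_normalized"
    arm: pd.Series = None  # miRNA -> {5p, 3p, unspecified}
    high_confidence: pd.Series = None

    def __post_init__(self):
        if self.dialect not in {"batch_normalized", "rpm", "log2_ratio"}:
            raise ValidationError(f"unknown dialect {self.dialect!r}")
        if self.dialect == "rpm" and (self.values.to_numpy() < 0).any():
            raise ValidationError("rpm dialect values must be >= 0")
        if self.arm is None:
            self.arm = pd.Series(
                [arm_from_id(m) for m in self.values.index],
                index=self.values.index)
        if self.high_confidence is None:
            self.high_confidence = pd.Series(True, index=self.values.index)

    @property
    def mirnas(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def subset(self, mirnas: Iterable[str]) -> "ExpressionMatrix":
        mirnas = [m for m in self.values.index if m in set(mirnas)]
        return ExpressionMatrix(self.values.loc[mirnas], self.dialect,
                                self.arm.loc[mirnas],
                                self.high_confidence.loc[mirnas])


def arm_from_id(mirna: str) -> str:
    """Arm from the canonical -5p/-3p ID suffix; otherwise unspecified."""
    if mirna.endswith("-5p"):
        return "5p"
    if mirna.endswith("-3p"):
        return "3p"
    return "unspecified"


def load_expression(path, dialect: str,
                    annotations: Optional[pd.DataFrame] = None
                    ) -> ExpressionMatrix:
    """Read a miRNA x sample TSV; ``annotations`` may carry columns
    ``mirna, arm, high_confidence``."""
    values = pd.read_csv(path, sep="\t", index_col=0)
    arm = high = None
    if annotations is not None:
        ann = annotations.set_index("mirna")
        arm = ann["arm"].reindex(values.index).fillna("unspecified")
        high = ann["high_confidence"].reindex(values.index).fillna(False)
    return ExpressionMatrix(values, dialect, arm, high)


# ---------------------------------------------------------------------------
# filtering and normalization
# ---------------------------------------------------------------------------

def filter_expressed(matrix: ExpressionMatrix, scope: str = "pan_cancer"
                     ) -> ExpressionMatrix:
    """Drop miRNAs undetectable (level exactly 0) in more than 30% of
    samples (pan-cancer scope) or 10% (single-cancer scope)."""
    if scope not in {"pan_cancer", "single_cancer"}:
        raise ValidationError(f"unknown scope {scope!r}")
    threshold = 0.30 if scope == "pan_cancer" else 0.10
    zero_frac = (matrix.values == 0).mean(axis=1)
    keep = zero_frac[zero_frac <= threshold].index
    return matrix.subset(keep)


def pan_cancer_normalize(matrix: ExpressionMatrix,
                         cancer_labels: pd.Series) -> ExpressionMatrix:
    """Equalize per-cancer location and spread of each miRNA.

    Within each cancer type: subtract the per-miRNA median, then divide by
    the maximum absolute deviation from it, giving median exactly 0 and
    values in [-1, 1] (constant miRNAs map to 0). Idempotent.
    """
    labels = cancer_labels.reindex(matrix.samples)
    if labels.isna().any():
        missing = list(labels[labels.isna()].index[:3])
        raise ValidationError(f"samples without a cancer label: {missing}")
    out = matrix.values.copy().astype(float)
    for cancer, cols in matrix.values.columns.groupby(labels).items():
        if len(cols) < 2:
            raise ValidationError(
                f"cancer {cancer!r} has a single sample; cannot normalize")
        block = out[cols]
        med = block.median(axis=1)
        dev = block.sub(med, axis=0)
        denom = dev.abs().max(axis=1).replace(0.0, np.inf)
        out[cols] = dev.div(denom, axis=0)
    return ExpressionMatrix(out, matrix.dialect, matrix.arm,
                            matrix.high_confidence)


def reference_normalize(matrix: ExpressionMatrix,
                        reference_mirna: str = "hsa-miR-451a",
                        pseudocount: float = 1.0,
                        log: bool = True) -> ExpressionMatrix:
    """Re-express RPM levels relative to a reference miRNA per sample.

    ``log2(x + pc) - log2(x_ref + pc)`` per sample column (or the plain
    ratio with ``log=False``). The reference row becomes identically 0
    (or 1), and per-sample global rescaling cancels exactly.
    """
    if matrix.dialect != "rpm":
        raise ValidationError("reference_normalize expects the rpm dialect")
    if reference_mirna not in matrix.values.index:
        raise ValidationError(f"reference miRNA {reference_mirna!r} absent")
    ref = matrix.values.loc[reference_mirna]
    zero_frac = float((ref == 0).mean())
    if zero_frac > 0.10:
        warnings.warn(
            f"reference miRNA {reference_mirna} is zero in "
            f"{100 * zero_frac:.0f}% of samples")
    shifted = matrix.values + pseudocount
    if log:
        out = np.log2(shifted).sub(np.log2(ref + pseudocount), axis=1)
        dialect = "log2_ratio"
    else:
        out = shifted.div(ref + pseudocount, axis=1)
        dialect = "rpm"
    return ExpressionMatrix(out, dialect, matrix.arm, matrix.high_confidence)


# ---------------------------------------------------------------------------
# groups and differential test
# ---------------------------------------------------------------------------

def class_predicate(mutation_class: str,
                    hotspot_residues: Optional[Iterable[int]] = None
                    ) -> Callable[[pd.DataFrame], pd.Series]:
    """Row predicate over a mutation table for a named mutation class."""
    residues = set(int(r) for r in hotspot_residues) if hotspot_residues else set()

    def pred(df: pd.DataFrame) -> pd.Series:
        if mutation_class == "any":
            return pd.Series(True, index=df.index)
        if mutation_class == "hotspot":
            if not residues:
                raise ValidationError("hotspot class requires hotspot_residues")
            return (df["consequence"] == "missense") & df["aa_pos"].isin(residues)
        if mutation_class == "deleterious":
            return df["consequence"].isin(DELETERIOUS)
        if mutation_class in {"missense", "synonymous", "nonsense",
                              "frameshift", "splice_site", "inframe_indel",
                              "start_stop", "other"}:
            return df["consequence"] == mutation_class
        raise ValidationError(f"unknown mutation class {mutation_class!r}")

    return pred


def define_groups(samples: pd.DataFrame, muts: pd.DataFrame, gene: str,
                  mutation_class: str | Callable,
                  hotspot_residues: Optional[Iterable[int]] = None
                  ) -> tuple[set[str], set[str]]:
    """(mutated, reference) sample sets for one gene and mutation class.

    Mutated: >=1 mutation of the class in the gene. Reference: no mutation
    of any class in the gene. Samples carrying only other-class mutations
    in the gene belong to neither.
    """
    pred = (mutation_class if callable(mutation_class)
            else class_predicate(mutation_class, hotspot_residues))
    in_gene = muts[muts["gene"] == gene]
    mutated = set(in_gene.loc[pred(in_gene), "sample_id"])
    if not mutated:
        raise ValidationError(
            f"no samples with {mutation_class!r} mutations in {gene}")
    with_any = set(in_gene["sample_id"])
    reference = set(samples["sample_id"]) - with_any
    return mutated, reference


def _rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    if np.ptp(np.concatenate([x, y])) == 0:
        return 1.0
    n_min = min(len(x), len(y))
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (n_min <= EXACT_MAX_N and not has_ties) else "asymptotic"
    return float(sps.mannwhitneyu(x, y, alternative="two-sided",
                                  method=method).pvalue)


def diff_test(matrix: ExpressionMatrix, mutated: Iterable[str],
              reference: Iterable[str], pseudocount: float = 1.0
              ) -> pd.DataFrame:
    """Per-miRNA two-sided rank-sum comparison of mutated vs reference.

    Effect is the difference of group medians (normalized/log dialects) or
    the log2 fold change of group medians with a pseudocount (rpm dialect).
    Returns columns ``mirna, arm, n_mut, n_ref, effect, p, p_adjusted,
    direction`` with Benjamini-Hochberg adjusted p-values as an extra
    column.
    """
    mut_cols = [s for s in matrix.samples if s in set(mutated)]
    ref_cols = [s for s in matrix.samples if s in set(reference)]
    if not mut_cols or not ref_cols:
        raise ValidationError("both groups must be non-empty")
    X = matrix.values[mut_cols].to_numpy(float)
    Y = matrix.values[ref_cols].to_numpy(float)
    med_x = np.median(X, axis=1)
    med_y = np.median(Y, axis=1)
    if matrix.dialect == "rpm":
        effect = np.log2(med_x + pseudocount) - np.log2(med_y + pseudocount)
    else:
        effect = med_x - med_y

    n_min = min(X.shape[1], Y.shape[1])
    constant = (np.ptp(np.hstack([X, Y]), axis=1) == 0)
    if n_min > EXACT_MAX_N:
        with np.errstate(all="ignore"):
            res = sps.mannwhitneyu(X, Y, alternative="two-sided",
                                   method="asymptotic", axis=1)
        pvals = np.asarray(res.pvalue, float)
    else:
        pvals = np.array([_rank_sum_p(X[i], Y[i]) for i in range(X.shape[0])])
    pvals[constant] = 1.0
    effect[constant] = 0.0
    out = pd.DataFrame({
        "mirna": matrix.mirnas,
        "arm": matrix.arm.to_numpy(),
        "n_mut": len(mut_cols),
        "n_ref": len(ref_cols),
        "effect": effect,
        "p": pvals,
    })
    out["p_adjusted"] = multipletests(out["p"], method="fdr_bh")[1]
    out["direction"] = np.where(out["effect"] < 0, "down", "up")
    return out


# ---------------------------------------------------------------------------
# summaries over differential results
# ---------------------------------------------------------------------------

def direction_summary(results: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Counts and percentages of down- vs upregulated miRNAs among results
    significant at ``alpha``."""
    sig = results[results["p"] < alpha]
    n_down = int((sig["direction"] == "down").sum())
    n_up = int((sig["direction"] == "up").sum())
    total = n_down + n_up
    from .stats import pct
    return {"n_significant": total, "n_down": n_down, "n_up": n_up,
            "down_pct": pct(n_down, total), "up_pct": pct(n_up, total)}


def arm_asymmetry(results: pd.DataFrame, alpha: float = 0.05) -> dict:
    """5p/3p composition of significantly down- and upregulated miRNAs,
    with a two-sided Fisher test of the arm x direction table. miRNAs with
    unspecified arm are excluded."""
    if results.empty:
        sig = results
    else:
        sig = results[(results["p"] < alpha)
                      & results["arm"].isin(["5p", "3p"])]
    if sig.empty:
        warnings.warn("no significant arm-annotated miRNAs")
        return {"n_significant": 0, "table": ((0, 0), (0, 0)), "p": None,
                "down": {}, "up": {}}
    t = {(a, d): int(((sig["arm"] == a) & (sig["direction"] == d)).sum())
         for a in ("5p", "3p") for d in ("down", "up")}
    table = ((t[("5p", "down")], t[("5p", "up")]),
             (t[("3p", "down")], t[("3p", "up")]))
    _, p = sps.fisher_exact(np.array(table))

    def _prop(d):
        tot = t[("5p", d)] + t[("3p", d)]
        return {"n_5p": t[("5p", d)], "n_3p": t[("3p", d)],
                "prop_5p": t[("5p", d)] / tot if tot else np.nan,
                "prop_3p": t[("3p", d)] / tot if tot else np.nan}

    return {"n_significant": int(len(sig)), "table": table, "p": float(p),
            "down": _prop("down"), "up": _prop("up")}


def highconf_subset(results: pd.DataFrame,
                    flags: pd.Series) -> pd.DataFrame:
    """Restrict differential results to high-confidence miRNAs."""
    keep = set(flags[flags.astype(bool)].index)
    return results[results["mirna"].isin(keep)].copy()
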