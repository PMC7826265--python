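"""Clinical association of mutation groups.

Overall survival (Kaplan-Meier curves, log-rank test, and a univariate Cox
fit on the group indicator for the direction of the effect), mutation
occurrence across tumor stages stratified by cancer type (Cochran-Mantel-
Haenszel, with per-cancer Fisher tests alongside), and co-occurrence with
thresholded gene-level copy-number calls.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats as sps
from statsmodels.stats.contingency_tables import StratifiedTable

from .types import ValidationError

EARLY_STAGES = ("I", "II")
LATE_STAGES = ("III", "IV")
DELETION_THRESHOLD = -1  # thresholded call <= -1 counts as deletion
AMPLIFICATION_THRESHOLD = 1


@dataclass
class SurvivalResult:
    label: str
    n_mutated: int
    n_reference: int
    logrank_statistic: Optional[float]
    p: Optional[float]
    hazard_ratio: Optional[float]
    hr_ci: tuple[Optional[float], Optional[float]]
    curves: dict[str, pd.DataFrame] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "n_mutated": self.n_mutated,
            "n_reference": self.n_reference,
            "logrank_statistic": self.logrank_statistic,
            "p": self.p,
            "hazard_ratio": self.hazard_ratio,
            "hr_ci": list(self.hr_ci),
            "curves": {k: v.to_dict(orient="list")
                       for k, v in self.curves.items()},
        }


def km_logrank(samples: pd.DataFrame, mutated: Iterable[str],
               reference: Iterable[str], label: str = "") -> SurvivalResult:
    """Two-group survival comparison.

    ``samples`` must carry ``sample_id, os_time, os_event``. Kaplan-Meier
    product-limit estimates are computed per group, the groups are compared
    with the log-rank test, and a univariate Cox model on the group
    indicator gives the hazard ratio (mutated vs reference, Breslow ties).
    """
    df = samples.set_index("sample_id")
    mutated = [s for s in mutated if s in df.index]
    reference = [s for s in reference if s in df.index]
    if not mutated or not reference:
        raise ValidationError("both survival groups must be non-empty")
    mut = df.loc[mutated]
    ref = df.loc[reference]

    curves = {}
    for name, grp in (("mutated", mut), ("reference", ref)):
        km = KaplanMeierFitter()
        km.fit(grp["os_time"], grp["os_event"], label=name)
        sf = km.survival_function_.reset_index()
        sf.columns = ["time", "survival"]
        curves[name] = sf

    if mut["os_event"].sum() + ref["os_event"].sum() == 0:
        warnings.warn(f"{label}: no events in either group; no test performed")
        return SurvivalResult(label, len(mut), len(ref), None, None, None,
                              (None, None), curves)

    lr = logrank_test(mut["os_time"], ref["os_time"],
                      event_observed_A=mut["os_event"],
                      event_observed_B=ref["os_event"])
    cox_df = pd.concat([
        mut[["os_time", "os_event"]].assign(group=1),
        ref[["os_time", "os_event"]].assign(group=0),
    ])
    hr = ci_lo = ci_hi = None
    try:
        cph = CoxPHFitter()
        cph.fit(cox_df, duration_col="os_time", event_col="os_event")
        hr = float(np.exp(cph.params_["group"]))
        ci = cph.confidence_intervals_
        with np.errstate(over="ignore"):
            ci_lo = float(np.exp(ci.iloc[0, 0]))
            ci_hi = float(np.exp(ci.iloc[0, 1]))
    except Exception as exc:  # degenerate fits (e.g. identical groups)
        warnings.warn(f"{label}: Cox fit failed ({exc})")
        if (mut[["os_time", "os_event"]].reset_index(drop=True)
                .equals(ref[["os_time", "os_event"]].reset_index(drop=True))):
            hr = 1.0
    return SurvivalResult(label, len(mut), len(ref),
                          float(lr.test_statistic), float(lr.p_value),
                          hr, (ci_lo, ci_hi), curves)


@dataclass
class StratifiedStageResult:
    n_strata: int
    statistic: float
    p: float
    tables: dict[str, tuple]  # cancer -> 2x2 (mutation presence x stage)
    per_stratum_fisher: dict[str, float]


def stage_dichotomy(stage: pd.Series,
                    early: Iterable[str] = EARLY_STAGES) -> pd.Series:
    """Early (I-II) vs late (III-IV) indicator; sub-stage suffixes (IIIa)
    are reduced to their base numeral."""
    base = stage.astype(str).str.upper().str.extract(r"^(IV|III|II|I)")[0]
    return base.isin([s.upper() for s in early])


def cmh_stage_test(samples: pd.DataFrame, mutated: Iterable[str],
                   early: Iterable[str] = EARLY_STAGES,
                   strata_col: str = "cancer_type") -> StratifiedStageResult:
    """Cochran-Mantel-Haenszel test of mutation presence vs stage dichotomy
    across cancer-type strata (no continuity correction); per-stratum
    Fisher exact tests are returned alongside."""
    df = samples.dropna(subset=["stage"]).copy()
    df["mutated"] = df["sample_id"].isin(set(mutated))
    df["early"] = stage_dichotomy(df["stage"], early)
    tables, fisher_p = {}, {}
    arrays = []
    for stratum, grp in df.groupby(strata_col):
        a = int((grp["mutated"] & grp["early"]).sum())
        b = int((grp["mutated"] & ~grp["early"]).sum())
        c = int((~grp["mutated"] & grp["early"]).sum())
        d = int((~grp["mutated"] & ~grp["early"]).sum())
        tables[stratum] = ((a, b), (c, d))
        if min(a + b, c + d) > 0 and min(a + c, b + d) > 0:
            arrays.append(np.array([[a, b], [c, d]]))
            _, p = sps.fisher_exact([[a, b], [c, d]])
            fisher_p[stratum] = float(p)
    if not arrays:
        raise ValidationError("all strata are degenerate; CMH undefined")
    st = StratifiedTable(arrays)
    res = st.test_null_odds(correction=False)
    return StratifiedStageResult(len(arrays), float(res.statistic),
                                 float(res.pvalue), tables, fisher_p)


def cnv_cooccurrence(samples: pd.DataFrame, cnv: pd.DataFrame,
                     muts: pd.DataFrame, gene: str,
                     hotspot_residues: Optional[Iterable[int]] = None
                     ) -> tuple[pd.DataFrame, float]:
    """Deletion/amplification proportions by mutation class of one gene.

    Samples are partitioned by their mutations in ``gene`` into
    none / hotspot / deleterious / other (priority in that order when a
    sample carries several); deletions are thresholded calls <= -1 and
    amplifications >= +1. Returns the per-class table and the Fisher p for
    deletion x mutation-presence.
    """
    if gene not in cnv.columns:
        raise ValidationError(f"no copy-number calls for {gene!r}")
    calls = cnv.set_index("sample_id")[gene]
    covered = calls.dropna()
    if len(covered) < 0.5 * len(samples):
        warnings.warn(f"copy-number calls missing for >50% of samples ({gene})")

    residues = set(int(r) for r in hotspot_residues or [])
    in_gene = muts[muts["gene"] == gene]
    hot = set(in_gene.loc[(in_gene["consequence"] == "missense")
                          & in_gene["aa_pos"].isin(residues), "sample_id"])
    from .stats import DELETERIOUS
    dele = set(in_gene.loc[in_gene["consequence"].isin(DELETERIOUS),
                           "sample_id"])
    anym = set(in_gene["sample_id"])

    def _class(sid):
        if sid in hot:
            return "hotspot"
        if sid in dele:
            return "deleterious"
        if sid in anym:
            return "other"
        return "none"

    rows = []
    df = samples[samples["sample_id"].isin(covered.index)].copy()
    df["mclass"] = df["sample_id"].map(_class)
    df["call"] = df["sample_id"].map(calls)
    for mclass in ("none", "hotspot", "deleterious", "other"):
        grp = df[df["mclass"] == mclass]
        if grp.empty:
            continue
        n_del = int((grp["call"] <= DELETION_THRESHOLD).sum())
        n_amp = int((grp["call"] >= AMPLIFICATION_THRESHOLD).sum())
        rows.append({"mutation_class": mclass, "n": len(grp),
                     "n_deleted": n_del, "n_amplified": n_amp,
                     "deletion_prop": n_del / len(grp),
                     "amplification_prop": n_amp / len(grp)})
    table = pd.DataFrame(rows)
    mutated_mask = df["mclass"] != "none"
    a = int((mutated_mask & (df["call"] <= DELETION_THRESHOLD)).sum())
    b = int((mutated_mask & (df["call"] > DELETION_THRESHOLD)).sum())
    c = int((~mutated_mask & (df["call"] <= DELETION_THRESHOLD)).sum())
    d = int((~mutated_mask & (df["call"] > DELETION_THRESHOLD)).sum())
    if a + c == 0:
        p = 1.0
    else:
        _, p = sps.fisher_exact([[a, b], [c, d]])
    return table, float(p)
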