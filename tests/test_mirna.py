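"""Expression filtering, normalizations, groups, and differential tests."""
import numpy as np
import pandas as pd
import pytest

from mutatlas import mirna
from mutatlas.mirna import ExpressionMatrix
from mutatlas.types import ValidationError


def _matrix(values, samples=None, mirnas=None, dialect="batch_normalized"):
    values = np.asarray(values, float)
    mirnas = mirnas or [f"m{i}-5p" for i in range(values.shape[0])]
    samples = samples or [f"S{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=mirnas,
                                         columns=samples), dialect)


# ---------------------------------------------------------------------------
# detectability filter
# ---------------------------------------------------------------------------

def test_filter_expressed_thresholds():
    n = 100
    vals = np.ones((3, n))
    vals[0, :31] = 0.0  # 31% zeros: dropped pan-cancer
    vals[1, :30] = 0.0  # 30%: kept pan-cancer, dropped single-cancer
    m = _matrix(vals)
    assert list(mirna.filter_expressed(m, "pan_cancer").mirnas) == ["m1-5p", "m2-5p"]
    assert list(mirna.filter_expressed(m, "single_cancer").mirnas) == ["m2-5p"]


def test_filter_expressed_random_matches_fraction_oracle():
    rng = np.random.default_rng(2)
    vals = rng.normal(size=(50, 40))
    vals[rng.random(vals.shape) < 0.25] = 0.0
    m = _matrix(vals)
    kept = set(mirna.filter_expressed(m, "pan_cancer").mirnas)
    for i, name in enumerate(m.mirnas):
        frac = (vals[i] == 0).mean()
        assert (name in kept) == (frac <= 0.30)


def test_filter_expressed_negative_values_are_detected_signal():
    m = _matrix([[-1.0] * 10])  # negative but nonzero: never dropped
    assert len(mirna.filter_expressed(m, "single_cancer").mirnas) == 1


# ---------------------------------------------------------------------------
# per-cancer normalization
# ---------------------------------------------------------------------------

def test_pan_cancer_normalize_hand_example():
    m = _matrix([[1.0, 2.0, 3.0, 10.0]])
    labels = pd.Series(["C"] * 4, index=m.samples)
    out = mirna.pan_cancer_normalize(m, labels).values.iloc[0].tolist()
    # median 2.5, max |x - med| = 7.5
    assert out == pytest.approx([-0.2, -1 / 15, 1 / 15, 1.0])


def test_pan_cancer_normalize_constant_mirna_maps_to_zero():
    m = _matrix([[5.0] * 6])
    labels = pd.Series(["C"] * 6, index=m.samples)
    out = mirna.pan_cancer_normalize(m, labels)
    assert (out.values.to_numpy() == 0).all()


def test_pan_cancer_normalize_postconditions_and_idempotence():
    rng = np.random.default_rng(4)
    m = _matrix(rng.normal(2, 5, size=(30, 60)))
    labels = pd.Series(rng.choice(["A", "B", "C"], 60), index=m.samples)
    out = mirna.pan_cancer_normalize(m, labels)
    for cancer in "ABC":
        block = out.values.loc[:, (labels == cancer).to_numpy()]
        assert np.allclose(block.median(axis=1), 0.0, atol=1e-12)
    assert (out.values.abs().to_numpy() <= 1 + 1e-12).all()
    again = mirna.pan_cancer_normalize(out, labels)
    assert np.allclose(again.values.to_numpy(), out.values.to_numpy(),
                       atol=1e-12)


def test_pan_cancer_normalize_single_sample_cancer_errors():
    m = _matrix([[1.0, 2.0, 3.0]])
    labels = pd.Series(["A", "A", "B"], index=m.samples)
    with pytest.raises(ValidationError, match="single sample"):
        mirna.pan_cancer_normalize(m, labels)


# ---------------------------------------------------------------------------
# reference normalization
# ---------------------------------------------------------------------------

def _rpm_matrix():
    rng = np.random.default_rng(5)
    vals = rng.lognormal(5, 1, size=(10, 8))
    names = [f"m{i}-3p" for i in range(9)] + ["hsa-miR-451a"]
    return _matrix(vals, mirnas=names, dialect="rpm")


def test_reference_row_becomes_zero():
    out = mirna.reference_normalize(_rpm_matrix())
    assert np.allclose(out.values.loc["hsa-miR-451a"], 0.0)


def test_reference_normalize_scale_invariance():
    m = _rpm_matrix()
    scaled = m.values.copy()
    scaled["S3"] = scaled["S3"] * 8  # per-sample library-size artifact
    out_a = mirna.reference_normalize(m, pseudocount=0.0)
    out_b = mirna.reference_normalize(
        ExpressionMatrix(scaled, "rpm", m.arm, m.high_confidence),
        pseudocount=0.0)
    assert np.allclose(out_a.values.to_numpy(), out_b.values.to_numpy(),
                       atol=1e-12)


def test_reference_normalize_hand_value():
    vals = pd.DataFrame({"S0": [100.0, 25.0]}, index=["m1-5p", "hsa-miR-451a"])
    out = mirna.reference_normalize(ExpressionMatrix(vals, "rpm"),
                                    pseudocount=1.0)
    assert out.values.loc["m1-5p", "S0"] == pytest.approx(np.log2(101 / 26))
    assert out.dialect == "log2_ratio"


def test_reference_normalize_errors_and_warnings():
    m = _rpm_matrix()
    with pytest.raises(ValidationError, match="absent"):
        mirna.reference_normalize(m, "no-such-mirna")
    vals = m.values.copy()
    vals.loc["hsa-miR-451a", :] = 0.0
    with pytest.warns(UserWarning, match="zero"):
        mirna.reference_normalize(
            ExpressionMatrix(vals, "rpm", m.arm, m.high_confidence))


# ---------------------------------------------------------------------------
# group definition
# ---------------------------------------------------------------------------

def _mut_table():
    rows = [
        ("S1", "SMAD4", "missense", 361),    # hotspot carrier
        ("S1", "SMAD4", "synonymous", 100),  # also a synonymous mutation
        ("S2", "SMAD4", "synonymous", 120),  # synonymous-only
        ("S3", "SMAD4", "frameshift", 50),
        ("S4", "TNRC6A", "missense", 10),    # other gene only
    ]
    df = pd.DataFrame(rows, columns=["sample_id", "gene", "consequence",
                                     "aa_pos"])
    df["aa_pos"] = df["aa_pos"].astype("Int64")
    return df


def _sample_table():
    return pd.DataFrame({"sample_id": [f"S{i}" for i in range(1, 6)],
                         "cancer_type": "PAAD"})


def test_define_groups_hotspot_membership():
    mutated, reference = mirna.define_groups(
        _sample_table(), _mut_table(), "SMAD4", "hotspot",
        hotspot_residues=[361])
    assert mutated == {"S1"}
    # S2 (synonymous-only) and S3 (frameshift) carry SMAD4 mutations:
    # excluded from the reference; S4/S5 are mutation-free in SMAD4
    assert reference == {"S4", "S5"}


def test_define_groups_deleterious_and_empty():
    mutated, reference = mirna.define_groups(
        _sample_table(), _mut_table(), "SMAD4", "deleterious")
    assert mutated == {"S3"} and reference == {"S4", "S5"}
    with pytest.raises(ValidationError, match="nonsense"):
        mirna.define_groups(_sample_table(), _mut_table(), "SMAD4", "nonsense")


def test_define_groups_match_ground_truth(cohort, cohort_tables):
    truth = cohort["truth"]
    muts, samples = cohort_tables["mutations"], cohort_tables["samples"]
    expected = set(truth.groups["DICER1|hotspot"])
    mutated, reference = mirna.define_groups(samples, muts, "DICER1",
                                             "hotspot",
                                             hotspot_residues=[1709])
    assert mutated == expected
    assert reference == set(samples["sample_id"]) - set(
        truth.groups.get("DICER1|any", []))


# ---------------------------------------------------------------------------
# differential test
# ---------------------------------------------------------------------------

def test_diff_test_exact_rank_sum_enumeration():
    vals = pd.DataFrame([[1.0, 2.0, 3.0, 4.0, 5.0, 6.0]], index=["m-5p"],
                        columns=[f"S{i}" for i in range(6)])
    m = ExpressionMatrix(vals)
    res = mirna.diff_test(m, ["S0", "S1", "S2"], ["S3", "S4", "S5"])
    # fully separated groups of 3: exact two-sided p = 2/C(6,3) = 0.1
    assert res["p"].iloc[0] == pytest.approx(0.1)
    assert res["direction"].iloc[0] == "down"
    assert res["effect"].iloc[0] == pytest.approx(2.0 - 5.0)


def test_diff_test_constant_mirna():
    vals = pd.DataFrame([[3.0] * 8], index=["m-5p"],
                        columns=[f"S{i}" for i in range(8)])
    res = mirna.diff_test(ExpressionMatrix(vals), ["S0", "S1", "S2"],
                          ["S3", "S4", "S5"])
    assert res["p"].iloc[0] == 1.0 and res["effect"].iloc[0] == 0.0


def test_diff_test_rpm_effect_is_log2_fold_change():
    vals = pd.DataFrame([[8.0, 8.0, 2.0, 2.0]], index=["m-3p"],
                        columns=list("ABCD"))
    res = mirna.diff_test(ExpressionMatrix(vals, "rpm"), ["A", "B"],
                          ["C", "D"], pseudocount=0.0)
    assert res["effect"].iloc[0] == pytest.approx(2.0)  # log2(8/2)
    assert res["direction"].iloc[0] == "up"


def test_diff_test_requires_nonempty_groups():
    vals = pd.DataFrame([[1.0, 2.0]], index=["m"], columns=["A", "B"])
    with pytest.raises(ValidationError):
        mirna.diff_test(ExpressionMatrix(vals), [], ["A"])


def test_diff_test_detects_planted_shift():
    rng = np.random.default_rng(6)
    n = 200
    base = rng.normal(0, 1, size=(1, 2 * n))
    base[0, :n] -= 0.5
    vals = pd.DataFrame(base, index=["m-5p"],
                        columns=[f"S{j}" for j in range(2 * n)])
    res = mirna.diff_test(ExpressionMatrix(vals),
                          [f"S{j}" for j in range(n)],
                          [f"S{j}" for j in range(n, 2 * n)])
    assert res["p"].iloc[0] < 0.05
    assert res["direction"].iloc[0] == "down"


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def _results(n5_down, n5_up, n3_down, n3_up, p=0.01):
    rows = []
    for arm, direction, k in (("5p", "down", n5_down), ("5p", "up", n5_up),
                              ("3p", "down", n3_down), ("3p", "up", n3_up)):
        eff = -1.0 if direction == "down" else 1.0
        rows += [{"mirna": f"m{len(rows) + i}-{arm}", "arm": arm,
                  "effect": eff, "p": p, "direction": direction}
                 for i in range(k)]
    return pd.DataFrame(rows, columns=["mirna", "arm", "effect", "p",
                                       "direction"])


def test_arm_asymmetry_extreme_table():
    res = _results(20, 0, 0, 20)
    out = mirna.arm_asymmetry(res)
    assert out["down"]["prop_5p"] == 1.0 and out["up"]["prop_3p"] == 1.0
    from scipy.stats import fisher_exact
    _, p = fisher_exact([[20, 0], [0, 20]])
    assert out["p"] == pytest.approx(p)


def test_arm_asymmetry_ignores_unspecified_and_nonsignificant():
    res = _results(5, 5, 5, 5)
    res.loc[0, "arm"] = "unspecified"
    res.loc[1, "p"] = 0.5
    out = mirna.arm_asymmetry(res)
    assert out["n_significant"] == 18


def test_arm_asymmetry_empty_warns():
    with pytest.warns(UserWarning):
        out = mirna.arm_asymmetry(_results(0, 0, 0, 0))
    assert out["n_significant"] == 0 and out["p"] is None


def test_direction_summary_percentages():
    out = mirna.direction_summary(_results(49, 14, 0, 0))
    assert (out["n_down"], out["n_up"]) == (49, 14)
    assert (out["down_pct"], out["up_pct"]) == (78, 22)


def test_highconf_subset_masks():
    res = _results(3, 0, 0, 3)
    flags = pd.Series(False, index=res["mirna"])
    flags.iloc[:2] = True
    assert len(mirna.highconf_subset(res, flags)) == 2
    assert len(mirna.highconf_subset(res, ~flags)) == 4
    assert mirna.highconf_subset(res, flags & False).empty


def test_arm_from_id():
    assert mirna.arm_from_id("hsa-miR-21-5p") == "5p"
    assert mirna.arm_from_id("hsa-miR-21-3p") == "3p"
    assert mirna.arm_from_id("hsa-miR-451a") == "unspecified"
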