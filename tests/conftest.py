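import pandas as pd
import pytest

from mutatlas import consensus, stats, synthetic
from mutatlas.types import load_transcripts


@pytest.fixture(scope="session")
def cohort_config():
    return synthetic.CohortConfig(
        seed=11,
        n_samples_per_cancer=12,
        cancer_types=("PAAD", "COAD", "UCEC"),
        hotspot_spec=(
            synthetic.HotspotSpec("SMAD4", 361, 8, ("PAAD", "COAD")),
            synthetic.HotspotSpec("DICER1", 1709, 5, ("UCEC",)),
        ),
        deleterious_rate=0.06,
        background_snv_rate=0.4,
        noise_call_rate=0.8,
        hypermutated_fraction=0.05,
    )


@pytest.fixture(scope="session")
def cohort(cohort_config, tmp_path_factory):
    """One generated bundle shared across the suite."""
    out = tmp_path_factory.mktemp("cohort")
    bundle, truth = synthetic.generate_cohort(cohort_config, out)
    return {"bundle": bundle, "truth": truth, "config": cohort_config}


@pytest.fixture(scope="session")
def cohort_tables(cohort):
    """Consensus mutation table and flagged sample table from the bundle."""
    bundle = cohort["bundle"]
    clinical = pd.read_csv(bundle["clinical"], sep="\t")
    models = load_transcripts(bundle["transcripts"])
    muts = consensus.run_consensus(bundle["calls_dir"], bundle["regions"],
                                   clinical, models)
    muts_df = consensus.mutations_to_frame(muts)
    samples = stats.flag_hypermutated(clinical)
    return {"mutations": muts_df, "samples": samples, "objects": muts}


@pytest.fixture(scope="session")
def truth_frame(cohort):
    """Planted mutations as a DataFrame in the consensus table layout."""
    rows = []
    for m in cohort["truth"].mutations:
        rows.append({
            "sample_id": m["sample_id"],
            "cancer_type": m["sample_id"].rsplit("-", 1)[0],
            "gene": m["gene"], "chrom": m["chrom"], "pos": m["pos"],
            "ref": m["ref"], "alt": m["alt"],
            "consequence": m["consequence"], "aa_pos": m["aa_pos"],
            "mclass": m["mclass"],
        })
    df = pd.DataFrame(rows)
    df["aa_pos"] = df["aa_pos"].astype("Int64")
    return df
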