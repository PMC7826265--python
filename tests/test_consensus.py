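"""Consensus stage: dialect parsing, reliability filters, merging,
region restriction, and consequence classification."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mutatlas import consensus, dialects
from mutatlas.types import (
    Caller,
    CallerVariant,
    Consequence,
    ConsensusMutation,
    GeneRegion,
    ParseError,
    TranscriptModel,
    ValidationError,
    normalize_variant,
)


def _variant(caller=Caller.MUSE, **kw):
    base = dict(caller=caller, sample_id="S1", chrom="chr1", pos=100,
                ref="A", alt="G", filter_status="PASS", t_alt_reads=10,
                n_alt_reads=0, t_alt_freq=0.2, n_alt_freq=0.0,
                t_depth=50, n_depth=40)
    if caller in {Caller.VARSCAN2, Caller.SOMATICSNIPER}:
        base["ssc"] = 60.0
    else:
        base["bq"] = 35.0
    base.update(kw)
    return CallerVariant(**base)


# ---------------------------------------------------------------------------
# file parsing
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("caller", list(Caller))
def test_read_caller_file_keeps_only_pass(tmp_path, caller):
    recs = [_variant(caller, pos=100 + i) for i in range(3)]
    recs += [_variant(caller, pos=300 + i, filter_status="REJECT")
             for i in range(2)]
    path = tmp_path / f"S1.{caller.value}.vcf"
    dialects.write_vcf(path, caller, recs, ["chr1"])
    out = consensus.read_caller_file(path, caller)
    assert len(out) == 3
    assert all(r.filter_status == "PASS" for r in out)


def test_read_caller_file_round_trips_fields(tmp_path):
    for caller in Caller:
        rec = _variant(caller, pos=123, t_alt_reads=13, t_depth=65,
                       n_alt_reads=2, n_depth=50, n_alt_freq=2 / 50,
                       t_alt_freq=13 / 65)
        path = tmp_path / f"S1.{caller.value}.vcf"
        dialects.write_vcf(path, caller, [rec], ["chr1"])
        (out,) = consensus.read_caller_file(path, caller)
        assert (out.pos, out.ref, out.alt) == (123, "A", "G")
        assert (out.t_alt_reads, out.n_alt_reads) == (13, 2)
        assert out.t_alt_freq == pytest.approx(13 / 65)
        assert out.n_alt_freq == pytest.approx(2 / 50)
        if caller in {Caller.VARSCAN2, Caller.SOMATICSNIPER}:
            assert out.ssc == 60.0 and out.bq is None
        else:
            assert out.bq == 35.0 and out.ssc is None


def test_read_caller_file_empty_with_header(tmp_path):
    path = tmp_path / "S1.MuSE.vcf"
    dialects.write_vcf(path, Caller.MUSE, [], ["chr1"])
    assert consensus.read_caller_file(path, Caller.MUSE) == []


def test_read_caller_file_unknown_dialect(tmp_path):
    path = tmp_path / "S1.MuSE.vcf"
    dialects.write_vcf(path, Caller.MUSE, [], ["chr1"])
    with pytest.raises(Exception, match="dialect"):
        consensus.read_caller_file(path, "Strelka")


# ---------------------------------------------------------------------------
# reliability filters
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("kw,kept", [
    # tumor alt-read support when the normal is clean
    (dict(t_alt_reads=1, n_alt_reads=0), False),
    (dict(t_alt_reads=2, n_alt_reads=0), True),
    # 5x frequency ratio (inclusive boundary), only when normal freq > 0
    (dict(t_alt_freq=0.20, n_alt_freq=0.05, n_alt_reads=2), False),
    (dict(t_alt_freq=0.25, n_alt_freq=0.05, n_alt_reads=2), True),
    (dict(t_alt_freq=0.249, n_alt_freq=0.05, n_alt_reads=2), False),
])
def test_filter_read_support_criteria(kw, kept):
    calls = [_variant(**kw)]
    assert (len(consensus.apply_reliability_filters(calls)) == 1) is kept


@pytest.mark.parametrize("caller,field,value,kept", [
    (Caller.VARSCAN2, "ssc", 29.0, False),
    (Caller.VARSCAN2, "ssc", 30.0, False),   # strict >30
    (Caller.SOMATICSNIPER, "ssc", 31.0, True),
    (Caller.MUSE, "bq", 19.0, False),
    (Caller.MUTECT2, "bq", 20.0, False),     # strict >20
    (Caller.MUSE, "bq", 21.0, True),
])
def test_filter_quality_criteria(caller, field, value, kept):
    calls = [_variant(caller, **{field: value})]
    assert (len(consensus.apply_reliability_filters(calls)) == 1) is kept


def _oracle_predicate(c: CallerVariant) -> bool:
    """Independent restatement of the filter conjunction."""
    ok = True
    if c.n_alt_reads == 0:
        ok &= c.t_alt_reads >= 2
    if c.n_alt_freq > 0:
        ok &= c.t_alt_freq >= 5 * c.n_alt_freq
    if c.ssc is not None:
        ok &= c.ssc > 30
    if c.bq is not None:
        ok &= c.bq > 20
    return ok


@settings(max_examples=300, deadline=None, derandomize=True)
@given(
    t_alt=st.integers(0, 5), n_alt=st.integers(0, 3),
    t_freq=st.sampled_from([0.0, 0.01, 0.1, 0.24, 0.25, 0.26, 0.5, 1.0]),
    n_freq=st.sampled_from([0.0, 0.01, 0.05, 0.1, 0.2]),
    ssc=st.sampled_from([None, 0.0, 29.0, 30.0, 30.5, 100.0]),
    bq=st.sampled_from([None, 0.0, 19.0, 20.0, 20.5, 40.0]),
)
def test_filter_matches_bruteforce_predicate(t_alt, n_alt, t_freq, n_freq,
                                             ssc, bq):
    caller = Caller.VARSCAN2 if ssc is not None else Caller.MUSE
    if ssc is not None and bq is not None:
        bq = None  # no caller reports both
    c = _variant(caller, t_alt_reads=t_alt, n_alt_reads=n_alt,
                 t_alt_freq=t_freq, n_alt_freq=n_freq, ssc=ssc, bq=bq)
    assert consensus.passes_reliability_filters(c) == _oracle_predicate(c)


# ---------------------------------------------------------------------------
# merging
# ---------------------------------------------------------------------------

CLIN = pd.DataFrame({"sample_id": ["S1", "S2"], "cancer_type": ["PAAD", "COAD"]})


def test_merge_deduplicates_across_callers():
    per = {Caller.MUTECT2: [_variant(Caller.MUTECT2)],
           Caller.VARSCAN2: [_variant(Caller.VARSCAN2)]}
    (m,) = consensus.merge_callers(per, CLIN)
    assert m.callers == {Caller.MUTECT2, Caller.VARSCAN2}
    assert m.cancer_type == "PAAD"


def test_merge_single_caller_preserves_count():
    calls = [_variant(pos=100 + i) for i in range(5)]
    out = consensus.merge_callers({Caller.MUSE: calls}, CLIN)
    assert len(out) == 5


def test_merge_indel_representations_collapse():
    # identical deletion written with and without a shared trailing base
    a = _variant(Caller.MUSE, pos=100, ref="ATT", alt="AT")
    b = _variant(Caller.VARSCAN2, pos=100, ref="AT", alt="A")
    out = consensus.merge_callers({Caller.MUSE: [a], Caller.VARSCAN2: [b]}, CLIN)
    assert len(out) == 1
    assert out[0].callers == {Caller.MUSE, Caller.VARSCAN2}


def test_merge_unknown_sample_raises():
    with pytest.raises(ValidationError, match="S9"):
        consensus.merge_callers(
            {Caller.MUSE: [_variant(sample_id="S9")]}, CLIN)


def test_merge_count_equals_distinct_keys_randomized():
    rng = np.random.default_rng(5)
    calls_by_caller = {c: [] for c in Caller}
    keys = set()
    for _ in range(400):
        caller = list(Caller)[rng.integers(0, 4)]
        pos = int(rng.integers(100, 140))
        sid = ["S1", "S2"][rng.integers(0, 2)]
        calls_by_caller[caller].append(
            _variant(caller, sample_id=sid, pos=pos))
        keys.add((sid, "chr1", pos, "A", "G"))
    out = consensus.merge_callers(calls_by_caller, CLIN)
    assert len(out) == len(keys)


def test_merge_idempotent_and_monotone():
    rng = np.random.default_rng(6)
    per = {c: [_variant(c, pos=int(rng.integers(100, 130)))
               for _ in range(30)] for c in Caller}
    out1 = consensus.merge_callers(per, CLIN)
    # re-split the merge output by caller and merge again
    resplit = {c: [] for c in Caller}
    for m in out1:
        for c in m.callers:
            resplit[c].append(_variant(c, sample_id=m.sample_id, pos=m.pos,
                                       ref=m.ref, alt=m.alt))
    out2 = consensus.merge_callers(resplit, CLIN)
    assert {m.key() for m in out2} == {m.key() for m in out1}
    assert {m.key(): m.callers for m in out2} == {m.key(): m.callers
                                                  for m in out1}
    # adding calls never decreases the consensus count
    per2 = {c: list(v) for c, v in per.items()}
    per2[Caller.MUSE] = per2[Caller.MUSE] + [_variant(pos=500)]
    out3 = consensus.merge_callers(per2, CLIN)
    assert len(out3) >= len(out1)
    assert {m.key() for m in out1} <= {m.key() for m in out3}


# ---------------------------------------------------------------------------
# region restriction
# ---------------------------------------------------------------------------

def _mut(pos, chrom="chr1", sample="S1"):
    return ConsensusMutation(sample_id=sample, chrom=chrom, pos=pos,
                             ref="A", alt="G", callers={Caller.MUSE})


def test_restrict_region_boundaries():
    # exon at 0-based [100, 200); extended region [98, 202)
    region = GeneRegion("G1", [("chr1", 98, 202)])
    # VCF pos 202 -> 0-based 201, second intronic nt past the exon: inside
    kept = consensus.restrict_to_regions([_mut(202)], [region])
    assert len(kept) == 1 and kept[0].gene == "G1"
    # one bp further: outside
    assert consensus.restrict_to_regions([_mut(203)], [region]) == []
    # first base of the extension
    assert len(consensus.restrict_to_regions([_mut(99)], [region])) == 1
    assert consensus.restrict_to_regions([_mut(98)], [region]) == []


def test_restrict_matches_linear_scan_oracle():
    rng = np.random.default_rng(7)
    regions = [GeneRegion("G1", [("chr1", 100, 150), ("chr1", 300, 360)]),
               GeneRegion("G2", [("chr1", 500, 520)]),
               GeneRegion("G3", [("chr2", 100, 200)])]
    muts = [_mut(int(rng.integers(1, 700)),
                 chrom=["chr1", "chr2"][rng.integers(0, 2)])
            for _ in range(500)]

    def scan(m):
        for r in regions:
            for c, s, e in r.intervals:
                if c == m.chrom and s <= m.pos - 1 < e:
                    return r.gene
        return None

    expected = [(m.pos, m.chrom, scan(m)) for m in muts if scan(m)]
    got = consensus.restrict_to_regions(muts, regions)
    assert [(m.pos, m.chrom, m.gene) for m in got] == expected


def test_overlapping_regions_rejected():
    regions = [GeneRegion("G1", [("chr1", 100, 200)]),
               GeneRegion("G2", [("chr1", 150, 250)])]
    with pytest.raises(ValidationError, match="overlap"):
        consensus.restrict_to_regions([], regions)


# ---------------------------------------------------------------------------
# consequence classification
# ---------------------------------------------------------------------------

@pytest.fixture
def toy_transcript():
    # CDS: ATG CGA AAA TTT GGC TAA split over two exons of 9 nt
    #       M   R   K   F   G   *
    return TranscriptModel("G1", "chr1", "+", [(100, 109), (200, 209)],
                           "ATGCGAAAATTTGGCTAA")


def _gmut(pos, ref, alt, gene="G1"):
    m = _mut(pos)
    m.gene = gene
    m.ref, m.alt = ref, alt
    return m


def test_classify_stop_gain(toy_transcript):
    # CGA -> TGA at codon 2: CDS idx 3 is genomic 103 (1-based 104)
    cons, change = consensus.classify_consequence(
        _gmut(104, "C", "T"), toy_transcript)
    assert cons is Consequence.NONSENSE
    assert change == (2, "R", "*")


def test_classify_missense_and_synonymous(toy_transcript):
    # AAA -> AGA (K3R), CDS idx 7 = genomic 107 -> 1-based 108
    cons, change = consensus.classify_consequence(
        _gmut(108, "A", "G"), toy_transcript)
    assert cons is Consequence.MISSENSE and change == (3, "K", "R")
    # AAA -> AAG (K3=), CDS idx 8 = genomic 108 -> 1-based 109
    cons, change = consensus.classify_consequence(
        _gmut(109, "A", "G"), toy_transcript)
    assert cons is Consequence.SYNONYMOUS and change == (3, "K", "K")


def test_classify_frameshift_and_inframe(toy_transcript):
    cons, change = consensus.classify_consequence(
        _gmut(104, "C", "CT"), toy_transcript)
    assert cons is Consequence.FRAMESHIFT and change[2] == "fs"
    cons, _ = consensus.classify_consequence(
        _gmut(103, "GCGA", "G"), toy_transcript)
    assert cons is Consequence.INFRAME_INDEL


def test_classify_splice_site(toy_transcript):
    # first exon ends at 0-based 109 -> first intronic base pos0=109 (VCF 110)
    for vcf_pos in (110, 111, 199, 200):
        cons, _ = consensus.classify_consequence(
            _gmut(vcf_pos, "A", "G"), toy_transcript)
        assert cons is Consequence.SPLICE_SITE, vcf_pos
    # third intronic base: not a splice window; inside no exon -> other
    cons, _ = consensus.classify_consequence(_gmut(112, "A", "G"),
                                             toy_transcript)
    assert cons is Consequence.OTHER


def test_classify_start_codon_hit(toy_transcript):
    cons, _ = consensus.classify_consequence(_gmut(101, "A", "G"),
                                             toy_transcript)
    assert cons is Consequence.START_STOP


def test_classify_minus_strand():
    # same CDS on the minus strand: genomic bases are the reverse complement
    cds = "ATGCGAAAATTTGGCTAA"
    model = TranscriptModel("G2", "chr1", "-", [(100, 118)], cds)
    # CDS idx 3 ('C' of CGA) -> genomic pos0 = 118-1-3 = 114, base G
    assert model.ref_base(114) == "G"
    m = _gmut(115, "G", "A", gene="G2")  # G>A genomic = C>T coding
    cons, change = consensus.classify_consequence(m, model)
    assert cons is Consequence.NONSENSE and change == (2, "R", "*")


def test_classify_ref_mismatch_raises(toy_transcript):
    with pytest.raises(ValidationError, match="REF"):
        consensus.classify_consequence(_gmut(104, "G", "T"), toy_transcript)


def test_classify_requires_matching_gene(toy_transcript):
    with pytest.raises(ValidationError):
        consensus.classify_consequence(_gmut(104, "C", "T", gene="OTHER"),
                                       toy_transcript)


# ---------------------------------------------------------------------------
# synthetic round trip
# ---------------------------------------------------------------------------

def test_consensus_recovers_planted_ground_truth(cohort, cohort_tables):
    truth = cohort["truth"]
    planted = {(m["sample_id"], m["chrom"], m["pos"], m["ref"], m["alt"]):
               (m["consequence"], m["aa_pos"]) for m in truth.mutations}
    recovered = {}
    for m in cohort_tables["objects"]:
        aa = m.protein_change[0] if m.protein_change else None
        recovered[m.key()] = (m.consequence.value, aa)
    assert recovered == planted


def test_normalize_variant_examples():
    assert normalize_variant(100, "ATT", "AT") == (100, "AT", "A")
    assert normalize_variant(100, "TA", "TG") == (101, "A", "G")
    assert normalize_variant(100, "A", "G") == (100, "A", "G")
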