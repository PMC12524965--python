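"""Filtering cascade: threshold semantics, set algebra, and algebraic laws."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from liquidpanel import (CloneVariant, FilterConfig, SimulationTruth,
                         apply_reporting_threshold, depth_vaf_filter,
                         matched_germline_subtract, population_germline_filter,
                         qc_sample, random_germline_snps, simulate_variant_table)
from liquidpanel.classify import classify_table
from liquidpanel.variants import as_variant_table

CFG = FilterConfig()


def _tbl(rows):
    return as_variant_table([
        {"sample_id": "s1", "gene": "ALK", "chrom": "chr2", "pos": 100 + i,
         "ref": "A", "alt": "T", **r} for i, r in enumerate(rows)
    ])


# ---------------------------------------------------------------------------
# stage semantics


@pytest.mark.parametrize("fraction,expected", [
    (0.06, "fail"),   # the excluded low-cfDNA plasma sample
    (0.20, "pass"),   # boundary: threshold itself passes
    (1.0, "pass"),
])
def test_qc_sample_threshold(fraction, expected):
    assert qc_sample(fraction, CFG) == expected


def test_qc_sample_rejects_out_of_range():
    with pytest.raises(ValueError):
        qc_sample(1.2, CFG)


@pytest.mark.parametrize("depth,vaf,kept", [
    (5000, 0.0285, True),   # a surviving low-VAF driver
    (99, 0.30, False),      # below 100x coverage floor
    (5000, 0.004, False),   # below 0.5% VAF floor
    (100, 0.005, True),     # inclusive boundaries
])
def test_depth_vaf_filter_boundaries(depth, vaf, kept):
    out = depth_vaf_filter(_tbl([{"depth": depth, "vaf": vaf}]), CFG)
    assert (len(out) == 1) is kept


def test_flagged_artifacts_and_duplicates_removed():
    out = depth_vaf_filter(_tbl([
        {"depth": 5000, "vaf": 0.3, "artifact_flag": True},
        {"depth": 5000, "vaf": 0.3, "duplicate_flag": True},
        {"depth": 5000, "vaf": 0.3},
    ]), CFG)
    assert len(out) == 1


@pytest.mark.parametrize("gnomad,dbsnp,kept", [
    (0.02, None, False),    # common in gnomAD
    (None, 0.01, False),    # dbSNP-common at the 1% bound (inclusive)
    (0.01, None, True),     # gnomAD bound is strict 'more than 1.0%'
    (None, None, True),     # missing frequencies: not demonstrably common
    (0.001, 0.001, True),
])
def test_population_germline_filter(gnomad, dbsnp, kept):
    out = population_germline_filter(
        _tbl([{"depth": 1000, "vaf": 0.5, "gnomad_af": gnomad, "dbsnp_common_maf": dbsnp}]), CFG)
    assert (len(out) == 1) is kept


def test_matched_germline_subtraction_is_set_difference():
    shared = [{"depth": 1000, "vaf": 0.5} for _ in range(50)]
    private = [{"depth": 1000, "vaf": 0.05} for _ in range(5)]
    tumour = _tbl(shared + private)
    germ = _tbl(shared)  # same positions 100..149
    out = matched_germline_subtract(tumour, germ)
    assert len(out) == 5
    assert set(out["pos"]) == set(range(150, 155))


def test_missing_germline_set_warns_not_fails(caplog):
    t = _tbl([{"depth": 1000, "vaf": 0.5}])
    with caplog.at_level("WARNING"):
        out = matched_germline_subtract(t, None)
    assert len(out) == 1
    assert any("germline" in r.message for r in caplog.records)


def test_empty_germline_set_is_identity():
    t = _tbl([{"depth": 1000, "vaf": 0.5}])
    assert len(matched_germline_subtract(t, _tbl([]))) == 1


@pytest.mark.parametrize("tier,vaf,kept", [
    ("pathogenic", 0.0138, True),    # driver just above the 1% reporting bound
    ("pathogenic", 0.009, False),
    ("pathogenic", 0.01, False),     # bound is strict
    ("VUS", 0.50, False),            # tier gate
])
def test_reporting_threshold(tier, vaf, kept):
    t = _tbl([{"depth": 1000, "vaf": vaf}])
    t["tier"] = tier
    assert (len(apply_reporting_threshold(t, CFG)) == 1) is kept


# ---------------------------------------------------------------------------
# algebraic laws of the cascade

record_st = st.fixed_dictionaries({
    "depth": st.integers(min_value=0, max_value=5000),
    "vaf": st.floats(min_value=0, max_value=1, allow_nan=False),
    "gnomad_af": st.one_of(st.none(), st.floats(min_value=0, max_value=0.5, allow_nan=False)),
    "dbsnp_common_maf": st.one_of(st.none(), st.floats(min_value=0, max_value=0.5, allow_nan=False)),
    "artifact_flag": st.booleans(),
})
table_st = st.lists(record_st, min_size=0, max_size=25).map(_tbl)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(table_st)
def test_cascade_idempotent_and_order_invariant(tbl):
    stages = [lambda d: depth_vaf_filter(d, CFG), lambda d: population_germline_filter(d, CFG)]
    once = stages[1](stages[0](tbl))
    assert stages[1](stages[0](once)).index.tolist() == once.index.tolist()  # idempotent
    other = stages[0](stages[1](tbl))
    assert other.index.tolist() == once.index.tolist()  # stages commute


@settings(max_examples=40, deadline=None, derandomize=True)
@given(table_st,
       st.integers(min_value=0, max_value=5000),
       st.floats(min_value=0, max_value=1, allow_nan=False))
def test_raising_thresholds_never_enlarges_retained_set(tbl, min_depth, min_vaf):
    low = depth_vaf_filter(tbl, CFG)
    strict = FilterConfig(min_depth=max(CFG.min_depth, min_depth),
                          min_vaf=max(CFG.min_vaf, min_vaf))
    high = depth_vaf_filter(tbl, strict)
    assert set(high.index) <= set(low.index)


# ---------------------------------------------------------------------------
# generator truth labels


def test_cascade_on_generator_truth_labels(panel):
    """Over 50 seeds: common SNPs and artefacts always removed, clonal
    drivers at reportable expected VAF always retained."""
    for seed in range(50):
        truth = SimulationTruth(
            purity=0.57,
            clones=[CloneVariant(gene="ALK", clonal_fraction=1.0),     # E[VAF] 0.285
                    CloneVariant(gene="PTPN11", clonal_fraction=0.1)],  # E[VAF] 0.0285
            germline_snps=random_germline_snps(panel, 40, seed=seed + 1000),
            artifact_rate=0.1, seed=seed,
        )
        tab = simulate_variant_table(truth, panel, mean_depth=2228)
        out = population_germline_filter(depth_vaf_filter(tab, CFG), CFG)
        out = apply_reporting_threshold(classify_table(out), CFG)
        assert not (out["truth_class"] == "germline_snp").any()
        assert not (out["truth_class"] == "artifact").any()
        assert (out["truth_class"] == "somatic_driver").sum() == 2
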