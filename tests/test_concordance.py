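"""Compartment concordance, VAF trajectories, and purity inversion."""

import numpy as np
import pandas as pd
import pytest

from liquidpanel import (SampleMeta, classify_concordance, forward_mix,
                         purity_from_vaf, scenario_clonal_evolution, vaf_trajectory)
from liquidpanel.classify import classify_table
from liquidpanel.filtering import FilterConfig, apply_reporting_threshold, depth_vaf_filter
from liquidpanel.variants import as_variant_table


def _tbl(sample, keys, vafs=None):
    vafs = vafs or [0.3] * len(keys)
    return as_variant_table([
        {"sample_id": sample, "gene": "ALK", "chrom": c, "pos": p, "ref": r, "alt": a,
         "vaf": v, "depth": 1000}
        for (c, p, r, a), v in zip(keys, vafs)
    ])


K = [("chr2", i, "A", "T") for i in range(1, 30)]


def test_identical_sets_all_shared():
    pairs, counts = classify_concordance(_tbl("ct", K[:5]), _tbl("tu", K[:5]))
    assert counts == {"shared": 5, "ctDNA_only": 0, "tumour_only": 0}
    assert all(p.vaf_ctdna is not None and p.vaf_tumour is not None for p in pairs)


@pytest.mark.parametrize("a,b", [(3, 4), (0, 7), (5, 0)])
def test_disjoint_sets_counted_by_brute_force(a, b):
    pairs, counts = classify_concordance(_tbl("ct", K[:a]), _tbl("tu", K[10:10 + b]))
    assert counts == {"shared": 0, "ctDNA_only": a, "tumour_only": b}
    assert len(pairs) == a + b


def test_swap_symmetry():
    ct, tu = _tbl("ct", K[:6]), _tbl("tu", K[3:9])
    _, fwd = classify_concordance(ct, tu)
    _, rev = classify_concordance(tu, ct)
    assert fwd["shared"] == rev["shared"]
    assert fwd["ctDNA_only"] == rev["tumour_only"]
    assert fwd["tumour_only"] == rev["ctDNA_only"]
    assert sum(fwd.values()) == sum(rev.values())


def test_mismatched_patients_rejected():
    meta = {
        "ct": SampleMeta("ct", "P1", "ctDNA_blood"),
        "tu": SampleMeta("tu", "P2", "tumour"),
    }
    with pytest.raises(ValueError, match="patient"):
        classify_concordance(_tbl("ct", K[:2]), _tbl("tu", K[:2]), meta=meta)


# ---------------------------------------------------------------------------
# trajectories


def test_trajectory_event_labels():
    lost = [("diagnosis", _tbl("a", K[:1], [0.0285])),
            ("remission", _tbl("b", [])),
            ("relapse", _tbl("c", []))]
    traj = vaf_trajectory(lost)
    assert traj["event"].tolist() == ["lost"]

    returned = [("diagnosis", _tbl("a", K[:1], [0.285])),
                ("remission", _tbl("b", [])),
                ("relapse", _tbl("c", K[:1], [0.98]))]
    assert vaf_trajectory(returned)["event"].tolist() == ["lost_then_emergent"]

    flat = [("diagnosis", _tbl("a", K[:1], [0.3])),
            ("relapse", _tbl("b", K[:1], [0.31]))]
    assert vaf_trajectory(flat)["event"].tolist() == ["stable"]

    rising = [("diagnosis", _tbl("a", K[:1], [0.1])),
              ("relapse", _tbl("b", K[:1], [0.4]))]
    assert vaf_trajectory(rising)["event"].tolist() == ["rising"]

    emergent = [("diagnosis", _tbl("a", [])),
                ("relapse", _tbl("b", K[:1], [0.4]))]
    assert vaf_trajectory(emergent)["event"].tolist() == ["emergent"]


def test_single_timepoint_rejected():
    with pytest.raises(ValueError, match="two timepoints"):
        vaf_trajectory([("diagnosis", _tbl("a", K[:1]))])


def test_below_reporting_threshold_counts_as_absent_but_vaf_retained():
    series = [("diagnosis", _tbl("a", K[:1], [0.3])),
              ("relapse", _tbl("b", K[:1], [0.004]))]
    traj = vaf_trajectory(series)
    assert traj["event"].tolist() == ["lost"]
    assert traj["vaf_relapse"].iloc[0] == pytest.approx(0.004)


# ---------------------------------------------------------------------------
# purity


@pytest.mark.parametrize("state", ["het_diploid", "hom_loh"])
def test_purity_round_trips_forward_mixing(state):
    for p in np.arange(0.05, 0.96, 0.05):
        est = purity_from_vaf(forward_mix(p, state), state)
        assert est.purity == pytest.approx(p, abs=1e-9)
        assert not est.clipped


def test_purity_special_cases():
    assert purity_from_vaf(0.5, "het_diploid").purity == 1.0
    assert purity_from_vaf(0.0, "het_diploid").purity == 0.0
    assert purity_from_vaf(0.0, "hom_loh").purity == 0.0
    # homozygous variant at ~10.5% VAF implies ~19% tumour content
    assert purity_from_vaf(0.105, "hom_loh").purity == pytest.approx(0.19, abs=0.001)


def test_purity_error_paths():
    with pytest.raises(ValueError, match="impossible"):
        purity_from_vaf(1.0, "het_diploid")
    with pytest.raises(ValueError, match="copy state"):
        purity_from_vaf(0.1, "triploid")
    with pytest.raises(ValueError, match="vaf"):
        purity_from_vaf(1.2, "hom_loh")
    est = purity_from_vaf(0.8, "het_diploid")
    assert est.purity == 1.0 and est.clipped


# ---------------------------------------------------------------------------
# canonical scenario, end to end


def _drivers(table):
    cfg = FilterConfig()
    out = apply_reporting_threshold(classify_table(depth_vaf_filter(table, cfg)), cfg)
    return out


def test_scenario_labels_match_generator_truth_over_seeds():
    """Concordance categories and trajectory labels recover the scenario
    truth for every seed."""
    for seed in range(50):
        sc = scenario_clonal_evolution(seed)
        diag_ct = _drivers(sc.samples["diagnosis_ctdna"][1])
        diag_tu = _drivers(sc.samples["diagnosis_tumour"][1])
        pairs, counts = classify_concordance(diag_ct, diag_tu)
        assert counts == {"shared": 1, "ctDNA_only": 1, "tumour_only": 0}
        cats = {pp: next(p.category for p in pairs
                         if _protein_of(diag_ct, diag_tu, p.key) == pp)
                for pp in sc.truth_concordance_diagnosis}
        assert cats == sc.truth_concordance_diagnosis

        series = [(tp, _drivers(sc.samples[f"{tp}_ctdna" if tp != "diagnosis" else "diagnosis_ctdna"][1]))
                  for tp in sc.ctdna_timepoint_order]
        traj = vaf_trajectory(series)
        events = dict(zip(traj["protein_change"], traj["event"]))
        assert events == sc.truth_events


def _protein_of(ct, tu, key):
    for df in (ct, tu):
        hit = df[(df["chrom"] == key[0]) & (df["pos"] == key[1])
                 & (df["ref"] == key[2]) & (df["alt"] == key[3])]
        if len(hit):
            return hit["protein_change"].iloc[0]
    return None
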