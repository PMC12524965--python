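"""Coverage z-score caller: baseline algebra, oracle equivalence, detection."""

import numpy as np
import pandas as pd
import pytest

from liquidpanel import (CoverageZScoreCaller, SimulationTruth, call_amplifications,
                         compute_baseline, simulate_coverage, z_scores)


def _cov(depths, genes=None, chroms=None):
    n = len(depths)
    genes = genes or [f"G{i}" for i in range(n)]
    chroms = chroms or ["chr1"] * n
    return pd.DataFrame({
        "sample_id": "s1",
        "target_id": [f"t{i}" for i in range(n)],
        "gene": genes, "chrom": chroms,
        "start": np.arange(n) * 1000, "end": np.arange(n) * 1000 + 250,
        "umi_depth": depths,
    })


def test_uniform_depth_baseline_is_constant():
    base = compute_baseline(_cov([500.0] * 42), trim_fraction=0.0)
    assert base.mu == 500.0
    assert base.sigma == 0.0
    with pytest.raises(ValueError, match="sigma"):
        z_scores(_cov([500.0] * 42), base)


def test_chrx_and_known_amplified_never_in_baseline():
    cov = _cov([100.0] * 10, genes=["MYCN"] * 2 + ["ATRX"] * 2 + [f"G{i}" for i in range(6)],
               chroms=["chr2"] * 2 + ["chrX"] * 2 + ["chr1"] * 6)
    base = compute_baseline(cov, known_amplified={"MYCN"}, chrx_genes={"ATRX"},
                            trim_fraction=0.0)
    ids = {cov.loc[i, "target_id"] for i in range(4)}
    assert not ids & base.included_targets
    assert base.excluded["t0"] == "known_amplified"
    assert base.excluded["t2"] == "chrX"


def test_spiked_gene_trimmed_out_of_baseline():
    # 42 genes x 4 targets, one gene at 50x the neutral depth
    rng = np.random.default_rng(0)
    depths = rng.normal(1000, 30, size=168)
    genes = [f"G{i // 4}" for i in range(168)]
    depths[:4] = 50_000.0  # G0 spiked
    base = compute_baseline(_cov(list(depths), genes=genes), trim_fraction=0.05)
    spiked = {"t0", "t1", "t2", "t3"}
    assert not spiked & base.included_targets
    assert all(base.excluded[t] == "trimmed" for t in spiked)
    assert base.mu == pytest.approx(1000, rel=0.01)


def test_too_few_surviving_targets_fails_loudly():
    with pytest.raises(ValueError, match="survive"):
        compute_baseline(_cov([100.0] * 6), trim_fraction=0.2)


def test_z_equals_independent_brute_force():
    """Per-target z matches an independent (x-mu)/sigma recomputation to 1e-12."""
    depths = [100.0] * 40 + [1000.0] * 2
    cov = _cov(depths)
    base = compute_baseline(cov, trim_fraction=0.0)
    scored = z_scores(cov, base)
    x = np.asarray(depths)
    mu, sigma = x.mean(), x.std(ddof=0)  # brute-force oracle
    np.testing.assert_allclose(scored["z"], (x - mu) / sigma, atol=1e-12)
    np.testing.assert_allclose(scored["inverse_z"], -(x - mu) / sigma, atol=1e-12)


def test_unit_and_zero_deviation():
    cov = _cov(list(np.arange(1, 43, dtype=float)))
    base = compute_baseline(cov, trim_fraction=0.0)
    z = z_scores(_cov([base.mu, base.mu + base.sigma] + [base.mu] * 40), base)["z"]
    assert z.iloc[0] == pytest.approx(0.0, abs=1e-12)
    assert z.iloc[1] == pytest.approx(1.0, abs=1e-12)


def test_baseline_z_has_mean_zero_sd_one():
    rng = np.random.default_rng(3)
    cov = _cov(list(rng.lognormal(7, 0.2, size=100)))
    base = compute_baseline(cov, trim_fraction=0.05)
    scored = z_scores(cov, base)
    in_base = scored[scored["in_baseline"]]["z"].to_numpy()
    assert in_base.mean() == pytest.approx(0.0, abs=1e-10)
    assert in_base.std(ddof=0) == pytest.approx(1.0, abs=1e-10)


def test_scale_invariance():
    rng = np.random.default_rng(4)
    depths = rng.lognormal(7, 0.3, size=60)
    a, b = _cov(list(depths)), _cov(list(depths * 7.3))
    za = z_scores(a, compute_baseline(a))["z"]
    zb = z_scores(b, compute_baseline(b))["z"]
    np.testing.assert_allclose(za, zb, rtol=1e-10)


def test_gene_z_is_median_and_thresholds_partition():
    rng = np.random.default_rng(8)
    depths = list(rng.normal(1000, 30, size=160)) + [50_000.0, 60_000.0]
    cov = _cov(depths, genes=[f"G{i // 4}" for i in range(160)] + ["AMP", "AMP"])
    base = compute_baseline(cov, trim_fraction=0.05)  # spikes trimmed out of baseline
    scored = z_scores(cov, base)
    calls = {c.gene: c for c in call_amplifications(scored, z_amp=5, z_gain=2)}
    assert calls["AMP"].gene_z == pytest.approx(np.median(scored["z"].iloc[160:]))
    assert calls["AMP"].status == "amplified"
    assert calls["G0"].status == "neutral"
    with pytest.raises(ValueError, match="thresholds"):
        call_amplifications(scored, z_amp=2, z_gain=5)


def test_mna_simulation_called_amplified(panel):
    """MYCN copy number 50 at purity 0.3 is called in >=95/100 seeds."""
    caller = CoverageZScoreCaller()
    hits = 0
    for seed in range(100):
        truth = SimulationTruth(purity=0.3, amplified_genes={"MYCN": 50}, seed=seed)
        calls = caller.fit_predict(simulate_coverage(truth, panel, noise_cv=0.1, seed=seed))
        status = calls.set_index("gene")["status"]
        hits += status["MYCN"] == "amplified"
    assert hits >= 95


def test_copy_neutral_yields_no_amplification_calls(panel):
    caller = CoverageZScoreCaller()
    for seed in range(30):
        truth = SimulationTruth(purity=0.3, seed=seed)
        calls = caller.fit_predict(simulate_coverage(truth, panel, noise_cv=0.1, seed=seed))
        assert not (calls["status"] == "amplified").any()


def test_amplification_outside_panel_footprint_invisible(panel):
    """A gene amplified only in regions the panel does not cover is never called."""
    truth = SimulationTruth(purity=0.3, amplified_genes={"OFFPANEL": 50}, seed=1)
    cov = simulate_coverage(truth, panel, noise_cv=0.1, seed=1)
    calls = CoverageZScoreCaller().fit_predict(cov)
    assert "OFFPANEL" not in set(calls["gene"])
    assert not (calls["status"] == "amplified").any()


def test_estimator_fit_attributes_and_params(panel):
    truth = SimulationTruth(purity=0.3, seed=2)
    caller = CoverageZScoreCaller(z_amp=6.0)
    caller.fit(simulate_coverage(truth, panel, noise_cv=0.05, seed=2))
    assert caller.mu_ == caller.baseline_.mu > 0
    assert caller.sigma_ > 0
    assert caller.get_params()["z_amp"] == 6.0
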