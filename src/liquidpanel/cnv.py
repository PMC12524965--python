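"""Oncogene amplification calling from per-target panel coverage.

On a targeted panel, an amplified oncogene shows UMI coverage far above the
copy-neutral level of the other genes in the *same* sample.  The caller is
within-sample:

1. a *baseline* is built from the sample's per-target depths after
   excluding known-amplified genes and X-chromosomal genes, then
   symmetrically trimming the top and bottom ``trim_fraction`` of the
   remaining depths — removing any residual over-/under-represented
   targets;
2. every target (including excluded ones) is scored against that baseline:
   ``z = (x − μ) / σ`` with μ, σ the mean and (population) SD of the
   surviving depths;
3. a gene's score is the median of its targets' z; genes are called
   ``amplified`` (z ≥ z_amp), ``gain`` (z_gain ≤ z < z_amp) or ``neutral``.

Coverage tables are DataFrames with columns ``sample_id, target_id, gene,
chrom, start, end, umi_depth``.  An amplification confined to genome regions
the panel does not cover is invisible here by construction — the caller can
only see targets it has.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

COVERAGE_COLUMNS = ["sample_id", "target_id", "gene", "chrom", "start", "end", "umi_depth"]

#: Default gene-level z thresholds for amplification and gain calls.
DEFAULT_Z_AMP = 5.0
DEFAULT_Z_GAIN = 2.0
DEFAULT_TRIM = 0.05

MIN_BASELINE_TARGETS = 5


@dataclass
class CoverageBaseline:
    """Trimmed within-sample coverage baseline (μ, σ) and what was excluded."""

    included_targets: frozenset[str]
    mu: float
    sigma: float
    excluded: dict[str, str] = field(default_factory=dict)  # target_id -> reason

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if not self.included_targets:
            raise ValueError("baseline must include at least one target")


@dataclass
class CnvCall:
    """Gene-level copy-number call with its z-score evidence."""

    gene: str
    gene_z: float
    status: str  # amplified | gain | neutral
    target_z: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"gene": self.gene, "gene_z": self.gene_z, "status": self.status,
                "target_z": dict(self.target_z)}


def compute_baseline(
    coverages: pd.DataFrame,
    known_amplified: set[str] | frozenset[str] = frozenset(),
    chrx_genes: set[str] | frozenset[str] = frozenset(),
    trim_fraction: float = DEFAULT_TRIM,
) -> CoverageBaseline:
    """Build the trimmed coverage baseline for one sample.

    Raises ``ValueError`` when fewer than 5 targets survive the exclusions
    and trimming — too few to estimate a spread.
    """
    if not 0 <= trim_fraction < 0.5:
        raise ValueError("trim_fraction must be in [0, 0.5)")
    if coverages["sample_id"].nunique() > 1:
        raise ValueError("baseline is within-sample; got multiple sample_ids")
    excluded: dict[str, str] = {}
    df = coverages
    mask = pd.Series(True, index=df.index)
    for idx, row in df.iterrows():
        if row["gene"] in known_amplified:
            excluded[row["target_id"]] = "known_amplified"
            mask.loc[idx] = False
        elif row["gene"] in chrx_genes or str(row["chrom"]) in {"chrX", "X"}:
            excluded[row["target_id"]] = "chrX"
            mask.loc[idx] = False
    kept = df.loc[mask].sort_values("umi_depth", kind="stable")
    k = int(np.floor(trim_fraction * len(kept)))
    if k > 0:
        for tid in kept["target_id"].iloc[:k]:
            excluded[tid] = "trimmed"
        for tid in kept["target_id"].iloc[len(kept) - k:]:
            excluded[tid] = "trimmed"
        kept = kept.iloc[k: len(kept) - k]
    if len(kept) < MIN_BASELINE_TARGETS:
        raise ValueError(
            f"only {len(kept)} targets survive baseline exclusion/trimming "
            f"(need >= {MIN_BASELINE_TARGETS}); relax exclusions or trim_fraction"
        )
    depths = kept["umi_depth"].to_numpy(dtype=float)
    return CoverageBaseline(
        included_targets=frozenset(kept["target_id"]),
        mu=float(depths.mean()),
        sigma=float(depths.std(ddof=0)),
        excluded=excluded,
    )


def z_scores(coverages: pd.DataFrame, baseline: CoverageBaseline) -> pd.DataFrame:
    """Score every target against the baseline: z = (x − μ)/σ.

    Excluded targets are scored too (that is where the amplification signal
    lives); they simply did not shape μ and σ.  Returns the coverage table
    with ``z`` and ``inverse_z`` (the −z presentation some coverage plots
    use) columns appended.
    """
    if baseline.sigma <= 0:
        raise ValueError(
            "baseline sigma is 0 (constant coverage); add noise or widen the baseline"
        )
    out = coverages.copy()
    x = out["umi_depth"].to_numpy(dtype=float)
    out["z"] = (x - baseline.mu) / baseline.sigma
    out["inverse_z"] = -out["z"]
    out["in_baseline"] = out["target_id"].isin(baseline.included_targets)
    return out


def call_amplifications(
    scored: pd.DataFrame,
    z_amp: float = DEFAULT_Z_AMP,
    z_gain: float = DEFAULT_Z_GAIN,
) -> list[CnvCall]:
    """Aggregate per-target z to gene level (median) and call status."""
    if not z_amp > z_gain > 0:
        raise ValueError("thresholds must satisfy z_amp > z_gain > 0")
    calls: list[CnvCall] = []
    for gene, grp in scored.groupby("gene", sort=True):
        if grp.empty:
            continue
        gz = float(grp["z"].median())
        status = "amplified" if gz >= z_amp else ("gain" if gz >= z_gain else "neutral")
        calls.append(CnvCall(gene=gene, gene_z=gz, status=status,
                             target_z=dict(zip(grp["target_id"], grp["z"]))))
    return calls


class CoverageZScoreCaller(BaseEstimator):
    """Within-sample amplification caller as an sklearn-style estimator.

    ``fit(X)`` computes the trimmed baseline from one sample's coverage
    table (fitted attributes ``baseline_``, ``mu_``, ``sigma_``);
    ``transform(X)`` appends per-target z-scores; ``predict(X)`` returns a
    gene-level call DataFrame (gene, gene_z, status).
    """

    def __init__(
        self,
        z_amp: float = DEFAULT_Z_AMP,
        z_gain: float = DEFAULT_Z_GAIN,
        trim_fraction: float = DEFAULT_TRIM,
        known_amplified: tuple[str, ...] = (),
        chrx_genes: tuple[str, ...] = ("ATRX", "DDX3X"),
    ) -> None:
        self.z_amp = z_amp
        self.z_gain = z_gain
        self.trim_fraction = trim_fraction
        self.known_amplified = known_amplified
        self.chrx_genes = chrx_genes

    def fit(self, X: pd.DataFrame, y=None) -> "CoverageZScoreCaller":
        self.baseline_ = compute_baseline(
            X,
            known_amplified=frozenset(self.known_amplified),
            chrx_genes=frozenset(self.chrx_genes),
            trim_fraction=self.trim_fraction,
        )
        self.mu_ = self.baseline_.mu
        self.sigma_ = self.baseline_.sigma
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return z_scores(X, self.baseline_)

    def predict(self, X: pd.DataFrame) -> pd.DataFrame:
        calls = call_amplifications(self.transform(X), z_amp=self.z_amp, z_gain=self.z_gain)
        return pd.DataFrame(
            [{"gene": c.gene, "gene_z": c.gene_z, "status": c.status} for c in calls]
        )

    def fit_predict(self, X: pd.DataFrame, y=None) -> pd.DataFrame:
        return self.fit(X).predict(X)
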