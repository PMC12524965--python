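"""Somatic variant filtering cascade for targeted cfDNA panels.

Raw UMI-consensus variant calls from a deep (~2000×) panel contain, besides
true somatic mutations, sequencing artefacts, PCR duplicates and the
patient's own germline polymorphisms.  The cascade removes them in four
independent, order-invariant stages:

1. depth/VAF floor — drop calls with coverage < ``min_depth`` or allele
   fraction < ``min_vaf``, plus anything flagged artefact/duplicate;
2. population-germline removal — drop variants common (≥ 1% MAF) in any
   of the five continental super-populations (dbSNP-common / gnomAD);
3. matched-germline subtraction — drop variants present in the patient's
   own germline call set (WGS), when available;
4. reporting threshold — after classification, report only driver-tier
   variants with VAF strictly above ``reporting_vaf``.

Each stage is a pure per-record predicate, so the cascade is idempotent and
its stages commute.  Records are never mutated: filters either drop rows or
annotate a ``filter`` column with the reason (VCF FILTER semantics).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .variants import validate_variants, variant_keys, KEY_COLUMNS

logger = logging.getLogger(__name__)

DRIVER_TIERS = frozenset({"pathogenic", "likely_pathogenic"})


@dataclass
class FilterConfig:
    """Thresholds of the filtering cascade.

    min_depth
        Minimum UMI read depth; calls below are unreliable (default 100×).
    min_vaf
        Minimum allele fraction retained, as a fraction (default 0.005).
    max_population_af
        Population allele frequency at or above which a variant is treated
        as a common germline polymorphism (default 0.01).
    reporting_vaf
        Strict lower bound on VAF for reporting a driver (default 0.01).
    cfdna_fraction_threshold
        Minimum cfDNA fraction for a plasma sample to enter analysis at all
        (default 0.20).
    """

    min_depth: int = 100
    min_vaf: float = 0.005
    max_population_af: float = 0.01
    reporting_vaf: float = 0.01
    cfdna_fraction_threshold: float = 0.20

    def __post_init__(self) -> None:
        if self.min_depth < 0:
            raise ValueError("min_depth must be >= 0")
        for name in ("min_vaf", "max_population_af", "reporting_vaf", "cfdna_fraction_threshold"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0,1], got {v}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "FilterConfig":
        return cls(**d)


def qc_sample(cfdna_fraction: float, cfg: FilterConfig | None = None) -> str:
    """Sample-level QC gate on cfDNA fraction.

    Plasma samples whose cell-free DNA fraction falls below the threshold
    carry too little tumour signal and are excluded from all downstream
    stages.  Returns ``"pass"`` or ``"fail"``; the threshold itself passes.
    """
    cfg = cfg or FilterConfig()
    if not 0 <= cfdna_fraction <= 1:
        raise ValueError(f"cfDNA fraction must be in [0,1], got {cfdna_fraction}")
    return "fail" if cfdna_fraction < cfg.cfdna_fraction_threshold else "pass"


def depth_vaf_filter(variants: pd.DataFrame, cfg: FilterConfig | None = None) -> pd.DataFrame:
    """Retain calls with depth >= min_depth and vaf >= min_vaf (inclusive).

    Records flagged as sequencing artefacts or PCR duplicates are removed
    regardless of depth/VAF.  Missing depth (e.g. a transcription of a
    published table without a coverage column) is retained: only
    demonstrably shallow calls are dropped.
    """
    cfg = cfg or FilterConfig()
    if variants.empty:
        return variants
    validate_variants(variants)
    depth = pd.to_numeric(variants["depth"], errors="coerce")
    vaf = pd.to_numeric(variants["vaf"], errors="coerce")
    flagged = (
        variants["artifact_flag"].fillna(False).astype(bool)
        | variants["duplicate_flag"].fillna(False).astype(bool)
    )
    keep = (
        ~flagged
        & (depth.isna() | (depth >= cfg.min_depth))
        & (vaf >= cfg.min_vaf)
    )
    return variants.loc[keep].copy()


def population_germline_filter(variants: pd.DataFrame, cfg: FilterConfig | None = None) -> pd.DataFrame:
    """Remove variants common in the population (likely germline).

    A record is dropped when its dbSNP-common MAF (max across the five
    super-populations) is >= ``max_population_af`` or its gnomAD exome
    frequency exceeds ``max_population_af``.  Missing frequencies mean the
    variant is not demonstrably common and it is retained.
    """
    cfg = cfg or FilterConfig()
    if variants.empty:
        return variants
    dbsnp = pd.to_numeric(variants["dbsnp_common_maf"], errors="coerce")
    gnomad = pd.to_numeric(variants["gnomad_af"], errors="coerce")
    common = (dbsnp >= cfg.max_population_af) | (gnomad > cfg.max_population_af)
    return variants.loc[~common.fillna(False)].copy()


def matched_germline_subtract(
    variants: pd.DataFrame, germline: pd.DataFrame | None
) -> pd.DataFrame:
    """Subtract the patient's matched germline call set by genomic key.

    When no germline set is available (most patients lack WGS) the input is
    returned unchanged with a warning, mirroring the study design in which
    only a subset of cases had matched constitutional sequencing.
    """
    if germline is None:
        logger.warning("no matched germline set supplied; skipping germline subtraction")
        return variants
    if variants.empty or germline.empty:
        return variants
    germ_keys = variant_keys(germline)
    keys = variants[KEY_COLUMNS].apply(tuple, axis=1)
    keep = ~keys.isin(germ_keys)
    n_removed = int((~keep).sum())
    logger.info("matched germline subtraction removed %d/%d variants", n_removed, len(variants))
    return variants.loc[keep].copy()


def apply_reporting_threshold(
    classified: pd.DataFrame, cfg: FilterConfig | None = None
) -> pd.DataFrame:
    """Keep driver-tier variants with VAF strictly above the reporting bound.

    Requires a ``tier`` column (see :mod:`liquidpanel.classify`).
    """
    cfg = cfg or FilterConfig()
    if classified.empty:
        return classified
    if "tier" not in classified.columns:
        raise ValueError("apply_reporting_threshold requires classified variants (tier column)")
    vaf = pd.to_numeric(classified["vaf"], errors="coerce")
    keep = classified["tier"].isin(DRIVER_TIERS) & (vaf > cfg.reporting_vaf)
    return classified.loc[keep].copy()


class VariantFilter(BaseEstimator, TransformerMixin):
    """sklearn-style transformer running the pre-classification cascade.

    ``transform`` applies depth/VAF, population-germline and (optionally)
    matched-germline stages and returns the retained rows.  The transformer
    is stateless — ``fit`` only validates — but exposes the thresholds as
    estimator parameters so the cascade composes with sklearn pipelines and
    grid search.
    """

    def __init__(
        self,
        min_depth: int = 100,
        min_vaf: float = 0.005,
        max_population_af: float = 0.01,
        reporting_vaf: float = 0.01,
        cfdna_fraction_threshold: float = 0.20,
    ) -> None:
        self.min_depth = min_depth
        self.min_vaf = min_vaf
        self.max_population_af = max_population_af
        self.reporting_vaf = reporting_vaf
        self.cfdna_fraction_threshold = cfdna_fraction_threshold

    def _config(self) -> FilterConfig:
        return FilterConfig(
            min_depth=self.min_depth,
            min_vaf=self.min_vaf,
            max_population_af=self.max_population_af,
            reporting_vaf=self.reporting_vaf,
            cfdna_fraction_threshold=self.cfdna_fraction_threshold,
        )

    def fit(self, X: pd.DataFrame, y=None) -> "VariantFilter":
        validate_variants(X)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame, germline: pd.DataFrame | None = None) -> pd.DataFrame:
        cfg = self._config()
        out = depth_vaf_filter(X, cfg)
        out = population_germline_filter(out, cfg)
        if germline is not None:
            out = matched_germline_subtract(out, germline)
        return out


def annotate_filter_column(variants: pd.DataFrame, cfg: FilterConfig | None = None,
                           germline: pd.DataFrame | None = None) -> pd.DataFrame:
    """Return the full table with a VCF-style ``filter`` column.

    Values: ``PASS``, or a semicolon-joined subset of ``artifact``,
    ``low_depth``, ``low_vaf``, ``pop_germline``, ``matched_germline``.
    """
    cfg = cfg or FilterConfig()
    if variants.empty:
        out = variants.copy()
        out["filter"] = pd.Series(dtype=object)
        return out
    validate_variants(variants)
    depth = pd.to_numeric(variants["depth"], errors="coerce")
    vaf = pd.to_numeric(variants["vaf"], errors="coerce")
    dbsnp = pd.to_numeric(variants["dbsnp_common_maf"], errors="coerce")
    gnomad = pd.to_numeric(variants["gnomad_af"], errors="coerce")

    reasons: list[str] = []
    germ_keys = variant_keys(germline) if germline is not None and not germline.empty else set()
    for idx, row in variants.iterrows():
        r = []
        if bool(row.get("artifact_flag")) or bool(row.get("duplicate_flag")):
            r.append("artifact")
        if not pd.isna(depth.loc[idx]) and depth.loc[idx] < cfg.min_depth:
            r.append("low_depth")
        if pd.isna(vaf.loc[idx]) or vaf.loc[idx] < cfg.min_vaf:
            r.append("low_vaf")
        if (not pd.isna(dbsnp.loc[idx]) and dbsnp.loc[idx] >= cfg.max_population_af) or (
            not pd.isna(gnomad.loc[idx]) and gnomad.loc[idx] > cfg.max_population_af
        ):
            r.append("pop_germline")
        if germ_keys and tuple(row[k] for k in KEY_COLUMNS) in germ_keys:
            r.append("matched_germline")
        reasons.append(";".join(r) if r else "PASS")
    out = variants.copy()
    out["filter"] = reasons
    return out
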