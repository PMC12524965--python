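"""Pathogenicity tiering from in-silico scores and COSMIC presence.

Filtered variants are tiered from four lines of evidence: REVEL (ensemble
missense pathogenicity, [0,1]), SIFT (deleterious/tolerated, score <= 0.05
deleterious), PolyPhen-2 (PRD/POD/B calls), and presence of a COSMIC
somatic-catalogue identifier.  The rules fire in a fixed order and the tier
is a deterministic function of the evidence:

1. **pathogenic** — REVEL > 0.7 AND a COSMIC entry exists;
2. **likely_pathogenic** — COSMIC entry AND SIFT deleterious AND PolyPhen
   damaging (PRD/POD), covering hotspot variants whose REVEL is missing; OR
   a truncating consequence (frameshift / splice donor / nonsense) in a
   known driver gene, covering loss-of-function events no missense scorer
   rates;
3. **VUS** — any single line of damaging evidence without meeting the above;
4. **benign** — otherwise.

"Driver" means tier pathogenic or likely_pathogenic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .panel import default_panel
from .variants import TRUNCATING_CONSEQUENCES, VALID_CONSEQUENCES

TIERS = ("pathogenic", "likely_pathogenic", "VUS", "benign")
DRIVER_TIERS = frozenset({"pathogenic", "likely_pathogenic"})

#: REVEL score strictly above which a COSMIC-listed variant is pathogenic.
REVEL_PATHOGENIC = 0.7
#: SIFT score at or below which a variant is deleterious (fallback when no call).
SIFT_DELETERIOUS_MAX = 0.05
#: PolyPhen-2 score fallback for "possibly damaging" when no call is given.
POLYPHEN_DAMAGING_MIN = 0.446


def _is_missing(x) -> bool:
    if x is None:
        return True
    if isinstance(x, float) and np.isnan(x):
        return True
    if isinstance(x, str) and x.strip() in {"", "N/A", "NA", "nan"}:
        return True
    return pd.isna(x)


def _sift_deleterious(call, score) -> bool:
    if not _is_missing(call):
        return str(call).lower().startswith("del")
    if not _is_missing(score):
        return float(score) <= SIFT_DELETERIOUS_MAX
    return False


def _polyphen_damaging(call, score) -> bool:
    if not _is_missing(call):
        return str(call).upper() in {"PRD", "POD"}
    if not _is_missing(score):
        return float(score) >= POLYPHEN_DAMAGING_MIN
    return False


def classify_variant(variant: dict | pd.Series, driver_genes: set[str] | frozenset[str],
                     revel_threshold: float = REVEL_PATHOGENIC) -> tuple[str, list[str]]:
    """Tier one variant; returns ``(tier, fired_evidence_rules)``.

    ``variant`` needs the annotation fields of the canonical table
    (``revel_score``, ``cosmic_id``, ``sift_call``/``sift_score``,
    ``polyphen_call``/``polyphen_score``, ``consequence``, ``gene``).
    An unknown consequence string is rejected.
    """
    cons = variant.get("consequence")
    if not _is_missing(cons) and cons not in VALID_CONSEQUENCES:
        raise ValueError(f"unknown consequence {cons!r} for variant {variant.get('gene')} "
                         f"{variant.get('protein_change')}")

    cosmic = not _is_missing(variant.get("cosmic_id"))
    revel = variant.get("revel_score")
    revel_hit = (not _is_missing(revel)) and float(revel) > revel_threshold
    sift_del = _sift_deleterious(variant.get("sift_call"), variant.get("sift_score"))
    pp_dam = _polyphen_damaging(variant.get("polyphen_call"), variant.get("polyphen_score"))
    truncating = (not _is_missing(cons)) and cons in TRUNCATING_CONSEQUENCES \
        and variant.get("gene") in driver_genes

    evidence = []
    if cosmic:
        evidence.append("cosmic_present")
    if revel_hit:
        evidence.append("revel_gt_0.7")
    if sift_del:
        evidence.append("sift_deleterious")
    if pp_dam:
        evidence.append("polyphen_damaging")
    if truncating:
        evidence.append("truncating_in_driver_gene")

    if revel_hit and cosmic:
        tier = "pathogenic"
    elif (cosmic and sift_del and pp_dam) or truncating:
        tier = "likely_pathogenic"
    elif evidence:
        tier = "VUS"
    else:
        tier = "benign"
    return tier, evidence


class PathogenicityClassifier(BaseEstimator):
    """Rule-based tier assignment as an sklearn-style classifier.

    ``predict`` returns the tier per row; ``transform`` returns the input
    with ``tier``, ``evidence`` and ``is_driver`` columns appended.  The
    rules are fixed; ``fit`` records the driver-gene set (default: the
    bundled panel's gene list).
    """

    def __init__(self, driver_genes: tuple[str, ...] | None = None,
                 revel_threshold: float = REVEL_PATHOGENIC) -> None:
        self.driver_genes = driver_genes
        self.revel_threshold = revel_threshold

    def fit(self, X: pd.DataFrame | None = None, y=None) -> "PathogenicityClassifier":
        genes = self.driver_genes
        self.driver_genes_ = frozenset(genes) if genes is not None else frozenset(default_panel().genes)
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "driver_genes_"):
            self.fit()

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        self._check_fitted()
        return np.array(
            [classify_variant(row, self.driver_genes_, self.revel_threshold)[0]
             for _, row in X.iterrows()],
            dtype=object,
        )

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        self._check_fitted()
        out = X.copy()
        tiers, evid = [], []
        for _, row in X.iterrows():
            t, e = classify_variant(row, self.driver_genes_, self.revel_threshold)
            tiers.append(t)
            evid.append(",".join(e))
        out["tier"] = tiers
        out["evidence"] = evid
        out["is_driver"] = out["tier"].isin(DRIVER_TIERS)
        return out


def classify_table(variants: pd.DataFrame, driver_genes: set[str] | None = None) -> pd.DataFrame:
    """Tier every row of a variant table (thin wrapper over the estimator)."""
    clf = PathogenicityClassifier(tuple(sorted(driver_genes)) if driver_genes else None)
    return clf.fit().transform(variants)


CELL_LINE_MATERIALS = frozenset({"cell_line"})
CTDNA_MATERIALS = frozenset({"ctDNA_blood", "ctDNA_bonemarrow"})


@dataclass
class DriverSummary:
    """Cohort-level driver counts.

    ``gene_pathogenic_patient_counts`` counts pathogenic-tier variants in
    patient-derived materials only (ctDNA + germline), excluding cell-line
    controls, which is how per-gene pathogenic tallies are reported for a
    patient cohort.
    """

    n_ctdna_samples_with_driver: int = 0
    n_ctdna_driver_variants: int = 0
    gene_sample_counts: dict = field(default_factory=dict)          # all materials
    gene_sample_counts_ctdna: dict = field(default_factory=dict)
    gene_variant_counts_ctdna: dict = field(default_factory=dict)
    gene_pathogenic_patient_counts: dict = field(default_factory=dict)
    per_sample_driver_counts: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_ctdna_samples_with_driver": self.n_ctdna_samples_with_driver,
            "n_ctdna_driver_variants": self.n_ctdna_driver_variants,
            "gene_sample_counts": dict(self.gene_sample_counts),
            "gene_sample_counts_ctdna": dict(self.gene_sample_counts_ctdna),
            "gene_variant_counts_ctdna": dict(self.gene_variant_counts_ctdna),
            "gene_pathogenic_patient_counts": dict(self.gene_pathogenic_patient_counts),
            "per_sample_driver_counts": dict(self.per_sample_driver_counts),
        }


def summarize_drivers(classified: pd.DataFrame, metadata: pd.DataFrame) -> DriverSummary:
    """Aggregate driver-tier variants into per-sample / per-gene counts.

    ``metadata`` maps ``sample_id`` to ``material`` (and optionally patient,
    timepoint, risk group).  A sample contributes once per gene to the
    gene-level sample counts however many variants it carries there.
    """
    if classified.empty:
        return DriverSummary()
    if "tier" not in classified.columns:
        raise ValueError("summarize_drivers requires classified variants (tier column)")
    meta = metadata.set_index("sample_id")["material"]
    material = classified["sample_id"].map(meta)
    if material.isna().any():
        missing = classified.loc[material.isna(), "sample_id"].unique()
        raise ValueError(f"samples without metadata: {list(missing)}")

    drivers = classified[classified["tier"].isin(DRIVER_TIERS)].copy()
    drivers["material"] = material.loc[drivers.index]
    is_ctdna = drivers["material"].isin(CTDNA_MATERIALS)
    ctdna = drivers[is_ctdna]

    patient = drivers[~drivers["material"].isin(CELL_LINE_MATERIALS)]
    path_patient = patient[patient["tier"] == "pathogenic"]

    return DriverSummary(
        n_ctdna_samples_with_driver=int(ctdna["sample_id"].nunique()),
        n_ctdna_driver_variants=int(len(ctdna)),
        gene_sample_counts=drivers.groupby("gene")["sample_id"].nunique().to_dict(),
        gene_sample_counts_ctdna=ctdna.groupby("gene")["sample_id"].nunique().to_dict(),
        gene_variant_counts_ctdna=ctdna.groupby("gene").size().to_dict(),
        gene_pathogenic_patient_counts=path_patient.groupby("gene").size().to_dict(),
        per_sample_driver_counts=drivers.groupby("sample_id").size().to_dict(),
    )
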