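"""Cross-compartment and longitudinal variant comparison, and tumour purity
from VAF.

A liquid biopsy samples the pooled DNA of every tumour site while a needle
biopsy samples one; comparing the two call sets per patient therefore
splits the union into ``shared``, ``ctDNA_only`` and ``tumour_only``
variants, the tabular equivalent of a two-set Venn diagram.  Across
timepoints, per-variant VAF series are labelled for clonal dynamics
(emergent / lost / rising / falling / stable / lost_then_emergent).

Purity (tumour-cell content) follows from VAF through an explicit mixing
model of tumour and normal cells:

* heterozygous variant in a diploid tumour — tumour cells carry 1 alt of 2
  alleles, normal cells 0 of 2::

      vaf = p/2            =>  purity = 2·vaf

* homozygous variant after loss of heterozygosity — tumour cells are
  hemizygous mutant (1 alt of 1 allele), normal cells diploid reference::

      vaf = p/(2 − p)      =>  purity = 2·vaf/(1 + vaf)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .variants import KEY_COLUMNS

MATERIALS = ("ctDNA_blood", "ctDNA_bonemarrow", "tumour", "germline", "cell_line")
TIMEPOINTS = ("diagnosis", "post_chemo", "remission", "relapse")
RISK_GROUPS = ("low", "intermediate", "high")
ASSAYS = ("tNGS", "WGS", "ddPCR", "sanger", "agena")

COPY_STATES = ("het_diploid", "hom_loh")


@dataclass(frozen=True)
class SampleMeta:
    """Identity and context of one sequenced sample."""

    sample_id: str
    patient_id: str
    material: str
    timepoint: str | None = None
    risk_group: str | None = None
    assay: str = "tNGS"

    def __post_init__(self) -> None:
        if self.material not in MATERIALS:
            raise ValueError(f"unknown material {self.material!r}")
        if self.timepoint is not None and self.timepoint not in TIMEPOINTS:
            raise ValueError(f"unknown timepoint {self.timepoint!r}")
        if self.risk_group is not None and self.risk_group not in RISK_GROUPS:
            raise ValueError(f"unknown risk group {self.risk_group!r}")


@dataclass
class ConcordancePair:
    """One variant of the cross-compartment union and where it was seen."""

    key: tuple
    gene: str
    category: str  # shared | ctDNA_only | tumour_only
    vaf_ctdna: float | None = None
    vaf_tumour: float | None = None


# ---------------------------------------------------------------------------
# compartment concordance


def classify_concordance(
    ctdna: pd.DataFrame,
    tumour: pd.DataFrame,
    meta: dict[str, SampleMeta] | None = None,
) -> tuple[list[ConcordancePair], dict[str, int]]:
    """Categorise the union of two driver call sets by compartment.

    Matching is on genomic key (chrom, pos, ref, alt).  When sample
    metadata is supplied, the two compartments must come from the same
    patient; mismatched patients raise.
    Returns the per-variant pairs and the Venn counts
    ``{"shared": ..., "ctDNA_only": ..., "tumour_only": ...}``.
    """
    if meta is not None:
        patients = set()
        for df in (ctdna, tumour):
            for sid in df.get("sample_id", pd.Series(dtype=object)).unique():
                if sid not in meta:
                    raise ValueError(f"sample {sid} has no metadata")
                patients.add(meta[sid].patient_id)
        if len(patients) > 1:
            raise ValueError(f"concordance pairs require one patient, got {sorted(patients)}")

    def _index(df: pd.DataFrame) -> dict[tuple, pd.Series]:
        out = {}
        for _, row in df.iterrows():
            out[tuple(row[k] for k in KEY_COLUMNS)] = row
        return out

    ct_idx, tu_idx = _index(ctdna), _index(tumour)
    pairs: list[ConcordancePair] = []
    for key in sorted(set(ct_idx) | set(tu_idx), key=str):
        in_ct, in_tu = key in ct_idx, key in tu_idx
        cat = "shared" if (in_ct and in_tu) else ("ctDNA_only" if in_ct else "tumour_only")
        row = ct_idx.get(key, tu_idx.get(key))
        pairs.append(
            ConcordancePair(
                key=key,
                gene=row.get("gene"),
                category=cat,
                vaf_ctdna=float(ct_idx[key]["vaf"]) if in_ct else None,
                vaf_tumour=float(tu_idx[key]["vaf"]) if in_tu else None,
            )
        )
    counts = {"shared": 0, "ctDNA_only": 0, "tumour_only": 0}
    for p in pairs:
        counts[p.category] += 1
    return pairs, counts


# ---------------------------------------------------------------------------
# longitudinal trajectories


def vaf_trajectory(
    samples: list[tuple[str, pd.DataFrame]],
    reporting_vaf: float = 0.01,
    rel_tol: float = 0.2,
) -> pd.DataFrame:
    """Label per-variant VAF dynamics across ordered timepoints.

    ``samples`` is a list of ``(timepoint, variant_table)`` in temporal
    order (at least two).  A variant is *present* at a timepoint when its
    VAF exceeds ``reporting_vaf``; below-threshold observations count as
    absent for labelling but their raw VAF is retained in the series.

    Labels: ``emergent`` (absent then present), ``lost`` (present then
    absent for good), ``lost_then_emergent`` (present, cleared, returned —
    a nonmonotone treatment-response pattern), ``rising``/``falling``
    (present throughout, monotone relative change beyond ``rel_tol``),
    ``stable`` otherwise.
    """
    if len(samples) < 2:
        raise ValueError("trajectory needs at least two timepoints")
    timepoints = [tp for tp, _ in samples]
    series: dict[tuple, dict] = {}
    for tp, df in samples:
        for _, row in df.iterrows():
            key = tuple(row[k] for k in KEY_COLUMNS)
            rec = series.setdefault(key, {"gene": row.get("gene"),
                                          "protein_change": row.get("protein_change"),
                                          "vafs": {t: 0.0 for t in timepoints}})
            rec["vafs"][tp] = float(row["vaf"])

    rows = []
    for key, rec in sorted(series.items(), key=lambda kv: str(kv[0])):
        vafs = [rec["vafs"][t] for t in timepoints]
        present = [v > reporting_vaf for v in vafs]
        rows.append({
            "chrom": key[0], "pos": key[1], "ref": key[2], "alt": key[3],
            "gene": rec["gene"], "protein_change": rec["protein_change"],
            **{f"vaf_{t}": v for t, v in zip(timepoints, vafs)},
            "event": _label_series(vafs, present, rel_tol),
        })
    return pd.DataFrame(rows)


def _label_series(vafs: list[float], present: list[bool], rel_tol: float) -> str:
    if not any(present):
        return "stable"  # never detected: flat at zero
    first, last = present[0], present[-1]
    # any present -> absent -> present excursion is a nonmonotone pattern
    went_absent_after_present = False
    for i in range(1, len(present)):
        if present[i - 1] and not present[i]:
            went_absent_after_present = True
        if went_absent_after_present and present[i]:
            return "lost_then_emergent"
    if first and not last:
        return "lost"
    if not first and last:
        return "emergent"
    # present at both ends without clearing: look at monotone VAF change
    obs = [v for v, p in zip(vafs, present) if p]
    lo, hi = min(obs), max(obs)
    if obs[-1] >= obs[0] * (1 + rel_tol) and obs == sorted(obs):
        return "rising"
    if obs[-1] <= obs[0] * (1 - rel_tol) and obs == sorted(obs, reverse=True):
        return "falling"
    return "stable"


# ---------------------------------------------------------------------------
# purity from VAF


@dataclass
class PurityEstimate:
    vaf: float
    copy_state: str
    purity: float
    clipped: bool = False


def forward_mix(purity: float, copy_state: str) -> float:
    """Expected VAF when tumour cells at ``purity`` mix with normal cells.

    het_diploid: tumour cells contribute 1 alt / 2 alleles; hom_loh: tumour
    cells are hemizygous mutant (1 alt / 1 allele) against diploid-reference
    normal cells.
    """
    if not 0 <= purity <= 1:
        raise ValueError(f"purity must be in [0,1], got {purity}")
    if copy_state == "het_diploid":
        return purity / 2.0
    if copy_state == "hom_loh":
        return purity / (2.0 - purity)
    raise ValueError(f"unsupported copy state {copy_state!r}; expected one of {COPY_STATES}")


def purity_from_vaf(vaf: float, copy_state: str) -> PurityEstimate:
    """Invert the mixing model: tumour-cell content implied by a VAF."""
    if not 0 <= vaf <= 1:
        raise ValueError(f"vaf must be in [0,1], got {vaf}")
    if copy_state == "het_diploid":
        if vaf == 1.0:
            raise ValueError("VAF 1.0 is impossible for a heterozygous diploid variant")
        purity = 2.0 * vaf
    elif copy_state == "hom_loh":
        purity = 2.0 * vaf / (1.0 + vaf)
    else:
        raise ValueError(f"unsupported copy state {copy_state!r}; expected one of {COPY_STATES}")
    clipped = purity > 1.0
    return PurityEstimate(vaf=vaf, copy_state=copy_state,
                          purity=min(purity, 1.0), clipped=clipped)
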