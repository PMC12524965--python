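"""Synthetic panel data with known ground truth.

Every downstream stage (filtering, tiering, CNV calling, concordance,
ddPCR) is exercised against data generated here, so parameter recovery can
be checked against the exact truth that produced the data.  The generator
emulates the *output* of a UMI-consensus targeted pipeline — an annotated
variant table and a per-target coverage table — not reads.

Somatic signal model: a tumour of purity ``p`` mixed with normal cells.
A clone at clonal fraction ``f`` carrying a heterozygous diploid variant
has expected VAF ``p·f/2``; a homozygous variant after LOH has expected
VAF ``q/(2−q)`` with ``q = p·f`` (see :mod:`liquidpanel.concordance`).
Alt reads are drawn binomially at a lognormal per-target depth centred on
``mean_depth`` (study-scale default 2228×).  Germline SNPs appear at VAF
≈ 50% or 100% with their population MAF recorded; artefacts appear below
0.5% VAF and never carry a COSMIC ID.  A gene amplified to copy number
``C`` in tumour cells of purity ``p`` has expected relative coverage
``(2(1−p) + C·p)/2`` of the copy-neutral level.

All simulators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .concordance import SampleMeta, forward_mix, COPY_STATES
from .ddpcr import DropletCounts
from .panel import PanelDefinition, default_panel
from .variants import as_variant_table, empty_variant_table
from .cnv import COVERAGE_COLUMNS

#: Study-scale mean UMI consensus depth.
DEFAULT_MEAN_DEPTH = 2228

# Annotation score ranges by truth label: drawn so that the configured
# pathogenic/benign ranges do not overlap on REVEL.
REVEL_PATHOGENIC_RANGE = (0.72, 0.99)
REVEL_BENIGN_RANGE = (0.0, 0.5)

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class CloneVariant:
    """One somatic variant carried by a tumour clone."""

    gene: str
    clonal_fraction: float
    copy_state: str = "het_diploid"
    chrom: str | None = None
    pos: int | None = None
    ref: str | None = None
    alt: str | None = None
    protein_change: str | None = None
    base_change: str | None = None
    pathogenic: bool = True
    consequence: str = "missense"

    def __post_init__(self) -> None:
        if not 0 < self.clonal_fraction <= 1:
            raise ValueError("clonal fraction must be in (0,1]")
        if self.copy_state not in COPY_STATES:
            raise ValueError(f"unsupported copy state {self.copy_state!r}")


@dataclass(frozen=True)
class GermlineSNP:
    chrom: str
    pos: int
    ref: str
    alt: str
    maf: float
    gene: str | None = None

    def __post_init__(self) -> None:
        if not 0 < self.maf <= 0.5:
            raise ValueError("population MAF must be in (0, 0.5]")


@dataclass
class SimulationTruth:
    """Ground-truth record from which one sample's data is generated."""

    purity: float
    clones: list[CloneVariant] = field(default_factory=list)
    amplified_genes: dict[str, int] = field(default_factory=dict)
    germline_snps: list[GermlineSNP] = field(default_factory=list)
    artifact_rate: float = 0.05  # expected artefacts per panel target
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.purity <= 1:
            raise ValueError(f"purity must be in [0,1], got {self.purity}")
        for gene, cn in self.amplified_genes.items():
            if cn < 0 or int(cn) != cn:
                raise ValueError(f"copy number for {gene} must be a non-negative integer")
        if self.artifact_rate < 0:
            raise ValueError("artifact_rate must be >= 0")

    def expected_vaf(self, clone: CloneVariant) -> float:
        return forward_mix(self.purity * clone.clonal_fraction, clone.copy_state)


def random_germline_snps(panel: PanelDefinition, n: int, seed: int,
                         maf_low: float = 0.01, maf_high: float = 0.5) -> list[GermlineSNP]:
    """Place ``n`` common SNPs at random panel positions with MAF ~ U[lo, hi]."""
    rng = np.random.default_rng(seed)
    snps = []
    targets = panel.targets
    for i in range(n):
        t = targets[int(rng.integers(len(targets)))]
        pos = int(rng.integers(t.start + 1, t.end + 1))  # 1-based
        ref, alt = rng.choice(_BASES, size=2, replace=False)
        snps.append(GermlineSNP(chrom=t.chrom, pos=pos, ref=str(ref), alt=str(alt),
                                maf=float(rng.uniform(maf_low, maf_high)), gene=t.gene))
    return snps


def _lognormal(rng: np.random.Generator, mean: float, cv: float, size=None):
    """Lognormal draws with the given arithmetic mean and coefficient of variation."""
    if cv == 0:
        return np.full(size, mean) if size is not None else mean
    sigma2 = np.log1p(cv**2)
    mu = np.log(mean) - sigma2 / 2
    return rng.lognormal(mu, np.sqrt(sigma2), size=size)


def _pathogenic_annotations(rng: np.random.Generator, missing_revel: bool) -> dict:
    return {
        "sift_score": round(float(rng.uniform(0.0, 0.05)), 3),
        "sift_call": "deleterious",
        "polyphen_score": round(float(rng.uniform(0.85, 1.0)), 3),
        "polyphen_call": "PRD",
        "revel_score": None if missing_revel else round(float(rng.uniform(*REVEL_PATHOGENIC_RANGE)), 3),
        "cosmic_id": f"COSV{int(rng.integers(10_000_000, 99_999_999))}",
    }


def _benign_annotations(rng: np.random.Generator) -> dict:
    return {
        "sift_score": round(float(rng.uniform(0.2, 1.0)), 3),
        "sift_call": "tolerated",
        "polyphen_score": round(float(rng.uniform(0.0, 0.4)), 3),
        "polyphen_call": "B",
        "revel_score": round(float(rng.uniform(*REVEL_BENIGN_RANGE)), 3),
        "cosmic_id": None,
    }


def simulate_variant_table(
    truth: SimulationTruth,
    panel: PanelDefinition | None = None,
    mean_depth: float = DEFAULT_MEAN_DEPTH,
    depth_cv: float = 0.3,
    missing_revel_fraction: float = 0.1,
    sample_id: str = "SIM1",
) -> pd.DataFrame:
    """Generate the annotated variant table of one sample.

    Emits somatic clone variants, germline SNPs and low-VAF artefacts with
    annotations drawn from non-overlapping score distributions according to
    each variant's truth label.  Rows whose binomial draw yields zero alt
    reads are not emitted (a caller only reports supported alleles).
    Truth labels travel in ``truth_class`` / ``truth_expected_vaf`` columns.
    """
    if mean_depth <= 0:
        raise ValueError("mean_depth must be > 0")
    panel = panel or default_panel()
    rng = np.random.default_rng(truth.seed)
    gene_pos_cursor: dict[str, int] = {}
    records: list[dict] = []

    for clone in truth.clones:
        exp_vaf = truth.expected_vaf(clone)
        chrom, pos, ref, alt = clone.chrom, clone.pos, clone.ref, clone.alt
        if chrom is None or pos is None:
            targets = panel.targets_for(clone.gene)
            if not targets:
                raise ValueError(f"clone gene {clone.gene} not on panel and no coordinates given")
            t = targets[0]
            offset = gene_pos_cursor.get(clone.gene, 0)
            gene_pos_cursor[clone.gene] = offset + 7
            chrom, pos = t.chrom, t.start + 1 + offset
        if ref is None or alt is None:
            ref, alt = (str(b) for b in rng.choice(_BASES, size=2, replace=False))
        depth = max(1, int(round(_lognormal(rng, mean_depth, depth_cv))))
        alt_reads = int(rng.binomial(depth, exp_vaf))
        missing_revel = clone.pathogenic and (rng.uniform() < missing_revel_fraction)
        ann = (_pathogenic_annotations(rng, missing_revel) if clone.pathogenic
               else _benign_annotations(rng))
        if alt_reads == 0:
            continue
        records.append({
            "sample_id": sample_id, "gene": clone.gene, "chrom": chrom, "pos": pos,
            "ref": ref, "alt": alt, "vaf": alt_reads / depth, "depth": depth,
            "base_change": clone.base_change, "protein_change": clone.protein_change,
            "consequence": clone.consequence, **ann,
            "gnomad_af": None, "dbsnp_common_maf": None,
            "truth_class": "somatic_driver" if clone.pathogenic else "somatic_passenger",
            "truth_expected_vaf": exp_vaf,
        })

    for snp in truth.germline_snps:
        # genotype by Hardy-Weinberg conditional on carrying the allele
        p_hom = snp.maf**2 / (snp.maf**2 + 2 * snp.maf * (1 - snp.maf))
        hom = rng.uniform() < p_hom
        exp_vaf = 1.0 if hom else 0.5
        depth = max(1, int(round(_lognormal(rng, mean_depth, depth_cv))))
        alt_reads = int(rng.binomial(depth, exp_vaf))
        ann = _benign_annotations(rng)
        if alt_reads == 0:
            continue
        records.append({
            "sample_id": sample_id, "gene": snp.gene, "chrom": snp.chrom, "pos": snp.pos,
            "ref": snp.ref, "alt": snp.alt, "vaf": alt_reads / depth, "depth": depth,
            "consequence": "other", **ann,
            "gnomad_af": snp.maf, "dbsnp_common_maf": snp.maf,
            "truth_class": "germline_snp", "truth_expected_vaf": exp_vaf,
        })

    n_artifacts = int(rng.poisson(truth.artifact_rate * len(panel.targets)))
    for i in range(n_artifacts):
        t = panel.targets[int(rng.integers(len(panel.targets)))]
        pos = int(rng.integers(t.start + 1, t.end + 1))
        ref, alt = (str(b) for b in rng.choice(_BASES, size=2, replace=False))
        exp_vaf = float(rng.uniform(0.0005, 0.0049))
        depth = max(1, int(round(_lognormal(rng, mean_depth, depth_cv))))
        alt_reads = int(rng.binomial(depth, exp_vaf))
        ann = _benign_annotations(rng)
        if alt_reads == 0:
            continue
        records.append({
            "sample_id": sample_id, "gene": t.gene, "chrom": t.chrom, "pos": pos,
            "ref": ref, "alt": alt, "vaf": alt_reads / depth, "depth": depth,
            "consequence": "other", **ann, "cosmic_id": None,
            "gnomad_af": None, "dbsnp_common_maf": None, "artifact_flag": False,
            "truth_class": "artifact", "truth_expected_vaf": exp_vaf,
        })

    if not records:
        df = empty_variant_table()
        for col in ("truth_class", "truth_expected_vaf"):
            df[col] = pd.Series(dtype=object)
        return df
    df = as_variant_table(records)
    # drop accidental key collisions (same random position drawn twice)
    df = df.drop_duplicates(subset=["sample_id", "chrom", "pos", "ref", "alt"], keep="first")
    return df.reset_index(drop=True)


def simulate_coverage(
    truth: SimulationTruth,
    panel: PanelDefinition | None = None,
    noise_cv: float = 0.1,
    seed: int | None = None,
    mean_depth: float = DEFAULT_MEAN_DEPTH,
    x_ploidy: int = 2,
    sample_id: str = "SIM1",
) -> pd.DataFrame:
    """Generate per-target UMI coverage for one sample.

    Expected relative coverage of a gene at tumour copy number ``C`` and
    purity ``p`` is ``(2(1−p) + C·p)/2``; X-chromosome targets are scaled
    by ``x_ploidy/2``.  Multiplicative lognormal noise with coefficient of
    variation ``noise_cv``.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    panel = panel or default_panel()
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    p = truth.purity
    rows = []
    for t in panel.targets:
        cn = truth.amplified_genes.get(t.gene, 2)
        rel = (2 * (1 - p) + cn * p) / 2.0
        if t.gene in panel.chrx_genes or t.chrom in {"chrX", "X"}:
            rel *= x_ploidy / 2.0
        depth = mean_depth * rel * float(_lognormal(rng, 1.0, noise_cv))
        rows.append({
            "sample_id": sample_id, "target_id": t.target_id, "gene": t.gene,
            "chrom": t.chrom, "start": t.start, "end": t.end,
            "umi_depth": depth,
        })
    return pd.DataFrame(rows, columns=COVERAGE_COLUMNS)


def expected_relative_coverage(purity: float, copy_number: int) -> float:
    """Closed-form fold change over copy-neutral: (2(1−p) + C·p)/2."""
    return (2 * (1 - purity) + copy_number * purity) / 2.0


def simulate_droplets(lambda_wt: float, lambda_mut: float, n_droplets: int,
                      seed: int) -> DropletCounts:
    """Partition templates over droplets; positives are Binomial(n, 1−e^{−λ})."""
    if lambda_wt < 0 or lambda_mut < 0:
        raise ValueError("lambda must be >= 0")
    if n_droplets <= 0:
        raise ValueError("n_droplets must be > 0")
    rng = np.random.default_rng(seed)
    p_wt = 1.0 - np.exp(-lambda_wt)
    p_mut = 1.0 - np.exp(-lambda_mut)
    return DropletCounts(
        n_total=n_droplets,
        n_mut_pos=int(rng.binomial(n_droplets, p_mut)),
        n_wt_pos=int(rng.binomial(n_droplets, p_wt)),
    )


# ---------------------------------------------------------------------------
# canonical longitudinal scenario

ALK_R1275Q = CloneVariant(
    gene="ALK", clonal_fraction=0.1, chrom="chr2", pos=29432664, ref="G", alt="A",
    protein_change="p.(R1275Q)", base_change="c.(3824G>A)",
)
ALK_F1174L = CloneVariant(
    gene="ALK", clonal_fraction=1.0, chrom="chr2", pos=29443695, ref="C", alt="A",
    protein_change="p.(F1174L)", base_change="c.(3522C>A)",
)


@dataclass
class ClonalEvolutionScenario:
    """Multi-timepoint sample set emulating two co-occurring ALK clones.

    At diagnosis the plasma carries both clones (the major F1174L clone and
    a minor R1275Q clone) while the single-site tumour biopsy samples only
    the R1275Q-bearing region.  Therapy clears the detectable disease; at
    relapse the F1174L clone returns alone, near-fixed in ctDNA.

    ``samples`` maps sample name → ``(SampleMeta, variant_table)``;
    ``truth_events`` maps protein change → expected ctDNA trajectory label;
    ``truth_concordance_diagnosis`` maps protein change → expected
    ctDNA-vs-tumour category at diagnosis.
    """

    samples: dict[str, tuple[SampleMeta, pd.DataFrame]]
    truth_events: dict[str, str]
    truth_concordance_diagnosis: dict[str, str]
    ctdna_timepoint_order: tuple[str, ...] = ("diagnosis", "remission", "relapse")


def scenario_clonal_evolution(seed: int = 0, panel: PanelDefinition | None = None,
                              mean_depth: float = 5000) -> ClonalEvolutionScenario:
    """Build the canonical two-clone ALK clonal-evolution case.

    Expected VAFs: diagnosis ctDNA 28.5% (F1174L) and 2.85% (R1275Q);
    diagnosis tumour 32% (R1275Q only); remission ctDNA none; relapse
    tumour 46.1% and relapse ctDNA ~98% (F1174L homozygous via LOH of the
    wild-type allele).
    """
    panel = panel or default_panel()
    patient = "P_ctD4"

    def tbl(truth: SimulationTruth, sid: str) -> pd.DataFrame:
        return simulate_variant_table(truth, panel, mean_depth=mean_depth,
                                      depth_cv=0.1, missing_revel_fraction=0.0,
                                      sample_id=sid)

    diag_ct = SimulationTruth(purity=0.57, clones=[ALK_R1275Q, ALK_F1174L],
                              artifact_rate=0.02, seed=seed * 10 + 1)
    diag_tu = SimulationTruth(purity=0.64, clones=[replace(ALK_R1275Q, clonal_fraction=1.0)],
                              artifact_rate=0.0, seed=seed * 10 + 2)
    remission = SimulationTruth(purity=0.0, clones=[ALK_R1275Q, ALK_F1174L],
                                artifact_rate=0.02, seed=seed * 10 + 3)
    relapse_ct = SimulationTruth(
        purity=2 * 0.98 / (1 + 0.98),  # hom_loh mixing inverted at VAF 0.98
        clones=[replace(ALK_F1174L, copy_state="hom_loh")],
        artifact_rate=0.02, seed=seed * 10 + 4)
    relapse_tu = SimulationTruth(purity=0.922, clones=[ALK_F1174L],
                                 artifact_rate=0.0, seed=seed * 10 + 5)

    def meta(sid: str, material: str, timepoint: str, assay: str = "tNGS") -> SampleMeta:
        return SampleMeta(sample_id=sid, patient_id=patient, material=material,
                          timepoint=timepoint, risk_group="high", assay=assay)

    samples = {
        "diagnosis_ctdna": (meta("ctD4", "ctDNA_blood", "diagnosis"), tbl(diag_ct, "ctD4")),
        "diagnosis_tumour": (meta("T4_diag", "tumour", "diagnosis", "sanger"), tbl(diag_tu, "T4_diag")),
        "remission_ctdna": (meta("ctD4_rem", "ctDNA_blood", "remission", "ddPCR"), tbl(remission, "ctD4_rem")),
        "relapse_ctdna": (meta("ctD4_rel", "ctDNA_blood", "relapse", "ddPCR"), tbl(relapse_ct, "ctD4_rel")),
        "relapse_tumour": (meta("T4_rel", "tumour", "relapse", "tNGS"), tbl(relapse_tu, "T4_rel")),
    }
    return ClonalEvolutionScenario(
        samples=samples,
        truth_events={"p.(R1275Q)": "lost", "p.(F1174L)": "lost_then_emergent"},
        truth_concordance_diagnosis={"p.(R1275Q)": "shared", "p.(F1174L)": "ctDNA_only"},
    )
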