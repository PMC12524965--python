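"""Readers, writers, run configuration and the end-to-end pipeline driver.

Formats
-------
* variants: VCF 4.2 (uncompressed text, via pysam) or the published-table
  TSV dialect (``table1_tsv``).  VCF positions are 1-based and preserved;
  BED intervals are 0-based half-open.  Numeric INFO values are serialized
  as strings holding the full ``repr`` so that write→read round-trips are
  exact (VCF ``Float`` INFO is 32-bit in htslib and would truncate).
* coverage: TSV with columns ``sample_id, target_id, gene, chrom, start,
  end, umi_depth``.
* panel: BED3 + gene + target_id columns.
* metadata: TSV with ``sample_id, patient_id, material, timepoint,
  risk_group, assay[, cfdna_fraction]``.
* droplets: CSV with ``well, target, n_total, n_mut_pos, n_wt_pos``.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
import yaml

from . import __version__
from .classify import classify_table, summarize_drivers, DriverSummary
from .cnv import CoverageZScoreCaller, COVERAGE_COLUMNS
from .concordance import classify_concordance, SampleMeta
from .ddpcr import DropletCounts, quantify
from .filtering import (FilterConfig, VariantFilter, apply_reporting_threshold,
                        matched_germline_subtract, qc_sample)
from .panel import PanelDefinition, PanelTarget
from .variants import VARIANT_COLUMNS, as_variant_table, empty_variant_table, validate_variants

logger = logging.getLogger(__name__)

FIXTURE_DIR = Path(__file__).parent / "fixtures"
TABLE1_FIXTURE = FIXTURE_DIR / "table1.tsv"

# INFO keys <-> canonical columns (all serialized as VCF String to keep
# full float precision; '' encodes missing)
_INFO_MAP = {
    "VAF": "vaf", "DP": "depth", "GENE": "gene",
    "BASE_CHANGE": "base_change", "PROTEIN_CHANGE": "protein_change",
    "CONSEQUENCE": "consequence",
    "SIFT": "sift_score", "SIFT_CALL": "sift_call",
    "POLYPHEN": "polyphen_score", "POLYPHEN_CALL": "polyphen_call",
    "REVEL": "revel_score", "COSMIC_ID": "cosmic_id",
    "GNOMAD_AF": "gnomad_af", "DBSNP_MAF": "dbsnp_common_maf",
    "SAMPLE": "sample_id",
}
_FLOAT_COLUMNS = {"vaf", "sift_score", "polyphen_score", "revel_score",
                  "gnomad_af", "dbsnp_common_maf"}
_INT_COLUMNS = {"depth"}


# ---------------------------------------------------------------------------
# variants


def write_vcf(variants: pd.DataFrame, path: str | Path) -> Path:
    """Write a variant table as a site-level VCF 4.2 text file."""
    path = Path(path)
    header = pysam.VariantHeader()
    for key in _INFO_MAP:
        if _INFO_MAP[key] in _INT_COLUMNS:
            header.info.add(key, 1, "Integer", _INFO_MAP[key])
        else:
            header.info.add(key, 1, "String", f"{_INFO_MAP[key]} (full-precision string)")
    header.info.add("ARTIFACT", 0, "Flag", "flagged recurrent artefact")
    header.info.add("DUPLICATE", 0, "Flag", "flagged PCR duplicate")
    chroms = sorted({str(c) for c in variants["chrom"].dropna().unique()})
    for c in chroms:
        header.contigs.add(c, length=300_000_000)
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        ordered = variants.sort_values(["chrom", "pos", "ref", "alt", "sample_id"],
                                       kind="stable")
        for _, row in ordered.iterrows():
            rec = vf.new_record(
                contig=str(row["chrom"]),
                start=int(row["pos"]) - 1,
                stop=int(row["pos"]),
                alleles=(str(row["ref"]), str(row["alt"])),
            )
            for key, col in _INFO_MAP.items():
                val = row.get(col)
                if val is None or (isinstance(val, float) and np.isnan(val)) or pd.isna(val):
                    continue
                if col in _FLOAT_COLUMNS:
                    rec.info[key] = repr(float(val))
                elif col in _INT_COLUMNS:
                    rec.info[key] = int(val)
                else:
                    rec.info[key] = str(val).replace(";", "_").replace(" ", "_")
            if bool(row.get("artifact_flag")):
                rec.info["ARTIFACT"] = True
            if bool(row.get("duplicate_flag")):
                rec.info["DUPLICATE"] = True
            vf.write(rec)
    return path


def _read_vcf(path: Path) -> pd.DataFrame:
    records = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            row: dict = {
                "chrom": rec.chrom, "pos": rec.pos,
                "ref": rec.ref, "alt": rec.alts[0] if rec.alts else None,
            }
            for key, col in _INFO_MAP.items():
                if key in rec.info:
                    val = rec.info[key]
                    if isinstance(val, tuple):
                        val = val[0]
                    if col in _FLOAT_COLUMNS:
                        row[col] = float(val)
                    elif col in _INT_COLUMNS:
                        row[col] = int(val)
                    else:
                        row[col] = str(val)
            row["artifact_flag"] = "ARTIFACT" in rec.info
            row["duplicate_flag"] = "DUPLICATE" in rec.info
            records.append(row)
    if not records:
        return empty_variant_table()
    return as_variant_table(records)


_BASE_CHANGE_RE = re.compile(r"c\.\(?\d+([ACGT])>([ACGT])\)?$")


def _read_table1_tsv(path: Path) -> pd.DataFrame:
    """Parse the published-table TSV dialect.

    Columns: sample, material, vaf_percent, gene, chrom_location,
    base_change, protein_change, cosmic_id, sift_call, sift_score,
    polyphen_call, polyphen_score, revel_score, consequence.
    VAF is printed in percent; positions are not printed, so ref/alt are
    recovered from the coding change where it is a substitution and the
    genomic key is left blank otherwise.  Depth is not printed and left
    missing.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    records = []
    for ln, row in raw.iterrows():
        def _get(col, cast=None):
            v = row.get(col, "")
            if v is None or str(v).strip() in {"", "N/A", "NA"}:
                return None
            return cast(v) if cast else str(v).strip()

        try:
            base_change = _get("base_change")
            ref = alt = None
            if base_change:
                m = _BASE_CHANGE_RE.search(base_change.replace(" ", ""))
                if m:
                    ref, alt = m.group(1), m.group(2)
            chrom_loc = _get("chrom_location") or ""
            chrom = chrom_loc.split()[0] if chrom_loc else None
            sift_call = _get("sift_call")
            records.append({
                "sample_id": _get("sample"),
                "material": _get("material"),
                "gene": _get("gene"),
                "chrom": chrom, "pos": None, "ref": ref, "alt": alt,
                "vaf": _get("vaf_percent", float) / 100.0,
                "depth": None,
                "base_change": base_change,
                "protein_change": _get("protein_change"),
                "consequence": _get("consequence") or "missense",
                "cosmic_id": _get("cosmic_id"),
                "sift_call": "deleterious" if sift_call == "Del" else sift_call,
                "sift_score": _get("sift_score", float),
                "polyphen_call": _get("polyphen_call"),
                "polyphen_score": _get("polyphen_score", float),
                "revel_score": _get("revel_score", float),
            })
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: malformed row at line {ln + 2}: {exc}") from exc
    return as_variant_table(records)


def read_variants(path: str | Path, dialect: str = "vcf") -> pd.DataFrame:
    """Read an annotated variant table (``vcf`` or ``table1_tsv`` dialect)."""
    path = Path(path)
    if dialect == "vcf":
        df = _read_vcf(path)
    elif dialect == "table1_tsv":
        df = _read_table1_tsv(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}; expected 'vcf' or 'table1_tsv'")
    return validate_variants(df, context=str(path))


def load_table1_fixture() -> pd.DataFrame:
    """The bundled machine-readable transcription of the published variant table."""
    return read_variants(TABLE1_FIXTURE, dialect="table1_tsv")


def table1_metadata() -> pd.DataFrame:
    """Sample metadata for the bundled fixture, inferred from sample naming."""
    df = load_table1_fixture()
    rows = []
    for sid, grp in df.groupby("sample_id"):
        rows.append({"sample_id": sid, "patient_id": sid,
                     "material": grp["material"].iloc[0]})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# coverage / panel / metadata / droplets


def write_coverage_tsv(coverage: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    coverage[COVERAGE_COLUMNS].to_csv(path, sep="\t", index=False)
    return path


def read_coverage_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in COVERAGE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: coverage TSV missing columns {missing}")
    return df


def write_panel_bed(panel: PanelDefinition, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for t in sorted(panel.targets, key=lambda t: (t.chrom, t.start)):
            fh.write(f"{t.chrom}\t{t.start}\t{t.end}\t{t.gene}\t{t.target_id}\n")
    return path


def read_panel_bed(path: str | Path, chrx_genes: set[str] | None = None) -> PanelDefinition:
    targets = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 5:
                raise ValueError(f"{path}:{ln}: expected BED3+gene+target_id")
            chrom, start, end, gene, tid = parts[:5]
            targets.append(PanelTarget(target_id=tid, gene=gene, chrom=chrom,
                                       start=int(start), end=int(end)))
    genes = sorted({t.gene for t in targets})
    chrx = frozenset(chrx_genes) if chrx_genes is not None else frozenset(
        t.gene for t in targets if t.chrom in {"chrX", "X"})
    return PanelDefinition(targets=targets, genes=genes, chrx_genes=chrx)


def read_metadata_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "patient_id": str})
    for col in ("sample_id", "material"):
        if col not in df.columns:
            raise ValueError(f"{path}: metadata TSV missing column {col!r}")
    return df


def read_droplets_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    needed = ["well", "target", "n_total", "n_mut_pos", "n_wt_pos"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: droplet CSV missing columns {missing}")
    return df


def write_truth_json(truth, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(asdict(truth), fh, indent=2, default=str)
    return path


# ---------------------------------------------------------------------------
# run configuration and pipeline


@dataclass
class RunConfig:
    """Everything one pipeline run needs; round-trips through YAML/JSON."""

    variants_path: str
    metadata_path: str
    variants_dialect: str = "vcf"
    germline_path: str | None = None
    coverage_path: str | None = None
    panel_bed_path: str | None = None
    droplets_path: str | None = None
    filter: FilterConfig = field(default_factory=FilterConfig)
    z_amp: float = 5.0
    z_gain: float = 2.0
    trim_fraction: float = 0.05
    seed: int = 0
    out_dir: str = "liquidpanel_out"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["filter"] = self.filter.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if isinstance(d.get("filter"), dict):
            d["filter"] = FilterConfig.from_dict(d["filter"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
        return path

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class ReportBundle:
    """Tabular end-of-run report: every count re-derivable from the
    intermediate tables written next to it."""

    driver_summary: DriverSummary
    cnv_calls: dict          # sample_id -> list of gene-level call dicts
    concordance: dict        # patient_id -> Venn counts
    qc: dict                 # sample_id -> pass/fail
    ddpcr: list              # per-well quantification dicts
    provenance: dict

    def to_dict(self) -> dict:
        return {
            "driver_summary": self.driver_summary.to_dict(),
            "cnv_calls": self.cnv_calls,
            "concordance": self.concordance,
            "qc": self.qc,
            "ddpcr": self.ddpcr,
            "provenance": self.provenance,
        }

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
        return path


def run_pipeline(cfg: RunConfig) -> ReportBundle:
    """QC → filter → classify → CNV → concordance → report.

    Deterministic given the config (and its seed); samples with variants
    but no coverage, or coverage but no variants, are tolerated and
    reported with whatever evidence exists.
    """
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    meta = read_metadata_tsv(cfg.metadata_path)
    variants = read_variants(cfg.variants_path, cfg.variants_dialect)

    # sample-level QC on cfDNA fraction where recorded
    qc: dict[str, str] = {}
    if "cfdna_fraction" in meta.columns:
        for _, row in meta.iterrows():
            frac = row["cfdna_fraction"]
            if pd.notna(frac):
                qc[row["sample_id"]] = qc_sample(float(frac), cfg.filter)
    failed = {s for s, status in qc.items() if status == "fail"}
    if failed:
        logger.info("excluding QC-failed samples: %s", sorted(failed))
        variants = variants[~variants["sample_id"].isin(failed)]

    n_raw = len(variants)
    filt = VariantFilter(**cfg.filter.to_dict()).fit(variants)
    germline = None
    if cfg.germline_path:
        germline = read_variants(cfg.germline_path, cfg.variants_dialect)
    retained = filt.transform(variants)
    if germline is not None:
        retained = matched_germline_subtract(retained, germline)
    logger.info("filtering: %d raw -> %d retained", n_raw, len(retained))

    classified = classify_table(retained)
    reportable = apply_reporting_threshold(classified, cfg.filter)
    classified.to_csv(out_dir / "classified_variants.tsv", sep="\t", index=False)
    reportable.to_csv(out_dir / "reportable_drivers.tsv", sep="\t", index=False)
    summary = summarize_drivers(reportable, meta)

    # per-sample CNV calls (tolerate missing coverage)
    cnv_calls: dict[str, list] = {}
    if cfg.coverage_path:
        coverage = read_coverage_tsv(cfg.coverage_path)
        caller = CoverageZScoreCaller(z_amp=cfg.z_amp, z_gain=cfg.z_gain,
                                      trim_fraction=cfg.trim_fraction)
        scored_frames = []
        for sid, cov in coverage.groupby("sample_id"):
            calls = caller.fit_predict(cov)
            cnv_calls[str(sid)] = calls.to_dict(orient="records")
            scored_frames.append(caller.transform(cov))
        pd.concat(scored_frames).to_csv(out_dir / "target_zscores.tsv", sep="\t", index=False)

    # per-patient ctDNA vs tumour concordance on drivers
    concordance: dict[str, dict] = {}
    if "patient_id" in meta.columns:
        mat = meta.set_index("sample_id")["material"]
        pat = meta.set_index("sample_id")["patient_id"]
        rep = reportable.copy()
        rep["material"] = rep["sample_id"].map(mat)
        rep["patient_id"] = rep["sample_id"].map(pat)
        for pid, grp in rep.groupby("patient_id"):
            ct = grp[grp["material"].isin({"ctDNA_blood", "ctDNA_bonemarrow"})]
            tu = grp[grp["material"] == "tumour"]
            if len(ct) or len(tu):
                _, counts = classify_concordance(ct, tu)
                concordance[str(pid)] = counts

    ddpcr_out = []
    if cfg.droplets_path:
        for _, row in read_droplets_csv(cfg.droplets_path).iterrows():
            q = quantify(DropletCounts(n_total=int(row["n_total"]),
                                       n_mut_pos=int(row["n_mut_pos"]),
                                       n_wt_pos=int(row["n_wt_pos"])))
            ddpcr_out.append({"well": row["well"], "target": row["target"],
                              "lambda_mut": q.lambda_mut, "lambda_wt": q.lambda_wt,
                              "fractional_abundance": q.fractional_abundance,
                              "detected": q.detected})

    bundle = ReportBundle(
        driver_summary=summary,
        cnv_calls=cnv_calls,
        concordance=concordance,
        qc=qc,
        ddpcr=ddpcr_out,
        provenance={
            "config_hash": cfg.config_hash(),
            "seed": cfg.seed,
            "liquidpanel_version": __version__,
            "n_raw_variants": n_raw,
            "n_retained_variants": int(len(retained)),
            "n_reportable_drivers": int(len(reportable)),
        },
    )
    bundle.write(out_dir / "report.json")
    return bundle
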