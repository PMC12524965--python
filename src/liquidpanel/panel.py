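"""Gene-panel model: targets, genes and the bundled 42-gene neuroblastoma panel.

A targeted cfDNA panel is a set of non-overlapping genomic intervals
(*targets*), each belonging to exactly one gene.  Coverage is tabulated per
target; variants are annotated per gene.  X-chromosomal genes are flagged
because they are excluded from coverage baselines (copy number on chrX
depends on sex, not tumour biology).

Coordinates follow BED convention: 0-based, half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class PanelTarget:
    """One targeted interval of the capture panel."""

    target_id: str
    gene: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("target chromosome must be non-empty")
        if not self.start < self.end:
            raise ValueError(
                f"target {self.target_id}: start must be < end ({self.start} >= {self.end})"
            )


@dataclass
class PanelDefinition:
    """A capture panel: genes, their targets and the chrX-flagged subset."""

    targets: list[PanelTarget]
    genes: list[str]
    chrx_genes: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        gene_set = set(self.genes)
        for t in self.targets:
            if t.gene not in gene_set:
                raise ValueError(f"target {t.target_id} maps to unknown gene {t.gene}")
        # targets must not overlap within a gene
        by_gene: dict[str, list[PanelTarget]] = {}
        for t in self.targets:
            by_gene.setdefault(t.gene, []).append(t)
        for gene, ts in by_gene.items():
            ts = sorted(ts, key=lambda t: (t.chrom, t.start))
            for a, b in zip(ts, ts[1:]):
                if a.chrom == b.chrom and b.start < a.end:
                    raise ValueError(f"overlapping targets in gene {gene}: {a.target_id}/{b.target_id}")
        if not self.chrx_genes <= gene_set:
            raise ValueError("chrx_genes must be a subset of the panel genes")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def targets_for(self, gene: str) -> list[PanelTarget]:
        return [t for t in self.targets if t.gene == gene]

    def gene_of(self, target_id: str) -> str:
        for t in self.targets:
            if t.target_id == target_id:
                return t.gene
        raise KeyError(target_id)


# Core oncogenes / tumour-suppressors recurrently altered in neuroblastoma;
# the remainder fills the panel to its configured size with genes a
# paediatric solid-tumour panel would plausibly carry.
CORE_GENES: dict[str, str] = {
    "ALK": "chr2", "MYCN": "chr2", "TP53": "chr17", "PTPN11": "chr12",
    "KRAS": "chr12", "NRAS": "chr1", "CREBBP": "chr16", "SMARCA4": "chr19",
    "NF1": "chr17", "ATM": "chr11", "CHEK2": "chr22", "CDK4": "chr12",
    "MDM2": "chr12", "CCND1": "chr11", "FGFR1": "chr8",
}

FILLER_GENES: dict[str, str] = {
    "ATRX": "chrX", "DDX3X": "chrX", "PHOX2B": "chr4", "LIN28B": "chr6",
    "ARID1A": "chr1", "ARID1B": "chr6", "BARD1": "chr2", "BRCA2": "chr13",
    "CDKN2A": "chr9", "PTEN": "chr10", "BRAF": "chr7", "HRAS": "chr11",
    "MET": "chr7", "FGFR2": "chr10", "EZH2": "chr7", "SETD2": "chr3",
    "TERT": "chr5", "CIC": "chr19", "KIT": "chr4", "PDGFRA": "chr4",
    "RET": "chr10", "SOS1": "chr2", "RAF1": "chr3", "MYC": "chr8",
    "CDK6": "chr7", "CCND2": "chr12", "MDM4": "chr1",
}

DEFAULT_CHRX_GENES = frozenset({"ATRX", "DDX3X"})

#: Number of genes on the assay this package models.
DEFAULT_PANEL_SIZE = 42


def default_panel(n_genes: int = DEFAULT_PANEL_SIZE, targets_per_gene: int = 4) -> PanelDefinition:
    """Build the bundled panel: 15 core neuroblastoma genes plus fillers.

    Target coordinates are synthetic (the real capture design is proprietary);
    each gene gets ``targets_per_gene`` non-overlapping 250 bp targets laid out
    deterministically, which is all the coverage statistics depend on.
    """
    all_genes = {**CORE_GENES, **FILLER_GENES}
    if n_genes > len(all_genes):
        raise ValueError(f"at most {len(all_genes)} genes available, requested {n_genes}")
    genes = (list(CORE_GENES) + list(FILLER_GENES))[:n_genes]

    targets: list[PanelTarget] = []
    for gi, gene in enumerate(genes):
        chrom = all_genes[gene]
        base = 1_000_000 + gi * 100_000  # synthetic, well-separated loci
        for k in range(targets_per_gene):
            start = base + k * 1_000
            targets.append(
                PanelTarget(
                    target_id=f"{gene}_t{k + 1}",
                    gene=gene,
                    chrom=chrom,
                    start=start,
                    end=start + 250,
                )
            )
    chrx = DEFAULT_CHRX_GENES & set(genes)
    return PanelDefinition(targets=targets, genes=genes, chrx_genes=frozenset(chrx))
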