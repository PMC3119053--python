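"""SNP-to-gene mapping, distance categories, and the piebald-gene call.

Each SNP is assigned to its nearest gene on the same chromosome, measured to
the closer edge of the gene's 1-based inclusive interval (distance zero when
intragenic), and binned: intragenic, cis (<= 2.5 kb, putatively cis-acting),
proximal (<= 20 kb), distal (> 20 kb).  The piebald-gene call merges this map
with association and differential-expression evidence: a gene qualifies
either by being DE with a cis SNP, or by lacking DE but having a
significantly associated SNP within 1 Mb.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeTable

CIS_BP = 2_500
PROXIMAL_BP = 20_000
REGION_BP = 1_000_000

INTRAGENIC = "intragenic"
CIS = "cis"
PROXIMAL = "proximal"
DISTAL = "distal"
UNMAPPED = "unmapped"


@dataclass
class GeneAnnotation:
    gene_id: str
    chromosome: str
    start_bp: int
    end_bp: int

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError(f"gene {self.gene_id}: start_bp > end_bp")
        if self.start_bp < 1:
            raise ValueError(f"gene {self.gene_id}: coordinates are 1-based")


@dataclass
class SnpGeneMapping:
    snp_id: str
    nearest_gene_id: str | None
    distance_bp: int | None
    category: str
    genes_within_1Mb: set = field(default_factory=set)


def read_gene_annotation(path) -> list[GeneAnnotation]:
    """Read a BED-like TSV (chrom, start_bp, end_bp, gene_id; 1-based inclusive)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "gene_id": str})
    for col in ("chrom", "start_bp", "end_bp", "gene_id"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    genes = [
        GeneAnnotation(r.gene_id, r.chrom, int(r.start_bp), int(r.end_bp))
        for r in df.itertuples(index=False)
    ]
    if len({g.gene_id for g in genes}) != len(genes):
        raise ValueError(f"{path}: duplicate gene ids")
    return genes


def _as_gene_list(genes) -> list[GeneAnnotation]:
    if isinstance(genes, pd.DataFrame):
        return [
            GeneAnnotation(r.gene_id, r.chrom, int(r.start_bp), int(r.end_bp))
            for r in genes.itertuples(index=False)
        ]
    return list(genes)


def _snp_frame(snps) -> pd.DataFrame:
    if isinstance(snps, GenotypeTable):
        return pd.DataFrame(
            {"snp_id": snps.snp_ids, "chrom": snps.chromosomes, "bp": snps.positions}
        )
    return pd.DataFrame(snps, columns=["snp_id", "chrom", "bp"])


def classify_distance(distance_bp: int, intragenic: bool) -> str:
    if intragenic:
        return INTRAGENIC
    if distance_bp <= CIS_BP:
        return CIS
    if distance_bp <= PROXIMAL_BP:
        return PROXIMAL
    return DISTAL


def map_snps_to_genes(snps, genes, region_bp: int = REGION_BP) -> list[SnpGeneMapping]:
    """Assign each SNP its nearest same-chromosome gene and a distance category.

    ``snps`` is a :class:`~piebaldnet.genotypes.GenotypeTable` or an iterable
    of (snp_id, chrom, bp); ``genes`` a list of :class:`GeneAnnotation` or a
    BED-like DataFrame.  Distance is to the nearer interval edge, zero inside
    the gene; exact-distance ties go to the gene with the lower start
    coordinate.  ``genes_within_1Mb`` collects every gene whose interval edge
    lies within ``region_bp`` of the SNP.  SNPs on chromosomes without genes
    are returned unmapped.
    """
    snp_df = _snp_frame(snps)
    gene_list = _as_gene_list(genes)
    by_chrom: dict[str, list[GeneAnnotation]] = {}
    for g in gene_list:
        by_chrom.setdefault(str(g.chromosome), []).append(g)
    for lst in by_chrom.values():
        lst.sort(key=lambda g: (g.start_bp, g.gene_id))

    mappings: list[SnpGeneMapping] = []
    for chrom, sub in snp_df.groupby("chrom", sort=False):
        chrom_genes = by_chrom.get(str(chrom))
        if not chrom_genes:
            for r in sub.itertuples(index=False):
                mappings.append(
                    SnpGeneMapping(r.snp_id, None, None, UNMAPPED, set())
                )
            continue
        starts = np.array([g.start_bp for g in chrom_genes])
        ends = np.array([g.end_bp for g in chrom_genes])
        for r in sub.itertuples(index=False):
            pos = int(r.bp)
            inside = (starts <= pos) & (pos <= ends)
            dist = np.where(
                inside, 0, np.minimum(np.abs(pos - starts), np.abs(pos - ends))
            )
            best = int(np.argmin(dist))  # argmin keeps lowest start on ties
            within = {
                g.gene_id for g, d in zip(chrom_genes, dist) if d <= region_bp
            }
            mappings.append(
                SnpGeneMapping(
                    snp_id=r.snp_id,
                    nearest_gene_id=chrom_genes[best].gene_id,
                    distance_bp=int(dist[best]),
                    category=classify_distance(int(dist[best]), bool(inside[best])),
                    genes_within_1Mb=within,
                )
            )
    order = {s: i for i, s in enumerate(snp_df["snp_id"])}
    mappings.sort(key=lambda m: order[m.snp_id])
    return mappings


def mapping_frame(mappings: list[SnpGeneMapping]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "snp_id": [m.snp_id for m in mappings],
            "nearest_gene_id": [m.nearest_gene_id for m in mappings],
            "distance_bp": [m.distance_bp for m in mappings],
            "category": [m.category for m in mappings],
            "genes_within_1Mb": [",".join(sorted(m.genes_within_1Mb)) for m in mappings],
        }
    )


def call_piebald_genes(
    de_results,
    assoc_records,
    mappings: list[SnpGeneMapping],
    significant_snps: set,
    cis_bp: int = CIS_BP,
) -> pd.DataFrame:
    """Merge DE and association evidence into the piebald-associated gene table.

    A gene qualifies via criterion (i) when it is DE-flagged in at least one
    contrast and some SNP maps to it as nearest gene within ``cis_bp``
    (intragenic or cis); via criterion (ii) when it shows no DE but a SNP
    from ``significant_snps`` lies within the 1 Mb region.  Each qualifying
    gene is listed once with its criterion, the most associated SNP within
    1 Mb (smallest p-value), and a DE summary.
    """
    de_by_gene = {r.gene_id: r for r in de_results}
    assoc_by_snp = {r.snp_id: r for r in assoc_records}

    cis_genes: dict[str, int] = {}
    region_sig: dict[str, list[str]] = {}
    region_all: dict[str, list[str]] = {}
    for m in mappings:
        if (
            m.nearest_gene_id is not None
            and m.distance_bp is not None
            and m.distance_bp <= cis_bp
        ):
            cis_genes[m.nearest_gene_id] = min(
                cis_genes.get(m.nearest_gene_id, m.distance_bp), m.distance_bp
            )
        for gene in m.genes_within_1Mb:
            region_all.setdefault(gene, []).append(m.snp_id)
            if m.snp_id in significant_snps:
                region_sig.setdefault(gene, []).append(m.snp_id)

    universe = set(cis_genes) | set(region_all) | set(de_by_gene)
    rows = []
    for gene in sorted(universe):
        de = de_by_gene.get(gene)
        is_de = de is not None and de.n_de_contrasts >= 1
        crit = None
        if is_de and gene in cis_genes:
            crit = "i"
        elif not is_de and gene in region_sig:
            crit = "ii"
        if crit is None:
            continue
        local = region_all.get(gene, [])
        best_snp, best_p, best_or = None, np.nan, np.nan
        scored = [
            (assoc_by_snp[s].p_value, s)
            for s in local
            if s in assoc_by_snp and np.isfinite(assoc_by_snp[s].p_value)
        ]
        if scored:
            best_p, best_snp = min(scored)
            best_or = assoc_by_snp[best_snp].odds_ratio
        rows.append(
            {
                "gene_id": gene,
                "criterion": crit,
                "best_snp": best_snp,
                "best_p": best_p,
                "best_or": best_or,
                "n_de_contrasts": de.n_de_contrasts if de else 0,
                "piebald_score": de.piebald_score if de else np.nan,
                "colour_category": de.colour_category if de else "absent",
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "criterion",
            "best_snp",
            "best_p",
            "best_or",
            "n_de_contrasts",
            "piebald_score",
            "colour_category",
        ],
    )
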