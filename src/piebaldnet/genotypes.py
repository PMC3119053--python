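"""Genotype I/O, quality filtering, allele sharing, and matched-control selection.

Genotypes are coded as copies of the B allele (0, 1, 2) with -1 for a missing
call.  Pairwise genetic similarity between animals is measured as mean
identity-by-state (IBS) sharing, ``mean over SNPs of (2 - |g_i - g_j|) / 2``
restricted to SNPs where both animals have a call.  Controls are matched to
cases greedily on that similarity, without replacement, mirroring a stepwise
three-controls-per-case design.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError, PoolExhaustedError

MISSING = -1

CASE = "case"
CONTROL = "control"
UNLABELLED = "unlabelled"


@dataclass
class GenotypeTable:
    """Animals x SNPs genotype matrix with map and phenotype labels.

    Attributes
    ----------
    animal_ids : list of str
        Row identifiers, unique, in input order.
    snp_ids : list of str
        Column identifiers, unique, in map order.
    chromosomes : ndarray of str
        Per-SNP chromosome name.
    positions : ndarray of int
        Per-SNP 1-based basepair position.
    calls : ndarray of int8, shape (n_animals, n_snps)
        B-allele copy counts; ``MISSING`` (-1) marks a missing call.
    labels : dict
        animal_id -> "case" | "control" | "unlabelled".
    """

    animal_ids: list[str]
    snp_ids: list[str]
    chromosomes: np.ndarray
    positions: np.ndarray
    calls: np.ndarray
    labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.chromosomes = np.asarray(self.chromosomes, dtype=object)
        n_a, n_s = self.calls.shape
        if len(self.animal_ids) != n_a:
            raise ValueError(
                f"calls has {n_a} rows but {len(self.animal_ids)} animal ids"
            )
        if len(self.snp_ids) != n_s:
            raise ValueError(f"calls has {n_s} columns but {len(self.snp_ids)} snp ids")
        if len(set(self.animal_ids)) != n_a:
            raise ValueError("duplicate animal ids")
        if len(set(self.snp_ids)) != n_s:
            raise ValueError("duplicate snp ids")
        if len(self.positions) != n_s or len(self.chromosomes) != n_s:
            raise ValueError("map arrays do not match the number of SNPs")
        if n_s and self.positions.min() < 1:
            raise ValueError("positions must be 1-based (>= 1)")
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotype codes must be 0, 1, 2 or missing (-1)")
        for a in self.labels:
            if a not in set(self.animal_ids):
                raise ValueError(f"label for unknown animal {a!r}")

    # -- convenience views -------------------------------------------------

    @property
    def n_animals(self) -> int:
        return len(self.animal_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def status_of(self, animal_id: str) -> str:
        return self.labels.get(animal_id, UNLABELLED)

    def animals_with_status(self, status: str) -> list[str]:
        return [a for a in self.animal_ids if self.status_of(a) == status]

    @property
    def case_ids(self) -> list[str]:
        return self.animals_with_status(CASE)

    @property
    def control_ids(self) -> list[str]:
        return self.animals_with_status(CONTROL)

    def animal_index(self, ids) -> np.ndarray:
        pos = {a: i for i, a in enumerate(self.animal_ids)}
        return np.array([pos[a] for a in ids], dtype=np.intp)

    def snp_index(self, ids) -> np.ndarray:
        pos = {s: i for i, s in enumerate(self.snp_ids)}
        return np.array([pos[s] for s in ids], dtype=np.intp)

    def subset_animals(self, ids) -> "GenotypeTable":
        idx = self.animal_index(ids)
        return GenotypeTable(
            animal_ids=list(ids),
            snp_ids=list(self.snp_ids),
            chromosomes=self.chromosomes.copy(),
            positions=self.positions.copy(),
            calls=self.calls[idx].copy(),
            labels={a: self.status_of(a) for a in ids if a in self.labels},
        )

    def subset_snps(self, ids) -> "GenotypeTable":
        idx = self.snp_index(ids)
        return GenotypeTable(
            animal_ids=list(self.animal_ids),
            snp_ids=list(ids),
            chromosomes=self.chromosomes[idx].copy(),
            positions=self.positions[idx].copy(),
            calls=self.calls[:, idx].copy(),
            labels=dict(self.labels),
        )

    # -- I/O ---------------------------------------------------------------

    def to_files(self, genotype_path, map_path, phenotype_path) -> None:
        """Write the genotype TSV (rows=animals), map TSV and phenotype TSV."""
        geno = pd.DataFrame(self.calls, index=self.animal_ids, columns=self.snp_ids)
        geno = geno.astype(object).where(geno != MISSING, "NA")
        geno.index.name = "animal_id"
        geno.to_csv(genotype_path, sep="\t")
        pd.DataFrame(
            {
                "snp_id": self.snp_ids,
                "chrom": self.chromosomes,
                "bp": self.positions,
            }
        ).to_csv(map_path, sep="\t", index=False)
        pd.DataFrame(
            {
                "animal_id": self.animal_ids,
                "status": [self.status_of(a) for a in self.animal_ids],
            }
        ).to_csv(phenotype_path, sep="\t", index=False)


@dataclass
class SharingMatrix:
    """Symmetric matrix of mean IBS allele sharing between animals."""

    animal_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.animal_ids)
        if self.values.shape != (n, n):
            raise ValueError("sharing matrix shape does not match animal ids")

    def sharing(self, a: str, b: str) -> float:
        pos = {x: i for i, x in enumerate(self.animal_ids)}
        return float(self.values[pos[a], pos[b]])


# ---------------------------------------------------------------------------
# Reading


def _parse_code(token: str, path, line_no: int) -> int:
    token = token.strip()
    if token in ("NA", "", ".", "nan", "-1"):
        return MISSING
    if token in ("0", "1", "2"):
        return int(token)
    raise ParseError(f"{path}: line {line_no}: unknown genotype code {token!r}")


def read_genotypes(genotype_path, map_path, phenotype_path=None) -> GenotypeTable:
    """Read a genotype matrix with its SNP map and optional phenotype labels.

    ``genotype_path`` is either a TSV with animals as rows and SNP columns
    (codes 0/1/2/NA) or an uncompressed VCF (detected by extension), in which
    case only biallelic sites are kept and the code is the ALT-allele count.
    The map TSV must carry ``snp_id``, ``chrom``, ``bp`` (1-based) for every
    SNP in the matrix; the phenotype TSV carries ``animal_id``, ``status``.
    """
    genotype_path = Path(genotype_path)
    if genotype_path.suffix.lower() == ".vcf":
        animal_ids, snp_ids, chroms, positions, calls = _read_vcf(genotype_path)
    else:
        geno = pd.read_csv(genotype_path, sep="\t", index_col=0, dtype=str)
        animal_ids = [str(a) for a in geno.index]
        snp_ids = [str(s) for s in geno.columns]
        raw = geno.to_numpy(dtype=str)
        raw = np.char.strip(raw.astype(str))
        calls = np.full(raw.shape, MISSING, dtype=np.int8)
        for tok, code in (("0", 0), ("1", 1), ("2", 2)):
            calls[raw == tok] = code
        known = np.isin(raw, ("0", "1", "2", "NA", "", ".", "nan", "-1"))
        if not known.all():
            i, j = np.argwhere(~known)[0]
            _parse_code(raw[i, j], genotype_path, i + 2)
        chroms = positions = None

    map_df = pd.read_csv(map_path, sep="\t", dtype={"snp_id": str, "chrom": str})
    for col in ("snp_id", "chrom", "bp"):
        if col not in map_df.columns:
            raise ParseError(f"{map_path}: missing required column {col!r}")
    map_df = map_df.set_index("snp_id")
    missing_from_map = [s for s in snp_ids if s not in map_df.index]
    if missing_from_map:
        raise ParseError(
            f"{map_path}: SNPs absent from map: {missing_from_map[:5]} ..."
            if len(missing_from_map) > 5
            else f"{map_path}: SNPs absent from map: {missing_from_map}"
        )
    extra = [s for s in map_df.index if s not in set(snp_ids)]
    if extra:
        raise ParseError(
            f"{map_path}: map lists SNPs absent from the genotype matrix: {extra[:5]}"
        )
    map_df = map_df.loc[snp_ids]
    if chroms is None:
        chroms = map_df["chrom"].to_numpy(dtype=object)
        positions = map_df["bp"].to_numpy(dtype=np.int64)

    labels: dict[str, str] = {}
    if phenotype_path is not None:
        pheno = pd.read_csv(phenotype_path, sep="\t", dtype=str)
        for col in ("animal_id", "status"):
            if col not in pheno.columns:
                raise ParseError(f"{phenotype_path}: missing required column {col!r}")
        known = set(animal_ids)
        for ln, row in enumerate(pheno.itertuples(index=False), start=2):
            if row.animal_id not in known:
                raise ParseError(
                    f"{phenotype_path}: line {ln}: unknown animal {row.animal_id!r}"
                )
            status = row.status.strip().lower()
            if status not in (CASE, CONTROL, UNLABELLED):
                raise ParseError(
                    f"{phenotype_path}: line {ln}: unknown status {row.status!r}"
                )
            labels[row.animal_id] = status

    return GenotypeTable(
        animal_ids=animal_ids,
        snp_ids=snp_ids,
        chromosomes=chroms,
        positions=positions,
        calls=calls,
        labels=labels,
    )


def _read_vcf(path):
    """Read biallelic sites from a VCF into ALT-allele count codes."""
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise ImportError("VCF input requires the cyvcf2 package") from exc

    vcf = VCF(str(path))
    animal_ids = list(vcf.samples)
    snp_ids, chroms, positions, columns = [], [], [], []
    for var in vcf:
        if len(var.ALT) != 1:
            continue
        snp_ids.append(var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}")
        chroms.append(var.CHROM)
        positions.append(var.POS)
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = var.gt_types
        col = np.where(gt == 0, 0, np.where(gt == 1, 1, np.where(gt == 3, 2, MISSING)))
        columns.append(col.astype(np.int8))
    calls = (
        np.column_stack(columns)
        if columns
        else np.empty((len(animal_ids), 0), dtype=np.int8)
    )
    return (
        animal_ids,
        snp_ids,
        np.asarray(chroms, dtype=object),
        np.asarray(positions, dtype=np.int64),
        calls,
    )


# ---------------------------------------------------------------------------
# Filtering


def filter_snps(
    table: GenotypeTable,
    min_call_rate: float = 0.0,
    min_maf: float = 0.0,
    require_polymorphic: bool = True,
) -> GenotypeTable:
    """Drop SNPs failing call-rate / MAF / polymorphism criteria.

    All criteria are evaluated over labelled (case or control) animals only,
    so the quality of unphenotyped animals cannot change the analysis set.
    SNP order is preserved.
    """
    if not 0 <= min_call_rate <= 1 or not 0 <= min_maf <= 1:
        raise ValueError("thresholds must lie in [0, 1]")
    labelled = [
        a for a in table.animal_ids if table.status_of(a) in (CASE, CONTROL)
    ] or list(table.animal_ids)
    calls = table.calls[table.animal_index(labelled)]
    observed = calls != MISSING
    n_obs = observed.sum(axis=0)
    call_rate = n_obs / max(len(labelled), 1)

    b_count = np.where(observed, calls, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n_obs > 0, b_count / (2.0 * n_obs), np.nan)
    maf = np.fmin(freq, 1.0 - freq)

    keep = call_rate >= min_call_rate
    if min_maf > 0:
        keep &= ~np.isnan(maf) & (maf >= min_maf)
    if require_polymorphic:
        # at least two distinct observed codes among labelled animals
        mn = np.where(observed, calls, 3).min(axis=0)
        mx = np.where(observed, calls, -2).max(axis=0)
        keep &= (n_obs > 0) & (mx > mn)
    kept_ids = [s for s, k in zip(table.snp_ids, keep) if k]
    return table.subset_snps(kept_ids)


# ---------------------------------------------------------------------------
# Allele sharing and matched controls


def allele_sharing(table: GenotypeTable) -> SharingMatrix:
    """Mean identity-by-state sharing between every pair of animals.

    sharing(i, j) = mean over SNPs with both calls present of
    (2 - |g_i - g_j|) / 2.  Pairs with no jointly observed SNP get NaN.
    """
    if table.n_animals < 2:
        raise ValueError("allele sharing needs at least two animals")
    g = table.calls.astype(np.float64)
    g[table.calls == MISSING] = np.nan
    n = table.n_animals
    values = np.empty((n, n), dtype=float)
    for i in range(n):
        diff = np.abs(g - g[i])  # NaN wherever either call missing
        score = (2.0 - diff) / 2.0
        cnt = np.sum(~np.isnan(score), axis=1)
        with np.errstate(invalid="ignore"):
            values[i] = np.where(cnt > 0, np.nansum(score, axis=1) / cnt, np.nan)
    # exact symmetry and unit diagonal for animals with any observed call
    values = (values + values.T) / 2.0
    has_call = (table.calls != MISSING).any(axis=1)
    values[np.diag_indices(n)] = np.where(has_call, 1.0, np.nan)
    return SharingMatrix(animal_ids=list(table.animal_ids), values=values)


def select_controls(
    matrix: SharingMatrix,
    case_ids,
    candidate_ids=None,
    k_per_case: int = 3,
):
    """Greedy matched-control selection on allele sharing, without replacement.

    Cases are processed in the given order; each receives the ``k_per_case``
    available candidates with the highest sharing (ties broken by candidate
    order in the matrix).  A selected control is removed from the pool before
    the next case is processed.

    Returns
    -------
    (selected, provenance)
        ``selected`` is the ordered list of chosen control ids; ``provenance``
        maps each case id to its k matched controls.
    """
    case_ids = list(case_ids)
    pos = {a: i for i, a in enumerate(matrix.animal_ids)}
    for c in case_ids:
        if c not in pos:
            raise ValueError(f"case {c!r} not present in the sharing matrix")
    if candidate_ids is None:
        case_set = set(case_ids)
        candidate_ids = [a for a in matrix.animal_ids if a not in case_set]
    candidate_ids = list(candidate_ids)
    for c in candidate_ids:
        if c not in pos:
            raise ValueError(f"candidate {c!r} not present in the sharing matrix")
    if k_per_case * len(case_ids) > len(candidate_ids):
        raise PoolExhaustedError(
            f"pool of {len(candidate_ids)} candidates cannot supply "
            f"{k_per_case} controls for each of {len(case_ids)} cases"
        )

    available = dict.fromkeys(candidate_ids)  # insertion-ordered set
    selected: list[str] = []
    provenance: dict[str, list[str]] = {}
    for case in case_ids:
        if len(available) < k_per_case:
            raise PoolExhaustedError(
                f"control pool exhausted while matching case {case!r}"
            )
        row = matrix.values[pos[case]]
        # stable sort on -sharing keeps candidate (matrix) order on ties
        cands = list(available)
        shar = np.array([row[pos[c]] for c in cands])
        shar = np.where(np.isnan(shar), -np.inf, shar)
        order = np.argsort(-shar, kind="stable")
        chosen = [cands[i] for i in order[:k_per_case]]
        for c in chosen:
            del available[c]
        provenance[case] = chosen
        selected.extend(chosen)
    return selected, provenance
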