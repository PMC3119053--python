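"""Single-SNP case-control association and the all-pairs two-locus epistasis scan.

Single-SNP association works on the 2x2 allele-count table (B vs b alleles by
case/control): a Pearson chi-square without continuity correction at 1 df, and
the cross-product odds ratio oriented to be >= 1.  A SNP is called significant
only under a dual rule: its case-minus-control mean-genotype difference must
lie beyond ``sd_multiplier`` empirical standard deviations of the genome-wide
difference distribution AND its chi-square p-value must fall below
``p_threshold``.

Epistasis between two loci is tested on the 9x2 contingency table of joint
genotype counts (nine two-locus genotype combinations by case/control) with a
Pearson chi-square evaluated at a fixed 8 degrees of freedom; cells with zero
expected count contribute nothing.  Pairs closer than 100 kb on one chromosome
are flagged, since their signal may reflect linkage disequilibrium rather
than epistasis.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import CASE, CONTROL, MISSING, GenotypeTable

logger = logging.getLogger(__name__)

DEFAULT_P_THRESHOLD = 0.001
DEFAULT_SD_MULTIPLIER = 3.0
DEFAULT_PROXIMITY_BP = 100_000


@dataclass
class AssociationRecord:
    """Per-SNP allelic case-control statistics."""

    snp_id: str
    freq_case: float
    freq_control: float
    geno_diff: float
    chi2: float
    df: int
    p_value: float
    odds_ratio: float
    passes_sd_rule: bool = False
    significant: bool = False


@dataclass
class EpistasisRecord:
    """Two-locus 9x2 contingency test result for an unordered SNP pair."""

    snp_a: str
    snp_b: str
    chi2: float
    df: int
    p_value: float
    proximity_flag: bool
    significant: bool


# ---------------------------------------------------------------------------
# Odds ratios and reconstruction from printed summaries


def allelic_odds_ratio(a: float, b: float, c: float, d: float) -> float:
    """Cross-product ratio of the allele table, oriented to be >= 1.

    ``a``/``b`` are case B/b allele counts; ``c``/``d`` control B/b counts.
    Identical group frequencies give 1.0 exactly; a zero cell with unequal
    frequencies gives NaN (no pseudo-count is applied).
    """
    ad, bc = a * d, b * c
    if ad == bc:
        return 1.0
    if ad == 0 or bc == 0:
        return float("nan")
    return max(ad / bc, bc / ad)


def reconstruct_allele_counts(
    freq_case: float,
    freq_control: float,
    n_case_alleles: int,
    n_control_alleles: int,
    decimals_case: int = 2,
    decimals_control: int = 2,
    printed_or: float | None = None,
):
    """Recover the integer allele-count table behind printed group frequencies.

    A printed frequency with ``d`` decimals constrains the integer B-allele
    count ``k`` to ``k / n in [f - 0.5*10^-d, f + 0.5*10^-d)`` (round half
    up).  When several count tables are consistent with both frequencies the
    published odds ratio, if supplied, disambiguates: the unique table whose
    cross-product OR rounds to ``printed_or`` at two decimals is returned.

    Returns the table ``(a, b, c, d)`` = case B, case b, control B, control b.
    """

    def candidates(f, d, n):
        half = 0.5 * 10.0 ** (-d)
        lo = math.ceil((f - half) * n - 1e-9)
        hi = math.ceil((f + half) * n - 1e-9)  # exclusive upper bound
        return [k for k in range(max(lo, 0), min(hi, n + 1))]

    case_counts = candidates(freq_case, decimals_case, n_case_alleles)
    ctrl_counts = candidates(freq_control, decimals_control, n_control_alleles)
    if not case_counts or not ctrl_counts:
        raise ValueError("no integer counts are consistent with the printed frequencies")

    tables = [
        (ca, n_case_alleles - ca, co, n_control_alleles - co)
        for ca, co in product(case_counts, ctrl_counts)
    ]
    if len(tables) == 1:
        return tables[0]
    if printed_or is None:
        raise ValueError(
            f"{len(tables)} count tables are consistent with the printed "
            "frequencies; pass printed_or to disambiguate"
        )
    matching = [
        t for t in tables if round(allelic_odds_ratio(*t), 2) == round(printed_or, 2)
    ]
    if len(matching) != 1:
        raise ValueError(
            f"{len(matching)} candidate tables reproduce OR {printed_or}; "
            "reconstruction is ambiguous"
        )
    return matching[0]


# ---------------------------------------------------------------------------
# Single-SNP association


def _pearson_2x2(a: float, b: float, c: float, d: float) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) and p for a 2x2 table."""
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0 or n == 0:
        return 0.0, 1.0
    chi2 = n * (a * d - b * c) ** 2 / denom
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def snp_association(table: GenotypeTable) -> list[AssociationRecord]:
    """Allelic association statistics for every SNP in the table.

    Works over non-missing calls only.  A SNP with no observed call in one of
    the groups is emitted with NaN statistics and counted in a logged warning.
    Significance flags are left False; fill them with
    :func:`significant_snps`.
    """
    cases = table.case_ids
    controls = table.control_ids
    if not cases or not controls:
        raise ValueError("association needs at least one case and one control")

    gc = table.calls[table.animal_index(cases)].astype(np.float64)
    gn = table.calls[table.animal_index(controls)].astype(np.float64)
    gc[gc == MISSING] = np.nan
    gn[gn == MISSING] = np.nan

    n_case_obs = np.sum(~np.isnan(gc), axis=0)
    n_ctrl_obs = np.sum(~np.isnan(gn), axis=0)
    b_case = np.nansum(gc, axis=0)
    b_ctrl = np.nansum(gn, axis=0)

    records: list[AssociationRecord] = []
    n_degenerate = 0
    for j, snp in enumerate(table.snp_ids):
        if n_case_obs[j] == 0 or n_ctrl_obs[j] == 0:
            n_degenerate += 1
            records.append(
                AssociationRecord(
                    snp_id=snp,
                    freq_case=np.nan,
                    freq_control=np.nan,
                    geno_diff=np.nan,
                    chi2=np.nan,
                    df=1,
                    p_value=np.nan,
                    odds_ratio=np.nan,
                )
            )
            continue
        a = b_case[j]
        b = 2.0 * n_case_obs[j] - a
        c = b_ctrl[j]
        d = 2.0 * n_ctrl_obs[j] - c
        chi2, p = _pearson_2x2(a, b, c, d)
        records.append(
            AssociationRecord(
                snp_id=snp,
                freq_case=a / (2.0 * n_case_obs[j]),
                freq_control=c / (2.0 * n_ctrl_obs[j]),
                geno_diff=float(np.nanmean(gc[:, j]) - np.nanmean(gn[:, j])),
                chi2=chi2,
                df=1,
                p_value=p,
                odds_ratio=allelic_odds_ratio(a, b, c, d),
            )
        )
    if n_degenerate:
        logger.warning(
            "%d SNPs had no observed calls in one group; statistics set missing",
            n_degenerate,
        )
    return records


def significant_snps(
    records: list[AssociationRecord],
    p_threshold: float = DEFAULT_P_THRESHOLD,
    sd_multiplier: float = DEFAULT_SD_MULTIPLIER,
) -> set[str]:
    """Apply the dual significance rule, mutating the records in place.

    The genotype-difference rule compares each SNP's case-minus-control mean
    genotype against the empirical distribution over all scored SNPs: a SNP
    passes when its absolute deviation from the genome-wide mean strictly
    exceeds ``sd_multiplier`` standard deviations.  Final significance is the
    conjunction with the chi-square rule ``p < p_threshold``.
    """
    diffs = np.array([r.geno_diff for r in records], dtype=float)
    finite = diffs[np.isfinite(diffs)]
    if finite.size < 2:
        raise ValueError("need at least two finite genotype differences")
    mean = float(finite.mean())
    sd = float(finite.std(ddof=0))
    significant: set[str] = set()
    for r in records:
        r.passes_sd_rule = bool(
            np.isfinite(r.geno_diff) and abs(r.geno_diff - mean) > sd_multiplier * sd
        )
        r.significant = bool(
            r.passes_sd_rule and np.isfinite(r.p_value) and r.p_value < p_threshold
        )
        if r.significant:
            significant.add(r.snp_id)
    return significant


# ---------------------------------------------------------------------------
# Two-locus epistasis scan


def epistasis_scan(
    table: GenotypeTable,
    snp_ids,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    proximity_bp: int = DEFAULT_PROXIMITY_BP,
) -> list[EpistasisRecord]:
    """Test every unordered SNP pair for a case/control difference in joint genotype.

    For each pair a 9x2 table of joint-genotype counts (animals non-missing at
    both loci) is tested with a Pearson chi-square at a fixed 8 degrees of
    freedom; rows with zero expected count contribute 0.  Returns exactly
    C(n, 2) records.  Pairs with fewer than two distinct observed joint
    genotypes get NaN statistics.
    """
    snp_ids = list(snp_ids)
    if len(snp_ids) < 2:
        raise ValueError("epistasis scan needs at least two SNPs")
    col = table.snp_index(snp_ids)
    chrom = table.chromosomes[col]
    pos = table.positions[col]
    cases = table.animal_index(table.case_ids)
    controls = table.animal_index(table.control_ids)
    if cases.size == 0 or controls.size == 0:
        raise ValueError("epistasis scan needs at least one case and one control")

    G = table.calls[:, col].astype(np.int16)
    m = len(snp_ids)
    records: list[EpistasisRecord] = []
    df = 8
    for ai in range(m - 1):
        rest = np.arange(ai + 1, m)
        ga = G[:, ai]
        gb = G[:, rest]
        valid = (ga != MISSING)[:, None] & (gb != MISSING)
        joint = ga[:, None] * 3 + gb  # 0..8 where valid
        counts = np.zeros((2, 9, rest.size), dtype=np.int64)
        for gi, grp in enumerate((cases, controls)):
            jg = joint[grp]
            vg = valid[grp]
            for cell in range(9):
                counts[gi, cell] = ((jg == cell) & vg).sum(axis=0)
        cc, cn = counts[0].astype(float), counts[1].astype(float)
        row_tot = cc + cn
        col_case = cc.sum(axis=0)
        col_ctrl = cn.sum(axis=0)
        n_tot = col_case + col_ctrl
        with np.errstate(invalid="ignore", divide="ignore"):
            e_case = row_tot * col_case / n_tot
            e_ctrl = row_tot * col_ctrl / n_tot
            term = np.where(e_case > 0, (cc - e_case) ** 2 / np.where(e_case > 0, e_case, 1), 0.0)
            term += np.where(e_ctrl > 0, (cn - e_ctrl) ** 2 / np.where(e_ctrl > 0, e_ctrl, 1), 0.0)
        chi2 = term.sum(axis=0)
        n_rows_observed = (row_tot > 0).sum(axis=0)
        pvals = stats.chi2.sf(chi2, df=df)
        same_chr = chrom[rest] == chrom[ai]
        near = same_chr & (np.abs(pos[rest] - pos[ai]) < proximity_bp)
        for k, bi in enumerate(rest):
            if n_rows_observed[k] < 2 or n_tot[k] == 0:
                records.append(
                    EpistasisRecord(
                        snp_a=snp_ids[ai],
                        snp_b=snp_ids[bi],
                        chi2=np.nan,
                        df=df,
                        p_value=np.nan,
                        proximity_flag=bool(near[k]),
                        significant=False,
                    )
                )
                continue
            records.append(
                EpistasisRecord(
                    snp_a=snp_ids[ai],
                    snp_b=snp_ids[bi],
                    chi2=float(chi2[k]),
                    df=df,
                    p_value=float(pvals[k]),
                    proximity_flag=bool(near[k]),
                    significant=bool(pvals[k] < p_threshold),
                )
            )
    return records


# ---------------------------------------------------------------------------
# Linkage disequilibrium


def ld_r2(table: GenotypeTable, snp_a: str, snp_b: str) -> float:
    """Composite LD: squared Pearson correlation of genotype codes.

    Computed over animals non-missing at both SNPs; NaN when fewer than two
    such animals remain or either SNP has zero variance among them.
    """
    ja, jb = table.snp_index([snp_a, snp_b])
    ga = table.calls[:, ja].astype(float)
    gb = table.calls[:, jb].astype(float)
    keep = (ga != MISSING) & (gb != MISSING)
    ga, gb = ga[keep], gb[keep]
    if ga.size < 2 or ga.std() == 0 or gb.std() == 0:
        return float("nan")
    r = np.corrcoef(ga, gb)[0, 1]
    return float(r * r)


# ---------------------------------------------------------------------------
# Tabular export


def association_frame(records: list[AssociationRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "snp_id": [r.snp_id for r in records],
            "freq_case": [r.freq_case for r in records],
            "freq_control": [r.freq_control for r in records],
            "geno_diff": [r.geno_diff for r in records],
            "chi2": [r.chi2 for r in records],
            "df": [r.df for r in records],
            "p_value": [r.p_value for r in records],
            "odds_ratio": [r.odds_ratio for r in records],
            "passes_sd_rule": [r.passes_sd_rule for r in records],
            "significant": [r.significant for r in records],
        }
    )


def epistasis_frame(records: list[EpistasisRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "snp_a": [r.snp_a for r in records],
            "snp_b": [r.snp_b for r in records],
            "chi2": [r.chi2 for r in records],
            "df": [r.df for r in records],
            "p_value": [r.p_value for r in records],
            "proximity_flag": [r.proximity_flag for r in records],
            "significant": [r.significant for r in records],
        }
    )
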