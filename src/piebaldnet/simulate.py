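"""Synthetic cohorts, microarrays and TFBS tables with planted, recorded signals.

The generator emulates the statistical shape of a matched case-control
pigmentation study: a small case group and a control pool genotyped at many
SNPs with family-like relatedness, a handful of SNPs whose case allele
frequency is shifted, SNP pairs whose *joint* genotype distribution differs
between cases and controls (epistasis), a five-variety two-colour microarray
hybridised in a 20-slide dye-swap loop with variety-specific expression
shifts planted in chosen genes, and a TF-to-gene binding-site table in which
planted memberships carry perfect similarity scores.

Every planted signal is recorded in a :class:`GroundTruth` so downstream
stages can be tested for recovery; identical seed and configuration give
bit-identical outputs.

Relatedness uses a Balding-Nichols construction: each family's allele
frequency is a Beta draw around the population frequency with divergence
``fst``.  Epistatic pairs are planted by reweighting the case joint-genotype
distribution with a 3x3 penetrance-style weight table, so the signal is
exactly the kind of saturated 9-cell departure the two-locus contingency
test looks for.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .expression import VARIETIES
from .genotypes import CASE, CONTROL, MISSING, GenotypeTable

#: Default 3x3 case-weight table over joint genotypes (rows = locus A genotype
#: 0/1/2, columns = locus B).  The diagonal concentration makes cases enriched
#: for matched genotypes at the two loci -- a saturated interaction with weak
#: marginal signal of its own.
DEFAULT_PENETRANCE = (
    (0.9, 0.1, 0.1),
    (0.1, 0.9, 0.1),
    (0.1, 0.1, 0.9),
)

_DE_VARIETIES = ("PBW", "PBB")  # piebald tissues receive the planted shift


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic generators.

    The defaults mirror the matched cohort and loop-design array the pipeline
    is built for: 24 cases against a 72-control pool genotyped at 5,000 SNPs,
    and a 20-hybridisation five-variety array over 200 genes.
    """

    n_cases: int = 24
    n_controls_pool: int = 72
    n_snps: int = 5000
    n_chromosomes: int = 26
    chrom_length_bp: int = 150_000_000
    n_assoc_snps: int = 12
    assoc_freq_delta: float = 0.35
    n_epistatic_pairs: int = 3
    epistasis_penetrance_table: tuple = DEFAULT_PENETRANCE
    n_families: int = 8
    fst: float = 0.05
    n_genes: int = 200
    n_de_genes: int = 10
    de_effect_sd: float = 2.0
    noise_sds: dict = field(
        default_factory=lambda: {
            "gene": 2.0,
            "array_gene": 0.3,
            "dye_gene": 0.2,
            "variety_gene": 0.5,
            "residual": 0.5,
        }
    )
    comparison_group_sd: float = 0.25
    mu_log2: float = 8.0
    low_snr_fraction: float = 0.05
    missing_rate: float = 0.0
    n_tfs: int = 4
    tfbs_density: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        positive = {
            "n_cases": self.n_cases,
            "n_controls_pool": self.n_controls_pool,
            "n_snps": self.n_snps,
            "n_chromosomes": self.n_chromosomes,
            "chrom_length_bp": self.chrom_length_bp,
            "n_families": self.n_families,
            "n_genes": self.n_genes,
        }
        for name, value in positive.items():
            if int(value) < 1:
                raise ConfigurationError(f"{name} must be >= 1, got {value}")
        non_negative = {
            "n_assoc_snps": self.n_assoc_snps,
            "n_epistatic_pairs": self.n_epistatic_pairs,
            "n_de_genes": self.n_de_genes,
            "n_tfs": self.n_tfs,
        }
        for name, value in non_negative.items():
            if int(value) < 0:
                raise ConfigurationError(f"{name} must be >= 0, got {value}")
        for name, value in (
            ("assoc_freq_delta", self.assoc_freq_delta),
            ("tfbs_density", self.tfbs_density),
            ("low_snr_fraction", self.low_snr_fraction),
            ("missing_rate", self.missing_rate),
            ("fst", self.fst),
        ):
            if not 0.0 <= float(value) <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {value}")
        pen = np.asarray(self.epistasis_penetrance_table, dtype=float)
        if pen.shape != (3, 3) or pen.min() < 0 or pen.max() > 1:
            raise ConfigurationError(
                "epistasis_penetrance_table must be a 3x3 matrix of probabilities"
            )
        for name, sd in {**self.noise_sds, "comparison_group": self.comparison_group_sd}.items():
            if sd < 0:
                raise ConfigurationError(f"noise SD {name!r} must be >= 0")
        if self.n_assoc_snps + 2 * self.n_epistatic_pairs > self.n_snps:
            raise ConfigurationError(
                "n_assoc_snps + 2 * n_epistatic_pairs exceeds n_snps"
            )
        if self.n_assoc_snps + 2 * self.n_epistatic_pairs > self.n_genes:
            raise ConfigurationError(
                "planted SNPs outnumber genes; raise n_genes so each planted "
                "SNP can anchor a distinct gene"
            )
        if self.n_de_genes > self.n_genes - 2 * self.n_epistatic_pairs:
            raise ConfigurationError(
                "n_de_genes exceeds the genes left after anchoring epistatic pairs"
            )


@dataclass
class GroundTruth:
    """Record of every planted signal, for recovery testing."""

    assoc_snp_ids: set
    epistatic_pairs: set  # of 2-tuples (snp_a, snp_b), a < b lexically
    de_gene_ids: dict  # gene -> {variety: signed log2 shift}
    tf_memberships: dict  # tf -> set of target genes
    planted_variance_components: dict
    gene_ids: list = field(default_factory=list)
    tf_ids: list = field(default_factory=list)
    snp_gene_plan: dict = field(default_factory=dict)  # planted snp -> anchored gene
    intersection_gene_ids: set = field(default_factory=set)

    def to_json(self, path) -> None:
        payload = {
            "assoc_snp_ids": sorted(self.assoc_snp_ids),
            "epistatic_pairs": sorted(map(list, self.epistatic_pairs)),
            "de_gene_ids": {g: dict(v) for g, v in sorted(self.de_gene_ids.items())},
            "tf_memberships": {t: sorted(g) for t, g in sorted(self.tf_memberships.items())},
            "planted_variance_components": self.planted_variance_components,
            "gene_ids": self.gene_ids,
            "tf_ids": self.tf_ids,
            "snp_gene_plan": self.snp_gene_plan,
            "intersection_gene_ids": sorted(self.intersection_gene_ids),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def _hwe_probs(p: float) -> np.ndarray:
    return np.array([(1 - p) ** 2, 2 * p * (1 - p), p * p])


def _fit_joint_to_marginals(
    weights: np.ndarray, row_marginal: np.ndarray, col_marginal: np.ndarray,
    n_iter: int = 200,
) -> np.ndarray:
    """Iterative proportional fitting of a positive 3x3 weight table.

    Returns the joint distribution with the given marginals whose odds-ratio
    (interaction) structure matches ``weights``; starting weights of exactly
    zero are floored so the fit stays strictly positive.
    """
    m = np.maximum(np.asarray(weights, dtype=float), 1e-9).copy()
    for _ in range(n_iter):
        m *= (row_marginal / m.sum(axis=1))[:, None]
        m *= col_marginal / m.sum(axis=0)
    return m / m.sum()


# ---------------------------------------------------------------------------
# Cohort


def simulate_cohort(config: SimulationConfig) -> tuple[GenotypeTable, GroundTruth]:
    """Simulate genotypes for a matched case-control cohort with planted signals.

    Null SNPs follow Hardy-Weinberg proportions at family-shifted allele
    frequencies (Balding-Nichols), identically in cases and controls.
    Planted associated SNPs shift the case allele frequency by
    ``assoc_freq_delta``.  Planted epistatic pairs draw case joint genotypes
    from a penetrance-weighted product distribution, giving both a saturated
    9-cell interaction and a marginal frequency shift so the pair members
    reach the single-SNP significant set that seeds the pairwise scan.
    """
    rng = np.random.default_rng(config.seed)
    n_cases, n_pool = config.n_cases, config.n_controls_pool
    n_animals = n_cases + n_pool
    m = config.n_snps

    animal_ids = [f"case{i + 1:03d}" for i in range(n_cases)] + [
        f"ctrl{i + 1:03d}" for i in range(n_pool)
    ]
    labels = {a: CASE for a in animal_ids[:n_cases]}
    labels.update({a: CONTROL for a in animal_ids[n_cases:]})

    snp_ids = [f"snp{j + 1:05d}" for j in range(m)]
    chroms = np.array(
        [f"chr{(j % config.n_chromosomes) + 1}" for j in range(m)], dtype=object
    )
    positions = rng.integers(1, config.chrom_length_bp + 1, size=m)

    # planted indices: associated SNPs first, then epistatic pair members
    planted = rng.permutation(m)[: config.n_assoc_snps + 2 * config.n_epistatic_pairs]
    assoc_idx = planted[: config.n_assoc_snps]
    epi_idx = planted[config.n_assoc_snps :]

    calls = np.empty((n_animals, m), dtype=np.int8)
    family = rng.integers(0, config.n_families, size=n_animals)

    # null SNPs: Balding-Nichols family frequencies around a common frequency
    null_mask = np.ones(m, dtype=bool)
    null_mask[planted] = False
    p_global = rng.uniform(0.15, 0.85, size=m)
    fst = max(config.fst, 1e-6)
    shape = (1.0 - fst) / fst
    for j in np.nonzero(null_mask)[0]:
        p_fam = rng.beta(p_global[j] * shape, (1 - p_global[j]) * shape, size=config.n_families)
        calls[:, j] = rng.binomial(2, p_fam[family])

    # associated SNPs: case frequency shifted by assoc_freq_delta
    for j in assoc_idx:
        p_ctrl = rng.uniform(0.25, 0.45)
        p_case = min(p_ctrl + config.assoc_freq_delta, 0.98)
        calls[:n_cases, j] = rng.binomial(2, p_case, size=n_cases)
        calls[n_cases:, j] = rng.binomial(2, p_ctrl, size=n_pool)

    # epistatic pairs: penetrance-weighted joint genotypes in cases.  The
    # pairwise scan is defined over the single-SNP significant set, so pair
    # members carry a marginal shift strong enough to reach it reliably; the
    # joint table is fitted (IPF) to those exact marginals so the planted
    # interaction rides on top of, not instead of, the marginal signal.
    pen = np.asarray(config.epistasis_penetrance_table, dtype=float)
    pairs = []
    for k in range(config.n_epistatic_pairs):
        ja, jb = epi_idx[2 * k], epi_idx[2 * k + 1]
        pa = rng.uniform(0.35, 0.55)
        pb = rng.uniform(0.35, 0.55)
        shift = config.assoc_freq_delta + 0.10
        pa_case = min(pa + shift, 0.98)
        pb_case = min(pb + shift, 0.98)
        joint_case = _fit_joint_to_marginals(
            pen, _hwe_probs(pa_case), _hwe_probs(pb_case)
        )
        cells = rng.choice(9, size=n_cases, p=joint_case.ravel())
        calls[:n_cases, ja] = cells // 3
        calls[:n_cases, jb] = cells % 3
        calls[n_cases:, ja] = rng.binomial(2, pa, size=n_pool)
        calls[n_cases:, jb] = rng.binomial(2, pb, size=n_pool)
        pairs.append(tuple(sorted((snp_ids[ja], snp_ids[jb]))))

    if config.missing_rate > 0:
        mask = rng.random(calls.shape) < config.missing_rate
        calls[mask] = MISSING

    table = GenotypeTable(
        animal_ids=animal_ids,
        snp_ids=snp_ids,
        chromosomes=chroms,
        positions=positions,
        calls=calls,
        labels=labels,
    )

    truth = _plan_truth(config, rng, snp_ids, assoc_idx, epi_idx, pairs)
    return table, truth


def _plan_truth(config, rng, snp_ids, assoc_idx, epi_idx, pairs) -> GroundTruth:
    """Lay out genes, DE effects and TF memberships consistent with the cohort.

    Each planted SNP anchors its own gene (the SNP will fall inside the gene
    when coordinates are laid out, making it the SNP's nearest gene).  DE
    shifts go to genes anchored by associated SNPs -- those genes then carry
    both expression and cis-association evidence.  Epistatic-pair genes stay
    non-DE; the first TF targets all of them, so the planted intersection of
    the regulatory and epistatic networks is exactly the epistatic gene set.
    """
    gene_ids = [f"gene{i + 1:04d}" for i in range(config.n_genes)]
    tf_ids = [f"TF{i + 1:02d}" for i in range(config.n_tfs)]

    snp_gene_plan: dict[str, str] = {}
    cursor = 0
    for j in list(assoc_idx) + list(epi_idx):
        snp_gene_plan[snp_ids[j]] = gene_ids[cursor]
        cursor += 1
    assoc_genes = [snp_gene_plan[snp_ids[j]] for j in assoc_idx]
    epi_genes = sorted({snp_gene_plan[snp_ids[j]] for j in epi_idx})
    free_genes = gene_ids[cursor:]

    de_gene_ids: dict[str, dict[str, float]] = {}
    de_pool = assoc_genes + free_genes
    for i in range(config.n_de_genes):
        gene = de_pool[i]
        sign = 1.0 if i % 2 == 0 else -1.0
        de_gene_ids[gene] = {v: sign * config.de_effect_sd for v in _DE_VARIETIES}

    tf_memberships: dict[str, set] = {}
    if config.n_tfs > 0:
        # TF 1 binds every epistatic-pair gene; the rest bind non-candidate
        # decoys so spurious pairwise hits cannot enlarge the intersection.
        tf_memberships[tf_ids[0]] = set(epi_genes)
        decoy_pool = [g for g in free_genes if g not in de_gene_ids]
        for t, tf in enumerate(tf_ids[1:], start=1):
            k = min(3, len(decoy_pool))
            if k:
                chosen = rng.choice(len(decoy_pool), size=k, replace=False)
                tf_memberships[tf] = {decoy_pool[c] for c in chosen}
            else:
                tf_memberships[tf] = set()

    return GroundTruth(
        assoc_snp_ids={snp_ids[j] for j in assoc_idx},
        epistatic_pairs=set(pairs),
        de_gene_ids=de_gene_ids,
        tf_memberships=tf_memberships,
        planted_variance_components={
            k: float(v) ** 2 for k, v in config.noise_sds.items()
        },
        gene_ids=gene_ids,
        tf_ids=tf_ids,
        snp_gene_plan=snp_gene_plan,
        intersection_gene_ids=set(epi_genes) if config.n_tfs > 0 else set(),
    )


# ---------------------------------------------------------------------------
# Gene annotation


def simulate_gene_annotation(
    config: SimulationConfig, table: GenotypeTable, truth: GroundTruth,
    gene_span_bp: int = 20_000,
) -> pd.DataFrame:
    """Lay gene intervals on the simulated chromosomes.

    Genes anchored by planted SNPs are placed so the SNP falls inside the
    gene (distance zero -- the SNP's nearest gene).  Remaining genes are
    placed uniformly, rejecting intervals that would cover a planted SNP and
    so tie with an anchored gene.  Returns a BED-like DataFrame with 1-based
    inclusive coordinates (chrom, start_bp, end_bp, gene_id).
    """
    rng = np.random.default_rng(config.seed + 104729)  # distinct stream
    snp_pos = {s: (c, p) for s, c, p in zip(table.snp_ids, table.chromosomes, table.positions)}
    planted_sites = [snp_pos[s] for s in truth.snp_gene_plan]

    rows = []
    anchored = {}
    for snp, gene in truth.snp_gene_plan.items():
        chrom, pos = snp_pos[snp]
        offset = int(rng.integers(1, gene_span_bp))
        start = max(1, pos - offset)
        end = start + gene_span_bp - 1
        anchored[gene] = (chrom, start, end)
        rows.append((chrom, start, end, gene))

    chrom_names = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    for gene in truth.gene_ids:
        if gene in anchored:
            continue
        while True:
            chrom = chrom_names[int(rng.integers(0, config.n_chromosomes))]
            start = int(rng.integers(1, max(config.chrom_length_bp - gene_span_bp, 2)))
            end = start + gene_span_bp - 1
            covers_planted = any(
                c == chrom and start <= p <= end for c, p in planted_sites
            )
            if not covers_planted:
                break
        rows.append((chrom, start, end, gene))

    df = pd.DataFrame(rows, columns=["chrom", "start_bp", "end_bp", "gene_id"])
    return df.sort_values(["chrom", "start_bp"], kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Microarray


def loop_design() -> pd.DataFrame:
    """The 20-hybridisation dye-swap loop over the five varieties.

    All ten unordered variety pairs are hybridised twice, once in each dye
    orientation, so every variety appears on eight slides, four per dye.
    """
    rows = []
    h = 0
    for va, vb in combinations(VARIETIES, 2):
        for red, green in ((va, vb), (vb, va)):
            h += 1
            hyb = f"hyb{h:02d}"
            array = f"A{h:02d}"
            rows.append((hyb, array, 1, "red", red))
            rows.append((hyb, array, 1, "green", green))
    return pd.DataFrame(
        rows, columns=["hybridisation_id", "array_id", "print_block", "dye", "variety"]
    )


def simulate_microarray(config: SimulationConfig, truth: GroundTruth) -> pd.DataFrame:
    """Simulate raw two-colour intensities for the 20-hybridisation loop design.

    Each log2 signal is mu + C + G + AG + DG + VG + e with components drawn
    at the configured SDs; planted DE genes receive their variety-specific VG
    shifts.  Foreground is background + 2^signal, so the acquisition step's
    background correction recovers the signal exactly; a ``low_snr_fraction``
    of genes is emitted below the signal-to-noise threshold in every
    hybridisation and should be removed during acquisition.
    """
    rng = np.random.default_rng(config.seed + 224737)  # distinct stream
    design = loop_design()
    genes = truth.gene_ids
    n_genes = len(genes)
    sds = config.noise_sds

    arrays = design["array_id"].unique()
    g_eff = rng.normal(0.0, sds["gene"], size=n_genes)
    ag_eff = {a: rng.normal(0.0, sds["array_gene"], size=n_genes) for a in arrays}
    dg_eff = {d: rng.normal(0.0, sds["dye_gene"], size=n_genes) for d in ("red", "green")}
    vg_eff = {v: rng.normal(0.0, sds["variety_gene"], size=n_genes) for v in VARIETIES}
    gene_pos = {g: i for i, g in enumerate(genes)}
    for gene, shifts in truth.de_gene_ids.items():
        for variety, shift in shifts.items():
            vg_eff[variety][gene_pos[gene]] += shift
    c_eff = {
        (row.array_id, row.print_block, row.dye): rng.normal(0.0, config.comparison_group_sd)
        for row in design.itertuples(index=False)
    }

    n_low = int(round(config.low_snr_fraction * n_genes))
    low_snr = set(rng.choice(n_genes, size=n_low, replace=False)) if n_low else set()

    records = []
    for row in design.itertuples(index=False):
        cell = (row.array_id, row.print_block, row.dye)
        e = rng.normal(0.0, sds["residual"], size=n_genes)
        signal = (
            config.mu_log2
            + c_eff[cell]
            + g_eff
            + ag_eff[row.array_id]
            + dg_eff[row.dye]
            + vg_eff[row.variety]
            + e
        )
        background = 2.0 ** rng.normal(5.0, 0.2, size=n_genes)
        foreground = background + 2.0 ** signal
        for i, gene in enumerate(genes):
            fg = background[i] * 1.5 if i in low_snr else foreground[i]
            records.append(
                (
                    row.hybridisation_id,
                    row.array_id,
                    row.print_block,
                    row.dye,
                    row.variety,
                    f"probe_{gene}",
                    gene,
                    fg,
                    background[i],
                )
            )
    return pd.DataFrame(
        records,
        columns=[
            "hybridisation_id",
            "array_id",
            "print_block",
            "dye",
            "variety",
            "probe_id",
            "gene_id",
            "foreground",
            "background",
        ],
    )


# ---------------------------------------------------------------------------
# TFBS table


def simulate_tfbs(config: SimulationConfig, truth: GroundTruth) -> pd.DataFrame:
    """TF-to-gene binding-site table with planted memberships at similarity 1.

    Decoy records are drawn over the remaining TF x gene grid at rate
    ``tfbs_density`` with core/matrix similarities strictly below 1, so a
    confidence filter at 1.0 recovers exactly the planted memberships.
    """
    rng = np.random.default_rng(config.seed + 350377)  # distinct stream
    rows = []
    for tf in truth.tf_ids:
        for gene in sorted(truth.tf_memberships.get(tf, ())):
            rows.append((tf, gene, f"prom_{gene}", 1.0, 1.0))
    if config.tfbs_density > 0:
        for tf in truth.tf_ids:
            members = truth.tf_memberships.get(tf, set())
            for gene in truth.gene_ids:
                if gene in members:
                    continue
                if rng.random() < config.tfbs_density:
                    rows.append(
                        (
                            tf,
                            gene,
                            f"prom_{gene}",
                            round(float(rng.uniform(0.80, 0.999)), 4),
                            round(float(rng.uniform(0.80, 0.999)), 4),
                        )
                    )
    return pd.DataFrame(
        rows,
        columns=["tf_name", "gene_id", "promoter_id", "core_similarity", "matrix_similarity"],
    )
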