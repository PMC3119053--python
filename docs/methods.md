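# Methods

`piebaldnet` implements an integrated analysis of a polygenic pigmentation
phenotype (piebald, an asymmetric white-spotting morph in Merino sheep) that
combines four strands of evidence: matched case-control SNP association,
an exhaustive two-locus contingency scan, mixed-model normalization of a
five-variety two-colour microarray, and the intersection of a TFBS-derived
regulatory network with an epistasis-derived gene network. This note records
the models, the parameters that matter, the numerical choices, and what the
synthetic-data tests do and do not demonstrate.

## Cohort construction

Genotypes are coded 0/1/2 as copies of the B allele, with missing calls
excluded pairwise from every statistic. Genetic similarity between two
animals is mean identity-by-state sharing,

    s(i, j) = mean over jointly called SNPs of (2 − |g_i − g_j|) / 2,

bounded in [0, 1] with s = 1 for identical genotypes. Controls are matched
to cases greedily: cases are processed in input order and each takes the
`k = 3` unselected candidates with the highest sharing (ties broken by
candidate order in the matrix); a selected control leaves the pool. The
procedure is deterministic given the matrix and the case order. With 24
cases this yields exactly 72 matched controls.

## Single-SNP association

Each SNP is tested on its 2×2 allele-count table (B vs b alleles by
case/control) with a Pearson chi-square, no continuity correction, 1 df.
The allelic odds ratio is the cross-product `ad/bc`, oriented to be ≥ 1;
a zero cell with unequal frequencies yields a missing OR (no pseudo-count).
A SNP is *significant* only under a dual rule: its case-minus-control mean
genotype difference must lie strictly beyond 3 empirical standard deviations
(population SD, ddof = 0) of the distribution of that difference over all
scored SNPs, **and** its chi-square p-value must fall below 0.001. The two
conditions are a conjunction; neither alone suffices.

Worked-example odds ratios are recovered from published group allele
frequencies by interval arithmetic: a frequency printed with `d` decimals
constrains the integer B-count to `k/n ∈ [f − 0.5·10^−d, f + 0.5·10^−d)`.
Where several integer tables are consistent with both frequencies, the
published OR (itself a function of the true counts) picks the unique
consistent table. This is count reconstruction from rounded summaries, not
fitting: the OR the package reports is always the cross-product of the
reconstructed integer table.

## Two-locus epistasis scan

Every unordered pair of significant SNPs is tested on the 9×2 table of
joint-genotype counts (nine two-locus genotype combinations by case/control)
over animals called at both loci, with a Pearson chi-square evaluated at a
**fixed 8 degrees of freedom**; cells with zero expected count contribute
nothing. Pairs closer than 100 kb on one chromosome are flagged (their
signal may reflect linkage disequilibrium rather than epistasis); flagged
pairs are retained by default and can be excluded by configuration.

Two properties of this test matter for interpretation:

- it responds to *marginal* group differences as well as interactions —
  a pair of two independently associated SNPs is usually "significant"
  without any epistasis. Pair significance therefore means "the joint
  genotype distribution separates cases from controls", exactly as defined,
  not "interaction after removing main effects";
- with 24 cases spread over 9 cells the expected counts are ~2.7 and the
  fixed-df chi-square is conservative (measured marginal null rate ≈ 3×10⁻⁴
  at nominal 0.001 over 60 replicate cohorts). Calibration is demonstrated
  in the asymptotic regime (192 cases / 576 controls, same 1:3 ratio), where
  the measured marginal rate is 0.0010. Because pairs sharing a SNP are
  strongly dependent, calibration is always assessed as an aggregate over
  many replicate cohorts, never from a single scan.

The same asymptotics apply to the single-SNP test: at 48/144 alleles its
p-value carries discreteness atoms (notably at p = 1, mass ≈ 3%, from
tables with exactly proportional counts), so strict Kolmogorov–Smirnov
uniformity is checked on the larger null cohort as well.

Composite LD between two SNPs is the squared Pearson correlation of
genotype codes over jointly called animals (no phasing).

## Microarray acquisition and normalization

The expression data emulate a two-colour skin microarray hybridised in a
20-slide loop: all ten unordered pairs of the five varieties — NOR (white,
normal), PBW (white, piebald), PBB (black, piebald), RSW (white, recessive
black), RSB (black, recessive black) — each hybridised twice, once per dye
orientation. Every variety appears on eight slides, four per dye.

Acquisition keeps a probe only if foreground/background ≥ 2 in at least one
hybridisation, collapses multi-probe genes to the probe with the highest
mean background-corrected intensity, subtracts background with a floor of 1,
and takes log2.

Normalization fits the ANOVA mixed model

    Y = μ + C + G + AG + DG + VG + e

with `C` a fixed comparison-group effect (one level per array × print-block
× dye cell) and `G` (gene), `AG` (array×gene), `DG` (dye×gene), `VG`
(variety×gene), `e` independent zero-mean normal effects. Variance
components are estimated by EM-REML on the mixed-model equations. Because
every random factor is an interaction with gene, the equations have an
arrow structure: after absorbing the fixed cells the coefficient matrix is
block diagonal by gene, so exact inverse-block traces (needed for the EM
updates) cost one small factorization per gene; genes with identical local
designs are batched into a single factorization. The REML log-likelihood is
evaluated every iteration from the factorization
(`ln|V| + ln|X'V⁻¹X| = N ln σ²_e + Σ q_r ln σ²_r + ln|S| + Σ_g ln|D_g|`)
and is non-decreasing under the exact EM steps; the implementation is
cross-checked against a dense `ln|V|`-based evaluation in the tests.

Numerical choices: components are floored at `1e-7 · var(y)`; the ridge
λ_r = σ²_e/σ²_r is floored at `1e-5` because below that the float64 rounding
noise amplified through the near-null directions of the per-gene effect
split exceeds the shrinkage bias the ridge removes. When the residual
variance collapses below `1e-6 · var(y)` the data fit the structural part
exactly: REML sits on the σ²_e = 0 boundary where EM is degenerate, so the
solver refits once with the minimal ridge (effectively unshrunk solutions)
and stops. In that regime the decomposition of a per-gene constant among
G/AG/DG/VG is not identified — variety-gene solutions are recovered exactly
*up to a per-gene additive constant*, which all seven contrasts difference
out. Convergence otherwise requires the relative change of every component
to drop below `1e-6` (default cap 2000 iterations; typical fits converge in
100–200).

Normalized expression is reported per gene × variety as `μ̂ + Ĝ + V̂G`, on
the log2-intensity scale.

## Contrasts and DE calling

Seven fixed contrasts on normalized expression:

    DE1 = PBB − PBW                      (black vs white within piebald)
    DE2 = PBB − RSB                      (piebald vs recessive within black)
    DE3 = PBW − NOR                      (piebald vs normal within white)
    DE4 = PBW − RSW                      (piebald vs recessive within white)
    DE5 = PBW − ½(NOR + RSW)             (piebald vs others within white)
    DE6 = ½(PBW+PBB) − ⅓(NOR+RSW+RSB)    (piebald vs non-piebald)
    DE7 = ½(PBB+RSB) − ⅓(NOR+PBW+RSW)    (black vs white)

Each contrast is standardized across genes and a gene is called DE in a
contrast when |z| ≥ 2.57 (the threshold is kept as the literal constant
2.57, two-sided normal tail mass ≈ 0.0102, not recomputed as 2.576). The
standardization is across-gene (empirical mean and SD of the contrast over
all genes), a choice made because the model-based alternative (a standard
error from the fit) is not uniquely implied by the DE rule; it is flagged
here as a choice. A zero-spread contrast yields no calls. The per-gene
*piebald score* is mean(DE3, DE5, DE6) — the three contrasts that compare
piebald with non-piebald tissue and that are the most strongly correlated
across genes — and colours network nodes: over (z ≥ +2.57), under
(z ≤ −2.57), unchanged, or absent for genes never measured on the array.

## SNP-to-gene annotation and the piebald-gene call

Gene intervals are 1-based inclusive; strand is ignored. Each SNP maps to
its nearest same-chromosome gene, distance measured to the nearer interval
edge (0 when intragenic); exact ties go to the gene with the lower start.
Categories: intragenic, cis (≤ 2,500 bp), proximal (≤ 20,000 bp), distal
(> 20 kb); SNPs on gene-less chromosomes stay unmapped. "Within 1 Mb" means
SNP-to-gene-edge distance ≤ 1,000,000 bp for both the gene-centric and
SNP-centric phrasings.

A gene is *piebald-associated* when either (i) it is DE in ≥ 1 contrast and
a SNP maps to it as nearest gene within 2.5 kb, or (ii) it shows no DE but a
SNP from the dual-rule significant set lies within 1 Mb. Each qualifying
gene is reported once with its criterion and its most associated SNP within
1 Mb (smallest p-value).

## Networks

The regulatory network links a TF to a candidate (piebald-associated) gene
when a binding-site record passes the confidence filter: core **and** matrix
similarity ≥ 1.0 (exact-match confidence). Candidate genes are carried as
nodes even when unlinked, coloured by the piebald score; TF nodes enter when
they link ≥ 1 candidate.

The epistatic network joins the nearest genes of the two SNPs in each
significant pair. Pairs collapsing onto one gene are dropped as self-edges
(but still count toward that gene's pair tally); several pairs mapping to
one gene pair collapse to a single edge annotated with the pair count. A
*hub* is a gene participating in strictly more than 20 significant pairs
(tallied per gene, after SNP→gene mapping, before edge collapsing); the
reduced network keeps the edges incident to at least one hub.

The *intersecting landscape* is the set of gene nodes **linked** (degree
≥ 1) in both networks; TF nodes and isolated candidate nodes never count.
Counting only wired-in genes matters because the 9×2 test is significant for
pairs of marginally associated SNPs, so the epistatic network legitimately
contains many associated genes; requiring a TF link on the regulatory side
is what makes the intersection selective. The pipeline intersects the
regulatory network with the **full** epistatic network: the hub reduction is
a display-complexity device, and at desk scale no gene reaches the >20-pair
bar; the reduced network is still built and exported. Exports are
Cytoscape-compatible SIF, GraphML (with node type, colour, degree and
intersection tags) and a node-attribute TSV, each with a round-trip reader.

## Synthetic data: what it emulates, and what it does not

The generator's defaults are the study conditions the pipeline targets:
24 cases and a 72-control pool genotyped at 5,000 SNPs on 26 chromosomes,
12 planted associated SNPs at Δfreq = 0.35, 3 planted epistatic pairs,
8 relatedness families (Balding–Nichols Beta-shifted family frequencies at
F = 0.05 — enough structure to exercise control matching without modelling
real pedigrees), 200 genes on the 20-hybridisation loop with 10 DE genes at
±2.0 log2 units in the piebald tissues (PBW, PBB), per-component noise SDs
(gene 2.0, array×gene 0.3, dye×gene 0.2, variety×gene 0.5, residual 0.5,
comparison-group 0.25 around a log2 mean of 8), 4 TFs, decoy binding sites
at density 0.02 with similarity < 1, and 5% of genes emitted below the
signal-to-noise threshold. Null SNP frequencies are uniform on
[0.15, 0.85], the common-variant spectrum a genotyping array targets.

Epistatic pairs are planted by reweighting the case joint-genotype table
with a 3×3 penetrance-style weight matrix (default: diagonal concentration,
a saturated interaction) and then fitting it by iterative proportional
fitting to exact target marginals. The members carry a marginal case
frequency shift of Δ + 0.10 over control frequencies in [0.35, 0.55]:
the pairwise scan is *defined* over the single-SNP significant set, so
planted pairs must reliably clear the single-locus entry rule for the
two-locus machinery to be exercised at all; the IPF step guarantees the
planted interaction rides on top of, not instead of, that marginal signal.

Planted SNPs anchor genes that contain them (distance 0), decoy genes are
placed away from planted SNPs, the first TF binds every epistatic-pair
gene, and the remaining TFs bind non-candidate decoys. The planted
regulatory∩epistatic intersection is therefore exactly the epistatic-pair
gene set, and chance significant pairs among the associated SNPs cannot
enlarge it (their genes are never TF-linked).

What passing the synthetic tests does **not** show about real data: the
generator has no linkage disequilibrium, recombination map, or
sequence-level promoters; family structure is exchangeable rather than
pedigree-derived; expression noise is Gaussian on the log2 scale with
exactly the model's variance structure (so the normalization model is
correctly specified by construction); and TFBS decoys are independent
noise rather than homologous-motif artefacts. Recovery rates measured here
are upper bounds on what identically parameterized real data would give.

## Problem sizes used in the checks

The acceptance checks run at desk scale, chosen once: the pairwise-scan
identity on a 226-SNP/96-animal cohort (25,425 pairs); calibration on
192/576 null cohorts (5,000 SNPs for the KS check; 40 replicate 60-SNP
cohorts, 70,800 pairs, for the epistasis rate); variance-component recovery
on 200-gene/20-hybridisation arrays at σ²_VG = 0.5, σ²_e = 0.25 over 10–20
replicate fits; and end-to-end intersection recovery over 10–20 pipeline
runs at the full default configuration. Dataset-level tallies from the
motivating study (226 associated SNPs, 645 significant pairs, 13
intersection genes, and so on) depend on the real genotype and expression
data and are not reproduced by synthetic cohorts; the rules that produced
them are what the tests pin down.

## Known limitations

- The dual significance rule uses the absolute deviation of the genotype
  difference from the genome-wide mean; a signed one-tailed variant is not
  implemented.
- The OR reconstruction requires the published OR when the printed
  frequencies leave more than one integer table; if no consistent table
  reproduces the OR the function refuses rather than guessing.
- The EM-REML solver targets the crossed gene-interaction structure of this
  model; it is not a general-purpose mixed-model engine (no arbitrary
  random-effect covariances, no AI-REML acceleration).
- Network exports cover SIF/GraphML/TSV; binary Cytoscape sessions, layout
  and module-enrichment statistics are out of scope.
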