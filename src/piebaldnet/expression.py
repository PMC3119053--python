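"""Two-colour microarray acquisition, mixed-model normalization and DE calling.

The normalization model for a background-corrected, log2-scale intensity
reading is

    Y = mu + C + G + AG + DG + VG + e

where ``C`` is a fixed "comparison group" effect for readings sharing an
array slide, printing block and dye channel, and ``G`` (gene), ``AG``
(array x gene), ``DG`` (dye x gene), ``VG`` (variety x gene) and ``e`` are
independent zero-mean normal random effects.  Variance components are
estimated by EM-REML on the mixed-model equations and the BLUP solutions of
the variety-by-gene effect, offset by ``mu + G``, serve as the normalized
expression of each gene in each variety.

The mixed-model equations have an arrow structure: every random effect is an
interaction with gene, so after absorbing the fixed comparison-group cells
the coefficient matrix is block diagonal by gene.  The solver factorizes one
small block per gene (and genes sharing an identical local design are batched
together), which keeps exact EM-REML trace computations cheap even with
thousands of genes.

Seven differential-expression contrasts (DE1-DE7) compare the five skin
varieties NOR, PBW, PBB, RSW, RSB; a gene is called DE in a contrast when its
value lies beyond ``sd_threshold`` (default 2.57) across-gene standard
deviations from the across-gene mean of that contrast.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VARIETIES = ("NOR", "PBW", "PBB", "RSW", "RSB")

#: Contrast definitions as {variety: coefficient} on normalized expression.
CONTRASTS: dict[str, dict[str, float]] = {
    # black vs white within piebald
    "DE1": {"PBB": 1.0, "PBW": -1.0},
    # piebald vs recessive within black
    "DE2": {"PBB": 1.0, "RSB": -1.0},
    # piebald vs normal within white
    "DE3": {"PBW": 1.0, "NOR": -1.0},
    # piebald vs recessive within white
    "DE4": {"PBW": 1.0, "RSW": -1.0},
    # piebald vs others within white
    "DE5": {"PBW": 1.0, "NOR": -0.5, "RSW": -0.5},
    # piebald vs non-piebald
    "DE6": {"PBW": 0.5, "PBB": 0.5, "NOR": -1 / 3, "RSW": -1 / 3, "RSB": -1 / 3},
    # black vs white
    "DE7": {"PBB": 0.5, "RSB": 0.5, "NOR": -1 / 3, "PBW": -1 / 3, "RSW": -1 / 3},
}

CONTRAST_NAMES = tuple(CONTRASTS)

#: Contrasts comparing piebald against non-piebald tissue; their mean is the
#: per-gene "piebald score" used to colour network nodes.
PIEBALD_CONTRASTS = ("DE3", "DE5", "DE6")

DEFAULT_SNR_MIN = 2.0
DEFAULT_DE_SD = 2.57

INTENSITY_COLUMNS = (
    "hybridisation_id",
    "array_id",
    "print_block",
    "dye",
    "variety",
    "probe_id",
    "gene_id",
    "foreground",
    "background",
)

_FACTORS = ("gene", "array_gene", "dye_gene", "variety_gene")

#: smallest ridge used in the mixed-model equations; below this the float64
#: rounding noise amplified through the near-null effect-split directions
#: would exceed the shrinkage bias the ridge removes
RIDGE_MIN = 1e-5


def _check_intensity(df: pd.DataFrame) -> None:
    missing = [c for c in INTENSITY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"intensity table is missing columns {missing}")


# ---------------------------------------------------------------------------
# Acquisition


def acquire(
    raw: pd.DataFrame, snr_min: float = DEFAULT_SNR_MIN, floor: float = 1.0
) -> pd.DataFrame:
    """Apply the acquisition filters and return log2 background-corrected data.

    A probe is kept only if its foreground/background ratio reaches
    ``snr_min`` in at least one hybridisation (a probe below the ratio in
    *all* hybridisations is deemed undetectable).  Genes represented by
    several surviving probes are collapsed to the probe with the highest
    mean background-corrected intensity across hybridisations.  The output
    carries one probe per gene and a ``log2_intensity`` column equal to
    ``log2(max(foreground - background, floor))``.
    """
    _check_intensity(raw)
    if raw.empty:
        raise ValueError("intensity table is empty")
    df = raw.copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        snr = df["foreground"] / df["background"]
    detectable = snr.groupby(df["probe_id"]).transform("max") >= snr_min
    df = df[detectable]
    if df.empty:
        raise ValueError(f"all probes fall below signal-to-noise {snr_min}")

    corrected = np.maximum(df["foreground"] - df["background"], floor)
    df = df.assign(log2_intensity=np.log2(corrected), _corrected=corrected)

    probe_mean = df.groupby(["gene_id", "probe_id"])["_corrected"].mean()
    best = probe_mean.groupby(level="gene_id").idxmax()
    keep_probes = {probe for (_gene, probe) in best}
    df = df[df["probe_id"].isin(keep_probes)].drop(columns="_corrected")
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# EM-REML normalization


@dataclass
class NormalizationFit:
    """REML variance components and effect solutions of the normalization model."""

    mu: float
    comparison_group_effects: pd.Series
    variance_components: dict[str, float]
    gene_solutions: pd.Series
    variety_gene_solutions: pd.DataFrame
    normalized_expression: pd.DataFrame
    converged: bool
    iterations: int
    loglik_history: np.ndarray = field(default_factory=lambda: np.empty(0))


def _local_designs(df: pd.DataFrame):
    """Per-gene local design matrices for the arrow-structured MME.

    Returns the fixed-cell index per record, the per-gene record groups,
    and for each gene its (Z, factor_of_column, level keys) local design.
    """
    cell = list(zip(df["array_id"], df["print_block"], df["dye"]))
    cell_levels = sorted(set(cell), key=repr)
    cell_idx = {c: i for i, c in enumerate(cell_levels)}
    xcol = np.array([cell_idx[c] for c in cell], dtype=np.intp)

    designs = {}
    for gene, sub in df.groupby("gene_id", sort=True):
        arrays = sorted(set(sub["array_id"]), key=repr)
        dyes = sorted(set(sub["dye"]), key=repr)
        varieties = sorted(set(sub["variety"]), key=repr)
        cols: list[tuple[int, object]] = [(0, gene)]
        cols += [(1, a) for a in arrays]
        cols += [(2, d) for d in dyes]
        cols += [(3, v) for v in varieties]
        col_idx = {key: i for i, key in enumerate(cols)}
        n_g, q_g = len(sub), len(cols)
        Z = np.zeros((n_g, q_g))
        for r, (a, d, v) in enumerate(zip(sub["array_id"], sub["dye"], sub["variety"])):
            Z[r, 0] = 1.0
            Z[r, col_idx[(1, a)]] = 1.0
            Z[r, col_idx[(2, d)]] = 1.0
            Z[r, col_idx[(3, v)]] = 1.0
        factor_of_col = np.array([f for f, _ in cols], dtype=np.intp)
        designs[gene] = (
            sub.index.to_numpy(),
            Z,
            factor_of_col,
            [key for _, key in cols],
        )
    return xcol, cell_levels, designs


def fit_normalization_model(
    data: pd.DataFrame,
    tol: float = 1e-6,
    max_iter: int = 2000,
    initial_components: dict[str, float] | None = None,
) -> NormalizationFit:
    """EM-REML fit of the mu + C + G + AG + DG + VG + e normalization model.

    ``data`` is the output of :func:`acquire` (or any long-format table with
    the intensity columns plus ``log2_intensity``).  Iterates the EM updates
    of the five variance components until the relative change of every
    component drops below ``tol``; the REML log-likelihood is recorded at
    every iteration and is non-decreasing under exact EM steps.
    """
    _check_intensity(data)
    if "log2_intensity" not in data.columns:
        data = acquire(data)
    df = data.reset_index(drop=True)
    y = df["log2_intensity"].to_numpy(dtype=float)
    n_genes = df["gene_id"].nunique()
    if n_genes < 2:
        raise ValueError("normalization needs at least two genes")
    if df["variety"].nunique() < 2:
        raise ValueError("normalization needs at least two varieties")

    xcol, cell_levels, designs = _local_designs(df)
    p = len(cell_levels)
    N = y.size
    if N <= p:
        raise ValueError("fewer observations than fixed comparison-group cells")

    xtx = np.bincount(xcol, minlength=p).astype(float)
    xty = np.bincount(xcol, weights=y, minlength=p)
    yty = float(y @ y)

    # group genes whose local design (Z pattern and fixed-cell pattern) agrees
    groups: dict[bytes, dict] = {}
    gene_order = []
    for gene, (rows, Z, foc, keys) in designs.items():
        gene_order.append(gene)
        sig = Z.tobytes() + foc.tobytes() + xcol[rows].tobytes()
        grp = groups.setdefault(
            sig,
            {"Z": Z, "foc": foc, "genes": [], "rows": [], "keys": []},
        )
        grp["genes"].append(gene)
        grp["rows"].append(rows)
        grp["keys"].append(keys)

    q_r = np.zeros(4)
    for grp in groups.values():
        counts = np.bincount(grp["foc"], minlength=4)
        q_r += counts * len(grp["genes"])

    for grp in groups.values():
        Z, foc = grp["Z"], grp["foc"]
        rows0 = grp["rows"][0]
        grp["ZtZ"] = Z.T @ Z
        ZtX = np.zeros((Z.shape[1], p))
        np.add.at(ZtX.T, xcol[rows0], Z)  # records of every member share xcol pattern
        grp["ZtX"] = ZtX
        grp["Zty"] = np.stack([y[rows] @ Z for rows in grp["rows"]])
        grp["ysum_by_gene"] = np.array([float(y[rows] @ y[rows]) for rows in grp["rows"]])

    var_y = float(np.var(y)) or 1.0
    floor_v = 1e-7 * var_y
    if initial_components is None:
        comps = np.full(4, var_y / 8.0)
        sig_e = var_y / 2.0
    else:
        comps = np.array([max(initial_components[f], floor_v) for f in _FACTORS])
        sig_e = max(initial_components["residual"], floor_v)

    def _inv(mat):
        try:
            return np.linalg.inv(mat)
        except np.linalg.LinAlgError:
            return np.linalg.pinv(mat)

    logliks = []
    converged = False
    boundary = False
    it = 0
    for it in range(1, max_iter + 1):
        # work with the lambda-scaled mixed-model equations: blocks
        # Z'Z + diag(lambda_r) stay O(1)-conditioned even as sigma2_e -> 0,
        # where the unscaled form degenerates (the per-gene effect split is
        # only identified through the ridge).
        # the ridge keeps a numerically meaningful floor: below ~1e-7 the
        # amplification of float64 rounding noise in the near-null space of
        # Z'Z (the per-gene effect split) would swamp the solutions
        lam = np.maximum(sig_e / np.maximum(comps, floor_v), RIDGE_MIN)
        logdet_blocks = 0.0  # sum of ln|D*_g| in the unscaled metric
        S_l = np.diag(xtx.astype(float))
        s_rhs = xty.copy()
        q_total = 0
        for grp in groups.values():
            g_count = len(grp["genes"])
            q_g = grp["Z"].shape[1]
            q_total += g_count * q_g
            D_l = grp["ZtZ"] + np.diag(lam[grp["foc"]])
            Dinv_l = _inv(D_l)
            DW = Dinv_l @ grp["ZtX"]  # q x p
            S_l -= g_count * (grp["ZtX"].T @ DW)
            s_rhs -= DW.T @ grp["Zty"].sum(axis=0)
            grp["Dinv_l"], grp["DW"] = Dinv_l, DW
            _, ld = np.linalg.slogdet(D_l)
            logdet_blocks += g_count * (ld - q_g * np.log(sig_e))

        Sinv_l = _inv(S_l)
        beta = Sinv_l @ s_rhs

        ssq = np.zeros(4)
        trace = np.zeros(4)
        e_term = yty - float(beta @ xty)
        for grp in groups.values():
            g_count = len(grp["genes"])
            Dinv_l, DW = grp["Dinv_l"], grp["DW"]
            u_hat = (grp["Zty"] - (grp["ZtX"] @ beta)[None, :]) @ Dinv_l.T
            grp["u_hat"] = u_hat
            e_term -= float((u_hat * grp["Zty"]).sum())
            diag_c = sig_e * (
                np.diag(Dinv_l) + np.einsum("ij,jk,ik->i", DW, Sinv_l, DW)
            )
            for f in range(4):
                sel = grp["foc"] == f
                ssq[f] += float((u_hat[:, sel] ** 2).sum())
                trace[f] += g_count * float(diag_c[sel].sum())

        y_py = e_term / sig_e
        _, logdet_sl = np.linalg.slogdet(S_l)
        logdet_s = logdet_sl - p * np.log(sig_e)
        loglik = -0.5 * (
            N * np.log(sig_e)
            + float(q_r @ np.log(np.maximum(comps, floor_v)))
            + logdet_blocks
            + logdet_s
            + y_py
        )
        logliks.append(loglik)
        if boundary:
            converged = True
            break

        new_comps = (ssq + trace) / np.maximum(q_r, 1.0)
        new_sig_e = e_term / (N - p)
        new_comps = np.maximum(new_comps, 0.0)
        new_sig_e = max(new_sig_e, floor_v)
        if new_sig_e <= 1e-6 * var_y:
            # residual variance collapsed: the data fit the structural part
            # exactly and REML sits on the sigma2_e = 0 boundary where EM is
            # degenerate.  Refit once with the minimal ridge (effectively
            # unshrunk solutions) and stop there.
            logger.info("residual variance at boundary; stopping with unshrunk fit")
            boundary = True
            report_comps = new_comps.copy()
            sig_e = floor_v
            comps = np.full(4, sig_e / RIDGE_MIN)
            continue

        old = np.append(comps, sig_e)
        new = np.append(new_comps, new_sig_e)
        rel = np.abs(new - old) / np.maximum(np.abs(old), floor_v)
        comps, sig_e = new_comps, new_sig_e
        if np.all(rel < tol):
            converged = True
            break
    if not converged:
        logger.warning("EM-REML did not converge within %d iterations", max_iter)

    reported = report_comps if boundary else comps
    variance_components = {f: float(max(c, 0.0)) for f, c in zip(_FACTORS, reported)}
    variance_components["residual"] = 0.0 if boundary else float(sig_e)

    mu = float(np.mean(beta))
    cell_effects = pd.Series(
        beta - mu, index=pd.Index([repr(c) for c in cell_levels], name="cell")
    )

    gene_sol = {}
    vg = {}
    for grp in groups.values():
        for gi, gene in enumerate(grp["genes"]):
            u = grp["u_hat"][gi]
            keys = grp["keys"][gi]
            for col, (f, key) in enumerate(zip(grp["foc"], keys)):
                if f == 0:
                    gene_sol[gene] = float(u[col])
                elif f == 3:
                    vg.setdefault(gene, {})[key] = float(u[col])

    genes = sorted(gene_sol)
    varieties = sorted({v for d in vg.values() for v in d})
    # present five-variety data in canonical variety order
    if set(varieties) <= set(VARIETIES):
        varieties = [v for v in VARIETIES if v in set(varieties)]
    gene_solutions = pd.Series([gene_sol[g] for g in genes], index=pd.Index(genes, name="gene_id"))
    vg_df = pd.DataFrame(
        [[vg.get(g, {}).get(v, np.nan) for v in varieties] for g in genes],
        index=gene_solutions.index,
        columns=varieties,
    )
    normalized = vg_df.add(gene_solutions, axis=0) + mu

    return NormalizationFit(
        mu=mu,
        comparison_group_effects=cell_effects,
        variance_components=variance_components,
        gene_solutions=gene_solutions,
        variety_gene_solutions=vg_df,
        normalized_expression=normalized,
        converged=converged,
        iterations=it,
        loglik_history=np.asarray(logliks),
    )


def reml_loglik_dense(data: pd.DataFrame, components: dict[str, float]) -> float:
    """Direct dense-matrix REML log-likelihood of the normalization model.

    Builds V = sum_r sigma2_r Z_r Z_r' + sigma2_e I explicitly.  Quadratic in
    memory and cubic in time, intended as an independent cross-check of the
    structured solver on small inputs.
    """
    _check_intensity(data)
    df = data.reset_index(drop=True)
    y = df["log2_intensity"].to_numpy(dtype=float)
    n = y.size
    cell = pd.Series(list(zip(df["array_id"], df["print_block"], df["dye"])))
    X = pd.get_dummies(cell.apply(repr)).to_numpy(dtype=float)

    def indicator(*cols):
        key = df[list(cols)].astype(str).agg("|".join, axis=1)
        return pd.get_dummies(key).to_numpy(dtype=float)

    V = components["residual"] * np.eye(n)
    for f, cols in (
        ("gene", ("gene_id",)),
        ("array_gene", ("array_id", "gene_id")),
        ("dye_gene", ("dye", "gene_id")),
        ("variety_gene", ("variety", "gene_id")),
    ):
        Z = indicator(*cols)
        V += components[f] * (Z @ Z.T)
    Vinv = np.linalg.inv(V)
    XtVinvX = X.T @ Vinv @ X
    beta = np.linalg.solve(XtVinvX, X.T @ Vinv @ y)
    resid = y - X @ beta
    _, ld_v = np.linalg.slogdet(V)
    _, ld_x = np.linalg.slogdet(XtVinvX)
    return float(-0.5 * (ld_v + ld_x + resid @ Vinv @ resid))


# ---------------------------------------------------------------------------
# Contrasts and DE calling


@dataclass
class DEResult:
    """Per-gene contrast values, z-scores, DE flags and network colour."""

    gene_id: str
    de_values: dict[str, float]
    z_scores: dict[str, float] = field(default_factory=dict)
    de_flags: dict[str, bool] = field(default_factory=dict)
    n_de_contrasts: int = 0
    piebald_score: float = float("nan")
    colour_category: str = "unchanged"


def compute_contrasts(fit) -> list[DEResult]:
    """Evaluate the seven DE contrasts on normalized gene-by-variety expression.

    ``fit`` may be a :class:`NormalizationFit` or a gene x variety DataFrame.
    All five varieties must be present.
    """
    expr = fit.normalized_expression if isinstance(fit, NormalizationFit) else fit
    for v in VARIETIES:
        if v not in expr.columns:
            raise ValueError(f"missing variety {v!r} in normalized expression")
    results = []
    for gene, row in expr.iterrows():
        values = {
            name: float(sum(coef * row[v] for v, coef in spec.items()))
            for name, spec in CONTRASTS.items()
        }
        results.append(DEResult(gene_id=str(gene), de_values=values))
    return results


def call_de(
    results: list[DEResult], sd_threshold: float = DEFAULT_DE_SD
) -> list[DEResult]:
    """Standardize each contrast across genes and flag |z| >= sd_threshold.

    A contrast with zero across-gene standard deviation yields no DE calls
    (all flags False) and a logged warning.  Mutates and returns ``results``.
    """
    if len(results) < 3:
        raise ValueError("DE calling needs at least three genes")
    mat = np.array(
        [[r.de_values[c] for c in CONTRAST_NAMES] for r in results], dtype=float
    )
    mean = mat.mean(axis=0)
    sd = mat.std(axis=0, ddof=0)
    degenerate = sd == 0
    if degenerate.any():
        logger.warning(
            "contrasts %s have zero spread across genes; no DE calls made there",
            [c for c, b in zip(CONTRAST_NAMES, degenerate) if b],
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (mat - mean) / np.where(degenerate, np.nan, sd)
    for i, r in enumerate(results):
        r.z_scores = {c: float(z[i, j]) for j, c in enumerate(CONTRAST_NAMES)}
        r.de_flags = {
            c: bool(not degenerate[j] and abs(z[i, j]) >= sd_threshold)
            for j, c in enumerate(CONTRAST_NAMES)
        }
        r.n_de_contrasts = sum(r.de_flags.values())
    return results


def de_gene_subset(results: list[DEResult], min_contrasts: int = 4) -> list[DEResult]:
    """Genes called DE in at least ``min_contrasts`` of the seven contrasts."""
    return [r for r in results if r.n_de_contrasts >= min_contrasts]


def contrast_correlations(
    results: list[DEResult], sd_threshold: float = DEFAULT_DE_SD
) -> pd.DataFrame:
    """Pearson correlations of the 7 contrasts across genes; colour each gene.

    Also fills, per gene, the piebald score (mean of DE3, DE5, DE6 -- the
    piebald versus non-piebald contrasts) and a colour category: "over"
    ("under") when the score's across-gene z exceeds +(-)``sd_threshold``,
    else "unchanged".  Genes never seen on the array are represented
    downstream as "absent"; they do not appear among ``results``.
    """
    if len(results) < 3:
        raise ValueError("contrast correlations need at least three genes")
    mat = np.array(
        [[r.de_values[c] for c in CONTRAST_NAMES] for r in results], dtype=float
    )
    corr = pd.DataFrame(
        np.corrcoef(mat, rowvar=False), index=CONTRAST_NAMES, columns=CONTRAST_NAMES
    )
    score = mat[:, [CONTRAST_NAMES.index(c) for c in PIEBALD_CONTRASTS]].mean(axis=1)
    mean, sd = score.mean(), score.std(ddof=0)
    for i, r in enumerate(results):
        r.piebald_score = float(score[i])
        if sd == 0:
            r.colour_category = "unchanged"
        else:
            z = (score[i] - mean) / sd
            r.colour_category = "over" if z >= sd_threshold else "under" if z <= -sd_threshold else "unchanged"
    return corr


def de_frame(results: list[DEResult]) -> pd.DataFrame:
    """Flatten DE results into a TSV-ready DataFrame."""
    rows = []
    for r in results:
        row = {"gene_id": r.gene_id}
        row.update({c: r.de_values[c] for c in CONTRAST_NAMES})
        row.update({f"z_{c}": r.z_scores.get(c, np.nan) for c in CONTRAST_NAMES})
        row.update({f"flag_{c}": r.de_flags.get(c, False) for c in CONTRAST_NAMES})
        row["n_de_contrasts"] = r.n_de_contrasts
        row["piebald_score"] = r.piebald_score
        row["colour_category"] = r.colour_category
        rows.append(row)
    return pd.DataFrame(rows)
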