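"""Acquisition filters, mixed-model normalization and DE contrast calling."""

import numpy as np
import pandas as pd
import pytest

from piebaldnet.expression import (
    CONTRAST_NAMES,
    VARIETIES,
    acquire,
    call_de,
    compute_contrasts,
    contrast_correlations,
    de_gene_subset,
    fit_normalization_model,
    reml_loglik_dense,
)
from piebaldnet.simulate import SimulationConfig, simulate_cohort, simulate_microarray

from conftest import EXPRESSION_ROWS


def intensity_record(hyb, dye, variety, probe, gene, fg, bg, array=None):
    return {
        "hybridisation_id": hyb,
        "array_id": array or f"A_{hyb}",
        "print_block": 1,
        "dye": dye,
        "variety": variety,
        "probe_id": probe,
        "gene_id": gene,
        "foreground": fg,
        "background": bg,
    }


def small_noise_config(**kw):
    defaults = dict(
        n_snps=50, n_assoc_snps=2, n_epistatic_pairs=1, n_genes=30, n_de_genes=2,
        low_snr_fraction=0.0,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


# ---------------------------------------------------------------------------
# Acquisition


def test_snr_filter_requires_one_passing_hybridisation():
    rows = []
    for h in range(3):
        rows.append(intensity_record(f"h{h}", "red", "NOR", "p_low", "gA", 150.0, 100.0))
    for h in range(3):
        fg = 250.0 if h == 0 else 150.0  # one hybridisation above ratio 2
        rows.append(intensity_record(f"h{h}", "red", "NOR", "p_ok", "gB", fg, 100.0))
    out = acquire(pd.DataFrame(rows))
    assert set(out["probe_id"]) == {"p_ok"}


def test_multi_probe_gene_collapses_to_most_abundant():
    rows = []
    for h in range(2):
        rows.append(intensity_record(f"h{h}", "red", "NOR", "p500", "g", 600.0, 100.0))
        rows.append(intensity_record(f"h{h}", "red", "NOR", "p800", "g", 900.0, 100.0))
    out = acquire(pd.DataFrame(rows))
    assert set(out["probe_id"]) == {"p800"}


def test_background_correction_arithmetic():
    rows = [intensity_record("h0", "red", "NOR", "p", "g", 1024.0, 0.0)]
    out = acquire(pd.DataFrame(rows))
    assert out["log2_intensity"].iloc[0] == pytest.approx(10.0)


def test_all_probes_filtered_is_an_error():
    rows = [intensity_record("h0", "red", "NOR", "p", "g", 150.0, 100.0)]
    with pytest.raises(ValueError):
        acquire(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Normalization model


def test_loglik_matches_dense_oracle():
    cfg = small_noise_config(n_genes=8, n_de_genes=2, seed=3)
    _, truth = simulate_cohort(cfg)
    acq = acquire(simulate_microarray(cfg, truth))
    comps = {"gene": 1.5, "array_gene": 0.2, "dye_gene": 0.1,
             "variety_gene": 0.4, "residual": 0.3}
    fit = fit_normalization_model(acq, max_iter=1, initial_components=comps)
    assert fit.loglik_history[0] == pytest.approx(reml_loglik_dense(acq, comps), abs=1e-8)


def test_loglik_nondecreasing_and_components_nonnegative():
    cfg = small_noise_config(n_genes=40, seed=7)
    _, truth = simulate_cohort(cfg)
    fit = fit_normalization_model(acquire(simulate_microarray(cfg, truth)))
    assert fit.converged
    diffs = np.diff(fit.loglik_history)
    assert np.all(diffs >= -1e-7)
    assert all(v >= 0 for v in fit.variance_components.values())


def test_zero_noise_recovers_planted_effects_up_to_gene_constant():
    cfg = small_noise_config(
        n_genes=30, n_de_genes=4, de_effect_sd=2.0, seed=2,
        noise_sds={"gene": 0.0, "array_gene": 0.0, "dye_gene": 0.0,
                   "variety_gene": 0.0, "residual": 0.0},
    )
    _, truth = simulate_cohort(cfg)
    fit = fit_normalization_model(acquire(simulate_microarray(cfg, truth)))
    vg = fit.variety_gene_solutions
    for gene, shifts in truth.de_gene_ids.items():
        planted = np.array([shifts.get(v, 0.0) for v in vg.columns])
        dev = vg.loc[gene].to_numpy() - planted
        dev -= dev.mean()  # per-gene constant is unidentified
        assert np.abs(dev).max() < 1e-2
    null_genes = [g for g in vg.index if g not in truth.de_gene_ids]
    spread = vg.loc[null_genes].sub(vg.loc[null_genes].mean(axis=1), axis=0)
    assert float(spread.abs().max().max()) < 1e-2


def test_fit_invariant_to_record_order():
    cfg = small_noise_config(n_genes=12, seed=11)
    _, truth = simulate_cohort(cfg)
    acq = acquire(simulate_microarray(cfg, truth))
    fit1 = fit_normalization_model(acq)
    shuffled = acq.sample(frac=1.0, random_state=4).reset_index(drop=True)
    fit2 = fit_normalization_model(shuffled)
    for k in fit1.variance_components:
        assert fit1.variance_components[k] == pytest.approx(
            fit2.variance_components[k], rel=1e-6, abs=1e-10
        )
    pd.testing.assert_frame_equal(
        fit1.normalized_expression, fit2.normalized_expression, atol=1e-6
    )


def test_variance_component_recovery_within_sampling_error():
    true = {"gene": 4.0, "array_gene": 0.09, "dye_gene": 0.04,
            "variety_gene": 0.5, "residual": 0.25}
    sds = {"gene": 2.0, "array_gene": 0.3, "dye_gene": 0.2,
           "variety_gene": float(np.sqrt(0.5)), "residual": 0.5}
    est = []
    for seed in range(8):
        cfg = SimulationConfig(n_genes=200, n_de_genes=0, low_snr_fraction=0.0,
                               noise_sds=sds, seed=seed)
        _, truth = simulate_cohort(cfg)
        fit = fit_normalization_model(acquire(simulate_microarray(cfg, truth)))
        est.append([fit.variance_components[k] for k in true])
    est = np.array(est)
    for i, k in enumerate(true):
        mean, sd = est[:, i].mean(), est[:, i].std(ddof=1)
        assert abs(mean - true[k]) <= 3 * sd, k


# ---------------------------------------------------------------------------
# Contrasts


def test_contrast_arithmetic_on_reference_rows():
    expr = pd.DataFrame(EXPRESSION_ROWS).T
    expr.index.name = "gene_id"
    results = {r.gene_id: r for r in compute_contrasts(expr[list(VARIETIES)])}
    assert results["ATRN"].de_values["DE3"] == pytest.approx(2.27, abs=1e-9)
    assert results["ATRN"].de_values["DE5"] == pytest.approx(0.85, abs=1e-9)
    assert results["IGFBP7"].de_values["DE3"] == pytest.approx(-1.67, abs=1e-9)


def test_equal_varieties_give_zero_contrasts():
    expr = pd.DataFrame({v: [5.0, 7.0] for v in VARIETIES}, index=["g1", "g2"])
    for r in compute_contrasts(expr):
        assert all(abs(v) < 1e-12 for v in r.de_values.values())


def test_contrasts_invariant_to_per_gene_constant():
    rng = np.random.default_rng(0)
    expr = pd.DataFrame(rng.normal(8, 1, size=(5, 5)), columns=list(VARIETIES))
    shifted = expr.add(rng.normal(0, 3, size=5), axis=0)
    r1 = compute_contrasts(expr)
    r2 = compute_contrasts(shifted)
    for a, b in zip(r1, r2):
        for c in CONTRAST_NAMES:
            assert a.de_values[c] == pytest.approx(b.de_values[c])


def test_missing_variety_is_named():
    expr = pd.DataFrame({v: [1.0] for v in VARIETIES if v != "RSW"})
    with pytest.raises(ValueError, match="RSW"):
        compute_contrasts(expr)


# ---------------------------------------------------------------------------
# DE calling


def test_single_outlier_flagged_in_one_contrast():
    rng = np.random.default_rng(1)
    expr = pd.DataFrame(
        rng.normal(0, 0.01, size=(100, 5)), columns=list(VARIETIES),
        index=[f"g{i}" for i in range(100)],
    )
    expr.loc["g0", "PBB"] += 10.0  # drives DE1 and DE2 strongly
    results = call_de(compute_contrasts(expr))
    flagged = {r.gene_id: r.de_flags for r in results}
    assert flagged["g0"]["DE1"] and flagged["g0"]["DE2"]
    others = [r for r in results if r.gene_id != "g0"]
    assert all(not r.de_flags["DE1"] for r in others)


def test_min_contrast_threshold_semantics():
    from piebaldnet.expression import DEResult

    r4 = DEResult("g4", {}, de_flags={c: c in ("DE1", "DE2", "DE3", "DE4") for c in CONTRAST_NAMES})
    r4.n_de_contrasts = 4
    r3 = DEResult("g3", {}, de_flags={c: c in ("DE1", "DE2", "DE3") for c in CONTRAST_NAMES})
    r3.n_de_contrasts = 3
    assert de_gene_subset([r4, r3], min_contrasts=4) == [r4]


def test_flagged_fraction_matches_normal_tail():
    rng = np.random.default_rng(12)
    n = 200_000
    values = rng.standard_normal(n)
    from piebaldnet.expression import DEResult

    results = [DEResult(f"g{i}", {c: 0.0 for c in CONTRAST_NAMES}) for i in range(n)]
    for r, v in zip(results, values):
        r.de_values["DE1"] = float(v)
    call_de(results, sd_threshold=2.57)
    frac = np.mean([r.de_flags["DE1"] for r in results])
    # two-sided N(0,1) tail mass beyond 2.57 is about 0.0102
    assert frac == pytest.approx(0.0102, abs=0.0012)


def test_zero_spread_contrast_flags_nothing():
    expr = pd.DataFrame({v: [1.0, 2.0, 3.0] for v in VARIETIES})
    results = call_de(compute_contrasts(expr))
    assert all(not any(r.de_flags.values()) for r in results)


# ---------------------------------------------------------------------------
# Correlations and colouring


def test_correlation_extremes():
    rng = np.random.default_rng(2)
    base = rng.normal(size=20)
    from piebaldnet.expression import DEResult

    results = []
    for i in range(20):
        vals = {c: float(base[i]) for c in CONTRAST_NAMES}
        vals["DE7"] = float(-base[i])
        results.append(DEResult(f"g{i}", vals))
    corr = contrast_correlations(results)
    assert corr.loc["DE1", "DE2"] == pytest.approx(1.0)
    assert corr.loc["DE1", "DE7"] == pytest.approx(-1.0)


def test_piebald_contrasts_correlate_highest_with_shared_signal():
    rng = np.random.default_rng(8)
    n = 300
    shared = rng.normal(0, 1.0, size=n)
    from piebaldnet.expression import DEResult

    results = []
    for i in range(n):
        vals = {c: float(rng.normal(0, 1.0)) for c in CONTRAST_NAMES}
        for c in ("DE3", "DE5", "DE6"):
            vals[c] = float(shared[i] + rng.normal(0, 0.4))
        results.append(DEResult(f"g{i}", vals))
    corr = contrast_correlations(results)
    pairs = {
        (a, b): corr.loc[a, b]
        for i, a in enumerate(CONTRAST_NAMES)
        for b in CONTRAST_NAMES[i + 1:]
    }
    top3 = sorted(pairs, key=pairs.get, reverse=True)[:3]
    assert set(top3) == {("DE3", "DE5"), ("DE3", "DE6"), ("DE5", "DE6")}


def test_colour_categories_follow_piebald_score():
    rng = np.random.default_rng(3)
    from piebaldnet.expression import DEResult

    results = []
    for i in range(100):
        vals = {c: float(rng.normal(0, 0.1)) for c in CONTRAST_NAMES}
        results.append(DEResult(f"g{i}", vals))
    for c in ("DE3", "DE5", "DE6"):
        results[0].de_values[c] = 5.0
        results[1].de_values[c] = -5.0
    contrast_correlations(results)
    assert results[0].colour_category == "over"
    assert results[1].colour_category == "under"
    assert results[2].colour_category == "unchanged"
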