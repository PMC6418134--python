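"""PCA immune index: standardization, dichotomization, prognostic models."""

import numpy as np
import pandas as pd
import pytest

from gcna import (
    compute_immune_index,
    dichotomize_index,
    generate_cohort,
    index_cox,
    predict_survival_curves,
)

from conftest import make_study, signal_config

BLOCK = ["IGHA1", "IGHD", "IGHG1", "IGHG3", "IGLC2", "IGLJ3"]


def test_scores_standardized_and_oriented(block_study):
    idx = compute_immune_index(block_study, BLOCK)
    s = idx.sample_scores.to_numpy()
    assert abs(s.mean()) < 1e-9
    assert abs(s.std(ddof=1) - 1.0) < 1e-9
    gene_mean = block_study.expression.values.loc[BLOCK].mean(axis=0)
    assert np.corrcoef(s, gene_mean)[0, 1] > 0


def test_two_identical_genes_reduce_to_standardized_gene():
    rng = np.random.default_rng(0)
    g = rng.normal(7, 2, 100)
    study = make_study(np.vstack([g, g]), ["A", "B"])
    idx = compute_immune_index(study, ["A", "B"])
    z = (g - g.mean()) / g.std(ddof=1)
    assert np.allclose(idx.sample_scores.to_numpy(), z, atol=1e-9)
    assert idx.explained_variance_fraction == pytest.approx(1.0)


def test_tight_block_concentrates_variance(block_study):
    idx = compute_immune_index(block_study, BLOCK)
    assert idx.explained_variance_fraction > 0.8


def test_index_invariant_under_per_gene_affine_rescaling(block_study):
    idx = compute_immune_index(block_study, BLOCK)
    vals = block_study.expression.values.copy()
    rng = np.random.default_rng(1)
    for g in BLOCK:
        vals.loc[g] = vals.loc[g] * float(rng.uniform(0.5, 3)) + float(rng.uniform(-5, 5))
    rescaled = block_study.with_expression(vals)
    idx2 = compute_immune_index(rescaled, BLOCK)
    assert np.allclose(idx.sample_scores, idx2.sample_scores, atol=1e-9)


def test_index_guards():
    rng = np.random.default_rng(2)
    study = make_study(np.vstack([rng.normal(7, 1, 50), np.full(50, 7.0)]), ["A", "FLAT"])
    with pytest.raises(ValueError, match="at least 2"):
        compute_immune_index(study, ["A"])
    with pytest.raises(ValueError, match="FLAT"):
        compute_immune_index(study, ["A", "FLAT"])


# ---------------------------------------------------------------------------
# Dichotomization
# ---------------------------------------------------------------------------

def _index_from_scores(scores):
    s = pd.Series(scores, index=[f"S{i}" for i in range(len(scores))])
    from gcna.index import ImmuneIndex
    return ImmuneIndex(sample_scores=s, loadings=pd.Series([1.0], index=["g"]),
                       explained_variance_fraction=1.0)


def test_forty_percent_split_of_1_to_10():
    idx = dichotomize_index(_index_from_scores(np.arange(1.0, 11.0)), 40)
    assert (idx.group == "low").sum() == 4
    assert (idx.group == "high").sum() == 6


def test_median_split_of_symmetric_scores():
    idx = dichotomize_index(_index_from_scores(np.arange(-5.0, 5.0) + 0.5), 50)
    assert (idx.group == "low").sum() == (idx.group == "high").sum()


def test_cutoff_approximates_normal_quantile():
    rng = np.random.default_rng(3)
    idx = dichotomize_index(_index_from_scores(rng.standard_normal(100_000)), 40)
    assert idx.cutoff_value == pytest.approx(-0.2533, abs=0.02)


def test_low_group_fraction_tracks_percentile(block_study):
    idx = dichotomize_index(compute_immune_index(block_study, BLOCK), 40)
    frac = (idx.group == "low").mean()
    assert abs(frac - 0.40) <= 1.0 / block_study.n_samples + 1e-12


def test_identical_scores_rejected():
    with pytest.raises(ValueError, match="identical"):
        dichotomize_index(_index_from_scores(np.ones(10)), 40)


# ---------------------------------------------------------------------------
# Prognostic models
# ---------------------------------------------------------------------------

def test_discrete_model_requires_two_groups(block_study):
    idx = compute_immune_index(block_study, BLOCK)
    with pytest.raises(ValueError, match="dichotomized"):
        index_cox(block_study, idx, mode="discrete")
    one_group = dichotomize_index(idx, 40)
    one_group.group[:] = "high"
    with pytest.raises(ValueError, match="both index groups"):
        index_cox(block_study, one_group, mode="discrete")


def test_protective_block_yields_protective_index(block_study):
    idx = dichotomize_index(compute_immune_index(block_study, BLOCK), 40)
    m1 = index_cox(block_study, idx, mode="continuous")
    m2 = index_cox(block_study, idx, mode="discrete")
    r1 = m1.result_for("immune_index")
    r2 = m2.result_for("high_index")
    assert r1.HR < 1 and r1.p < 0.05
    assert r2.HR < 1 and r2.p < 0.05


def test_null_index_hr_centers_on_one():
    hrs = []
    for rep in range(25):
        cfg = signal_config(rng_seed=7000 + rep, n_samples=500, n_genes=10,
                            gene_log_hr={}, with_block=True)
        study = generate_cohort(cfg, 0)
        idx = dichotomize_index(compute_immune_index(study, BLOCK), 40)
        hrs.append(index_cox(study, idx, mode="continuous").result_for("immune_index").HR)
    assert 0.9 < float(np.mean(hrs)) < 1.1


# ---------------------------------------------------------------------------
# Predicted survival curves
# ---------------------------------------------------------------------------

def test_curves_start_at_one_and_order_by_hazard(block_study):
    idx = dichotomize_index(compute_immune_index(block_study, BLOCK), 40)
    model = index_cox(block_study, idx, mode="discrete")
    assert model.result_for("high_index").HR < 1
    curves = predict_survival_curves(model, horizon=10.0)
    at0 = curves[curves["time"] == 0.0]
    assert np.allclose(at0["survival"], 1.0)
    for node in curves["node"].unique():
        sub = curves[curves["node"] == node].pivot(index="time", columns="group",
                                                   values="survival")
        # protective high index: its curve dominates at every time
        assert (sub["high"] >= sub["low"] - 1e-12).all()
        assert (sub["high"].diff().dropna() <= 1e-12).all()  # monotone non-increasing


def test_curve_guards(block_study):
    idx = dichotomize_index(compute_immune_index(block_study, BLOCK), 40)
    model = index_cox(block_study, idx, mode="discrete")
    with pytest.raises(ValueError, match="horizon"):
        predict_survival_curves(model, horizon=0.0)
    cont = index_cox(block_study, idx, mode="continuous")
    with pytest.raises(ValueError, match="discrete"):
        predict_survival_curves(cont, horizon=5.0)


def test_curves_match_closed_form_exponential_truth():
    """Binary-group exponential truth: predicted curves within 0.02 of
    exp(-lambda * exp(B x) * t) at n = 5000."""
    rng = np.random.default_rng(9)
    n = 5000
    high = rng.binomial(1, 0.5, n).astype(float)
    lam0, b = 0.12, -0.5
    t = rng.exponential(1.0 / (lam0 * np.exp(b * high)))
    study = make_study(
        np.vstack([7 + rng.normal(0, 1, n), 7 + rng.normal(0, 1, n)]),
        ["A", "B"],
        event=np.ones(n), time=t, node=rng.binomial(1, 0.5, n).astype(float),
    )
    from gcna.index import ImmuneIndex
    scores = pd.Series(np.where(high == 1, 1.0, -1.0), index=study.clinical.index)
    idx = ImmuneIndex(
        sample_scores=scores,
        loadings=pd.Series([1.0], index=["A"]),
        explained_variance_fraction=1.0,
        cutoff_percentile=50.0,
        cutoff_value=0.0,
        group=pd.Series(np.where(high == 1, "high", "low"), index=study.clinical.index),
    )
    model = index_cox(study, idx, mode="discrete", adjust=[])
    curves = predict_survival_curves(model, horizon=8.0)
    for grp, x in (("low", 0.0), ("high", 1.0)):
        sub = curves[curves["group"] == grp]
        truth = np.exp(-lam0 * np.exp(b * x) * sub["time"].to_numpy())
        assert np.abs(sub["survival"].to_numpy() - truth).max() < 0.02
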