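"""The PCA immune index: a standardized first-principal-component score.

A set of highly correlated genes (here the discovered immunoglobulin block)
is collapsed into a single per-sample score: genes are standardized, the
first principal component is extracted, and the component scores are
re-standardized to mean 0, sd 1.  The eigenvector sign is fixed by requiring
a positive correlation between the score and the mean expression of the gene
set, so a higher score means higher block expression (the protective
direction).  The score is dichotomized at an empirical percentile (default
40th) into low (reference) and high groups.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .data import CohortStudy
from .survival import CoxResult, _fit_cox


@dataclass
class ImmuneIndex:
    """Per-sample component scores, loadings and (optionally) groups."""

    sample_scores: pd.Series
    loadings: pd.Series
    explained_variance_fraction: float
    cutoff_percentile: float | None = None
    cutoff_value: float | None = None
    group: pd.Series | None = None  # "low" / "high"

    @property
    def gene_set(self) -> list[str]:
        return list(self.loadings.index)


def compute_immune_index(study: CohortStudy, gene_set: list[str]) -> ImmuneIndex:
    """First-PC score over a gene set, standardized and sign-oriented.

    Genes are z-scored across samples (correlation-matrix PCA), so the index
    is invariant under per-gene affine rescaling of the input expression.
    """
    if len(gene_set) < 2:
        raise ValueError("gene_set must contain at least 2 genes")
    if study.n_samples < 3:
        raise ValueError("need at least 3 samples")
    missing = [g for g in gene_set if g not in study.expression.values.index]
    if missing:
        raise KeyError(f"genes not in study: {missing}")
    X = study.expression.values.loc[list(gene_set)].T.to_numpy(dtype=float)  # samples x genes
    sd = X.std(axis=0, ddof=1)
    zero = [g for g, s in zip(gene_set, sd) if s == 0]
    if zero:
        raise ValueError(f"zero-variance gene(s) in index set: {zero}")
    Z = (X - X.mean(axis=0)) / sd
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    raw = Z @ Vt[0]
    scores = (raw - raw.mean()) / raw.std(ddof=1)
    loadings = Vt[0].copy()
    mean_expr = X.mean(axis=1)
    if np.corrcoef(scores, mean_expr)[0, 1] < 0:
        scores, loadings = -scores, -loadings
    evf = float(s[0] ** 2 / (s**2).sum())
    return ImmuneIndex(
        sample_scores=pd.Series(scores, index=study.clinical.index, name="immune_index"),
        loadings=pd.Series(loadings, index=list(gene_set), name="loading"),
        explained_variance_fraction=evf,
    )


def dichotomize_index(index: ImmuneIndex, percentile: float = 40.0) -> ImmuneIndex:
    """Split samples at an empirical percentile of the score.

    The cutoff is the linearly interpolated empirical percentile; scores at
    or below the cutoff form the low (reference) group.
    """
    if not (0 < percentile < 100):
        raise ValueError("percentile must lie in (0, 100)")
    scores = index.sample_scores
    if scores.nunique() <= 1:
        raise ValueError("all scores identical; percentile cutoff undefined")
    cutoff = float(np.percentile(scores.to_numpy(), percentile))
    group = pd.Series(
        np.where(scores.to_numpy() <= cutoff, "low", "high"),
        index=scores.index,
        name="group",
    )
    return replace(index, cutoff_percentile=float(percentile), cutoff_value=cutoff, group=group)


@dataclass
class IndexCoxModel:
    """A fitted node-adjusted Cox model of the immune index.

    ``mode`` is "continuous" (score per unit) or "discrete" (high vs low,
    low = reference).  ``results`` has one entry per modeled term;
    ``fitter`` keeps the lifelines fit for survival-curve prediction.
    """

    mode: str
    results: list[CoxResult]
    fitter: object
    frame: pd.DataFrame

    def result_for(self, term: str) -> CoxResult:
        for r in self.results:
            if r.term == term:
                return r
        raise KeyError(term)


def index_cox(
    study: CohortStudy,
    index: ImmuneIndex,
    mode: str = "continuous",
    adjust: list[str] = ("node",),
) -> IndexCoxModel:
    """Node-adjusted Cox model of recurrence on the immune index.

    Continuous mode regresses on the score itself; discrete mode on the
    high-vs-low indicator (low = reference), requiring both groups present.
    """
    if mode not in ("continuous", "discrete"):
        raise ValueError(f"unknown mode {mode!r}")
    adjust = list(adjust)
    df, n_dropped = study.survival_frame([], adjust)
    if mode == "continuous":
        term = "immune_index"
        df[term] = index.sample_scores.loc[df.index]
    else:
        if index.group is None:
            raise ValueError("discrete mode requires a dichotomized index")
        groups = index.group.loc[df.index]
        if groups.nunique() < 2:
            raise ValueError("both index groups must be present for the discrete model")
        term = "high_index"
        df[term] = (groups == "high").astype(float)
    terms = [term] + [c for c in adjust if c in df.columns]
    covs = {t: [c for c in terms if c != t] for t in terms}
    results, cph = _fit_cox(df, terms, covs, n_dropped)
    return IndexCoxModel(mode=mode, results=results, fitter=cph, frame=df)


def predict_survival_curves(model: IndexCoxModel, horizon: float) -> pd.DataFrame:
    """Predicted relapse-free survival per index group x node level.

    Baseline cumulative hazard is the Breslow-type estimator of the fitted
    Cox model.  Returns a tidy table (time, group, node, survival) on the
    event-time grid up to ``horizon``, starting at t = 0 with survival 1.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    if model.mode != "discrete":
        raise ValueError("survival curves are predicted from the discrete model")
    df = model.frame
    times = np.unique(
        np.concatenate(
            [[0.0], df.loc[df["event"] == 1, "time"].to_numpy(), [horizon]]
        )
    )
    times = times[times <= horizon]
    node_levels = sorted(df["node"].unique()) if "node" in df.columns else [None]

    # right-continuous step baseline: S0(t) at the largest event time <= t, S0(0) = 1
    bs = model.fitter.baseline_survival_
    bs_times = bs.index.to_numpy(dtype=float)
    bs_vals = bs.iloc[:, 0].to_numpy(dtype=float)
    pos = np.searchsorted(bs_times, times, side="right") - 1
    s0 = np.where(pos >= 0, bs_vals[np.clip(pos, 0, None)], 1.0)

    rows = []
    for high in (0.0, 1.0):
        for node in node_levels:
            profile = {"high_index": high}
            if node is not None:
                profile["node"] = node
            X = pd.DataFrame([profile])
            ph = float(model.fitter.predict_partial_hazard(X).iloc[0])
            for t, s in zip(times, s0**ph):
                rows.append(
                    {
                        "time": float(t),
                        "group": "high" if high == 1.0 else "low",
                        "node": node,
                        "survival": float(s),
                    }
                )
    return pd.DataFrame(rows)
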