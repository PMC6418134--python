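"""Cox proportional-hazards screening and node logistic regression.

The per-gene screen fits recurrence ~ gene expression (continuous) adjusted
for node status; coefficients B are per log2-expression unit and HR = exp(B).
Ties are handled by Efron's approximation (the lifelines default), samples
with a missing event or missing adjustment covariate are dropped listwise,
and the number dropped is recorded on every result.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from scipy.linalg import qr
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .data import CohortStudy


@dataclass
class CoxResult:
    """One modeled term of a Cox proportional-hazards fit."""

    term: str
    B: float
    HR: float
    p: float
    ci_low: float
    ci_high: float
    covariates: list[str] = field(default_factory=list)
    n: int = 0
    n_events: int = 0
    n_dropped: int = 0
    converged: bool = True
    note: str = ""

    def __post_init__(self) -> None:
        if self.converged and np.isfinite(self.B):
            assert abs(self.HR - np.exp(self.B)) <= 1e-12 * max(1.0, self.HR)


@dataclass
class ORResult:
    """One term of a logistic regression for node status."""

    term: str
    OR: float
    p: float
    ci_low: float
    ci_high: float
    n: int = 0
    converged: bool = True
    note: str = ""


def significance_stars(p: float) -> str:
    """The reporting convention: * for p < 0.05, ** for p < 0.01."""
    if not np.isfinite(p):
        return ""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def _flagged(term: str, covariates: list[str], note: str, n: int = 0, n_events: int = 0) -> CoxResult:
    return CoxResult(
        term=term, B=np.nan, HR=np.nan, p=np.nan, ci_low=np.nan, ci_high=np.nan,
        covariates=covariates, n=n, n_events=n_events, converged=False, note=note,
    )


def _fit_cox(df: pd.DataFrame, terms: list[str], covariates_of: dict[str, list[str]],
             n_dropped: int) -> tuple[list[CoxResult], CoxPHFitter]:
    """Fit one Cox model on a complete-case frame, one result per term."""
    n_events = int(df["event"].sum())
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df, duration_col="time", event_col="event")
    out = []
    for t in terms:
        row = cph.summary.loc[t]
        out.append(
            CoxResult(
                term=t,
                B=float(row["coef"]),
                HR=float(np.exp(row["coef"])),
                p=float(row["p"]),
                ci_low=float(np.exp(row["coef lower 95%"])),
                ci_high=float(np.exp(row["coef upper 95%"])),
                covariates=covariates_of[t],
                n=len(df),
                n_events=n_events,
                n_dropped=n_dropped,
            )
        )
    return out, cph


def fit_cox_gene(study: CohortStudy, gene: str, adjust: list[str] = ("node",)) -> CoxResult:
    """Node-adjusted Cox fit of recurrence on one gene's expression.

    Raises on degenerate input (zero-variance gene, fewer than two events);
    a fit that fails to converge is returned flagged, not raised.
    """
    adjust = list(adjust)
    df, n_dropped = study.survival_frame([gene], adjust)
    if df[gene].nunique() <= 1:
        raise ValueError(f"gene {gene!r} has zero variance in the complete-case sample")
    if df["event"].sum() < 2:
        raise ValueError(f"fewer than 2 events after listwise deletion for {gene!r}")
    try:
        return _fit_cox(df, [gene], {gene: adjust}, n_dropped)[0][0]
    except (ConvergenceError, np.linalg.LinAlgError) as err:
        return _flagged(gene, adjust, f"non-convergence: {err}", len(df), int(df["event"].sum()))


def screen_genes(study: CohortStudy, genes: list[str],
                 adjust: list[str] = ("node",)) -> list[CoxResult]:
    """Per-gene node-adjusted Cox screen; per-gene failures become flagged rows."""
    if not genes:
        raise ValueError("screen_genes requires a non-empty gene list")
    results = []
    for g in genes:
        try:
            results.append(fit_cox_gene(study, g, adjust))
        except (ValueError, KeyError) as err:
            results.append(_flagged(g, list(adjust), str(err)))
    return results


def screen_table(results: list[CoxResult], fdr: bool = False) -> pd.DataFrame:
    """Tabular screen report (Gene, B, HR, P, CI, n_events, stars; optional BH q)."""
    df = pd.DataFrame(
        {
            "Gene": [r.term for r in results],
            "B": [r.B for r in results],
            "HR": [r.HR for r in results],
            "P": [r.p for r in results],
            "CI_low": [r.ci_low for r in results],
            "CI_high": [r.ci_high for r in results],
            "n_events": [r.n_events for r in results],
            "Sig": [significance_stars(r.p) for r in results],
        }
    )
    if fdr:
        ok = np.isfinite(df["P"].to_numpy())
        q = np.full(len(df), np.nan)
        if ok.any():
            q[ok] = multipletests(df["P"].to_numpy()[ok], method="fdr_bh")[1]
        df["q_BH"] = q
    return df


def fit_logistic_node(study: CohortStudy, gene: str) -> ORResult:
    """Logistic regression of node status on one gene's expression (MLE)."""
    df = pd.DataFrame(
        {
            "node": study.clinical["node_status"].astype(float),
            "x": study.gene_values(gene).astype(float).to_numpy(),
        }
    ).dropna()
    classes = df["node"].unique()
    if len(classes) < 2:
        raise ValueError("both node classes must be present for logistic regression")
    X = sm.add_constant(df[["x"]])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(df["node"], X).fit(disp=0, maxiter=200)
        if not res.mle_retvals.get("converged", False):
            raise PerfectSeparationError("logistic fit did not converge")
        ci = res.conf_int().loc["x"]
        return ORResult(
            term=gene,
            OR=float(np.exp(res.params["x"])),
            p=float(res.pvalues["x"]),
            ci_low=float(np.exp(ci[0])),
            ci_high=float(np.exp(ci[1])),
            n=len(df),
        )
    except (PerfectSeparationError, np.linalg.LinAlgError) as err:
        return ORResult(term=gene, OR=np.nan, p=np.nan, ci_low=np.nan, ci_high=np.nan,
                        n=len(df), converged=False, note=str(err))


def multivariable_cox(study: CohortStudy, terms: list[str],
                      adjust: list[str] = ("node",)) -> list[CoxResult]:
    """One joint Cox fit of all terms plus adjustment covariates.

    The design matrix must be full rank; collinear columns are named in the
    error (found by pivoted QR).
    """
    terms, adjust = list(terms), list(adjust)
    if len(set(terms)) != len(terms):
        dups = sorted({t for t in terms if terms.count(t) > 1})
        raise ValueError(f"rank deficiency: duplicated terms {dups}")
    df, n_dropped = study.survival_frame(terms, adjust)
    cols = [c for c in df.columns if c not in ("time", "event")]
    X = df[cols].to_numpy()
    rank = np.linalg.matrix_rank(X - X.mean(axis=0))
    if rank < len(cols):
        _, _, piv = qr((X - X.mean(axis=0)), pivoting=True)
        collinear = sorted(cols[i] for i in piv[rank:])
        raise ValueError(f"rank-deficient design; collinear terms: {collinear}")
    all_terms = terms + [c for c in adjust if c in cols]
    covs = {t: [c for c in all_terms if c != t] for t in all_terms}
    return _fit_cox(df, all_terms, covs, n_dropped)[0]
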