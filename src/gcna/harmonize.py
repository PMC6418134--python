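"""Reading, probe collapsing, cross-cohort moment alignment and merging.

Multi-cohort microarray studies mix platforms and processing pipelines, so
expression distributions differ in location and scale between cohorts.  Here
each non-reference cohort is put on the log2 scale and then mapped by a single
global linear transform so its pooled mean and standard deviation match a
chosen reference cohort.  A linear map cannot also set skewness and kurtosis,
so those are reported as diagnostics rather than matched.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .data import GENE_LEVEL, PROBE_LEVEL, CLINICAL_COLUMNS, CohortStudy, ExpressionMatrix

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _infer_sep(path: str, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "," if str(path).endswith(".csv") else "\t"


def read_expression_table(
    path: str,
    sep: str | None = None,
    cohort: str = "",
    scale_tag: str = GENE_LEVEL,
) -> ExpressionMatrix:
    """Read a delimited expression table (row IDs in column 1, samples in header).

    Duplicate sample IDs in the header are rejected.  Duplicate row IDs are
    rejected for gene-level tables but permitted for probe-level ones.  Any
    non-numeric cell raises an error naming its row and column.
    """
    sep = _infer_sep(path, sep)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)
    samples = header[1:]
    if len(set(samples)) != len(samples):
        dups = sorted({s for s in samples if samples.count(s) > 1})
        raise ValueError(f"duplicate sample IDs in header of {path}: {dups}")
    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    raw.columns = samples
    num = raw.apply(lambda col: pd.to_numeric(col, errors="coerce"))
    bad = num.isna() & raw.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"unparsable cell in {path}: row {raw.index[r]!r}, column {raw.columns[c]!r} "
            f"= {raw.iat[r, c]!r}"
        )
    if num.isna().to_numpy().any():
        raise ValueError(f"missing expression cells in {path} are not supported")
    return ExpressionMatrix(num.astype(float), cohort=cohort, scale_tag=scale_tag)


def write_expression_table(m: ExpressionMatrix, path: str) -> None:
    m.values.to_csv(path, sep="\t", index_label="gene")


def read_probe_map(path: str, sep: str | None = None) -> dict[str, str]:
    """Two-column (probe_id, gene_symbol) table -> mapping."""
    sep = _infer_sep(path, sep)
    df = pd.read_csv(path, sep=sep, dtype=str, header=0)
    if df.shape[1] < 2:
        raise ValueError(f"probe map {path} needs two columns (probe_id, gene_symbol)")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def read_clinical_table(path: str, sep: str | None = None) -> pd.DataFrame:
    sep = _infer_sep(path, sep)
    df = pd.read_csv(path, sep=sep, index_col="sample_id")
    df.index = df.index.astype(str)
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"clinical table {path} missing columns: {missing}")
    return df


def write_clinical_table(clinical: pd.DataFrame, path: str) -> None:
    clinical.to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# Probe collapse
# ---------------------------------------------------------------------------

def collapse_probes(m: ExpressionMatrix, probe_to_gene: Mapping[str, str]) -> ExpressionMatrix:
    """Collapse a probe-level matrix to gene level by per-gene median.

    Probes absent from the mapping are dropped (count logged).  Each retained
    probe must map to exactly one gene symbol; the median across a gene's
    probes represents the gene in every sample.
    """
    if not probe_to_gene:
        raise ValueError("probe_to_gene mapping is empty")
    if m.scale_tag != PROBE_LEVEL:
        raise ValueError("collapse_probes expects a probe-level matrix")
    probes = m.values.index
    mapped = probes.map(lambda p: probe_to_gene.get(str(p)))
    keep = mapped.notna()
    n_dropped = int((~keep).sum())
    if n_dropped:
        log.info("collapse_probes: dropped %d unmapped probes", n_dropped)
    vals = m.values.loc[keep].copy()
    vals.index = pd.Index(mapped[keep], name="gene")
    collapsed = vals.groupby(level=0, sort=True).median()
    return ExpressionMatrix(collapsed, cohort=m.cohort, scale_tag=GENE_LEVEL)


# ---------------------------------------------------------------------------
# Moment alignment
# ---------------------------------------------------------------------------

def pooled_moments(m: ExpressionMatrix) -> dict[str, float]:
    """Mean, sd, skewness and excess kurtosis of all values pooled together."""
    x = m.values.to_numpy().ravel()
    return {
        "mean": float(np.mean(x)),
        "sd": float(np.std(x, ddof=1)),
        "skewness": float(stats.skew(x)),
        "kurtosis": float(stats.kurtosis(x)),
    }


def harmonize_to_reference(
    target: ExpressionMatrix,
    reference: ExpressionMatrix,
    target_scale: str = "log2",
) -> tuple[ExpressionMatrix, dict]:
    """Align a cohort's pooled distribution to a reference cohort.

    If ``target_scale == "linear"`` the values are first log2-transformed
    (non-positive values are rejected).  A single global linear map then sets
    the pooled mean and standard deviation equal to the reference's.  Returns
    the aligned matrix and a diagnostics dict with pooled moments before and
    after (skewness/kurtosis are diagnostics only: a linear map preserves
    them).
    """
    if target.scale_tag != GENE_LEVEL or reference.scale_tag != GENE_LEVEL:
        raise ValueError("harmonization requires gene-level matrices")
    vals = target.values
    if target_scale == "linear":
        if (vals.to_numpy() <= 0).any():
            raise ValueError("non-positive values on a declared-linear scale")
        vals = np.log2(vals)
    elif target_scale != "log2":
        raise ValueError(f"unknown target_scale {target_scale!r}")

    x = vals.to_numpy()
    mu_t, sd_t = float(x.mean()), float(x.std(ddof=1))
    if sd_t == 0:
        raise ValueError("zero-variance target matrix cannot be harmonized")
    ref = reference.values.to_numpy()
    mu_r, sd_r = float(ref.mean()), float(ref.std(ddof=1))

    aligned = (vals - mu_t) / sd_t * sd_r + mu_r
    out = ExpressionMatrix(aligned, cohort=target.cohort, scale_tag=GENE_LEVEL)
    diagnostics = {
        "cohort": target.cohort,
        "target_scale": target_scale,
        "before": pooled_moments(ExpressionMatrix(vals, target.cohort)),
        "after": pooled_moments(out),
        "reference": pooled_moments(reference),
    }
    return out, diagnostics


# ---------------------------------------------------------------------------
# Merging
# ---------------------------------------------------------------------------

def merge_cohorts(studies: list[CohortStudy]) -> CohortStudy:
    """Merge harmonized studies: gene intersection, samples concatenated.

    Gene order follows the first study restricted to the intersection.
    Sample-ID collisions across studies are an error.
    """
    if not studies:
        raise ValueError("merge_cohorts needs at least one study")
    if len(studies) == 1:
        s = studies[0]
        return CohortStudy(s.expression.copy(), s.clinical.copy(), list(s.provenance))

    common = set(studies[0].genes)
    for s in studies[1:]:
        common &= set(s.genes)
    if not common:
        raise ValueError("empty gene intersection across studies")
    gene_order = [g for g in studies[0].genes if g in common]

    all_samples: list[str] = []
    for s in studies:
        all_samples.extend(s.expression.sample_ids)
    if len(set(all_samples)) != len(all_samples):
        dups = sorted({x for x in all_samples if all_samples.count(x) > 1})
        raise ValueError(f"colliding sample IDs across studies: {dups[:5]}")

    expr = pd.concat([s.expression.values.loc[gene_order] for s in studies], axis=1)
    clin = pd.concat([s.clinical for s in studies], axis=0)
    provenance = [p for s in studies for p in s.provenance]
    label = "+".join(provenance)
    return CohortStudy(ExpressionMatrix(expr, cohort=label), clin, provenance)
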