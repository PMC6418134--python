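"""Core containers: expression matrices, clinical tables and merged cohort studies.

Expression values are log2 intensities held in a genes x samples DataFrame.
Clinical records carry a recurrence indicator (0/1, NaN = unknown), follow-up
time in years, axillary lymph-node status (0/1, NaN = unknown) and a cohort
label.  A :class:`CohortStudy` pairs the two with identical sample ordering and
is the input to every downstream stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

GENE_LEVEL = "gene_level"
PROBE_LEVEL = "probe_level"

#: Columns every clinical table must provide (sample_id is the index).
CLINICAL_COLUMNS = ("recurrence_event", "followup_time", "node_status", "cohort")


@dataclass
class ExpressionMatrix:
    """A genes x samples matrix of expression values.

    Parameters
    ----------
    values
        DataFrame indexed by gene symbol (or probe ID when
        ``scale_tag == "probe_level"``), columns are sample IDs.
    cohort
        Label of the source cohort ("" for merged matrices).
    scale_tag
        ``"gene_level"`` (unique row IDs required) or ``"probe_level"``
        (duplicate row IDs permitted, one row per probe).
    """

    values: pd.DataFrame
    cohort: str = ""
    scale_tag: str = GENE_LEVEL

    def __post_init__(self) -> None:
        if self.scale_tag not in (GENE_LEVEL, PROBE_LEVEL):
            raise ValueError(f"unknown scale_tag {self.scale_tag!r}")
        cols = pd.Index(self.values.columns.astype(str))
        if cols.duplicated().any():
            dups = sorted(set(cols[cols.duplicated()]))
            raise ValueError(f"duplicate sample IDs: {dups}")
        if self.scale_tag == GENE_LEVEL:
            idx = self.values.index
            if idx.duplicated().any():
                dups = sorted(set(idx[idx.duplicated()]))
                raise ValueError(f"duplicate gene IDs in gene-level matrix: {dups}")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("expression values must be numeric")
        if not np.isfinite(arr).all():
            raise ValueError("expression values must be finite (no NaN/inf)")

    @property
    def gene_ids(self) -> list[str]:
        return [str(g) for g in self.values.index]

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.values.columns]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.copy(), self.cohort, self.scale_tag)


def validate_clinical(clinical: pd.DataFrame) -> pd.DataFrame:
    """Check a clinical table (indexed by sample_id) and return it.

    Follow-up time must be strictly positive; recurrence_event and node_status
    are 0/1 with NaN meaning unknown.  Records with an unknown event are kept
    here (they still carry expression) and dropped listwise by survival fits.
    """
    missing = [c for c in CLINICAL_COLUMNS if c not in clinical.columns]
    if missing:
        raise ValueError(f"clinical table missing columns: {missing}")
    if clinical.index.duplicated().any():
        dups = sorted(set(clinical.index[clinical.index.duplicated()]))
        raise ValueError(f"duplicate sample IDs in clinical table: {dups}")
    t = pd.to_numeric(clinical["followup_time"], errors="raise")
    if (t <= 0).any() or t.isna().any():
        bad = clinical.index[(t <= 0) | t.isna()].tolist()
        raise ValueError(f"followup_time must be strictly positive, bad samples: {bad[:5]}")
    for col in ("recurrence_event", "node_status"):
        v = pd.to_numeric(clinical[col], errors="raise")
        ok = v.isna() | v.isin([0, 1])
        if not ok.all():
            raise ValueError(f"{col} must be 0/1 or missing")
    return clinical


@dataclass
class CohortStudy:
    """Aligned expression + clinical data for one or more (merged) cohorts.

    Invariant: ``expression.sample_ids`` and ``clinical.index`` are the same
    samples in the same order.  The clinical table is reindexed to the
    expression column order at construction.
    """

    expression: ExpressionMatrix
    clinical: pd.DataFrame
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.expression.scale_tag != GENE_LEVEL:
            raise ValueError("CohortStudy requires a gene-level expression matrix")
        validate_clinical(self.clinical)
        expr_samples = self.expression.sample_ids
        if set(expr_samples) != set(map(str, self.clinical.index)):
            only_e = set(expr_samples) - set(map(str, self.clinical.index))
            only_c = set(map(str, self.clinical.index)) - set(expr_samples)
            raise ValueError(
                f"expression/clinical sample mismatch: "
                f"{sorted(only_e)[:5]} only in expression, {sorted(only_c)[:5]} only in clinical"
            )
        self.clinical = self.clinical.loc[expr_samples]
        if not self.provenance:
            self.provenance = [self.expression.cohort or "unknown"]

    # -- convenience -------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.expression.shape[1]

    @property
    def genes(self) -> list[str]:
        return self.expression.gene_ids

    def gene_values(self, gene: str) -> pd.Series:
        if gene not in self.expression.values.index:
            raise KeyError(f"gene {gene!r} not in study")
        return self.expression.values.loc[gene]

    def subset_samples(self, sample_ids: list[str]) -> "CohortStudy":
        """Restrict the study to the given samples (order preserved)."""
        expr = ExpressionMatrix(
            self.expression.values[list(sample_ids)],
            self.expression.cohort,
            self.expression.scale_tag,
        )
        return CohortStudy(expr, self.clinical.loc[list(sample_ids)].copy(), list(self.provenance))

    def survival_frame(self, genes: list[str], adjust: list[str]) -> tuple[pd.DataFrame, int]:
        """Listwise-complete frame (time, event, genes, adjustment covariates).

        Returns the frame and the number of samples dropped for a missing
        event or a missing adjustment covariate.
        """
        df = pd.DataFrame(
            {
                "time": self.clinical["followup_time"].astype(float),
                "event": self.clinical["recurrence_event"].astype(float),
            }
        )
        for cov in adjust:
            if cov == "node":
                df["node"] = self.clinical["node_status"].astype(float)
            elif cov in self.clinical.columns:
                df[cov] = pd.to_numeric(self.clinical[cov])
            else:
                raise KeyError(f"unknown adjustment covariate {cov!r}")
        for g in genes:
            df[g] = self.gene_values(g).astype(float).to_numpy()
        n0 = len(df)
        df = df.dropna()
        return df, n0 - len(df)

    def with_expression(self, values: pd.DataFrame) -> "CohortStudy":
        expr = replace(self.expression, values=values)
        return CohortStudy(expr, self.clinical.copy(), list(self.provenance))
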