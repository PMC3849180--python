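"""Relative quantification from Ct values and expression-correlation screens.

qPCR expression is quantified by the comparative-Ct method with an
assumed amplification efficiency of 2: for each sample,

    dCt  = Ct(target) - Ct(reference)
    ddCt = dCt(sample) - dCt(calibrator)
    RQ   = 2 ** (-ddCt)

with a small-RNA reference (U6) for miRNA assays and a housekeeping mRNA
(beta-actin) for gene assays. Correlation screens relate miRNA level to
candidate-target level across a panel of cell lines or tissues with the
Pearson product-moment coefficient; by default the screen correlates
log2 relative levels (-dCt), the scale on which qPCR noise is additive.
The two-sided p-value comes from t = r*sqrt((n-2)/(1-r^2)) on n-2
degrees of freedom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "QpcrRecord",
    "CorrelationResult",
    "relative_quantity",
    "pearson_p_from_r",
    "correlation_screen",
    "panel_screen",
    "ct_table_to_levels",
]


@dataclass(frozen=True)
class QpcrRecord:
    """One sample's Ct quartet for a target/reference assay pair."""

    sample: str
    target_ct: float
    reference_ct: float
    calibrator_target_ct: float
    calibrator_reference_ct: float

    def __post_init__(self) -> None:
        vals = (
            self.target_ct,
            self.reference_ct,
            self.calibrator_target_ct,
            self.calibrator_reference_ct,
        )
        if not all(math.isfinite(v) for v in vals):
            raise ValueError(f"sample {self.sample}: non-finite Ct value")

    @property
    def ddct(self) -> float:
        return (self.target_ct - self.reference_ct) - (
            self.calibrator_target_ct - self.calibrator_reference_ct
        )

    @property
    def rq(self) -> float:
        return 2.0 ** (-self.ddct)


def relative_quantity(record: QpcrRecord) -> float:
    """RQ = 2^(-ddCt); 1.0 when the sample is its own calibrator."""
    return record.rq


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation over n shared samples with two-sided p."""

    n: int
    r: float
    p: float
    gene: str | None = None

    @property
    def direction(self) -> str:
        if self.r < 0:
            return "inverse"
        if self.r > 0:
            return "positive"
        return "none"


def pearson_p_from_r(r: float, n: int) -> float:
    """Two-sided p for a Pearson r at sample size n via the t transform."""
    if n < 3:
        raise ValueError("need at least 3 samples")
    if not -1.0 <= r <= 1.0:
        raise ValueError("r out of [-1, 1]")
    if abs(r) == 1.0:
        return 0.0
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    return 2.0 * stats.t.sf(abs(t), df=n - 2)


def correlation_screen(
    mirna_levels: dict[str, float] | pd.Series,
    gene_levels: dict[str, float] | pd.Series,
) -> CorrelationResult:
    """Pearson r and two-sided p over the samples shared by both vectors.

    Sample order is irrelevant; constant vectors and n < 3 are rejected
    (r undefined / p meaningless).
    """
    x = pd.Series(mirna_levels, dtype=float)
    y = pd.Series(gene_levels, dtype=float)
    shared = sorted(set(x.index) & set(y.index))
    if len(shared) < 3:
        raise ValueError(f"need at least 3 shared samples, got {len(shared)}")
    xv = x[shared].to_numpy()
    yv = y[shared].to_numpy()
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise ValueError("constant vector: Pearson r undefined")
    r, p = stats.pearsonr(xv, yv)
    return CorrelationResult(n=len(shared), r=float(r), p=float(p))


def ct_table_to_levels(
    ct: pd.DataFrame,
    reference_assay: str,
) -> pd.DataFrame:
    """Long-format Ct table -> assay x sample log2 relative levels.

    Input columns: sample, assay, ct. The level of assay a in sample s is
    -(Ct[a,s] - Ct[ref,s]) = -dCt, i.e. log2 expression relative to the
    reference assay. The reference row is dropped from the output.
    """
    required = {"sample", "assay", "ct"}
    if not required <= set(ct.columns):
        raise ValueError(f"Ct table must have columns {sorted(required)}")
    wide = ct.pivot(index="assay", columns="sample", values="ct")
    if reference_assay not in wide.index:
        raise ValueError(f"reference assay {reference_assay!r} missing from Ct table")
    if wide.isna().any().any():
        missing = wide.columns[wide.isna().any()].tolist()
        raise ValueError(f"missing Ct values for samples {missing}")
    levels = -(wide - wide.loc[reference_assay])
    return levels.drop(index=reference_assay)


def panel_screen(
    panel: pd.DataFrame,
    mirna_row: str,
    genes: list[str],
    *,
    inverse_r_threshold: float = 0.3,
) -> list[CorrelationResult]:
    """Correlate one miRNA's level against each gene across panel samples.

    ``panel`` is an assay x sample table of (log2 relative) levels.
    Each gene gets a CorrelationResult; ``direction`` summarises the sign
    and |r| >= inverse_r_threshold marks an apparent (anti)correlation in
    the report written by the pipeline.
    """
    if mirna_row not in panel.index:
        raise ValueError(f"miRNA row {mirna_row!r} absent from panel")
    out: list[CorrelationResult] = []
    mir = panel.loc[mirna_row]
    for gene in genes:
        if gene not in panel.index:
            raise ValueError(f"gene {gene!r} absent from panel")
        res = correlation_screen(mir, panel.loc[gene])
        out.append(CorrelationResult(n=res.n, r=res.r, p=res.p, gene=gene))
    return out
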