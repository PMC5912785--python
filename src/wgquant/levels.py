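"""Fold-ratio arithmetic for mRNA (FPKM) and protein (densitometry) levels.

Covers the ratio bookkeeping used when comparing destruction-complex
components: FPKM ratios between genes at a developmental stage, loading-
control normalization of immunoblot bands, chaining of fold measures
through shared intermediates (e.g., endogenous protein A -> tagged A ->
tagged B -> endogenous B, which yields the endogenous APC2:Axin ratio of
~5-fold from the three measured links), and the one-sample t test against a
fold of 1 used for blot series.

Fold measures larger than 5-fold or smaller than 0.2-fold require serial-
dilution verification (``dilution_verified``); unverified extreme folds
trigger a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ExpressionTable",
    "FoldMeasure",
    "fpkm_ratio",
    "normalize_band",
    "chain_folds",
    "one_sample_fold_test",
]

DILUTION_HIGH = 5.0
DILUTION_LOW = 0.2


@dataclass
class ExpressionTable:
    """Rows of (gene, stage, fpkm); (gene, stage) must be unique."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"gene", "stage", "fpkm"}
        if not required.issubset(self.frame.columns):
            raise ValueError(f"expression table needs columns {sorted(required)}")
        if (self.frame["fpkm"] < 0).any():
            raise ValueError("fpkm values must be >= 0")
        if self.frame.duplicated(["gene", "stage"]).any():
            raise ValueError("(gene, stage) pairs must be unique")

    @classmethod
    def from_records(cls, records) -> "ExpressionTable":
        return cls(pd.DataFrame(records, columns=["gene", "stage", "fpkm"]))

    def fpkm(self, gene: str, stage: str) -> float:
        sel = self.frame[(self.frame["gene"] == gene) & (self.frame["stage"] == stage)]
        if sel.empty:
            raise KeyError(f"no FPKM entry for ({gene}, {stage})")
        return float(sel["fpkm"].iloc[0])


@dataclass(frozen=True)
class FoldMeasure:
    """A measured fold change numerator/denominator with its spread."""

    numerator: str
    denominator: str
    fold: float
    sd: float = 0.0
    n_blots: int = 1
    dilution_verified: bool = False

    def __post_init__(self) -> None:
        if self.fold <= 0:
            raise ValueError("fold must be > 0")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if (self.fold > DILUTION_HIGH or self.fold < DILUTION_LOW) and not self.dilution_verified:
            warnings.warn(
                f"fold {self.fold:g} ({self.numerator}/{self.denominator}) exceeds the "
                "5-fold/0.2-fold range and is not marked dilution_verified"
            )

    @property
    def relative_sd(self) -> float:
        return self.sd / self.fold

    def inverted(self) -> "FoldMeasure":
        return replace(
            self,
            numerator=self.denominator,
            denominator=self.numerator,
            fold=1.0 / self.fold,
            sd=self.sd / self.fold**2,  # same relative sd
        )

    def formatted(self) -> str:
        """Paper-style '~Nx' rounding to the nearest integer fold."""
        return f"~{round(self.fold):d}x"


def fpkm_ratio(
    table: ExpressionTable, gene_a: str, gene_b: str, stage: str, rounded: bool = False
) -> float:
    """FPKM of ``gene_a`` over ``gene_b`` at one stage; with ``rounded`` the
    ratio is rounded to the nearest integer fold as printed (~19x style)."""
    a = table.fpkm(gene_a, stage)
    b = table.fpkm(gene_b, stage)
    if b == 0:
        raise ZeroDivisionError(f"denominator FPKM for {gene_b} at {stage} is 0")
    r = a / b
    return float(round(r)) if rounded else r


def normalize_band(band_intensity: float, loading_intensity: float) -> float:
    """Densitometry band intensity normalized to its loading control."""
    if loading_intensity <= 0:
        raise ValueError("loading-control intensity must be > 0")
    return band_intensity / loading_intensity


def chain_folds(measures: list[FoldMeasure]) -> FoldMeasure:
    """Compose a chain of fold measures through shared labels.

    Each link is oriented (inverting as needed) so its denominator matches
    the running label; the combined fold is the product and the combined
    relative sd adds the links' relative sds in quadrature (first-order
    propagation).  Raises on a non-composable chain, naming the broken link.
    """
    if not measures:
        raise ValueError("empty chain")
    if len(measures) == 1:
        return measures[0]
    first, second = measures[0], measures[1]
    shared = {first.numerator, first.denominator} & {second.numerator, second.denominator}
    if not shared:
        raise ValueError(f"links 0 and 1 share no label: {first} / {second}")
    start = (
        first.denominator if first.numerator in shared else first.numerator
    )
    current = start
    fold = 1.0
    rel_var = 0.0
    verified = True
    for i, m in enumerate(measures):
        if m.denominator == current:
            link = m
        elif m.numerator == current:
            link = m.inverted()
        else:
            raise ValueError(
                f"chain broken at link {i}: {m.numerator}/{m.denominator} does not "
                f"connect to '{current}'"
            )
        fold *= link.fold
        rel_var += link.relative_sd**2
        verified &= m.dilution_verified or (DILUTION_LOW <= m.fold <= DILUTION_HIGH)
        current = link.numerator
    return FoldMeasure(
        numerator=current,
        denominator=start,
        fold=fold,
        sd=fold * float(np.sqrt(rel_var)),
        n_blots=sum(m.n_blots for m in measures),
        dilution_verified=verified,
    )


def one_sample_fold_test(folds, null: float = 1.0) -> tuple[float, float]:
    """One-sample t test of per-blot folds against a null fold (default 1).

    Returns (t, p); a zero-spread sample is degenerate and raises.
    """
    arr = np.asarray(folds, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least 2 blots")
    if arr.std(ddof=1) == 0:
        if float(arr[0]) == null:
            return 0.0, 1.0
        raise ValueError("zero-variance fold sample; t statistic undefined")
    res = sps.ttest_1samp(arr, popmean=null)
    return float(res.statistic), float(res.pvalue)
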