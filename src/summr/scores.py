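"""Unweighted genetic scores and confounder scans on individual-level data.

MR's "no confounding" assumption is probed empirically: build an unweighted
genetic score (the per-individual count of exposure-increasing alleles over
the instrument SNPs) and regress a panel of candidate confounders on it —
linear regression for quantitative traits, logistic for binary ones, each
judged against a Bonferroni threshold over the whole scan family.  A score
associated only with its own exposure behaves like a valid instrument; an
association with, say, BMI or smoking would signal confounding/pleiotropy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import ValidationError
from .instrument_io import InstrumentVariant

logger = logging.getLogger(__name__)

TRAIT_TYPES = ("quantitative", "binary")


@dataclass(frozen=True)
class ScanResult:
    """One score-vs-trait regression outcome."""

    trait_name: str
    test_type: str  # "linear" | "logistic"
    estimate: float
    se: float
    pvalue: float
    n: int
    alpha_used: float
    significant: bool

    def __post_init__(self) -> None:
        if self.significant != (self.pvalue < self.alpha_used):
            raise ValidationError(f"{self.trait_name}: significant inconsistent with pvalue/alpha")


def orientation_from_instruments(instruments: Sequence[InstrumentVariant]) -> np.ndarray:
    """True where the table's effect allele is the trait-increasing allele."""
    return np.array([iv.beta_exposure >= 0 for iv in instruments], dtype=bool)


def build_unweighted_score(
    dosages: np.ndarray,
    increasing_allele_orientation: Optional[np.ndarray] = None,
    missing: str = "error",
) -> np.ndarray:
    """Per-individual count of trait-increasing alleles over the instrument SNPs.

    Parameters
    ----------
    dosages
        ``(n_individuals, n_snps)`` effect-allele dosage matrix with entries in
        [0, 2] (hard calls or imputed dosages).
    increasing_allele_orientation
        Per-SNP flags; where False the dosage counts the trait-*decreasing*
        allele and ``2 - dosage`` is used instead.  Default: all True.
    missing
        ``"error"`` (default) rejects NaN dosages; ``"mean"`` imputes each
        SNP's column mean (i.e. twice its effect-allele frequency).
    """
    d = np.asarray(dosages, dtype=float)
    if d.ndim != 2:
        raise ValidationError("dosage matrix must be 2-D (individuals x SNPs)")
    nan_mask = np.isnan(d)
    if nan_mask.any():
        if missing == "error":
            raise ValidationError("missing dosages present (pass missing='mean' to impute)")
        if missing != "mean":
            raise ValidationError(f"unknown missing policy {missing!r}")
        col_means = np.nanmean(d, axis=0)
        d = np.where(nan_mask, np.broadcast_to(col_means, d.shape), d)
    if (d < 0).any() or (d > 2).any():
        raise ValidationError("dosages must lie in [0, 2]")
    if increasing_allele_orientation is not None:
        flip = ~np.asarray(increasing_allele_orientation, dtype=bool)
        if flip.shape != (d.shape[1],):
            raise ValidationError("orientation flags must have one entry per SNP")
        d = np.where(flip, 2.0 - d, d)
    return d.sum(axis=1)


def scan_confounders(
    scores: np.ndarray,
    trait_panel: pd.DataFrame,
    trait_types: Mapping[str, str],
    alpha: float,
) -> list[ScanResult]:
    """Regress each panel trait on the genetic score.

    Quantitative traits: OLS of trait on (intercept, score).  Binary traits:
    logistic regression of trait on (intercept, score).  Regressions are
    unadjusted — the score is the sole predictor.  A binary trait with a
    single observed class is skipped with a warning.  Rows with a missing
    trait value are dropped per trait.
    """
    if not 0 < alpha < 1:
        raise ValidationError(f"alpha must be in (0, 1), got {alpha}")
    scores = np.asarray(scores, dtype=float)
    if len(scores) != len(trait_panel):
        raise ValidationError("score vector and trait panel lengths differ")
    results: list[ScanResult] = []
    for trait in trait_panel.columns:
        ttype = trait_types.get(trait)
        if ttype is None:
            raise ValidationError(f"no declared type for trait {trait!r}")
        if ttype not in TRAIT_TYPES:
            raise ValidationError(f"{trait}: unknown trait type {ttype!r}")
        y = pd.to_numeric(trait_panel[trait], errors="coerce").to_numpy(dtype=float)
        keep = ~np.isnan(y)
        yk, xk = y[keep], scores[keep]
        design = sm.add_constant(xk)
        if ttype == "binary":
            classes = np.unique(yk)
            if len(classes) < 2:
                logger.warning("trait %s has a single class; skipped", trait)
                continue
            fit = sm.Logit(yk, design).fit(disp=0)
            test_type = "logistic"
        else:
            fit = sm.OLS(yk, design).fit()
            test_type = "linear"
        est, se, p = float(fit.params[1]), float(fit.bse[1]), float(fit.pvalues[1])
        results.append(
            ScanResult(
                trait_name=trait,
                test_type=test_type,
                estimate=est,
                se=se,
                pvalue=p,
                n=int(keep.sum()),
                alpha_used=alpha,
                significant=p < alpha,
            )
        )
    return results


def scan_report(results: Sequence[ScanResult]) -> pd.DataFrame:
    """Forest-plot-ready table of scan outcomes."""
    return pd.DataFrame(
        {
            "trait": [r.trait_name for r in results],
            "test_type": [r.test_type for r in results],
            "estimate": [r.estimate for r in results],
            "se": [r.se for r in results],
            "pvalue": [r.pvalue for r in results],
            "n": [r.n for r in results],
            "alpha": [r.alpha_used for r in results],
            "significant": [r.significant for r in results],
        }
    )
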