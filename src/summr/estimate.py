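"""Wald ratios, the inverse-variance weighted (IVW) causal estimate, and per-SD scaling.

The causal effect of an exposure on a binary outcome is estimated from GWAS
summary statistics in two steps.  Each SNP j with exposure effect gamma_j
(se sigma_gj) and outcome log-odds Gamma_j (se sigma_Gj) contributes a Wald
ratio

    ratio_j = Gamma_j / gamma_j,      se_j = sigma_Gj / |gamma_j|

(first-order standard error: uncertainty in gamma_j is ignored, the classical
summary-data convention).  Ratios are pooled by fixed-effect inverse-variance
weighting,

    beta_IVW = sum_j w_j ratio_j / sum_j w_j,   w_j = se_j^-2,
    se_IVW   = (sum_j w_j)^-1/2,

which is algebraically the slope of a weighted through-origin regression of
Gamma on gamma with weights sigma_Gj^-2.  For reporting, beta_IVW (log-odds of
disease per exposure unit) is rescaled to an odds ratio per one population SD
of the exposure, OR = exp(beta_IVW * s); a binary exposure uses s = 1 so the
OR is per unit increase in its log-odds.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import EstimationError, ValidationError
from .instrument_io import HarmonizedInstrument, estimable

logger = logging.getLogger(__name__)

#: Two-sided 95% normal quantile, Phi^-1(0.975), used for every CI here.
Z_95 = 1.959964


@dataclass(frozen=True)
class WaldRatio:
    """Single-SNP causal estimate: outcome log-odds per exposure unit."""

    rsid: str
    ratio: float
    se_ratio: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.se_ratio) and self.se_ratio > 0):
            raise ValidationError(f"{self.rsid}: se_ratio must be > 0")


@dataclass(frozen=True)
class ExposureSpec:
    """Reporting scale for one exposure.

    ``sd_scale`` is the population standard deviation in native units
    (e.g. 4.81 kg/m^2 for BMI, 0.60 ln(pmol/L) for fasting insulin); a binary
    exposure is reported per unit log-odds, so its scale is fixed at 1.
    """

    name: str
    sd_scale: float
    binary_exposure: bool = False

    def __post_init__(self) -> None:
        if not (math.isfinite(self.sd_scale) and self.sd_scale > 0):
            raise ValidationError(f"{self.name}: sd_scale must be > 0")
        if self.binary_exposure and self.sd_scale != 1:
            raise ValidationError(f"{self.name}: binary exposure requires sd_scale = 1")


@dataclass(frozen=True)
class MREstimate:
    """Combined causal estimate with its per-SD odds-ratio report."""

    beta: float
    se: float
    sd_scale: float
    or_per_sd: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_snps: int

    def __post_init__(self) -> None:
        if self.n_snps < 1:
            raise ValidationError("n_snps must be >= 1")
        if not (self.ci_low < self.or_per_sd < self.ci_high):
            raise ValidationError("CI must bracket the point estimate")
        if self.or_per_sd <= 0:
            raise ValidationError("odds ratio must be positive")


def wald_ratio(h: HarmonizedInstrument) -> WaldRatio:
    """Per-SNP Wald ratio Gamma/gamma with first-order standard error."""
    if h.beta_exposure == 0:
        raise EstimationError(f"{h.rsid}: zero exposure effect, Wald ratio undefined")
    return WaldRatio(
        rsid=h.rsid,
        ratio=h.logor_outcome / h.beta_exposure,
        se_ratio=h.se_outcome / abs(h.beta_exposure),
    )


def ivw_estimate(ratios: Sequence[WaldRatio]) -> tuple[float, float]:
    """Fixed-effect inverse-variance pooled causal estimate ``(beta, se)``."""
    if not ratios:
        raise EstimationError("ivw_estimate requires at least one Wald ratio")
    w = np.array([r.se_ratio**-2 for r in ratios])
    b = np.array([r.ratio for r in ratios])
    wsum = w.sum()
    return float((w * b).sum() / wsum), float(wsum**-0.5)


def ivw_from_harmonized(harmonized: Sequence[HarmonizedInstrument]) -> tuple[float, float, int]:
    """Wald ratios + IVW over the estimable records; returns (beta, se, n_snps)."""
    usable = estimable(harmonized)
    if not usable:
        raise EstimationError("no estimable (as_is/swapped) harmonized records")
    ratios = [wald_ratio(h) for h in usable]
    beta, se = ivw_estimate(ratios)
    return beta, se, len(ratios)


def scale_and_report(beta: float, se: float, spec: ExposureSpec, n_snps: int = 1) -> MREstimate:
    """Rescale a per-unit log-odds estimate to the per-SD odds-ratio report.

    The p-value is the two-sided normal p of beta/se and is unchanged by the
    (positive) scale factor.
    """
    if not (math.isfinite(se) and se > 0):
        raise EstimationError("se must be positive and finite")
    s = spec.sd_scale
    z = beta / se
    return MREstimate(
        beta=beta,
        se=se,
        sd_scale=s,
        or_per_sd=math.exp(beta * s),
        ci_low=math.exp((beta - Z_95 * se) * s),
        ci_high=math.exp((beta + Z_95 * se) * s),
        pvalue=float(2 * stats.norm.sf(abs(z))),
        n_snps=n_snps,
    )


def se_from_ci(or_point: float, ci_low: float, ci_high: float) -> tuple[float, float]:
    """Back-derive ``(log OR, se)`` from a published OR with 95% CI.

    ``se = (ln ci_high - ln ci_low) / (2 * 1.959964)``.  A zero-width CI is
    accepted but flagged degenerate (se = 0), since downstream estimators
    require positive standard errors.
    """
    if not (0 < ci_low <= or_point <= ci_high):
        raise ValidationError(
            f"CI ordering violated: need 0 < {ci_low} <= {or_point} <= {ci_high}"
        )
    se = (math.log(ci_high) - math.log(ci_low)) / (2 * Z_95)
    if se == 0:
        logger.warning("degenerate CI (zero width) for OR=%s", or_point)
    return math.log(or_point), se


# ---------------------------------------------------------------------------
# Display formatting (raw precision is always kept in the dataclasses)
# ---------------------------------------------------------------------------


def format_or_ci(est: MREstimate) -> str:
    """Render ``OR (low to high)`` with 2 decimals, journal-table style."""
    return f"{est.or_per_sd:.2f} ({est.ci_low:.2f} to {est.ci_high:.2f})"


def format_pvalue(p: float) -> str:
    """Two significant figures; scientific below 1e-3, leading-zero-free otherwise."""
    if p < 1e-3:
        return f"{p:.1e}"
    return f"{p:.2g}".lstrip("0") if p < 1 else f"{p:.2g}"
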