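"""Pleiotropy diagnostics: Bonferroni screens, exclusion reruns, leave-one-out.

A single pleiotropic SNP can drive a pooled MR estimate.  Three complementary
checks are provided: (1) a per-SNP screen of the SNP-outcome associations
against a Bonferroni-corrected threshold (e.g. alpha = 0.05/49 for a 49-SNP
instrument set); (2) a full rerun of the IVW pipeline with flagged or named
variants excluded, reported next to the baseline; (3) leave-one-out estimates,
one per omitted SNP, plus a per-SNP scatter export (gamma_j, Gamma_j,
sigma_Gj) for plotting.  Screens use the pooled (META) outcome associations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from scipy import stats

from .errors import EstimationError, ValidationError
from .estimate import ExposureSpec, MREstimate, ivw_from_harmonized, scale_and_report
from .instrument_io import HarmonizedInstrument, estimable


@dataclass(frozen=True)
class SnpScreenResult:
    """One SNP's outcome association tested against a Bonferroni threshold."""

    rsid: str
    logor_outcome: float
    se_outcome: float
    pvalue: float
    alpha: float
    flagged: bool

    def __post_init__(self) -> None:
        if self.flagged != (self.pvalue < self.alpha):
            raise ValidationError(f"{self.rsid}: flagged inconsistent with pvalue/alpha")


@dataclass(frozen=True)
class LeaveOneOutResult:
    dropped_rsid: str
    beta: float
    se: float


@dataclass(frozen=True)
class SensitivityReport:
    """Baseline vs exclusion-rerun estimates plus leave-one-out diagnostics."""

    baseline: MREstimate
    excluded_rsids: tuple[str, ...]
    rerun: MREstimate
    leave_one_out: tuple[LeaveOneOutResult, ...]

    def __post_init__(self) -> None:
        if self.rerun.n_snps != self.baseline.n_snps - len(self.excluded_rsids):
            raise ValidationError("rerun.n_snps must equal baseline.n_snps minus exclusions")


def bonferroni_alpha(n_tests: int, family_alpha: float = 0.05) -> float:
    """Per-test significance threshold controlling the family-wise error rate."""
    if n_tests < 1:
        raise ValidationError(f"n_tests must be >= 1, got {n_tests}")
    return family_alpha / n_tests


def screen_snps(
    harmonized: Sequence[HarmonizedInstrument], alpha: float
) -> list[SnpScreenResult]:
    """Two-sided normal p of each SNP's outcome log-odds; flag if p < alpha.

    |z| = |Gamma_j| / sigma_Gj is invariant to allele re-orientation, so the
    screen does not depend on the harmonization sign convention.
    """
    if not 0 < alpha < 1:
        raise ValidationError(f"alpha must be in (0, 1), got {alpha}")
    results = []
    for h in estimable(harmonized):
        p = float(2 * stats.norm.sf(abs(h.logor_outcome) / h.se_outcome))
        results.append(
            SnpScreenResult(
                rsid=h.rsid,
                logor_outcome=h.logor_outcome,
                se_outcome=h.se_outcome,
                pvalue=p,
                alpha=alpha,
                flagged=p < alpha,
            )
        )
    return results


def rerun_excluding(
    harmonized: Sequence[HarmonizedInstrument],
    excluded: Iterable[str],
    spec: ExposureSpec,
) -> SensitivityReport:
    """Recompute the IVW estimate without the named SNPs, keeping the baseline.

    ``excluded`` must be a subset of the harmonized rsids and must not empty
    the instrument set.
    """
    excluded = tuple(sorted(set(excluded)))
    usable = estimable(harmonized)
    rsids = {h.rsid for h in usable}
    unknown = [e for e in excluded if e not in rsids]
    if unknown:
        raise ValidationError(f"excluded rsid(s) not in the instrument set: {', '.join(unknown)}")
    reduced = [h for h in usable if h.rsid not in excluded]
    if not reduced:
        raise EstimationError("exclusion would leave zero SNPs")
    baseline = _estimate(usable, spec)
    rerun = _estimate(reduced, spec)
    loo = leave_one_out(usable) if len(usable) >= 2 else ()
    return SensitivityReport(
        baseline=baseline, excluded_rsids=excluded, rerun=rerun, leave_one_out=tuple(loo)
    )


def _estimate(harmonized, spec: ExposureSpec) -> MREstimate:
    beta, se, n = ivw_from_harmonized(harmonized)
    return scale_and_report(beta, se, spec, n_snps=n)


def leave_one_out(harmonized: Sequence[HarmonizedInstrument]) -> list[LeaveOneOutResult]:
    """IVW estimates each omitting one SNP (pleiotropic-outlier diagnostic)."""
    usable = estimable(harmonized)
    if len(usable) < 2:
        raise EstimationError("leave-one-out requires at least 2 SNPs")
    results = []
    for i, h in enumerate(usable):
        beta, se, _ = ivw_from_harmonized(usable[:i] + usable[i + 1 :])
        results.append(LeaveOneOutResult(dropped_rsid=h.rsid, beta=beta, se=se))
    return results


def scatter_table(harmonized: Sequence[HarmonizedInstrument]) -> pd.DataFrame:
    """Per-SNP (gamma, Gamma, se) records for effect-vs-effect scatter plots."""
    usable = estimable(harmonized)
    return pd.DataFrame(
        {
            "rsid": [h.rsid for h in usable],
            "beta_exposure": [h.beta_exposure for h in usable],
            "logor_outcome": [h.logor_outcome for h in usable],
            "se_outcome": [h.se_outcome for h in usable],
        }
    )


def screen_report(results: Sequence[SnpScreenResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "rsid": [r.rsid for r in results],
            "logor_outcome": [r.logor_outcome for r in results],
            "se_outcome": [r.se_outcome for r in results],
            "pvalue": [r.pvalue for r in results],
            "alpha": [r.alpha for r in results],
            "flagged": [r.flagged for r in results],
        }
    )
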