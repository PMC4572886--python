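"""Synthetic two-sample GWAS generator with known causal ground truth.

The generator emulates the data-generating process of a two-sample MR study
of a continuous exposure and a binary disease outcome:

* biallelic SNPs in Hardy-Weinberg equilibrium at given allele frequencies,
  independent of each other (no LD — instruments are distinct loci);
* a continuous exposure ``X = sum_j gamma_j g_j + a*U + eps`` with a shared
  standard-normal confounder ``U``;
* disease ``D ~ Bernoulli(logistic(b0 + beta*X + d*U + sum_j pi_j g_j))``
  where ``beta`` is the causal effect of interest and ``pi_j`` optional
  direct (pleiotropic) SNP effects;
* two *non-overlapping* samples: a population exposure GWAS (per-SNP linear
  regressions of X on dosage) and a case-control outcome GWAS (per-SNP
  logistic regressions of status on dosage), drawn from independent RNG
  streams;
* an individual-level panel of 11 mixed quantitative/binary traits for
  genetic-score confounder scans, with genetic links only where the design
  plants them.

Every operation is fully deterministic given ``(design, seed)``.  The default
design mirrors the scale of the motivating study: 36 SNPs, exposure GWAS
n = 50,000, and an outcome GWAS of 1,287 cases / 8,273 controls.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import SimulationError, ValidationError
from .instrument_io import InstrumentVariant, OutcomeAssociation

#: Non-palindromic allele pairs a simulated SNP may carry.
_ALLELE_PAIRS = (("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"), ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T"))

#: Confounder-scan panel: name, mean, sd (quantitative) or prevalence (binary).
TRAIT_REGISTRY: tuple[tuple[str, str, float, float], ...] = (
    ("age", "quantitative", 50.0, 10.0),
    ("age_menarche", "quantitative", 13.0, 1.5),
    ("age_menopause", "quantitative", 50.0, 4.0),
    ("bmi", "quantitative", 26.0, 4.5),
    ("fasting_glucose", "quantitative", 4.9, 0.65),
    ("fasting_insulin", "quantitative", 3.8, 0.60),
    ("insulin_30min", "quantitative", 5.5, 0.58),
    ("physical_activity", "quantitative", 0.0, 1.0),
    ("energy_intake", "quantitative", 2000.0, 500.0),
    ("education", "binary", 0.45, 0.0),
    ("smoking", "binary", 0.30, 0.0),
)

TRAIT_TYPES: dict[str, str] = {name: kind for name, kind, _, _ in TRAIT_REGISTRY}


@dataclass(frozen=True)
class SimulationDesign:
    """Ground-truth parameters of one synthetic two-sample study.

    ``gamma_true`` are per-allele exposure effects in exposure-SD units;
    ``causal_beta`` is the disease log-odds per exposure unit.  ``trait_links``
    plants additional per-allele genetic effects on named panel traits (in
    trait units), on top of ``exposure_trait`` which always receives the
    built exposure itself.
    """

    n_snps: int = 36
    allele_freqs: Optional[np.ndarray] = None
    gamma_true: Optional[np.ndarray] = None
    causal_beta: float = 0.85
    confounder_effect_on_exposure: float = 0.3
    confounder_effect_on_outcome: float = 0.3
    pleiotropy_betas: Optional[np.ndarray] = None
    n_exposure_cohort: int = 50_000
    n_cases: int = 1_287
    n_controls: int = 8_273
    baseline_logodds: float = -2.0
    exposure_noise_sd: Optional[float] = None
    n_trait_panel: int = 10_000
    exposure_trait: str = "fasting_insulin"
    trait_links: Mapping[str, float] = field(default_factory=dict)
    effect_alleles: Optional[Sequence[str]] = None
    other_alleles: Optional[Sequence[str]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snps < 1:
            raise ValidationError("n_snps must be >= 1")
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValidationError("n_cases and n_controls must be >= 1")
        if self.allele_freqs is not None:
            f = np.asarray(self.allele_freqs, dtype=float)
            if f.shape != (self.n_snps,):
                raise ValidationError("allele_freqs must have one entry per SNP")
            if (f <= 0.01).any() or (f >= 0.5).any():
                raise ValidationError("allele_freqs must lie in (0.01, 0.5)")
        if self.gamma_true is not None and np.asarray(self.gamma_true).shape != (self.n_snps,):
            raise ValidationError("gamma_true must have one entry per SNP")
        if self.pleiotropy_betas is not None and np.asarray(self.pleiotropy_betas).shape != (self.n_snps,):
            raise ValidationError("pleiotropy_betas must have one entry per SNP")
        if self.exposure_trait not in TRAIT_TYPES:
            raise ValidationError(f"unknown exposure_trait {self.exposure_trait!r}")
        for t in self.trait_links:
            if t not in TRAIT_TYPES:
                raise ValidationError(f"trait link targets unknown trait {t!r}")


def default_design(seed: int = 0, n_snps: int = 36, **overrides) -> SimulationDesign:
    """A fully-specified design at the default study scale.

    Allele frequencies are drawn U(0.1, 0.4) and per-allele exposure effects
    U(0.02, 0.06) — together about 2% of exposure variance explained and a
    mean single-SNP F statistic around 30 in a 50,000-person exposure GWAS —
    with allele labels assigned from non-palindromic pairs.  The draw is
    deterministic in ``seed`` and independent of the cohort-simulation
    streams.
    """
    rng = _rng(seed, 0)
    f = rng.uniform(0.1, 0.4, size=n_snps)
    gamma = rng.uniform(0.02, 0.06, size=n_snps)
    pairs = [_ALLELE_PAIRS[i] for i in rng.integers(0, len(_ALLELE_PAIRS), size=n_snps)]
    base = dict(
        n_snps=n_snps,
        allele_freqs=f,
        gamma_true=gamma,
        effect_alleles=tuple(p[0] for p in pairs),
        other_alleles=tuple(p[1] for p in pairs),
        seed=seed,
    )
    base.update(overrides)
    return SimulationDesign(**base)


@dataclass
class CohortPanel:
    """Individual-level data for one simulated cohort."""

    genotypes: np.ndarray
    exposure: Optional[np.ndarray]
    confounder: np.ndarray
    disease: Optional[np.ndarray]
    traits: Optional[pd.DataFrame]
    seed: int


# ---------------------------------------------------------------------------
# RNG plumbing: independent streams per cohort role (two-sample independence)
# ---------------------------------------------------------------------------

_EXPOSURE_STREAM = 1
_OUTCOME_STREAM = 2
_PANEL_STREAM = 3


def _rng(seed: int, stream: int, label: str = "") -> np.random.Generator:
    salt = zlib.crc32(label.encode()) if label else 0
    return np.random.default_rng(np.random.SeedSequence([int(seed), stream, salt]))


def _genotypes(rng: np.random.Generator, n: int, freqs: np.ndarray) -> np.ndarray:
    """Hardy-Weinberg dosages: sum of two independent allele draws."""
    f = freqs[None, :]
    return ((rng.random((n, len(freqs))) < f).astype(np.float64)
            + (rng.random((n, len(freqs))) < f))


def _realized(design: SimulationDesign) -> tuple[np.ndarray, np.ndarray, list[str], list[str], list[str]]:
    if design.allele_freqs is None or design.gamma_true is None:
        raise ValidationError("design needs explicit allele_freqs and gamma_true (see default_design)")
    f = np.asarray(design.allele_freqs, dtype=float)
    gamma = np.asarray(design.gamma_true, dtype=float)
    rsids = [f"rs{j + 1}" for j in range(design.n_snps)]
    ea = list(design.effect_alleles) if design.effect_alleles is not None else ["A"] * design.n_snps
    oa = list(design.other_alleles) if design.other_alleles is not None else ["G"] * design.n_snps
    return f, gamma, rsids, ea, oa


def _noise_sd(design: SimulationDesign, f: np.ndarray, gamma: np.ndarray) -> float:
    """Residual exposure sd chosen so total exposure variance is ~1 (SD units)."""
    if design.exposure_noise_sd is not None:
        return design.exposure_noise_sd
    var_g = float((gamma**2 * 2 * f * (1 - f)).sum())
    var_u = design.confounder_effect_on_exposure**2
    return float(np.sqrt(max(0.1, 1.0 - var_g - var_u)))


def _exposure(rng, g, gamma, design, f):
    u = rng.standard_normal(g.shape[0])
    eps = rng.standard_normal(g.shape[0]) * _noise_sd(design, f, gamma)
    x = g @ gamma + design.confounder_effect_on_exposure * u + eps
    return x, u


# ---------------------------------------------------------------------------
# Per-SNP GWAS fits (vectorised across SNPs)
# ---------------------------------------------------------------------------


def _snp_linear_fits(g: np.ndarray, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Marginal simple-regression slope and se of x on each dosage column."""
    n = g.shape[0]
    gc = g - g.mean(axis=0)
    xc = x - x.mean()
    sxx = (gc**2).sum(axis=0)
    if (sxx == 0).any():
        raise SimulationError("monomorphic SNP in exposure cohort")
    sxy = gc.T @ xc
    beta = sxy / sxx
    rss = (xc**2).sum() - beta * sxy
    se = np.sqrt(rss / (n - 2) / sxx)
    return beta, se


def _logistic_newton(
    counts_n: np.ndarray, counts_k: np.ndarray, max_iter: int = 100, tol: float = 1e-12
) -> tuple[np.ndarray, np.ndarray]:
    """Two-parameter logistic fits on (m, 3) dosage-cell totals/successes.

    Newton-Raphson on the aggregated score equations; counts may be
    fractional (population cell weights), in which case the returned se is a
    formal quantity only.  Returns per-row (slope, se_slope).
    """
    gvals = np.array([0.0, 1.0, 2.0])
    ntot = counts_n.sum(axis=1)
    ktot = counts_k.sum(axis=1)
    if (ktot <= 0).any() or (ktot >= ntot).any():
        raise SimulationError("a sample with no cases or no controls cannot be fit")
    a = np.log(ktot / (ntot - ktot))
    b = np.zeros(counts_n.shape[0])
    for _ in range(max_iter):
        p = expit(a[:, None] + b[:, None] * gvals)
        w = counts_n * p * (1 - p)
        resid = counts_k - counts_n * p
        ga = resid.sum(axis=1)
        gb = (resid * gvals).sum(axis=1)
        haa = w.sum(axis=1)
        hab = (w * gvals).sum(axis=1)
        hbb = (w * gvals**2).sum(axis=1)
        det = haa * hbb - hab**2
        if (det <= 0).any() or not np.isfinite(det).all():
            raise SimulationError("singular information matrix in per-SNP logistic fit")
        da = (hbb * ga - hab * gb) / det
        db = (haa * gb - hab * ga) / det
        a += da
        b += db
        if max(np.abs(da).max(), np.abs(db).max()) < tol:
            break
    else:
        raise SimulationError("per-SNP logistic fit did not converge")
    se_b = np.sqrt(haa / det)
    return b, se_b


def _snp_logistic_fits(g: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP logistic regression of case status on dosage.

    Exact maximum-likelihood Newton-Raphson on the aggregated 3x2
    dosage-by-status count table of each SNP (dosages are hard calls in
    {0, 1, 2}, so the table is sufficient).  Identical to the full
    individual-level logistic MLE, but vectorised across SNPs.
    Returns per-SNP (log-odds per allele, se).
    """
    m = g.shape[1]
    counts_n = np.empty((m, 3))
    counts_k = np.empty((m, 3))
    yb = y.astype(np.float64)
    for dose in (0, 1, 2):
        mask = g == dose
        counts_n[:, dose] = mask.sum(axis=0)
        counts_k[:, dose] = yb @ mask
    return _logistic_newton(counts_n, counts_k)


def marginal_causal_logor(design: SimulationDesign, gh_points: int = 81) -> float:
    """The population-averaged causal log-OR per exposure unit — the estimand.

    With a binary outcome, summary MR built on per-SNP *marginal* logistic
    GWAS coefficients identifies the population-averaged (marginal) causal
    odds ratio, which is attenuated relative to the conditional coefficient
    ``causal_beta`` whenever other risk variation (the rest of the exposure,
    the confounder) is integrated out — the classic non-collapsibility of the
    odds ratio.  Under the null the two coincide at zero.

    Computed analytically, with no sampling: per SNP, the three dosage-cell
    disease probabilities are Gauss-Hermite integrals of the logistic model
    over the remaining (approximately normal) linear predictor; the limiting
    per-SNP GWAS coefficient is the Hardy-Weinberg-weighted logistic
    projection onto (intercept, dosage); Wald ratios are then pooled with
    their limiting IVW weights.  (Logistic slopes are invariant to
    outcome-dependent case-control sampling, so the sampling scheme does not
    enter.)
    """
    f, gamma, *_ = _realized(design)
    if design.pleiotropy_betas is not None and np.any(design.pleiotropy_betas):
        raise ValidationError("estimand is defined for designs without pleiotropy")
    beta = design.causal_beta
    if beta == 0:
        return 0.0
    a_exp = design.confounder_effect_on_exposure
    d_out = design.confounder_effect_on_outcome
    eps_sd = _noise_sd(design, f, gamma)
    var_g = gamma**2 * 2 * f * (1 - f)
    mean_g = gamma * 2 * f
    # per SNP: the rest of the outcome linear predictor is approximately
    # normal (CLT over the other SNPs plus the normal confounder and noise)
    s2 = beta**2 * (var_g.sum() - var_g + eps_sd**2) + (beta * a_exp + d_out) ** 2
    mu = design.baseline_logodds + beta * (mean_g.sum() - mean_g)
    z, w = np.polynomial.hermite_e.hermegauss(gh_points)
    w = w / w.sum()
    k = np.array([0.0, 1.0, 2.0])
    eta = (
        mu[:, None, None]
        + beta * np.outer(gamma, k)[:, :, None]
        + np.sqrt(s2)[:, None, None] * z[None, None, :]
    )
    cell_p = (expit(eta) * w).sum(axis=2)
    hw = np.stack([(1 - f) ** 2, 2 * f * (1 - f), f**2], axis=1)
    slope, _ = _logistic_newton(hw, hw * cell_p)
    ratios = slope / gamma
    # limiting IVW weights: gamma_j^2 / var(Gamma_hat_j) with var proportional
    # to 1 / (dosage variance x p(1-p) mass); constant factors cancel
    pbar = (hw * cell_p).sum(axis=1)
    weights = gamma**2 * 2 * f * (1 - f) * pbar * (1 - pbar)
    return float(np.average(ratios, weights=weights))


# ---------------------------------------------------------------------------
# Cohort simulators
# ---------------------------------------------------------------------------


def simulate_exposure_cohort(
    design: SimulationDesign, seed: Optional[int] = None
) -> tuple[CohortPanel, list[InstrumentVariant]]:
    """Population exposure GWAS: individual data plus the instrument table.

    Each SNP's (gamma_hat, se) comes from the marginal linear regression of
    the exposure on its dosage in ``n_exposure_cohort`` individuals.
    """
    seed = design.seed if seed is None else seed
    rng = _rng(seed, _EXPOSURE_STREAM)
    f, gamma, rsids, ea, oa = _realized(design)
    g = _genotypes(rng, design.n_exposure_cohort, f)
    x, u = _exposure(rng, g, gamma, design, f)
    beta_hat, se_hat = _snp_linear_fits(g, x)
    instruments = [
        InstrumentVariant(
            rsid=rsids[j],
            effect_allele=ea[j],
            other_allele=oa[j],
            beta_exposure=float(beta_hat[j]),
            se_exposure=float(se_hat[j]),
        )
        for j in range(design.n_snps)
    ]
    panel = CohortPanel(genotypes=g, exposure=x, confounder=u, disease=None, traits=None, seed=seed)
    return panel, instruments


def simulate_case_control(
    design: SimulationDesign,
    seed: Optional[int] = None,
    cohort_label: str = "UK",
    n_cases: Optional[int] = None,
    n_controls: Optional[int] = None,
    max_chunks: int = 200,
) -> list[OutcomeAssociation]:
    """Case-control outcome GWAS: per-SNP logistic summary statistics.

    A fresh population (independent RNG stream and genotypes — the two-sample
    design) is drawn in chunks; individuals accumulate into the case and
    control pools until the quotas are met.  If the disease is too rare to
    yield the requested cases within ``max_chunks`` draws, a
    :class:`SimulationError` advises raising ``baseline_logodds``.
    """
    seed = design.seed if seed is None else seed
    rng = _rng(seed, _OUTCOME_STREAM, cohort_label)
    f, gamma, rsids, ea, oa = _realized(design)
    want_cases = design.n_cases if n_cases is None else n_cases
    want_controls = design.n_controls if n_controls is None else n_controls
    pleio = (
        np.asarray(design.pleiotropy_betas, dtype=float)
        if design.pleiotropy_betas is not None
        else None
    )
    chunk = max(10_000, 2 * (want_cases + want_controls))
    case_rows: list[np.ndarray] = []
    control_rows: list[np.ndarray] = []
    got_cases = got_controls = 0
    for _ in range(max_chunks):
        g = _genotypes(rng, chunk, f)
        x, u = _exposure(rng, g, gamma, design, f)
        eta = design.baseline_logodds + design.causal_beta * x + design.confounder_effect_on_outcome * u
        if pleio is not None:
            eta = eta + g @ pleio
        d = rng.random(chunk) < expit(eta)
        if got_cases < want_cases:
            take = g[d][: want_cases - got_cases]
            case_rows.append(take)
            got_cases += take.shape[0]
        if got_controls < want_controls:
            take = g[~d][: want_controls - got_controls]
            control_rows.append(take)
            got_controls += take.shape[0]
        if got_cases >= want_cases and got_controls >= want_controls:
            break
    else:
        raise SimulationError(
            f"could not draw {want_cases} cases within {max_chunks} chunks; "
            "increase baseline_logodds (disease too rare)"
        )
    g_all = np.vstack(case_rows + control_rows)
    y = np.zeros(g_all.shape[0], dtype=bool)
    y[:want_cases] = True
    logor, se = _snp_logistic_fits(g_all, y)
    return [
        OutcomeAssociation(
            rsid=rsids[j],
            effect_allele=ea[j],
            other_allele=oa[j],
            logor_outcome=float(logor[j]),
            se_outcome=float(se[j]),
            cohort=cohort_label,
        )
        for j in range(design.n_snps)
    ]


def simulate_trait_panel(
    design: SimulationDesign, seed: Optional[int] = None
) -> tuple[CohortPanel, dict[str, str]]:
    """Individual-level 11-trait panel for genetic-score confounder scans.

    The trait named ``design.exposure_trait`` is the built exposure mapped to
    its registry scale (mean + sd * X); traits named in ``design.trait_links``
    additionally receive the given per-allele effect times total dosage; all
    other traits are independent of genotype.  Returns the panel and the
    trait-type declaration consumed by :func:`summr.scores.scan_confounders`.
    """
    seed = design.seed if seed is None else seed
    rng = _rng(seed, _PANEL_STREAM)
    f, gamma, rsids, _, _ = _realized(design)
    n = design.n_trait_panel
    g = _genotypes(rng, n, f)
    x, u = _exposure(rng, g, gamma, design, f)
    total_dose = g.sum(axis=1)
    traits: dict[str, np.ndarray] = {}
    for name, kind, loc, scale in TRAIT_REGISTRY:
        if kind == "binary":
            traits[name] = (rng.random(n) < loc).astype(float)
        elif name == design.exposure_trait:
            traits[name] = loc + scale * x
        else:
            traits[name] = loc + scale * rng.standard_normal(n)
        link = design.trait_links.get(name)
        if link:
            if kind == "binary":
                raise ValidationError(f"genetic links on binary trait {name!r} are not supported")
            traits[name] = traits[name] + link * total_dose
    panel = CohortPanel(
        genotypes=g,
        exposure=x,
        confounder=u,
        disease=None,
        traits=pd.DataFrame(traits),
        seed=seed,
    )
    return panel, dict(TRAIT_TYPES)
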