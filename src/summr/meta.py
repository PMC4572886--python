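"""Fixed-effect inverse-variance meta-analysis of per-SNP outcome associations.

Case-control cohorts (e.g. a UK and an Australian endometrial-cancer GWAS)
are analysed separately and their per-SNP log-odds ratios pooled *before* MR
estimation, assuming one common true effect per SNP:

    w_i = se_i^-2,  logor_meta = sum w_i logor_i / sum w_i,  se_meta = (sum w_i)^-1/2.

Cochran's Q is computed and logged for each pooled SNP but never filters:
heterogeneity gating is deliberately not part of the pipeline.
"""

from __future__ import annotations

import logging
import math
from typing import Sequence

from scipy import stats

from .errors import EstimationError, HarmonizationError
from .instrument_io import OutcomeAssociation

logger = logging.getLogger(__name__)

META_COHORT = "META"


def fixed_effect_meta(inputs: Sequence[tuple[float, float]]) -> tuple[float, float]:
    """Precision-weighted pooled ``(logor, se)`` over per-cohort estimates."""
    if not inputs:
        raise EstimationError("fixed_effect_meta requires at least one input")
    wsum = 0.0
    bsum = 0.0
    for logor, se in inputs:
        if se <= 0:
            raise EstimationError("all standard errors must be > 0")
        w = se**-2
        wsum += w
        bsum += w * logor
    return bsum / wsum, wsum**-0.5


def cochran_q(inputs: Sequence[tuple[float, float]]) -> tuple[float, int, float]:
    """Heterogeneity statistic ``(Q, df, p)`` for a fixed-effect pool."""
    pooled, _ = fixed_effect_meta(inputs)
    q = sum((logor - pooled) ** 2 / se**2 for logor, se in inputs)
    df = len(inputs) - 1
    p = float(stats.chi2.sf(q, df)) if df > 0 else 1.0
    return q, df, p


def meta_outcome_tables(
    tables: Sequence[Sequence[OutcomeAssociation]],
) -> tuple[list[OutcomeAssociation], dict[str, list[str]]]:
    """Pool per-SNP associations across cohort tables into a ``META`` table.

    Tables must already share a strand convention; within that, records for
    the same rsid whose alleles are exactly swapped relative to the first
    occurrence are sign-flipped into its orientation, and incompatible allele
    pairs raise :class:`HarmonizationError`.  A SNP present in a single cohort
    passes through (with its se unchanged).  Returns the pooled records plus a
    map of rsid -> contributing cohort labels.
    """
    reference: dict[str, OutcomeAssociation] = {}
    per_rsid: dict[str, list[tuple[float, float]]] = {}
    contributors: dict[str, list[str]] = {}
    order: list[str] = []
    for table in tables:
        for rec in table:
            ref = reference.get(rec.rsid)
            if ref is None:
                reference[rec.rsid] = rec
                per_rsid[rec.rsid] = []
                contributors[rec.rsid] = []
                order.append(rec.rsid)
                logor = rec.logor_outcome
            elif (rec.effect_allele, rec.other_allele) == (ref.effect_allele, ref.other_allele):
                logor = rec.logor_outcome
            elif (rec.effect_allele, rec.other_allele) == (ref.other_allele, ref.effect_allele):
                logor = -rec.logor_outcome
            else:
                raise HarmonizationError(
                    f"{rec.rsid}: allele labels {rec.effect_allele}/{rec.other_allele} in cohort "
                    f"{rec.cohort} conflict with {ref.effect_allele}/{ref.other_allele}"
                )
            per_rsid[rec.rsid].append((logor, rec.se_outcome))
            contributors[rec.rsid].append(rec.cohort)

    pooled: list[OutcomeAssociation] = []
    for rsid in order:
        logor, se = fixed_effect_meta(per_rsid[rsid])
        if len(per_rsid[rsid]) > 1:
            q, df, p = cochran_q(per_rsid[rsid])
            logger.info("%s: Cochran Q=%.3f df=%d p=%.3g (logged, never filtered on)", rsid, q, df, p)
        ref = reference[rsid]
        pooled.append(
            OutcomeAssociation(
                rsid=rsid,
                effect_allele=ref.effect_allele,
                other_allele=ref.other_allele,
                logor_outcome=logor,
                se_outcome=se,
                cohort=META_COHORT,
            )
        )
    if not math.isfinite(sum(r.logor_outcome for r in pooled)):
        raise EstimationError("non-finite pooled estimate")
    return pooled, contributors
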