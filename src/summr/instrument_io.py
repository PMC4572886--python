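"""Reading, validation, allele harmonization and QC filtering of GWAS summary tables.

Two-sample Mendelian randomization consumes two kinds of summary-statistic
tables: *instrument* tables giving each SNP's per-allele effect on an exposure
(the weighting factors), and *outcome* tables giving each SNP's log-odds
effect on disease in one case-control cohort.  Before any estimation the two
must be *harmonized*: oriented so that effect sizes in both tables refer to
the same allele.  This module owns those tables, their invariants, and the
pre-estimation filters (allele harmonization, genotyping QC, and named-variant
exclusion lists).

File dialect: TSV, UTF-8, header row with fixed column names, ``#``-prefixed
comment lines ignored.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

import pandas as pd

from .errors import HarmonizationError, ValidationError

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")

#: Allele pairs whose strand cannot be resolved from labels alone.
PALINDROMIC_PAIRS = frozenset({frozenset(("A", "T")), frozenset(("C", "G"))})

#: Harmonization outcomes. Only ``as_is`` and ``swapped`` enter estimation.
ACTIONS = ("as_is", "swapped", "dropped_palindromic", "dropped_mismatch")

INSTRUMENT_COLUMNS = ("rsid", "effect_allele", "other_allele", "beta_exposure", "se_exposure")
OUTCOME_COLUMNS = ("rsid", "effect_allele", "other_allele", "logor_outcome", "se_outcome", "cohort")
OUTCOME_CI_COLUMNS = ("rsid", "effect_allele", "other_allele", "or_point", "ci_low", "ci_high", "cohort")
QC_COLUMNS = ("rsid", "call_rate", "maf", "hwe_p_cases", "hwe_p_controls", "imputed", "imputation_r2")


def _check_allele(allele: str, field: str) -> str:
    allele = str(allele).strip().upper()
    if allele not in VALID_ALLELES:
        raise ValidationError(f"{field} must be one of A/C/G/T, got {allele!r}")
    return allele


@dataclass(frozen=True)
class InstrumentVariant:
    """One SNP's per-effect-allele association with an exposure.

    ``beta_exposure`` is in native exposure units (e.g. ln(pmol/L) for fasting
    insulin); ``locus_label`` is an optional gene/locus tag (e.g. "FTO")
    consumed by exclusion rules.
    """

    rsid: str
    effect_allele: str
    other_allele: str
    beta_exposure: float
    se_exposure: float
    locus_label: Optional[str] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "effect_allele", _check_allele(self.effect_allele, "effect_allele"))
        object.__setattr__(self, "other_allele", _check_allele(self.other_allele, "other_allele"))
        if self.effect_allele == self.other_allele:
            raise ValidationError(f"{self.rsid}: effect and other allele are identical")
        if not math.isfinite(self.beta_exposure):
            raise ValidationError(f"{self.rsid}: beta_exposure is not finite")
        if not (math.isfinite(self.se_exposure) and self.se_exposure > 0):
            raise ValidationError(f"{self.rsid}: se_exposure must be > 0")

    @property
    def is_palindromic(self) -> bool:
        return frozenset((self.effect_allele, self.other_allele)) in PALINDROMIC_PAIRS


@dataclass(frozen=True)
class OutcomeAssociation:
    """One SNP's log-odds association with disease in one cohort."""

    rsid: str
    effect_allele: str
    other_allele: str
    logor_outcome: float
    se_outcome: float
    cohort: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "effect_allele", _check_allele(self.effect_allele, "effect_allele"))
        object.__setattr__(self, "other_allele", _check_allele(self.other_allele, "other_allele"))
        if self.effect_allele == self.other_allele:
            raise ValidationError(f"{self.rsid}: effect and other allele are identical")
        if not math.isfinite(self.logor_outcome):
            raise ValidationError(f"{self.rsid}: logor_outcome is not finite")
        if not (math.isfinite(self.se_outcome) and self.se_outcome > 0):
            raise ValidationError(f"{self.rsid}: se_outcome must be > 0")


@dataclass(frozen=True)
class HarmonizedInstrument:
    """An instrument/outcome pair oriented to a common effect allele.

    After alignment the effect allele is the exposure-increasing allele, so
    ``beta_exposure >= 0``; the outcome log-odds is sign-flipped in tandem.
    Records with a ``dropped_*`` action are retained for reporting but must
    not enter estimation.
    """

    rsid: str
    beta_exposure: float
    se_exposure: float
    logor_outcome: float
    se_outcome: float
    harmonization_action: str

    def __post_init__(self) -> None:
        if self.harmonization_action not in ACTIONS:
            raise ValidationError(f"{self.rsid}: unknown action {self.harmonization_action!r}")
        if self.se_exposure <= 0 or self.se_outcome <= 0:
            raise ValidationError(f"{self.rsid}: standard errors must be > 0")
        if self.estimable and self.beta_exposure < 0:
            raise ValidationError(f"{self.rsid}: estimable record must have beta_exposure >= 0")

    @property
    def estimable(self) -> bool:
        return self.harmonization_action in ("as_is", "swapped")


@dataclass(frozen=True)
class VariantQCRecord:
    """Per-variant genotyping quality metrics for the outcome GWAS."""

    rsid: str
    call_rate: float
    maf: float
    hwe_p_cases: float
    hwe_p_controls: float
    imputed: bool
    imputation_r2: float = 1.0

    def __post_init__(self) -> None:
        for name, lo, hi in (
            ("call_rate", 0.0, 1.0),
            ("maf", 0.0, 0.5),
            ("hwe_p_cases", 0.0, 1.0),
            ("hwe_p_controls", 0.0, 1.0),
            ("imputation_r2", 0.0, 1.0),
        ):
            v = getattr(self, name)
            if not (math.isfinite(v) and lo <= v <= hi):
                raise ValidationError(f"{self.rsid}: {name}={v} outside [{lo}, {hi}]")


# ---------------------------------------------------------------------------
# Table IO
# ---------------------------------------------------------------------------


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str, skip_blank_lines=True)


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {', '.join(missing)}")


def _to_float(value, row: int, column: str):
    try:
        return float(value)
    except (TypeError, ValueError):
        raise ValidationError(f"row {row}: non-numeric {column} ({value!r})") from None


def read_instrument_table(path) -> list[InstrumentVariant]:
    """Read an instrument TSV into validated records, preserving row order.

    Raises :class:`ValidationError` naming the offending (1-based data) row on
    a missing column, a non-numeric beta/se, an invariant violation, or a
    duplicate rsid.
    """
    df = _read_tsv(path)
    _require_columns(df, INSTRUMENT_COLUMNS, path)
    records: list[InstrumentVariant] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False), start=1):
        rsid = str(row.rsid).strip()
        if rsid in seen:
            raise ValidationError(f"row {i}: duplicate rsid {rsid}")
        seen.add(rsid)
        locus = getattr(row, "locus_label", None)
        if locus is not None and (pd.isna(locus) or str(locus).strip() == ""):
            locus = None
        try:
            records.append(
                InstrumentVariant(
                    rsid=rsid,
                    effect_allele=row.effect_allele,
                    other_allele=row.other_allele,
                    beta_exposure=_to_float(row.beta_exposure, i, "beta_exposure"),
                    se_exposure=_to_float(row.se_exposure, i, "se_exposure"),
                    locus_label=None if locus is None else str(locus).strip(),
                )
            )
        except ValidationError as err:
            raise ValidationError(f"row {i}: {err}") from None
    return records


def read_outcome_table(path) -> list[OutcomeAssociation]:
    """Read an outcome TSV into validated records.

    Two column layouts are accepted: ``logor_outcome``/``se_outcome`` directly,
    or published ``or_point``/``ci_low``/``ci_high`` columns which are
    converted via :func:`summr.estimate.se_from_ci`.  (rsid, cohort) pairs must
    be unique.
    """
    from .estimate import se_from_ci  # local import: avoids a module cycle

    df = _read_tsv(path)
    has_logor = all(c in df.columns for c in ("logor_outcome", "se_outcome"))
    has_ci = all(c in df.columns for c in ("or_point", "ci_low", "ci_high"))
    if not (has_logor or has_ci):
        raise ValidationError(
            f"{path}: need either logor_outcome/se_outcome or or_point/ci_low/ci_high columns"
        )
    _require_columns(df, ("rsid", "effect_allele", "other_allele", "cohort"), path)
    records: list[OutcomeAssociation] = []
    seen: set[tuple[str, str]] = set()
    for i, row in enumerate(df.itertuples(index=False), start=1):
        rsid = str(row.rsid).strip()
        cohort = str(row.cohort).strip()
        if (rsid, cohort) in seen:
            raise ValidationError(f"row {i}: duplicate (rsid, cohort) = ({rsid}, {cohort})")
        seen.add((rsid, cohort))
        if has_logor:
            logor = _to_float(row.logor_outcome, i, "logor_outcome")
            se = _to_float(row.se_outcome, i, "se_outcome")
        else:
            logor, se = se_from_ci(
                _to_float(row.or_point, i, "or_point"),
                _to_float(row.ci_low, i, "ci_low"),
                _to_float(row.ci_high, i, "ci_high"),
            )
        try:
            records.append(
                OutcomeAssociation(
                    rsid=rsid,
                    effect_allele=row.effect_allele,
                    other_allele=row.other_allele,
                    logor_outcome=logor,
                    se_outcome=se,
                    cohort=cohort,
                )
            )
        except ValidationError as err:
            raise ValidationError(f"row {i}: {err}") from None
    return records


def read_qc_table(path) -> list[VariantQCRecord]:
    """Read a per-variant QC metrics TSV."""
    df = _read_tsv(path)
    _require_columns(df, QC_COLUMNS, path)
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        imputed = str(row.imputed).strip().lower() in ("1", "true", "yes")
        try:
            records.append(
                VariantQCRecord(
                    rsid=str(row.rsid).strip(),
                    call_rate=_to_float(row.call_rate, i, "call_rate"),
                    maf=_to_float(row.maf, i, "maf"),
                    hwe_p_cases=_to_float(row.hwe_p_cases, i, "hwe_p_cases"),
                    hwe_p_controls=_to_float(row.hwe_p_controls, i, "hwe_p_controls"),
                    imputed=imputed,
                    imputation_r2=_to_float(row.imputation_r2, i, "imputation_r2"),
                )
            )
        except ValidationError as err:
            raise ValidationError(f"row {i}: {err}") from None
    return records


def write_instrument_table(path, variants: Iterable[InstrumentVariant], header_comments: Sequence[str] = ()) -> None:
    df = pd.DataFrame(
        {
            "rsid": [v.rsid for v in variants],
            "effect_allele": [v.effect_allele for v in variants],
            "other_allele": [v.other_allele for v in variants],
            "beta_exposure": [repr(v.beta_exposure) for v in variants],
            "se_exposure": [repr(v.se_exposure) for v in variants],
            "locus_label": [v.locus_label or "" for v in variants],
        }
    )
    _write_tsv(path, df, header_comments)


def write_outcome_table(path, records: Iterable[OutcomeAssociation], header_comments: Sequence[str] = ()) -> None:
    df = pd.DataFrame(
        {
            "rsid": [r.rsid for r in records],
            "effect_allele": [r.effect_allele for r in records],
            "other_allele": [r.other_allele for r in records],
            "logor_outcome": [repr(r.logor_outcome) for r in records],
            "se_outcome": [repr(r.se_outcome) for r in records],
            "cohort": [r.cohort for r in records],
        }
    )
    _write_tsv(path, df, header_comments)


def _write_tsv(path, df: pd.DataFrame, header_comments: Sequence[str]) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# Harmonization
# ---------------------------------------------------------------------------


def harmonize(
    instruments: Sequence[InstrumentVariant],
    outcomes: Sequence[OutcomeAssociation],
    cohort: str,
    palindromic_policy: str = "trust",
) -> list[HarmonizedInstrument]:
    """Allele-align instrument and outcome tables for one cohort.

    For each instrument SNP found in the outcome table: identical allele pairs
    pass through (``as_is``); exactly swapped pairs negate the outcome
    log-odds (``swapped``); incompatible pairs are kept as ``dropped_mismatch``.
    Palindromic A/T and C/G SNPs are taken at face value under the default
    ``"trust"`` policy (appropriate for curated variant lists whose strand is
    pre-resolved) and marked ``dropped_palindromic`` under ``"strict"``.

    Every aligned record is then oriented so the effect allele is the
    exposure-increasing allele (``beta_exposure >= 0``), flipping the outcome
    sign in tandem; the IVW estimate is invariant to this convention.

    Instruments absent from the outcome table are reported via a warning, not
    silently dropped; zero overlap is a :class:`HarmonizationError`.
    """
    if palindromic_policy not in ("trust", "strict"):
        raise ValidationError(f"unknown palindromic_policy {palindromic_policy!r}")
    if not instruments or not outcomes:
        raise ValidationError("harmonize requires nonempty instrument and outcome tables")
    by_rsid: dict[str, OutcomeAssociation] = {}
    for rec in outcomes:
        if rec.cohort != cohort:
            continue
        if rec.rsid in by_rsid:
            raise ValidationError(f"duplicate outcome record for {rec.rsid} in cohort {cohort}")
        by_rsid[rec.rsid] = rec

    results: list[HarmonizedInstrument] = []
    missing: list[str] = []
    for iv in instruments:
        out = by_rsid.get(iv.rsid)
        if out is None:
            missing.append(iv.rsid)
            continue
        if palindromic_policy == "strict" and iv.is_palindromic:
            action, logor = "dropped_palindromic", out.logor_outcome
        elif (out.effect_allele, out.other_allele) == (iv.effect_allele, iv.other_allele):
            action, logor = "as_is", out.logor_outcome
        elif (out.effect_allele, out.other_allele) == (iv.other_allele, iv.effect_allele):
            action, logor = "swapped", -out.logor_outcome
        else:
            action, logor = "dropped_mismatch", out.logor_outcome
        beta = iv.beta_exposure
        if action in ("as_is", "swapped") and beta < 0:
            beta, logor = -beta, -logor
        results.append(
            HarmonizedInstrument(
                rsid=iv.rsid,
                beta_exposure=beta,
                se_exposure=iv.se_exposure,
                logor_outcome=logor,
                se_outcome=out.se_outcome,
                harmonization_action=action,
            )
        )
    if missing:
        logger.warning(
            "%d instrument SNP(s) absent from outcome table for cohort %s: %s",
            len(missing), cohort, ", ".join(missing),
        )
    if not results:
        raise HarmonizationError(f"no instrument rsid overlaps the outcome table for cohort {cohort}")
    return results


def estimable(harmonized: Iterable[HarmonizedInstrument]) -> list[HarmonizedInstrument]:
    """The subset of harmonized records that may enter estimation."""
    return [h for h in harmonized if h.estimable]


# ---------------------------------------------------------------------------
# QC filtering and exclusion lists
# ---------------------------------------------------------------------------


def qc_filter(records: Sequence[VariantQCRecord]) -> tuple[list[str], list[tuple[str, str]]]:
    """Partition variants into QC pass/fail per the outcome-GWAS genotyping rules.

    A variant passes iff
    ``[(call_rate >= 0.95 and maf >= 0.05) or (call_rate >= 0.99 and maf < 0.05)]``
    and ``hwe_p_cases > 1e-12`` and ``hwe_p_controls > 1e-7`` and, when
    imputed, ``imputation_r2 >= 0.6``.  Call-rate/MAF bounds are inclusive,
    HWE bounds strictly exceeded.  Fail reasons name the first violated rule
    in that order.
    """
    passed: list[str] = []
    failed: list[tuple[str, str]] = []
    for rec in records:
        if not ((rec.call_rate >= 0.95 and rec.maf >= 0.05) or (rec.call_rate >= 0.99 and rec.maf < 0.05)):
            failed.append((rec.rsid, "call_rate/maf"))
        elif not rec.hwe_p_cases > 1e-12:
            failed.append((rec.rsid, "hwe_cases"))
        elif not rec.hwe_p_controls > 1e-7:
            failed.append((rec.rsid, "hwe_controls"))
        elif rec.imputed and rec.imputation_r2 < 0.6:
            failed.append((rec.rsid, "imputation_r2"))
        else:
            passed.append(rec.rsid)
    return passed, failed


def exclude_variants(
    instruments: Sequence[InstrumentVariant],
    exclusion: Iterable[str],
) -> list[InstrumentVariant]:
    """Remove instruments whose rsid or locus label is in the exclusion set.

    Typical uses: dropping FTO-locus variants from insulin and diabetes
    instrument sets (their exposure effects run through adiposity), or a named
    rsid for a sensitivity rerun.  Names matching nothing produce a warning,
    not an error; the number removed is logged.
    """
    exclusion = set(exclusion)
    kept = [
        iv for iv in instruments
        if iv.rsid not in exclusion and (iv.locus_label is None or iv.locus_label not in exclusion)
    ]
    matched = {iv.rsid for iv in instruments if iv.rsid in exclusion}
    matched |= {iv.locus_label for iv in instruments if iv.locus_label in exclusion}
    unmatched = exclusion - matched
    if unmatched:
        logger.warning("exclusion name(s) matched no variant: %s", ", ".join(sorted(unmatched)))
    logger.info("excluded %d of %d variants", len(instruments) - len(kept), len(instruments))
    return kept


def reoriented(iv: InstrumentVariant) -> InstrumentVariant:
    """The same variant expressed on the opposite effect allele."""
    return replace(
        iv,
        effect_allele=iv.other_allele,
        other_allele=iv.effect_allele,
        beta_exposure=-iv.beta_exposure,
    )
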