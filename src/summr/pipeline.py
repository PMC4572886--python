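"""End-to-end orchestration: harmonize -> meta -> IVW -> scale -> sensitivity -> report.

A run is driven by a YAML/JSON config naming, per exposure, the instrument
table, exclusion list, reporting SD and test-family size, plus the per-cohort
outcome tables.  Outputs mirror a journal-style results section: a per-SD
odds-ratio table (one row per exposure), a Bonferroni screen block, an
exclusion-rerun sensitivity block, leave-one-out and scatter exports, and a
JSON-lines manifest.  Given fixed config and inputs the report TSVs are
byte-identical across runs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError, ValidationError
from .estimate import ExposureSpec, format_or_ci, format_pvalue, ivw_from_harmonized, scale_and_report
from .instrument_io import (
    estimable,
    exclude_variants,
    harmonize,
    read_instrument_table,
    read_outcome_table,
)
from .meta import META_COHORT, meta_outcome_tables
from .sensitivity import (
    bonferroni_alpha,
    leave_one_out,
    rerun_excluding,
    scatter_table,
    screen_report,
    screen_snps,
)

logger = logging.getLogger(__name__)

_TOP_KEYS = {"output_dir", "palindromic_policy", "exposures", "outcomes", "seed", "family_alpha"}
_EXPOSURE_KEYS = {"name", "sd", "binary", "instruments", "exclude", "n_tests"}
_OUTCOME_KEYS = {"cohort", "path"}


@dataclass(frozen=True)
class ExposureConfig:
    name: str
    sd: float
    instruments_path: str
    binary: bool = False
    exclude: tuple[str, ...] = ()
    n_tests: Optional[int] = None

    @property
    def spec(self) -> ExposureSpec:
        return ExposureSpec(name=self.name, sd_scale=self.sd, binary_exposure=self.binary)


@dataclass(frozen=True)
class RunConfig:
    exposures: tuple[ExposureConfig, ...]
    outcomes: tuple[tuple[str, str], ...]  # (cohort label, path)
    output_dir: str = "summr_out"
    palindromic_policy: str = "trust"
    family_alpha: float = 0.05
    seed: int = 0
    config_hash: str = ""


@dataclass
class AnalysisReport:
    """In-memory mirror of the written report files."""

    estimates: pd.DataFrame
    sensitivity: pd.DataFrame
    screens: pd.DataFrame
    provenance: dict = field(default_factory=dict)
    output_dir: Optional[Path] = None


def validate_config(path) -> RunConfig:
    """Parse and validate a run config, collecting *all* problems before failing."""
    raw = Path(path).read_bytes()
    try:
        doc = yaml.safe_load(raw)
    except yaml.YAMLError as err:
        raise ConfigError([f"unparseable config: {err}"]) from None
    if not isinstance(doc, dict):
        raise ConfigError(["config must be a mapping"])
    problems: list[str] = []
    for key in doc:
        if key not in _TOP_KEYS:
            problems.append(f"unknown key {key!r}")
    base = Path(path).parent

    exposures: list[ExposureConfig] = []
    seen_names: set[str] = set()
    for i, entry in enumerate(doc.get("exposures") or []):
        if not isinstance(entry, dict):
            problems.append(f"exposures[{i}]: must be a mapping")
            continue
        for key in entry:
            if key not in _EXPOSURE_KEYS:
                problems.append(f"exposures[{i}]: unknown key {key!r}")
        name = entry.get("name")
        if not name:
            problems.append(f"exposures[{i}]: missing name")
            continue
        if name in seen_names:
            problems.append(f"exposures[{i}]: duplicate exposure name {name!r}")
        seen_names.add(name)
        sd = entry.get("sd")
        binary = bool(entry.get("binary", False))
        if sd is None or not isinstance(sd, (int, float)) or sd <= 0:
            problems.append(f"{name}: sd must be a positive number, got {sd!r}")
            continue
        if binary and sd != 1:
            problems.append(f"{name}: binary exposure requires sd = 1, got {sd}")
        ipath = entry.get("instruments")
        if not ipath:
            problems.append(f"{name}: missing instruments path")
            continue
        ipath = str((base / ipath).resolve()) if not Path(ipath).is_absolute() else ipath
        if not Path(ipath).exists():
            problems.append(f"{name}: instrument file not found: {ipath}")
        n_tests = entry.get("n_tests")
        if n_tests is not None and (not isinstance(n_tests, int) or n_tests < 1):
            problems.append(f"{name}: n_tests must be a positive integer")
        exposures.append(
            ExposureConfig(
                name=str(name),
                sd=float(sd),
                binary=binary,
                instruments_path=ipath,
                exclude=tuple(entry.get("exclude") or ()),
                n_tests=n_tests,
            )
        )
    if not exposures and not any(p.startswith("exposures") for p in problems):
        problems.append("at least one exposure is required")

    outcomes: list[tuple[str, str]] = []
    seen_cohorts: set[str] = set()
    for i, entry in enumerate(doc.get("outcomes") or []):
        if not isinstance(entry, dict):
            problems.append(f"outcomes[{i}]: must be a mapping")
            continue
        for key in entry:
            if key not in _OUTCOME_KEYS:
                problems.append(f"outcomes[{i}]: unknown key {key!r}")
        cohort = entry.get("cohort")
        opath = entry.get("path")
        if not cohort or not opath:
            problems.append(f"outcomes[{i}]: needs both cohort and path")
            continue
        if cohort in seen_cohorts:
            problems.append(f"outcomes[{i}]: duplicate cohort label {cohort!r}")
        seen_cohorts.add(cohort)
        opath = str((base / opath).resolve()) if not Path(opath).is_absolute() else opath
        if not Path(opath).exists():
            problems.append(f"outcomes[{i}]: outcome file not found: {opath}")
        outcomes.append((str(cohort), opath))
    if not outcomes:
        problems.append("at least one outcome cohort is required")

    policy = doc.get("palindromic_policy", "trust")
    if policy not in ("trust", "strict"):
        problems.append(f"palindromic_policy must be 'trust' or 'strict', got {policy!r}")

    if problems:
        raise ConfigError(problems)
    return RunConfig(
        exposures=tuple(exposures),
        outcomes=tuple(outcomes),
        output_dir=str(doc.get("output_dir", "summr_out")),
        palindromic_policy=policy,
        family_alpha=float(doc.get("family_alpha", 0.05)),
        seed=int(doc.get("seed", 0)),
        config_hash=hashlib.sha256(raw).hexdigest(),
    )


def run_pipeline(config: RunConfig) -> AnalysisReport:
    """Execute the full summary-statistic MR analysis described by ``config``."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort_tables = []
    for cohort, path in config.outcomes:
        records = [r for r in read_outcome_table(path) if r.cohort == cohort]
        if not records:
            raise ValidationError(f"outcome table {path} has no records for cohort {cohort!r}")
        cohort_tables.append(records)

    meta_records, contributors = meta_outcome_tables(cohort_tables)

    est_rows: list[dict] = []
    sens_rows: list[dict] = []
    screen_frames: list[pd.DataFrame] = []
    manifest: list[dict] = []
    for exp in config.exposures:
        try:
            instruments = read_instrument_table(exp.instruments_path)
            instruments = exclude_variants(instruments, exp.exclude)
            harmonized = harmonize(instruments, meta_records, META_COHORT, config.palindromic_policy)
            beta, se, n_snps = ivw_from_harmonized(harmonized)
            estimate = scale_and_report(beta, se, exp.spec, n_snps=n_snps)
            alpha = bonferroni_alpha(exp.n_tests or n_snps, config.family_alpha)
            screened = screen_snps(harmonized, alpha)
            flagged = tuple(s.rsid for s in screened if s.flagged)
        except Exception as err:
            raise type(err)(f"exposure {exp.name!r}: {err}") from err

        est_rows.append(
            {
                "exposure": exp.name,
                "sd_scale": estimate.sd_scale,
                "n_snps": estimate.n_snps,
                "beta": estimate.beta,
                "se": estimate.se,
                "or_per_sd": estimate.or_per_sd,
                "ci_low": estimate.ci_low,
                "ci_high": estimate.ci_high,
                "pvalue": estimate.pvalue,
            }
        )
        usable = estimable(harmonized)
        if flagged and len(flagged) < len(usable):
            report = rerun_excluding(harmonized, flagged, exp.spec)
            rr = report.rerun
            sens_rows.append(
                {
                    "exposure": exp.name,
                    "excluded_rsids": ",".join(report.excluded_rsids),
                    "n_snps": rr.n_snps,
                    "beta": rr.beta,
                    "se": rr.se,
                    "or_per_sd": rr.or_per_sd,
                    "ci_low": rr.ci_low,
                    "ci_high": rr.ci_high,
                    "pvalue": rr.pvalue,
                }
            )
        sc = screen_report(screened)
        sc.insert(0, "exposure", exp.name)
        screen_frames.append(sc)

        scatter = scatter_table(harmonized)
        _write_tsv(outdir / f"scatter_{exp.name}.tsv", scatter)
        if len(usable) >= 2:
            loo = leave_one_out(harmonized)
            _write_tsv(
                outdir / f"leave_one_out_{exp.name}.tsv",
                pd.DataFrame(
                    {
                        "dropped_rsid": [r.dropped_rsid for r in loo],
                        "beta": [r.beta for r in loo],
                        "se": [r.se for r in loo],
                    }
                ),
            )
        manifest.append(
            {
                "stage": "exposure",
                "exposure": exp.name,
                "n_instruments": len(instruments),
                "n_snps_estimated": n_snps,
                "alpha": alpha,
                "flagged": list(flagged),
                "or_per_sd": estimate.or_per_sd,
                "display": f"{format_or_ci(estimate)} p={format_pvalue(estimate.pvalue)}",
            }
        )

    estimates = pd.DataFrame(est_rows)
    sensitivity = pd.DataFrame(
        sens_rows,
        columns=["exposure", "excluded_rsids", "n_snps", "beta", "se", "or_per_sd", "ci_low", "ci_high", "pvalue"],
    )
    screens = pd.concat(screen_frames, ignore_index=True)
    _write_tsv(outdir / "estimates.tsv", estimates)
    _write_tsv(outdir / "sensitivity.tsv", sensitivity)
    _write_tsv(outdir / "screen.tsv", screens)
    _write_display_table(outdir / "estimates_display.tsv", estimates)

    provenance = {
        "package_version": __version__,
        "config_hash": config.config_hash,
        "cohorts": [c for c, _ in config.outcomes],
        "n_meta_snps": len(meta_records),
        "contributors": contributors,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
    }
    with open(outdir / "manifest.jsonl", "w", encoding="utf-8") as fh:
        fh.write(json.dumps({"stage": "provenance", **provenance}) + "\n")
        for entry in manifest:
            fh.write(json.dumps(entry) + "\n")
    logger.info("pipeline complete: %d exposure(s) -> %s", len(config.exposures), outdir)
    return AnalysisReport(
        estimates=estimates,
        sensitivity=sensitivity,
        screens=screens,
        provenance=provenance,
        output_dir=outdir,
    )


def _write_tsv(path: Path, df: pd.DataFrame) -> None:
    # full float precision (repr) so reports are exactly reproducible
    df = df.copy()
    for col in df.columns:
        if df[col].dtype.kind == "f":
            df[col] = df[col].map(repr)
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def _write_display_table(path: Path, estimates: pd.DataFrame) -> None:
    """Journal-style rounding: OR/CI to 2 decimals, p to 2 significant figures."""
    rows = []
    for row in estimates.itertuples(index=False):
        rows.append(
            {
                "exposure": row.exposure,
                "sd": row.sd_scale,
                "n_snps": row.n_snps,
                "or_per_sd_95ci": f"{row.or_per_sd:.2f} ({row.ci_low:.2f} to {row.ci_high:.2f})",
                "pvalue": format_pvalue(row.pvalue),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, lineterminator="\n")
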