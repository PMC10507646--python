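"""End-to-end study orchestration.

For each exposure-outcome pair the pipeline runs the full analysis chain:

    select instruments (p < threshold) -> LD clump -> F screen (warn-only)
    -> harmonize to a shared effect allele -> MR-PRESSO outlier removal
    -> causal estimates (IVW fixed/random, MR-Egger, weighted median)
    -> sensitivity battery (Cochran's Q, Egger intercept, leave-one-out)

One pair's failure (no instruments, no overlapping SNPs, unreadable outcome
file) never aborts the study: the pair is marked failed with a reason and the
remaining pairs proceed. All randomness derives deterministically from the
study seed, so rerunning a study with the same configuration produces
byte-identical output tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd
import yaml

from . import estimators as est
from . import instruments as ins
from . import io as sio
from . import sensitivity as sens
from .exceptions import SummaryMRError

logger = logging.getLogger(__name__)

__all__ = ["StudyConfig", "PairResult", "run_pair", "run_study", "verify_printed_results"]

DEFAULT_METHODS = ("ivw_fixed", "ivw_random", "egger", "weighted_median")


@dataclass
class StudyConfig:
    """Study-level configuration: trait tables, thresholds and options.

    ``exposures``/``outcomes`` are (name, summary-stat path) lists; every
    exposure is analyzed against every outcome. Threshold defaults follow the
    conventional relaxed instrument screen (p < 5e-7, clump r^2 < 0.001
    within 10,000 kb, F > 10 warn-only, palindromic ambiguity window 0.08,
    95% CIs).
    """

    exposures: List[Tuple[str, str]]
    outcomes: List[Tuple[str, str]]
    ld_matrix_path: Optional[str] = None
    p_threshold: float = ins.DEFAULT_P_THRESHOLD
    clump_r2: float = ins.DEFAULT_CLUMP_R2
    clump_window_kb: int = ins.DEFAULT_CLUMP_WINDOW_KB
    min_f: float = ins.DEFAULT_MIN_F
    palindrome_window: float = sio.PALINDROME_EAF_WINDOW
    alpha: float = 0.05
    methods: Sequence[str] = DEFAULT_METHODS
    presso_enabled: bool = True
    presso_n_sim: int = 1000
    n_boot: int = 1000
    seed: int = 0
    output_dir: Optional[str] = None

    def __post_init__(self):
        if not self.exposures or not self.outcomes:
            raise ValueError("at least one exposure and one outcome are required")
        unknown = set(self.methods) - set(DEFAULT_METHODS)
        if unknown:
            raise ValueError(f"unknown method(s): {sorted(unknown)}")
        if self.output_dir is not None:
            paths = {str(p) for _, p in list(self.exposures) + list(self.outcomes)}
            if str(self.output_dir) in paths:
                raise ValueError("output_dir must differ from every input path")

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("exposures", "outcomes"):
            if key in raw:
                raw[key] = [tuple(item) for item in raw[key]]
        if "methods" in raw:
            raw["methods"] = tuple(raw["methods"])
        return cls(**raw)


@dataclass
class PairResult:
    """Everything computed for one exposure-outcome pair."""

    exposure: str
    outcome: str
    failed: bool = False
    reason: Optional[str] = None
    nsnp_initial: int = 0
    nsnp_after_clump: int = 0
    nsnp_after_harmonization: int = 0
    nsnp_after_outlier_removal: int = 0
    estimates: List[est.MREstimate] = field(default_factory=list)
    sensitivity: Optional[sens.SensitivityReport] = None
    weak_instruments: bool = False

    @property
    def flags(self) -> Dict[str, bool]:
        return {
            "weak_instruments": self.weak_instruments,
            "pleiotropy_detected": bool(
                self.sensitivity and self.sensitivity.pleiotropy_detected
            ),
            "heterogeneity_detected": bool(
                self.sensitivity and self.sensitivity.heterogeneity_detected
            ),
        }


def _pair_seed(study_seed: int, pair_index: int) -> int:
    # Deterministic per-pair seed, kept below 2**31.
    return (study_seed * 100_003 + 7919 * pair_index + 1) % (2**31 - 1)


def run_pair(
    exposure_records: Sequence[sio.SummaryRecord],
    outcome_records: Sequence[sio.SummaryRecord],
    config: StudyConfig,
    exposure_name: str = "exposure",
    outcome_name: str = "outcome",
    ld: Optional[pd.DataFrame] = None,
    seed: Optional[int] = None,
) -> PairResult:
    """Run the full per-pair analysis chain. Returns a failed PairResult
    (never raises) when the pair cannot be analyzed."""
    result = PairResult(exposure=exposure_name, outcome=outcome_name)
    seed = config.seed if seed is None else seed
    try:
        iset = ins.build_instrument_set(
            exposure_records,
            ld=ld,
            p_threshold=config.p_threshold,
            clump_r2=config.clump_r2,
            clump_window_kb=config.clump_window_kb,
            min_f=config.min_f,
        )
    except SummaryMRError as exc:
        result.failed, result.reason = True, str(exc)
        return result
    result.nsnp_initial = sum(r.pval < config.p_threshold for r in exposure_records)
    result.nsnp_after_clump = len(iset.records)
    result.weak_instruments = bool(iset.weak)

    pairs = sio.harmonize(iset.records, outcome_records, config.palindrome_window)
    kept = sio.retained(pairs)
    result.nsnp_after_harmonization = len(kept)
    if not kept:
        result.failed = True
        result.reason = (
            "no overlapping SNPs"
            if not pairs
            else "no SNPs retained after harmonization"
        )
        return result

    presso_result = None
    analysis = kept
    if config.presso_enabled and len(kept) >= 4:
        presso_result = sens.mr_presso(
            kept, n_sim=config.presso_n_sim, seed=_sub_seed(seed, 1)
        )
        if presso_result.outliers:
            outliers = set(presso_result.outliers)
            analysis = [p for p in kept if p.snp_id not in outliers]
            logger.info(
                "%s vs %s: removed %d MR-PRESSO outlier(s): %s",
                exposure_name,
                outcome_name,
                len(outliers),
                ", ".join(sorted(outliers)),
            )
    result.nsnp_after_outlier_removal = len(analysis)

    for method in config.methods:
        try:
            result.estimates.append(_estimate(method, analysis, config, seed))
        except SummaryMRError as exc:
            logger.warning(
                "%s vs %s: %s skipped (%s)", exposure_name, outcome_name, method, exc
            )

    try:
        q_stat, q_df, q_pval = sens.cochran_q(analysis)
    except SummaryMRError:
        q_stat, q_df, q_pval = 0.0, 0, 1.0
    try:
        egger = est.mr_egger(analysis, alpha=config.alpha)
        intercept, intercept_se, intercept_p = (
            egger.intercept,
            egger.intercept_se,
            egger.intercept_p,
        )
    except SummaryMRError:
        intercept = intercept_se = 0.0
        intercept_p = 1.0
    loo: Dict[str, est.MREstimate] = {}
    if len(analysis) >= 2:
        loo = sens.leave_one_out(analysis, alpha=config.alpha)
    result.sensitivity = sens.SensitivityReport(
        q_stat=q_stat,
        q_df=q_df,
        q_pval=q_pval,
        egger_intercept=intercept,
        egger_intercept_se=intercept_se,
        egger_intercept_p=intercept_p,
        presso=presso_result,
        loo_estimates=loo,
    )
    logger.info(
        "%s vs %s: %d selected -> %d clumped -> %d harmonized -> %d analyzed",
        exposure_name,
        outcome_name,
        result.nsnp_initial,
        result.nsnp_after_clump,
        result.nsnp_after_harmonization,
        result.nsnp_after_outlier_removal,
    )
    return result


def _sub_seed(seed: int, stream: int) -> int:
    return (seed * 31 + stream) % (2**31 - 1)


def _estimate(method: str, pairs, config: StudyConfig, seed: int) -> est.MREstimate:
    if method == "ivw_fixed":
        return est.ivw(pairs, model="fixed", alpha=config.alpha)
    if method == "ivw_random":
        return est.ivw(pairs, model="random", alpha=config.alpha)
    if method == "egger":
        return est.mr_egger(pairs, alpha=config.alpha).slope
    if method == "weighted_median":
        return est.weighted_median(
            pairs, n_boot=config.n_boot, seed=_sub_seed(seed, 2), alpha=config.alpha
        )
    raise ValueError(f"unknown method {method!r}")


def run_study(config: StudyConfig) -> Tuple[pd.DataFrame, pd.DataFrame, List[PairResult]]:
    """Run every exposure x outcome pair and build the result tables.

    Returns (estimates table, sensitivity table, per-pair results). With
    ``config.output_dir`` set, the tables are also written as
    ``estimates.tsv`` and ``sensitivity.tsv`` in the summary_io schemas.
    Raises a study-level error only when an exposure file is unreadable; an
    unreadable outcome file fails just its pairs.
    """
    ld = ins.read_ld_matrix(config.ld_matrix_path) if config.ld_matrix_path else None
    exposures = [
        (name, sio.read_summary_stats(path)) for name, path in config.exposures
    ]

    results: List[PairResult] = []
    pair_index = 0
    for exp_name, exp_records in exposures:
        for out_name, out_path in config.outcomes:
            seed = _pair_seed(config.seed, pair_index)
            pair_index += 1
            try:
                out_records = sio.read_summary_stats(out_path)
            except Exception as exc:  # unreadable outcome: isolate the pair
                results.append(
                    PairResult(
                        exposure=exp_name,
                        outcome=out_name,
                        failed=True,
                        reason=f"unreadable outcome file: {exc}",
                    )
                )
                continue
            results.append(
                run_pair(
                    exp_records,
                    out_records,
                    config,
                    exposure_name=exp_name,
                    outcome_name=out_name,
                    ld=ld,
                    seed=seed,
                )
            )

    estimates_table = _estimates_frame(results, config)
    sensitivity_table = _sensitivity_frame(results)
    n_failed = sum(r.failed for r in results)
    if n_failed:
        logger.warning("%d of %d pair(s) failed", n_failed, len(results))
    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        sio.write_table(estimates_table, out / "estimates.tsv", "estimates")
        sio.write_table(sensitivity_table, out / "sensitivity.tsv", "sensitivity")
    return estimates_table, sensitivity_table, results


def _estimates_frame(results: Sequence[PairResult], config: StudyConfig) -> pd.DataFrame:
    rows = []
    for res in results:
        for e in res.estimates:
            # Auto-report random-effects IVW alongside fixed when Q flags
            # heterogeneity; both are present when requested explicitly.
            rows.append(
                {
                    "exposure": res.exposure,
                    "outcome": res.outcome,
                    "method": e.method,
                    "nsnp": e.nsnp,
                    "beta": e.beta,
                    "se": e.se,
                    "or": e.or_value,
                    "ci_low": e.ci_low,
                    "ci_high": e.ci_high,
                    "pval": e.pval,
                }
            )
    return pd.DataFrame(rows, columns=sio._SCHEMA_COLUMNS["estimates"])


def _sensitivity_frame(results: Sequence[PairResult]) -> pd.DataFrame:
    rows = []
    for res in results:
        if res.sensitivity is None:
            continue
        s = res.sensitivity
        rows.append(
            {
                "exposure": res.exposure,
                "outcome": res.outcome,
                "presso_global_p": s.presso.global_p_display if s.presso else "NA",
                "egger_intercept_p": s.egger_intercept_p,
                "cochran_q": s.q_stat,
                "df": s.q_df,
                "q_pval": s.q_pval,
                "outliers": " ".join(s.presso.outliers) if (s.presso and s.presso.outliers) else "NA",
            }
        )
    return pd.DataFrame(rows, columns=sio._SCHEMA_COLUMNS["sensitivity"])


def verify_printed_results(
    table: pd.DataFrame, rel_tol: float = 0.05
) -> pd.DataFrame:
    """Check published OR / 95% CI / p triples for internal consistency.

    ``table`` needs columns (or, ci_low, ci_high, printed_p); rounding of
    3-decimal ORs and CI bounds dominates the discrepancy, hence the default
    5% relative tolerance. Malformed rows (OR outside its CI) are listed with
    ``status='malformed'`` rather than raising.
    """
    out_rows = []
    for row in table.to_dict("records"):
        or_value = row.get("or", row.get("or_value"))
        entry = {
            "or": or_value,
            "ci_low": row["ci_low"],
            "ci_high": row["ci_high"],
            "printed_p": row["printed_p"],
        }
        try:
            recomputed = est.p_from_or_ci(or_value, row["ci_low"], row["ci_high"])
        except (ValueError, TypeError) as exc:
            entry.update(
                {"recomputed_p": float("nan"), "rel_discrepancy": float("nan"),
                 "status": f"malformed: {exc}"}
            )
            out_rows.append(entry)
            continue
        rel = abs(recomputed - row["printed_p"]) / row["printed_p"]
        entry.update(
            {
                "recomputed_p": recomputed,
                "rel_discrepancy": rel,
                "status": "pass" if rel <= rel_tol else "fail",
            }
        )
        out_rows.append(entry)
    return pd.DataFrame(out_rows)
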