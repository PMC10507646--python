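"""Sensitivity battery for two-sample MR: Cochran's Q heterogeneity test,
MR-Egger intercept flag, MR-PRESSO (global / outlier / distortion tests) and
leave-one-out analysis.

MR-PRESSO works on the residual sum of squares of outcome betas about the
leave-one-out IVW fit: a SNP whose outcome association is poorly predicted by
the causal model inflates the observed RSS relative to RSS values simulated
under the no-pleiotropy model, giving a global heterogeneity p-value; the same
comparison per SNP (Bonferroni-corrected) flags individual outliers, and a
distortion test asks whether removing the flagged outliers moved the estimate
more than removing an equally sized random subset would.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

from .estimators import IVWEstimator, MREstimate, _ratio_arrays
from .exceptions import InsufficientSNPsError
from .io import HarmonizedPair, pairs_to_arrays, retained

logger = logging.getLogger(__name__)

__all__ = [
    "SensitivityReport",
    "PressoResult",
    "MRPresso",
    "cochran_q",
    "q_pvalue",
    "egger_intercept_flag",
    "mr_presso",
    "leave_one_out",
    "loo_sign_consistency",
]


@dataclass
class PressoResult:
    """MR-PRESSO outcome.

    ``global_p`` is the empirical fraction of simulated RSS values at or above
    the observed one; when no simulated value reaches it, ``global_p`` is 0.0
    and ``global_p_bound`` carries the reporting bound 1/n_sim (display as
    e.g. "<0.001").
    """

    global_p: float
    global_p_bound: Optional[float]
    outliers: list[str]
    corrected: Optional[MREstimate]
    distortion_p: Optional[float]

    @property
    def global_p_display(self) -> str:
        if self.global_p_bound is not None:
            return f"<{self.global_p_bound:g}"
        return f"{self.global_p:g}"


@dataclass
class SensitivityReport:
    """Per-pair sensitivity summary mirroring the Q / Egger-intercept /
    MR-PRESSO / leave-one-out battery."""

    q_stat: float
    q_df: int
    q_pval: float
    egger_intercept: float
    egger_intercept_se: float
    egger_intercept_p: float
    presso: Optional[PressoResult] = None
    loo_estimates: Dict[str, MREstimate] = field(default_factory=dict)

    @property
    def heterogeneity_detected(self) -> bool:
        return self.q_pval < 0.05

    @property
    def pleiotropy_detected(self) -> bool:
        return egger_intercept_flag(self.egger_intercept_p)


def q_pvalue(q_stat: float, q_df: int) -> float:
    """Upper-tail chi-square probability of a Cochran Q statistic."""
    if q_stat < 0 or q_df < 1:
        raise ValueError(f"need q_stat >= 0 and q_df >= 1, got ({q_stat}, {q_df})")
    return float(stats.chi2.sf(q_stat, q_df))


def cochran_q(pairs: Sequence[HarmonizedPair]) -> tuple[float, int, float]:
    """Cochran's Q = sum_j w_j (theta_j - theta_IVW)^2 with w_j = 1/sigma_j^2.

    Returns (Q, df, p) with df = J - 1 and p the upper chi-square tail.
    Requires at least 2 retained SNPs.
    """
    bx, sx, by, sy = pairs_to_arrays(pairs)
    if len(bx) < 2:
        raise InsufficientSNPsError("cochran_q", 2, len(bx))
    theta, sigma = _ratio_arrays(bx, sx, by, sy, "first")
    w = 1.0 / sigma**2
    pooled = float(np.sum(w * theta) / np.sum(w))
    q = float(np.sum(w * (theta - pooled) ** 2))
    df = len(theta) - 1
    return q, df, q_pvalue(q, df)


def egger_intercept_flag(intercept_p: float) -> bool:
    """Directional pleiotropy is declared when the Egger intercept p < 0.05
    (strictly)."""
    if not (0.0 < intercept_p <= 1.0):
        raise ValueError(f"intercept_p must lie in (0,1], got {intercept_p}")
    return intercept_p < 0.05


class MRPresso(BaseEstimator):
    """MR-PRESSO residual-resampling test, scikit-learn style.

    Parameters
    ----------
    n_sim : int
        Number of simulated replicates for the global and outlier tests
        (>= 100).
    outlier_alpha : float
        Threshold on the Bonferroni-corrected per-SNP outlier p-value.
    global_alpha : float
        Nominal level of the global test (reported, not enforced).
    n_distortion : int
        Random outlier sets drawn for the distortion test.
    random_state : int, optional
        Seed for the simulation draws.

    Attributes (after ``fit``)
    --------------------------
    global_pvalue_, global_pvalue_bound_ : empirical global-test p (and the
        "<1/n_sim" bound when zero simulated RSS values exceed the observed).
    outlier_mask_ : boolean array marking outlier SNPs.
    outlier_pvalues_ : Bonferroni-corrected per-SNP outlier p-values.
    corrected_ : MREstimate or None — IVW (fixed) on the non-outliers.
    distortion_pvalue_ : float or None — only when outliers were found.

    Notes
    -----
    Procedure: for each SNP j the leave-one-out IVW estimate theta^{(-j)}
    predicts beta_Yj; the observed weighted RSS (weights 1/sigma_Yj^2) is
    compared against ``n_sim`` replicates in which beta_Yj* is redrawn from
    Normal(theta^{(-j)} beta_Xj, sigma_Yj^2) with the exposure betas held
    fixed. Per-SNP contributions yield the outlier test. Requires >= 4 SNPs;
    with fewer, fall back to Cochran's Q and the Egger intercept.
    """

    def __init__(
        self,
        n_sim: int = 1000,
        outlier_alpha: float = 0.05,
        global_alpha: float = 0.05,
        n_distortion: int = 1000,
        random_state: Optional[int] = None,
    ):
        self.n_sim = n_sim
        self.outlier_alpha = outlier_alpha
        self.global_alpha = global_alpha
        self.n_distortion = n_distortion
        self.random_state = random_state

    def fit(self, X, y, outcome_se=None, snp_ids: Optional[Sequence[str]] = None):
        if self.n_sim < 100:
            raise ValueError(f"n_sim must be >= 100, got {self.n_sim}")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        bx = X[:, 0]
        by = np.asarray(y, dtype=float).ravel()
        sy = np.asarray(outcome_se, dtype=float).ravel()
        nsnp = len(bx)
        if nsnp < 4:
            raise InsufficientSNPsError(
                "MRPresso (fall back to Cochran's Q / Egger intercept)", 4, nsnp
            )
        if np.any(sy <= 0):
            raise ValueError("outcome_se must be strictly positive")
        if np.any(bx == 0):
            raise ValueError("exposure betas must be nonzero")
        ids = list(snp_ids) if snp_ids is not None else [str(i) for i in range(nsnp)]

        rng = np.random.default_rng(self.random_state)
        theta = by / bx
        w_ratio = bx**2 / sy**2  # IVW weights in ratio space
        wy = 1.0 / sy**2

        num, den = float(np.sum(w_ratio * theta)), float(np.sum(w_ratio))
        theta_full = num / den
        theta_loo = (num - w_ratio * theta) / (den - w_ratio)

        res_obs = wy * (by - theta_loo * bx) ** 2
        rss_obs = float(np.sum(res_obs))

        # Simulated replicates under the no-pleiotropy model; exposure fixed.
        by_star = rng.normal(theta_loo * bx, sy, size=(self.n_sim, nsnp))
        theta_star = by_star / bx
        num_s = theta_star @ w_ratio
        theta_loo_s = (num_s[:, None] - w_ratio * theta_star) / (den - w_ratio)
        res_s = wy * (by_star - theta_loo_s * bx) ** 2
        rss_s = res_s.sum(axis=1)

        n_exceed = int(np.sum(rss_s >= rss_obs))
        self.global_pvalue_ = n_exceed / self.n_sim
        self.global_pvalue_bound_ = 1.0 / self.n_sim if n_exceed == 0 else None

        outlier_p = (res_s >= res_obs).mean(axis=0) * nsnp  # Bonferroni by J
        self.outlier_pvalues_ = np.minimum(outlier_p, 1.0)
        self.outlier_mask_ = self.outlier_pvalues_ < self.outlier_alpha
        self.outliers_ = [ids[i] for i in np.flatnonzero(self.outlier_mask_)]
        self.nsnp_ = nsnp

        keep = ~self.outlier_mask_
        if self.outlier_mask_.any() and keep.sum() >= 1:
            corrected = IVWEstimator(model="fixed").fit(
                bx[keep][:, None], by[keep], outcome_se=sy[keep]
            )
            self.corrected_ = corrected.estimate_
            self.distortion_pvalue_ = self._distortion(
                rng, bx, by, sy, theta_full, self.corrected_.beta, int(self.outlier_mask_.sum())
            )
        else:
            self.corrected_ = None
            self.distortion_pvalue_ = None
        return self

    def _distortion(self, rng, bx, by, sy, theta_full, theta_corr, n_out) -> float:
        """Distortion test: is the shift after outlier removal larger than the
        shift from removing an equally sized random subset?"""
        nsnp = len(bx)
        d_obs = abs(theta_corr - theta_full)
        w_ratio = bx**2 / sy**2
        theta = by / bx
        num, den = float(np.sum(w_ratio * theta)), float(np.sum(w_ratio))
        d_null = np.empty(self.n_distortion)
        for b in range(self.n_distortion):
            drop = rng.choice(nsnp, size=n_out, replace=False)
            num_b = num - float(np.sum(w_ratio[drop] * theta[drop]))
            den_b = den - float(np.sum(w_ratio[drop]))
            d_null[b] = abs(num_b / den_b - theta_full)
        return float(np.mean(d_null >= d_obs))


def mr_presso(
    pairs: Sequence[HarmonizedPair],
    n_sim: int = 1000,
    seed: Optional[int] = None,
    outlier_alpha: float = 0.05,
    global_alpha: float = 0.05,
) -> PressoResult:
    """Run MR-PRESSO on harmonized pairs; see :class:`MRPresso`."""
    kept = retained(pairs)
    bx, sx, by, sy = pairs_to_arrays(pairs)
    est = MRPresso(
        n_sim=n_sim,
        outlier_alpha=outlier_alpha,
        global_alpha=global_alpha,
        random_state=seed,
    ).fit(bx[:, None], by, outcome_se=sy, snp_ids=[p.snp_id for p in kept])
    return PressoResult(
        global_p=est.global_pvalue_,
        global_p_bound=est.global_pvalue_bound_,
        outliers=est.outliers_,
        corrected=est.corrected_,
        distortion_p=est.distortion_pvalue_,
    )


def leave_one_out(pairs: Sequence[HarmonizedPair], alpha: float = 0.05) -> Dict[str, MREstimate]:
    """Fixed-effect IVW re-estimated J times, each excluding one SNP.

    Returns a map from the excluded snp_id to the J-1 SNP estimate, plus an
    ``"all"`` entry holding the full-set estimate. Requires J >= 2.
    """
    kept = retained(pairs)
    if len(kept) < 2:
        raise InsufficientSNPsError("leave_one_out", 2, len(kept))
    out: Dict[str, MREstimate] = {}
    from .estimators import ivw as _ivw

    for i, pair in enumerate(kept):
        subset = kept[:i] + kept[i + 1 :]
        out[pair.snp_id] = _ivw(subset, model="fixed", alpha=alpha)
    out["all"] = _ivw(kept, model="fixed", alpha=alpha)
    return out


def loo_sign_consistency(loo: Dict[str, MREstimate]) -> bool:
    """True when every leave-one-out CI excludes the null on the same side as
    the full estimate's sign (OR CI entirely above or entirely below 1)."""
    if not loo:
        raise ValueError("leave-one-out map is empty")
    if len(loo) <= 1:
        return True  # nothing to compare against: vacuously consistent
    full = loo.get("all", next(iter(loo.values())))
    sign = np.sign(full.beta)
    if sign == 0:
        return False
    from ._stats import Z_975

    for key, est in loo.items():
        if key == "all":
            continue
        lo = est.beta - Z_975 * est.se
        hi = est.beta + Z_975 * est.se
        if sign > 0 and lo <= 0:
            return False
        if sign < 0 and hi >= 0:
            return False
    return True
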