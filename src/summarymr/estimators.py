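"""Causal-effect estimators for two-sample Mendelian randomization.

Given per-SNP harmonized summary associations (beta_Xj, sigma_Xj) with the
exposure and (beta_Yj, sigma_Yj) with the outcome, every estimator here
targets the causal effect theta of the exposure on the outcome under the
instrumental-variable assumptions. The per-SNP Wald ratio is
theta_j = beta_Yj / beta_Xj with first-order standard error
sigma_j = sigma_Yj / |beta_Xj| (a delta-method second-order form is available).

Estimators are scikit-learn style: construct with hyperparameters, call
``fit(X, y, outcome_se=...)`` where ``X`` has the exposure betas in column 0
(and optionally exposure SEs in column 1) and ``y`` holds the outcome betas,
then read trailing-underscore attributes (``effect_``, ``se_``, ``pvalue_``,
...). The module-level functions (:func:`ivw`, :func:`mr_egger`,
:func:`weighted_median`, :func:`wald_ratio`) are thin wrappers that accept
lists of :class:`~summarymr.io.HarmonizedPair`.

Implemented methods
-------------------
* inverse-variance weighted (IVW), fixed effects and multiplicative random
  effects (SE inflated by max(1, sqrt(Q/(J-1))));
* MR-Egger weighted regression with a free intercept (directional-pleiotropy
  test on the intercept);
* weighted median of the ratio estimates, with a parametric-bootstrap SE —
  consistent when valid instruments carry at least half the weight.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted

from ._stats import P_FLOOR, Z_975, two_sided_p
from .exceptions import DegenerateInstrumentError, InsufficientSNPsError

__all__ = [
    "MREstimate",
    "EggerResult",
    "IVWEstimator",
    "EggerRegression",
    "WeightedMedianEstimator",
    "wald_ratio",
    "ivw",
    "mr_egger",
    "weighted_median",
    "estimate_to_or",
    "p_from_or_ci",
    "cochran_q_from_arrays",
]


@dataclass
class MREstimate:
    """A method's causal estimate on the beta (log-odds) scale with its
    odds-ratio translation.

    ``ci_low``/``ci_high`` bracket ``or_value`` on the OR scale:
    exp(beta -/+ z * se).
    """

    method: str
    beta: float
    se: float
    pval: float
    nsnp: int
    or_value: float
    ci_low: float
    ci_high: float

    @classmethod
    def from_beta(
        cls, method: str, beta: float, se: float, nsnp: int, alpha: float = 0.05
    ) -> "MREstimate":
        or_value, ci_low, ci_high, pval = estimate_to_or(beta, se, alpha)
        return cls(
            method=method,
            beta=float(beta),
            se=float(se),
            pval=pval,
            nsnp=int(nsnp),
            or_value=or_value,
            ci_low=ci_low,
            ci_high=ci_high,
        )


@dataclass
class EggerResult:
    """MR-Egger slope estimate plus the intercept (pleiotropy) triplet."""

    slope: MREstimate
    intercept: float
    intercept_se: float
    intercept_p: float

    @property
    def pleiotropy_detected(self) -> bool:
        """Directional-pleiotropy flag: intercept p strictly below 0.05."""
        return self.intercept_p < 0.05


# ---------------------------------------------------------------------------
# scalar conversions
# ---------------------------------------------------------------------------

def estimate_to_or(
    beta: float, se: float, alpha: float = 0.05
) -> tuple[float, float, float, float]:
    """(OR, CI low, CI high, two-sided p) for a beta-scale estimate.

    OR = exp(beta); CI = exp(beta -/+ z_{1-alpha/2} * se). With se = 0 the CI
    collapses to the point and p is 0 for nonzero beta, 1 otherwise.
    """
    if se < 0:
        raise ValueError(f"se must be >= 0, got {se}")
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must lie in (0,1), got {alpha}")
    z = Z_975 if alpha == 0.05 else float(stats.norm.ppf(1.0 - alpha / 2.0))
    or_value = float(np.exp(beta))
    ci_low = float(np.exp(beta - z * se))
    ci_high = float(np.exp(beta + z * se))
    return or_value, ci_low, ci_high, two_sided_p(beta, se)


def p_from_or_ci(or_value: float, ci_low: float, ci_high: float) -> float:
    """Recover the two-sided p-value implied by a printed OR with 95% CI.

    Inverts the normal-CI construction: beta = ln OR,
    se = (ln CI_high - ln CI_low) / (2 z_0.975), p = 2(1 - Phi(|beta|/se)).
    Useful for checking the internal consistency of published OR/CI/p triples.
    """
    if not (0.0 < ci_low <= or_value <= ci_high):
        raise ValueError(
            f"need 0 < ci_low <= or <= ci_high, got ({or_value}, {ci_low}, {ci_high})"
        )
    beta = float(np.log(or_value))
    se = float((np.log(ci_high) - np.log(ci_low)) / (2.0 * Z_975))
    return two_sided_p(beta, se)


def wald_ratio(pair, se_order: str = "first") -> tuple[float, float]:
    """Per-SNP causal estimate theta = beta_Y / beta_X and its SE.

    ``se_order='first'`` gives sigma_Y / |beta_X| (exposure beta treated as
    known); ``'second'`` adds the delta-method term for noise in beta_X:
    sqrt(sigma_Y^2/beta_X^2 + beta_Y^2 sigma_X^2 / beta_X^4).
    """
    bx, sx = pair.beta_exposure, pair.se_exposure
    by, sy = pair.beta_outcome, pair.se_outcome
    if bx == 0:
        raise DegenerateInstrumentError(
            f"SNP {pair.snp_id}: exposure beta is 0; Wald ratio undefined"
        )
    theta = by / bx
    if se_order == "first":
        se = sy / abs(bx)
    elif se_order == "second":
        se = float(np.sqrt(sy**2 / bx**2 + by**2 * sx**2 / bx**4))
    else:
        raise ValueError(f"se_order must be 'first' or 'second', got {se_order!r}")
    return float(theta), float(se)


def _ratio_arrays(
    bx: np.ndarray, sx: np.ndarray, by: np.ndarray, sy: np.ndarray, se_order: str
) -> tuple[np.ndarray, np.ndarray]:
    if np.any(bx == 0):
        raise DegenerateInstrumentError("exposure beta is 0 for at least one SNP")
    theta = by / bx
    if se_order == "first":
        sigma = sy / np.abs(bx)
    elif se_order == "second":
        sigma = np.sqrt(sy**2 / bx**2 + by**2 * sx**2 / bx**4)
    else:
        raise ValueError(f"se_order must be 'first' or 'second', got {se_order!r}")
    if np.any(sigma <= 0):
        raise ValueError("ratio SEs must be strictly positive")
    return theta, sigma


def cochran_q_from_arrays(theta: np.ndarray, sigma: np.ndarray) -> float:
    """Cochran's Q of ratio estimates about their fixed-effect IVW mean."""
    w = 1.0 / sigma**2
    pooled = float(np.sum(w * theta) / np.sum(w))
    return float(np.sum(w * (theta - pooled) ** 2))


# ---------------------------------------------------------------------------
# estimator classes
# ---------------------------------------------------------------------------

class _BaseMREstimator(RegressorMixin, BaseEstimator):
    """Shared fit-input handling for summary-data MR estimators."""

    _min_snps = 1

    def _unpack(self, X, y, outcome_se):
        X = check_array(X, ensure_2d=True, dtype=float)
        y = check_array(y, ensure_2d=False, dtype=float).ravel()
        if X.shape[1] not in (1, 2):
            raise ValueError(
                "X must have 1 or 2 columns: exposure betas and optionally "
                f"exposure SEs; got {X.shape[1]}"
            )
        if outcome_se is None:
            raise ValueError("outcome_se (per-SNP outcome standard errors) is required")
        sy = check_array(outcome_se, ensure_2d=False, dtype=float).ravel()
        if len(y) != X.shape[0] or len(sy) != X.shape[0]:
            raise ValueError("X, y and outcome_se must have equal length")
        if np.any(sy <= 0):
            raise ValueError("outcome_se must be strictly positive")
        minimum = self._required_snps()
        if X.shape[0] < minimum:
            raise InsufficientSNPsError(type(self).__name__, minimum, X.shape[0])
        bx = X[:, 0]
        sx = X[:, 1] if X.shape[1] == 2 else np.zeros_like(bx)
        if X.shape[1] == 2 and np.any(sx <= 0):
            raise ValueError("exposure SEs (X column 1) must be strictly positive")
        return bx, sx, y, sy

    def _required_snps(self) -> int:
        return self._min_snps

    def predict(self, X):
        """Predicted outcome betas: effect_ * beta_exposure (+ intercept_ if any)."""
        check_is_fitted(self, "effect_")
        X = check_array(X, ensure_2d=True, dtype=float)
        return getattr(self, "intercept_", 0.0) + self.effect_ * X[:, 0]

    def _finalize(self, method: str, beta: float, se: float, nsnp: int):
        self.effect_ = float(beta)
        self.se_ = float(se)
        self.pvalue_ = two_sided_p(beta, se)
        self.nsnp_ = int(nsnp)
        self.estimate_ = MREstimate.from_beta(method, beta, se, nsnp, self.alpha)


class IVWEstimator(_BaseMREstimator):
    """Inverse-variance weighted meta-analysis of per-SNP Wald ratios.

    theta_hat = sum(w_j theta_j) / sum(w_j) with w_j = 1/sigma_j^2. Under
    ``model='fixed'`` the SE is (sum w_j)^{-1/2}; under ``model='random'``
    (multiplicative random effects) it is inflated by max(1, sqrt(Q/(J-1))),
    so homogeneous data give identical fixed and random results. The
    fixed-effect estimate is algebraically the weighted least-squares slope of
    beta_Y on beta_X through the origin with weights 1/sigma_Yj^2.

    Parameters
    ----------
    model : {'fixed', 'random'}
        Fixed requires >= 1 SNP, random >= 2.
    se_order : {'first', 'second'}
        Wald-ratio SE order; first-order is the conventional default.
    alpha : float
        CI level for the OR translation (0.05 -> 95% CI).

    Attributes
    ----------
    effect_, se_, pvalue_, nsnp_ : fitted causal estimate and metadata.
    q_stat_, q_df_, q_pval_ : Cochran heterogeneity statistic about the
        fixed-effect mean (J >= 2 only).
    estimate_ : MREstimate
        The full record including the OR and 95% CI.
    """

    def __init__(self, model: str = "fixed", se_order: str = "first", alpha: float = 0.05):
        self.model = model
        self.se_order = se_order
        self.alpha = alpha

    def _required_snps(self) -> int:
        return 1 if self.model == "fixed" else 2

    def fit(self, X, y, outcome_se=None):
        if self.model not in ("fixed", "random"):
            raise ValueError(f"model must be 'fixed' or 'random', got {self.model!r}")
        bx, sx, by, sy = self._unpack(X, y, outcome_se)
        theta, sigma = _ratio_arrays(bx, sx, by, sy, self.se_order)
        w = 1.0 / sigma**2
        beta = float(np.sum(w * theta) / np.sum(w))
        se_fixed = float(np.sum(w) ** -0.5)
        nsnp = len(theta)
        if nsnp >= 2:
            self.q_stat_ = float(np.sum(w * (theta - beta) ** 2))
            self.q_df_ = nsnp - 1
            self.q_pval_ = float(stats.chi2.sf(self.q_stat_, self.q_df_))
        else:
            self.q_stat_ = self.q_df_ = self.q_pval_ = None
        if self.model == "random":
            scale = max(1.0, float(np.sqrt(self.q_stat_ / (nsnp - 1))))
            se = se_fixed * scale
        else:
            se = se_fixed
        self._finalize(f"ivw_{self.model}", beta, se, nsnp)
        return self


class EggerRegression(_BaseMREstimator):
    """MR-Egger: weighted regression of outcome betas on exposure betas with a
    free intercept.

    Inputs are first oriented so every exposure beta is non-negative (a joint
    sign flip of each pair, which leaves the Wald ratios unchanged). The slope
    estimates the causal effect under the InSIDE assumption; a nonzero
    intercept indicates directional horizontal pleiotropy. Coefficient SEs
    come from the weighted-least-squares covariance scaled by
    max(1, sqrt(RSS_w/(J-2))) — under-dispersion is not rewarded.

    Requires >= 3 SNPs and nonzero spread in the exposure betas.

    Attributes
    ----------
    effect_, se_, pvalue_ : slope estimate (causal effect).
    intercept_, intercept_se_, intercept_pvalue_ : pleiotropy triplet.
    pleiotropy_ : bool, True when intercept_pvalue_ < 0.05.
    """

    _min_snps = 3

    def __init__(self, se_order: str = "first", alpha: float = 0.05):
        self.se_order = se_order
        self.alpha = alpha

    def fit(self, X, y, outcome_se=None):
        bx, sx, by, sy = self._unpack(X, y, outcome_se)
        if np.any(bx == 0):
            raise DegenerateInstrumentError("exposure beta is 0 for at least one SNP")
        flip = np.sign(bx)
        bx, by = bx * flip, by * flip
        if np.ptp(bx) == 0:
            raise ValueError("exposure betas are collinear (zero spread); Egger slope undefined")
        w = 1.0 / sy**2
        design = np.column_stack([np.ones_like(bx), bx])
        sw = np.sqrt(w)
        coef, *_ = np.linalg.lstsq(design * sw[:, None], by * sw, rcond=None)
        resid = by - design @ coef
        rss_w = float(np.sum(w * resid**2))
        nsnp = len(bx)
        scale = max(1.0, float(np.sqrt(rss_w / (nsnp - 2))))
        cov = np.linalg.inv(design.T @ (design * w[:, None]))
        ses = np.sqrt(np.diag(cov)) * scale
        self.intercept_ = float(coef[0])
        self.intercept_se_ = float(ses[0])
        self.intercept_pvalue_ = two_sided_p(coef[0], ses[0])
        self.pleiotropy_ = self.intercept_pvalue_ < 0.05
        self._finalize("egger", float(coef[1]), float(ses[1]), nsnp)
        return self


def _interp_weighted_median(theta: np.ndarray, w: np.ndarray) -> float:
    order = np.argsort(theta, kind="stable")
    t = theta[order]
    wn = w[order] / np.sum(w)
    s = np.cumsum(wn) - 0.5 * wn
    return float(np.interp(0.5, s, t))


class WeightedMedianEstimator(_BaseMREstimator):
    """Weighted median of the per-SNP Wald ratios.

    Order the ratio estimates theta_(1) <= ... <= theta_(J) with normalized
    inverse-variance weights w'_j, form cumulative midpoint scores
    s_j = (sum_{k<=j} w'_k) - w'_j/2, and linearly interpolate theta against s
    at s = 1/2. The estimate is consistent whenever valid instruments carry at
    least 50% of the total weight, which is what makes it the standard
    robustness companion to IVW.

    The SE is a parametric bootstrap: each replicate redraws
    theta_j* ~ Normal(theta_j, sigma_j^2), recomputes the weighted median with
    the original weights, and the SE is the standard deviation over
    ``n_boot`` replicates (seeded via ``random_state``).
    """

    _min_snps = 3

    def __init__(
        self,
        n_boot: int = 1000,
        random_state: Optional[int] = None,
        se_order: str = "first",
        alpha: float = 0.05,
    ):
        self.n_boot = n_boot
        self.random_state = random_state
        self.se_order = se_order
        self.alpha = alpha

    def fit(self, X, y, outcome_se=None):
        if self.n_boot < 1:
            raise ValueError(f"n_boot must be >= 1, got {self.n_boot}")
        bx, sx, by, sy = self._unpack(X, y, outcome_se)
        theta, sigma = _ratio_arrays(bx, sx, by, sy, self.se_order)
        w = 1.0 / sigma**2
        beta = _interp_weighted_median(theta, w)
        rng = np.random.default_rng(self.random_state)
        draws = rng.normal(theta, sigma, size=(self.n_boot, len(theta)))
        boots = np.array([_interp_weighted_median(d, w) for d in draws])
        se = float(np.std(boots, ddof=1)) if self.n_boot > 1 else 0.0
        self._finalize("weighted_median", beta, se, len(theta))
        return self


# ---------------------------------------------------------------------------
# functional surface over HarmonizedPair lists
# ---------------------------------------------------------------------------

def _fit_on_pairs(est: _BaseMREstimator, pairs: Sequence) -> _BaseMREstimator:
    from .io import pairs_to_arrays  # local import to avoid a cycle

    bx, sx, by, sy = pairs_to_arrays(pairs)
    X = np.column_stack([bx, sx]) if np.all(sx > 0) else bx[:, None]
    return est.fit(X, by, outcome_se=sy)


def ivw(pairs, model: str = "fixed", se_order: str = "first", alpha: float = 0.05) -> MREstimate:
    """IVW causal estimate from a list of harmonized pairs."""
    return _fit_on_pairs(IVWEstimator(model=model, se_order=se_order, alpha=alpha), pairs).estimate_


def mr_egger(pairs, alpha: float = 0.05) -> EggerResult:
    """MR-Egger slope and intercept triplet from harmonized pairs."""
    est = _fit_on_pairs(EggerRegression(alpha=alpha), pairs)
    return EggerResult(
        slope=est.estimate_,
        intercept=est.intercept_,
        intercept_se=est.intercept_se_,
        intercept_p=est.intercept_pvalue_,
    )


def weighted_median(
    pairs, n_boot: int = 1000, seed: Optional[int] = None, alpha: float = 0.05
) -> MREstimate:
    """Weighted-median causal estimate with a seeded bootstrap SE."""
    est = _fit_on_pairs(
        WeightedMedianEstimator(n_boot=n_boot, random_state=seed, alpha=alpha), pairs
    )
    return est.estimate_
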