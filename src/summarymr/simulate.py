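"""Synthetic paired GWAS summary statistics with known ground truth.

The generator follows the standard additive structural model for two-sample
MR with summary data. For SNP j with true exposure effect beta_Xj drawn from
``exposure_effect_dist``:

    observed exposure effect  b_Xj = beta_Xj + Normal(0, exposure_se^2)
    observed outcome effect   b_Yj = theta * beta_Xj + alpha_j
                                      + Normal(0, outcome_se^2)

where theta is the causal effect and alpha_j is a direct (pleiotropic)
SNP-to-outcome effect, zero for valid instruments and drawn from
``pleiotropy_dist`` for the ``invalid_fraction`` of invalid ones
(``balanced_flag`` forces the pleiotropy mean to 0, so the InSIDE condition
holds with balanced pleiotropy; a nonzero mean produces directional
pleiotropy). P-values come from the two-sided normal test z = beta/se,
matching how downstream instrument selection treats them.

Variants are laid out on one synthetic chromosome at 100 kb spacing (1-based
coordinates) so the clumping window rule is exercisable, with effect-allele
frequencies uniform on ``eaf_range`` and a configurable fraction of
palindromic (A/T, G/C) allele pairs. Equal configs and seeds give
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
import yaml

from .exceptions import ValidationError

__all__ = ["SimulationConfig", "GroundTruth", "simulate_summary_stats", "simulate_ld_matrix"]

_NONPALINDROMIC_PAIRS = (("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"))
_PALINDROMIC_PAIRS = (("A", "T"), ("G", "C"))

#: Spacing between consecutive synthetic variants, in base pairs.
POSITION_SPACING_BP = 100_000


@dataclass
class SimulationConfig:
    """Full data-generating specification for one exposure/outcome pair.

    Defaults emulate a UK-Biobank-scale air-pollution exposure instrumented
    by a modest panel of common variants against a large disease GWAS: 16
    instruments (the size of a typical fine-particulate panel), strong
    per-SNP exposure effects (F approximately (0.05/0.005)^2 = 100), no
    invalid instruments, and a causal effect of 0.5 on the log-odds scale.
    """

    n_snps: int = 16
    causal_effect: float = 0.5
    exposure_effect_dist: Tuple[float, float] = (0.05, 0.01)
    exposure_se: float = 0.005
    outcome_se: float = 0.01
    invalid_fraction: float = 0.0
    pleiotropy_dist: Tuple[float, float] = (0.0, 0.01)
    balanced_flag: bool = True
    n_exposure: int = 423_796
    n_outcome: int = 400_000
    eaf_range: Tuple[float, float] = (0.1, 0.9)
    palindromic_fraction: float = 0.1
    ld_blocks: Optional[Sequence[Tuple[int, float]]] = None
    seed: int = 0

    def __post_init__(self):
        if self.n_snps < 1:
            raise ValidationError("n_snps", f"must be >= 1, got {self.n_snps}")
        for name in ("exposure_se", "outcome_se"):
            if getattr(self, name) <= 0:
                raise ValidationError(name, "must be strictly positive")
        for name in ("invalid_fraction", "palindromic_fraction"):
            frac = getattr(self, name)
            if not (0.0 <= frac <= 1.0):
                raise ValidationError(name, f"must lie in [0,1], got {frac}")
        for name in ("exposure_effect_dist", "pleiotropy_dist"):
            dist = tuple(getattr(self, name))
            if len(dist) != 2 or dist[1] < 0:
                raise ValidationError(name, f"must be (mean, sd >= 0), got {dist}")
            object.__setattr__(self, name, dist)
        lo, hi = self.eaf_range
        if not (0.0 < lo < hi < 1.0):
            raise ValidationError("eaf_range", f"must satisfy 0 < lo < hi < 1, got {self.eaf_range}")
        for name in ("n_exposure", "n_outcome"):
            if getattr(self, name) <= 2:
                raise ValidationError(name, "GWAS sample size must exceed 2")
        if self.ld_blocks is not None:
            blocks = [tuple(b) for b in self.ld_blocks]
            if sum(size for size, _ in blocks) != self.n_snps:
                raise ValidationError(
                    "ld_blocks",
                    f"block sizes must sum to n_snps={self.n_snps}, "
                    f"got {sum(s for s, _ in blocks)}",
                )
            for size, r2 in blocks:
                if size < 1:
                    raise ValidationError("ld_blocks", f"block size must be >= 1, got {size}")
                if not (0.0 <= r2 <= 1.0):
                    raise ValidationError("ld_blocks", f"block r^2 must lie in [0,1], got {r2}")
            object.__setattr__(self, "ld_blocks", blocks)

    @property
    def n_invalid(self) -> int:
        """Number of invalid instruments: invalid_fraction * J, rounded."""
        return int(round(self.invalid_fraction * self.n_snps))

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in cls.__dataclass_fields__.values()}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(sorted(unknown)[0], "unknown configuration field")
        return cls(**raw)

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


@dataclass
class GroundTruth:
    """What the generator actually did: the causal effect, which SNPs are
    invalid instruments, and each SNP's direct (pleiotropic) outcome effect
    (zero for every valid instrument)."""

    true_theta: float
    invalid_snp_ids: Set[str]
    per_snp_alpha: Dict[str, float]


def _draw_alleles(rng: np.random.Generator, n_snps: int, palindromic_fraction: float):
    n_pal = int(round(palindromic_fraction * n_snps))
    pal_idx = set(rng.choice(n_snps, size=n_pal, replace=False).tolist()) if n_pal else set()
    effect, other = [], []
    for j in range(n_snps):
        pairs = _PALINDROMIC_PAIRS if j in pal_idx else _NONPALINDROMIC_PAIRS
        ea, oa = pairs[rng.integers(len(pairs))]
        if rng.random() < 0.5:
            ea, oa = oa, ea
        effect.append(ea)
        other.append(oa)
    return effect, other


def _pvals(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    from scipy import stats

    z = np.abs(beta) / se
    return np.maximum(2.0 * stats.norm.sf(z), 1e-300)


def simulate_summary_stats(
    config: SimulationConfig,
) -> Tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate paired exposure/outcome summary tables and the ground truth.

    Both tables use the canonical tab-delimited dialect columns (SNP, chr,
    pos, effect_allele, other_allele, eaf, beta, se, pval, n), share SNP ids,
    positions and alleles, and are byte-identical across runs with the same
    config (the seed lives inside the config).
    """
    rng = np.random.default_rng(config.seed)
    J = config.n_snps
    snp_ids = [f"rs{1000000 + j}" for j in range(J)]
    positions = [1 + j * POSITION_SPACING_BP for j in range(J)]
    effect_allele, other_allele = _draw_alleles(rng, J, config.palindromic_fraction)
    eaf = rng.uniform(config.eaf_range[0], config.eaf_range[1], size=J)

    mean_x, sd_x = config.exposure_effect_dist
    true_beta_x = rng.normal(mean_x, sd_x, size=J)

    invalid_idx = rng.choice(J, size=config.n_invalid, replace=False)
    alpha = np.zeros(J)
    mean_a, sd_a = config.pleiotropy_dist
    if config.balanced_flag:
        mean_a = 0.0
    if config.n_invalid:
        alpha[invalid_idx] = rng.normal(mean_a, sd_a, size=config.n_invalid)

    beta_x_obs = true_beta_x + rng.normal(0.0, config.exposure_se, size=J)
    beta_y_obs = (
        config.causal_effect * true_beta_x
        + alpha
        + rng.normal(0.0, config.outcome_se, size=J)
    )

    se_x = np.full(J, config.exposure_se)
    se_y = np.full(J, config.outcome_se)

    def table(beta, se, n):
        return pd.DataFrame(
            {
                "SNP": snp_ids,
                "chr": ["1"] * J,
                "pos": positions,
                "effect_allele": effect_allele,
                "other_allele": other_allele,
                "eaf": eaf,
                "beta": beta,
                "se": se,
                "pval": _pvals(beta, se),
                "n": n,
            }
        )

    exposure = table(beta_x_obs, se_x, config.n_exposure)
    outcome = table(beta_y_obs, se_y, config.n_outcome)
    truth = GroundTruth(
        true_theta=config.causal_effect,
        invalid_snp_ids={snp_ids[i] for i in invalid_idx},
        per_snp_alpha=dict(zip(snp_ids, alpha.tolist())),
    )
    return exposure, outcome, truth


def simulate_ld_matrix(config: SimulationConfig) -> pd.DataFrame:
    """Block-diagonal r^2 matrix keyed by the generator's SNP ids.

    ``config.ld_blocks`` is a list of (size, within-block r^2) pairs
    partitioning the J SNPs in positional order; absent blocks mean fully
    independent SNPs (identity matrix). The result is symmetric with unit
    diagonal and zeros off-block.
    """
    J = config.n_snps
    snp_ids = [f"rs{1000000 + j}" for j in range(J)]
    mat = np.eye(J)
    blocks = config.ld_blocks or [(1, 0.0)] * J
    if sum(size for size, _ in blocks) != J:
        raise ValidationError("ld_blocks", f"block sizes must sum to n_snps={J}")
    start = 0
    for size, r2 in blocks:
        stop = start + size
        mat[start:stop, start:stop] = r2
        np.fill_diagonal(mat[start:stop, start:stop], 1.0)
        start = stop
    return pd.DataFrame(mat, index=snp_ids, columns=snp_ids)
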