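"""Shared fixtures: small hand-built record sets and simulated studies."""

from __future__ import annotations

import numpy as np
import pytest

from summarymr import HarmonizedPair, SimulationConfig, SummaryRecord, simulate_summary_stats


def make_record(
    snp_id="rs1",
    effect_allele="A",
    other_allele="G",
    beta=0.1,
    se=0.01,
    pval=1e-9,
    chrom="1",
    pos=1000,
    eaf=0.3,
    n=100_000,
) -> SummaryRecord:
    return SummaryRecord(
        snp_id=snp_id,
        effect_allele=effect_allele,
        other_allele=other_allele,
        beta=beta,
        se=se,
        pval=pval,
        chrom=chrom,
        pos=pos,
        eaf=eaf,
        n=n,
    )


def make_pair(
    snp_id="rs1", bx=0.1, sx=0.01, by=0.05, sy=0.02, status="aligned", eaf=0.3
) -> HarmonizedPair:
    return HarmonizedPair(
        snp_id=snp_id,
        beta_exposure=bx,
        se_exposure=sx,
        beta_outcome=by,
        se_outcome=sy,
        eaf=eaf,
        status=status,
    )


def pairs_from_ratios(theta, sigma, bx=1.0):
    """Harmonized pairs whose Wald ratios and first-order SEs are exactly
    (theta_j, sigma_j): beta_X = bx, beta_Y = theta*bx, se_Y = sigma*|bx|."""
    return [
        make_pair(
            snp_id=f"rs{j}",
            bx=bx,
            sx=1e-6,
            by=t * bx,
            sy=s * abs(bx),
        )
        for j, (t, s) in enumerate(zip(theta, sigma))
    ]


def simulate_arrays(
    seed,
    n_snps=50,
    causal_effect=0.5,
    invalid_fraction=0.0,
    pleiotropy_dist=(0.0, 0.01),
    balanced_flag=True,
    palindromic_fraction=0.0,
):
    """(beta_x, se_x, beta_y, se_y, truth) from the synthetic generator."""
    cfg = SimulationConfig(
        n_snps=n_snps,
        causal_effect=causal_effect,
        invalid_fraction=invalid_fraction,
        pleiotropy_dist=pleiotropy_dist,
        balanced_flag=balanced_flag,
        palindromic_fraction=palindromic_fraction,
        seed=seed,
    )
    exposure, outcome, truth = simulate_summary_stats(cfg)
    return (
        exposure["beta"].to_numpy(),
        exposure["se"].to_numpy(),
        outcome["beta"].to_numpy(),
        outcome["se"].to_numpy(),
        truth,
    )


@pytest.fixture
def worked_ivw_pairs():
    """The two-ratio worked example: theta=(1,2), sigma=(0.5,1) -> IVW 1.2."""
    return pairs_from_ratios([1.0, 2.0], [0.5, 1.0])


@pytest.fixture
def simulated_pairs():
    """50 valid instruments at theta=0.5 from the seeded generator, as
    harmonized pairs."""
    bx, sx, by, sy = simulate_arrays(7)[:4]
    return [
        make_pair(snp_id=f"rs{j}", bx=bx[j], sx=sx[j], by=by[j], sy=sy[j])
        for j in range(len(bx))
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
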