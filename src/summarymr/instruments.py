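"""Instrument selection: genome-wide significance filtering, greedy LD
clumping against an explicit LD matrix, and instrument-strength statistics.

Defaults mirror a conventional relaxed two-sample MR instrument screen:
p < 5e-7, clump r^2 < 0.001 within a 10,000 kb window, and an F > 10
weak-instrument gate (warn-only). Clumping here takes an explicit SNP-by-SNP
r^2 matrix (e.g. from :func:`summarymr.simulate.simulate_ld_matrix` or a
user-supplied TSV) rather than a remote reference panel, so results are fully
deterministic; SNP pairs absent from the matrix are treated as unlinked with
a logged warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import pandas as pd

from .exceptions import NoInstrumentsError
from .io import SummaryRecord

logger = logging.getLogger(__name__)

__all__ = [
    "InstrumentSet",
    "select_instruments",
    "ld_clump",
    "f_statistic",
    "snp_r2",
    "build_instrument_set",
    "read_ld_matrix",
    "write_ld_matrix",
]

DEFAULT_P_THRESHOLD = 5e-7
DEFAULT_CLUMP_R2 = 0.001
DEFAULT_CLUMP_WINDOW_KB = 10_000
DEFAULT_MIN_F = 10.0


@dataclass
class InstrumentSet:
    """A selected, LD-independent instrument panel with strength metrics."""

    records: list[SummaryRecord]
    p_threshold: float
    clump_r2: float
    clump_window_kb: int
    per_snp_r2: Dict[str, float] = field(default_factory=dict)
    per_snp_f: Dict[str, float] = field(default_factory=dict)

    @property
    def snp_ids(self) -> list[str]:
        return [r.snp_id for r in self.records]

    @property
    def weak(self) -> list[str]:
        """SNPs whose F-statistic falls below the conventional bound of 10."""
        return [s for s, f in self.per_snp_f.items() if f < DEFAULT_MIN_F]


def select_instruments(
    exposure: Sequence[SummaryRecord], p_threshold: float = DEFAULT_P_THRESHOLD
) -> list[SummaryRecord]:
    """Records with association p strictly below ``p_threshold``, input order
    preserved. Raises :class:`NoInstrumentsError` when nothing survives."""
    if not (0.0 < p_threshold < 1.0):
        raise ValueError(f"p_threshold must lie in (0,1), got {p_threshold}")
    selected = [r for r in exposure if r.pval < p_threshold]
    if not selected:
        raise NoInstrumentsError(p_threshold)
    return selected


def read_ld_matrix(path) -> pd.DataFrame:
    """Square SNP-labelled r^2 matrix from a TSV with header row and index
    column of SNP ids."""
    ld = pd.read_csv(path, sep="\t", index_col=0)
    if list(ld.index) != list(ld.columns):
        raise ValueError("LD matrix row and column labels differ")
    return ld


def write_ld_matrix(ld: pd.DataFrame, path) -> None:
    ld.to_csv(path, sep="\t", float_format="%.17g")


def _pair_r2(ld: Optional[pd.DataFrame], a: str, b: str, warned: set) -> float:
    if ld is None:
        return 0.0
    if a in ld.index and b in ld.columns:
        return float(ld.loc[a, b])
    key = frozenset((a, b))
    if key not in warned:
        warned.add(key)
        logger.warning("LD matrix missing pair (%s, %s); assuming r^2 = 0", a, b)
    return 0.0


def ld_clump(
    records: Sequence[SummaryRecord],
    ld: Optional[pd.DataFrame],
    clump_r2: float = DEFAULT_CLUMP_R2,
    window_kb: int = DEFAULT_CLUMP_WINDOW_KB,
) -> list[SummaryRecord]:
    """Greedy LD clumping.

    Repeatedly take the unclaimed SNP with the lowest p-value as an index SNP
    and remove every unclaimed SNP on the same chromosome within
    ``window_kb`` kilobases whose r^2 with the index is >= ``clump_r2``. Ties
    in p break on (chromosome, position, snp_id) so the result does not depend
    on input order; index SNPs are returned in selection order (most
    significant first).
    """
    for rec in records:
        if rec.pos is None or rec.chrom is None:
            raise ValueError(
                f"SNP {rec.snp_id}: chromosome/position required for clumping"
            )
    warned: set = set()
    pending = sorted(records, key=lambda r: (r.pval, r.chrom, r.pos, r.snp_id))
    result: list[SummaryRecord] = []
    claimed: set[str] = set()
    window_bp = window_kb * 1000
    for index in pending:
        if index.snp_id in claimed:
            continue
        result.append(index)
        claimed.add(index.snp_id)
        for other in pending:
            if other.snp_id in claimed:
                continue
            if other.chrom != index.chrom:
                continue
            if abs(other.pos - index.pos) > window_bp:
                continue
            if _pair_r2(ld, index.snp_id, other.snp_id, warned) >= clump_r2:
                claimed.add(other.snp_id)
    return result


def f_statistic(r2: float, n: int) -> float:
    """Instrument-strength F-statistic, F = R^2 (N - 2) / (1 - R^2)."""
    if not (0.0 <= r2 < 1.0):
        raise ValueError(f"r2 must lie in [0,1), got {r2}")
    if n <= 2:
        raise ValueError(f"sample size must exceed 2, got {n}")
    return r2 * (n - 2) / (1.0 - r2)


def snp_r2(record: SummaryRecord) -> float:
    """Variance in a unit-variance exposure explained by one SNP:
    2 EAF (1 - EAF) beta^2, clipped to [0, 1)."""
    if record.eaf is None:
        raise ValueError(
            f"SNP {record.snp_id}: EAF missing; supply R^2 externally to "
            "compute the F-statistic"
        )
    r2 = 2.0 * record.eaf * (1.0 - record.eaf) * record.beta**2
    return min(max(r2, 0.0), 1.0 - 1e-12)


def build_instrument_set(
    exposure: Sequence[SummaryRecord],
    ld: Optional[pd.DataFrame] = None,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    clump_r2: float = DEFAULT_CLUMP_R2,
    clump_window_kb: int = DEFAULT_CLUMP_WINDOW_KB,
    min_f: float = DEFAULT_MIN_F,
    aggregate_r2: Optional[float] = None,
) -> InstrumentSet:
    """Full instrument screen: p-value selection, LD clumping, F-statistics.

    Per-SNP R^2 from allele frequencies is the default route into the F
    formula; passing ``aggregate_r2`` instead applies one caller-supplied R^2
    to every SNP (both routes are logged). SNPs with F below ``min_f`` trigger
    a warning but are not removed.
    """
    selected = select_instruments(exposure, p_threshold)
    clumped = ld_clump(selected, ld, clump_r2, clump_window_kb)
    per_r2: Dict[str, float] = {}
    per_f: Dict[str, float] = {}
    for rec in clumped:
        if aggregate_r2 is not None:
            r2 = aggregate_r2
        elif rec.eaf is not None:
            r2 = snp_r2(rec)
        else:
            continue
        per_r2[rec.snp_id] = r2
        if rec.n is not None and rec.n > 2:
            per_f[rec.snp_id] = f_statistic(r2, rec.n)
    route = "aggregate" if aggregate_r2 is not None else "per-SNP frequency-based"
    logger.info("instrument strength computed via %s R^2 for %d SNP(s)", route, len(per_f))
    weak = [s for s, f in per_f.items() if f < min_f]
    if weak:
        logger.warning(
            "weak instruments (F < %g): %s", min_f, ", ".join(sorted(weak))
        )
    return InstrumentSet(
        records=clumped,
        p_threshold=p_threshold,
        clump_r2=clump_r2,
        clump_window_kb=clump_window_kb,
        per_snp_r2=per_r2,
        per_snp_f=per_f,
    )
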