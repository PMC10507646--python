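"""Reading, validating and writing GWAS summary statistics, and harmonization.

The on-disk dialect is a single tab-delimited UTF-8 text format with a header
row; missing values are written as ``.`` (a bare empty field is also accepted
on input); numbers use the C locale. Default column names are::

    SNP  chr  pos  effect_allele  other_allele  eaf  beta  se  pval  n

Any other header can be mapped onto these via the ``dialect`` argument of
:func:`read_summary_stats`.

Harmonization aligns exposure and outcome records to a shared effect allele:
identical allele labels pass through, swapped labels flip the outcome beta
sign and complement its frequency, strand relabellings (A<->T, C<->G) are
attempted before a pair is declared incompatible, and palindromic SNPs (A/T or
G/C) are dropped whenever the effect-allele frequency is too close to 0.5 to
resolve strand (or is missing).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, fields as dc_fields
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import FormatError, ValidationError

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Canonical column names of the tab-delimited summary-statistic dialect,
#: keyed by SummaryRecord field name.
DEFAULT_DIALECT = {
    "snp_id": "SNP",
    "chrom": "chr",
    "pos": "pos",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "eaf": "eaf",
    "beta": "beta",
    "se": "se",
    "pval": "pval",
    "n": "n",
}

MANDATORY_FIELDS = ("snp_id", "effect_allele", "other_allele", "beta", "se", "pval")

#: Default half-width of the palindromic ambiguity window: palindromic SNPs
#: with EAF in [0.5 - w, 0.5 + w] (i.e. [0.42, 0.58]) on either side are
#: dropped as strand-ambiguous.
PALINDROME_EAF_WINDOW = 0.08


@dataclass
class SummaryRecord:
    """One SNP's association with one trait.

    Attributes
    ----------
    snp_id : str
        Variant identifier (rsID-style).
    chrom : str or None
        Chromosome label; optional (required only for LD clumping).
    pos : int or None
        1-based base-pair position; optional (required only for clumping).
    effect_allele, other_allele : str
        Single bases in {A, C, G, T}; must differ.
    eaf : float or None
        Effect-allele frequency in (0, 1), or None when unknown.
    beta : float
        Per-effect-allele association estimate.
    se : float
        Standard error of beta; strictly positive.
    pval : float
        Association p-value in (0, 1].
    n : int or None
        GWAS sample size, or None when unknown.
    """

    snp_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    chrom: Optional[str] = None
    pos: Optional[int] = None
    eaf: Optional[float] = None
    n: Optional[int] = None

    def __post_init__(self):
        if not self.snp_id:
            raise ValidationError("snp_id", "must be non-empty")
        for field in ("effect_allele", "other_allele"):
            allele = getattr(self, field)
            if allele not in VALID_BASES:
                raise ValidationError(field, f"must be one of A/C/G/T, got {allele!r}")
        if self.effect_allele == self.other_allele:
            raise ValidationError("other_allele", "must differ from effect_allele")
        if self.eaf is not None and not (0.0 < self.eaf < 1.0):
            raise ValidationError("eaf", f"must lie in (0,1), got {self.eaf!r}")
        if not math.isfinite(self.beta):
            raise ValidationError("beta", f"must be finite, got {self.beta!r}")
        if not (math.isfinite(self.se) and self.se > 0):
            raise ValidationError("se", f"must be > 0, got {self.se!r}")
        if not (0.0 < self.pval <= 1.0):
            raise ValidationError("pval", f"must lie in (0,1], got {self.pval!r}")
        if self.n is not None and self.n <= 0:
            raise ValidationError("n", f"must be > 0, got {self.n!r}")
        if self.pos is not None and self.pos < 1:
            raise ValidationError("pos", f"1-based position must be >= 1, got {self.pos!r}")

    @property
    def is_palindromic(self) -> bool:
        """True for A/T and G/C variants, whose strand is label-ambiguous."""
        return COMPLEMENT[self.effect_allele] == self.other_allele


@dataclass
class HarmonizedPair:
    """Per-SNP exposure/outcome effects aligned to the exposure effect allele.

    ``status`` is one of ``aligned`` (labels matched directly or after a strand
    relabelling), ``flipped`` (outcome alleles were swapped, so the outcome
    beta sign was flipped and its frequency complemented),
    ``dropped_palindromic`` (A/T or G/C with ambiguous frequency) or
    ``dropped_incompatible`` (allele sets irreconcilable by swap/strand flip).
    Only ``aligned`` and ``flipped`` pairs enter estimation.
    """

    snp_id: str
    beta_exposure: float
    se_exposure: float
    beta_outcome: float
    se_outcome: float
    eaf: Optional[float]
    status: str

    RETAINED = ("aligned", "flipped")

    def __post_init__(self):
        if self.status not in (
            "aligned",
            "flipped",
            "dropped_palindromic",
            "dropped_incompatible",
        ):
            raise ValidationError("status", f"unknown status {self.status!r}")
        if self.status in self.RETAINED:
            if self.se_exposure <= 0:
                raise ValidationError("se_exposure", "must be > 0")
            if self.se_outcome <= 0:
                raise ValidationError("se_outcome", "must be > 0")

    @property
    def retained(self) -> bool:
        return self.status in self.RETAINED


def retained(pairs: Iterable[HarmonizedPair]) -> list[HarmonizedPair]:
    """The subset of pairs that survived harmonization."""
    return [p for p in pairs if p.retained]


# ---------------------------------------------------------------------------
# reading / writing
# ---------------------------------------------------------------------------

def _parse_optional(value, cast):
    if value is None:
        return None
    if isinstance(value, float) and math.isnan(value):
        return None
    s = str(value).strip()
    if s in ("", "."):
        return None
    return cast(s)


def read_summary_stats(
    path, dialect: Optional[dict] = None, strict: bool = True
) -> list[SummaryRecord]:
    """Read a tab-delimited summary-statistic file into validated records.

    Parameters
    ----------
    path : path-like
        File to read.
    dialect : dict, optional
        Mapping from SummaryRecord field names to the column headers actually
        present in the file; defaults to :data:`DEFAULT_DIALECT`. Only the
        listed fields are read.
    strict : bool
        When True, any row violating a record invariant raises a
        :class:`ValidationError` naming the row and field. When False the row
        is skipped and a warning with the skip count is logged.

    Returns
    -------
    list of SummaryRecord, in file order.
    """
    colmap = dict(DEFAULT_DIALECT)
    if dialect:
        colmap.update(dialect)
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=["."], keep_default_na=False)
    missing = [colmap[f] for f in MANDATORY_FIELDS if colmap[f] not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s): {', '.join(missing)}")

    records: list[SummaryRecord] = []
    skipped = 0
    for idx, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        raw = dict(zip(df.columns, row))

        def get(field):
            col = colmap[field]
            return raw.get(col) if col in df.columns else None

        try:
            rec = SummaryRecord(
                snp_id=str(get("snp_id")).strip(),
                chrom=_parse_optional(get("chrom"), str),
                pos=_parse_optional(get("pos"), lambda s: int(float(s))),
                effect_allele=str(get("effect_allele")).strip().upper(),
                other_allele=str(get("other_allele")).strip().upper(),
                eaf=_parse_optional(get("eaf"), float),
                beta=_require(get("beta"), "beta", float),
                se=_require(get("se"), "se", float),
                pval=_require(get("pval"), "pval", float),
                n=_parse_optional(get("n"), lambda s: int(float(s))),
            )
        except (ValidationError, ValueError, TypeError) as exc:
            if strict:
                if isinstance(exc, ValidationError):
                    raise ValidationError(exc.field, f"line {idx}: {exc}") from exc
                raise FormatError(f"{path} line {idx}: {exc}") from exc
            skipped += 1
            continue
        records.append(rec)
    if skipped:
        logger.warning("%s: skipped %d invalid row(s)", path, skipped)
    return records


def _require(value, field, cast):
    parsed = _parse_optional(value, cast)
    if parsed is None:
        raise ValidationError(field, "mandatory value missing")
    return parsed


_SCHEMA_COLUMNS = {
    "summary_stats": list(DEFAULT_DIALECT.values()),
    "harmonized": [
        "SNP",
        "beta_exposure",
        "se_exposure",
        "beta_outcome",
        "se_outcome",
        "eaf",
        "status",
    ],
    "estimates": [
        "exposure",
        "outcome",
        "method",
        "nsnp",
        "beta",
        "se",
        "or",
        "ci_low",
        "ci_high",
        "pval",
    ],
    "sensitivity": [
        "exposure",
        "outcome",
        "presso_global_p",
        "egger_intercept_p",
        "cochran_q",
        "df",
        "q_pval",
        "outliers",
    ],
}


def write_table(objects, path, schema: str) -> None:
    """Write records/estimates to a tab-delimited file under a named schema.

    ``schema`` is one of ``summary_stats`` (list of SummaryRecord),
    ``harmonized`` (list of HarmonizedPair), ``estimates`` or ``sensitivity``
    (DataFrames or lists of dicts with the schema's columns). Floats are
    written with 17 significant digits so that read(write(x)) round-trips
    exactly; missing values are written as ``.``.
    """
    if schema not in _SCHEMA_COLUMNS:
        raise ValueError(
            f"unknown schema {schema!r}; expected one of {sorted(_SCHEMA_COLUMNS)}"
        )
    cols = _SCHEMA_COLUMNS[schema]
    if schema == "summary_stats":
        df = records_to_frame(objects)
    elif schema == "harmonized":
        df = pd.DataFrame(
            [
                {
                    "SNP": p.snp_id,
                    "beta_exposure": p.beta_exposure,
                    "se_exposure": p.se_exposure,
                    "beta_outcome": p.beta_outcome,
                    "se_outcome": p.se_outcome,
                    "eaf": p.eaf,
                    "status": p.status,
                }
                for p in objects
            ],
            columns=cols,
        )
    else:
        df = pd.DataFrame(objects, columns=cols) if not isinstance(objects, pd.DataFrame) else objects
        extra = [c for c in df.columns if c not in cols]
        if extra:
            raise ValueError(f"schema {schema!r} does not admit column(s) {extra}")
        df = df.reindex(columns=cols)
    df.to_csv(path, sep="\t", index=False, na_rep=".", float_format="%.17g")


def records_to_frame(records: Sequence[SummaryRecord]) -> pd.DataFrame:
    """Summary records as a DataFrame in the canonical column order."""
    return pd.DataFrame(
        [
            {
                "SNP": r.snp_id,
                "chr": r.chrom,
                "pos": r.pos,
                "effect_allele": r.effect_allele,
                "other_allele": r.other_allele,
                "eaf": r.eaf,
                "beta": r.beta,
                "se": r.se,
                "pval": r.pval,
                "n": r.n,
            }
            for r in records
        ],
        columns=_SCHEMA_COLUMNS["summary_stats"],
    )


def read_harmonized(path) -> list[HarmonizedPair]:
    df = pd.read_csv(
        path, sep="\t", na_values=["."], keep_default_na=False,
        float_precision="round_trip",
    )
    pairs = []
    for row in df.itertuples(index=False):
        eaf = None if (isinstance(row.eaf, str) and row.eaf == "") or pd.isna(row.eaf) else float(row.eaf)
        pairs.append(
            HarmonizedPair(
                snp_id=str(row.SNP),
                beta_exposure=float(row.beta_exposure),
                se_exposure=float(row.se_exposure),
                beta_outcome=float(row.beta_outcome),
                se_outcome=float(row.se_outcome),
                eaf=eaf,
                status=str(row.status),
            )
        )
    return pairs


def read_estimates(path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", na_values=["."], keep_default_na=False,
        float_precision="round_trip",
    )


# ---------------------------------------------------------------------------
# harmonization
# ---------------------------------------------------------------------------

def _check_unique(records: Sequence[SummaryRecord], side: str) -> dict:
    by_id = {}
    for rec in records:
        if rec.snp_id in by_id:
            raise ValidationError("snp_id", f"duplicate {rec.snp_id!r} in {side} records")
        by_id[rec.snp_id] = rec
    return by_id


def _ambiguous(eaf: Optional[float], window: float) -> bool:
    # Missing EAF on a palindromic SNP is always ambiguous.
    return eaf is None or abs(eaf - 0.5) <= window


def harmonize(
    exposure: Sequence[SummaryRecord],
    outcome: Sequence[SummaryRecord],
    palindrome_eaf_window: float = PALINDROME_EAF_WINDOW,
) -> list[HarmonizedPair]:
    """Align outcome effects to the exposure effect allele, SNP by SNP.

    Returns one :class:`HarmonizedPair` per SNP present on both sides, in
    exposure order, with ``status`` recording the action taken. SNPs present
    on only one side are not errors; their count is logged and they simply do
    not appear in the result.

    For palindromic variants (A/T, G/C) the allele labels cannot distinguish
    strands, so the effect-allele frequency decides: if either side's EAF lies
    within ``palindrome_eaf_window`` of 0.5 (or is missing) the SNP is dropped
    as ambiguous; otherwise frequencies on the same side of 0.5 mean the
    strands agree (aligned) and opposite sides mean the outcome is reported on
    the other strand's allele (flipped).
    """
    exp_by_id = _check_unique(exposure, "exposure")
    out_by_id = _check_unique(outcome, "outcome")
    unmatched = (set(exp_by_id) - set(out_by_id)) | (set(out_by_id) - set(exp_by_id))
    if unmatched:
        logger.info("harmonize: %d SNP(s) present on one side only", len(unmatched))

    pairs: list[HarmonizedPair] = []
    for rec in exposure:
        if rec.snp_id not in out_by_id:
            continue
        out = out_by_id[rec.snp_id]
        pairs.append(_harmonize_one(rec, out, palindrome_eaf_window))
    n_dropped = sum(not p.retained for p in pairs)
    if n_dropped:
        logger.info("harmonize: dropped %d of %d shared SNP(s)", n_dropped, len(pairs))
    return pairs


def _harmonize_one(
    exp: SummaryRecord, out: SummaryRecord, window: float
) -> HarmonizedPair:
    ea, oa = exp.effect_allele, exp.other_allele

    def pair(beta_outcome, eaf, status):
        return HarmonizedPair(
            snp_id=exp.snp_id,
            beta_exposure=exp.beta,
            se_exposure=exp.se,
            beta_outcome=beta_outcome,
            se_outcome=out.se,
            eaf=eaf,
            status=status,
        )

    if exp.is_palindromic:
        # Outcome alleles must form the same complementary pair.
        if {out.effect_allele, out.other_allele} != {ea, oa}:
            return pair(out.beta, exp.eaf, "dropped_incompatible")
        if _ambiguous(exp.eaf, window) or _ambiguous(out.eaf, window):
            return pair(out.beta, exp.eaf, "dropped_palindromic")
        # Frequencies resolve the strand: label-identical orientation first.
        out_eaf = out.eaf if out.effect_allele == ea else 1.0 - out.eaf
        out_beta = out.beta if out.effect_allele == ea else -out.beta
        same_side = (exp.eaf - 0.5) * (out_eaf - 0.5) > 0
        if same_side:
            status = "aligned" if out.effect_allele == ea else "flipped"
            return pair(out_beta, exp.eaf, status)
        # Opposite sides: the outcome is on the other strand, which for a
        # palindromic SNP is equivalent to an allele swap.
        status = "flipped" if out.effect_allele == ea else "aligned"
        return pair(-out_beta, exp.eaf, status)

    observed = (out.effect_allele, out.other_allele)
    if observed == (ea, oa):
        return pair(out.beta, exp.eaf, "aligned")
    if observed == (oa, ea):
        return pair(-out.beta, exp.eaf, "flipped")
    # Strand relabelling before giving up.
    cea, coa = COMPLEMENT[ea], COMPLEMENT[oa]
    if observed == (cea, coa):
        return pair(out.beta, exp.eaf, "aligned")
    if observed == (coa, cea):
        return pair(-out.beta, exp.eaf, "flipped")
    return pair(out.beta, exp.eaf, "dropped_incompatible")


def pairs_to_arrays(
    pairs: Sequence[HarmonizedPair],
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """(beta_exposure, se_exposure, beta_outcome, se_outcome) arrays of the
    retained pairs, in input order."""
    kept = retained(pairs)
    bx = np.array([p.beta_exposure for p in kept])
    sx = np.array([p.se_exposure for p in kept])
    by = np.array([p.beta_outcome for p in kept])
    sy = np.array([p.se_outcome for p in kept])
    return bx, sx, by, sy
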