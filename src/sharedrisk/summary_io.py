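"""GWAS summary-statistic records, effect-scale conversions and TSV/gene-list I/O.

The central data model is :class:`VariantAssociation`, one variant's
association with one trait on the log-odds (beta) scale.  Studies that
publish odds ratios with 95% confidence intervals are converted on read:

    beta = ln(OR)
    se   = (ln(CI_high) - ln(CI_low)) / (2 * 1.96)

and the forward conversion is

    Z  = beta / se
    P  = 2 * Phi(-|Z|)
    OR = e^beta,  95% CI = (e^(beta - 1.96 se), e^(beta + 1.96 se)).

p-values are carried both linearly and as log10 so that associations far
below double-precision underflow (p < 1e-300) survive round-trips.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .exceptions import ConfigurationError, EmptyInputError

log = logging.getLogger(__name__)

#: Critical value used throughout for 95% intervals (the conventional 1.96,
#: matching how published tables are produced, not Phi^-1(0.975) to 15 digits).
Z_95 = 1.96

#: Genome-wide significance threshold for instrument selection.
GENOME_WIDE_P = 5.0e-8

_DNA = frozenset("ACGT")


def _is_dna(allele: str) -> bool:
    return bool(allele) and set(allele.upper()) <= _DNA


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EffectScale:
    """An effect reported on every common scale at once.

    ``odds_ratio = e^beta`` exactly; ``log10_p`` is always finite even when
    ``p`` underflows to 0.0.
    """

    beta: float
    se: float
    z: float
    p: float
    log10_p: float
    odds_ratio: float
    ci_low: float
    ci_high: float

    def format_p(self) -> str:
        if self.log10_p < -300.0:
            return "<1e-300"
        return f"{self.p:.2g}"


@dataclass
class VariantAssociation:
    """One variant's association with one trait (beta scale).

    ``pval`` may be 0.0 when the association underflows double precision;
    ``log10_p`` then carries the magnitude.
    """

    variant_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    eaf: float | None = None
    trait: str = ""
    ancestry: str = ""
    log10_p: float | None = None

    def __post_init__(self) -> None:
        self.effect_allele = self.effect_allele.upper()
        self.other_allele = self.other_allele.upper()
        if self.effect_allele == self.other_allele:
            raise ValueError(
                f"{self.variant_id}: effect allele equals other allele "
                f"({self.effect_allele})"
            )
        if not (_is_dna(self.effect_allele) and _is_dna(self.other_allele)):
            raise ValueError(
                f"{self.variant_id}: alleles must be over A/C/G/T, got "
                f"{self.effect_allele}/{self.other_allele}"
            )
        if not self.se > 0:
            raise ValueError(f"{self.variant_id}: se must be positive, got {self.se}")
        if self.pos < 1:
            raise ValueError(f"{self.variant_id}: position must be >= 1, got {self.pos}")
        if self.eaf is not None and not (0.0 <= self.eaf <= 1.0):
            raise ValueError(f"{self.variant_id}: eaf outside [0, 1]: {self.eaf}")
        if not (0.0 <= self.pval <= 1.0):
            raise ValueError(f"{self.variant_id}: p-value outside [0, 1]: {self.pval}")
        if self.log10_p is None:
            self.log10_p = math.log10(self.pval) if self.pval > 0 else -math.inf


@dataclass(frozen=True)
class GeneList:
    """A named, ordered, case-normalized set of gene symbols."""

    name: str
    symbols: tuple[str, ...]

    @staticmethod
    def from_symbols(name: str, symbols: Iterable[str]) -> "GeneList":
        seen: dict[str, None] = {}
        for s in symbols:
            s = s.strip().upper()
            if s:
                seen.setdefault(s, None)
        return GeneList(name=name, symbols=tuple(seen))

    def __len__(self) -> int:
        return len(self.symbols)


# ---------------------------------------------------------------------------
# Effect-scale conversions
# ---------------------------------------------------------------------------


def effect_transform(beta: float, se: float) -> EffectScale:
    """Convert (beta, se) to Z, two-sided normal p, OR and 95% CI.

    The p-value is computed in log space so that |Z| ~ 40 still yields a
    finite ``log10_p``.
    """
    if not se > 0:
        raise ValueError(f"se must be positive, got {se}")
    z = beta / se
    # log p = log 2 + log Phi(-|z|)
    log_p = math.log(2.0) + norm.logsf(abs(z))
    log10_p = log_p / math.log(10.0)
    p = min(1.0, math.exp(log_p)) if log_p > -745 else 0.0
    return EffectScale(
        beta=beta,
        se=se,
        z=z,
        p=p,
        log10_p=log10_p,
        odds_ratio=math.exp(beta),
        ci_low=math.exp(beta - Z_95 * se),
        ci_high=math.exp(beta + Z_95 * se),
    )


def beta_from_or(odds_ratio: float, ci_low: float | None = None,
                 ci_high: float | None = None, pval: float | None = None,
                 ) -> tuple[float, float]:
    """Invert the OR/CI report back to (beta, se).

    With a 95% CI: ``se = (ln(hi) - ln(lo)) / (2 * 1.96)``.  With only OR and
    p (documented fallback): ``se = |ln(OR)| / |Phi^-1(p/2)|``.
    """
    if odds_ratio <= 0:
        raise ValueError(f"odds ratio must be positive, got {odds_ratio}")
    beta = math.log(odds_ratio)
    if ci_low is not None and ci_high is not None:
        if not (0 < ci_low <= ci_high):
            raise ValueError(f"bad CI ({ci_low}, {ci_high})")
        se = (math.log(ci_high) - math.log(ci_low)) / (2.0 * Z_95)
    elif pval is not None:
        if not (0.0 < pval < 1.0):
            raise ValueError(f"cannot recover se from p={pval}")
        z = abs(norm.ppf(pval / 2.0))
        if z == 0 or beta == 0:
            raise ValueError("cannot recover se from a null OR or p = 1")
        se = abs(beta) / z
    else:
        raise ValueError("need either a CI or a p-value to recover se")
    if not se > 0:
        raise ValueError(f"recovered se is not positive ({se})")
    return beta, se


def check_consistency(rec: VariantAssociation, tol: float = 0.05) -> bool:
    """Strict-consistency check between (beta, se) and the reported p.

    Off by default in the readers because published tables round; compares
    log10 p within ``tol`` relative tolerance (plus one digit of slack for
    rounded inputs).
    """
    expected = effect_transform(rec.beta, rec.se).log10_p
    got = rec.log10_p if rec.log10_p is not None else math.log10(rec.pval)
    if math.isinf(expected) or math.isinf(got):
        return math.isinf(expected) and math.isinf(got)
    return abs(expected - got) <= max(0.5, tol * abs(expected))


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

#: Built-in column-name mappings.  Values are source-file column names keyed
#: by canonical field.  ``beta``-scale dialects carry beta/se; ``or``-scale
#: dialects carry odds_ratio (+ ci_low/ci_high and/or pval) and are converted
#: on read.
DIALECTS: dict[str, dict[str, str]] = {
    "plain": {
        "variant_id": "variant_id", "chrom": "chrom", "pos": "pos",
        "effect_allele": "effect_allele", "other_allele": "other_allele",
        "eaf": "eaf", "beta": "beta", "se": "se", "pval": "pval",
        "trait": "trait", "ancestry": "ancestry",
    },
    # EBI/NHGRI GWAS-catalog-style harmonized summary statistics.
    "gwascat": {
        "variant_id": "variant_id", "chrom": "chromosome",
        "pos": "base_pair_location", "effect_allele": "effect_allele",
        "other_allele": "other_allele", "eaf": "effect_allele_frequency",
        "odds_ratio": "odds_ratio", "ci_low": "ci_lower", "ci_high": "ci_upper",
        "pval": "p_value",
    },
}

_MANDATORY = ("variant_id", "chrom", "pos", "effect_allele", "other_allele", "pval")


def read_associations(path, dialect: str | Mapping[str, str] = "plain",
                      strict_consistency: bool = False,
                      ) -> list[VariantAssociation]:
    """Read a tab-delimited association table into beta-scale records.

    ``dialect`` is either the name of a built-in column mapping or a mapping
    {canonical field -> column name}.  OR-scale inputs are converted to the
    beta scale; rows with unparseable alleles, non-positive se or other
    invariant violations are rejected with row-numbered diagnostics.
    """
    mapping = DIALECTS[dialect] if isinstance(dialect, str) else dict(dialect)
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path}: file is empty") from None
    for fld in _MANDATORY:
        if fld not in mapping or mapping[fld] not in df.columns:
            raise ConfigurationError(
                f"{path}: mandatory column for '{fld}' "
                f"({mapping.get(fld, '<unmapped>')}) not in header {list(df.columns)}"
            )
    has_beta = "beta" in mapping and mapping["beta"] in df.columns
    has_or = "odds_ratio" in mapping and mapping["odds_ratio"] in df.columns
    if not (has_beta or has_or):
        raise ConfigurationError(f"{path}: neither a beta nor an odds-ratio column mapped")
    if len(df) == 0:
        raise EmptyInputError(f"{path}: no data rows")

    def col(row, fld, default=None):
        name = mapping.get(fld)
        if name is None or name not in df.columns:
            return default
        v = row[name]
        return default if pd.isna(v) else v

    records: list[VariantAssociation] = []
    for i, row in df.iterrows():
        rownum = i + 2  # 1-based, after the header line
        try:
            pval = float(col(row, "pval"))
            if has_beta:
                beta = float(col(row, "beta"))
                se_raw = col(row, "se")
                if se_raw is None:
                    raise ValueError("missing se")
                se = float(se_raw)
            else:
                or_ = float(col(row, "odds_ratio"))
                lo = col(row, "ci_low")
                hi = col(row, "ci_high")
                if lo is not None and hi is not None:
                    beta, se = beta_from_or(or_, float(lo), float(hi))
                else:
                    beta, se = beta_from_or(or_, pval=pval)
            eaf = col(row, "eaf")
            rec = VariantAssociation(
                variant_id=str(col(row, "variant_id")),
                chrom=str(col(row, "chrom")),
                pos=int(float(col(row, "pos"))),
                effect_allele=str(col(row, "effect_allele")),
                other_allele=str(col(row, "other_allele")),
                eaf=float(eaf) if eaf is not None else None,
                beta=beta, se=se, pval=pval,
                trait=str(col(row, "trait", "")),
                ancestry=str(col(row, "ancestry", "")),
            )
            if strict_consistency and not check_consistency(rec):
                raise ValueError("beta/se inconsistent with reported p-value")
        except (TypeError, ValueError) as exc:
            log.warning("%s row %d rejected: %s", path, rownum, exc)
            continue
        records.append(rec)
    return records


def write_associations(records: Sequence[VariantAssociation], path,
                       provenance: str = "sharedrisk") -> None:
    """Write records as a plain-dialect TSV with a commented provenance line."""
    df = pd.DataFrame(
        {
            "variant_id": [r.variant_id for r in records],
            "chrom": [r.chrom for r in records],
            "pos": [r.pos for r in records],
            "effect_allele": [r.effect_allele for r in records],
            "other_allele": [r.other_allele for r in records],
            "eaf": [r.eaf for r in records],
            "beta": [r.beta for r in records],
            "se": [r.se for r in records],
            "pval": [r.pval for r in records],
            "trait": [r.trait for r in records],
            "ancestry": [r.ancestry for r in records],
        }
    )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# {provenance}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_gene_list(path, name: str | None = None) -> GeneList:
    """Read a one-symbol-per-line gene list (``#`` comments ignored)."""
    symbols = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                symbols.append(line)
    return GeneList.from_symbols(name or str(path), symbols)


def write_gene_list(genes: GeneList, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# {genes.name}\n")
        for s in genes.symbols:
            fh.write(s + "\n")


# ---------------------------------------------------------------------------
# Instrument selection
# ---------------------------------------------------------------------------


def filter_genome_wide(records: Sequence[VariantAssociation],
                       threshold: float = GENOME_WIDE_P,
                       ) -> list[VariantAssociation]:
    """Keep records with p strictly below the genome-wide threshold.

    The comparison is on log10 p so that underflowed p-values (stored as 0.0
    with a finite log10_p) are retained; input order is preserved.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    log_thr = math.log10(threshold)
    return [r for r in records
            if (r.log10_p if r.log10_p is not None else math.log10(r.pval)) < log_thr]


def apply_exclusion_list(records: Sequence[VariantAssociation],
                         excluded_ids: Iterable[str],
                         reason: str = "excluded by user list",
                         ) -> list[VariantAssociation]:
    """Drop records whose variant_id appears in the exclusion list.

    A quality-control mechanism for instruments that fail external review
    (e.g. unreplicated association signals); each removal is logged with the
    supplied reason, and ids absent from the records produce a warning.
    """
    excluded = set(excluded_ids)
    present = {r.variant_id for r in records}
    for missing in sorted(excluded - present):
        log.warning("exclusion id %s not present in records; no-op", missing)
    kept = []
    for r in records:
        if r.variant_id in excluded:
            log.info("removed %s: %s", r.variant_id, reason)
        else:
            kept.append(r)
    return kept


def read_exclusion_list(path) -> set[str]:
    """One variant id per line; ``#`` comments ignored."""
    ids = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                ids.add(line.split()[0])
    return ids
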