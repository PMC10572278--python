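"""Allele harmonization of two-sample summary statistics and LD clumping.

Two-sample Mendelian randomization needs the exposure and outcome effects of
every instrument expressed relative to the same effect allele on the same
strand.  For each shared variant we compare allele pairs and:

* keep the outcome as-is when alleles match;
* negate the outcome beta (and reflect its allele frequency) when the
  effect/other labels are swapped;
* apply an A<->T / C<->G strand complement first when the pairs only match
  after complementation, then the above;
* treat palindromic variants (A/T or C/G, their own complements) per policy:
  drop them outright (default), or infer orientation from allele frequency —
  retained only when both frequencies are on the same side of the 0.3/0.7
  minor-allele cutoff;
* drop irreconcilable pairs with an explicit reason.

Harmonization never changes effect magnitudes or standard errors — only
signs and allele labels — and applying it twice is the identity.

LD clumping prunes correlated instruments greedily: the variant with the
smallest exposure p-value becomes an index, removing every other variant
within the window whose r^2 with it reaches the threshold, and so on.
r^2 comes from a user-supplied offline matrix or long-format table; pairs
absent from the table are treated as independent (r^2 = 0) with a warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import pandas as pd

from .exceptions import ConfigurationError, EmptyInputError
from .loci import _chrom_sort_key, normalize_chrom
from .summary_io import VariantAssociation, effect_transform

log = logging.getLogger(__name__)

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Minor-allele-frequency cutoff below which a palindromic variant's
#: orientation can be inferred from frequency.
PALINDROME_MAF_CUTOFF = 0.3


def classify_palindromic(effect_allele: str, other_allele: str) -> bool:
    """True iff the unordered allele pair is {A,T} or {C,G}.

    Multi-base alleles cannot be palindromic SNPs; they return False with a
    warning.
    """
    a, b = effect_allele.upper(), other_allele.upper()
    if len(a) != 1 or len(b) != 1:
        log.warning("multi-base alleles %s/%s cannot be palindromic", a, b)
        return False
    return {a, b} in ({"A", "T"}, {"C", "G"})


def _complement(allele: str) -> str | None:
    try:
        return "".join(COMPLEMENT[c] for c in allele)
    except KeyError:
        return None


@dataclass
class HarmonizationFlags:
    swapped: bool = False
    strand_flipped: bool = False
    palindromic: bool = False
    inferred_by_maf: bool = False
    dropped_reason: str | None = None


@dataclass
class HarmonizedInstrument:
    """Exposure (gamma) and outcome (Gamma) effects aligned to one allele."""

    variant_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    gamma: float
    se_gamma: float
    Gamma: float
    se_Gamma: float
    eaf_exposure: float | None = None
    eaf_outcome: float | None = None
    pval_exposure: float | None = None
    flags: HarmonizationFlags = field(default_factory=HarmonizationFlags)

    @property
    def retained(self) -> bool:
        return self.flags.dropped_reason is None


def align_pair(exposure: VariantAssociation, outcome: VariantAssociation,
               policy: str = "drop",
               maf_cutoff: float = PALINDROME_MAF_CUTOFF,
               ) -> HarmonizedInstrument:
    """Align one outcome record to the exposure's effect allele.

    ``policy`` is "drop" (exclude palindromic variants) or "infer" (keep a
    palindromic variant only when both allele frequencies fall on the same
    side of the MAF cutoff, flagging it inferred_by_maf).
    """
    if exposure.variant_id != outcome.variant_id:
        raise ValueError(
            f"variant id mismatch: {exposure.variant_id} vs {outcome.variant_id}"
        )
    if policy not in ("drop", "infer"):
        raise ConfigurationError(f"unknown palindrome policy {policy!r}")

    inst = HarmonizedInstrument(
        variant_id=exposure.variant_id, chrom=exposure.chrom, pos=exposure.pos,
        effect_allele=exposure.effect_allele, other_allele=exposure.other_allele,
        gamma=exposure.beta, se_gamma=exposure.se,
        Gamma=outcome.beta, se_Gamma=outcome.se,
        eaf_exposure=exposure.eaf, eaf_outcome=outcome.eaf,
        pval_exposure=exposure.pval,
    )
    ea, oa = exposure.effect_allele, exposure.other_allele
    oea, ooa = outcome.effect_allele, outcome.other_allele

    def drop(reason: str) -> HarmonizedInstrument:
        inst.flags.dropped_reason = reason
        return inst

    def swap() -> None:
        inst.Gamma = -inst.Gamma
        if inst.eaf_outcome is not None:
            inst.eaf_outcome = 1.0 - inst.eaf_outcome
        inst.flags.swapped = True

    if classify_palindromic(ea, oa):
        inst.flags.palindromic = True
        if {oea, ooa} != {ea, oa}:
            return drop("incompatible_alleles")
        if policy == "drop":
            return drop("palindromic")
        # infer-by-MAF: allele labels cannot distinguish strands, so the
        # frequencies must both be clearly on one side of the cutoff.
        fe, fo = inst.eaf_exposure, inst.eaf_outcome
        if fe is None or fo is None:
            return drop("palindromic_missing_eaf")
        # frequency of the *exposure effect allele* in the outcome study,
        # under the labelling the outcome file used
        fo_aligned = fo if oea == ea else 1.0 - fo
        lo, hi = maf_cutoff, 1.0 - maf_cutoff
        if (fe < lo and fo_aligned < lo) or (fe > hi and fo_aligned > hi):
            if oea != ea:
                swap()
            inst.flags.inferred_by_maf = True
            return inst
        if (fe < lo and fo_aligned > hi) or (fe > hi and fo_aligned < lo):
            return drop("palindromic_discordant_maf")
        return drop("palindromic_intermediate_maf")

    # non-palindromic
    if (oea, ooa) == (ea, oa):
        return inst
    if (oea, ooa) == (oa, ea):
        swap()
        return inst
    # indels / multi-base alleles are never strand-complemented
    if len(ea) > 1 or len(oa) > 1 or len(oea) > 1 or len(ooa) > 1:
        return drop("incompatible_alleles")
    cea, coa = _complement(oea), _complement(ooa)
    if (cea, coa) == (ea, oa):
        inst.flags.strand_flipped = True
        return inst
    if (cea, coa) == (oa, ea):
        inst.flags.strand_flipped = True
        swap()
        return inst
    return drop("incompatible_alleles")


@dataclass
class HarmonizationReport:
    n_exposure: int
    n_outcome: int
    n_matched: int
    n_kept: int
    n_swapped: int
    n_strand_flipped: int
    n_palindromic: int
    n_inferred_by_maf: int
    dropped: dict[str, int]

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def harmonize_dataset(exposure: Sequence[VariantAssociation],
                      outcome: Sequence[VariantAssociation],
                      policy: str = "drop",
                      maf_cutoff: float = PALINDROME_MAF_CUTOFF,
                      ) -> tuple[list[HarmonizedInstrument], HarmonizationReport]:
    """Inner-join exposure and outcome on variant_id and align every pair.

    Returns all instruments (retained and dropped, each dropped one carrying
    its reason) in deterministic (chrom, pos, id) order, plus a count report.
    Raises :class:`EmptyInputError` when no retained instruments remain.
    """
    out_by_id: dict[str, VariantAssociation] = {}
    for rec in outcome:
        if rec.variant_id in out_by_id:
            log.warning("duplicate outcome record for %s; keeping the first",
                        rec.variant_id)
            continue
        out_by_id[rec.variant_id] = rec
    instruments = []
    for exp in exposure:
        if exp.variant_id in out_by_id:
            instruments.append(align_pair(exp, out_by_id[exp.variant_id],
                                          policy=policy, maf_cutoff=maf_cutoff))
    instruments.sort(key=lambda i: (_chrom_sort_key(i.chrom), i.pos, i.variant_id))
    dropped: dict[str, int] = {}
    for i in instruments:
        if not i.retained:
            dropped[i.flags.dropped_reason] = dropped.get(i.flags.dropped_reason, 0) + 1
    report = HarmonizationReport(
        n_exposure=len(exposure), n_outcome=len(outcome),
        n_matched=len(instruments),
        n_kept=sum(i.retained for i in instruments),
        n_swapped=sum(i.flags.swapped for i in instruments),
        n_strand_flipped=sum(i.flags.strand_flipped for i in instruments),
        n_palindromic=sum(i.flags.palindromic for i in instruments),
        n_inferred_by_maf=sum(i.flags.inferred_by_maf for i in instruments),
        dropped=dropped,
    )
    if report.n_matched == 0:
        raise EmptyInputError("no shared variant ids between exposure and outcome")
    if report.n_kept == 0:
        raise EmptyInputError(
            f"all {report.n_matched} matched variants were dropped: {dropped}"
        )
    return instruments, report


# ---------------------------------------------------------------------------
# LD clumping
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ClumpConfig:
    """Greedy p-value clumping parameters (two-sample MR convention)."""

    r2_threshold: float = 0.001
    window: int = 10_000_000
    rank: str = "pval"

    def __post_init__(self) -> None:
        if not (0.0 < self.r2_threshold <= 1.0):
            raise ConfigurationError(f"r2_threshold outside (0, 1]: {self.r2_threshold}")
        if self.window <= 0:
            raise ConfigurationError(f"window must be positive: {self.window}")


LDSource = Callable[[str, str], float]


def ld_lookup_from_table(source) -> LDSource:
    """Build an r^2 lookup from a square-matrix or long-format pairwise table.

    Accepts a pandas DataFrame, a mapping {(id1, id2): r2}, or a path to a
    TSV in either layout (square: header and first column are variant ids;
    long: columns id1, id2, r2).  Missing pairs return 0.0.
    """
    if callable(source):
        return source
    pairs: dict[tuple[str, str], float] = {}
    if isinstance(source, Mapping):
        for (a, b), r2 in source.items():
            pairs[(a, b)] = pairs[(b, a)] = float(r2)
    else:
        if not isinstance(source, pd.DataFrame):
            try:
                source = pd.read_csv(source, sep="\t", comment="#", index_col=0)
            except Exception as exc:
                raise ConfigurationError(f"cannot read LD table: {exc}") from exc
            if not (source.shape[1] == source.shape[0]
                    and set(source.columns) == set(source.index)):
                source = source.reset_index()
        if set(source.columns) >= {"id1", "id2", "r2"}:
            for a, b, r2 in source[["id1", "id2", "r2"]].itertuples(index=False):
                pairs[(str(a), str(b))] = pairs[(str(b), str(a))] = float(r2)
        elif source.shape[0] == source.shape[1] and set(source.columns) == set(source.index):
            for a in source.index:
                for b in source.columns:
                    pairs[(str(a), str(b))] = float(source.at[a, b])
        else:
            raise ConfigurationError(
                "LD table is neither square (ids on both axes) nor long "
                "(columns id1, id2, r2)"
            )
    bad = [v for v in pairs.values() if not (0.0 <= v <= 1.0)]
    if bad:
        raise ConfigurationError(f"r2 values outside [0, 1]: {bad[:3]}")

    def lookup(a: str, b: str) -> float:
        return pairs.get((a, b), 0.0)

    return lookup


def ld_clump(instruments: Sequence[HarmonizedInstrument],
             ld: LDSource | Mapping | pd.DataFrame | str | None = None,
             config: ClumpConfig = ClumpConfig(),
             ) -> list[HarmonizedInstrument]:
    """Greedy LD clumping of retained instruments by exposure p-value.

    Repeatedly takes the unclumped variant with the smallest exposure
    p-value as an index (ties broken by chrom, pos, id) and removes every
    other unclumped same-chromosome variant within the window whose r^2
    with the index reaches the threshold.  With no LD source all pairs are
    treated as independent and the input passes through (a warning is
    emitted once per missing pair's lookup source, not per pair).
    """
    if ld is None:
        log.warning("no LD source supplied; all pairs treated as r2 = 0")
        lookup: LDSource = lambda a, b: 0.0
    else:
        lookup = ld_lookup_from_table(ld)
    candidates = [i for i in instruments if i.retained]
    order = sorted(
        candidates,
        key=lambda i: (i.pval_exposure if i.pval_exposure is not None
                       else effect_transform(i.gamma, i.se_gamma).p,
                       _chrom_sort_key(i.chrom), i.pos, i.variant_id),
    )
    removed: set[str] = set()
    kept: list[HarmonizedInstrument] = []
    for index in order:
        if index.variant_id in removed:
            continue
        kept.append(index)
        for other in order:
            if other.variant_id in removed or other.variant_id == index.variant_id:
                continue
            if normalize_chrom(other.chrom) != normalize_chrom(index.chrom):
                continue
            if abs(other.pos - index.pos) > config.window:
                continue
            if lookup(index.variant_id, other.variant_id) >= config.r2_threshold:
                removed.add(other.variant_id)
    kept.sort(key=lambda i: (_chrom_sort_key(i.chrom), i.pos, i.variant_id))
    return kept
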