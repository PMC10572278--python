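"""Synthetic two-sample GWAS summary statistics with known causal structure.

The generator follows the instrumental-variable causal graph: each variant
j has a true exposure effect gamma_j ~ Normal(0, gamma_sd^2); the true
outcome effect is theta * gamma_j plus an optional pleiotropic direct
effect alpha_j ~ Normal(mu_alpha, sd_alpha^2) on a configurable fraction
of instruments, an optional correlation between alpha_j and instrument
strength (an InSIDE violation), and an optional shared-confounder path.
Observed effects add independent Gaussian sampling noise in each sample
(the two-sample design), and instruments can be required to pass the
genome-wide significance threshold in the exposure sample via rejection
sampling — which reproduces winner's-curse selection; recovery studies of
the estimators themselves can disable selection by setting the threshold
to None.

By default the effect allele is labelled as the exposure-increasing allele
(as GWAS risk-variant tables report), so directional pleiotropy is defined
relative to that orientation and survives the MR-Egger sign convention.

Allele structure is generated to exercise harmonization: a configurable
fraction of variants is palindromic (A/T or C/G, frequencies near 0.5),
and stated fractions of outcome rows are emitted strand-complemented
and/or with swapped allele labels.  A truth record stores every latent
quantity so downstream expectations can be computed without re-simulation.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .exceptions import SimulationError
from .harmonize import COMPLEMENT, HarmonizedInstrument
from .summary_io import GENOME_WIDE_P, GeneList, VariantAssociation, effect_transform

_NONPALINDROMIC_PAIRS = (("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                         ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T"))
_PALINDROMIC_PAIRS = (("A", "T"), ("T", "A"), ("C", "G"), ("G", "C"))


@dataclass
class SimulationConfig:
    """Study conditions for a simulated two-sample MR dataset.

    Defaults emulate a well-powered autoimmune-disease GWAS pair: exposure
    log-odds effects with sd 0.15 (odds ratios mostly 1.1-1.6), exposure
    standard errors of 0.03 and outcome standard errors of 0.05.
    """

    n_instruments: int = 30
    theta: float = 0.5                     # true causal effect beta_XY
    gamma_sd: float = 0.15                 # sd of true exposure effects
    se_gamma: float | tuple[float, float] = 0.03
    se_Gamma: float | tuple[float, float] = 0.05
    mu_alpha: float = 0.0                  # mean pleiotropic direct effect
    sd_alpha: float = 0.0
    pleiotropic_fraction: float = 1.0      # fraction of instruments with alpha
    inside_corr: float = 0.0               # corr(alpha, gamma); 0 = InSIDE holds
    confounder_effect: float = 0.0
    palindromic_fraction: float = 0.0
    strand_flip_fraction: float = 0.0
    allele_swap_fraction: float = 0.0
    palindrome_eaf_spread: float = 0.35    # palindromic eaf ~ U(0.5 +/- spread)
    selection_threshold: float | None = GENOME_WIDE_P
    orient_exposure_increasing: bool = True
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("pleiotropic_fraction", "palindromic_fraction",
                     "strand_flip_fraction", "allele_swap_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} outside [0, 1]: {v}")
        if self.gamma_sd < 0 or self.sd_alpha < 0:
            raise ValueError("sd parameters must be >= 0")
        if not (-1.0 <= self.inside_corr <= 1.0):
            raise ValueError(f"inside_corr outside [-1, 1]: {self.inside_corr}")


def _per_instrument(value, n, rng):
    if isinstance(value, (tuple, list)):
        lo, hi = value
        return rng.uniform(lo, hi, size=n)
    return np.full(n, float(value))


_MAX_REJECTION = 10_000


def draw_effects(config: SimulationConfig, rng: np.random.Generator) -> dict:
    """Draw all latent and observed effect sizes (the numeric core).

    Returns a dict of numpy arrays: gamma_true, alpha, Gamma_true,
    gamma_hat, Gamma_hat, se_gamma, se_Gamma, is_pleiotropic.
    """
    J = config.n_instruments
    sg = _per_instrument(config.se_gamma, J, rng)
    sG = _per_instrument(config.se_Gamma, J, rng)

    n_pleio = int(round(config.pleiotropic_fraction * J))
    pleio = np.zeros(J, dtype=bool)
    pleio[rng.choice(J, size=n_pleio, replace=False)] = True

    thr_z = None
    if config.selection_threshold is not None:
        thr_z = float(-norm.ppf(config.selection_threshold / 2.0))

    gamma_true = np.empty(J)
    gamma_hat = np.empty(J)
    for j in range(J):
        for attempt in range(_MAX_REJECTION):
            gt = rng.normal(0.0, config.gamma_sd)
            if config.orient_exposure_increasing:
                gt = abs(gt)
            gh = gt + rng.normal(0.0, sg[j])
            if thr_z is None or abs(gh) / sg[j] > thr_z:
                gamma_true[j], gamma_hat[j] = gt, gh
                break
        else:
            raise SimulationError(
                f"instrument {j}: selection threshold "
                f"{config.selection_threshold} unreachable at se_gamma={sg[j]} "
                f"after {_MAX_REJECTION} attempts"
            )

    # pleiotropic direct effects, optionally correlated with strength
    z = rng.normal(size=J)
    if config.inside_corr != 0.0 and config.gamma_sd > 0:
        g_std = (gamma_true - gamma_true.mean()) / max(gamma_true.std(), 1e-12)
        mix = config.inside_corr * g_std + math.sqrt(1 - config.inside_corr**2) * z
    else:
        mix = z
    alpha = np.where(pleio, config.mu_alpha + config.sd_alpha * mix, 0.0)

    # shared-confounder path: the variant influences a confounder C that in
    # turn affects the outcome, bypassing the exposure (independence violation)
    conf = config.confounder_effect * rng.normal(size=J)
    Gamma_true = config.theta * gamma_true + alpha + conf
    Gamma_hat = Gamma_true + rng.normal(0.0, sG)
    return {
        "gamma_true": gamma_true, "alpha": alpha, "Gamma_true": Gamma_true,
        "gamma_hat": gamma_hat, "Gamma_hat": Gamma_hat,
        "se_gamma": sg, "se_Gamma": sG, "is_pleiotropic": pleio,
    }


def simulate_instruments(config: SimulationConfig,
                         rng: np.random.Generator | None = None,
                         ) -> tuple[list[HarmonizedInstrument], dict]:
    """Already-harmonized instruments straight from the generative model.

    The fast path for estimator recovery studies: no allele bookkeeping,
    no file round-trip.  Returns (instruments, truth record).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    eff = draw_effects(config, rng)
    pvals = 2.0 * norm.sf(np.abs(eff["gamma_hat"]) / eff["se_gamma"])
    instruments = []
    for j in range(config.n_instruments):
        chrom = str(j % 22 + 1)
        pos = 10_000_000 + (j // 22) * 5_000_000 + (j % 22)
        instruments.append(HarmonizedInstrument(
            variant_id=f"rsSIM{j:04d}", chrom=chrom, pos=pos,
            effect_allele="A", other_allele="G",
            gamma=float(eff["gamma_hat"][j]), se_gamma=float(eff["se_gamma"][j]),
            Gamma=float(eff["Gamma_hat"][j]), se_Gamma=float(eff["se_Gamma"][j]),
            pval_exposure=float(pvals[j]),
        ))
    truth = _truth_record(config, eff)
    return instruments, truth


def _truth_record(config: SimulationConfig, eff: dict, **extra) -> dict:
    truth = {"config": asdict(config)}
    truth.update({k: np.asarray(v).tolist() for k, v in eff.items()})
    truth.update(extra)
    return truth


def simulate_two_sample(config: SimulationConfig,
                        ) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Simulate exposure and outcome summary-statistic tables plus truth.

    The tables use the plain TSV dialect of the readers; outcome rows are
    emitted with strand complements and/or swapped allele labels at the
    configured fractions (the encodings harmonization must undo), and the
    truth record stores every latent quantity, allele assignment and
    encoding flag.  Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    eff = draw_effects(config, rng)
    J = config.n_instruments

    n_pal = int(round(config.palindromic_fraction * J))
    is_pal = np.zeros(J, dtype=bool)
    is_pal[rng.choice(J, size=n_pal, replace=False)] = True
    flipped = rng.random(J) < config.strand_flip_fraction
    swapped = rng.random(J) < config.allele_swap_fraction

    exp_rows, out_rows = [], []
    alleles, eafs = [], []
    for j in range(J):
        if is_pal[j]:
            ea, oa = _PALINDROMIC_PAIRS[rng.integers(len(_PALINDROMIC_PAIRS))]
            eaf = float(np.clip(rng.uniform(0.5 - config.palindrome_eaf_spread,
                                            0.5 + config.palindrome_eaf_spread),
                                0.05, 0.95))
        else:
            ea, oa = _NONPALINDROMIC_PAIRS[rng.integers(len(_NONPALINDROMIC_PAIRS))]
            eaf = float(rng.uniform(0.05, 0.95))
        alleles.append((ea, oa))
        eafs.append(eaf)
        chrom = str(j % 22 + 1)
        pos = 10_000_000 + (j // 22) * 5_000_000 + (j % 22)
        vid = f"rsSIM{j:04d}"
        gh, sgj = float(eff["gamma_hat"][j]), float(eff["se_gamma"][j])
        Gh, sGj = float(eff["Gamma_hat"][j]), float(eff["se_Gamma"][j])
        exp_rows.append((vid, chrom, pos, ea, oa, eaf, gh, sgj,
                         effect_transform(gh, sgj).p, "exposure"))

        o_ea, o_oa, o_beta = ea, oa, Gh
        o_eaf = float(np.clip(eaf + rng.normal(0.0, 0.01), 0.01, 0.99))
        if swapped[j]:
            o_ea, o_oa, o_beta, o_eaf = o_oa, o_ea, -o_beta, 1.0 - o_eaf
        if flipped[j]:
            o_ea = "".join(COMPLEMENT[c] for c in o_ea)
            o_oa = "".join(COMPLEMENT[c] for c in o_oa)
        out_rows.append((vid, chrom, pos, o_ea, o_oa, o_eaf, o_beta, sGj,
                         effect_transform(o_beta, sGj).p, "outcome"))

    cols = ["variant_id", "chrom", "pos", "effect_allele", "other_allele",
            "eaf", "beta", "se", "pval", "trait"]
    exposure = pd.DataFrame(exp_rows, columns=cols)
    outcome = pd.DataFrame(out_rows, columns=cols)
    truth = _truth_record(
        config, eff,
        effect_allele=[a for a, _ in alleles],
        other_allele=[b for _, b in alleles],
        eaf=eafs,
        is_palindromic=is_pal.tolist(),
        outcome_strand_flipped=flipped.tolist(),
        outcome_allele_swapped=swapped.tolist(),
    )
    return exposure, outcome, truth


# ---------------------------------------------------------------------------
# Overlap-list generators
# ---------------------------------------------------------------------------


def simulate_overlap_lists(n_query: int, n_subject: int, N_background: int,
                           k_true: int, seed: int | None = None,
                           ) -> tuple[GeneList, GeneList]:
    """Two gene lists from a synthetic universe sharing exactly k_true symbols."""
    if k_true > min(n_query, n_subject):
        raise ValueError(f"k_true={k_true} exceeds min list size")
    if n_query + n_subject - k_true > N_background:
        raise ValueError("lists cannot fit in the background with that overlap")
    rng = np.random.default_rng(seed)
    need = n_query + n_subject - k_true
    idx = rng.choice(N_background, size=need, replace=False)
    symbols = [f"GENE{i:06d}" for i in idx]
    shared = symbols[:k_true]
    q_only = symbols[k_true:n_query]
    s_only = symbols[n_query:]
    return (GeneList.from_symbols("query", shared + q_only),
            GeneList.from_symbols("subject", shared + s_only))


def simulate_overlap_loci(n_query: int, n_subject: int, k_true: int,
                          seed: int | None = None, window: int = 500_000,
                          ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two lead-variant tables whose windows share exactly k_true overlaps.

    Overlapping pairs place the subject lead within half a window of the
    query lead; all other leads are separated by several window widths so
    no accidental overlap can occur.  Returns (query, subject) tables in
    the plain TSV dialect (one lead variant per locus).
    """
    if k_true > min(n_query, n_subject):
        raise ValueError(f"k_true={k_true} exceeds min list size")
    rng = np.random.default_rng(seed)
    spacing = 4 * window
    rows_q, rows_s = [], []

    def row(i, chrom, pos, tag):
        return (f"rs{tag}{i:04d}", chrom, int(pos), "A", "G", 0.3,
                0.3, 0.03, 1e-12, tag)

    slot = 0
    for i in range(max(n_query, n_subject)):
        chrom = str(slot % 22 + 1)
        base = 1_000_000 + (slot // 22) * spacing
        slot += 1
        if i < k_true:
            offset = int(rng.integers(-window // 2 + 1, window // 2))
            rows_q.append(row(i, chrom, base, "Q"))
            rows_s.append(row(i, chrom, base + offset, "S"))
        else:
            if i < n_query:
                rows_q.append(row(i, chrom, base, "Q"))
            if i < n_subject:
                chrom2 = str(slot % 22 + 1)
                base2 = 1_000_000 + (slot // 22) * spacing
                slot += 1
                rows_s.append(row(i, chrom2, base2, "S"))
    cols = ["variant_id", "chrom", "pos", "effect_allele", "other_allele",
            "eaf", "beta", "se", "pval", "trait"]
    return pd.DataFrame(rows_q, columns=cols), pd.DataFrame(rows_s, columns=cols)
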