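"""Two-sample Mendelian randomization estimators and sensitivity analyses.

Given J harmonized instruments with exposure effects gamma_j (se_gamma_j)
and outcome effects Gamma_j (se_Gamma_j), the per-variant Wald ratio is
beta_j = Gamma_j / gamma_j with first-order standard error
se_j = se_Gamma_j / |gamma_j|.  The combined estimators are:

* IVW — weighted regression of Gamma on gamma through the origin with
  weights 1/se_Gamma^2; algebraically the inverse-variance weighted average
  of the Wald ratios.  The default multiplicative random-effects model
  inflates (never deflates) the fixed-effect standard error by the residual
  scale sqrt(Q / (J - 1)) when instruments are over-dispersed.
* MR-Egger — the same regression with an unconstrained intercept after
  orienting all instruments to gamma_j > 0; the slope is the causal
  estimate under the InSIDE assumption and the intercept estimates the mean
  directional pleiotropic effect.  Inference uses a t distribution with
  J - 2 degrees of freedom.
* Weighted median — the 50% weighted quantile of the ordered Wald ratios,
  consistent whenever more than half of the weight lies on valid
  instruments; its standard error comes from a parametric bootstrap.
* Weighted mode — the argmax of a weighted Gaussian kernel density over the
  Wald ratios with the modified Silverman bandwidth
  h = phi * 0.9 * min(sd, mad/0.6745) * J^(-1/5); consistent when the
  largest group of instruments sharing one ratio is valid.

Cochran's Q (and the Egger analogue Q') quantifies ratio heterogeneity, and
the sensitivity suite produces leave-one-out, single-variant, funnel and
scatter tables ready for plotting.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import chi2
from scipy.stats import t as t_dist

from .exceptions import DegenerateInputError
from .harmonize import HarmonizedInstrument
from .summary_io import effect_transform

log = logging.getLogger(__name__)

METHOD_ORDER = ("Inverse-variance weight", "Weighted median", "Weighted mode",
                "MR Egger")


@dataclass(frozen=True)
class MRResult:
    """One method's causal estimate on the log-odds scale, plus OR/CI."""

    method: str
    n_snps: int
    beta: float
    se: float
    p: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    log10_p: float = math.nan
    model: str | None = None
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_p: float | None = None


@dataclass(frozen=True)
class HeterogeneityResult:
    method: str
    Q: float
    df: int
    p: float


@dataclass(frozen=True)
class WaldRatio:
    variant_id: str
    ratio: float
    se: float
    p: float


def _arrays(instruments: Sequence[HarmonizedInstrument],
            require_gamma: bool = True):
    """Retained instruments as numpy arrays; gamma == 0 dropped with a log."""
    rows = []
    for i in instruments:
        if not i.retained:
            continue
        if require_gamma and i.gamma == 0.0:
            log.warning("instrument %s has gamma = 0; dropped from estimation",
                        i.variant_id)
            continue
        rows.append((i.variant_id, i.gamma, i.se_gamma, i.Gamma, i.se_Gamma))
    ids = [r[0] for r in rows]
    g, sg, G, sG = (np.array([r[j] for r in rows], dtype=float) for j in (1, 2, 3, 4))
    return ids, g, sg, G, sG


def _result(method: str, n: int, beta: float, se: float,
            p_from: str = "normal", df: int | None = None,
            model: str | None = None, **extra) -> MRResult:
    scale = effect_transform(beta, se)
    if p_from == "t":
        p = 2.0 * float(t_dist.sf(abs(beta / se), df))
        log10_p = math.log10(p) if p > 0 else -math.inf
    else:
        p, log10_p = scale.p, scale.log10_p
    return MRResult(method=method, n_snps=n, beta=beta, se=se, p=p,
                    log10_p=log10_p, odds_ratio=scale.odds_ratio,
                    ci_low=scale.ci_low, ci_high=scale.ci_high,
                    model=model, **extra)


# ---------------------------------------------------------------------------
# Per-variant ratios
# ---------------------------------------------------------------------------


def wald_ratios(instruments: Sequence[HarmonizedInstrument]) -> list[WaldRatio]:
    """Per-variant causal estimates beta_j = Gamma_j / gamma_j with
    first-order (delta-method) standard errors se_Gamma_j / |gamma_j|."""
    ids, g, sg, G, sG = _arrays(instruments)
    out = []
    for vid, gj, Gj, sGj in zip(ids, g, G, sG):
        ratio = Gj / gj
        se = sGj / abs(gj)
        out.append(WaldRatio(vid, ratio, se, effect_transform(ratio, se).p))
    return out


def _ratio_arrays(instruments):
    ids, g, sg, G, sG = _arrays(instruments)
    b = G / g
    se = sG / np.abs(g)
    return ids, b, se, g, sg, G, sG


# ---------------------------------------------------------------------------
# IVW
# ---------------------------------------------------------------------------


def mr_ivw(instruments: Sequence[HarmonizedInstrument],
           model: str = "mre") -> MRResult:
    """Inverse-variance weighted estimate (regression through the origin).

    ``model`` is "mre" (multiplicative random effects, default: the
    fixed-effect se is multiplied by max(1, sqrt(Q/(J-1)))) or "fixed".
    """
    if model not in ("mre", "fixed"):
        raise ValueError(f"unknown IVW model {model!r}")
    ids, g, sg, G, sG = _arrays(instruments)
    n = len(ids)
    if n < 2:
        raise DegenerateInputError(
            f"IVW needs >= 2 instruments, got {n}; use the Wald ratio for a "
            "single instrument"
        )
    w = 1.0 / sG**2
    denom = float(np.sum(w * g**2))
    beta = float(np.sum(w * g * G)) / denom
    se_fixed = 1.0 / math.sqrt(denom)
    Q = float(np.sum(w * (G - beta * g) ** 2))
    se = se_fixed
    if model == "mre":
        se = se_fixed * max(1.0, math.sqrt(Q / (n - 1)))
    return _result("Inverse-variance weight", n, beta, se, model=model)


# ---------------------------------------------------------------------------
# MR-Egger
# ---------------------------------------------------------------------------


def mr_egger(instruments: Sequence[HarmonizedInstrument]) -> MRResult:
    """Weighted regression of Gamma on gamma with a pleiotropy intercept.

    Instruments are first oriented so every gamma_j > 0 (the estimate is
    not invariant to allele-coding sign).  Standard errors are inflated by
    max(1, residual scale); both slope and intercept are tested against a
    t distribution with J - 2 degrees of freedom.
    """
    ids, g, sg, G, sG = _arrays(instruments)
    n = len(ids)
    if n < 3:
        raise DegenerateInputError(f"MR-Egger needs >= 3 instruments, got {n}")
    sign = np.sign(g)
    g, G = g * sign, G * sign
    if np.ptp(g) == 0.0:
        raise DegenerateInputError(
            "MR-Egger needs variation in |gamma|; all exposure effects are equal"
        )
    w = 1.0 / sG**2
    X = np.column_stack([np.ones(n), g])
    XtW = X.T * w
    cov_unscaled = np.linalg.inv(XtW @ X)
    coef = cov_unscaled @ (XtW @ G)
    resid = G - X @ coef
    rss_w = float(np.sum(w * resid**2))
    scale = max(1.0, math.sqrt(rss_w / (n - 2)))
    se_int, se_slope = np.sqrt(np.diag(cov_unscaled)) * scale
    intercept, slope = coef
    intercept_p = 2.0 * float(t_dist.sf(abs(intercept / se_int), n - 2))
    return _result("MR Egger", n, float(slope), float(se_slope),
                   p_from="t", df=n - 2,
                   intercept=float(intercept), intercept_se=float(se_int),
                   intercept_p=intercept_p)


# ---------------------------------------------------------------------------
# Weighted median
# ---------------------------------------------------------------------------


def weighted_median_estimate(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Interpolated 50% weighted quantile of the ratios.

    Ratios are ordered; with normalized weights w_(j), the standardized
    cumulative positions are p_j = (S_j - w_(j)/2) / S_J and the estimate is
    the linear interpolation of the ordered ratios at p = 0.5.
    """
    order = np.argsort(ratios)
    b = np.asarray(ratios, dtype=float)[order]
    w = np.asarray(weights, dtype=float)[order]
    S = np.cumsum(w)
    p = (S - w / 2.0) / S[-1]
    return float(np.interp(0.5, p, b))


def _parametric_bootstrap(estimate_fn, g, sg, G, sG, n_boot, rng):
    est = np.empty(n_boot)
    for i in range(n_boot):
        gb = rng.normal(g, sg)
        Gb = rng.normal(G, sG)
        est[i] = estimate_fn(gb, Gb)
    return float(np.std(est, ddof=1))


def _median_from_effects(g, G, sG):
    b = G / g
    w = g**2 / sG**2  # 1 / first-order ratio variance
    return weighted_median_estimate(b, w)


def weighted_median(instruments: Sequence[HarmonizedInstrument],
                    n_boot: int = 1000, seed: int | None = None) -> MRResult:
    """Weighted-median causal estimate with parametric-bootstrap se.

    Valid when instruments carrying more than half of the total weight are
    free of pleiotropy.  ``seed`` makes the bootstrap bit-reproducible; an
    unseeded call draws a seed from OS entropy and logs it.
    """
    ids, g, sg, G, sG = _arrays(instruments)
    n = len(ids)
    if n < 2:
        raise DegenerateInputError(f"weighted median needs >= 2 instruments, got {n}")
    beta = _median_from_effects(g, G, sG)
    rng = _seeded_rng(seed, "weighted_median")
    se = _parametric_bootstrap(lambda gb, Gb: _median_from_effects(gb, Gb, sG),
                               g, sg, G, sG, n_boot, rng)
    return _result("Weighted median", n, beta, se)


# ---------------------------------------------------------------------------
# Weighted mode
# ---------------------------------------------------------------------------


def _weighted_mad(b: np.ndarray, w: np.ndarray) -> float:
    center = weighted_median_estimate(b, w)
    return weighted_median_estimate(np.abs(b - center), w)


def mode_bandwidth(b: np.ndarray, w: np.ndarray, phi: float = 1.0) -> float:
    """Modified Silverman bandwidth h = phi * 0.9 * min(sd, mad/0.6745) * J^-0.2
    with weighted dispersion measures."""
    wn = w / np.sum(w)
    mean = float(np.sum(wn * b))
    sd = math.sqrt(float(np.sum(wn * (b - mean) ** 2)))
    mad = _weighted_mad(b, w) / 0.6745
    spread = min(sd, mad) if mad > 0 else sd
    return phi * 0.9 * spread * len(b) ** (-1.0 / 5.0)


def weighted_mode_estimate(b: np.ndarray, w: np.ndarray, phi: float = 1.0) -> float:
    """Argmax of the weighted Gaussian KDE over the ratios."""
    h = mode_bandwidth(b, w, phi)
    if h == 0.0 or np.ptp(b) == 0.0:
        return float(b[0])
    wn = w / np.sum(w)

    def neg_density(x):
        return -float(np.sum(wn * np.exp(-0.5 * ((x - b) / h) ** 2)))

    grid = np.linspace(b.min() - 3 * h, b.max() + 3 * h, 1024)
    dens = (wn[None, :] * np.exp(-0.5 * ((grid[:, None] - b[None, :]) / h) ** 2)).sum(axis=1)
    x0 = grid[int(np.argmax(dens))]
    res = minimize_scalar(neg_density, bounds=(x0 - 2 * h, x0 + 2 * h),
                          method="bounded", options={"xatol": 1e-12})
    return float(res.x) if res.success else float(x0)


def weighted_mode(instruments: Sequence[HarmonizedInstrument],
                  phi: float = 1.0, n_boot: int = 1000,
                  seed: int | None = None) -> MRResult:
    """Weighted-mode causal estimate with parametric-bootstrap se.

    ``phi`` scales the kernel bandwidth; 1 is the conventional default.
    """
    ids, g, sg, G, sG = _arrays(instruments)
    n = len(ids)
    if n < 2:
        raise DegenerateInputError(f"weighted mode needs >= 2 instruments, got {n}")
    b = G / g
    w = g**2 / sG**2
    beta = weighted_mode_estimate(b, w, phi)
    rng = _seeded_rng(seed, "weighted_mode")
    se = _parametric_bootstrap(
        lambda gb, Gb: weighted_mode_estimate(Gb / gb, gb**2 / sG**2, phi),
        g, sg, G, sG, n_boot, rng)
    return _result("Weighted mode", n, beta, se)


def _seeded_rng(seed: int | None, what: str) -> np.random.Generator:
    if seed is None:
        seed = int(np.random.SeedSequence().entropy % (2**31))
        log.info("%s: no seed supplied; drew %d from OS entropy", what, seed)
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Heterogeneity
# ---------------------------------------------------------------------------


def heterogeneity(instruments: Sequence[HarmonizedInstrument],
                  ivw: MRResult | None = None,
                  egger: MRResult | None = None) -> list[HeterogeneityResult]:
    """Cochran's Q about the IVW fit (df = J - 1) and, with >= 3 instruments,
    the Egger analogue Q' about the intercept-bearing fit (df = J - 2), both
    on the Wald-ratio scale with weights 1/se_j^2."""
    ids, b, se, g, sg, G, sG = _ratio_arrays(instruments)
    n = len(ids)
    if n < 2:
        raise DegenerateInputError(f"heterogeneity needs >= 2 instruments, got {n}")
    w = 1.0 / se**2
    if ivw is None:
        ivw = mr_ivw(instruments, model="fixed")
    Q = float(np.sum(w * (b - ivw.beta) ** 2))
    out = [HeterogeneityResult("Inverse-variance weight", Q, n - 1,
                               float(chi2.sf(Q, n - 1)))]
    if n >= 3:
        try:
            if egger is None:
                egger = mr_egger(instruments)
        except DegenerateInputError as exc:
            log.warning("Egger heterogeneity skipped: %s", exc)
            return out
        fit = egger.beta + egger.intercept / np.abs(g)
        Qp = float(np.sum(w * (b - fit) ** 2))
        out.append(HeterogeneityResult("MR Egger", Qp, n - 2,
                                       float(chi2.sf(Qp, n - 2))))
    return out


# ---------------------------------------------------------------------------
# Sensitivity suite
# ---------------------------------------------------------------------------


@dataclass
class SensitivityTables:
    leave_one_out: pd.DataFrame
    single_snp: pd.DataFrame
    funnel: pd.DataFrame
    scatter: pd.DataFrame
    fits: dict[str, dict[str, float]] = field(default_factory=dict)


def sensitivity_suite(instruments: Sequence[HarmonizedInstrument],
                      seed: int | None = None,
                      ivw_model: str = "mre") -> SensitivityTables:
    """Leave-one-out, single-variant, funnel and scatter tables.

    Leave-one-out rows re-estimate IVW without each variant (falling back
    to the Wald ratio when only one remains) plus an "All" row; the
    single-variant table lists each Wald ratio plus the overall IVW and
    (when possible) MR-Egger rows; funnel pairs each ratio with its
    precision 1/se; scatter carries the harmonized effects with per-method
    fitted slopes/intercepts.
    """
    ids, b, se, g, sg, G, sG = _ratio_arrays(instruments)
    n = len(ids)
    if n < 2:
        raise DegenerateInputError(f"sensitivity suite needs >= 2 instruments, got {n}")
    retained = [i for i in instruments if i.retained and i.gamma != 0.0]

    overall = mr_ivw(retained, model=ivw_model)
    loo_rows = []
    for k, vid in enumerate(ids):
        rest = [i for i in retained if i.variant_id != vid]
        if len(rest) >= 2:
            r = mr_ivw(rest, model=ivw_model)
            loo_rows.append((vid, r.n_snps, r.beta, r.se, r.p))
        else:
            wr = wald_ratios(rest)[0]
            loo_rows.append((vid, 1, wr.ratio, wr.se, wr.p))
    loo_rows.append(("All", overall.n_snps, overall.beta, overall.se, overall.p))
    leave_one_out = pd.DataFrame(loo_rows,
                                 columns=["excluded", "n_snps", "beta", "se", "p"])

    single_rows = [(vid, bj, sej, effect_transform(bj, sej).p)
                   for vid, bj, sej in zip(ids, b, se)]
    single_rows.append(("All - Inverse-variance weight", overall.beta,
                        overall.se, overall.p))
    fits = {"Inverse-variance weight": {"slope": overall.beta, "intercept": 0.0}}
    if n >= 3:
        try:
            egger = mr_egger(retained)
        except DegenerateInputError as exc:
            log.warning("Egger rows skipped in sensitivity tables: %s", exc)
        else:
            single_rows.append(("All - MR Egger", egger.beta, egger.se, egger.p))
            fits["MR Egger"] = {"slope": egger.beta, "intercept": egger.intercept}
    single_snp = pd.DataFrame(single_rows, columns=["variant_id", "beta", "se", "p"])

    funnel = pd.DataFrame({"variant_id": ids, "beta": b, "precision": 1.0 / se})
    scatter = pd.DataFrame({"variant_id": ids, "gamma": g, "se_gamma": sg,
                            "Gamma": G, "se_Gamma": sG})
    return SensitivityTables(leave_one_out=leave_one_out, single_snp=single_snp,
                             funnel=funnel, scatter=scatter, fits=fits)


# ---------------------------------------------------------------------------
# Combined runner
# ---------------------------------------------------------------------------


@dataclass
class MRReport:
    results: list[MRResult]
    heterogeneity: list[HeterogeneityResult]
    sensitivity: SensitivityTables | None
    not_applicable: dict[str, str] = field(default_factory=dict)

    def results_table(self) -> pd.DataFrame:
        rows = [(r.method, r.n_snps, r.beta, r.se, r.p, r.odds_ratio,
                 r.ci_low, r.ci_high) for r in self.results]
        return pd.DataFrame(rows, columns=["method", "n_snps", "beta", "se",
                                           "p", "or", "or_ci_low", "or_ci_high"])


def run_all(instruments: Sequence[HarmonizedInstrument],
            ivw_model: str = "mre", phi: float = 1.0,
            n_boot: int = 1000, seed: int | None = None) -> MRReport:
    """Run the four estimators plus heterogeneity and sensitivity analyses.

    Methods that cannot run at the available instrument count are reported
    as not-applicable rather than aborting the report; a single instrument
    yields the Wald ratio alone.
    """
    results: list[MRResult] = []
    not_applicable: dict[str, str] = {}
    retained = [i for i in instruments if i.retained and i.gamma != 0.0]
    n = len(retained)
    if n == 0:
        raise DegenerateInputError("no retained instruments with nonzero gamma")
    if n == 1:
        wr = wald_ratios(retained)[0]
        results.append(_result("Wald ratio", 1, wr.ratio, wr.se))
        for m in METHOD_ORDER:
            not_applicable[m] = "needs >= 2 instruments (>= 3 for MR Egger)"
        return MRReport(results=results, heterogeneity=[], sensitivity=None,
                        not_applicable=not_applicable)

    seeds = np.random.SeedSequence(seed).spawn(2) if seed is not None else [None, None]

    def seed_of(ss):
        return int(ss.generate_state(1)[0] % (2**31)) if ss is not None else None

    runners = {
        "Inverse-variance weight": lambda: mr_ivw(retained, model=ivw_model),
        "Weighted median": lambda: weighted_median(retained, n_boot=n_boot,
                                                   seed=seed_of(seeds[0])),
        "Weighted mode": lambda: weighted_mode(retained, phi=phi, n_boot=n_boot,
                                               seed=seed_of(seeds[1])),
        "MR Egger": lambda: mr_egger(retained),
    }
    for method in METHOD_ORDER:
        try:
            results.append(runners[method]())
        except DegenerateInputError as exc:
            not_applicable[method] = str(exc)
    het = heterogeneity(retained) if n >= 2 else []
    sens = sensitivity_suite(retained, seed=seed, ivw_model=ivw_model)
    return MRReport(results=results, heterogeneity=het, sensitivity=sens,
                    not_applicable=not_applicable)
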