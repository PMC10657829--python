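"""Two-sample Mendelian randomization engine.

Summary-statistics MR for a single exposure/outcome pair: instrument
selection (p-value threshold, greedy LD clumping, F-statistic filter),
allele harmonization between the two GWAS tables, five causal estimators
(Wald ratio, inverse-variance weighted, MR-Egger, weighted median, simple
and weighted mode), and the standard sensitivity battery (Cochran's Q,
Egger intercept, MR-PRESSO global / outlier / distortion tests, Steiger
directionality).

Conventions: per-SNP instrument strength F = (beta / se)^2; Wald-ratio
standard errors are first-order (se_out / |beta_exp|); random-effects IVW
uses the multiplicative model, inflating the fixed-effect standard error by
sqrt(max(1, Q / (n - 1))); p-values use normal quantiles by default with a
t option.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

GWAS_COLUMNS = [
    "rsid", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "p", "n",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_PALINDROMIC = ({"A", "T"}, {"C", "G"})

METHOD_MINIMUM = {
    "wald": 1, "ivw": 1, "egger": 3,
    "weighted_median": 3, "simple_mode": 3, "weighted_mode": 3,
}


@dataclass(frozen=True)
class IvConfig:
    p_threshold: float = 1e-5
    clump_window: int = 500_000
    clump_r2: float = 0.1
    f_min: float = 10.0

    def __post_init__(self) -> None:
        for name in ("p_threshold", "clump_window", "clump_r2", "f_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class HarmonizedSnp:
    rsid: str
    beta_exp: float
    se_exp: float
    beta_out: float
    se_out: float
    eaf_exp: float
    eaf_out: float
    palindromic: bool
    action_taken: str  # kept | flipped | dropped


@dataclass(frozen=True)
class MrResult:
    method: str
    beta: float
    se: float
    or_: float
    ci95: tuple[float, float]
    p: float
    n_snps: int

    @classmethod
    def from_beta(cls, method: str, beta: float, se: float, n_snps: int,
                  df: int | None = None) -> "MrResult":
        if se > 0:
            z = beta / se
            if df is not None and df > 0:
                p = 2 * stats.t.sf(abs(z), df)
            else:
                p = 2 * stats.norm.sf(abs(z))
        else:
            p = 0.0 if beta != 0 else 1.0
        return cls(
            method=method,
            beta=float(beta),
            se=float(se),
            or_=math.exp(beta),
            ci95=(math.exp(beta - 1.96 * se), math.exp(beta + 1.96 * se)),
            p=float(p),
            n_snps=n_snps,
        )


@dataclass(frozen=True)
class SensitivityReport:
    cochran_q: float | None = None
    q_df: int | None = None
    q_p: float | None = None
    egger_intercept: float | None = None
    intercept_se: float | None = None
    intercept_p: float | None = None
    presso_global_p: float | None = None
    presso_outliers: tuple[str, ...] = ()
    presso_distortion_p: float | None = None
    steiger_direction: bool | None = None
    steiger_p: float | None = None


# ---------------------------------------------------------------------------
# instrument selection


def read_gwas(path) -> pd.DataFrame:
    """GWAS summary TSV with the standard header; extra columns ignored."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(GWAS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"missing GWAS columns {sorted(missing)}")
    if (df["se"] <= 0).any():
        raise ValueError("non-positive standard errors in GWAS table")
    return df[GWAS_COLUMNS].copy()


def read_ld(path) -> dict[frozenset[str], float]:
    """Three-column TSV rsid_a, rsid_b, r2; absent pairs mean independence."""
    df = pd.read_csv(path, sep="\t", comment="#")
    return {
        frozenset((str(a), str(b))): float(r)
        for a, b, r in df.itertuples(index=False, name=None)
    }


def select_instruments(
    exposure: pd.DataFrame,
    ld_r2: Mapping[frozenset[str], float] | None,
    cfg: IvConfig = IvConfig(),
) -> pd.DataFrame:
    """p-threshold, greedy LD clumping, then F-statistic filter.

    Clumping iterates SNPs by ascending p and retains a SNP unless it lies
    within ``clump_window`` of an already-retained SNP on the same chromosome
    with r^2 above ``clump_r2`` (the index-SNP rule).  Pairs absent from the
    LD lookup are treated as independent.  An empty result is returned as an
    empty frame, not an exception.
    """
    ld_r2 = ld_r2 or {}
    df = exposure[exposure["p"] < cfg.p_threshold].sort_values(
        ["p", "rsid"], kind="mergesort"
    )
    kept: list[pd.Series] = []
    for _, snp in df.iterrows():
        clumped = False
        for idx_snp in kept:
            if idx_snp["chrom"] != snp["chrom"]:
                continue
            if abs(int(idx_snp["pos"]) - int(snp["pos"])) > cfg.clump_window:
                continue
            r2 = ld_r2.get(frozenset((str(idx_snp["rsid"]), str(snp["rsid"]))), 0.0)
            if r2 > cfg.clump_r2:
                clumped = True
                break
        if not clumped:
            kept.append(snp)
    if not kept:
        logger.warning("no instruments survive the p threshold")
        return exposure.iloc[0:0].copy()
    out = pd.DataFrame(kept)
    f_stat = (out["beta"] / out["se"]) ** 2
    out = out[f_stat > cfg.f_min].reset_index(drop=True)
    if out.empty:
        logger.warning("no instruments survive the F filter")
    return out


# ---------------------------------------------------------------------------
# harmonization


def _is_palindromic(a1: str, a2: str) -> bool:
    return {a1, a2} in _PALINDROMIC


def harmonize(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    palindrome_eaf_limit: float = 0.42,
) -> list[HarmonizedSnp]:
    """Align outcome effects to the exposure effect allele, SNP by SNP.

    Exact allele match is kept as-is; an exact swap flips the outcome beta
    sign and frequency.  Palindromic SNPs (A/T or C/G) carry no strand
    information, so they are resolved by effect-allele frequency: if both
    frequencies sit outside (limit, 1 - limit) they are oriented so the
    frequencies agree (flip when they disagree), otherwise dropped.  Any
    other allele configuration is dropped with the action recorded.
    """
    out_by_rsid = outcome.set_index("rsid")
    result: list[HarmonizedSnp] = []
    for _, e in exposure.iterrows():
        rsid = str(e["rsid"])
        if rsid not in out_by_rsid.index:
            continue
        o = out_by_rsid.loc[rsid]
        ea_e, oa_e = str(e["effect_allele"]), str(e["other_allele"])
        ea_o, oa_o = str(o["effect_allele"]), str(o["other_allele"])
        pal = _is_palindromic(ea_e, oa_e)

        def emit(beta_o, eaf_o, action):
            result.append(
                HarmonizedSnp(
                    rsid=rsid,
                    beta_exp=float(e["beta"]), se_exp=float(e["se"]),
                    beta_out=float(beta_o), se_out=float(o["se"]),
                    eaf_exp=float(e["eaf"]), eaf_out=float(eaf_o),
                    palindromic=pal, action_taken=action,
                )
            )

        if pal:
            if {ea_o, oa_o} != {ea_e, oa_e}:
                emit(o["beta"], o["eaf"], "dropped")
                continue
            lo, hi = palindrome_eaf_limit, 1.0 - palindrome_eaf_limit
            fe, fo = float(e["eaf"]), float(o["eaf"])
            informative = not (lo <= fe <= hi) and not (lo <= fo <= hi)
            if not informative:
                emit(o["beta"], o["eaf"], "dropped")
            elif (fe < 0.5) == (fo < 0.5):
                emit(o["beta"], o["eaf"], "kept")
            else:
                emit(-float(o["beta"]), 1.0 - fo, "flipped")
        elif (ea_o, oa_o) == (ea_e, oa_e):
            emit(o["beta"], o["eaf"], "kept")
        elif (ea_o, oa_o) == (oa_e, ea_e):
            emit(-float(o["beta"]), 1.0 - float(o["eaf"]), "flipped")
        else:
            emit(o["beta"], o["eaf"], "dropped")
    n_drop = sum(1 for h in result if h.action_taken == "dropped")
    if n_drop:
        logger.info("harmonization dropped %d of %d SNPs", n_drop, len(result))
    return result


def usable(snps: Iterable[HarmonizedSnp]) -> list[HarmonizedSnp]:
    return [s for s in snps if s.action_taken != "dropped"]


# ---------------------------------------------------------------------------
# estimators


def _ratios_weights(snps: Sequence[HarmonizedSnp]) -> tuple[np.ndarray, np.ndarray]:
    bx = np.array([s.beta_exp for s in snps])
    by = np.array([s.beta_out for s in snps])
    so = np.array([s.se_out for s in snps])
    if np.any(bx == 0):
        bad = [s.rsid for s in snps if s.beta_exp == 0]
        logger.warning("skipping SNPs with zero exposure beta: %s", bad)
        keep = bx != 0
        bx, by, so = bx[keep], by[keep], so[keep]
    ratios = by / bx
    weights = (bx / so) ** 2  # inverse of first-order Wald-ratio variance
    return ratios, weights


def wald_ratio(snp: HarmonizedSnp) -> MrResult:
    """Single-SNP causal estimate beta_out / beta_exp (first-order se)."""
    if snp.beta_exp == 0:
        raise ZeroDivisionError(f"zero exposure beta for {snp.rsid}")
    beta = snp.beta_out / snp.beta_exp
    se = snp.se_out / abs(snp.beta_exp)
    return MrResult.from_beta("wald", beta, se, 1)


def ivw(
    snps: Sequence[HarmonizedSnp],
    random_effects: bool = True,
    t_dist: bool = False,
) -> MrResult:
    """Inverse-variance-weighted estimate: origin regression of beta_out on
    beta_exp with weights 1/se_out^2.

    With one SNP this is exactly the Wald ratio.  Under ``random_effects``
    the fixed-effect standard error is inflated by sqrt(max(1, Q/(n-1)))
    (multiplicative model; never deflated below the fixed-effect se).
    """
    snps = usable(snps)
    if not snps:
        raise ValueError("IVW needs at least one usable SNP")
    if len(snps) == 1:
        r = wald_ratio(snps[0])
        return MrResult.from_beta("ivw", r.beta, r.se, 1)
    bx = np.array([s.beta_exp for s in snps])
    by = np.array([s.beta_out for s in snps])
    w = 1.0 / np.array([s.se_out for s in snps]) ** 2
    beta = float(np.sum(w * bx * by) / np.sum(w * bx * bx))
    se = float(1.0 / math.sqrt(np.sum(w * bx * bx)))
    if random_effects:
        q, dof, _ = cochran_q(snps)
        se *= math.sqrt(max(1.0, q / dof))
    return MrResult.from_beta(
        "ivw", beta, se, len(snps), df=len(snps) - 1 if t_dist else None
    )


def egger(
    snps: Sequence[HarmonizedSnp], t_dist: bool = True
) -> tuple[MrResult, float, float, float]:
    """MR-Egger: weighted regression with intercept after orienting each SNP
    so beta_exp >= 0.  Returns (slope result, intercept, intercept se,
    intercept p); a nonzero intercept indicates directional pleiotropy.
    """
    snps = usable(snps)
    if len(snps) < 3:
        raise ValueError(f"MR-Egger needs >= 3 SNPs, got {len(snps)}")
    bx = np.array([s.beta_exp for s in snps])
    by = np.array([s.beta_out for s in snps])
    so = np.array([s.se_out for s in snps])
    sign = np.where(bx < 0, -1.0, 1.0)
    bx, by = bx * sign, by * sign
    w = 1.0 / so**2
    X = np.column_stack([np.ones_like(bx), bx])
    wx = X * w[:, None]
    xtx_inv = np.linalg.inv(X.T @ wx)
    coef = xtx_inv @ (wx.T @ by)
    resid = by - X @ coef
    dof = len(snps) - 2
    # multiplicative overdispersion, floored at 1 as in the IVW model
    phi = max(1.0, float(np.sum(w * resid**2) / dof))
    cov = xtx_inv * phi
    intercept, slope = float(coef[0]), float(coef[1])
    se_int, se_slope = math.sqrt(cov[0, 0]), math.sqrt(cov[1, 1])
    if t_dist:
        p_int = 2 * stats.t.sf(abs(intercept / se_int), dof)
        result = MrResult.from_beta("egger", slope, se_slope, len(snps), df=dof)
    else:
        p_int = 2 * stats.norm.sf(abs(intercept / se_int))
        result = MrResult.from_beta("egger", slope, se_slope, len(snps))
    return result, intercept, se_int, float(p_int)


def _weighted_median_estimate(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios)
    r, w = ratios[order], weights[order]
    w = w / w.sum()
    cum = np.cumsum(w) - 0.5 * w  # standardized cumulative weights
    if cum[0] >= 0.5:
        return float(r[0])
    if cum[-1] <= 0.5:
        return float(r[-1])
    return float(np.interp(0.5, cum, r))


def weighted_median(
    snps: Sequence[HarmonizedSnp], n_boot: int = 1000, seed: int = 0
) -> MrResult:
    """Weighted-median estimator: consistent when SNPs carrying at least half
    of the inverse-variance weight are valid instruments.

    The estimate interpolates the ordered Wald ratios at cumulative weight
    0.5; the standard error is a parametric bootstrap over the summary
    statistics.
    """
    snps = usable(snps)
    if len(snps) < 3:
        raise ValueError(f"weighted median needs >= 3 SNPs, got {len(snps)}")
    ratios, weights = _ratios_weights(snps)
    est = _weighted_median_estimate(ratios, weights)
    se = _bootstrap_se(snps, _weighted_median_estimate, n_boot, seed, weighted=True)
    return MrResult.from_beta("weighted_median", est, se, len(snps))


def _mode_estimate(ratios: np.ndarray, weights: np.ndarray,
                   bandwidth_factor: float = 1.0) -> float:
    s = stats.median_abs_deviation(ratios, scale="normal")
    spread = min(np.std(ratios, ddof=1), s) if s > 0 else np.std(ratios, ddof=1)
    if spread == 0:
        return float(ratios[0])
    h = bandwidth_factor * 0.9 * spread * len(ratios) ** (-0.2)
    lo, hi = ratios.min() - 3 * h, ratios.max() + 3 * h
    grid = np.linspace(lo, hi, 512)
    dens = np.sum(
        weights[:, None] * np.exp(-0.5 * ((grid[None, :] - ratios[:, None]) / h) ** 2),
        axis=0,
    )
    return float(grid[np.argmax(dens)])


def mode_estimators(
    snps: Sequence[HarmonizedSnp],
    bandwidth_factor: float = 1.0,
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[MrResult, MrResult]:
    """Simple and weighted mode: the argmax of a Gaussian kernel density over
    the Wald ratios, unweighted and inverse-variance weighted respectively.
    Bandwidth is a modified Silverman rule on the ratio spread; zero spread
    returns the common ratio with zero se.
    """
    snps = usable(snps)
    if len(snps) < 3:
        raise ValueError(f"mode estimators need >= 3 SNPs, got {len(snps)}")
    ratios, ivw_w = _ratios_weights(snps)
    if np.ptp(ratios) <= 1e-12 * max(1.0, float(np.abs(ratios).max())):
        est = float(ratios[0])
        return (
            MrResult.from_beta("simple_mode", est, 0.0, len(snps)),
            MrResult.from_beta("weighted_mode", est, 0.0, len(snps)),
        )
    ones = np.ones_like(ratios)
    simple = _mode_estimate(ratios, ones, bandwidth_factor)
    weighted = _mode_estimate(ratios, ivw_w / ivw_w.sum(), bandwidth_factor)
    se_s = _bootstrap_se(
        snps, lambda r, w: _mode_estimate(r, np.ones_like(r), bandwidth_factor),
        n_boot, seed, weighted=False,
    )
    se_w = _bootstrap_se(
        snps, lambda r, w: _mode_estimate(r, w / w.sum(), bandwidth_factor),
        n_boot, seed + 1, weighted=True,
    )
    return (
        MrResult.from_beta("simple_mode", simple, se_s, len(snps)),
        MrResult.from_beta("weighted_mode", weighted, se_w, len(snps)),
    )


def _bootstrap_se(snps, estimator, n_boot, seed, weighted=True) -> float:
    """Parametric bootstrap: redraw each beta from N(beta_hat, se^2)."""
    rng = np.random.default_rng(seed)
    bx = np.array([s.beta_exp for s in snps])
    by = np.array([s.beta_out for s in snps])
    sx = np.array([s.se_exp for s in snps])
    so = np.array([s.se_out for s in snps])
    ests = np.empty(n_boot)
    for b in range(n_boot):
        bx_b = rng.normal(bx, sx)
        by_b = rng.normal(by, so)
        bx_b[bx_b == 0] = 1e-12
        ratios = by_b / bx_b
        weights = (bx_b / so) ** 2
        ests[b] = estimator(ratios, weights)
    return float(np.std(ests, ddof=1))


def cochran_q(snps: Sequence[HarmonizedSnp]) -> tuple[float, int, float]:
    """Heterogeneity of the per-SNP Wald ratios around the fixed-effect IVW.

    Q = sum_j w_j (theta_j - theta_IVW)^2 with first-order weights
    w_j = (beta_exp_j / se_out_j)^2; p from chi-square with n - 1 df.
    """
    snps = usable(snps)
    if len(snps) < 2:
        raise ValueError("Cochran's Q needs >= 2 SNPs")
    ratios, w = _ratios_weights(snps)
    theta = np.sum(w * ratios) / np.sum(w)
    q = float(np.sum(w * (ratios - theta) ** 2))
    dof = len(ratios) - 1
    return q, dof, float(stats.chi2.sf(q, dof))


# ---------------------------------------------------------------------------
# MR-PRESSO


def mr_presso(
    snps: Sequence[HarmonizedSnp],
    n_sim: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple[float, list[str], float | None]:
    """Pleiotropy residual sum of squares and outlier test.

    Global test: the observed leave-one-out weighted residual sum of squares
    is compared against its null distribution obtained by simulating outcome
    (and exposure) betas from the no-pleiotropy fitted model.  Outlier test:
    each SNP's observed residual contribution against its simulated null,
    Bonferroni-corrected at ``alpha``.  Distortion test: the shift in the
    IVW estimate after removing flagged outliers, referred to the
    distribution of shifts from removing random subsets of the same size.
    """
    snps = usable(snps)
    m = len(snps)
    if m < 4:
        raise ValueError(f"MR-PRESSO needs >= 4 SNPs, got {m}")
    rng = np.random.default_rng(seed)
    bx = np.array([s.beta_exp for s in snps])
    by = np.array([s.beta_out for s in snps])
    sx = np.array([s.se_exp for s in snps])
    so = np.array([s.se_out for s in snps])
    w = 1.0 / so**2

    def loo_theta(bx_a, by_a, w_a):
        """Leave-one-out IVW slope for each left-out index (vectorized)."""
        swxy = np.sum(w_a * bx_a * by_a)
        swxx = np.sum(w_a * bx_a * bx_a)
        return (swxy - w_a * bx_a * by_a) / (swxx - w_a * bx_a * bx_a)

    def rss_terms(bx_a, by_a):
        th = loo_theta(bx_a, by_a, w)
        return w * (by_a - th * bx_a) ** 2

    obs_terms = rss_terms(bx, by)
    obs_rss = float(obs_terms.sum())

    theta_loo = loo_theta(bx, by, w)
    sim_terms = np.empty((n_sim, m))
    for k in range(n_sim):
        bx_s = rng.normal(bx, sx)
        by_s = rng.normal(theta_loo * bx, so)  # expected under no pleiotropy
        sim_terms[k] = rss_terms(bx_s, by_s)
    sim_rss = sim_terms.sum(axis=1)
    global_p = float((1 + np.sum(sim_rss >= obs_rss)) / (1 + n_sim))

    outliers: list[str] = []
    if global_p < alpha:
        for j in range(m):
            p_j = (1 + np.sum(sim_terms[:, j] >= obs_terms[j])) / (1 + n_sim)
            if p_j < alpha / m:  # Bonferroni
                outliers.append(snps[j].rsid)

    distortion_p: float | None = None
    if outliers:
        out_idx = np.array([s.rsid in outliers for s in snps])
        keep = ~out_idx
        theta_all = np.sum(w * bx * by) / np.sum(w * bx * bx)
        theta_no = np.sum(w[keep] * bx[keep] * by[keep]) / np.sum(
            w[keep] * bx[keep] ** 2
        )
        obs_shift = abs(theta_all - theta_no)
        n_out = int(out_idx.sum())
        shifts = np.empty(n_sim)
        idx = np.arange(m)
        for k in range(n_sim):
            drop = rng.choice(idx, size=n_out, replace=False)
            mask = np.ones(m, bool)
            mask[drop] = False
            t = np.sum(w[mask] * bx[mask] * by[mask]) / np.sum(
                w[mask] * bx[mask] ** 2
            )
            shifts[k] = abs(theta_all - t)
        distortion_p = float((1 + np.sum(shifts >= obs_shift)) / (1 + n_sim))
    return global_p, outliers, distortion_p


# ---------------------------------------------------------------------------
# Steiger directionality


def steiger(
    snps: Sequence[HarmonizedSnp], n_exp: float, n_out: float
) -> tuple[bool, float]:
    """Directionality check: does the instrument set explain more variance in
    the exposure than in the outcome?

    Per-SNP variance explained uses the F-to-r^2 transform
    r^2 = F / (F + n - 2) with F = (beta/se)^2, summed over instruments.
    The p-value is a z-test on the Fisher-transformed aggregate correlations.
    """
    snps = usable(snps)
    if n_exp <= 2 or n_out <= 2:
        raise ValueError("sample sizes must exceed 2")
    if not snps:
        raise ValueError("no usable SNPs")

    def r2_sum(betas, ses, n):
        f = (np.array(betas) / np.array(ses)) ** 2
        return float(np.sum(f / (f + n - 2)))

    r2_exp = r2_sum([s.beta_exp for s in snps], [s.se_exp for s in snps], n_exp)
    r2_out = r2_sum([s.beta_out for s in snps], [s.se_out for s in snps], n_out)
    r_exp = math.sqrt(min(r2_exp, 1.0 - 1e-12))
    r_out = math.sqrt(min(r2_out, 1.0 - 1e-12))
    z = (np.arctanh(r_exp) - np.arctanh(r_out)) / math.sqrt(
        1.0 / (n_exp - 3) + 1.0 / (n_out - 3)
    )
    p = float(2 * stats.norm.sf(abs(z)))
    return bool(r2_exp > r2_out), p


# ---------------------------------------------------------------------------
# orchestration


def run_mr(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    ld: Mapping[frozenset[str], float] | None = None,
    cfg: IvConfig = IvConfig(),
    seed: int = 0,
    n_boot: int = 1000,
    presso_n_sim: int = 1000,
) -> tuple[list[MrResult], SensitivityReport, pd.DataFrame]:
    """Full single-exposure pipeline: select, harmonize, estimate, diagnose.

    Returns the estimator results (those whose SNP-count minimum is met), a
    sensitivity report, and a forest-style table (method, n_snps, OR, CI, p
    plus heterogeneity/pleiotropy columns).  "No valid instruments" is a
    recorded outcome: empty results and an all-None report.
    """
    instruments = select_instruments(exposure, ld, cfg)
    if instruments.empty:
        return [], SensitivityReport(), pd.DataFrame()
    snps = usable(harmonize(instruments, outcome))
    if not snps:
        return [], SensitivityReport(), pd.DataFrame()

    results: list[MrResult] = []
    if len(snps) == 1:
        results.append(wald_ratio(snps[0]))
    results.append(ivw(snps))
    rep: dict = {}
    if len(snps) >= 2:
        q, dof, q_p = cochran_q(snps)
        rep.update(cochran_q=q, q_df=dof, q_p=q_p)
    if len(snps) >= 3:
        egger_res, b0, b0_se, b0_p = egger(snps)
        results.append(egger_res)
        results.append(weighted_median(snps, n_boot=n_boot, seed=seed))
        sm, wm = mode_estimators(snps, n_boot=n_boot, seed=seed + 1)
        results.extend([sm, wm])
        rep.update(egger_intercept=b0, intercept_se=b0_se, intercept_p=b0_p)
    if len(snps) >= 4:
        gp, outl, dp = mr_presso(snps, n_sim=presso_n_sim, seed=seed + 2)
        rep.update(
            presso_global_p=gp, presso_outliers=tuple(outl), presso_distortion_p=dp
        )
    n_exp = float(exposure["n"].median())
    n_out = float(outcome["n"].median())
    direction, st_p = steiger(snps, n_exp, n_out)
    rep.update(steiger_direction=direction, steiger_p=st_p)
    report = SensitivityReport(**rep)

    betas = [r.beta for r in results]
    sign_disagreement = len({math.copysign(1, b) for b in betas if b != 0}) > 1
    forest = pd.DataFrame(
        {
            "method": [r.method for r in results],
            "n_snps": [r.n_snps for r in results],
            "beta": [r.beta for r in results],
            "se": [r.se for r in results],
            "OR": [r.or_ for r in results],
            "ci_low": [r.ci95[0] for r in results],
            "ci_high": [r.ci95[1] for r in results],
            "p": [r.p for r in results],
        }
    )
    forest["q_p"] = report.q_p
    forest["egger_intercept_p"] = report.intercept_p
    forest["sign_disagreement"] = sign_disagreement
    return results, report, forest


def confounder_screen(
    instruments: pd.DataFrame,
    snp_trait_map: Sequence[tuple[str, str]],
    exclusion_traits: Iterable[str],
) -> pd.DataFrame:
    """Drop instruments annotated to any excluded trait (pre-fetched lookup
    standing in for an online variant-trait catalogue)."""
    excl = {t.strip().lower() for t in exclusion_traits}
    flagged = {
        str(rsid)
        for rsid, trait in snp_trait_map
        if str(trait).strip().lower() in excl
    }
    if flagged & set(instruments["rsid"].astype(str)):
        logger.info("confounder screen removed %s", sorted(flagged))
    return instruments[~instruments["rsid"].astype(str).isin(flagged)].reset_index(
        drop=True
    )
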