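"""Two-sample Mendelian randomization from GWAS summary statistics.

Implements the standard estimator battery — inverse-variance weighted (IVW),
MR-Egger with its intercept pleiotropy test, weighted median, weighted mode,
and a simplified residual-sum-of-squares outlier procedure — together with
p-value/distance instrument selection, allele harmonization, and
Benjamini–Hochberg correction across a family of trait-pair tests.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import FitError, HarmonizationError, NoInstrumentsError

logger = logging.getLogger(__name__)

IVW = "IVW"
WEIGHTED_MEDIAN = "weighted_median"
MR_EGGER = "MR_Egger"
WEIGHTED_MODE = "weighted_mode"
MR_PRESSO = "MR_PRESSO"
METHODS = (IVW, WEIGHTED_MEDIAN, MR_EGGER, MR_PRESSO, WEIGHTED_MODE)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_AMBIGUOUS_EAF = (0.42, 0.58)


def _is_palindromic(a1: str, a2: str) -> bool:
    return _COMPLEMENT.get(a1) == a2


@dataclass
class HarmonizedSet:
    """Aligned per-SNP effects for one exposure–outcome pair."""

    snps: list[str]
    beta_exp: np.ndarray
    se_exp: np.ndarray
    beta_out: np.ndarray
    se_out: np.ndarray
    dropped: pd.DataFrame  # columns: snp, reason

    @property
    def n_snps(self) -> int:
        return len(self.snps)


@dataclass
class MRResult:
    """One causal estimate (log-odds / beta scale plus odds-ratio form)."""

    exposure: str
    outcome: str
    method: str
    beta: float
    se: float
    pval: float
    n_snps: int
    egger_intercept: float | None = None
    intercept_p: float | None = None
    presso_global_p: float | None = None
    outliers: list[str] = field(default_factory=list)
    fdr_q: float | None = None

    @property
    def or_value(self) -> float:
        return math.exp(self.beta)

    @property
    def or_ci(self) -> tuple[float, float]:
        return (math.exp(self.beta - 1.96 * self.se), math.exp(self.beta + 1.96 * self.se))

    @property
    def significant(self) -> bool | None:
        return None if self.fdr_q is None else bool(self.fdr_q < 0.05)


def select_instruments(
    exposure_stats: pd.DataFrame,
    p_threshold: float = 5e-8,
    clump_kb: float = 10_000.0,
    clump_r2: float = 0.001,
    ld: pd.DataFrame | None = None,
) -> list[str]:
    """Greedy p-value clumping of genome-wide-significant SNPs.

    SNPs are taken in ascending p-value order; a candidate is kept when it
    lies at least ``clump_kb`` kilobases from every kept SNP on the same
    chromosome and, if a pairwise LD matrix is supplied, has r² below
    ``clump_r2`` with all of them. Without positions or an LD matrix the
    corresponding constraint cannot be enforced and is skipped with a warning.
    """
    sig = exposure_stats.loc[exposure_stats["pval"] < p_threshold]
    if sig.empty:
        raise NoInstrumentsError(f"no SNP passes p < {p_threshold:g}")
    have_pos = {"chrom", "pos"}.issubset(sig.columns) and sig["pos"].notna().all()
    if not have_pos:
        logger.warning("no chrom/pos columns: distance clumping skipped")
    if ld is None and clump_r2 < 1:
        logger.warning("no LD matrix supplied: r2 clumping limited to physical distance")
    ordered = sig.sort_values(["pval", "snp"], kind="mergesort")
    kept: list[str] = []
    kept_loc: list[tuple] = []
    for row in ordered.itertuples(index=False):
        ok = True
        if have_pos:
            for chrom, pos in kept_loc:
                if chrom == row.chrom and abs(pos - row.pos) < clump_kb * 1000.0:
                    ok = False
                    break
        if ok and ld is not None:
            for other in kept:
                if row.snp in ld.index and other in ld.columns:
                    if float(ld.loc[row.snp, other]) ** 2 >= clump_r2:
                        ok = False
                        break
        if ok:
            kept.append(row.snp)
            if have_pos:
                kept_loc.append((row.chrom, row.pos))
    return kept


def harmonize(
    exposure_stats: pd.DataFrame,
    outcome_stats: pd.DataFrame,
    instruments: Sequence[str],
) -> HarmonizedSet:
    """Align outcome effect alleles with the exposure's.

    Swapped effect/other alleles flip the outcome beta; palindromic SNPs with
    missing or ambiguous allele frequency (either trait) are dropped, as are
    SNPs absent from the outcome or with irreconcilable alleles.
    """
    exp = exposure_stats.set_index("snp")
    out = outcome_stats.set_index("snp")
    rows, dropped = [], []
    for snp in instruments:
        if snp not in out.index:
            dropped.append((snp, "missing in outcome"))
            continue
        e, o = exp.loc[snp], out.loc[snp]
        e1, e2 = str(e["effect_allele"]), str(e["other_allele"])
        o1, o2 = str(o["effect_allele"]), str(o["other_allele"])
        beta_out = float(o["beta"])
        if _is_palindromic(e1, e2):
            eafs = [e.get("eaf", np.nan), o.get("eaf", np.nan)]
            if any(
                pd.isna(f) or _AMBIGUOUS_EAF[0] <= float(f) <= _AMBIGUOUS_EAF[1] for f in eafs
            ):
                dropped.append((snp, "ambiguous palindrome"))
                continue
            # unambiguous palindrome: align by frequency side
            if (float(e["eaf"]) - 0.5) * (float(o["eaf"]) - 0.5) < 0:
                beta_out = -beta_out
        elif (o1, o2) == (e1, e2):
            pass
        elif (o1, o2) == (e2, e1):
            beta_out = -beta_out
        elif (o1, o2) == (_COMPLEMENT.get(e1), _COMPLEMENT.get(e2)):
            pass  # strand flip, same orientation
        elif (o1, o2) == (_COMPLEMENT.get(e2), _COMPLEMENT.get(e1)):
            beta_out = -beta_out
        else:
            dropped.append((snp, "allele mismatch"))
            continue
        rows.append((snp, float(e["beta"]), float(e["se"]), beta_out, float(o["se"])))
    if not rows:
        raise HarmonizationError("no SNPs retained after harmonization")
    snps, beta_exp, se_exp, beta_out, se_out = map(list, zip(*rows))
    return HarmonizedSet(
        snps=snps,
        beta_exp=np.asarray(beta_exp),
        se_exp=np.asarray(se_exp),
        beta_out=np.asarray(beta_out),
        se_out=np.asarray(se_out),
        dropped=pd.DataFrame(dropped, columns=["snp", "reason"]),
    )


def _result(exposure, outcome, method, beta, se, pval, n, **extra) -> MRResult:
    return MRResult(
        exposure=exposure,
        outcome=outcome,
        method=method,
        beta=float(beta),
        se=float(se),
        pval=float(pval),
        n_snps=int(n),
        **extra,
    )


def ivw(h: HarmonizedSet, exposure: str = "exposure", outcome: str = "outcome") -> MRResult:
    """Fixed-effect inverse-variance-weighted estimate, inflated to
    multiplicative random effects when the heterogeneity ratio Q/(n−1)
    exceeds 1 (zero-intercept weighted regression formulation)."""
    if h.n_snps < 2:
        raise FitError("IVW needs at least 2 SNPs")
    w = (h.beta_exp / h.se_out) ** 2
    ratios = h.beta_out / h.beta_exp
    beta = float(np.sum(w * ratios) / np.sum(w))
    se_fixed = 1.0 / math.sqrt(np.sum(w))
    q = float(np.sum(w * (ratios - beta) ** 2))
    scale = q / (h.n_snps - 1)
    se = se_fixed * math.sqrt(scale) if scale > 1.0 else se_fixed
    pval = 2 * sps.norm.sf(abs(beta) / se)
    return _result(exposure, outcome, IVW, beta, se, pval, h.n_snps)


def mr_egger(h: HarmonizedSet, exposure: str = "exposure", outcome: str = "outcome") -> MRResult:
    """Weighted Egger regression with a free intercept (pleiotropy term).

    Exposure effects are oriented non-negative before regression; slope and
    intercept inference uses the weighted-least-squares t distribution.
    """
    if h.n_snps < 3:
        raise FitError("Egger regression needs at least 3 SNPs")
    sign = np.where(h.beta_exp < 0, -1.0, 1.0)
    bx, by = h.beta_exp * sign, h.beta_out * sign
    X = sm.add_constant(bx)
    fit = sm.WLS(by, X, weights=1.0 / h.se_out**2).fit()
    beta, se, pval = fit.params[1], fit.bse[1], fit.pvalues[1]
    return _result(
        exposure,
        outcome,
        MR_EGGER,
        beta,
        se,
        pval,
        h.n_snps,
        egger_intercept=float(fit.params[0]),
        intercept_p=float(fit.pvalues[0]),
    )


def _ratio_weights(h: HarmonizedSet) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP Wald ratios and inverse-variance weights (delta method)."""
    ratios = h.beta_out / h.beta_exp
    var = h.se_out**2 / h.beta_exp**2 + (h.beta_out**2 * h.se_exp**2) / h.beta_exp**4
    return ratios, 1.0 / var


def _weighted_percentile(values: np.ndarray, weights: np.ndarray, q: float = 0.5) -> float:
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cum = np.cumsum(w) - 0.5 * w
    cum /= np.sum(w)
    return float(np.interp(q, cum, v))


def _bootstrap_draws(h: HarmonizedSet, n_boot: int, seed: int):
    rng = np.random.default_rng(seed)
    bx = h.beta_exp + rng.standard_normal((n_boot, h.n_snps)) * h.se_exp
    by = h.beta_out + rng.standard_normal((n_boot, h.n_snps)) * h.se_out
    return bx, by


def weighted_median(
    h: HarmonizedSet,
    exposure: str = "exposure",
    outcome: str = "outcome",
    n_boot: int = 1000,
    seed: int = 0,
) -> MRResult:
    """Inverse-variance weighted median of the Wald ratios; the standard
    error comes from a seeded parametric bootstrap."""
    if h.n_snps < 3:
        raise FitError("weighted median needs at least 3 SNPs")
    ratios, weights = _ratio_weights(h)
    beta = _weighted_percentile(ratios, weights)
    bx, by = _bootstrap_draws(h, n_boot, seed)
    boot = np.empty(n_boot)
    for b in range(n_boot):
        r = by[b] / bx[b]
        v = h.se_out**2 / bx[b] ** 2 + (by[b] ** 2 * h.se_exp**2) / bx[b] ** 4
        boot[b] = _weighted_percentile(r, 1.0 / v)
    se = float(np.std(boot, ddof=1))
    pval = 2 * sps.norm.sf(abs(beta) / se)
    return _result(exposure, outcome, WEIGHTED_MEDIAN, beta, se, pval, h.n_snps)


def _weighted_mode_point(ratios: np.ndarray, weights: np.ndarray, bandwidth: float) -> float:
    s = 0.9 * min(np.std(ratios, ddof=1), sps.median_abs_deviation(ratios, scale="normal"))
    if s <= 0:
        return float(ratios[np.argmax(weights)])
    hband = max(bandwidth * s * len(ratios) ** (-0.2), 1e-12)
    grid = np.linspace(ratios.min() - 3 * hband, ratios.max() + 3 * hband, 512)
    dens = np.sum(
        weights[:, None] * np.exp(-0.5 * ((grid[None, :] - ratios[:, None]) / hband) ** 2),
        axis=0,
    )
    return float(grid[np.argmax(dens)])


def weighted_mode(
    h: HarmonizedSet,
    exposure: str = "exposure",
    outcome: str = "outcome",
    bandwidth: float = 1.0,
    n_boot: int = 1000,
    seed: int = 0,
) -> MRResult:
    """Mode of the smoothed, weight-tilted Wald-ratio density."""
    if h.n_snps < 3:
        raise FitError("weighted mode needs at least 3 SNPs")
    ratios, weights = _ratio_weights(h)
    beta = _weighted_mode_point(ratios, weights, bandwidth)
    bx, by = _bootstrap_draws(h, n_boot, seed)
    boot = np.empty(n_boot)
    for b in range(n_boot):
        r = by[b] / bx[b]
        v = h.se_out**2 / bx[b] ** 2 + (by[b] ** 2 * h.se_exp**2) / bx[b] ** 4
        boot[b] = _weighted_mode_point(r, 1.0 / v, bandwidth)
    se = float(np.std(boot, ddof=1))
    pval = 2 * sps.norm.sf(abs(beta) / se)
    return _result(exposure, outcome, WEIGHTED_MODE, beta, se, pval, h.n_snps)


def mr_presso(
    h: HarmonizedSet,
    exposure: str = "exposure",
    outcome: str = "outcome",
    n_sim: int = 1000,
    seed: int = 0,
    outlier_alpha: float = 0.05,
) -> MRResult:
    """Simplified residual-sum-of-squares global heterogeneity + outlier test.

    The observed weighted RSS around the IVW fit is compared with its
    distribution over ``n_sim`` datasets simulated from the fitted model and
    the per-SNP standard errors; per-SNP outlier p-values use the
    leave-one-out fit. Outliers at p < ``outlier_alpha``/n are removed and
    the IVW estimate recomputed on the remainder.
    """
    if h.n_snps < 4:
        raise FitError("the outlier test needs at least 4 SNPs")
    rng = np.random.default_rng(seed)
    w = 1.0 / h.se_out**2

    def _slope(bx, by, weights):
        return float(np.sum(weights * bx * by) / np.sum(weights * bx * bx))

    b_hat = _slope(h.beta_exp, h.beta_out, w)
    # leave-one-out observed residuals
    obs_res = np.empty(h.n_snps)
    for i in range(h.n_snps):
        mask = np.ones(h.n_snps, dtype=bool)
        mask[i] = False
        b_i = _slope(h.beta_exp[mask], h.beta_out[mask], w[mask])
        obs_res[i] = w[i] * (h.beta_out[i] - b_i * h.beta_exp[i]) ** 2
    rss_obs = float(obs_res.sum())

    by_sim = b_hat * h.beta_exp + rng.standard_normal((n_sim, h.n_snps)) * h.se_out
    bx_sim = h.beta_exp + rng.standard_normal((n_sim, h.n_snps)) * h.se_exp
    num = np.sum(w * bx_sim * by_sim, axis=1)
    den = np.sum(w * bx_sim * bx_sim, axis=1)
    b_sim = num / den
    res_sim = w * (by_sim - b_sim[:, None] * bx_sim) ** 2
    rss_sim = res_sim.sum(axis=1)

    global_p = float(np.mean(rss_sim >= rss_obs))
    snp_p = np.mean(res_sim >= obs_res[None, :], axis=0)
    outliers = [h.snps[i] for i in np.flatnonzero(snp_p < outlier_alpha / h.n_snps)]

    keep = np.array([s not in outliers for s in h.snps])
    if keep.sum() < 2:
        raise FitError("outlier removal left fewer than 2 SNPs")
    corrected = HarmonizedSet(
        snps=[s for s, k in zip(h.snps, keep) if k],
        beta_exp=h.beta_exp[keep],
        se_exp=h.se_exp[keep],
        beta_out=h.beta_out[keep],
        se_out=h.se_out[keep],
        dropped=h.dropped,
    )
    base = ivw(corrected, exposure, outcome)
    return _result(
        exposure,
        outcome,
        MR_PRESSO,
        base.beta,
        base.se,
        base.pval,
        corrected.n_snps,
        presso_global_p=global_p,
        outliers=outliers,
    )


def bh_fdr(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg adjusted q-values."""
    return multipletests(np.asarray(pvals, dtype=float), method="fdr_bh")[1]


def run_pair(
    exposure: str,
    outcome: str,
    exposure_stats: pd.DataFrame,
    outcome_stats: pd.DataFrame,
    p_threshold: float = 5e-8,
    clump_kb: float = 10_000.0,
    clump_r2: float = 0.001,
    ld: pd.DataFrame | None = None,
    n_presso: int = 1000,
    seed: int = 0,
) -> list[MRResult]:
    """All five estimators for one exposure → outcome direction."""
    instruments = select_instruments(exposure_stats, p_threshold, clump_kb, clump_r2, ld)
    h = harmonize(exposure_stats, outcome_stats, instruments)
    results = [ivw(h, exposure, outcome)]
    for fn in (
        lambda: weighted_median(h, exposure, outcome, seed=seed),
        lambda: mr_egger(h, exposure, outcome),
        lambda: mr_presso(h, exposure, outcome, n_sim=n_presso, seed=seed),
        lambda: weighted_mode(h, exposure, outcome, seed=seed),
    ):
        try:
            results.append(fn())
        except FitError as exc:
            logger.warning("%s -> %s: %s", exposure, outcome, exc)
    return results


def bidirectional_suite(
    trait_pairs: Sequence[tuple[str, str]],
    stats_by_trait: dict[str, pd.DataFrame],
    seed: int = 0,
    fdr_threshold: float = 0.05,
    **pair_kwargs,
) -> tuple[pd.DataFrame, list[tuple[str, str, str]]]:
    """Both directions of every trait pair, with per-method BH-FDR.

    The FDR family is the direction × pair tests within one estimator family.
    Pairs that fail (no instruments, too few SNPs) are recorded and skipped.
    Returns a long-format result table and the failure list.
    """
    results: list[MRResult] = []
    failures: list[tuple[str, str, str]] = []
    for t1, t2 in trait_pairs:
        for exposure, outcome in ((t1, t2), (t2, t1)):
            try:
                results += run_pair(
                    exposure,
                    outcome,
                    stats_by_trait[exposure],
                    stats_by_trait[outcome],
                    seed=seed,
                    **pair_kwargs,
                )
            except (NoInstrumentsError, HarmonizationError, FitError) as exc:
                failures.append((exposure, outcome, str(exc)))
    for method in METHODS:
        group = [r for r in results if r.method == method]
        if not group:
            continue
        qvals = bh_fdr([r.pval for r in group])
        for r, q in zip(group, qvals):
            r.fdr_q = float(q)
    table = results_table(results, fdr_threshold)
    return table, failures


def results_table(results: Sequence[MRResult], fdr_threshold: float = 0.05) -> pd.DataFrame:
    """Long-format result table (one row per exposure/outcome/method)."""
    rows = []
    for r in results:
        lo, hi = r.or_ci
        rows.append(
            {
                "exposure": r.exposure,
                "outcome": r.outcome,
                "method": r.method,
                "n_snps": r.n_snps,
                "beta": r.beta,
                "se": r.se,
                "or": r.or_value,
                "or_ci_low": lo,
                "or_ci_high": hi,
                "p": r.pval,
                "fdr_q": r.fdr_q,
                "significant": None if r.fdr_q is None else bool(r.fdr_q < fdr_threshold),
                "egger_intercept": r.egger_intercept,
                "intercept_p": r.intercept_p,
                "presso_global_p": r.presso_global_p,
                "outliers": ";".join(r.outliers) if r.outliers else "",
            }
        )
    return pd.DataFrame(rows)
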