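"""Ground-truth simulators for spontaneous-report tables and GWAS summary stats.

The report simulator injects drug–event associations by solving the 2x2 cell
probabilities for fixed drug and event margins so that the odds ratio of the
expected table equals the requested value exactly; the reporting odds ratio is
therefore the generative parameter, not an emergent one. Time-to-onset for an
injected pair is drawn from a Weibull with the configured scale/shape, so the
downstream Weibull fit also has a known truth.

The GWAS simulator emits two-trait summary statistics with a known causal
effect, instruments genome-wide significant by construction, optional
directional pleiotropy, and deliberately awkward allele coding (palindromic
pairs, swapped effect/other alleles) to exercise harmonization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigurationError
from .io import ROLE_CODES

_EPOCH = np.datetime64("2004-01-01")
_MAX_START_OFFSET_DAYS = 7200  # keeps start dates inside 2004Q1-2023Q4

_BASES = np.array(list("ACGT"))
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class InjectedSignal:
    """One drug–event association to plant in the simulated reports."""

    drug: str
    pt: str
    target_ror: float
    tto_scale_alpha: float
    tto_shape_beta: float

    def __post_init__(self):
        if self.target_ror <= 0:
            raise ConfigurationError("target_ror must be > 0")
        if self.tto_scale_alpha <= 0 or self.tto_shape_beta <= 0:
            raise ConfigurationError("Weibull scale and shape must be > 0")


@dataclass
class ReportSimConfig:
    """Configuration of one simulated spontaneous-report extract."""

    n_reports: int
    drugs: dict[str, float]
    psychiatric_pts: list[str]
    other_pts: list[str]
    injected_signals: list[InjectedSignal] = field(default_factory=list)
    sex_ratio: float = 0.5
    #: (low, high, weight) inclusive integer age bins of a mixture.
    age_distribution: list[tuple[int, int, float]] = field(
        default_factory=lambda: [(0, 17, 0.05), (18, 64, 0.60), (65, 85, 0.30), (86, 100, 0.05)]
    )
    role_probs: dict[str, float] = field(default_factory=lambda: {"PS": 1.0})
    duplicate_rate: float = 0.0
    missing_demo_rate: float = 0.0
    background_tto_alpha: float = 90.0
    background_tto_beta: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_reports <= 0:
            raise ConfigurationError("n_reports must be positive")
        share_sum = sum(self.drugs.values())
        if share_sum > 1.0 + 1e-12:
            raise ConfigurationError(f"drug shares sum to {share_sum:.4f} > 1")
        if any(s < 0 for s in self.drugs.values()):
            raise ConfigurationError("drug shares must be non-negative")
        for frac, name in [
            (self.sex_ratio, "sex_ratio"),
            (self.duplicate_rate, "duplicate_rate"),
            (self.missing_demo_rate, "missing_demo_rate"),
        ]:
            if not 0.0 <= frac < 1.0 and not (name == "sex_ratio" and frac == 1.0):
                raise ConfigurationError(f"{name}={frac} outside its allowed range")
        if set(self.role_probs) - set(ROLE_CODES):
            raise ConfigurationError(f"role codes must be a subset of {ROLE_CODES}")
        if abs(sum(self.role_probs.values()) - 1.0) > 1e-9:
            raise ConfigurationError("role_probs must sum to 1")
        for sig in self.injected_signals:
            if sig.drug not in self.drugs:
                raise ConfigurationError(f"signal drug {sig.drug!r} not in drug list")
            if sig.pt not in self.psychiatric_pts and sig.pt not in self.other_pts:
                raise ConfigurationError(f"signal PT {sig.pt!r} not in the PT vocabulary")

    @property
    def pt_vocabulary(self) -> list[str]:
        return list(self.psychiatric_pts) + list(self.other_pts)


def solve_cell_probability(odds_ratio: float, p_drug: float, p_pt: float) -> float:
    """Joint probability ``a`` of (drug, event) with both margins fixed.

    Solves ``a·d / (b·c) = odds_ratio`` with ``b = p_drug − a``,
    ``c = p_pt − a``, ``d = 1 − p_drug − p_pt + a``; the unique root inside
    the Fréchet bounds is returned.
    """
    if not (0 < p_drug < 1 and 0 < p_pt < 1):
        raise ConfigurationError("margins must lie strictly inside (0, 1)")
    lo = max(0.0, p_drug + p_pt - 1.0)
    hi = min(p_drug, p_pt)
    if odds_ratio == 1.0:
        return p_drug * p_pt
    A = odds_ratio - 1.0
    B = -((odds_ratio - 1.0) * (p_drug + p_pt) + 1.0)
    C = odds_ratio * p_drug * p_pt
    disc = B * B - 4.0 * A * C
    if disc < 0:
        raise ConfigurationError("no real solution for the requested odds ratio")
    root = math.sqrt(disc)
    candidates = [(-B - root) / (2 * A), (-B + root) / (2 * A)]
    for a in candidates:
        if lo < a < hi:
            return a
    raise ConfigurationError(
        f"target odds ratio {odds_ratio} infeasible for margins ({p_drug}, {p_pt})"
    )


def _pt_probability_vectors(config: ReportSimConfig, drug_names):
    """Per-drug categorical distribution over the PT vocabulary."""
    pts = config.pt_vocabulary
    n_pts = len(pts)
    pt_index = {p: i for i, p in enumerate(pts)}
    p_pt = 1.0 / n_pts  # uniform baseline margin per PT

    conditional = {}  # (drug involved?) per signal PT: P(pt | signal drug), P(pt | other)
    for sig in config.injected_signals:
        p_d = config.drugs[sig.drug]
        a = solve_cell_probability(sig.target_ror, p_d, p_pt)
        cond_in = a / p_d
        cond_out = (p_pt - a) / (1.0 - p_d)
        if not (0 < cond_in < 1 and 0 <= cond_out < 1):
            raise ConfigurationError(
                f"target_ror={sig.target_ror} pushes cell probabilities outside [0, 1]"
            )
        conditional[(sig.drug, sig.pt)] = (cond_in, cond_out)

    vectors = {}
    for drug in drug_names:
        probs = np.full(n_pts, 1.0 / n_pts)
        fixed = {}
        for (sig_drug, sig_pt), (cond_in, cond_out) in conditional.items():
            fixed[pt_index[sig_pt]] = cond_in if drug == sig_drug else cond_out
        if fixed:
            fixed_mass = sum(fixed.values())
            if fixed_mass >= 1.0:
                raise ConfigurationError("injected signals exhaust the PT probability mass")
            free = np.array([i for i in range(n_pts) if i not in fixed])
            probs[free] = (1.0 - fixed_mass) / free.size
            for i, p in fixed.items():
                probs[i] = p
        vectors[drug] = probs
    return vectors


def simulate_reports(config: ReportSimConfig) -> pd.DataFrame:
    """Generate a spontaneous-report table with known ground truth.

    Returns a frame with the canonical report columns plus three ground-truth
    columns that are not part of the on-disk format: ``superseded`` (row is an
    outdated case version that deduplication must remove), ``is_signal`` (row
    belongs to an injected drug–event pair) and ``tto_days`` (the raw Weibull
    draw before rounding into dates).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_reports

    drug_names = list(config.drugs)
    drug_shares = [config.drugs[d] for d in drug_names]
    rest = 1.0 - sum(drug_shares)
    if rest > 1e-12:
        drug_names.append("OTHER")
        drug_shares.append(rest)
    shares = np.asarray(drug_shares) / sum(drug_shares)

    pt_vectors = _pt_probability_vectors(config, drug_names)
    pts = np.asarray(config.pt_vocabulary)

    drug_idx = rng.choice(len(drug_names), size=n, p=shares)
    pt_idx = np.empty(n, dtype=np.int64)
    for k, drug in enumerate(drug_names):
        mask = drug_idx == k
        if mask.any():
            pt_idx[mask] = rng.choice(pts.size, size=int(mask.sum()), p=pt_vectors[drug])

    roles = rng.choice(list(config.role_probs), size=n, p=list(config.role_probs.values()))

    sex = np.where(rng.random(n) < config.sex_ratio, "F", "M")
    sex[rng.random(n) < config.missing_demo_rate] = "U"

    bins = config.age_distribution
    weights = np.asarray([w for _, _, w in bins], dtype=float)
    weights = weights / weights.sum()
    bin_idx = rng.choice(len(bins), size=n, p=weights)
    age = np.empty(n, dtype=float)
    for j, (lo, hi, _) in enumerate(bins):
        mask = bin_idx == j
        if mask.any():
            age[mask] = rng.integers(lo, hi + 1, size=int(mask.sum()))
    age[rng.random(n) < config.missing_demo_rate] = np.nan

    tto = config.background_tto_alpha * rng.weibull(config.background_tto_beta, size=n)
    is_signal = np.zeros(n, dtype=bool)
    drug_of = np.asarray(drug_names)[drug_idx]
    pt_of = pts[pt_idx]
    for sig in config.injected_signals:
        mask = (drug_of == sig.drug) & (pt_of == sig.pt)
        if mask.any():
            tto[mask] = sig.tto_scale_alpha * rng.weibull(sig.tto_shape_beta, size=int(mask.sum()))
            is_signal |= mask

    start_offset = rng.integers(0, _MAX_START_OFFSET_DAYS, size=n)
    start_date = _EPOCH + start_offset.astype("timedelta64[D]")

    base = pd.DataFrame(
        {
            "report_id": [f"R{i:07d}" for i in range(n)],
            "case_id": [f"C{i:07d}" for i in range(n)],
            "version": 0,
            "drug_name": drug_of,
            "role_code": roles,
            "pt_name": pt_of,
            "sex": sex,
            "age_years": age,
            "event_date": pd.to_datetime(start_date) + pd.to_timedelta(np.rint(tto), unit="D"),
            "start_date": pd.to_datetime(start_date),
            "superseded": False,
            "is_signal": is_signal,
            "tto_days": tto,
        }
    )

    n_dup = int(round(config.duplicate_rate * n))
    if n_dup:
        dup_pos = rng.choice(n, size=n_dup, replace=False)
        dups = base.iloc[dup_pos].copy()
        dups["report_id"] = [f"R{n + j:07d}" for j in range(n_dup)]
        dups["version"] = 1
        base.loc[base.index[dup_pos], "superseded"] = True
        base = pd.concat([base, dups], ignore_index=True)

    return base


def simulate_tto_sample(alpha: float, beta: float, n: int, seed: int | np.random.Generator = 0):
    """Raw Weibull(scale=alpha, shape=beta) time-to-onset draws, in days."""
    if alpha <= 0 or beta <= 0:
        raise ConfigurationError("Weibull scale and shape must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return alpha * rng.weibull(beta, size=n)


# --- GWAS summary statistics ------------------------------------------------

_GWS_Z = float(sps.norm.isf(5e-8 / 2.0))  # two-sided genome-wide significance


@dataclass
class GwasSimConfig:
    """Configuration for a two-trait summary-statistic simulation."""

    n_snps: int
    n_instruments: int
    causal_beta: float = 0.0
    instrument_strength: float = 0.05
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    sample_n_exposure: int = 100_000
    sample_n_outcome: int = 100_000
    palindromic_rate: float = 0.05
    allele_flip_rate: float = 0.30
    seed: int = 0

    def __post_init__(self):
        if self.n_snps <= 0 or self.n_instruments <= 0:
            raise ConfigurationError("n_snps and n_instruments must be positive")
        if self.n_instruments > self.n_snps:
            raise ConfigurationError("n_instruments cannot exceed n_snps")
        if self.sample_n_exposure <= 1 or self.sample_n_outcome <= 1:
            raise ConfigurationError("sample sizes must exceed 1")


def _draw_alleles(rng: np.random.Generator, n: int, palindromic_rate: float):
    """Effect/other allele pairs; ~palindromic_rate of them strand-ambiguous."""
    eff = np.empty(n, dtype="<U1")
    oth = np.empty(n, dtype="<U1")
    palindromic = rng.random(n) < palindromic_rate
    for i in range(n):
        if palindromic[i]:
            eff[i] = rng.choice(_BASES)
            oth[i] = _COMPLEMENT[eff[i]]
        else:
            while True:
                pair = rng.choice(_BASES, size=2, replace=False)
                if _COMPLEMENT[pair[0]] != pair[1]:
                    break
            eff[i], oth[i] = pair
    return eff, oth, palindromic


def simulate_gwas(config: GwasSimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Exposure and outcome summary-statistic tables with known causal effect.

    The first ``n_instruments`` SNPs (ids ``rs0000``…) carry positive true
    exposure effects sized so their exposure p-values fall below 5e-8 by
    construction; the rest are null. Outcome effects are
    ``causal_beta × true exposure effect + pleiotropy + noise``. Palindromic
    SNPs receive allele frequencies inside the ambiguous band, and a fraction
    of outcome rows have effect/other alleles swapped (with beta negated), so
    harmonization has real work to do.
    """
    rng = np.random.default_rng(config.seed)
    m, k = config.n_snps, config.n_instruments

    snp = np.array([f"rs{i:04d}" for i in range(m)])
    chrom = (np.arange(m) % 22) + 1
    pos = 1_000_000 + (np.arange(m) // 22) * 25_000_000 + rng.integers(0, 2_000_000, size=m)

    se_exp = (1.0 / math.sqrt(config.sample_n_exposure)) * rng.uniform(0.9, 1.1, size=m)
    se_out = (1.0 / math.sqrt(config.sample_n_outcome)) * rng.uniform(0.9, 1.1, size=m)

    b_true = np.zeros(m)
    raw = config.instrument_strength * (0.3 + np.abs(rng.standard_normal(k)))
    b_true[:k] = np.maximum(raw, (_GWS_Z + 3.5) * se_exp[:k])

    beta_exp = b_true + rng.standard_normal(m) * se_exp
    # guarantee instrument significance even against a 3.5-sigma noise draw
    weak = (np.abs(beta_exp[:k]) / se_exp[:k]) < _GWS_Z
    beta_exp[:k][weak] = (_GWS_Z + 0.1) * se_exp[:k][weak]
    pval_exp = 2.0 * sps.norm.sf(np.abs(beta_exp) / se_exp)

    pleio = np.zeros(m)
    if config.pleiotropy_mean != 0.0 or config.pleiotropy_sd > 0.0:
        pleio[:k] = config.pleiotropy_mean + config.pleiotropy_sd * rng.standard_normal(k)
    beta_out = config.causal_beta * b_true + pleio + rng.standard_normal(m) * se_out
    pval_out = 2.0 * sps.norm.sf(np.abs(beta_out) / se_out)

    eff, oth, palindromic = _draw_alleles(rng, m, config.palindromic_rate)
    eaf = rng.uniform(0.05, 0.95, size=m)
    eaf[palindromic] = rng.uniform(0.43, 0.57, size=int(palindromic.sum()))

    exposure = pd.DataFrame(
        {
            "snp": snp,
            "chrom": chrom,
            "pos": pos,
            "effect_allele": eff,
            "other_allele": oth,
            "beta": beta_exp,
            "se": se_exp,
            "pval": np.clip(pval_exp, 1e-320, 1.0),
            "eaf": eaf,
        }
    )

    outcome = exposure.copy()
    outcome["beta"] = beta_out
    outcome["se"] = se_out
    outcome["pval"] = np.clip(pval_out, 1e-320, 1.0)
    flip = rng.random(m) < config.allele_flip_rate
    outcome.loc[flip, ["effect_allele", "other_allele"]] = outcome.loc[
        flip, ["other_allele", "effect_allele"]
    ].to_numpy()
    outcome.loc[flip, "beta"] = -outcome.loc[flip, "beta"]
    outcome.loc[flip, "eaf"] = 1.0 - outcome.loc[flip, "eaf"]
    return exposure, outcome
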