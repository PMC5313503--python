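"""Synthetic respondents from a second-order factor model.

Responses are generated from the hierarchical structure the instrument's
factor analysis supports: one second-order depression severity g, three
first-order factors f_k = gamma_k g + sqrt(1 - gamma_k^2) eta_k, and per
item a standard-normal latent y_i = lambda_i f_k(i) + sqrt(1 - lambda_i^2)
eps_i, endorsed when y_i exceeds a common threshold tau.  lambda are the
published standardized loadings and gamma = (0.77, 0.70, 0.91).

The score-level moments reported for the two groups (non-clinical mean 6.5,
sd 6.0; clinical mean 28.5, sd 6.5) drive two generators:

* :func:`calibrate` fixes tau analytically so the expected non-clinical
  total is the non-clinical target, and finds the clinical g-shift mu by
  root bracketing so the expected clinical total matches the clinical
  target.  Only the group *means* are matched — per-item base rates are
  unidentifiable from score moments, so a single common tau is the minimal
  assumption, and the score sd is whatever the latent model implies.
* :func:`generate_score_surrogate` draws total scores directly from the two
  printed Normal moments (rounded, clipped to [0, 41]) for analyses where
  both moments matter, e.g. ROC operating points.

Retest responses shrink a subject's zero-mean latent deviation toward its
group mean by rho and top it up with a fresh structured deviation, which
preserves the marginal endorsement rates and gives corr(y, y') = rho per
item; rho is calibrated to a target score correlation by bisection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import instrument
from .errors import ValidationError

__all__ = [
    "GeneratorConfig",
    "SyntheticCohort",
    "default_config",
    "calibrate",
    "calibrate_retest",
    "expected_total_score",
    "generate",
    "generate_retest",
    "generate_score_surrogate",
    "cohort_to_frame",
]

Group = Literal["clinical", "nonclinical"]
_FACTOR_ORDER = ("cognitive", "somatic", "affective")


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the hierarchical response generator.

    ``threshold`` (tau), ``clinical_shift`` (mu, the clinical group's mean
    on the second-order factor) and ``retest_stability`` (rho) start unset
    and are filled in by the calibration routines.
    """

    loadings: dict[int, float]
    second_order: dict[str, float]
    item_factor: dict[int, str]
    threshold: float | None = None
    clinical_shift: float | None = None
    retest_stability: float | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        for iid, lam in self.loadings.items():
            if not 0 < lam < 1 or not math.isfinite(lam):
                raise ValidationError(f"item {iid}: loading must lie in (0, 1)")
            if iid not in self.item_factor:
                raise ValidationError(f"item {iid}: no factor membership")
        if set(self.item_factor) != set(self.loadings):
            raise ValidationError("loadings and factor map must cover the same items")

    @property
    def item_ids(self) -> list[int]:
        return sorted(self.loadings)

    def _arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        ids = self.item_ids
        lam = np.array([self.loadings[i] for i in ids])
        fidx = np.array([_FACTOR_ORDER.index(self.item_factor[i]) for i in ids])
        gam = np.array([self.second_order[f] for f in _FACTOR_ORDER])
        return lam, fidx, gam


@dataclass(frozen=True)
class SyntheticCohort:
    """Simulated 0/1 responses with group labels and total scores."""

    responses: pd.DataFrame  # subjects x I1..I41
    groups: np.ndarray
    scores: np.ndarray
    latent: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    latent_mean: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    def __len__(self) -> int:
        return len(self.responses)


def default_config() -> GeneratorConfig:
    """The instrument's published loadings; tau/mu/rho left for calibration."""
    item_factor = {
        i: name for name, ids in instrument.FACTOR_ITEMS.items() for i in ids
    }
    return GeneratorConfig(
        loadings=dict(instrument.FACTOR_LOADINGS),
        second_order=dict(instrument.SECOND_ORDER_LOADINGS),
        item_factor=item_factor,
    )


def expected_total_score(config: GeneratorConfig, group: Group) -> float:
    """Model-implied expected total: sum_i (1 - Phi(tau - lambda_i gamma_k mu_g))."""
    if config.threshold is None:
        raise ValidationError("config is not calibrated (threshold unset)")
    lam, fidx, gam = config._arrays()
    mu = 0.0 if group == "nonclinical" else config.clinical_shift
    if mu is None:
        raise ValidationError("config is not calibrated (clinical_shift unset)")
    return float(np.sum(1 - stats.norm.cdf(config.threshold - lam * gam[fidx] * mu)))


def calibrate(
    config: GeneratorConfig,
    target_nonclinical_mean: float = instrument.NONCLINICAL_MEAN,
    target_clinical_mean: float = instrument.CLINICAL_MEAN,
) -> GeneratorConfig:
    """Fix tau and the clinical shift mu to match the two group mean scores.

    With mu = 0 every item endorsement probability is 1 - Phi(tau), so the
    non-clinical equation k (1 - Phi(tau)) = target has the closed form
    tau = Phi^{-1}(1 - target / k).  mu is then the root of the monotone
    clinical expected-score equation, found by bracketing.
    """
    k = len(config.loadings)
    for t in (target_nonclinical_mean, target_clinical_mean):
        if not 0 < t < k:
            raise ValidationError(f"target mean {t} must lie strictly inside (0, {k})")
    tau = float(stats.norm.ppf(1 - target_nonclinical_mean / k))
    lam, fidx, gam = config._arrays()

    def clinical_gap(mu: float) -> float:
        return float(
            np.sum(1 - stats.norm.cdf(tau - lam * gam[fidx] * mu)) - target_clinical_mean
        )

    lo, hi = 0.0, 100.0
    if clinical_gap(lo) > 0 or clinical_gap(hi) < 0:
        raise ValidationError("clinical target not bracketed by the shift search range")
    mu = float(optimize.brentq(clinical_gap, lo, hi, xtol=1e-10))
    return replace(config, threshold=tau, clinical_shift=mu)


def _draw_latent(
    config: GeneratorConfig, n: int, rng: np.random.Generator
) -> np.ndarray:
    """One zero-mean structured deviation per subject: shared g and eta plus eps."""
    lam, fidx, gam = config._arrays()
    g = rng.standard_normal(n)
    eta = rng.standard_normal((n, len(_FACTOR_ORDER)))
    f = gam * g[:, None] + np.sqrt(1 - gam**2) * eta
    eps = rng.standard_normal((n, lam.size))
    return lam * f[:, fidx] + np.sqrt(1 - lam**2) * eps


def _finish(config: GeneratorConfig, mean: np.ndarray, latent: np.ndarray, groups: np.ndarray, prefix: str) -> SyntheticCohort:
    x = (latent > config.threshold).astype(np.int8)
    ids = config.item_ids
    df = pd.DataFrame(
        x,
        columns=[f"I{i}" for i in ids],
        index=[f"{prefix}{j + 1:05d}" for j in range(len(x))],
    )
    df.index.name = "subject_id"
    return SyntheticCohort(
        responses=df,
        groups=groups,
        scores=x.sum(axis=1).astype(int),
        latent=latent,
        latent_mean=mean,
    )


def generate(
    config: GeneratorConfig, n: int, group: Group, seed: int | None = None
) -> SyntheticCohort:
    """Draw ``n`` respondents of one group from the calibrated model."""
    if n < 1:
        raise ValidationError("n must be >= 1")
    if group not in ("clinical", "nonclinical"):
        raise ValidationError(f"unknown group {group!r}")
    if config.threshold is None or (group == "clinical" and config.clinical_shift is None):
        raise ValidationError("config must be calibrated before generating")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    lam, fidx, gam = config._arrays()
    mu = 0.0 if group == "nonclinical" else float(config.clinical_shift)
    mean = (lam * gam[fidx] * mu)[None, :].repeat(n, axis=0)
    latent = mean + _draw_latent(config, n, rng)
    groups = np.array([group] * n)
    return _finish(config, mean, latent, groups, "nc" if group == "nonclinical" else "cl")


def generate_retest(
    cohort: SyntheticCohort, config: GeneratorConfig, seed: int | None = None
) -> SyntheticCohort:
    """Time-2 responses for an existing cohort at stability rho."""
    rho = config.retest_stability
    if rho is None or not 0 <= rho <= 1:
        raise ValidationError("retest_stability must be set in [0, 1]")
    if cohort.latent is None:
        raise ValidationError("cohort carries no latent draws")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = len(cohort)
    u = cohort.latent - cohort.latent_mean
    fresh = _draw_latent(config, n, rng)
    latent2 = cohort.latent_mean + rho * u + math.sqrt(1 - rho**2) * fresh
    return _finish(config, cohort.latent_mean, latent2, cohort.groups, "rt")


def calibrate_retest(
    config: GeneratorConfig,
    target_r: float = instrument.RETEST_CORRELATION,
    n: int = 5000,
    seed: int = 0,
    tol: float = 1e-4,
) -> GeneratorConfig:
    """Set rho so the simulated time-1/time-2 score correlation hits ``target_r``.

    Uses common random numbers: the time-1 cohort and the fresh deviation
    are drawn once, so the achieved correlation is a continuous increasing
    function of rho and plain bisection applies.  The calibration sample is
    non-clinical, matching how retest stability is usually studied.
    """
    if not 0 < target_r < 1:
        raise ValidationError("target retest correlation must lie in (0, 1)")
    cal = config if config.threshold is not None else calibrate(config)
    cohort = generate(cal, n, "nonclinical", seed=seed)
    rng = np.random.default_rng(seed + 1)
    fresh = _draw_latent(cal, n, rng)
    u = cohort.latent - cohort.latent_mean
    s1 = cohort.scores.astype(float)

    def achieved(rho: float) -> float:
        latent2 = cohort.latent_mean + rho * u + math.sqrt(1 - rho**2) * fresh
        s2 = (latent2 > cal.threshold).sum(axis=1).astype(float)
        return float(np.corrcoef(s1, s2)[0, 1])

    lo, hi = 0.0, 1.0
    if achieved(1.0) < target_r:
        raise ValidationError("target retest correlation not reachable (rho bracket fails)")
    while hi - lo > tol:
        mid = (lo + hi) / 2
        if achieved(mid) < target_r:
            lo = mid
        else:
            hi = mid
    return replace(cal, retest_stability=(lo + hi) / 2)


def generate_score_surrogate(
    n_clin: int, n_nonclin: int, seed: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Total scores drawn directly from the printed group moments.

    Clinical scores ~ Normal(28.5, 6.5), non-clinical ~ Normal(6.5, 6.0),
    rounded to integers and clipped to [0, 41].  Returns (scores, labels)
    with label 1 = clinical; non-clinical subjects come first.
    """
    if n_clin < 1 or n_nonclin < 1:
        raise ValidationError("both group sizes must be positive")
    rng = np.random.default_rng(seed)
    nc = rng.normal(instrument.NONCLINICAL_MEAN, instrument.NONCLINICAL_SD, n_nonclin)
    cl = rng.normal(instrument.CLINICAL_MEAN, instrument.CLINICAL_SD, n_clin)
    scores = np.clip(np.rint(np.concatenate([nc, cl])), 0, 41).astype(int)
    labels = np.concatenate([np.zeros(n_nonclin, dtype=int), np.ones(n_clin, dtype=int)])
    return scores, labels


def cohort_to_frame(cohort: SyntheticCohort) -> pd.DataFrame:
    """The cohort in the responses-CSV dialect (subject_id, group, I1..I41)."""
    df = cohort.responses.reset_index()
    df.insert(1, "group", cohort.groups)
    return df
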