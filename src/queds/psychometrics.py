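"""Validation battery: reliability, known-groups separation, ROC, and
comparisons of correlations.

All operations work on plain arrays/DataFrames so they apply equally to
study data and to cohorts from :mod:`queds.synthetic`.  Conventions:

* dichotomous responses are 0/1 tables, subjects in rows, items in columns;
* group labels are 1 = clinical, 0 = non-clinical;
* a respondent is predicted clinical when score >= threshold, so
  sensitivity(t) = P(score >= t | clinical) and
  specificity(t) = P(score < t | non-clinical);
* the AUC is the pair-counting (Mann-Whitney) statistic with ties worth 1/2.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

__all__ = [
    "RocResult",
    "cronbach_alpha",
    "average_interitem_correlation",
    "test_retest",
    "known_groups_ttest",
    "roc_analysis",
    "sensitivity_specificity",
    "compare_dependent_correlations",
    "compare_independent_correlations",
    "validation_report",
]


def _as_matrix(responses) -> np.ndarray:
    x = np.asarray(responses, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValidationError("need a subjects x items table with >= 2 of each")
    return x


def cronbach_alpha(responses) -> float:
    """Cronbach's alpha (= KR-20 on dichotomous items).

    alpha = k/(k-1) * (1 - sum of item variances / variance of the total
    score).  Returns NaN (with a warning) when the total score has zero
    variance, where the coefficient is undefined.
    """
    x = _as_matrix(responses)
    k = x.shape[1]
    total_var = x.sum(axis=1).var(ddof=1)
    if total_var == 0:
        warnings.warn("total score has zero variance; alpha undefined", stacklevel=2)
        return float("nan")
    item_var = x.var(axis=0, ddof=1).sum()
    return float(k / (k - 1) * (1 - item_var / total_var))


def average_interitem_correlation(responses) -> float:
    """Mean product-moment correlation over all item pairs.

    Constant columns carry no correlation information and are dropped with
    a warning; fewer than two informative columns is an error.
    """
    x = _as_matrix(responses)
    keep = x.std(axis=0) > 0
    if not keep.all():
        warnings.warn(
            f"excluding {int((~keep).sum())} constant item column(s)", stacklevel=2
        )
    x = x[:, keep]
    if x.shape[1] < 2:
        raise ValidationError("fewer than two non-constant item columns")
    r = np.corrcoef(x, rowvar=False)
    iu = np.triu_indices_from(r, k=1)
    return float(r[iu].mean())


def test_retest(scores_t1, scores_t2) -> float:
    """Product-moment correlation between paired administrations."""
    a = np.asarray(scores_t1, dtype=float)
    b = np.asarray(scores_t2, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 3:
        raise ValidationError("need paired score vectors of equal length >= 3")
    if a.std() == 0 or b.std() == 0:
        warnings.warn("zero variance in a score vector; correlation undefined", stacklevel=2)
        return float("nan")
    return float(stats.pearsonr(a, b).statistic)


def known_groups_ttest(clinical_scores, nonclinical_scores) -> dict:
    """Pooled-variance two-sample t-test of the group difference.

    The statistic is computed on (non-clinical minus clinical), so a scale
    on which the clinical group scores higher yields a negative t.  Degrees
    of freedom are n1 + n2 - 2.
    """
    c = np.asarray(clinical_scores, dtype=float)
    nc = np.asarray(nonclinical_scores, dtype=float)
    if c.size < 2 or nc.size < 2:
        raise ValidationError("both groups need >= 2 observations")
    n1, n2 = nc.size, c.size
    sp2 = ((n1 - 1) * nc.var(ddof=1) + (n2 - 1) * c.var(ddof=1)) / (n1 + n2 - 2)
    if sp2 == 0:
        raise ValidationError("degenerate (zero) pooled variance")
    t = (nc.mean() - c.mean()) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
    df = n1 + n2 - 2
    p = 2 * stats.t.sf(abs(t), df)
    return {"t": float(t), "df": int(df), "p": float(p)}


@dataclass(frozen=True)
class RocResult:
    """ROC table, pair-counting AUC and the Youden-optimal threshold."""

    points: tuple[tuple[float, float, float], ...]  # (threshold, sens, spec)
    auc: float
    optimal_threshold: float
    youden_j: float


def _pair_count_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    # Mann-Whitney rank identity to the pair-counting statistic, ties = 1/2
    ranks = stats.rankdata(scores)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    r1 = ranks[labels == 1].sum()
    return float((r1 - n1 * (n1 + 1) / 2) / (n1 * n0))


def roc_analysis(scores, labels) -> RocResult:
    """ROC analysis of a score against clinical (1) / non-clinical (0) labels.

    Candidate thresholds are the distinct observed scores plus one above
    the maximum (the 'predict nobody' operating point).  The optimal
    threshold maximizes Youden's J = sensitivity + specificity - 1, with
    ties going to the smallest threshold.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape or s.ndim != 1:
        raise ValidationError("scores and labels must be equal-length vectors")
    if y.min() == y.max():
        raise ValidationError("both classes must be present")
    auc = _pair_count_auc(s, y)
    thresholds = sorted(set(s.tolist()) | {float(s.max()) + 1})
    points = []
    best: tuple[float, float] | None = None  # (-J, threshold)
    for t in thresholds:
        sens, spec = sensitivity_specificity(s, y, t)
        points.append((float(t), sens, spec))
        j = sens + spec - 1
        key = (-j, t)
        if best is None or key < best:
            best = key
    assert best is not None
    return RocResult(tuple(points), auc, best[1], -best[0])


def sensitivity_specificity(scores, labels, threshold: float) -> tuple[float, float]:
    """(sensitivity, specificity) at a threshold under the >= positivity rule."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    sens = float((s[y == 1] >= threshold).mean())
    spec = float((s[y == 0] < threshold).mean())
    return sens, spec


def _check_r(*rs: float) -> None:
    for r in rs:
        if not -1 < r < 1:
            raise ValidationError(f"correlation {r} outside (-1, 1); Fisher transform undefined")


def compare_dependent_correlations(r12: float, r13: float, r23: float, n: int) -> dict:
    """Steiger's Z for two correlations sharing variable 1, measured on one sample.

    Uses the pooled-r form: the Fisher-transformed difference z12 - z13 is
    scaled by the covariance of dependent correlations evaluated at
    rbar = (r12 + r13)/2.
    """
    _check_r(r12, r13, r23)
    if n <= 3:
        raise ValidationError("need n > 3")
    z12, z13 = math.atanh(r12), math.atanh(r13)
    rbar = (r12 + r13) / 2
    psi = r23 * (1 - 2 * rbar**2) - 0.5 * rbar**2 * (1 - 2 * rbar**2 - r23**2)
    s = psi / (1 - rbar**2) ** 2
    z = (z12 - z13) * math.sqrt((n - 3) / (2 * (1 - s)))
    return {"z": float(z), "p": float(2 * stats.norm.sf(abs(z)))}


def compare_independent_correlations(r1: float, n1: int, r2: float, n2: int) -> dict:
    """Fisher z test for correlations from two independent samples."""
    _check_r(r1, r2)
    if n1 <= 3 or n2 <= 3:
        raise ValidationError("need n > 3 in both samples")
    z = (math.atanh(r1) - math.atanh(r2)) / math.sqrt(1 / (n1 - 3) + 1 / (n2 - 3))
    return {"z": float(z), "p": float(2 * stats.norm.sf(abs(z)))}


# ---------------------------------------------------------------------------
# batch report


def validation_report(
    responses: pd.DataFrame,
    retest: pd.DataFrame | None = None,
) -> dict:
    """Run the whole battery on a responses table.

    ``responses`` uses the cohort CSV dialect: columns ``subject_id``,
    ``group`` ('clinical'/'nonclinical') and ``I1``..``I41``.  ``retest``,
    when given, is a second table with the same subjects at time 2; the
    retest correlation is computed on the intersection of subject ids.
    """
    from .context import builtin_queds

    ctx, factors = builtin_queds()
    item_cols = [f"I{q}" for q in ctx.item_ids]
    missing = [c for c in ["subject_id", "group", *item_cols] if c not in responses.columns]
    if missing:
        raise ValidationError(f"responses table missing columns: {missing[:4]}...")
    x = responses[item_cols].to_numpy(dtype=float)
    scores = x.sum(axis=1)
    groups = responses["group"].astype(str).to_numpy()

    report: dict = {"n_subjects": int(len(responses))}
    rel: dict = {"alpha_total": cronbach_alpha(x)}
    for f in factors:
        cols = [f"I{q}" for q in sorted(f.item_ids)]
        sub = responses[cols].to_numpy(dtype=float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rel[f"alpha_{f.name}"] = cronbach_alpha(sub)
            rel[f"avg_interitem_r_{f.name}"] = average_interitem_correlation(sub)
    report["reliability"] = rel

    labels = (groups == "clinical").astype(int)
    if 0 < labels.sum() < labels.size:
        tt = known_groups_ttest(scores[labels == 1], scores[labels == 0])
        roc = roc_analysis(scores, labels)
        sens, spec = sensitivity_specificity(scores, labels, roc.optimal_threshold)
        report["known_groups"] = {
            **tt,
            "auc": roc.auc,
            "optimal_threshold": roc.optimal_threshold,
            "youden_j": roc.youden_j,
            "sensitivity": sens,
            "specificity": spec,
        }

    if retest is not None:
        merged = responses.merge(retest, on="subject_id", suffixes=("_t1", "_t2"))
        t1 = merged[[f"{c}_t1" for c in item_cols]].to_numpy(dtype=float).sum(axis=1)
        t2 = merged[[f"{c}_t2" for c in item_cols]].to_numpy(dtype=float).sum(axis=1)
        report["retest"] = {"r": test_retest(t1, t2), "n": int(len(merged))}

    # subscale-total correlation structure with dependent comparisons
    subs = {
        f.name: responses[[f"I{q}" for q in sorted(f.item_ids)]]
        .to_numpy(dtype=float)
        .sum(axis=1)
        for f in factors
    }
    corr: dict = {}
    names = list(subs)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            corr[f"r_{a}_{b}"] = float(np.corrcoef(subs[a], subs[b])[0, 1])
        corr[f"r_{a}_total"] = float(np.corrcoef(subs[a], scores)[0, 1])
    report["subscale_correlations"] = corr
    return report
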