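"""Discrimination and calibration metrics, and the scheme-comparison cascade.

Discrimination: rank-based (Mann-Whitney) AUC with midrank tie handling —
the probability a random presence is scored above a random absence — and
the True Skill Statistic TSS = sensitivity + specificity - 1 swept over
thresholds 0.00, 0.01, ..., 1.00, reporting two standard binarization
rules (threshold maximizing TSS; 10th percentile of presence predictions).
Calibration: weighted Bernoulli deviance.

Scheme comparison follows the usual cascade: Shapiro-Wilk normality on
each sample, Levene homoscedasticity (centered on the mean) across the
pair, then a pooled-variance two-tailed t-test when both hold, otherwise
a two-sided Wilcoxon-Mann-Whitney test, at alpha = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

ALPHA = 0.05


def auc(scores, labels, weights=None) -> float:
    """Weighted Mann-Whitney AUC with midrank tie handling.

    Equals trapezoidal integration of the ROC curve. With weights, each
    presence/absence contributes its weight to the concordance sum.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, float)
    w = np.ones(len(scores)) if weights is None else np.asarray(weights, float)
    pos, neg = labels == 1, labels == 0
    if not pos.any() or not neg.any():
        raise ValueError("AUC needs both classes present")
    order = np.argsort(scores, kind="stable")
    s, l, ww = scores[order], labels[order], w[order]
    wp = np.where(l == 1, ww, 0.0)
    wn = np.where(l == 0, ww, 0.0)
    # group by tied score
    boundaries = np.flatnonzero(np.diff(s)) + 1
    grp_p = np.add.reduceat(wp, np.r_[0, boundaries])
    grp_n = np.add.reduceat(wn, np.r_[0, boundaries])
    cum_n_below = np.concatenate([[0.0], np.cumsum(grp_n)[:-1]])
    conc = np.sum(grp_p * (cum_n_below + 0.5 * grp_n))
    return float(conc / (wp.sum() * wn.sum()))


def weighted_deviance(scores, labels, weights=None,
                      normalization: str = "weights") -> float:
    """Weighted Bernoulli deviance -2 sum w [y ln p + (1-y) ln(1-p)] / norm.

    ``normalization='weights'`` (default) divides by sum(w): the mean
    deviance per unit weight, invariant to rescaling all weights.
    ``normalization='observations'`` divides by the number of rows — the
    convention of the classic BRT cross-validation tooling, under which a
    balanced-weight (WTGB) model's deviance is scaled by sum(w)/n and
    sits far below an unweighted model's on the same rows.
    """
    p = np.asarray(scores, float)
    y = np.asarray(labels, float)
    w = np.ones(len(p)) if weights is None else np.asarray(weights, float)
    if not (len(p) == len(y) == len(w)):
        raise ValueError("scores, labels and weights must have equal length")
    p = np.clip(p, 1e-12, 1 - 1e-12)
    total = -2.0 * np.sum(w * (y * np.log(p) + (1 - y) * np.log1p(-p)))
    if normalization == "weights":
        return float(total / np.sum(w))
    if normalization == "observations":
        return float(total / len(p))
    raise ValueError(f"unknown normalization {normalization!r}")


@dataclass
class TSSProfile:
    """TSS as a function of threshold plus the two selected thresholds."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    tss: np.ndarray
    t_max_tss: float
    tss_at_max: float
    t_p10: float
    tss_at_p10: float

    def as_table(self):
        import pandas as pd
        return pd.DataFrame({"threshold": self.thresholds, "sensitivity": self.sensitivity,
                             "specificity": self.specificity, "tss": self.tss})


def _confusion_rates(scores, labels, t):
    pred = scores >= t
    pos = labels == 1
    sens = np.mean(pred[pos]) if pos.any() else np.nan
    spec = np.mean(~pred[~pos]) if (~pos).any() else np.nan
    return sens, spec


def tss_profile(scores, labels) -> TSSProfile:
    """Sweep thresholds 0.00..1.00 in 0.01 steps; presence is score >= t.

    ``t_max_tss`` is the lowest maximizing threshold; ``t_p10`` is the
    10th percentile (linear interpolation) of the presence scores, with
    its TSS evaluated at that exact threshold.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, float)
    if not ((labels == 1).any() and (labels == 0).any()):
        raise ValueError("TSS needs both classes present")
    ts = np.round(np.arange(101) / 100.0, 2)
    pred = scores[None, :] >= ts[:, None]
    pos = labels == 1
    sens = pred[:, pos].mean(axis=1)
    spec = (~pred[:, ~pos]).mean(axis=1)
    tss = sens + spec - 1.0
    imax = int(np.argmax(tss))  # first (lowest) maximizing threshold
    t10 = float(np.percentile(scores[pos], 10))
    s10, sp10 = _confusion_rates(scores, labels, t10)
    return TSSProfile(ts, sens, spec, tss, float(ts[imax]), float(tss[imax]),
                      t10, float(s10 + sp10 - 1.0))


@dataclass
class ComparisonReport:
    """One pairwise scheme comparison for one species and metric."""

    species: str
    metric: str
    pair: tuple[str, str]
    normality_p: tuple[float, float]
    levene_p: float
    test_used: str  # t_test | wilcoxon_mann_whitney
    statistic: float
    p_value: float
    significant: bool

    def to_dict(self) -> dict:
        return {"species": self.species, "metric": self.metric,
                "pair": list(self.pair),
                "shapiro_p_a": self.normality_p[0], "shapiro_p_b": self.normality_p[1],
                "levene_p": self.levene_p, "test_used": self.test_used,
                "statistic": self.statistic, "p_value": self.p_value,
                "significant": self.significant}


def compare_metric_samples(sample_a, sample_b, species: str = "", metric: str = "",
                           pair: tuple[str, str] = ("A", "B"),
                           alpha: float = ALPHA) -> ComparisonReport:
    """Normality/homoscedasticity cascade, then t-test or rank test.

    Both Shapiro-Wilk p-values and the Levene (center=mean) p-value must
    exceed alpha for the pooled-variance two-tailed t-test; otherwise the
    two-sided Wilcoxon-Mann-Whitney test is used.
    """
    a = np.asarray(sample_a, float)
    b = np.asarray(sample_b, float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each sample needs >= 3 values")
    sw_a = stats.shapiro(a).pvalue
    sw_b = stats.shapiro(b).pvalue
    lev = stats.levene(a, b, center="mean").pvalue
    if sw_a > alpha and sw_b > alpha and lev > alpha:
        res = stats.ttest_ind(a, b, equal_var=True)
        test = "t_test"
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        test = "wilcoxon_mann_whitney"
    return ComparisonReport(species, metric, pair, (float(sw_a), float(sw_b)),
                            float(lev), test, float(res.statistic),
                            float(res.pvalue), bool(res.pvalue < alpha))


@dataclass
class CVMetrics:
    """Per-scheme metric samples assembled the way they are compared.

    TGB schemes contribute the n_folds held-out values of the final
    optimized model; RDM contributes one mean cross-validated value per
    replicate.
    """

    scheme: str
    species: str
    per_fold_auc: np.ndarray
    per_fold_deviance: np.ndarray
    mean_auc: float
    se_auc: float
    mean_deviance: float
    se_deviance: float
    replicate_means: Optional[dict] = None

    def to_dict(self) -> dict:
        d = {"scheme": self.scheme, "species": self.species,
             "mean_auc": self.mean_auc, "se_auc": self.se_auc,
             "mean_deviance": self.mean_deviance, "se_deviance": self.se_deviance,
             "auc_sample": self.per_fold_auc.tolist(),
             "deviance_sample": self.per_fold_deviance.tolist()}
        if self.replicate_means is not None:
            d["replicate_means"] = self.replicate_means
        return d


def _se(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1) / np.sqrt(len(x))) if len(x) > 1 else 0.0


def collect_cv_metrics(models, species: str, scheme: str,
                       expected_folds: Optional[int] = None) -> CVMetrics:
    """Assemble the metric samples for one species x scheme.

    For UTGB/WTGB pass the single CV-selected model (sample = its per-fold
    values, n = n_folds). For RDM pass the list of replicate models
    (sample = per-replicate mean CV values, n = number of replicates).
    """
    if scheme in ("UTGB", "WTGB"):
        model = models[0] if isinstance(models, (list, tuple)) else models
        if model.per_fold_auc is None:
            raise ValueError("model carries no cross-validation metrics")
        aucs = np.asarray(model.per_fold_auc, float)
        devs = np.asarray(model.per_fold_deviance, float)
        if expected_folds is not None and len(aucs) != expected_folds:
            raise ValueError(f"expected {expected_folds} folds, got {len(aucs)}")
        return CVMetrics(scheme, species, aucs, devs, float(aucs.mean()), _se(aucs),
                         float(devs.mean()), _se(devs))
    if scheme == "RDM":
        if not isinstance(models, (list, tuple)) or len(models) < 2:
            raise ValueError("RDM needs >= 2 replicate models")
        aucs = np.array([m.mean_cv_auc for m in models])
        devs = np.array([m.mean_cv_deviance for m in models])
        return CVMetrics(scheme, species, aucs, devs, float(aucs.mean()), _se(aucs),
                         float(devs.mean()), _se(devs),
                         replicate_means={"auc": aucs.tolist(), "deviance": devs.tolist(),
                                          "fold_auc": [np.asarray(m.per_fold_auc, float).tolist()
                                                       for m in models],
                                          "fold_deviance": [np.asarray(m.per_fold_deviance, float).tolist()
                                                            for m in models]})
    raise ValueError(f"unknown scheme {scheme!r}")
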