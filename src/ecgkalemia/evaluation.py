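"""ROC-based model evaluation and comparison.

Per model family and diagnostic threshold this module computes accuracy,
precision, sensitivity, specificity and F1 at the documented decision
threshold, plus AUC with a DeLong 95% confidence interval, and compares
families pairwise with the paired DeLong test on shared test scores.

AUC uses the Mann-Whitney concordance convention (ties count half), which
is exactly the statistic whose variance the DeLong placement components
estimate. Pairwise p-values are reported raw, as is conventional when no
multiplicity correction is pre-specified; a Holm-adjusted column is also
emitted, clearly labelled as an extra.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .errors import ValidationError

__all__ = [
    "ConfusionCounts",
    "EvaluationReport",
    "confusion_metrics",
    "f1_score",
    "roc_auc",
    "delong_variance",
    "delong_test",
    "roc_curve_points",
    "build_report",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Test-set confusion counts at a fixed decision threshold."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValidationError("confusion counts must be non-negative")
        if self.n == 0:
            raise ValidationError("confusion counts sum to zero")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionCounts":
        y_true = np.asarray(y_true).astype(int)
        y_pred = np.asarray(y_pred).astype(int)
        if y_true.shape != y_pred.shape:
            raise ValidationError("y_true and y_pred disagree in shape")
        return cls(
            tp=int(np.sum((y_true == 1) & (y_pred == 1))),
            fp=int(np.sum((y_true == 0) & (y_pred == 1))),
            fn=int(np.sum((y_true == 1) & (y_pred == 0))),
            tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        )


def confusion_metrics(counts: ConfusionCounts) -> dict:
    """Accuracy, precision, sensitivity, specificity from confusion counts.

    A ratio with a zero denominator is reported as None (absent), never
    silently coerced to 0.
    """
    n = counts.n

    def _ratio(num: int, den: int):
        return num / den if den > 0 else None

    return {
        "accuracy": (counts.tp + counts.tn) / n,
        "precision": _ratio(counts.tp, counts.tp + counts.fp),
        "sensitivity": _ratio(counts.tp, counts.tp + counts.fn),
        "specificity": _ratio(counts.tn, counts.tn + counts.fp),
    }


def f1_score(precision, sensitivity) -> float | None:
    """Harmonic mean of precision and sensitivity; 0 when either is 0.

    Returns None when either input is absent (undefined upstream ratio).
    """
    if precision is None or sensitivity is None:
        return None
    if not (0.0 <= precision <= 1.0 and 0.0 <= sensitivity <= 1.0):
        raise ValidationError("precision and sensitivity must lie in [0, 1]")
    if precision == 0.0 or sensitivity == 0.0:
        return 0.0
    return 2.0 * precision * sensitivity / (precision + sensitivity)


# ---------------------------------------------------------------------------
# AUC and DeLong machinery
# ---------------------------------------------------------------------------

def _check_binary(y_true: np.ndarray) -> np.ndarray:
    y = np.asarray(y_true).astype(int)
    classes = np.unique(y)
    if not np.array_equal(classes, [0, 1]):
        raise ValidationError(
            f"y_true must contain both classes 0 and 1, got classes {classes}"
        )
    return y


def roc_auc(y_true, scores) -> float:
    """Mann-Whitney AUC: P(score+ > score-) with half credit for ties.

    Computed from mid-ranks, which equals the trapezoidal area under the
    empirical ROC curve.
    """
    y = _check_binary(y_true)
    s = np.asarray(scores, dtype=float)
    if s.shape != y.shape:
        raise ValidationError("scores and y_true disagree in shape")
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    ranks = rankdata(s)  # mid-ranks handle ties with half credit
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0)
                 / (n_pos * n_neg))


def _placements(y: np.ndarray, s: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """DeLong placement values V10 (per positive) and V01 (per negative)."""
    pos, neg = s[y == 1], s[y == 0]
    # psi(x, y) = 1[x > y] + 0.5 * 1[x == y], vectorised by broadcasting
    cmp = (pos[:, None] > neg[None, :]).astype(float)
    cmp += 0.5 * (pos[:, None] == neg[None, :])
    return cmp.mean(axis=1), 1.0 - cmp.mean(axis=0)


def delong_variance(y_true, scores) -> tuple[float, float]:
    """AUC and its DeLong variance from placement-value dispersions.

    var = S10/n+ + S01/n- with S10, S01 the sample variances of the
    positive and negative placement values. The 95% CI is
    auc +- 1.96*sqrt(var), clipped to [0, 1].
    """
    y = _check_binary(y_true)
    s = np.asarray(scores, dtype=float)
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    if n_pos < 2 or n_neg < 2:
        raise ValidationError(
            f"need >= 2 samples per class, got {n_pos} positive / {n_neg} negative"
        )
    v10, v01 = _placements(y, s)
    auc = float(v10.mean())
    var = float(np.var(v10, ddof=1) / n_pos + np.var(v01, ddof=1) / n_neg)
    return auc, var


def auc_confidence_interval(y_true, scores, alpha: float = 0.05):
    """(auc, ci_low, ci_high) from the DeLong normal approximation."""
    auc, var = delong_variance(y_true, scores)
    z = norm.ppf(1.0 - alpha / 2.0)
    half = z * np.sqrt(max(var, 0.0))
    return auc, float(max(0.0, auc - half)), float(min(1.0, auc + half))


def delong_test(y_true, scores_a, scores_b) -> tuple[float, float]:
    """Paired DeLong test for the difference of two correlated AUCs.

    z = (auc_a - auc_b) / sqrt(var_a + var_b - 2 cov_ab), with the
    covariance estimated from the shared placement components; returns
    (z, two-sided p). Equal score vectors give z = 0, p = 1; a zero
    variance of the difference with unequal AUCs is a numerical error.
    """
    y = _check_binary(y_true)
    sa = np.asarray(scores_a, dtype=float)
    sb = np.asarray(scores_b, dtype=float)
    if sa.shape != y.shape or sb.shape != y.shape:
        raise ValidationError("paired scores must match y_true in shape")
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    if n_pos < 2 or n_neg < 2:
        raise ValidationError("need >= 2 samples per class")
    v10a, v01a = _placements(y, sa)
    v10b, v01b = _placements(y, sb)
    auc_a, auc_b = float(v10a.mean()), float(v10b.mean())
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1)
    var_diff = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / n_pos \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n_neg
    delta = auc_a - auc_b
    if var_diff <= 0:
        if abs(delta) < 1e-12:
            return 0.0, 1.0
        raise ValidationError(
            "zero variance of the AUC difference with unequal AUCs"
        )
    z = float(delta / np.sqrt(var_diff))
    p = float(2.0 * norm.sf(abs(z)))
    return z, p


def roc_curve_points(y_true, scores) -> pd.DataFrame:
    """Empirical ROC curve as (threshold, fpr, tpr) rows, for plotting."""
    y = _check_binary(y_true)
    s = np.asarray(scores, dtype=float)
    order = np.argsort(-s, kind="stable")
    y_sorted, s_sorted = y[order], s[order]
    distinct = np.nonzero(np.diff(s_sorted))[0]
    cut = np.concatenate([distinct, [y.size - 1]])
    tps = np.cumsum(y_sorted)[cut]
    fps = 1 + cut - tps
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    return pd.DataFrame({
        "threshold": np.concatenate([[np.inf], s_sorted[cut]]),
        "fpr": np.concatenate([[0.0], fps / n_neg]),
        "tpr": np.concatenate([[0.0], tps / n_pos]),
    })


# ---------------------------------------------------------------------------
# Report assembly
# ---------------------------------------------------------------------------

def _holm(pvals: np.ndarray) -> np.ndarray:
    order = np.argsort(pvals)
    m = pvals.size
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * pvals[idx])
        adj[idx] = min(1.0, running)
    return adj


@dataclass
class EvaluationReport:
    """Table-style evaluation surface across families and thresholds."""

    metrics: pd.DataFrame          # one row per (family, threshold)
    delong: pd.DataFrame           # pairwise tests per threshold
    roc_points: dict               # (family, threshold) -> ROC DataFrame
    confusion: dict                # (family, threshold) -> ConfusionCounts


def build_report(
    score_tables: Mapping[float, Mapping[str, pd.DataFrame]],
    decision_threshold: float = 0.5,
) -> EvaluationReport:
    """Assemble the full evaluation report from per-model score tables.

    ``score_tables[threshold][family]`` is a DataFrame with columns
    record_id, y_true, score on the shared test set. Families at one
    threshold must cover identical record_ids (the paired DeLong test
    requires it).
    """
    metric_rows, delong_rows = [], []
    roc_points, confusion = {}, {}
    for thr, families in score_tables.items():
        if not families:
            raise ValidationError(f"no score tables at threshold {thr}")
        ref_ids = None
        aligned = {}
        for fam, df in families.items():
            need = {"record_id", "y_true", "score"}
            if not need <= set(df.columns):
                raise ValidationError(
                    f"score table {fam}@{thr} lacks columns {need - set(df.columns)}"
                )
            df = df.sort_values("record_id").reset_index(drop=True)
            ids = tuple(df["record_id"])
            if ref_ids is None:
                ref_ids = ids
            elif ids != ref_ids:
                raise ValidationError(
                    f"record_ids of {fam}@{thr} do not match the other families"
                )
            aligned[fam] = df
        for fam, df in aligned.items():
            y = df["y_true"].to_numpy(dtype=int)
            s = df["score"].to_numpy(dtype=float)
            auc, lo, hi = auc_confidence_interval(y, s)
            counts = ConfusionCounts.from_predictions(y, s >= decision_threshold)
            cm = confusion_metrics(counts)
            metric_rows.append({
                "family": fam, "threshold": thr,
                "accuracy": cm["accuracy"], "precision": cm["precision"],
                "sensitivity": cm["sensitivity"],
                "specificity": cm["specificity"],
                "f1": f1_score(cm["precision"], cm["sensitivity"]),
                "auc": auc, "auc_ci_low": lo, "auc_ci_high": hi,
                "n_test": int(y.size), "n_test_pos": int(y.sum()),
            })
            roc_points[(fam, thr)] = roc_curve_points(y, s)
            confusion[(fam, thr)] = counts
        fams = list(aligned.keys())
        pvals, pairs = [], []
        for fam_a, fam_b in combinations(fams, 2):
            ya = aligned[fam_a]["y_true"].to_numpy(dtype=int)
            z, p = delong_test(
                ya,
                aligned[fam_a]["score"].to_numpy(dtype=float),
                aligned[fam_b]["score"].to_numpy(dtype=float),
            )
            pairs.append((fam_a, fam_b, z, p))
            pvals.append(p)
        if pairs:
            adj = _holm(np.asarray(pvals))
            for (fam_a, fam_b, z, p), ph in zip(pairs, adj):
                delong_rows.append({
                    "threshold": thr, "family_a": fam_a, "family_b": fam_b,
                    "z": z, "p_value": p, "p_value_holm": ph,
                })
    metrics = pd.DataFrame(metric_rows)
    delong = pd.DataFrame(
        delong_rows,
        columns=["threshold", "family_a", "family_b", "z", "p_value",
                 "p_value_holm"],
    )
    return EvaluationReport(metrics=metrics, delong=delong,
                            roc_points=roc_points, confusion=confusion)


def plot_roc(report: EvaluationReport, threshold: float, path) -> None:
    """Write a ROC figure for all families at one threshold (optional)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for (fam, thr), pts in report.roc_points.items():
        if thr != threshold:
            continue
        row = report.metrics.query("family == @fam and threshold == @thr").iloc[0]
        ax.plot(pts["fpr"], pts["tpr"], label=f"{fam} (AUC {row['auc']:.3f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.set_title(f"ROC at K+ >= {threshold} mmol/L")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
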