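"""Evaluation statistics and quality gates for gelation classifiers.

The positive class is always "gelator".  Model quality is judged by four
complementary statistics:

* Cohen's kappa — chance-corrected agreement, in [-1, 1];
* balanced accuracy — mean of sensitivity and specificity, in [0, 1];
* Hand's H measure — a coherent alternative to AUC: one minus the ratio of
  the severity-weighted expected minimum misclassification loss of the
  scorer to that of the best trivial (data-ignoring) classifier, where the
  misclassification-cost severity ``c`` is drawn from a Beta distribution
  (default Beta(2, 2)).  An ideal ranker scores 1; an uninformative ranker
  scores ~0 in this definition;
* an exact one-sided binomial test of accuracy against the no-information
  rate (NIR), the accuracy of always predicting the majority class.

A model is "good" when it passes every gate with strict inequality:
H > 0.6, kappa > 0.4, balanced accuracy > 0.7 and, where the NIR test is
meaningful, p < 1e-5.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.stats import beta as _beta, binom as _binom


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts with gelator as the positive class."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion-matrix counts must be non-negative")
        if self.n == 0:
            raise ValueError("empty confusion matrix")

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionMatrix":
        y_true = np.asarray(y_true, int)
        y_pred = np.asarray(y_pred, int)
        return cls(
            tp=int(((y_true == 1) & (y_pred == 1)).sum()),
            fn=int(((y_true == 1) & (y_pred == 0)).sum()),
            fp=int(((y_true == 0) & (y_pred == 1)).sum()),
            tn=int(((y_true == 0) & (y_pred == 0)).sum()),
        )


def cohen_kappa(cm: ConfusionMatrix) -> float:
    """(po - pe) / (1 - pe); undefined (error) when chance agreement pe = 1."""
    n = cm.n
    po = (cm.tp + cm.tn) / n
    pe = ((cm.tp + cm.fp) * (cm.tp + cm.fn) + (cm.fn + cm.tn) * (cm.fp + cm.tn)) / n**2
    if pe == 1.0:
        raise ValueError("kappa undefined: chance agreement is 1 (single-cell matrix)")
    return (po - pe) / (1 - pe)


def balanced_accuracy(cm: ConfusionMatrix) -> float:
    """Mean of sensitivity tp/(tp+fn) and specificity tn/(tn+fp)."""
    if cm.tp + cm.fn == 0 or cm.tn + cm.fp == 0:
        raise ValueError("balanced accuracy undefined: an actual class is empty")
    return 0.5 * (cm.tp / (cm.tp + cm.fn) + cm.tn / (cm.tn + cm.fp))


def roc_curve(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    """Threshold-sweep ROC points, ties grouped, from (0,0) to (1,1).

    Predict positive when score > threshold; thresholds sweep the distinct
    score values from high to low.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n0 == 0 or n1 == 0:
        raise ValueError("ROC undefined with a single class")
    order = np.argsort(-scores, kind="mergesort")
    s, y = scores[order], labels[order]
    tps, fps = [0], [0]
    i = 0
    while i < len(y):
        j = i
        while j < len(y) and s[j] == s[i]:
            j += 1
        tps.append(tps[-1] + int(y[i:j].sum()))
        fps.append(fps[-1] + (j - i) - int(y[i:j].sum()))
        i = j
    return np.array(fps) / n0, np.array(tps) / n1


def _upper_hull(fpr: np.ndarray, tpr: np.ndarray) -> np.ndarray:
    """Upper convex hull of ROC points (monotone chain), as an (m, 2) array."""
    hull: list[tuple[float, float]] = []
    for p in zip(fpr, tpr):
        while len(hull) >= 2:
            (x1, y1), (x2, y2) = hull[-2], hull[-1]
            if (x2 - x1) * (p[1] - y1) >= (p[0] - x1) * (y2 - y1):
                hull.pop()
            else:
                break
        hull.append(p)
    return np.array(hull)


def h_measure(scores, labels, severity: tuple[float, float] = (2.0, 2.0)) -> float:
    """Hand's H measure of a score vector against binary labels.

    For cost ``c`` (the severity of misclassifying a non-gelator, with
    ``1 - c`` for a gelator), the minimum expected loss over thresholds is
    attained on the ROC convex hull; H = 1 - E_c[min loss] / E_c[trivial
    loss], the expectation taken over ``c ~ Beta(severity)``.  Computed in
    closed form via incomplete-Beta increments between the hull's
    cost-indifference breakpoints.

    Constant scores (no ranking information) return 0.0 with a warning.
    """
    a, b = severity
    labels = np.asarray(labels, int)
    scores = np.asarray(scores, float)
    n = len(labels)
    pi1 = labels.sum() / n
    pi0 = 1.0 - pi1
    if pi0 == 0 or pi1 == 0:
        raise ValueError("H measure undefined with a single class")
    if np.all(scores == scores[0]):
        warnings.warn("constant scores: H measure set to its minimum, 0", stacklevel=2)
        return 0.0
    fpr, tpr = roc_curve(scores, labels)
    hull = _upper_hull(fpr, tpr)
    dF, dT = np.diff(hull[:, 0]), np.diff(hull[:, 1])
    # cost at which hull vertices i and i+1 give equal loss; decreasing in i
    breakpoints = pi1 * dT / (pi0 * dF + pi1 * dT)
    edges = np.concatenate(([1.0], breakpoints, [0.0]))
    mean_c = a / (a + b)
    cdf = lambda x: _beta.cdf(x, a, b)
    cdf_up = lambda x: _beta.cdf(x, a + 1, b)  # for partial first moments
    loss = 0.0
    for i in range(len(hull)):
        hi, lo = edges[i], edges[i + 1]
        if hi <= lo:
            continue
        int_c = mean_c * (cdf_up(hi) - cdf_up(lo))
        int_1mc = (cdf(hi) - cdf(lo)) - int_c
        loss += pi0 * hull[i, 0] * int_c + pi1 * (1.0 - hull[i, 1]) * int_1mc
    triv_int_c = mean_c * cdf_up(pi1)
    triv_int_1mc = (1.0 - cdf(pi1)) - mean_c * (1.0 - cdf_up(pi1))
    trivial_loss = pi0 * triv_int_c + pi1 * triv_int_1mc
    return float(1.0 - loss / trivial_loss)


def nir_binomial_test(n_correct: int, n: int, nir: float) -> float:
    """Exact one-sided binomial tail P(X >= n_correct | n, nir)."""
    if not 0 <= n_correct <= n:
        raise ValueError("n_correct must be in [0, n]")
    return float(_binom.sf(n_correct - 1, n, nir))


#: strict-inequality thresholds for a "good" model
DEFAULT_THRESHOLDS = {
    "h_measure": 0.6,
    "kappa": 0.4,
    "balanced_accuracy": 0.7,
    "nir_p_value": 1e-5,
}


@dataclass
class EvaluationReport:
    """One model's statistics on one compound set, plus the gate verdict.

    ``nir_p_value`` is None where an accuracy-vs-NIR test is not meaningful
    (external test sets); the gate then uses only kappa, balanced accuracy
    and H.
    """

    kappa: float
    balanced_accuracy: float
    h_measure: float
    n: int
    nir_p_value: float | None = None
    verdict: str = "not_good"
    failed_criteria: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1)


def quality_gate(
    report: EvaluationReport, thresholds: dict | None = None
) -> tuple[str, list[str]]:
    """Apply the strict-inequality gates; mutates and returns verdict + failures."""
    t = dict(DEFAULT_THRESHOLDS)
    if thresholds:
        t.update(thresholds)
    failed = []
    if not report.h_measure > t["h_measure"]:
        failed.append(f"h_measure {report.h_measure:.3f} <= {t['h_measure']}")
    if not report.kappa > t["kappa"]:
        failed.append(f"kappa {report.kappa:.3f} <= {t['kappa']}")
    if not report.balanced_accuracy > t["balanced_accuracy"]:
        failed.append(f"balanced_accuracy {report.balanced_accuracy:.3f} <= {t['balanced_accuracy']}")
    if report.nir_p_value is not None and not report.nir_p_value < t["nir_p_value"]:
        failed.append(f"nir_p_value {report.nir_p_value:.3g} >= {t['nir_p_value']}")
    report.verdict = "good" if not failed else "not_good"
    report.failed_criteria = failed
    return report.verdict, failed


def evaluate(
    y_true,
    y_pred,
    scores,
    with_nir: bool = False,
    thresholds: dict | None = None,
) -> EvaluationReport:
    """Full report from truth, hard calls and ranking scores."""
    y_true = np.asarray(y_true, int)
    cm = ConfusionMatrix.from_predictions(y_true, y_pred)
    p = None
    if with_nir:
        nir = max(y_true.mean(), 1 - y_true.mean())
        p = nir_binomial_test(cm.tp + cm.tn, cm.n, nir)
    report = EvaluationReport(
        kappa=cohen_kappa(cm),
        balanced_accuracy=balanced_accuracy(cm),
        h_measure=h_measure(scores, y_true),
        n=cm.n,
        nir_p_value=p,
    )
    quality_gate(report, thresholds)
    return report


def format_report_table(reports: dict[str, EvaluationReport]) -> str:
    """Human-readable table: method, kappa, balanced accuracy, H, p, verdict."""
    lines = [
        f"{'method':<14} {'kappa':>7} {'bal.acc':>8} {'H':>7} {'NIR p':>10} verdict"
    ]
    for name, r in reports.items():
        p = f"{r.nir_p_value:.2e}" if r.nir_p_value is not None else "-"
        lines.append(
            f"{name:<14} {r.kappa:>7.3f} {r.balanced_accuracy:>8.3f} "
            f"{r.h_measure:>7.3f} {p:>10} {r.verdict}"
        )
    return "\n".join(lines)
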