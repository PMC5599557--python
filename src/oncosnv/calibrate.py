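"""Score calibration and cautious classification.

Raw classifier scores in R are mapped to confidence values ("p-scores")
on [0, 1] with Platt scaling: p(s) = 1 / (1 + exp(A*s + B)), with (A, B)
maximising a regularised Bernoulli likelihood.  Confusion statistics,
the balanced-accuracy-versus-threshold cautious curve, and the
lower-peak threshold selection rule live here too.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score


@dataclass(frozen=True)
class PlattModel:
    """Sigmoid map from raw score to confidence.

    For a classifier whose larger raw scores mean more oncogenic, A < 0
    so that p increases with the score.
    """

    A: float
    B: float
    fitted_on: str = ""

    def __call__(self, scores) -> np.ndarray:
        s = np.asarray(scores, dtype=float)
        # numerically stable logistic
        z = self.A * s + self.B
        out = np.empty_like(z)
        pos = z >= 0
        out[pos] = np.exp(-z[pos]) / (1.0 + np.exp(-z[pos]))
        out[~pos] = 1.0 / (1.0 + np.exp(z[~pos]))
        return out


def fit_platt(raw_scores, labels, max_iter: int = 100, tol: float = 1e-8,
              fitted_on: str = "") -> PlattModel:
    """Fit Platt's sigmoid by Newton iteration.

    Targets are regularised: t+ = (N+ + 1)/(N+ + 2) for positives and
    t- = 1/(N- + 2) for negatives, which keeps the MAP estimate finite
    even for separable scores.
    """
    s = np.asarray(raw_scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape:
        raise ValueError("scores and labels differ in length")
    n_pos, n_neg = int((y == 1).sum()), int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes required to fit Platt scaling")
    t = np.where(y == 1, (n_pos + 1.0) / (n_pos + 2.0), 1.0 / (n_neg + 2.0))

    A, B = 0.0, np.log((n_neg + 1.0) / (n_pos + 1.0))
    for _ in range(max_iter):
        z = A * s + B
        p = np.where(z >= 0, np.exp(-np.clip(z, 0, None)) / (1 + np.exp(-np.clip(z, 0, None))),
                     1 / (1 + np.exp(np.clip(z, None, 0))))
        # gradient of negative log-likelihood wrt (A, B); d(-ll)/dz = p - t
        d = p - t
        g = np.array([np.dot(d, s), d.sum()])
        w = np.clip(p * (1 - p), 1e-12, None)
        h11 = np.dot(w, s * s)
        h12 = np.dot(w, s)
        h22 = w.sum()
        H = np.array([[h11, h12], [h12, h22]]) + 1e-12 * np.eye(2)
        step = np.linalg.solve(H, g)
        A += step[0]
        B += step[1]
        if np.abs(g).max() < tol:
            break
    return PlattModel(A=float(A), B=float(B), fitted_on=fitted_on)


@dataclass(frozen=True)
class ThresholdPair:
    """Default (0.5) and high-confidence decision thresholds."""

    cautious_tau: float
    default_tau: float = 0.5

    def __post_init__(self):
        if not 0.5 <= self.cautious_tau <= 1.0:
            raise ValueError("cautious_tau must lie in [0.5, 1]")


@dataclass
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int
    n_total: int | None = None

    def __post_init__(self):
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.n_total is None:
            self.n_total = self.n_predicted

    @property
    def n_predicted(self) -> int:
        return self.TP + self.FP + self.TN + self.FN

    @property
    def coverage(self) -> float:
        return self.n_predicted / self.n_total if self.n_total else 0.0


@dataclass
class MetricSet:
    sensitivity: float
    specificity: float
    balanced_accuracy: float
    MCC: float
    PPV: float
    AUC: float | None = None
    degenerate: set = field(default_factory=set)


def confusion_at_threshold(pscores, labels, tau: float) -> ConfusionCounts:
    """Cautious confusion counts at confidence cutoff tau.

    Predict driver when p >= tau, passenger when p <= 1 - tau; abstain on
    the open interval between (abstentions count only toward n_total).
    At tau = 0.5 a p-score of exactly 0.5 is a driver call.
    """
    if not 0.5 <= tau <= 1.0:
        raise ValueError("tau must lie in [0.5, 1]")
    p = np.asarray(pscores, dtype=float)
    y = np.asarray(labels, dtype=int)
    pred_pos = p >= tau
    pred_neg = (p <= 1.0 - tau) & ~pred_pos
    return ConfusionCounts(
        TP=int(np.sum(pred_pos & (y == 1))),
        FP=int(np.sum(pred_pos & (y == 0))),
        TN=int(np.sum(pred_neg & (y == 0))),
        FN=int(np.sum(pred_neg & (y == 1))),
        n_total=len(p),
    )


def _ratio(num, den, flag, degenerate):
    if den == 0:
        degenerate.add(flag)
        return 0.0
    return num / den


def compute_metrics(c: ConfusionCounts, auc_value: float | None = None) -> MetricSet:
    """Sensitivity, specificity, balanced accuracy, MCC and PPV from counts.

    A zero denominator yields 0 for that statistic and raises its
    degenerate flag rather than NaN, so threshold sweeps stay total.
    """
    degenerate: set = set()
    sens = _ratio(c.TP, c.TP + c.FN, "sensitivity", degenerate)
    spec = _ratio(c.TN, c.TN + c.FP, "specificity", degenerate)
    ppv = _ratio(c.TP, c.TP + c.FP, "PPV", degenerate)
    mcc_den = np.sqrt(float(c.TP + c.FP) * (c.TP + c.FN) * (c.TN + c.FP) * (c.TN + c.FN))
    mcc = _ratio(c.TP * c.TN - c.FP * c.FN, mcc_den, "MCC", degenerate)
    return MetricSet(
        sensitivity=sens,
        specificity=spec,
        balanced_accuracy=(sens + spec) / 2.0,
        MCC=float(mcc),
        PPV=ppv,
        AUC=auc_value,
        degenerate=degenerate,
    )


def auc(pscores, labels) -> float:
    """Rank-based AUC: probability a random positive outscores a random
    negative, ties counting one half."""
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("AUC requires both classes")
    return float(roc_auc_score(y, np.asarray(pscores, dtype=float)))


@dataclass
class CautiousCurve:
    tau_grid: np.ndarray
    balanced_accuracy: np.ndarray   # NaN where undefined
    coverage: np.ndarray
    defined: np.ndarray             # False where a class is absent or coverage is zero

    def __len__(self):
        return len(self.tau_grid)


def default_tau_grid(step: float = 0.01) -> np.ndarray:
    return np.round(np.arange(0.50, 1.0 + step / 2, step), 10)


def cautious_curve(pscores, labels, tau_grid=None) -> CautiousCurve:
    """Balanced accuracy and coverage across a grid of confidence cutoffs.

    Grid entries where no prediction is made, or where one class
    disappears from the accepted subset, are flagged undefined rather
    than interpolated.
    """
    tau_grid = default_tau_grid() if tau_grid is None else np.asarray(tau_grid, dtype=float)
    if np.any(np.diff(tau_grid) <= 0):
        raise ValueError("tau_grid must be strictly increasing")
    accs = np.full(len(tau_grid), np.nan)
    covs = np.zeros(len(tau_grid))
    defined = np.zeros(len(tau_grid), dtype=bool)
    for i, tau in enumerate(tau_grid):
        c = confusion_at_threshold(pscores, labels, tau)
        covs[i] = c.coverage
        if c.n_predicted == 0:
            continue
        m = compute_metrics(c)
        if {"sensitivity", "specificity"} & m.degenerate:
            continue
        accs[i] = m.balanced_accuracy
        defined[i] = True
    return CautiousCurve(tau_grid, accs, covs, defined)


def select_cautious_threshold(curve: CautiousCurve, min_coverage: float = 0.05,
                              policy: str = "lower_peak",
                              plateau_tolerance: float = 0.002) -> float:
    """Choose the high-confidence threshold from a cautious curve.

    Finds local maxima of balanced accuracy among defined entries with
    coverage >= min_coverage (plateaus collapse to their smallest tau)
    and returns the smallest-tau local maximum within
    ``plateau_tolerance`` of the best local maximum.  When the curve has
    two comparable peaks this picks the lower one, since higher p-scores
    are supported by fewer examples and are less reliable.
    """
    if policy != "lower_peak":
        raise ValueError(f"unknown policy {policy!r}")
    ok = curve.defined & (curve.coverage >= min_coverage)
    if not ok.any():
        raise ValueError(f"no defined curve entry with coverage >= {min_coverage}")
    taus = curve.tau_grid[ok]
    accs = curve.balanced_accuracy[ok]
    n = len(taus)
    peaks = []  # (tau, acc) local maxima, plateaus -> smallest tau
    i = 0
    while i < n:
        j = i
        while j + 1 < n and accs[j + 1] == accs[i]:
            j += 1
        left_ok = i == 0 or accs[i - 1] < accs[i]
        right_ok = j == n - 1 or accs[j + 1] < accs[i]
        if left_ok and right_ok:
            peaks.append((taus[i], accs[i]))
        i = j + 1
    best = max(acc for _, acc in peaks)
    for tau, acc in peaks:  # peaks are in increasing tau order
        if acc >= best - plateau_tolerance:
            return float(tau)
    raise AssertionError("unreachable: best peak always qualifies")
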