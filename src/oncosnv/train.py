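"""Feature-group integration under leave-one-chromosome-out evaluation.

Each autosome in turn is held out as a test set while the remaining
autosomes (plus any allosomal/mitochondrial records) supply a balanced
training sample, preventing positional leakage between train and test.
Feature groups are first ranked by their individual LOCO balanced
accuracy, then integrated greedily at the data level (concatenation);
a kernel-level comparator combines one Gaussian kernel per group as an
accuracy-weighted convex combination (a multiple-kernel-learning-style
aggregate).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.svm import SVC

from .calibrate import PlattModel, fit_platt
from .dataset import LabelledDataset, sample_balanced
from .features import FeatureMatrix, assemble_matrix

AUTOSOMES = {str(i) for i in range(1, 23)}

DEFAULT_C_GRID = tuple(np.logspace(-4, 4, 9))


@dataclass(frozen=True)
class TrainerConfig:
    classifier: str = "gradient_boosting"      # or "svm_gaussian"
    param_grid: tuple = DEFAULT_C_GRID         # regularisation values C
    n_repeats_model: int = 30
    n_repeats_tune: int = 10
    n_pos: int = 1_000
    n_neg: int = 1_000
    plateau_epsilon: float = 0.002
    standardise: bool = False
    gb_n_estimators: int = 300
    gb_max_depth: int = 3
    gb_learning_rate: float = 0.1
    gb_subsample: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.classifier not in {"gradient_boosting", "svm_gaussian"}:
            raise ValueError(f"unknown classifier {self.classifier!r}")
        if not self.param_grid:
            raise ValueError("param_grid must be non-empty")
        if self.n_repeats_model < 1 or self.n_repeats_tune < 1:
            raise ValueError("repeat counts must be >= 1")

    def with_(self, **kw) -> "TrainerConfig":
        return replace(self, **kw)


def _repeat_seed(base_seed: int, stream: str, repeat: int) -> int:
    """Deterministic per-repeat seed: hash of (base seed, stream label,
    repeat index), folded below 2**31."""
    h = (int(base_seed) * 2654435761) % (2 ** 63)
    for ch in stream:
        h = ((h ^ ord(ch)) * 1099511628211) % (2 ** 63)
    h = (h + int(repeat) * 40503) % (2 ** 63)
    return h % (2 ** 31 - 1)


def _make_classifier(cfg: TrainerConfig, C: float, seed: int):
    if cfg.classifier == "gradient_boosting":
        return GradientBoostingClassifier(
            n_estimators=cfg.gb_n_estimators, max_depth=cfg.gb_max_depth,
            learning_rate=cfg.gb_learning_rate, subsample=cfg.gb_subsample,
            random_state=seed)
    return SVC(kernel="rbf", C=C, gamma="scale")


def _balanced_accuracy_from_scores(scores, labels, threshold: float = 0.0) -> float:
    y = np.asarray(labels)
    pred = np.asarray(scores) >= threshold
    sens = pred[y == 1].mean() if (y == 1).any() else np.nan
    spec = (~pred[y == 0]).mean() if (y == 0).any() else np.nan
    return float((sens + spec) / 2.0)


def loco_folds(ds: LabelledDataset) -> list[tuple[list[str], str]]:
    """One fold per autosome present: (training chromosomes, held-out
    autosome).  X, Y and MT records only ever train."""
    chroms = set(ds.chroms)
    test_chroms = sorted(chroms & AUTOSOMES, key=int)
    if len(test_chroms) < 2:
        raise ValueError("LOCO-CV needs records on at least two autosomes")
    return [([c for c in sorted(chroms) if c != t], t) for t in test_chroms]


@dataclass
class FoldResult:
    held_out_chrom: str
    raw_scores: np.ndarray
    labels: np.ndarray
    balanced_accuracy: float


def _loco_pass(ds: LabelledDataset, fm: FeatureMatrix, cfg: TrainerConfig,
               C: float, seed: int, collect_scores: bool = False):
    """One LOCO sweep: per fold, balanced-sample the training pool, fit,
    score the held-out autosome.  Returns (mean balanced accuracy over
    non-degenerate folds, fold results)."""
    chrom_of = np.array([r.chrom for r in ds.records])
    y = ds.labels
    folds, accs = [], []
    for k, (_, test_chrom) in enumerate(loco_folds(ds)):
        test_idx = np.where(chrom_of == test_chrom)[0]
        train_pool = np.where(chrom_of != test_chrom)[0]
        y_test = y[test_idx]
        if len(np.unique(y_test)) < 2 or len(np.unique(y[train_pool])) < 2:
            warnings.warn(f"fold {test_chrom}: single-class fold skipped")
            continue
        rng_seed = _repeat_seed(seed, f"fold:{test_chrom}", k)
        train_idx = _balanced_indices(y, train_pool, cfg.n_pos, cfg.n_neg, rng_seed)
        Xd = fm.design(fit_rows=train_idx, standardise=cfg.standardise)
        clf = _make_classifier(cfg, C, rng_seed)
        clf.fit(Xd[train_idx], y[train_idx])
        scores = clf.decision_function(Xd[test_idx])
        acc = _balanced_accuracy_from_scores(scores, y_test)
        accs.append(acc)
        if collect_scores:
            folds.append(FoldResult(test_chrom, scores, y_test, acc))
    if not accs:
        raise ValueError("every LOCO fold was degenerate")
    return float(np.mean(accs)), folds


def _balanced_indices(y, pool, n_pos, n_neg, seed) -> np.ndarray:
    rng = np.random.default_rng(seed)
    out = []
    for label, n_req in ((1, n_pos), (0, n_neg)):
        members = pool[y[pool] == label]
        if len(members) <= n_req:
            out.append(members)
        else:
            out.append(rng.choice(members, size=n_req, replace=False))
    return np.sort(np.concatenate(out))


def evaluate_group(ds: LabelledDataset, builders: dict, group_name: str,
                   cfg: TrainerConfig, C: float | None = None):
    """Mean +/- sd LOCO balanced accuracy of a single feature group over
    cfg.n_repeats_model repeats (fresh balanced training samples each
    repeat)."""
    return evaluate_groups(ds, {group_name: builders[group_name]}, cfg, C=C)


def evaluate_groups(ds: LabelledDataset, builders: dict, cfg: TrainerConfig,
                    C: float | None = None, n_repeats: int | None = None):
    """LOCO balanced accuracy of the concatenation of ``builders``:
    (mean, sd) over repeats."""
    C = C if C is not None else cfg.param_grid[len(cfg.param_grid) // 2]
    n_repeats = n_repeats if n_repeats is not None else cfg.n_repeats_model
    fm = assemble_matrix(ds.records, builders)
    label = "+".join(builders)
    accs = [
        _loco_pass(ds, fm, cfg, C, _repeat_seed(cfg.seed, f"eval:{label}", rep))[0]
        for rep in range(n_repeats)
    ]
    return float(np.mean(accs)), float(np.std(accs))


@dataclass
class GreedyTrace:
    """Outcome of greedy sequential integration."""

    ranked_groups: list[str]
    individual_accuracy: dict[str, float]
    individual_sd: dict[str, float]
    cumulative_accuracy: list[float]     # entry i: accuracy of prefix of length i+2
    cumulative_standardised: list[bool]  # whether the standardised variant won
    selected_prefix: list[str] = field(default_factory=list)

    def prefix(self, length: int) -> list[str]:
        return self.ranked_groups[:length]


def rank_groups(ds: LabelledDataset, builders: dict, cfg: TrainerConfig):
    """Rank groups by individual LOCO balanced accuracy, descending; ties
    broken by group name so the ranking is input-order invariant."""
    results = {name: evaluate_group(ds, builders, name, cfg) for name in builders}
    ranked = sorted(results, key=lambda g: (-results[g][0], g))
    return ranked, {g: results[g][0] for g in results}, {g: results[g][1] for g in results}


def greedy_integrate(ds: LabelledDataset, builders: dict, cfg: TrainerConfig,
                     evaluate_both_scalings: bool = True) -> GreedyTrace:
    """Greedy data-level integration.

    Groups are ranked individually, the top two are concatenated, and
    remaining groups are appended in rank order, recording cumulative
    LOCO balanced accuracy at each step.  Raw and standardised variants
    are both evaluated (the better one is recorded) unless disabled.
    """
    if len(builders) < 2:
        raise ValueError("greedy integration needs at least two groups")
    ranked, individual, sds = rank_groups(ds, builders, cfg)
    cumulative, used_std = [], []
    for length in range(2, len(ranked) + 1):
        subset = {g: builders[g] for g in ranked[:length]}
        acc_raw, _ = evaluate_groups(ds, subset, cfg.with_(standardise=False))
        if evaluate_both_scalings:
            acc_std, _ = evaluate_groups(ds, subset, cfg.with_(standardise=True))
        else:
            acc_std = -np.inf
        cumulative.append(max(acc_raw, acc_std))
        used_std.append(acc_std > acc_raw)
    trace = GreedyTrace(ranked, individual, sds, cumulative, used_std)
    trace.selected_prefix = select_prefix(trace, cfg.plateau_epsilon)
    return trace


def select_prefix(trace: GreedyTrace, epsilon: float) -> list[str]:
    """Shortest prefix whose cumulative accuracy is within epsilon of the
    best prefix — the 'peak or plateau' stopping rule."""
    best = max(trace.cumulative_accuracy)
    for i, acc in enumerate(trace.cumulative_accuracy):
        if acc >= best - epsilon:
            return trace.prefix(i + 2)
    raise AssertionError("unreachable")


# ---------------------------------------------------------------------------
# kernel-level comparator


def _gaussian_kernel(XA, XB, sigma: float) -> np.ndarray:
    d2 = cdist(XA, XB, metric="sqeuclidean")
    return np.exp(-d2 / (2.0 * sigma ** 2))


def _median_sigma(X, rng, max_points: int = 500) -> float:
    idx = rng.choice(len(X), size=min(len(X), max_points), replace=False)
    d = cdist(X[idx], X[idx])
    med = np.median(d[np.triu_indices_from(d, k=1)])
    return float(med) if med > 0 else 1.0


def mkl_integrate(ds: LabelledDataset, builders: dict, cfg: TrainerConfig,
                  n_repeats: int | None = None,
                  group_accuracies: dict | None = None):
    """Kernel-level integration comparator.

    One Gaussian kernel per group (width from the median pairwise
    training distance), combined as a convex combination with weights
    proportional to each group's individual balanced accuracy above
    chance (floored at 0; uniform fallback when all floor), feeding a
    kernel SVM evaluated by LOCO.  Returns (mean, sd) balanced accuracy.
    """
    cfg = cfg.with_(classifier="svm_gaussian")
    n_repeats = n_repeats if n_repeats is not None else cfg.n_repeats_model
    if group_accuracies is None:
        _, group_accuracies, _ = rank_groups(ds, builders, cfg)
    w = np.array([max(group_accuracies[g] - 0.5, 0.0) for g in builders])
    if w.sum() <= 0:
        warnings.warn("all group weights floored at 0; falling back to uniform weights")
        w = np.ones(len(builders))
    w = w / w.sum()

    mats = {g: assemble_matrix(ds.records, {g: b}) for g, b in builders.items()}
    chrom_of = np.array([r.chrom for r in ds.records])
    y = ds.labels
    C = cfg.param_grid[len(cfg.param_grid) // 2]
    rep_accs = []
    for rep in range(n_repeats):
        accs = []
        for k, (_, test_chrom) in enumerate(loco_folds(ds)):
            test_idx = np.where(chrom_of == test_chrom)[0]
            train_pool = np.where(chrom_of != test_chrom)[0]
            if len(np.unique(y[test_idx])) < 2 or len(np.unique(y[train_pool])) < 2:
                continue
            seed = _repeat_seed(cfg.seed, f"mkl:{test_chrom}", rep * 1000 + k)
            rng = np.random.default_rng(seed)
            train_idx = _balanced_indices(y, train_pool, cfg.n_pos, cfg.n_neg, seed)
            K_tr = np.zeros((len(train_idx), len(train_idx)))
            K_te = np.zeros((len(test_idx), len(train_idx)))
            for wi, (g, fm) in zip(w, mats.items()):
                Xg = fm.design(fit_rows=train_idx, standardise=True)
                sigma = _median_sigma(Xg[train_idx], rng)
                K_tr += wi * _gaussian_kernel(Xg[train_idx], Xg[train_idx], sigma)
                K_te += wi * _gaussian_kernel(Xg[test_idx], Xg[train_idx], sigma)
            clf = SVC(kernel="precomputed", C=C)
            clf.fit(K_tr, y[train_idx])
            accs.append(_balanced_accuracy_from_scores(
                clf.decision_function(K_te), y[test_idx]))
        rep_accs.append(np.mean(accs))
    return float(np.mean(rep_accs)), float(np.std(rep_accs))


def tune_parameter(ds: LabelledDataset, builders: dict, cfg: TrainerConfig) -> float:
    """Grid-search the regularisation parameter by repeated LOCO balanced
    accuracy; ties go to the smaller value."""
    means = []
    for C in cfg.param_grid:
        mean, _ = evaluate_groups(ds, builders, cfg, C=C, n_repeats=cfg.n_repeats_tune)
        means.append(mean)
    means = np.asarray(means)
    grid = np.asarray(cfg.param_grid, dtype=float)
    best = np.max(means)
    return float(np.min(grid[means >= best - 1e-12]))


# ---------------------------------------------------------------------------
# final model


@dataclass
class FittedModel:
    """A trained classifier over selected feature groups with its
    calibration attached."""

    cfg: TrainerConfig
    C: float
    selected_groups: list[str]
    builders: dict
    estimator: object
    feature_matrix_template: FeatureMatrix
    train_col_means: np.ndarray
    standardisation: dict | None
    platt: PlattModel | None = None

    def _design_for(self, records) -> np.ndarray:
        fm = assemble_matrix(records, {g: self.builders[g] for g in self.selected_groups})
        X = fm.data.copy()
        X[fm.missing_mask] = np.take(self.train_col_means, np.where(fm.missing_mask)[1])
        if self.standardisation is not None:
            X = (X - self.standardisation["mean"]) / self.standardisation["sd"]
        return X

    def decision_scores(self, records) -> np.ndarray:
        return self.estimator.decision_function(self._design_for(records))

    def predict_pscores(self, records) -> np.ndarray:
        if self.platt is None:
            raise ValueError("model has no calibration attached; fit Platt scaling first")
        return self.platt(self.decision_scores(records))


def train_final(ds: LabelledDataset, selected_groups: list[str], builders: dict,
                cfg: TrainerConfig, C: float | None = None,
                calibrate: bool = True, n_calib_folds: int = 3) -> FittedModel:
    """Train one final model on the full dataset (balanced sample when the
    data exceed the configured sample sizes) and attach Platt calibration
    fitted on out-of-fold scores from an internal split."""
    C = C if C is not None else cfg.param_grid[len(cfg.param_grid) // 2]
    sub = {g: builders[g] for g in selected_groups}
    y_all = ds.labels
    if len(np.unique(y_all)) < 2:
        raise ValueError("single-class dataset is untrainable")
    train_idx = _balanced_indices(y_all, np.arange(len(ds)), cfg.n_pos, cfg.n_neg,
                                  _repeat_seed(cfg.seed, "final", 0))
    fm = assemble_matrix(ds.records, sub)
    X = fm.design(fit_rows=train_idx, standardise=cfg.standardise)
    # persist the imputation means actually used
    fit_vals = np.where(fm.missing_mask[train_idx], np.nan, fm.data[train_idx])
    with np.errstate(invalid="ignore"):
        col_means = np.nanmean(fit_vals, axis=0)
    col_means = np.where(np.isnan(col_means), 0.0, col_means)

    y = y_all[train_idx]
    Xt = X[train_idx]
    clf = _make_classifier(cfg, C, _repeat_seed(cfg.seed, "final_fit", 0))
    clf.fit(Xt, y)
    model = FittedModel(cfg=cfg, C=C, selected_groups=list(selected_groups),
                        builders=builders, estimator=clf,
                        feature_matrix_template=fm, train_col_means=col_means,
                        standardisation=fm.standardisation if cfg.standardise else None)
    if calibrate:
        model.platt = _out_of_fold_platt(Xt, y, cfg, C, n_calib_folds)
    return model


def _out_of_fold_platt(X, y, cfg: TrainerConfig, C: float, n_folds: int) -> PlattModel:
    """Platt calibration on out-of-fold scores from an internal stratified
    split, avoiding the optimism of calibrating on training scores."""
    from sklearn.model_selection import StratifiedKFold

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                          random_state=_repeat_seed(cfg.seed, "platt", 0))
    oof = np.zeros(len(y))
    for tr, te in skf.split(X, y):
        clf = _make_classifier(cfg, C, _repeat_seed(cfg.seed, "platt_fold", te[0]))
        clf.fit(X[tr], y[tr])
        oof[te] = clf.decision_function(X[te])
    return fit_platt(oof, y, fitted_on=f"out-of-fold scores, {n_folds}-fold internal split")
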