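"""Top-level modelling surface.

:class:`OncogenicityModel` bundles a labelled dataset with a registry of
feature-group builders and a trainer configuration; :meth:`fit` runs the
full procedure — group ranking, greedy data-level integration, optional
regularisation tuning and kernel-level comparison, final training,
Platt calibration and cautious-threshold selection — and returns an
:class:`OncogenicityResults` carrying the estimates, their spread over
cross-validation repeats, and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .calibrate import (
    CautiousCurve,
    PlattModel,
    ThresholdPair,
    cautious_curve,
    compute_metrics,
    confusion_at_threshold,
    select_cautious_threshold,
)
from .dataset import LabelledDataset
from .train import (
    FittedModel,
    GreedyTrace,
    TrainerConfig,
    _loco_pass,
    greedy_integrate,
    mkl_integrate,
    train_final,
    tune_parameter,
)
from .features import assemble_matrix


class OncogenicityModel:
    """Driver-versus-neutral classifier over integrated feature groups.

    Parameters
    ----------
    dataset : LabelledDataset
        Driver/neutral records spanning at least two autosomes.
    builders : dict[str, callable]
        Feature-group registry; each builder maps a record list to a
        :class:`~oncosnv.features.FeatureGroup`.
    config : TrainerConfig, optional
        Classifier choice, sampling sizes, repeat counts and seed.
    """

    def __init__(self, dataset: LabelledDataset, builders: dict,
                 config: TrainerConfig | None = None):
        if len(builders) < 1:
            raise ValueError("at least one feature-group builder required")
        self.dataset = dataset
        self.builders = dict(builders)
        self.config = config or TrainerConfig()

    @classmethod
    def from_tables(cls, positives, negatives, dataset_config, annotations,
                    builders, config=None) -> "OncogenicityModel":
        """Construct directly from raw catalogues, running the dataset
        pipeline (region routing, recurrence filter, window matching)."""
        from .dataset import build_dataset
        ds = build_dataset(positives, negatives, dataset_config, annotations)
        return cls(ds, builders, config)

    def fit(self, greedy: bool = True, tune: bool = False, compare_mkl: bool = False,
            evaluate_both_scalings: bool = True,
            min_coverage: float = 0.05) -> "OncogenicityResults":
        """Run the full selection + training + calibration procedure."""
        cfg = self.config
        trace = None
        if greedy and len(self.builders) >= 2:
            trace = greedy_integrate(self.dataset, self.builders, cfg,
                                     evaluate_both_scalings=evaluate_both_scalings)
            selected = trace.selected_prefix
            if evaluate_both_scalings and trace.cumulative_standardised:
                best_i = int(np.argmax(trace.cumulative_accuracy))
                cfg = cfg.with_(standardise=trace.cumulative_standardised[best_i])
        else:
            selected = list(self.builders)

        sub = {g: self.builders[g] for g in selected}
        best_C = tune_parameter(self.dataset, sub, cfg) if tune else None
        mkl_acc = mkl_integrate(self.dataset, self.builders, cfg,
                                n_repeats=cfg.n_repeats_model,
                                group_accuracies=trace.individual_accuracy if trace else None
                                ) if compare_mkl else None

        fitted = train_final(self.dataset, selected, self.builders, cfg, C=best_C)

        # out-of-sample calibrated scores for threshold selection
        fm = assemble_matrix(self.dataset.records, sub)
        eff_cfg = fitted.cfg
        _, folds = _loco_pass(self.dataset, fm, eff_cfg,
                              fitted.C, eff_cfg.seed, collect_scores=True)
        oof_scores = np.concatenate([f.raw_scores for f in folds])
        oof_labels = np.concatenate([f.labels for f in folds])
        pscores = fitted.platt(oof_scores)
        curve = cautious_curve(pscores, oof_labels)
        try:
            tau = select_cautious_threshold(curve, min_coverage=min_coverage)
        except ValueError:
            tau = 0.5
        loco_acc = float(np.mean([f.balanced_accuracy for f in folds]))
        loco_sd = float(np.std([f.balanced_accuracy for f in folds]))

        return OncogenicityResults(
            model=self, fitted=fitted, greedy_trace=trace,
            selected_groups=selected, best_C=fitted.C,
            loco_balanced_accuracy=loco_acc, loco_sd=loco_sd,
            mkl_balanced_accuracy=mkl_acc[0] if mkl_acc else None,
            oof_pscores=pscores, oof_labels=oof_labels,
            curve=curve, thresholds=ThresholdPair(cautious_tau=tau))


@dataclass
class OncogenicityResults:
    """Fit outcome: the trained calibrated classifier, the integration
    trace, cross-validated accuracy, and the selected thresholds."""

    model: OncogenicityModel
    fitted: FittedModel
    greedy_trace: GreedyTrace | None
    selected_groups: list[str]
    best_C: float
    loco_balanced_accuracy: float
    loco_sd: float
    mkl_balanced_accuracy: float | None
    oof_pscores: np.ndarray
    oof_labels: np.ndarray
    curve: CautiousCurve
    thresholds: ThresholdPair

    @property
    def platt(self) -> PlattModel:
        return self.fitted.platt

    def predict(self, records) -> np.ndarray:
        """Calibrated p-scores for new mutation records."""
        return self.fitted.predict_pscores(records)

    def metrics_at(self, tau: float = 0.5):
        """Confusion statistics of the out-of-fold predictions at a
        confidence cutoff."""
        c = confusion_at_threshold(self.oof_pscores, self.oof_labels, tau)
        return compute_metrics(c), c

    def summary(self) -> str:
        m05, c05 = self.metrics_at(0.5)
        mtau, ctau = self.metrics_at(self.thresholds.cautious_tau)
        lines = [
            "Oncogenic SNV classifier — fit summary",
            "=" * 54,
            f"records: {len(self.model.dataset)}  "
            f"(drivers {int(self.model.dataset.labels.sum())}, "
            f"neutrals {int((1 - self.model.dataset.labels).sum())})",
            f"classifier: {self.fitted.cfg.classifier}   C = {self.best_C:g}",
            f"selected groups: {', '.join(self.selected_groups)}",
            f"LOCO balanced accuracy: {self.loco_balanced_accuracy:.4f} "
            f"(sd {self.loco_sd:.4f})",
        ]
        if self.mkl_balanced_accuracy is not None:
            lines.append(f"kernel-level (MKL) comparator: {self.mkl_balanced_accuracy:.4f}")
        if self.greedy_trace is not None:
            lines.append("-" * 54)
            lines.append("greedy integration (group: individual acc | cumulative):")
            for i, g in enumerate(self.greedy_trace.ranked_groups):
                cum = ("      " if i == 0
                       else f"{self.greedy_trace.cumulative_accuracy[i - 1]:.4f}")
                lines.append(f"  {g:<16} {self.greedy_trace.individual_accuracy[g]:.4f} | {cum}")
        lines += [
            "-" * 54,
            f"Platt calibration: A = {self.platt.A:.4f}, B = {self.platt.B:.4f}",
            f"thresholds: default tau = {self.thresholds.default_tau:.2f}, "
            f"cautious tau = {self.thresholds.cautious_tau:.2f}",
            f"at tau=0.50: balanced acc {m05.balanced_accuracy:.4f}, "
            f"MCC {m05.MCC:.4f}, coverage {c05.coverage:.2%}",
            f"at tau={self.thresholds.cautious_tau:.2f}: balanced acc "
            f"{mtau.balanced_accuracy:.4f}, MCC {mtau.MCC:.4f}, "
            f"coverage {ctau.coverage:.2%}",
        ]
        return "\n".join(lines)
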