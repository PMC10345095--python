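"""Model/Results facade.

:class:`MMMIModel` is built from data (a synthetic or loaded cohort, or
explicit bags + encoded table + labels); :meth:`MMMIModel.fit` trains the
network and returns an :class:`MMMIResults` carrying the fitted parameters,
the training log, the held-out evaluation report and a ``summary()`` table.
Simulation (`from_spec`) and prediction hang off these two objects.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import CohortSpec, SyntheticCohort, generate_cohort
from .evaluation import feature_importance, one_vs_rest_report
from .network import CLASS_NAMES, MMMINet, ModelConfig
from .tabular import EncodedTable, encode_categoricals, impute_chained, standardize
from .training import (LossConfig, OptimSchedule, SplitAssignment,
                       predict_cohort, stratified_split, train)

__all__ = ["MMMIModel", "MMMIResults"]


class MMMIModel:
    """Multi-modal multi-instance nodal-status model bound to a dataset.

    Parameters
    ----------
    bags : list of MultiScaleBag (may be None for the tabular-only head)
    table : EncodedTable (complete; imputed if it has holes)
    labels : (n,) int array of 4-class nodal status
    config : ModelConfig (modality selects the full model or an ablation head)
    split : SplitAssignment or None (a fresh stratified 60/20/20 split is
        drawn at fit time if absent)
    """

    def __init__(self, bags, table: EncodedTable, labels,
                 config: ModelConfig | None = None,
                 split: SplitAssignment | None = None):
        self.bags = bags
        self.table = table
        self.labels = np.asarray(labels, int)
        if table is not None and np.isnan(table.matrix).any():
            self.table = impute_chained(table)
        cfg = config or ModelConfig()
        if self.table is not None:
            cfg.n_variables = self.table.matrix.shape[1]
        if bags:
            cfg.feature_dim = bags[0].feature_dim
            cfg.scales = tuple(sorted(bags[0].features))
        self.config = cfg
        self.split = split
        self._X, self._xstats = (None, None)
        if self.table is not None:
            self._X, self._xstats = standardize(self.table.matrix)

    # -- constructors ---------------------------------------------------------
    @classmethod
    def from_cohort(cls, cohort: SyntheticCohort,
                    config: ModelConfig | None = None,
                    split: SplitAssignment | None = None) -> "MMMIModel":
        table = encode_categoricals(cohort.records)
        return cls(cohort.bags, table, cohort.labels, config=config, split=split)

    @classmethod
    def from_spec(cls, spec: CohortSpec,
                  config: ModelConfig | None = None) -> "MMMIModel":
        """Simulate a cohort from a generator spec and bind a model to it."""
        return cls.from_cohort(generate_cohort(spec), config=config)

    # -- fitting --------------------------------------------------------------
    def fit(self, schedule: OptimSchedule | None = None,
            loss: LossConfig | None = None, seed: int = 0,
            verbose: bool = False) -> "MMMIResults":
        split = self.split or stratified_split(
            self.labels, seed=seed,
            ids=[b.patient_id for b in self.bags] if self.bags
            else [str(i) for i in range(len(self.labels))])
        net, log_df = train(self.bags, self._X, self.labels, split,
                            schedule=schedule, loss_config=loss,
                            config=self.config, seed=seed, verbose=verbose)
        return MMMIResults(self, net, split, log_df, seed)


class MMMIResults:
    """Fitted model: parameters, training log, diagnostics and reports."""

    def __init__(self, model: MMMIModel, net: MMMINet,
                 split: SplitAssignment, log: pd.DataFrame, seed: int):
        self.model = model
        self.net = net
        self.split = split
        self.log = log
        self.seed = seed

    @property
    def params(self) -> dict:
        return {k: v.data for k, v in self.net.params.items()}

    def _ids(self):
        return ([b.patient_id for b in self.model.bags] if self.model.bags
                else [str(i) for i in range(len(self.model.labels))])

    def _mean_bag(self):
        """Training-set mean pooled vector per scale, as a one-instance bag."""
        idx = self.split.indices(self._ids())["train"]
        return {sc: np.mean([self.model.bags[i].features[sc].mean(axis=0)
                             for i in idx], axis=0)[None, :]
                for sc in self.net.config.scales}

    def predict(self, subset: str | None = "test", bags=None, X=None,
                allow_missing: bool = False) -> np.ndarray:
        """4-class probabilities for a named partition of the bound data, or
        for new (bags, raw-table) inputs standardized with training stats.

        A missing image bag is a strict error unless ``allow_missing``: then
        the training-set mean pooled vector per scale is substituted (as a
        one-instance bag) and the substitution is logged.
        """
        if bags is not None or X is not None:
            Xs = None
            if X is not None:
                Xs, _ = standardize(np.asarray(X, float), self.model._xstats)
            use = list(bags) if bags is not None else [None] * len(Xs)
            if any(b is None for b in use):
                if not allow_missing:
                    raise ValueError(
                        "missing image bag(s); pass allow_missing=True to "
                        "substitute the training-set mean embedding")
                import logging
                logging.getLogger(__name__).warning(
                    "substituting training-mean bag for %d patient(s)",
                    sum(b is None for b in use))
                mean_bag = self._mean_bag()
                use = [mean_bag if b is None else b for b in use]
            return predict_cohort(self.net, use, Xs, np.arange(len(use)))
        idx = self.split.indices(self._ids())[subset]
        return predict_cohort(self.net, self.model.bags, self.model._X, idx)

    def evaluate(self, subset: str = "test", by=None, class_names=CLASS_NAMES
                 ) -> pd.DataFrame:
        """One-vs-rest report (AUC/CI/ACC/SEN/SPE at Youden cutpoints) on a
        partition, optionally stratified (``by`` = per-patient subgroup labels)."""
        idx = self.split.indices(self._ids())[subset]
        probs = self.predict(subset)
        sub = None if by is None else np.asarray(by)[idx]
        return one_vs_rest_report(probs, self.model.labels[idx],
                                  class_names=class_names, subgroups=sub)

    def feature_importance(self, subset: str = "train", top_k: int = 8):
        idx = self.split.indices(self._ids())[subset]
        return feature_importance(self.net, bags=self.model.bags,
                                  X=self.model._X, idx=idx, top_k=top_k)

    def tabular_importance(self, subset: str = "train") -> pd.Series:
        """Ranked per-variable importance from the encoder's feature masks."""
        idx = self.split.indices(self._ids())[subset]
        imp = feature_importance(self.net, X=self.model._X, idx=idx)["tabular"]
        cols = self.model.table.columns
        return pd.Series(imp, index=cols).sort_values(ascending=False)

    def summary(self) -> str:
        rep = self.evaluate("test")
        rep = rep[rep.subgroup == "all"]
        lines = [
            "Multi-modal multi-instance nodal status model",
            "=" * 61,
            f"modality head : {self.net.config.modality}",
            f"parameters    : {sum(v.size for v in self.params.values())}"
            f"   config hash {self.net.config_hash()}",
            f"epochs run    : {len(self.log)}   "
            f"best val metric {self.log.val_metric.max():.3f}",
            f"partitions    : " + " / ".join(
                f"{k}={len(v)}" for k, v in
                self.split.indices(self._ids()).items()),
            "-" * 61,
            f"{'class':<10}{'AUC':>8}{'95% CI':>18}{'ACC':>7}{'SEN':>7}{'SPE':>7}",
        ]
        for _, r in rep.iterrows():
            ci = (f"({r.ci_low:.3f}-{r.ci_high:.3f})"
                  if r.ci_low == r.ci_low else "(Na-Na)")
            lines.append(f"{r['class']:<10}{r.auc:>8.3f}{ci:>18}"
                         f"{r.accuracy:>7.3f}{r.sensitivity:>7.3f}"
                         f"{r.specificity:>7.3f}")
        lines.append("=" * 61)
        return "\n".join(lines)

    def save(self, path):
        self.net.save(path)
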