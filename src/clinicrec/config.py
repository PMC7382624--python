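"""Pipeline configuration: one YAML file drives every stage.

Defaults mirror the pipeline's reference operating point: order vocabulary
cutoff 256 entries, low-variance threshold SD < 0.01, 70/15/15 patient split
with 2011 calendar cuts, admissions-baseline usage threshold 50 inside a
2-day post-admission window, and a patient-level bootstrap of 10 000 rows ×
1000 iterations.  Every run writes a frozen copy of its resolved config.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from clinicrec.models import LossSpec, NetworkParams, TrainConfig
from clinicrec.partitioning import SplitSpec
from clinicrec.synthetic import CohortSpec


@dataclass
class PipelineConfig:
    seed: int = 0
    cohort: CohortSpec = field(default_factory=CohortSpec)
    vocab_min_count: int = 256
    sd_threshold: float = 0.01
    split: SplitSpec = field(default_factory=SplitSpec)
    logistic_train: TrainConfig = field(
        default_factory=lambda: TrainConfig(optimizer="sgd", learning_rate=0.01, epochs=1)
    )
    clinicnet_net: NetworkParams = field(default_factory=lambda: NetworkParams(hidden_units=(64, 64)))
    clinicnet_loss: LossSpec = field(default_factory=lambda: LossSpec(positive_weight=10.0))
    clinicnet_train: TrainConfig = field(default_factory=TrainConfig)
    baseline_min_usage: int = 50
    baseline_window: pd.Timedelta = pd.Timedelta(days=2)
    bootstrap_rows: int = 10_000
    bootstrap_iterations: int = 1_000

    def as_dict(self) -> dict:
        c = self.cohort
        s = self.split
        return {
            "seed": self.seed,
            "cohort": {
                "n_patients": c.n_patients,
                "n_items": c.n_items,
                "n_order_sets": c.n_order_sets,
                "date_start": str(c.date_start.date()),
                "date_end": str(c.date_end.date()),
                "powerlaw_alpha": c.powerlaw_alpha,
                "orderset_trigger_rate": c.orderset_trigger_rate,
                "orderset_preference": c.orderset_preference,
                "orderset_fill_rate": c.orderset_fill_rate,
                "context_signal_strength": c.context_signal_strength,
                "mean_admissions": c.mean_admissions,
                "mean_bursts_per_admission": c.mean_bursts_per_admission,
                "mean_orders_per_burst": c.mean_orders_per_burst,
            },
            "vocab": {"min_count": self.vocab_min_count},
            "transforms": {"sd_threshold": self.sd_threshold},
            "split": {
                "fractions": list(s.fractions),
                "train_before": str(s.train_before.date()),
                "val_year": s.val_year,
                "test_from": str(s.test_from.date()),
            },
            "models": {
                "logistic": _train_dict(self.logistic_train),
                "clinicnet": {
                    "net": {
                        "hidden_units": list(self.clinicnet_net.hidden_units),
                        "dropout_rate": self.clinicnet_net.dropout_rate,
                        "batch_norm": self.clinicnet_net.batch_norm,
                    },
                    "loss": {
                        "positive_weight": self.clinicnet_loss.positive_weight,
                        "l2_lambda": self.clinicnet_loss.l2_lambda,
                    },
                    "train": _train_dict(self.clinicnet_train),
                },
            },
            "baselines": {
                "min_usage": self.baseline_min_usage,
                "window_days": self.baseline_window / pd.Timedelta(days=1),
            },
            "bootstrap": {
                "rows_per_sample": self.bootstrap_rows,
                "iterations": self.bootstrap_iterations,
            },
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.as_dict(), sort_keys=True))


def _train_dict(t: TrainConfig) -> dict:
    return {
        "optimizer": t.optimizer,
        "learning_rate": t.learning_rate,
        "epochs": t.epochs,
        "batch_size": t.batch_size,
    }


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> PipelineConfig:
    """Build a PipelineConfig from a YAML file (all keys optional)."""
    raw: dict = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}
    if overrides:
        raw = {**raw, **overrides}
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> PipelineConfig:
    seed = int(raw.get("seed", 0))
    c = dict(raw.get("cohort", {}))
    cohort = CohortSpec(
        n_patients=int(c.get("n_patients", 200)),
        n_items=int(c.get("n_items", 120)),
        n_order_sets=int(c.get("n_order_sets", 12)),
        date_start=pd.Timestamp(c.get("date_start", "2008-01-01")),
        date_end=pd.Timestamp(c.get("date_end", "2014-12-31")),
        powerlaw_alpha=float(c.get("powerlaw_alpha", 1.75)),
        orderset_trigger_rate=float(c.get("orderset_trigger_rate", 0.25)),
        orderset_preference=float(c.get("orderset_preference", 0.9)),
        orderset_fill_rate=float(c.get("orderset_fill_rate", 0.7)),
        context_signal_strength=float(c.get("context_signal_strength", 0.3)),
        mean_admissions=float(c.get("mean_admissions", 1.5)),
        mean_bursts_per_admission=float(c.get("mean_bursts_per_admission", 4.0)),
        mean_orders_per_burst=float(c.get("mean_orders_per_burst", 3.0)),
        seed=seed,
    )
    s = dict(raw.get("split", {}))
    split = SplitSpec(
        fractions=tuple(s.get("fractions", (0.70, 0.15, 0.15))),
        train_before=pd.Timestamp(s.get("train_before", "2011-01-01")),
        val_year=int(s.get("val_year", 2011)),
        test_from=pd.Timestamp(s.get("test_from", "2012-01-01")),
        seed=seed,
    )
    m = dict(raw.get("models", {}))
    lg = dict(m.get("logistic", {}))
    logistic_train = TrainConfig(
        optimizer=lg.get("optimizer", "sgd"),
        learning_rate=float(lg.get("learning_rate", 0.01)),
        epochs=int(lg.get("epochs", 1)),
        batch_size=int(lg.get("batch_size", 1024)),
        seed=seed,
    )
    cn = dict(m.get("clinicnet", {}))
    net_raw = dict(cn.get("net", {}))
    net = NetworkParams(
        hidden_units=tuple(net_raw.get("hidden_units", (64, 64))),
        dropout_rate=float(net_raw.get("dropout_rate", 0.0)),
        batch_norm=bool(net_raw.get("batch_norm", False)),
    )
    loss_raw = dict(cn.get("loss", {}))
    loss = LossSpec(
        positive_weight=float(loss_raw.get("positive_weight", 10.0)),
        l2_lambda=float(loss_raw.get("l2_lambda", 0.0)),
    )
    tr = dict(cn.get("train", {}))
    clinicnet_train = TrainConfig(
        optimizer=tr.get("optimizer", "nadam"),
        learning_rate=float(tr.get("learning_rate", 0.001)),
        epochs=int(tr.get("epochs", 1)),
        batch_size=int(tr.get("batch_size", 1024)),
        seed=seed,
    )
    b = dict(raw.get("baselines", {}))
    bs = dict(raw.get("bootstrap", {}))
    return PipelineConfig(
        seed=seed,
        cohort=cohort,
        vocab_min_count=int(raw.get("vocab", {}).get("min_count", 256)),
        sd_threshold=float(raw.get("transforms", {}).get("sd_threshold", 0.01)),
        split=split,
        logistic_train=logistic_train,
        clinicnet_net=net,
        clinicnet_loss=loss,
        clinicnet_train=clinicnet_train,
        baseline_min_usage=int(b.get("min_usage", 50)),
        baseline_window=pd.Timedelta(days=float(b.get("window_days", 2))),
        bootstrap_rows=int(bs.get("rows_per_sample", 10_000)),
        bootstrap_iterations=int(bs.get("iterations", 1_000)),
    )
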