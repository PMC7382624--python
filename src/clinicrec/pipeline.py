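"""End-to-end experiment orchestration: simulate → featurize → split → train →
baseline → evaluate, with per-stage derived seeds and a run manifest.

One top-level seed fans out deterministically to every stage
(``stage_seed(seed, k) = (seed·1000003 + k) mod 2³¹``), so a rerun with the
same config and seed reproduces every artifact bit for bit, and individual
stages can be rerun in isolation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from clinicrec import io
from clinicrec.baselines import (
    fit_admission_baseline,
    orderset_contents_prediction,
    score_admission_baseline,
)
from clinicrec.config import PipelineConfig
from clinicrec.evaluation import (
    MetricReport,
    MetricUndefinedError,
    auroc,
    average_precision,
    bootstrap_ci,
    match_recall_threshold,
    prf_at_threshold,
)
from clinicrec.events import build_order_vocabulary
from clinicrec.features import (
    WindowSpec,
    apply_transforms,
    build_feature_rows,
    build_response_rows,
    fit_transform_stats,
)
from clinicrec.models import predict_scores, train_clinicnet, train_logistic
from clinicrec.partitioning import (
    apply_temporal_filter,
    filter_orderset_task_rows,
    split_patients,
)

logger = logging.getLogger("clinicrec")

_STAGE_IDS = {"simulate": 1, "split": 2, "logistic": 3, "clinicnet": 4, "bootstrap": 5}


def stage_seed(seed: int, stage: str, extra: int = 0) -> int:
    return (seed * 1_000_003 + _STAGE_IDS[stage] * 101 + extra) % (2**31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def setup_logging(level: str = "INFO", log_file: Path | None = None) -> None:
    handlers: list[logging.Handler] = [logging.StreamHandler(sys.stderr)]
    if log_file is not None:
        handlers.append(logging.FileHandler(log_file))
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        handlers=handlers,
        force=True,
    )


def simulate_stage(config: PipelineConfig, out: Path) -> None:
    from clinicrec.synthetic import generate_cohort

    out.mkdir(parents=True, exist_ok=True)
    spec = dataclasses.replace(config.cohort, seed=stage_seed(config.seed, "simulate"))
    events, order_sets, admissions = generate_cohort(spec)
    io.write_events(events, out / "events.tsv")
    io.write_order_sets(order_sets, out / "order_sets.tsv")
    io.write_admissions(admissions, out / "admissions.tsv")
    logger.info("simulated %d events for %d patients", len(events), spec.n_patients)


def run_experiment(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run the whole experiment into ``out_dir``; returns the report dict.

    Emits, per task (individual items; order sets) and per scorer (logistic,
    clinicnet, institutional order-set contents, admissions frequency), a
    MetricReport with patient-level bootstrap CIs.  The item task is
    evaluated both on the overall test set and on the order-set-provenance
    subset, where the recall-matched precision/F1 comparison against the
    institutional baseline is made.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.save(out / "config.resolved.yaml")

    stage = "simulate"
    try:
        simulate_stage(config, out)
        events = io.read_events(out / "events.tsv")
        order_sets = io.read_order_sets(out / "order_sets.tsv")
        admissions = io.read_admissions(out / "admissions.tsv")

        stage = "featurize"
        order_vocab = sorted(
            build_order_vocabulary(events, min_count=config.vocab_min_count)
        )
        if not order_vocab:
            raise RuntimeError(
                f"order vocabulary is empty at min_count={config.vocab_min_count}"
            )
        diag_codes = sorted(events.loc[events["category"] == "diagnosis_code", "item_id"].unique())
        feature_vocab = sorted(set(order_vocab) | set(diag_codes))
        demo = events.loc[events["category"] == "demographic", ["patient_id", "item_id"]]
        windows = WindowSpec()
        fm = build_feature_rows(events, feature_vocab, windows, demographics=demo)
        rm_items = build_response_rows(events, order_vocab, windows.response_horizon, kind="items")
        os_ids = sorted(order_sets)
        rm_sets = build_response_rows(events, os_ids, windows.response_horizon, kind="ordersets")
        io.write_sparse_matrix(fm.X, fm.row_index, fm.column_index, out / "features")
        logger.info(
            "featurized: %d rows, %d columns, %d order targets, %d order sets",
            fm.X.shape[0], fm.X.shape[1], len(order_vocab), len(os_ids),
        )

        stage = "split"
        split_spec = dataclasses.replace(config.split, seed=stage_seed(config.seed, "split"))
        assignment = split_patients(events["patient_id"].unique(), split_spec)
        io.write_split_manifest(assignment, out / "split.tsv")
        parts = apply_temporal_filter(fm.row_index, assignment, split_spec)
        parts_sets = {
            name: filter_orderset_task_rows(idx, rm_sets.Y) for name, idx in parts.items()
        }
        for name in ("train", "val", "test"):
            logger.info(
                "partition %s: %d item-task rows, %d order-set-task rows",
                name, len(parts[name]), len(parts_sets[name]),
            )
        if any(len(parts[p]) == 0 for p in ("train", "test")):
            raise RuntimeError("a partition is empty after temporal filtering")

        reports: dict[str, dict] = {}
        boot = dict(
            rows_per_sample=config.bootstrap_rows,
            iterations=config.bootstrap_iterations,
            seed=stage_seed(config.seed, "bootstrap"),
        )

        def evaluate(name, task, pids, scores, labels, extra_metrics=()):
            rep = MetricReport(model=name, task=task)
            metrics = {"auroc": auroc, "average_precision": average_precision}
            for mname, fn in metrics.items():
                if name == "institutional" and mname == "auroc":
                    continue  # single-operating-point predictor: ROC undefined in practice
                try:
                    rep.add(mname, bootstrap_ci(fn, pids, scores, labels, **boot))
                except MetricUndefinedError as err:
                    logger.warning("%s/%s %s undefined: %s", task, name, mname, err)
            for mname, fn in extra_metrics:
                rep.add(mname, bootstrap_ci(fn, pids, scores, labels, **boot))
            reports[f"{task}/{name}"] = rep.as_dict()
            return rep

        # ---- individual item task ------------------------------------------
        stage = "train-items"
        def subset(idx, transform_stats):
            sub = dataclasses.replace(
                fm, X=fm.X[idx], row_index=fm.row_index.iloc[idx].reset_index(drop=True)
            )
            return apply_transforms(sub, transform_stats)

        stats_items = fit_transform_stats(
            dataclasses.replace(
                fm,
                X=fm.X[parts["train"]],
                row_index=fm.row_index.iloc[parts["train"]].reset_index(drop=True),
            ),
            sd_threshold=config.sd_threshold,
        )
        io.write_json(stats_items.to_json(), out / "transform_stats.items.json")
        Xtr = subset(parts["train"], stats_items)
        Xte = subset(parts["test"], stats_items)
        Ytr = rm_items.Y[parts["train"]]
        Yte = np.asarray(rm_items.Y[parts["test"]].todense())
        pids_te = fm.row_index["patient_id"].to_numpy()[parts["test"]]

        cfg_lg = dataclasses.replace(
            config.logistic_train, seed=stage_seed(config.seed, "logistic", 0)
        )
        logistic_items = train_logistic(Xtr, Ytr, cfg_lg)
        cfg_cn = dataclasses.replace(
            config.clinicnet_train, seed=stage_seed(config.seed, "clinicnet", 0)
        )
        clinicnet_items = train_clinicnet(
            Xtr, Ytr, config.clinicnet_net, config.clinicnet_loss, cfg_cn,
            log_path=out / "clinicnet.items.train.jsonl",
        )
        logistic_items.save(out / "logistic.items.json")
        clinicnet_items.save(out / "clinicnet.items.json")

        stage = "evaluate-items"
        s_lg = predict_scores(logistic_items, Xte)
        s_cn = predict_scores(clinicnet_items, Xte)
        evaluate("logistic", "items_overall", pids_te, s_lg, Yte)
        evaluate("clinicnet", "items_overall", pids_te, s_cn, Yte)

        # order-set-provenance subset + institutional contents baseline
        stage = "baseline-institutional"
        test_rows = fm.row_index.iloc[parts["test"]].reset_index(drop=True)
        keep, inst_pred, n_excluded = orderset_contents_prediction(
            test_rows, order_sets, order_vocab
        )
        logger.info(
            "institutional subset: %d rows (%d dual-provenance rows excluded)",
            len(keep), n_excluded,
        )
        if len(keep):
            pids_sub = test_rows["patient_id"].to_numpy()[keep]
            Y_sub = Yte[keep]
            inst_dense = np.asarray(inst_pred.todense())
            rep_inst = evaluate("institutional", "items_orderset_subset", pids_sub, inst_dense, Y_sub)
            inst_recall = prf_at_threshold(inst_dense, Y_sub, 0.5).recall
            for name, scores in (("logistic", s_lg[keep]), ("clinicnet", s_cn[keep])):
                tau = match_recall_threshold(scores, Y_sub, inst_recall)
                extra = [
                    ("precision", lambda s, y, t=tau: prf_at_threshold(s, y, t).precision),
                    ("recall", lambda s, y, t=tau: prf_at_threshold(s, y, t).recall),
                    ("f1", lambda s, y, t=tau: prf_at_threshold(s, y, t).f1),
                ]
                rep = evaluate(name, "items_orderset_subset", pids_sub, scores, Y_sub, extra)
                rep.metrics["threshold"] = {"value": tau}
                reports[f"items_orderset_subset/{name}"] = rep.as_dict()
            extra_inst = [
                ("precision", lambda s, y: prf_at_threshold(s, y, 0.5).precision),
                ("recall", lambda s, y: prf_at_threshold(s, y, 0.5).recall),
                ("f1", lambda s, y: prf_at_threshold(s, y, 0.5).f1),
            ]
            for mname, fn in extra_inst:
                rep_inst.add(mname, bootstrap_ci(fn, pids_sub, inst_dense, Y_sub, **boot))
            reports["items_orderset_subset/institutional"] = rep_inst.as_dict()

        # ---- order-set task ------------------------------------------------
        stage = "train-ordersets"
        tr_os, te_os = parts_sets["train"], parts_sets["test"]
        if len(tr_os) and len(te_os):
            stats_sets = fit_transform_stats(
                dataclasses.replace(
                    fm,
                    X=fm.X[tr_os],
                    row_index=fm.row_index.iloc[tr_os].reset_index(drop=True),
                ),
                sd_threshold=config.sd_threshold,
            )
            Xtr_os = subset(tr_os, stats_sets)
            Xte_os = subset(te_os, stats_sets)
            Ytr_os = rm_sets.Y[tr_os]
            Yte_os = np.asarray(rm_sets.Y[te_os].todense())
            pids_os = fm.row_index["patient_id"].to_numpy()[te_os]

            logistic_sets = train_logistic(
                Xtr_os, Ytr_os,
                dataclasses.replace(config.logistic_train, seed=stage_seed(config.seed, "logistic", 1)),
            )
            clinicnet_sets = train_clinicnet(
                Xtr_os, Ytr_os, config.clinicnet_net, config.clinicnet_loss,
                dataclasses.replace(config.clinicnet_train, seed=stage_seed(config.seed, "clinicnet", 1)),
                log_path=out / "clinicnet.ordersets.train.jsonl",
            )
            stage = "baseline-admissions"
            train_patients = {p for p, part in assignment.items() if part == "train"}
            train_events = events[
                events["patient_id"].isin(train_patients)
                & (events["timestamp"] < split_spec.train_before)
            ]
            train_adm = admissions[
                admissions["patient_id"].isin(train_patients)
                & (admissions["timestamp"] < split_spec.train_before)
            ]
            adm_model = fit_admission_baseline(
                train_events, train_adm, os_ids,
                min_usage=config.baseline_min_usage, window=config.baseline_window,
            )
            io.write_json(adm_model.to_json(), out / "admission_baseline.json")

            stage = "evaluate-ordersets"
            test_rows_os = fm.row_index.iloc[te_os].reset_index(drop=True)
            evaluate("logistic", "ordersets", pids_os, predict_scores(logistic_sets, Xte_os), Yte_os)
            evaluate("clinicnet", "ordersets", pids_os, predict_scores(clinicnet_sets, Xte_os), Yte_os)
            evaluate(
                "admissions", "ordersets", pids_os,
                score_admission_baseline(adm_model, test_rows_os, admissions), Yte_os,
            )

        stage = "manifest"
        manifest = {
            "package_version": _version(),
            "seed": config.seed,
            "stage_seeds": {k: stage_seed(config.seed, k) for k in _STAGE_IDS},
            "input_hashes": {
                f.name: _sha256(f)
                for f in sorted(out.glob("*.tsv"))
            },
            "n_feature_rows": int(fm.X.shape[0]),
            "n_feature_columns": int(fm.X.shape[1]),
            "order_vocab_size": len(order_vocab),
            "n_order_sets": len(os_ids),
            "partition_rows": {k: int(len(v)) for k, v in parts.items()},
            "partition_rows_orderset_task": {k: int(len(v)) for k, v in parts_sets.items()},
        }
        io.write_json(manifest, out / "manifest.json")
        io.write_json(reports, out / "metric_reports.json")
        return reports
    except Exception:
        logger.exception("pipeline failed at stage %r; partial outputs kept in %s", stage, out)
        raise


def _version() -> str:
    from clinicrec import __version__

    return __version__
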