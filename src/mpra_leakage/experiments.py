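"""End-to-end experiment families quantifying layout-induced leakage.

Every experiment follows the same pipeline — generate (or accept) a dataset,
build features, construct a train/validation layout, fit a non-tweaked
random forest regressor on the confidence score, and score the validation
SNVs with the metric battery — and varies exactly one thing:

* ``run_baseline`` — the zebra layout (16-bp training blocks, 25/75);
* ``run_holdout_sweep`` — exclude each target reporter from training
  entirely, with or without enlarging the rest to complete training, plus
  the grouped holdout of duplicated reporters;
* ``run_block_shift_sweep`` — a single contiguous training block per
  reporter at several shifts from the 5' end;
* ``run_block_length_sweep`` — random non-overlapping training blocks of
  fixed length, several lengths, several samples each;
* ``run_irrelevant_control`` — alien (irrelevant, autocorrelated) features
  only, under zebra vs reporter holdout vs within-reporter shuffling: the
  leakage gap in its purest form;
* ``run_external_validation`` — train on the primary dataset, evaluate on a
  freshly generated, fully unseen reporter set.

Holdout-family models are always scored on the target reporter's
zebra-validation SNVs so deltas against the baseline compare identical
evaluation sets.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .features import (
    FeatureMatrix,
    alien_features,
    assemble,
    motif_features,
    shuffle_within_reporters,
    track_features,
)
from .layouts import (
    SplitConfig,
    SplitFamily,
    SplitLayout,
    build_layout,
)
from .metrics import auc_roc, evaluate, reports_to_frame
from .models import ModelSpec, Task, binary_scores, predict, train
from .synthetic import SyntheticConfig, SyntheticDataset, generate_dataset


class ExperimentError(ValueError):
    pass


@dataclass
class ExperimentConfig:
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    providers: tuple[str, ...] = ("track",)
    n_estimators: int = 500
    train_fraction: float = 0.25
    block_length: int = 16
    seeds: tuple[int, ...] = (0,)
    shifts: tuple[float, ...] = (0.0, 0.25, 0.5, 0.75)
    block_lengths: tuple[int, ...] = (1, 2, 4, 8, 16, 32, 64)
    samples_per_length: int = 10
    holdout_reference: bool = False
    holdout_targets_per_seed: int = 3
    include_complete_training: bool = True

    def __post_init__(self) -> None:
        if not self.seeds:
            raise ExperimentError("at least one seed is required")
        if not self.providers:
            raise ExperimentError("at least one feature provider is required")


@dataclass
class ExperimentResult:
    name: str
    tables: dict[str, pd.DataFrame]
    summary: dict
    manifest: dict


# ---------------------------------------------------------------------------
# shared pipeline pieces


def build_features(dataset: SyntheticDataset, providers: Sequence[str]) -> FeatureMatrix:
    parts = []
    for name in providers:
        if name == "motif":
            parts.append(motif_features(dataset, dataset.pwms))
        elif name == "track":
            parts.append(track_features(dataset, dataset.informative_tracks))
        elif name == "alien":
            parts.append(
                alien_features(dataset, dataset.alien_tracks,
                               dataset.config.alien_region_length)
            )
        else:
            raise ExperimentError(f"unknown feature provider {name!r}")
    return assemble(*parts)


def _subset(features: FeatureMatrix, mask: np.ndarray) -> FeatureMatrix:
    return FeatureMatrix(df=features.df.iloc[np.where(mask)[0]],
                         provenance=dict(features.provenance))


def fit_and_evaluate(
    dataset: SyntheticDataset,
    features: FeatureMatrix,
    layout: SplitLayout,
    model_seed: int,
    n_estimators: int,
    eval_layout: SplitLayout | None = None,
):
    """Train the confidence regressor on the layout's training rows and score
    the validation rows of ``eval_layout`` (default: the same layout)."""
    targets = dataset.confidences()
    spec = ModelSpec(task=Task.CONFIDENCE_REGRESSION,
                     n_estimators=n_estimators, seed=model_seed)
    model = train(_subset(features, layout.train_mask),
                  targets[layout.train_mask], spec)
    predictions = predict(model, features)
    reports = evaluate(predictions, dataset, eval_layout or layout)
    return reports, predictions


def _scope_metric(reports, scope: str, metric: str) -> float:
    for r in reports:
        if r.scope == scope:
            return float(r.metrics[metric])
    raise ExperimentError(f"scope {scope!r} absent from reports")


def _manifest(config: ExperimentConfig, name: str) -> dict:
    synth = dataclasses.asdict(config.synthetic)
    synth["pwm_set"] = (
        None if config.synthetic.pwm_set is None
        else [p.motif_id for p in config.synthetic.pwm_set]
    )
    cfg = dataclasses.asdict(config)
    cfg["synthetic"] = synth
    return {"experiment": name, "config": cfg}


def _dataset_for_seed(config: ExperimentConfig, seed: int) -> SyntheticDataset:
    synth = dataclasses.replace(config.synthetic, seed=int(seed))
    return generate_dataset(synth)


def _zebra_config(config: ExperimentConfig) -> SplitConfig:
    return SplitConfig(family=SplitFamily.ZEBRA,
                       block_length=config.block_length,
                       train_fraction=config.train_fraction)


# ---------------------------------------------------------------------------
# experiment families


def run_baseline(config: ExperimentConfig) -> ExperimentResult:
    tables: dict[str, pd.DataFrame] = {}
    pooled_auc, pooled_prc = [], []
    for seed in config.seeds:
        dataset = _dataset_for_seed(config, seed)
        features = build_features(dataset, config.providers)
        layout = build_layout(dataset, _zebra_config(config))
        reports, _ = fit_and_evaluate(dataset, features, layout, seed,
                                      config.n_estimators)
        tables[f"seed{seed}"] = reports_to_frame(reports)
        pooled_auc.append(_scope_metric(reports, "pooled", "AUCROC"))
        pooled_prc.append(_scope_metric(reports, "pooled", "AUPRC"))
    summary = {
        "mean_pooled_aucroc": float(np.mean(pooled_auc)),
        "mean_pooled_auprc": float(np.mean(pooled_prc)),
        "n_seeds": len(config.seeds),
    }
    return ExperimentResult("baseline", tables, summary,
                            _manifest(config, "baseline"))


def _holdout_config(target: str, complete: bool, base: ExperimentConfig) -> SplitConfig:
    return SplitConfig(
        family=SplitFamily.REPORTER_HOLDOUT,
        block_length=base.block_length,
        train_fraction=base.train_fraction,
        target_reporter_id=target,
        use_complete_training=complete,
    )


def run_holdout_sweep(config: ExperimentConfig) -> ExperimentResult:
    """Per-reporter holdout and complete-training holdout, with the grouped
    holdout for duplicated reporters, evaluated on zebra-validation SNVs."""
    if config.synthetic.n_reporters < 2:
        raise ExperimentError("holdout sweep needs at least two reporters")
    rows = []
    for seed in config.seeds:
        dataset = _dataset_for_seed(config, seed)
        features = build_features(dataset, config.providers)
        zebra = build_layout(dataset, _zebra_config(config))
        base_reports, _ = fit_and_evaluate(dataset, features, zebra, seed,
                                           config.n_estimators)
        seq_counts: dict[str, int] = {}
        for rep in dataset.reporters:
            seq_counts[rep.sequence] = seq_counts.get(rep.sequence, 0) + 1
        for rep in dataset.reporters:
            rid = rep.reporter_id
            row = {
                "seed": seed,
                "reporter_id": rid,
                "baseline_AUCROC": _scope_metric(base_reports, rid, "AUCROC"),
                "baseline_AUPRC": _scope_metric(base_reports, rid, "AUPRC"),
            }
            modes = [("holdout", False)]
            if config.include_complete_training:
                modes.append(("complete", True))
            for label, complete in modes:
                layout = build_layout(dataset, _holdout_config(rid, complete, config))
                reports, _ = fit_and_evaluate(dataset, features, layout, seed,
                                              config.n_estimators,
                                              eval_layout=zebra)
                row[f"{label}_AUCROC"] = _scope_metric(reports, rid, "AUCROC")
                row[f"{label}_AUPRC"] = _scope_metric(reports, rid, "AUPRC")
            if not config.include_complete_training:
                row["complete_AUCROC"] = float("nan")
                row["complete_AUPRC"] = float("nan")
            if seq_counts[rep.sequence] > 1:
                grouped_cfg = SplitConfig(
                    family=SplitFamily.GROUPED_HOLDOUT,
                    block_length=config.block_length,
                    train_fraction=config.train_fraction,
                    target_reporter_id=rid,
                )
                layout = build_layout(dataset, grouped_cfg)
                reports, _ = fit_and_evaluate(dataset, features, layout, seed,
                                              config.n_estimators,
                                              eval_layout=zebra)
                row["grouped_AUCROC"] = _scope_metric(reports, rid, "AUCROC")
                row["grouped_AUPRC"] = _scope_metric(reports, rid, "AUPRC")
            else:
                row["grouped_AUCROC"] = float("nan")
                row["grouped_AUPRC"] = float("nan")
            rows.append(row)
    table = pd.DataFrame(rows)
    degraded = table["holdout_AUPRC"] < table["baseline_AUPRC"]
    dup = table[np.isfinite(table["grouped_AUCROC"])]
    single_delta = float(np.mean(np.abs(dup["baseline_AUCROC"] - dup["holdout_AUCROC"]))) if len(dup) else float("nan")
    grouped_delta = float(np.mean(dup["baseline_AUCROC"] - dup["grouped_AUCROC"])) if len(dup) else float("nan")
    summary = {
        "fraction_reporters_auprc_degraded": float(np.mean(degraded)),
        "mean_holdout_delta_aucroc": float(
            np.mean(table["baseline_AUCROC"] - table["holdout_AUCROC"])
        ),
        "mean_complete_minus_holdout_aucroc": float(
            np.mean(table["complete_AUCROC"] - table["holdout_AUCROC"])
        ),
        "duplicate_single_holdout_abs_delta_aucroc": single_delta,
        "duplicate_grouped_holdout_delta_aucroc": grouped_delta,
    }
    return ExperimentResult("holdout_sweep", {"per_reporter": table}, summary,
                            _manifest(config, "holdout_sweep"))


def run_block_shift_sweep(config: ExperimentConfig) -> ExperimentResult:
    """Single-block layouts at each shift; per-reporter deltas vs baseline."""
    for s in config.shifts:
        if not (0.0 <= s <= 1.0 - config.train_fraction):
            raise ExperimentError(f"shift {s} outside [0, 1 - train_fraction]")
    rows = []
    for seed in config.seeds:
        dataset = _dataset_for_seed(config, seed)
        features = build_features(dataset, config.providers)
        zebra = build_layout(dataset, _zebra_config(config))
        base_reports, _ = fit_and_evaluate(dataset, features, zebra, seed,
                                           config.n_estimators)
        holdout_ref: dict[str, float] = {}
        if config.holdout_reference:
            for rep in dataset.reporters:
                layout = build_layout(
                    dataset, _holdout_config(rep.reporter_id, False, config)
                )
                reports, _ = fit_and_evaluate(dataset, features, layout, seed,
                                              config.n_estimators,
                                              eval_layout=zebra)
                holdout_ref[rep.reporter_id] = _scope_metric(
                    reports, rep.reporter_id, "AUCROC"
                )
        for shift in config.shifts:
            cfg = SplitConfig(family=SplitFamily.SINGLE_BLOCK,
                              train_fraction=config.train_fraction,
                              shift_fraction=shift)
            layout = build_layout(dataset, cfg)
            reports, _ = fit_and_evaluate(dataset, features, layout, seed,
                                          config.n_estimators)
            for rep in dataset.reporters:
                rows.append({
                    "seed": seed,
                    "shift": shift,
                    "reporter_id": rep.reporter_id,
                    "AUCROC": _scope_metric(reports, rep.reporter_id, "AUCROC"),
                    "AUPRC": _scope_metric(reports, rep.reporter_id, "AUPRC"),
                    "delta_AUCROC": (
                        _scope_metric(reports, rep.reporter_id, "AUCROC")
                        - _scope_metric(base_reports, rep.reporter_id, "AUCROC")
                    ),
                    "delta_AUPRC": (
                        _scope_metric(reports, rep.reporter_id, "AUPRC")
                        - _scope_metric(base_reports, rep.reporter_id, "AUPRC")
                    ),
                    "holdout_ref_AUCROC": holdout_ref.get(rep.reporter_id,
                                                          float("nan")),
                })
    table = pd.DataFrame(rows)
    per_shift = table.groupby("shift")["delta_AUCROC"].mean()
    mean_degradation = float(-per_shift.mean())
    summary = {
        "mean_delta_aucroc_by_shift": {float(k): float(v)
                                       for k, v in per_shift.items()},
        "mean_degradation_aucroc": mean_degradation,
        "across_shift_variance": float(per_shift.var(ddof=0)),
    }
    return ExperimentResult("block_shift_sweep", {"per_condition": table},
                            summary, _manifest(config, "block_shift_sweep"))


def run_block_length_sweep(config: ExperimentConfig) -> ExperimentResult:
    """Random-blocks layouts over a grid of block lengths; mean and sd of the
    pooled metrics per length, against the zebra reference."""
    if config.samples_per_length < 1:
        raise ExperimentError("samples_per_length must be >= 1")
    rows = []
    for seed in config.seeds:
        dataset = _dataset_for_seed(config, seed)
        features = build_features(dataset, config.providers)
        zebra = build_layout(dataset, _zebra_config(config))
        base_reports, _ = fit_and_evaluate(dataset, features, zebra, seed,
                                           config.n_estimators)
        zebra_auc = _scope_metric(base_reports, "pooled", "AUCROC")
        for length in config.block_lengths:
            for sample in range(config.samples_per_length):
                layout_seed = (int(seed) * 100003 + length * 101 + sample) % (2**31)
                cfg = SplitConfig(family=SplitFamily.RANDOM_BLOCKS,
                                  block_length=length,
                                  train_fraction=config.train_fraction,
                                  seed=layout_seed)
                layout = build_layout(dataset, cfg)
                reports, _ = fit_and_evaluate(dataset, features, layout, seed,
                                              config.n_estimators)
                rows.append({
                    "seed": seed,
                    "block_length": length,
                    "sample": sample,
                    "AUCROC": _scope_metric(reports, "pooled", "AUCROC"),
                    "AUPRC": _scope_metric(reports, "pooled", "AUPRC"),
                    "zebra_AUCROC": zebra_auc,
                })
    table = pd.DataFrame(rows)
    by_len = table.groupby("block_length")["AUCROC"].agg(["mean", "std"])
    if config.samples_per_length == 1:
        by_len["std"] = float("nan")
    spearman = float(
        stats.spearmanr(by_len.index.to_numpy(), by_len["mean"].to_numpy()).statistic
    ) if len(by_len) > 1 else float("nan")
    summary = {
        "mean_aucroc_by_length": {int(k): float(v)
                                  for k, v in by_len["mean"].items()},
        "sd_aucroc_by_length": {int(k): float(v)
                                for k, v in by_len["std"].items()},
        "spearman_length_vs_aucroc": spearman,
    }
    return ExperimentResult("block_length_sweep", {"per_condition": table},
                            summary, _manifest(config, "block_length_sweep"))


def run_irrelevant_control(config: ExperimentConfig) -> ExperimentResult:
    """Alien-features-only leakage control.

    Three conditions per seed: zebra (leaky), per-reporter holdout
    (leak-free; a rotating subset of ``holdout_targets_per_seed`` reporters
    is held out one at a time, and the held-out predictions are pooled, which
    keeps the sweep desk-sized), and zebra after shuffling alien values
    within reporters (destroying the local autocorrelation that carries the
    leak).
    """
    rows = []
    for i, seed in enumerate(config.seeds):
        dataset = _dataset_for_seed(config, seed)
        features = build_features(dataset, ("alien",))
        zebra = build_layout(dataset, _zebra_config(config))
        reports, _ = fit_and_evaluate(dataset, features, zebra, seed,
                                      config.n_estimators)
        zebra_auc = _scope_metric(reports, "pooled", "AUCROC")
        zebra_prc = _scope_metric(reports, "pooled", "AUPRC")

        # leave-one-out over a rotating target subset; pool their predictions.
        # Grouped holdout semantics: a duplicated reporter's sequence twin is
        # excluded from training as well, otherwise the twin's identical
        # features and correlated effects compensate for the holdout and the
        # reference is no longer leak-free.
        n_rep = len(dataset.reporters)
        k = max(1, min(config.holdout_targets_per_seed, n_rep))
        targets = [
            dataset.reporters[(i * k + j) % n_rep].reporter_id for j in range(k)
        ]
        snv_by_id = {s.snv_id: s for s in dataset.snvs}
        pooled_scores: list[float] = []
        pooled_labels: list[int] = []
        for target in targets:
            grouped_cfg = SplitConfig(
                family=SplitFamily.GROUPED_HOLDOUT,
                block_length=config.block_length,
                train_fraction=config.train_fraction,
                target_reporter_id=target,
            )
            layout = build_layout(dataset, grouped_cfg)
            _, predictions = fit_and_evaluate(dataset, features, layout, seed,
                                              config.n_estimators,
                                              eval_layout=zebra)
            conf = binary_scores(predictions)
            for sid, lab, c in zip(zebra.snv_ids, zebra.labels, conf):
                snv = snv_by_id[sid]
                if snv.reporter_id == target and lab == 1:
                    pooled_scores.append(float(c))
                    pooled_labels.append(abs(snv.direction))
        holdout_auc = auc_roc(pooled_scores, pooled_labels)

        rng = np.random.default_rng([int(seed), 11])
        shuffled = shuffle_within_reporters(features, dataset, rng)
        reports, _ = fit_and_evaluate(dataset, shuffled, zebra, seed,
                                      config.n_estimators)
        shuffled_auc = _scope_metric(reports, "pooled", "AUCROC")

        rows.append({
            "seed": seed,
            "zebra_AUCROC": zebra_auc,
            "zebra_AUPRC": zebra_prc,
            "holdout_targets": ",".join(targets),
            "holdout_AUCROC": holdout_auc,
            "shuffled_zebra_AUCROC": shuffled_auc,
        })
    table = pd.DataFrame(rows)
    summary = {
        "mean_zebra_aucroc": float(table["zebra_AUCROC"].mean()),
        "mean_zebra_auprc": float(table["zebra_AUPRC"].mean()),
        "mean_holdout_aucroc": float(table["holdout_AUCROC"].mean()),
        "mean_shuffled_zebra_aucroc": float(table["shuffled_zebra_AUCROC"].mean()),
        "leakage_gap_aucroc": float(
            (table["zebra_AUCROC"] - table["holdout_AUCROC"]).mean()
        ),
    }
    return ExperimentResult("irrelevant_control", {"per_seed": table}, summary,
                            _manifest(config, "irrelevant_control"))


def run_external_validation(
    config: ExperimentConfig,
    external_dataset: SyntheticDataset | None = None,
) -> ExperimentResult:
    """Train on the primary dataset, evaluate on a fully unseen reporter set.

    In synthetic mode the external set is a freshly seeded two-reporter
    dataset (disjoint site placements by construction).  Both the zebra-
    trained and the complete-trained model are scored, pooled over all
    external SNVs.
    """
    rows = []
    for seed in config.seeds:
        dataset = _dataset_for_seed(config, seed)
        features = build_features(dataset, config.providers)
        if external_dataset is None:
            ext_cfg = dataclasses.replace(
                config.synthetic, n_reporters=2, duplicate_reporter=False,
                seed=(int(seed) + 9973) % (2**31),
            )
            external = generate_dataset(ext_cfg)
        else:
            external = external_dataset
        ext_features = build_features(external, config.providers)
        ext_all = SplitLayout(
            snv_ids=[s.snv_id for s in external.snvs],
            labels=np.ones(len(external.snvs), dtype=np.int8),
            position_labels={r.reporter_id: np.ones(r.length, dtype=np.int8)
                             for r in external.reporters},
        )
        targets = dataset.confidences()
        zebra = build_layout(dataset, _zebra_config(config))
        for label, mask in (("zebra", zebra.train_mask),
                            ("complete", np.ones(len(dataset.snvs), dtype=bool))):
            spec = ModelSpec(task=Task.CONFIDENCE_REGRESSION,
                             n_estimators=config.n_estimators, seed=seed)
            model = train(_subset(features, mask), targets[mask], spec)
            predictions = predict(model, ext_features)
            reports = evaluate(predictions, external, ext_all)
            internal_auc = float("nan")
            if label == "zebra":
                internal_reports, _ = fit_and_evaluate(
                    dataset, features, zebra, seed, config.n_estimators
                )
                internal_auc = _scope_metric(internal_reports, "pooled", "AUCROC")
            rows.append({
                "seed": seed,
                "training": label,
                "external_AUCROC": _scope_metric(reports, "pooled", "AUCROC"),
                "external_AUPRC": _scope_metric(reports, "pooled", "AUPRC"),
                "internal_AUCROC": internal_auc,
            })
    table = pd.DataFrame(rows)
    zebra_rows = table[table["training"] == "zebra"]
    summary = {
        "mean_external_aucroc_zebra": float(zebra_rows["external_AUCROC"].mean()),
        "mean_external_aucroc_complete": float(
            table[table["training"] == "complete"]["external_AUCROC"].mean()
        ),
        "mean_internal_aucroc_zebra": float(zebra_rows["internal_AUCROC"].mean()),
    }
    return ExperimentResult("external_validation", {"per_condition": table},
                            summary, _manifest(config, "external_validation"))
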