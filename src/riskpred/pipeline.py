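"""End-to-end experiment orchestration.

One config drives the whole protocol: load or simulate genotypes -> QC
-> mode imputation -> class balancing -> stratified 70/30 train/test
split -> five-fold JMI stability selection on the training portion ->
threshold the stability weights into a panel -> train the MLP on the
training samples restricted to the panel (optionally grid-searched) ->
evaluate once on the untouched 30% test set.

The test partition is never seen by selection or training; this is
enforced structurally (fold groups and training rows are drawn from the
train split only, and the leakage guard asserts the index sets are
disjoint every run).  One master seed derives every stage seed by fixed
offsets, so a config reproduces its report bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import genotype_io as gio
from .evaluation import MetricReport, evaluate_report
from .genotype_io import GenotypeDataset, QCThresholds
from .mlp_classifier import MLPConfig, build_model, grid_search, predict_proba, train
from .stability_selection import (
    StabilityConfig,
    accumulate_weights,
    run_fold_selection,
    threshold_select,
)
from .synthetic_data import SimulationSpec, default_benchmark_spec, simulate_genotypes

__all__ = [
    "ExperimentConfig",
    "ExperimentResult",
    "benchmark_experiment_config",
    "run_experiment",
    "sweep_experiment",
]

# fixed offsets deriving stage seeds from the master seed
_OFF_SIM, _OFF_BALANCE, _OFF_SPLIT, _OFF_FOLDS, _OFF_MLP = 11, 23, 37, 53, 71


@dataclass(frozen=True)
class ExperimentConfig:
    """One experiment: exactly one input source plus all stage configs."""

    simulation: SimulationSpec | None = None
    input_path: str | None = None
    input_format: str = "tsv"  # tsv | vcf | ped
    labels_path: str | None = None
    map_path: str | None = None
    qc: QCThresholds = field(default_factory=QCThresholds)
    stability: StabilityConfig = field(default_factory=StabilityConfig)
    mlp: MLPConfig = field(default_factory=MLPConfig)
    grid_space: dict | None = None
    test_fraction: float = 0.30
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if (self.simulation is None) == (self.input_path is None):
            raise ValueError("provide exactly one of simulation / input_path")


@dataclass
class ExperimentResult:
    report: MetricReport
    weights: np.ndarray
    panel: np.ndarray
    model: object
    log: list[dict]
    train_sample_ids: list[str]
    test_sample_ids: list[str]


def benchmark_experiment_config(seed: int = 0) -> ExperimentConfig:
    """The simulation benchmark profile: the default 2,000-sample /
    5,000-SNP cohort, per-fold selection of 100 SNPs, threshold 0.6, and
    a reduced 2x64 MLP sized for the resulting small panel."""
    return ExperimentConfig(
        simulation=default_benchmark_spec(seed=seed),
        stability=StabilityConfig(folds=5, per_fold_k=100, threshold=0.6, seed=seed),
        mlp=MLPConfig(
            n_hidden_layers=2,
            hidden_units=64,
            activation="tanh",
            optimizer="adam",
            epochs=60,
            learning_rate=1e-3,
            dropout_rate=0.2,
            batch_size=32,
            seed=seed,
            strict_domains=False,
        ),
        seed=seed,
    )


def _hash(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


def _load(config: ExperimentConfig) -> GenotypeDataset:
    if config.simulation is not None:
        spec = replace(config.simulation, seed=config.seed + _OFF_SIM)
        return simulate_genotypes(spec)
    fmt = config.input_format
    if fmt == "tsv":
        return gio.read_matrix_tsv(config.input_path)
    if fmt == "vcf":
        if config.labels_path is None:
            raise ValueError("VCF input needs labels_path")
        return gio.read_vcf(config.input_path, config.labels_path)
    if fmt == "ped":
        if config.map_path is None:
            raise ValueError("PLINK input needs map_path")
        return gio.read_plink_text(config.input_path, config.map_path)
    raise ValueError(f"unknown input format {fmt!r}")


def _prepare(config: ExperimentConfig, log: list[dict]):
    """Shared front half: load -> QC -> impute -> balance -> split -> folds."""
    data = _load(config)
    log.append({"stage": "load", "n": data.n_samples, "q": data.n_snps,
                "hash": _hash(data.genotypes), "seed": config.seed})

    data, qc_report = gio.qc_filter(data, config.qc)
    log.append({"stage": "qc", "q_kept": data.n_snps,
                "removed": {k: len(v) for k, v in qc_report.items()}})

    data = gio.impute_mode(data)
    data = gio.balance_classes(data, seed=config.seed + _OFF_BALANCE)
    log.append({"stage": "balance", "n": data.n_samples,
                "cases": int(data.labels.sum())})

    train_set, test_set = gio.stratified_split(
        data, config.test_fraction, seed=config.seed + _OFF_SPLIT
    )
    assert set(train_set.sample_ids).isdisjoint(test_set.sample_ids), "leakage"
    log.append({"stage": "split", "n_train": train_set.n_samples,
                "n_test": test_set.n_samples, "hash_train": _hash(train_set.genotypes),
                "hash_test": _hash(test_set.genotypes)})

    stab = replace(config.stability, seed=config.seed + _OFF_FOLDS)
    indicators = run_fold_selection(train_set, stab)
    weights = accumulate_weights(indicators)
    log.append({"stage": "stability", "folds": stab.folds,
                "per_fold_k": stab.per_fold_k,
                "n_nonzero_weight": int((weights > 0).sum())})
    return train_set, test_set, weights, stab


def _fit_and_eval(config, train_set, test_set, panel, log) -> tuple[MetricReport, object]:
    features = train_set.genotypes[:, panel].astype(float)
    labels = np.asarray(train_set.labels)
    mlp_cfg = replace(config.mlp, seed=config.seed + _OFF_MLP)
    if config.grid_space is not None:
        mlp_cfg, _ = grid_search(
            features, labels, config.grid_space,
            seed=config.seed + _OFF_MLP, base_config=mlp_cfg,
        )
        log.append({"stage": "grid_search", "chosen": str(mlp_cfg)})
    model = build_model(panel.size, mlp_cfg)
    train(model, features, labels)
    log.append({"stage": "train", "final_loss": model.loss_trace[-1],
                "n_parameters": model.n_parameters()})
    report = evaluate_report(model, test_set, panel)
    log.append({"stage": "evaluate", "report": report.to_dict()})
    return report, model


def run_experiment(config: ExperimentConfig) -> ExperimentResult:
    """Execute the full protocol once and return report plus artifacts."""
    log: list[dict] = []
    train_set, test_set, weights, stab = _prepare(config, log)
    panel = threshold_select(weights, stab.threshold)
    if panel.size == 0:
        raise RuntimeError(
            f"no SNP reached stability weight {stab.threshold}; lower the threshold"
        )
    log.append({"stage": "panel", "threshold": stab.threshold,
                "panel_size": int(panel.size)})
    report, model = _fit_and_eval(config, train_set, test_set, panel, log)
    result = ExperimentResult(
        report=report, weights=weights, panel=panel, model=model,
        log=log, train_sample_ids=train_set.sample_ids,
        test_sample_ids=test_set.sample_ids,
    )
    if config.out_dir:
        _write_artifacts(config, train_set, result)
    return result


def sweep_experiment(
    config: ExperimentConfig, thresholds: list[float]
) -> list[dict]:
    """Re-use one stability run across a threshold sweep.

    For each threshold the MLP is retrained on the resulting panel and
    evaluated on the same held-out split; returns one row per threshold
    with panel size and the metric report (``None`` for empty panels).
    """
    log: list[dict] = []
    train_set, test_set, weights, _ = _prepare(config, log)
    rows = []
    for a in thresholds:
        panel = threshold_select(weights, a)
        row = {"threshold": a, "panel_size": int(panel.size), "report": None}
        if panel.size > 0:
            report, _ = _fit_and_eval(config, train_set, test_set, panel, log)
            row["report"] = report
        rows.append(row)
    return rows


def _write_artifacts(config, train_set, result: ExperimentResult) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    snp_ids = train_set.snp_ids()
    with open(out / "weights.tsv", "w") as fh:
        fh.write("snp_id\tweight\n")
        for sid, w in zip(snp_ids, result.weights):
            fh.write(f"{sid}\t{w:.3f}\n")
    with open(out / "panel.tsv", "w") as fh:
        fh.write("index\tsnp_id\n")
        for j in result.panel:
            fh.write(f"{j}\t{snp_ids[j]}\n")
    (out / "report.json").write_text(result.report.to_json())
    (out / "log.json").write_text(json.dumps(result.log, indent=2, default=str))
    result.model.save(out / "model", panel=[snp_ids[j] for j in result.panel])
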