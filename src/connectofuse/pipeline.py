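"""End-to-end orchestration: split -> fit mask & schema on train -> graphs ->
train -> evaluate, plus the retained-feature-count sweep.

Leakage hygiene is enforced here: the RFE mask, the phenotype vocabularies
and the min-max ranges are all fitted on the training split only and frozen
before the test split is touched.
"""

from __future__ import annotations

from dataclasses import dataclass
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .io import config_hash, read_phenotypes, read_timeseries_dir, save_checkpoint
from .metrics import MetricsReport
from .network import MultimodalGraphClassifier
from .phenotypes import PhenotypeSchema
from .selection import FeatureMask, svm_rfe
from .synthetic import SyntheticCohort
from .training import TrainConfig, build_dataset, connectome_vectors, evaluate, split_dataset, train

__all__ = ["ExperimentResult", "run_experiment", "run_cohort", "run_pipeline", "sweep"]


@dataclass
class ExperimentResult:
    report: MetricsReport
    history: pd.DataFrame
    mask: FeatureMask | None
    schema: PhenotypeSchema | None
    model: MultimodalGraphClassifier
    train_ids: list[str]
    test_ids: list[str]
    config_hash: str


def _train_config(config: PipelineConfig, seed: int) -> TrainConfig:
    t = config.train
    return TrainConfig(
        epochs=t.epochs,
        batch_size=t.batch_size,
        learning_rate=t.learning_rate,
        weight_decay=t.weight_decay,
        lr_step_size=t.lr_step_size,
        lr_gamma=t.lr_gamma,
        optimizer=t.optimizer,
        split_ratio=tuple(t.split_ratio),
        seed=seed,
    )


def run_experiment(
    timeseries: dict[str, np.ndarray],
    phenotypes: pd.DataFrame | None,
    labels: dict[str, int],
    config: PipelineConfig | None = None,
    seed: int | None = None,
    mask: FeatureMask | None = None,
) -> ExperimentResult:
    """Run the full pipeline in memory on already-loaded inputs.

    A pre-built ``mask`` (e.g. from a sweep's shared ranking) bypasses RFE;
    otherwise the mask is fitted on the training split when selection is
    enabled.
    """
    config = config or PipelineConfig()
    seed = config.seed if seed is None else seed
    ids = sorted(timeseries)
    y_all = np.array([labels[s] for s in ids], dtype=int)
    train_idx, test_idx = split_dataset(
        len(ids),
        ratio=tuple(config.train.split_ratio),
        seed=seed,
        stratified=config.train.stratified,
        labels=y_all,
    )
    train_ids = [ids[i] for i in train_idx]
    test_ids = [ids[i] for i in test_idx]

    if mask is None and config.selection.enabled:
        vec_ids, x_train = connectome_vectors({s: timeseries[s] for s in train_ids})
        y_train = np.array([labels[s] for s in vec_ids], dtype=int)
        sel = config.selection
        n_keep = min(sel.n_keep, x_train.shape[1])
        mask = svm_rfe(
            x_train, y_train, n_keep=n_keep,
            step_fraction=sel.step_fraction, C=sel.C, seed=seed,
            importance=sel.importance,
        )

    use_pheno = config.model.use_phenotype and phenotypes is not None
    schema = None
    if use_pheno:
        schema = PhenotypeSchema().fit(phenotypes.loc[train_ids])

    common = dict(
        mask=mask,
        schema=schema,
        shrinkage=config.graph.shrinkage,
        edge_rule=config.graph.edge_rule,
        top_k=config.graph.top_k,
    )
    pheno_arg = phenotypes if use_pheno else None
    train_ds = build_dataset({s: timeseries[s] for s in train_ids}, pheno_arg, labels, **common)
    test_ds = build_dataset({s: timeseries[s] for s in test_ids}, pheno_arg, labels, **common)

    n_roi = train_ds.node_feats.shape[1]
    model = MultimodalGraphClassifier(
        n_roi=n_roi,
        pheno_dim=schema.dim if schema else 0,
        d1=config.model.d1,
        d2=config.model.d2,
        clf_hidden=config.model.clf_hidden,
        pfe_layers=config.model.pfe_layers,
        use_phenotype=use_pheno,
        seed=seed,
    )
    history = train(model, train_ds, _train_config(config, seed))
    report = evaluate(model, test_ds)
    # hash the scientific configuration only — filesystem paths don't affect results
    dump = config.model_dump(mode="json")
    for key in ("timeseries_dir", "phenotype_csv", "output_dir"):
        dump.pop(key, None)
    chash = config_hash({**dump, "seed": seed})
    return ExperimentResult(
        report=report, history=history, mask=mask, schema=schema, model=model,
        train_ids=train_ids, test_ids=test_ids, config_hash=chash,
    )


def run_cohort(
    cohort: SyntheticCohort, config: PipelineConfig | None = None, seed: int | None = None
) -> ExperimentResult:
    """Run the pipeline on an in-memory synthetic cohort."""
    timeseries = {s.subject_id: s.timeseries for s in cohort.subjects}
    labels = {s.subject_id: s.label for s in cohort.subjects}
    pheno = cohort.phenotype_frame().set_index("subject_id")
    return run_experiment(timeseries, pheno, labels, config=config, seed=seed)


def run_pipeline(config: PipelineConfig, output_dir: str | Path | None = None) -> ExperimentResult:
    """Disk-to-disk run: read inputs, execute, write all artifacts.

    Writes mask CSV, model checkpoint, metrics JSON, per-epoch history CSV,
    ROC points CSV and a provenance record (config + seed + hash).
    """
    if config.timeseries_dir is None or config.phenotype_csv is None:
        raise ValueError("config must set timeseries_dir and phenotype_csv")
    outdir = Path(output_dir or config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    timeseries = read_timeseries_dir(config.timeseries_dir)
    pheno, n_dropped = read_phenotypes(config.phenotype_csv, label_column=config.label_column)
    ts_ids, ph_ids = set(timeseries), set(pheno.index)
    shared = sorted(ts_ids & ph_ids)
    if not shared:
        raise ValueError("no subject ids shared between time series and phenotypes")
    mismatched = sorted(ts_ids ^ ph_ids)
    timeseries = {s: timeseries[s] for s in shared}
    labels = {s: int(pheno.loc[s, config.label_column]) for s in shared}

    result = run_experiment(timeseries, pheno, labels, config=config)

    chash = result.config_hash
    if result.mask is not None:
        n_roi = next(iter(timeseries.values())).shape[1]
        result.mask.save_csv(outdir / "mask.csv", n_roi=n_roi)
    save_checkpoint(
        outdir / "checkpoint.json", result.model, result.schema,
        config={**config.model_dump(mode="json")},
    )
    metrics = result.report.to_dict()
    metrics.update({"config_hash": chash, "seed": config.seed, "n_dropped_phenotype_rows": n_dropped})
    (outdir / "metrics.json").write_text(json.dumps(metrics, indent=2))
    result.history.assign(config_hash=chash).to_csv(outdir / "history.csv", index=False)
    pd.DataFrame(result.report.roc_points, columns=["fpr", "tpr"]).assign(
        config_hash=chash
    ).to_csv(outdir / "roc.csv", index=False)
    provenance = {
        "config": config.model_dump(mode="json"),
        "config_hash": chash,
        "seed": config.seed,
        "n_subjects": len(shared),
        "unmatched_subject_ids": mismatched,
        "train_ids": result.train_ids,
        "test_ids": result.test_ids,
    }
    (outdir / "provenance.json").write_text(json.dumps(provenance, indent=2))
    return result


def sweep(
    timeseries: dict[str, np.ndarray],
    phenotypes: pd.DataFrame | None,
    labels: dict[str, int],
    n_keep_grid: list[int],
    config: PipelineConfig | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Accuracy and AUC as a function of the retained-feature count N.

    The RFE ranking is fitted once on the training split down to the smallest
    grid value; each N's mask is then the top-N features of that shared
    ranking (the rank-threshold reading), and a model is trained per N.
    """
    config = config or PipelineConfig()
    seed = config.seed if seed is None else seed
    grid = sorted(set(int(n) for n in n_keep_grid))
    if not grid:
        raise ValueError("empty n_keep grid")

    base = config.model_copy(deep=True)
    base.selection.n_keep = grid[0]
    ids = sorted(timeseries)
    y_all = np.array([labels[s] for s in ids], dtype=int)
    train_idx, _ = split_dataset(
        len(ids), ratio=tuple(base.train.split_ratio), seed=seed,
        stratified=base.train.stratified, labels=y_all,
    )
    train_ids = [ids[i] for i in train_idx]
    vec_ids, x_train = connectome_vectors({s: timeseries[s] for s in train_ids})
    y_train = np.array([labels[s] for s in vec_ids], dtype=int)
    sel = base.selection
    deep_mask = svm_rfe(
        x_train, y_train, n_keep=min(grid[0], x_train.shape[1]),
        step_fraction=sel.step_fraction, C=sel.C, seed=seed, importance=sel.importance,
    )

    rows = []
    for n_keep in grid:
        n_keep_eff = min(n_keep, deep_mask.n_original)
        mask_n = FeatureMask(
            retained=deep_mask.retained_at(n_keep_eff),
            ranking=deep_mask.ranking,
            n_original=deep_mask.n_original,
        )
        res = run_experiment(timeseries, phenotypes, labels, config=base, seed=seed, mask=mask_n)
        rows.append({"n_keep": n_keep, "acc": res.report.acc, "auc": res.report.auc})
    return pd.DataFrame(rows)
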