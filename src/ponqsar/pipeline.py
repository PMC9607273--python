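"""End-to-end pipeline: descriptors → filter → split → GA → validate → AD.

One global seed fans out to per-stage seeds through
``numpy.random.SeedSequence.spawn`` (stage order is fixed), so each
stage is individually reproducible and re-running a config byte-
reproduces every JSON artifact.

Artifacts land in ``<outdir>/``: config.json, descriptors.csv,
model.json, validation.json, ad.csv and run.log.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from . import dataset as ds
from .descriptors import DescriptorMatrix, compute_descriptor_matrix
from .domain import williams, write_ad_report
from .modeling import (
    GAConfig,
    MLRModel,
    ModelingError,
    drop_correlated,
    ga_select,
    load_fixture_model,
    ordered_split,
    predict,
)
from .validation import validate_model

_STAGES = ("embed", "ga", "lmo", "scramble")


class ConfigError(ValueError):
    pass


def stage_seeds(global_seed: int, names: Sequence[str] = _STAGES) -> dict:
    """Deterministic per-stage seeds derived from one global seed."""
    children = np.random.SeedSequence(global_seed).spawn(len(names))
    return {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(names, children)
    }


@dataclass
class RunConfig:
    """Everything one pipeline run needs, serializable to JSON."""

    dataset: str | None = None  # None → packaged PON1 table
    isozyme: Literal["Q", "R"] = "Q"
    descriptors: list[str] = field(default_factory=list)
    descriptor_file: str | None = None  # precomputed matrix, skips embedding
    corr_threshold: float = 0.95
    split_period: int = 5
    mode: Literal["ga", "fixture"] = "ga"
    ga: GAConfig = field(default_factory=GAConfig)
    lmo_fraction: float = 0.3
    lmo_iterations: int = 1000
    outdir: str = "runs/latest"
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.corr_threshold <= 1:
            raise ConfigError(
                f"corr_threshold must be in (0, 1], got {self.corr_threshold}"
            )
        if self.split_period < 2:
            raise ConfigError("split_period must be >= 2")
        if self.isozyme not in ("Q", "R"):
            raise ConfigError(f"isozyme must be Q or R, got {self.isozyme!r}")
        if self.mode not in ("ga", "fixture"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        if self.mode == "ga" and not self.descriptors and not self.descriptor_file:
            raise ConfigError("ga mode needs descriptors or a descriptor_file")
        if not 0 < self.lmo_fraction < 0.5:
            raise ConfigError("lmo_fraction must be in (0, 0.5)")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "ga" in d and isinstance(d["ga"], dict):
            d["ga"] = GAConfig(**d["ga"])
        return cls(**d)


@dataclass
class RunArtifacts:
    model: MLRModel
    report: "object"
    ad_table: pd.DataFrame
    paths: dict


def _setup_logger(path: Path) -> logging.Logger:
    logger = logging.getLogger(f"ponqsar.run.{path}")
    logger.setLevel(logging.INFO)
    logger.handlers.clear()
    fh = logging.FileHandler(path, mode="w")
    fh.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    logger.addHandler(fh)
    logger.addHandler(logging.StreamHandler())
    return logger


def run_pipeline(config: RunConfig) -> RunArtifacts:
    """Execute the full modelling chain and write artifacts."""
    config.validate()
    seeds = stage_seeds(config.seed)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log = _setup_logger(outdir / "run.log")

    (outdir / "config.json").write_text(
        json.dumps(config.to_dict(), indent=2, sort_keys=True) + "\n"
    )

    # ---- stage: dataset
    if config.dataset is None:
        cset = ds.load_pon1()
    else:
        cset = ds.load_compound_table(config.dataset)
    y = ds.log_response(cset, config.isozyme)
    response_name = f"log_rate_{config.isozyme.lower()}"
    log.info("stage=dataset n_compounds=%d response=%s", len(cset), response_name)

    # ---- stage: descriptors
    if config.descriptor_file is not None:
        matrix = DescriptorMatrix.read_csv(config.descriptor_file)
        if matrix.compound_ids != cset.ids:
            raise ConfigError(
                "descriptor_file compound ids do not match the dataset"
            )
    else:
        names = list(config.descriptors)
        if config.mode == "fixture" and not names:
            names = load_fixture_model(config.isozyme).descriptor_names
        matrix = compute_descriptor_matrix(cset, names, seed=seeds["embed"])
    log.info("stage=descriptors shape=%dx%d", *matrix.shape)
    matrix.write_csv(outdir / "descriptors.csv")

    # ---- stage: correlation filter (before the split, pipeline order)
    if config.mode == "ga" and matrix.shape[1] >= 2:
        filtered = drop_correlated(matrix, config.corr_threshold)
    else:
        filtered = matrix
    log.info(
        "stage=filter threshold=%.2f kept=%d of %d",
        config.corr_threshold,
        filtered.shape[1],
        matrix.shape[1],
    )

    # ---- stage: ordered split
    train_idx, test_idx = ordered_split(y, config.split_period)
    log.info(
        "stage=split period=%d n_train=%d n_test=%d",
        config.split_period,
        len(train_idx),
        len(test_idx),
    )
    ids = np.array(cset.ids)
    train_ids = ids[train_idx].tolist()

    # ---- stage: model
    if config.mode == "fixture":
        model = load_fixture_model(config.isozyme)
        model = MLRModel(
            intercept=model.intercept,
            terms=model.terms,
            response_name=response_name,
            train_ids=train_ids,
            provenance=model.provenance,
        )
    else:
        ga_cfg = dataclasses.replace(config.ga, seed=seeds["ga"])
        train_matrix = DescriptorMatrix(
            compound_ids=train_ids,
            descriptor_names=filtered.descriptor_names,
            values=filtered.values[train_idx],
            provenance=filtered.provenance,
        )
        ranked = ga_select(
            train_matrix, y[train_idx], ga_cfg, response_name=response_name
        )
        if not ranked:
            raise ModelingError("GA returned no valid model")
        model = ranked[0].model
        log.info(
            "stage=ga best_fitness=%.4f descriptors=%s",
            ranked[0].fitness,
            ",".join(ranked[0].descriptor_names),
        )
    model.to_json(outdir / "model.json")
    log.info("stage=model terms=%d provenance=%s", model.n_descriptors, model.provenance)

    # ---- stage: validation
    sub = matrix.subset(model.descriptor_names)
    yhat = predict(model, sub)
    report = validate_model(
        X_train=sub.values[train_idx],
        y_train=y[train_idx],
        yhat_train=yhat[train_idx],
        p=model.n_descriptors,
        y_test=y[test_idx] if len(test_idx) else None,
        yhat_test=yhat[test_idx] if len(test_idx) else None,
        lmo_fraction=config.lmo_fraction,
        lmo_iterations=config.lmo_iterations,
        seed=seeds["lmo"],
    )
    report.to_json(outdir / "validation.json")
    log.info(
        "stage=validation r2_tr=%.3f q2_loo=%.3f n_train=%d n_test=%d",
        report.r2_tr,
        report.q2_loo,
        report.n_train,
        report.n_test,
    )

    # ---- stage: applicability domain
    records, table = williams(model, matrix, y, train_ids=train_ids)
    write_ad_report(records, outdir / "ad.csv", outdir / "ad_summary.json")
    n_out = sum(r.category != "in_domain" for r in records)
    log.info("stage=ad h_star=%.3f outliers=%d", records[0].h_star, n_out)

    paths = {
        name: str(outdir / name)
        for name in (
            "config.json",
            "descriptors.csv",
            "model.json",
            "validation.json",
            "ad.csv",
            "ad_summary.json",
            "run.log",
        )
    }
    return RunArtifacts(model=model, report=report, ad_table=table, paths=paths)


def evaluate_fixture(
    isozyme: Literal["Q", "R"],
    matrix: DescriptorMatrix,
    responses: np.ndarray | None = None,
    split: Literal["rule", "printed"] = "rule",
    split_period: int = 5,
    lmo_iterations: int = 1000,
    seed: int = 0,
):
    """Apply a packaged published model (no refitting) and report metrics.

    With ``responses=None`` the packaged dataset's log rates are used;
    the matrix rows must then be the packaged compounds in order.
    ``split='rule'`` partitions train/test by the ordered-response rule;
    ``'printed'`` uses the packaged test-set flags.
    """
    model = load_fixture_model(isozyme)
    missing = [
        n for n in model.descriptor_names if n not in matrix.descriptor_names
    ]
    if missing:
        raise ModelingError(
            f"descriptor column(s) missing from matrix: {', '.join(missing)}"
        )
    if responses is None:
        cset = ds.load_pon1()
        if matrix.compound_ids != cset.ids:
            raise ConfigError(
                "matrix compound ids do not match the packaged dataset"
            )
        responses = ds.log_response(cset, isozyme)
        printed_mask = cset.test_mask(isozyme)
    else:
        responses = np.asarray(responses, dtype=float)
        printed_mask = None

    if split == "printed":
        if printed_mask is None:
            raise ConfigError("printed split needs the packaged dataset")
        test_idx = np.flatnonzero(printed_mask)
        train_idx = np.flatnonzero(~printed_mask)
    else:
        train_idx, test_idx = ordered_split(responses, split_period)

    sub = matrix.subset(model.descriptor_names)
    yhat = predict(model, sub)
    report = validate_model(
        X_train=sub.values[train_idx],
        y_train=responses[train_idx],
        yhat_train=yhat[train_idx],
        p=model.n_descriptors,
        y_test=responses[test_idx] if len(test_idx) else None,
        yhat_test=yhat[test_idx] if len(test_idx) else None,
        lmo_iterations=lmo_iterations,
        seed=seed,
    )
    return yhat, report
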