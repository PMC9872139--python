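"""End-to-end orchestration: screen -> auto-encoder -> LASSO-Cox -> evaluation.

Two arms share the same screened matrix:

* ``arm="ae"`` compresses the screened binary markers through the
  auto-encoder and selects among the continuous hidden features, and
* ``arm="direct"`` applies cross-validated LASSO-Cox straight to the binary
  markers (the comparison arm that tends to select many noise predictors,
  or none at all, on extremely sparse data).

One global seed fans out to per-stage seeds derived from a stable hash of
the stage name, so any stage can be rerun independently yet reproducibly.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import autoencoder as ae
from . import evaluate as ev
from .genotype import BinaryGenotypeMatrix, SurvivalData
from .lasso import cv_lasso_cox
from .screen import screen_markers

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "stage_seed", "run"]


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a per-stage seed below 2**31 from the global seed."""
    return (int(global_seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31 - 1)


@dataclass
class PipelineConfig:
    arm: str = "ae"  # "ae" or "direct"
    screen_alpha: float = 0.05
    run_screen: bool = True
    hidden_dim: int = 100
    learning_rate: float = 0.005
    batch_size: int = 32
    epochs: int = 200
    decoder_act: str = "sigmoid"
    loss: str = "mce"
    lasso_nfolds: int = 10
    lasso_rule: str = "min"
    eval_folds: int = 5
    eval_times: list[float] | None = None
    minprop: float = 0.1
    full_eval: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.arm not in ("ae", "direct"):
            raise ValueError("arm must be 'ae' or 'direct'")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as f:
            return cls(**(yaml.safe_load(f) or {}))


@dataclass
class PipelineResult:
    config: PipelineConfig
    screened: BinaryGenotypeMatrix | None
    screen_result: object | None
    features: pd.DataFrame | None
    selected: list[str]
    cv_lasso: object | None
    report: ev.SignatureReport | None
    history: ae.TrainHistory | None = None
    status: str = "ok"
    counts: dict = field(default_factory=dict)

    def summary(self) -> dict:
        out = {"status": self.status, "arm": self.config.arm, **self.counts}
        if self.report is not None:
            out.update(self.report.summary())
        return out


def run(
    config: PipelineConfig,
    X: BinaryGenotypeMatrix,
    surv: SurvivalData,
    outdir: str | Path | None = None,
) -> PipelineResult:
    """Run the configured arm of the pipeline on a genotype matrix + survival.

    When screening retains nothing the pipeline stops gracefully with
    ``status="no-signal"``.  All stage outputs are pure functions of
    (inputs, config, seed); with ``outdir`` set, intermediate artifacts are
    written as text files.
    """
    counts = {"n_samples": X.shape[0], "n_markers": X.shape[1]}

    if config.run_screen:
        X_red, screen_res = screen_markers(X, surv, alpha=config.screen_alpha)
    else:
        X_red, screen_res = X, None
    counts["n_screened"] = X_red.shape[1]
    if X_red.shape[1] == 0:
        logger.warning("pipeline: no markers survived screening; reporting no-signal")
        return PipelineResult(config, X_red, screen_res, None, [], None, None,
                              status="no-signal", counts=counts)

    history = None
    if config.arm == "ae":
        cfg = ae.AEConfig(
            p=X_red.shape[1],
            d=min(config.hidden_dim, X_red.shape[1]),
            decoder_act=config.decoder_act,
            loss=config.loss,
            learning_rate=config.learning_rate,
            batch_size=config.batch_size,
            epochs=config.epochs,
            seed=stage_seed(config.seed, "autoencoder"),
        )
        model, history = ae.train(X_red.values.astype(float), cfg)
        feats = ae.extract_features(model, X_red.values.astype(float))
        features = pd.DataFrame(feats, columns=[f"AE{j:03d}" for j in range(feats.shape[1])])
    else:
        features = pd.DataFrame(X_red.values.astype(float), columns=list(X_red.gene_ids))
    counts["n_extracted"] = features.shape[1]

    cv, beta = cv_lasso_cox(
        features.to_numpy(),
        surv,
        nfolds=config.lasso_nfolds,
        rule=config.lasso_rule,
        seed=stage_seed(config.seed, "lasso"),
    )
    sel_idx = np.flatnonzero(beta != 0.0)
    selected = [features.columns[j] for j in sel_idx]
    counts["n_selected"] = len(selected)
    if not selected:
        logger.warning("pipeline: LASSO selected no features; reporting no-signal")
        return PipelineResult(config, X_red, screen_res, features, [], cv, None,
                              history=history, status="no-signal", counts=counts)

    report = ev.evaluate_signature(
        features[selected],
        surv,
        cv_folds=config.eval_folds,
        seed=stage_seed(config.seed, "evaluate"),
        times=None if config.eval_times is None else np.asarray(config.eval_times, float),
        minprop=config.minprop,
        full=config.full_eval,
    )
    result = PipelineResult(config, X_red, screen_res, features, selected, cv, report,
                            history=history, counts=counts)
    if outdir is not None:
        _write_artifacts(result, Path(outdir))
    return result


def _write_artifacts(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    if result.screen_result is not None:
        result.screen_result.to_tsv(outdir / "screen.tsv")
    if result.features is not None:
        result.features.to_csv(outdir / "features.tsv", sep="\t", index=False)
    (outdir / "selected.txt").write_text("\n".join(result.selected) + "\n")
    if result.cv_lasso is not None:
        pd.DataFrame(
            {
                "lambda": result.cv_lasso.lambda_path,
                "cv_deviance": result.cv_lasso.cv_deviance,
                "cv_se": result.cv_lasso.cv_se,
            }
        ).to_csv(outdir / "cv_lasso.tsv", sep="\t", index=False)
    with open(outdir / "summary.json", "w") as f:
        json.dump(result.summary(), f, indent=2, default=float)
    logger.info("pipeline artifacts written to %s", outdir)
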