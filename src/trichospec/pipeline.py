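"""End-to-end orchestration: simulate (or load) -> preprocess -> two-level
OPLS-DA -> diagnostics -> cross-validated evaluation.

The two-level analysis mirrors the study design: first a genetics model
(Indica vs Sativa) on all spectra, then a variety model on the Sativa
subset only.  Every random draw derives from the single configured seed,
so a rerun with the same configuration is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import synthetic
from .diagnostics import EllipseSpec, contribution, hotelling_limit
from .evaluation import ConfusionMatrix, confusion, fisher_rxc
from .io import SpectraDataset, read_matrix_csv, write_matrix_csv
from .opls import CvConfig, CvResult, OplsModel, autofit, cross_validate, fit_oplsda
from .preprocess import PreprocessConfig, preprocess_dataset

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "LevelResult", "PipelineReport", "run"]


@dataclass
class PipelineConfig:
    """Everything a full run needs.  Defaults mirror the study settings:
    ROI 200-1800 cm^-1, 5th-order baseline, Pareto scaling, 7-fold CV,
    Hotelling alpha 0.05, at most 4 latent variables."""

    level: str = "both"                   # genetics | variety | both
    seed: int = 0
    input_csv: str | None = None          # load instead of simulate
    effect_size: float = synthetic.DEFAULT_EFFECT_SIZE
    design: synthetic.GeneratorDesign | None = None
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    cv: CvConfig = field(default_factory=CvConfig)
    use_autofit: bool = False
    genetics_components: tuple = (1, 1)   # (n_pred, n_orth)
    variety_components: tuple = (3, 1)
    alpha: float = 0.05
    outdir: str | None = None

    _SECTIONS = {"pipeline": None, "design": "design", "preprocess": "preprocess", "cv": "cv"}

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        """Parse a flat key=value config with section prefixes, e.g.
        ``design.noise_sd = 0.01`` or ``pipeline.level = both``."""
        cfg = cls()
        cfg.design = synthetic.default_design()
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{lineno}: expected key = value")
                key, value = (s.strip() for s in line.split("=", 1))
                section, _, name = key.partition(".")
                if not name:
                    section, name = "pipeline", section
                target = {"pipeline": cfg, "design": cfg.design,
                          "preprocess": cfg.preprocess, "cv": cfg.cv}.get(section)
                if target is None or not hasattr(target, name):
                    raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
                current = getattr(target, name)
                setattr(target, name, _coerce(value, current))
        return cfg


def _coerce(text: str, like):
    if isinstance(like, bool):
        return text.lower() in ("1", "true", "yes")
    if isinstance(like, int):
        return int(text)
    if isinstance(like, float):
        return float(text)
    if isinstance(like, tuple):
        parts = text.replace(",", " ").split()
        return tuple(type(e)(p) for e, p in zip(like, parts))
    return text


@dataclass
class LevelResult:
    """One classification level: the fitted model, cross-validation
    output, the resulting confusion matrix (with Fisher probability), the
    Hotelling ellipse of the main score plane, and score table."""

    level: str
    model: OplsModel
    cv: CvResult
    matrix: ConfusionMatrix
    ellipse: EllipseSpec | None
    scores: pd.DataFrame
    n_pred: int
    n_orth: int


@dataclass
class PipelineReport:
    config: PipelineConfig
    dataset: SpectraDataset
    clean: SpectraDataset
    genetics: LevelResult | None = None
    variety: LevelResult | None = None
    contributions: pd.DataFrame | None = None


def _fit_level(name: str, clean: SpectraDataset, labels, components,
               config: PipelineConfig) -> LevelResult:
    labels = list(labels)
    class_order = list(dict.fromkeys(labels))
    cv_cfg = dataclasses.replace(config.cv, seed=config.seed)
    if config.use_autofit:
        chosen = autofit(clean.matrix, labels, cv_cfg, class_order)
        n_pred, n_orth = chosen.n_pred, chosen.n_orth
        logger.info("%s autofit chose %d predictive + %d orthogonal (Q2=%.3f)",
                    name, n_pred, n_orth, chosen.q2)
    else:
        n_pred, n_orth = components
    model = fit_oplsda(clean.matrix, labels, n_pred=n_pred, n_orth=n_orth,
                       class_order=class_order)
    cv = cross_validate(clean.matrix, labels, n_pred, n_orth, cv_cfg, class_order)
    model.q2_cum = cv.q2
    matrix = confusion(labels, cv.predictions, class_order)
    matrix.fisher_p = fisher_rxc(matrix.counts, seed=config.seed)
    score_axes = np.column_stack([model.T[:, 0],
                                  model.To[:, 0] if model.n_orth else
                                  (model.T[:, 1] if model.n_pred > 1 else model.T[:, 0])])
    ellipse = hotelling_limit(score_axes, config.alpha) if score_axes.shape[0] > 2 else None
    scores = pd.DataFrame({
        "label": labels,
        **{f"t{a + 1}": model.T[:, a] for a in range(model.n_pred)},
        **{f"to{j + 1}": model.To[:, j] for j in range(model.n_orth)},
    })
    return LevelResult(level=name, model=model, cv=cv, matrix=matrix,
                       ellipse=ellipse, scores=scores, n_pred=n_pred, n_orth=n_orth)


def run(config: PipelineConfig, dataset: SpectraDataset | None = None) -> PipelineReport:
    """Execute the configured pipeline and (optionally) write the report
    bundle to ``config.outdir``."""
    if config.level not in ("genetics", "variety", "both"):
        raise ValueError(f"unknown level {config.level!r}")
    try:
        if dataset is None:
            if config.input_csv:
                dataset = read_matrix_csv(config.input_csv)
            else:
                design = config.design or synthetic.default_design(seed=config.seed)
                if config.design is None:
                    design.seed = config.seed
                effects = synthetic.default_class_effects(config.effect_size)
                dataset = synthetic.generate_dataset(design, class_effects=effects)
    except Exception as exc:
        raise RuntimeError(f"simulate stage failed: {exc}") from exc
    try:
        clean = preprocess_dataset(dataset, config.preprocess)
    except Exception as exc:
        raise RuntimeError(f"preprocess stage failed: {exc}") from exc

    report = PipelineReport(config=config, dataset=dataset, clean=clean)
    if config.level in ("genetics", "both"):
        labels = clean.labels["genetics"].tolist()
        report.genetics = _fit_level("genetics", clean, labels,
                                     config.genetics_components, config)
        # contribution of the Indica group against the Sativa group
        indica = clean.matrix[clean.labels["genetics"] == "Indica"]
        sativa = clean.matrix[clean.labels["genetics"] == "Sativa"]
        if indica.size and sativa.size:
            prof = contribution(report.genetics.model, indica, sativa)
            report.contributions = pd.DataFrame({
                "wavenumber": clean.grid,
                "bar": prof.bars,
                "flagged": prof.flagged,
            })
    if config.level in ("variety", "both"):
        sativa_ds = clean.subset((clean.labels["genetics"] == "Sativa").to_numpy())
        if sativa_ds.n_spectra == 0:
            raise RuntimeError("variety stage failed: no Sativa spectra")
        report.variety = _fit_level("variety", sativa_ds,
                                    sativa_ds.labels["class"].tolist(),
                                    config.variety_components, config)
    if config.outdir:
        _write_bundle(report, Path(config.outdir))
    return report


def _write_bundle(report: PipelineReport, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    write_matrix_csv(report.clean, outdir / "clean.csv")
    log_lines = [f"seed = {report.config.seed}", f"level = {report.config.level}"]
    for name in ("genetics", "variety"):
        res: LevelResult | None = getattr(report, name)
        if res is None:
            continue
        res.model.to_json(outdir / f"model_{name}.json")
        res.scores.to_csv(outdir / f"scores_{name}.csv", index=False)
        (outdir / f"confusion_{name}.txt").write_text(res.matrix.to_text() + "\n")
        log_lines += [
            f"{name}.n_pred = {res.n_pred}",
            f"{name}.n_orth = {res.n_orth}",
            f"{name}.r2x_cum = {res.model.r2x_cum:.6f}",
            f"{name}.q2 = {res.cv.q2:.6f}",
            f"{name}.cv_accuracy = {res.matrix.accuracy:.6f}",
            f"{name}.fisher_p = {res.matrix.fisher_p:.6e}",
        ]
    if report.contributions is not None:
        report.contributions.to_csv(outdir / "contributions_genetics.csv", index=False)
    cfg = dataclasses.asdict(report.config)
    (outdir / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    (outdir / "config.json").write_text(json.dumps(cfg, default=str, indent=2) + "\n")
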