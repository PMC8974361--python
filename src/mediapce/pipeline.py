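"""Reproducible pipeline: simulate -> series -> exposures -> index -> models.

Every run writes a fixed set of text artifacts (tidy CSV series, exposure
matrix, index JSON, model JSON, prediction grid, report) plus a
``manifest.json`` carrying the seed, the config hash and per-stage row
counts, so identical config + seed reproduce byte-identical output.
"""

from __future__ import annotations

import datetime as dt
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import models as md
from .study import StudyData, calibration_table, exposure_matrix, simulate_study
from .synthetic import GeneratorConfig

__all__ = ["PipelineConfig", "run_pipeline"]


class PipelineConfig(BaseModel):
    """Configuration for one end-to-end (simulated) pipeline run."""

    generator: GeneratorConfig = Field(default_factory=GeneratorConfig)
    window: int = 7
    agreement: float = 0.70
    write_documents: bool = False
    document_sources: list[str] = Field(default_factory=lambda: ["broadcast", "ap"])
    document_days: int = 10
    models: list[str] = Field(
        default_factory=lambda: ["intentions", "intentions-interaction", "beliefs"]
    )
    prediction_grid_points: int = 21
    seed: int = 0

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n", encoding="utf-8")


def _belief_frame(survey: pd.DataFrame, n_items: int, n_reverse: int) -> pd.Series:
    cols = [f"belief_{i+1}" for i in range(n_items)]
    reverse = cols[n_items - n_reverse:]
    return md.belief_scale(survey[cols], reverse)


def fit_named_model(study: StudyData, name: str) -> md.ModelResult:
    """Fit one of the named outcome models on an assembled study."""
    survey = study.survey
    scores = study.day_scores
    if name == "intentions":
        y, X, cl, w, info = md.build_design(survey, scores, outcome="intention")
        res = md.fit_weighted_logistic(y, X, weights=w, clusters=cl)
    elif name == "intentions-interaction":
        y, X, cl, w, info = md.build_design(
            survey, scores, outcome="intention", include_interaction=True
        )
        res = md.fit_weighted_logistic(y, X, weights=w, clusters=cl)
    elif name == "intentions-no-youtube":
        y, X, cl, w, info = md.build_design(
            survey, scores, outcome="intention", include_youtube=False
        )
        res = md.fit_weighted_logistic(y, X, weights=w, clusters=cl)
    elif name == "beliefs":
        bb = study.config.beliefs
        survey = survey.assign(
            belief_scale=_belief_frame(survey, bb.n_items, bb.n_reverse)
        )
        y, X, cl, w, info = md.build_design(survey, scores, outcome="belief_scale")
        res = md.fit_weighted_ols(y, X, weights=w, clusters=cl)
    elif name == "multilevel":
        y, X, cl, w, info = md.build_design(survey, scores, outcome="intention")
        res = md.fit_random_intercept_logistic(y, X, clusters=cl, weights=w)
    else:
        raise ValueError(f"unknown model {name!r}")
    res.extra.update(info)
    return res


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run the full pipeline and write its artifact bundle to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gen = config.generator.model_copy(update={"seed": config.seed})
    study = simulate_study(gen, window=config.window)
    counts: dict[str, int] = {}

    # daily series (tidy)
    tidy = (
        study.stream.series.rename_axis("date")
        .reset_index()
        .melt(id_vars="date", var_name="source_valence", value_name="value")
    )
    tidy[["source", "valence"]] = tidy["source_valence"].str.rsplit("_", n=1, expand=True)
    tidy = tidy[["date", "source", "valence", "value"]].sort_values(
        ["source", "valence", "date"], kind="stable"
    )
    tidy["date"] = tidy["date"].dt.date
    tidy.to_csv(outdir / "series.csv", index=False, float_format="%.10g")
    counts["series_rows"] = len(tidy)

    # optional document materialization over a short leading range
    if config.write_documents:
        from .records import write_jsonl

        d0 = gen.start_date
        d1 = min(gen.end_date, d0 + dt.timedelta(days=config.document_days - 1))
        docs = []
        for src in config.document_sources:
            docs.extend(study.stream.documents_for(src, d0, d1))
        counts["documents"] = write_jsonl(docs, outdir / "documents.jsonl")
        counts["videos"] = write_jsonl(study.stream.videos, outdir / "videos.jsonl")

    # per-respondent exposure matrix (shared within interview dates)
    exp = exposure_matrix(study)
    exp.to_csv(outdir / "exposure.csv", index=False, float_format="%.10g")
    counts["exposure_rows"] = len(exp)

    # day-level scores and survey
    study.day_scores.rename_axis("date").reset_index().assign(
        date=lambda d: d["date"].dt.date
    ).to_csv(outdir / "scores.csv", index=False, float_format="%.10g")
    study.survey.to_csv(outdir / "survey.csv", index=False, float_format="%.10g")
    study.followup.to_csv(outdir / "followup.csv", index=False, float_format="%.10g")
    counts["respondents"] = len(study.survey)
    counts["followup"] = len(study.followup)

    # composite index summary
    _write_json(
        outdir / "index.json",
        {v: idx.summary() for v, idx in study.indices.items()},
    )

    # models
    results = {}
    for name in config.models:
        res = fit_named_model(study, name)
        results[name] = res.to_json_dict()
    _write_json(outdir / "models.json", results)

    # adjusted-prediction grid from the interaction model
    if "intentions-interaction" in config.models:
        y, X, cl, w, _ = md.build_design(
            study.survey, study.day_scores, outcome="intention", include_interaction=True
        )
        est = md.ClusteredLogit().fit(X, y, sample_weight=w, clusters=cl)
        grid = np.linspace(
            X["anti_index"].min(), X["anti_index"].max(), config.prediction_grid_points
        )
        frames = []
        for smoker in (0, 1):
            frames.append(
                md.adjusted_predictions(
                    est, X, over="anti_index", grid=grid,
                    at={"established_smoker": float(smoker)},
                    products={"smoker_x_anti": ("established_smoker", "anti_index")},
                    sample_weight=w,
                )
            )
        pd.concat(frames, ignore_index=True).to_csv(
            outdir / "predictions.csv", index=False, float_format="%.10g"
        )

    manifest = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "generator_hash": gen.config_hash(),
        "counts": counts,
        "window": config.window,
    }
    _write_json(outdir / "manifest.json", manifest)
    _write_json(outdir / "config.json", config.model_dump(mode="json"))

    report = [
        f"pipeline run (config {config.config_hash()}, seed {config.seed})",
        f"window: {config.window} days",
        *(f"{k}: {v}" for k, v in sorted(counts.items())),
        *(
            f"model {name}: n={results[name]['n']}, clusters={results[name]['n_clusters']}"
            for name in results
        ),
    ]
    (outdir / "report.txt").write_text("\n".join(report) + "\n", encoding="utf-8")
    return {"study": study, "results": results, "manifest": manifest}
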