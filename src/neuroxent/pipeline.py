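"""End-to-end driver: simulate → band-decompose → coupling → grid-select →
screen → FCBF → classify.

The train/test boundary is structural: epoch sets and feature tables carry a
``split`` tag, parameter-grid search and feature selection refuse test-tagged
data, and test recordings only ever reach coupling computation for the
already-selected grid cell and model evaluation.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from . import __version__
from .classify import MODELS, ClassifierSpec, evaluate, fit
from .coupling import CouplingMatrix, grid_subject_coupling
from .entropy import EntropyParams
from .features import FeatureSet, FeatureTable, build_feature_table, fcbf
from .io import write_json, write_matrix
from .preprocessing import (
    CANONICAL_BANDS,
    EpochSet,
    Recording,
    band_decompose,
    notch_filter,
    segment_epochs,
)
from .simulate import SyntheticCohortSpec, generate_cohort
from .stats import (
    GridSelectionResult,
    parameter_grid_search,
    screen_connections,
    significant_counts,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "prepare_subject"]


@dataclass(frozen=True)
class PipelineConfig:
    """Validated configuration of a full analysis run."""

    seed: int
    cohort: SyntheticCohortSpec | None = None  # None -> caller supplies recordings
    band_names: tuple[str, ...] = tuple(b.name for b in CANONICAL_BANDS)
    metrics: tuple[str, ...] = ("cross_apen", "cross_sampen")
    ms: tuple[int, ...] = (1, 2)
    rs: tuple[float, ...] = (0.10, 0.15, 0.20, 0.25)
    alpha: float = 0.05
    fdr_scope: str = "band"
    fcbf_delta: float = 0.0
    epoch_duration_s: float = 5.0
    fir_order: int | None = None  # None -> per-band default (3 cycles of low edge)
    apply_notch: bool = False  # synthetic data has no line interference
    contrasts: tuple[tuple[str, str], ...] = (("HC", "MCI"), ("HC", "AD"))
    models: tuple[str, ...] = MODELS

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.fdr_scope not in ("band", "global"):
            raise ValueError("fdr_scope must be 'band' or 'global'")
        known = {b.name for b in CANONICAL_BANDS}
        if not set(self.band_names) <= known:
            raise ValueError(f"unknown bands {set(self.band_names) - known}")
        for m in self.models:
            if m not in MODELS:
                raise ValueError(f"unknown model {m!r}")

    @property
    def bands(self):
        return tuple(b for b in CANONICAL_BANDS if b.name in self.band_names)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cohort_raw = raw.pop("cohort", None)
        cohort = None
        if cohort_raw is not None:
            cohort_raw.setdefault("seed", raw.get("seed", 0))
            for key in ("n_train", "n_test"):
                if key in cohort_raw:
                    cohort_raw[key] = tuple(cohort_raw[key])
            cohort = SyntheticCohortSpec(**cohort_raw)
        for key in ("band_names", "metrics", "ms", "rs", "models"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "contrasts" in raw:
            raw["contrasts"] = tuple(tuple(c) for c in raw["contrasts"])
        return cls(cohort=cohort, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclass
class PipelineResult:
    """Artifacts of one pipeline run."""

    config: PipelineConfig
    grid: GridSelectionResult
    selected_params: EntropyParams
    train_stats: "object"  # DataFrame at the selected cell
    feature_sets: dict[str, FeatureSet]
    reports: dict[str, dict[str, dict]]  # contrast -> model -> report dict
    test_stats: dict[str, "object"]
    manifest: dict


def prepare_subject(
    recording: Recording,
    config: PipelineConfig,
    split: str,
) -> dict[str, EpochSet]:
    """Notch (optional), band-decompose, and epoch one recording."""
    rec = notch_filter(recording) if config.apply_notch else recording
    per_band = band_decompose(rec, config.bands, order=config.fir_order)
    out = {}
    for band, band_rec in per_band.items():
        es = segment_epochs(band_rec, config.epoch_duration_s, band=band)
        es.split = split
        out[band] = es
    return out


def _group_subjects(
    prepared: Sequence[dict[str, EpochSet]],
) -> dict[str, list[dict[str, EpochSet]]]:
    grouped: dict[str, list[dict[str, EpochSet]]] = {}
    for subj in prepared:
        group = next(iter(subj.values())).group
        grouped.setdefault(group, []).append(subj)
    return grouped


def _matrices_for_cell(
    cohort: Mapping[str, Sequence[Mapping[str, EpochSet]]],
    params: EntropyParams,
) -> dict[str, list[dict[str, CouplingMatrix]]]:
    out: dict[str, list[dict[str, CouplingMatrix]]] = {}
    for group, subjects in cohort.items():
        for subj in subjects:
            mats = {
                band: grid_subject_coupling(
                    es, (params.metric,), (params.m,), (params.r,)
                )[(params.metric, params.m, params.r)]
                for band, es in subj.items()
            }
            out.setdefault(group, []).append(mats)
    return out


def run_pipeline(
    config: PipelineConfig,
    outdir: str | Path | None = None,
    train_recordings: Sequence[Recording] | None = None,
    test_recordings: Sequence[Recording] | None = None,
) -> PipelineResult:
    """Execute the full analysis; see the module docstring for the stages."""
    t0 = time.perf_counter()
    if train_recordings is None or test_recordings is None:
        if config.cohort is None:
            raise ValueError("either a cohort spec or explicit recordings are required")
        train_recordings, test_recordings = generate_cohort(config.cohort)
    logger.info("preparing %d train / %d test subjects", len(train_recordings), len(test_recordings))
    train_prep = [prepare_subject(r, config, "train") for r in train_recordings]
    test_prep = [prepare_subject(r, config, "test") for r in test_recordings]
    train_grouped = _group_subjects(train_prep)
    test_grouped = _group_subjects(test_prep)

    logger.info("grid search over %d cells (training set only)",
                len(config.metrics) * len(config.ms) * len(config.rs))
    grid = parameter_grid_search(
        train_grouped, config.metrics, config.ms, config.rs,
        alpha=config.alpha, fdr_scope=config.fdr_scope,
    )
    selected_params = EntropyParams(
        metric=grid.selected_metric, m=grid.selected_m, r=grid.selected_r
    )
    train_stats = grid.tables[grid.selected]
    train_matrices = grid.matrices[grid.selected]

    logger.info("computing test-set matrices at selected cell %s", grid.selected)
    test_matrices = _matrices_for_cell(test_grouped, selected_params)

    feature_sets: dict[str, FeatureSet] = {}
    reports: dict[str, dict[str, dict]] = {}
    test_stats: dict[str, object] = {}
    for control, patient in config.contrasts:
        contrast = f"{control}_vs_{patient}"
        pair_train = {g: train_matrices[g] for g in (control, patient)}
        pair_test = {g: test_matrices[g] for g in (control, patient)}
        train_table = build_feature_table(pair_train, positive_label=patient, split="train")
        selected = fcbf(train_table, delta=config.fcbf_delta)
        if not selected.features:
            raise RuntimeError(f"FCBF selected no features for {contrast}")
        feature_sets[contrast] = selected
        test_table = build_feature_table(pair_test, positive_label=patient, split="test")
        test_stats[contrast] = screen_connections(
            pair_test, config.alpha, "mannwhitney_2group", config.fdr_scope
        )
        x_train = FeatureTable(
            train_table.x[selected.features], train_table.y, patient, split="train"
        )
        x_test = FeatureTable(
            test_table.x[selected.features], test_table.y, patient, split="test"
        )
        reports[contrast] = {}
        for model in config.models:
            spec = ClassifierSpec(model=model, seed=config.seed)
            fitted = fit(spec, x_train)
            reports[contrast][model] = evaluate(fitted, x_test).to_dict()

    manifest = {
        "package": "neuroxent",
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "selected_cell": list(grid.selected),
        "discriminative": grid.discriminative,
        "significant_counts_selected": significant_counts(train_stats).to_dict(),
        "runtime_s": round(time.perf_counter() - t0, 2),
    }
    result = PipelineResult(
        config=config,
        grid=grid,
        selected_params=selected_params,
        train_stats=train_stats,
        feature_sets=feature_sets,
        reports=reports,
        test_stats=test_stats,
        manifest=manifest,
    )
    if outdir is not None:
        _write_bundle(result, Path(outdir), train_matrices)
    return result


def _write_bundle(result: PipelineResult, outdir: Path, train_matrices) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    result.grid.counts.to_csv(outdir / "grid_counts.tsv", sep="\t")
    result.train_stats.to_csv(outdir / "train_stats_selected.tsv", sep="\t", index=False)
    for contrast, table in result.test_stats.items():
        table.to_csv(outdir / f"test_stats_{contrast}.tsv", sep="\t", index=False)
    features = {
        contrast: {"features": fs.features, "su_scores": fs.su_scores}
        for contrast, fs in result.feature_sets.items()
    }
    write_json(features, outdir / "selected_features.json")
    write_json(result.reports, outdir / "classifier_reports.json")
    write_json(result.manifest, outdir / "manifest.json")
    matdir = outdir / "train_matrices"
    matdir.mkdir(exist_ok=True)
    for group, subjects in train_matrices.items():
        for subj in subjects:
            for band, mat in subj.items():
                write_matrix(mat, matdir / f"{mat.subject_id}_{band}.tsv")
    logger.info("wrote result bundle to %s", outdir)
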