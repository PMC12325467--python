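"""End-to-end analysis pipeline.

Order of stages mirrors the analysis workflow: read and filter the landmark
dataset, superimpose everything in one generalized Procrustes analysis,
ordinate with PCA, fit per-species allometric regressions and extract the
CAC and multivariate-shape trajectory scores, fit Gompertz shape-growth
curves and the two adult-size thresholds, cluster specimens into ontogenetic
stages, and compare stage disparity with bootstrap CIs and overlapping-CI
tests.

Per-species failures (non-convergent curve, flat trajectory, too few
specimens) are recorded in the manifest and excluded from summaries; they
never abort the run.  Every random stage draws from an independent stream
derived from the global seed and the species name, so adding or removing a
species leaves the other species' results untouched.
"""

from __future__ import annotations

import json
import math
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .exceptions import ShellOntError
from .io import (
    LandmarkConfig,
    MaxSizeTable,
    SpeciesDataset,
    SpecimenRecord,
    read_landmarks,
    read_max_size_table,
    read_metadata,
    filter_ontogenetic_series,
)
from .procrustes import gpa, pca
from .allometry import fit_allometry, fit_allometry_with_sex
from .growth import (
    ThresholdResult,
    asymptote_threshold,
    distance85_threshold,
    fit_gompertz,
    pct_of_max,
    summarize_thresholds,
)
from .disparity import (
    STAGE_NAMES,
    bonferroni,
    bootstrap_disparity,
    stage_clusters,
    zou_ci_test,
)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "build_datasets"]

ALL_STAGES = ("allometry", "thresholds", "staging", "disparity")


@dataclass
class PipelineConfig:
    """Settings for one pipeline run; see the YAML example in the README."""

    landmarks_path: str
    metadata_path: str
    max_size_path: str
    out_dir: str = "results/pipeline"
    landmark_format: str | None = None
    # dataset filters
    min_n: int = 8
    min_fold: float = 3.0
    exclude_species: list[str] = field(default_factory=list)
    exclude_specimens: list[str] = field(default_factory=list)
    fill_scl_specimens: list[str] = field(default_factory=list)
    # inference settings
    seed: int = 0
    n_perm: int = 999
    n_grid: int = 1000
    ratio: float = 0.85
    ci_level: float = 0.90
    trajectory: str = "gompertz"  # or "linear"
    tangent: bool = True
    # staging / disparity
    cluster_k: int = 3
    n_boot: int = 1000
    boot_ci: float = 0.95
    rarefy: bool = True
    # per-species sexual size dimorphism: species -> larger sex
    dimorphic_species: dict[str, str] = field(default_factory=dict)
    run_sex_models: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f.name for f in cls.__dataclass_fields__.values()}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        for p in (self.landmarks_path, self.metadata_path, self.max_size_path):
            if not Path(p).exists():
                raise FileNotFoundError(f"input path does not exist: {p}")
        if self.trajectory not in ("gompertz", "linear"):
            raise ValueError(f"unknown trajectory {self.trajectory!r}")
        if not 0 < self.ratio <= 1:
            raise ValueError("ratio must be in (0, 1]")


@dataclass
class PipelineResult:
    """Tables and summaries produced by one run."""

    allometry: pd.DataFrame
    scores: pd.DataFrame
    thresholds: pd.DataFrame
    threshold_results: list[ThresholdResult]
    summary: dict
    stages: pd.DataFrame
    disparity: pd.DataFrame
    zou_tests: pd.DataFrame
    sex_models: pd.DataFrame
    filter_log: pd.DataFrame
    manifest: dict


def build_datasets(
    configs: list[LandmarkConfig], records: list[SpecimenRecord]
) -> list[SpeciesDataset]:
    """Pair landmark configurations with their metadata, grouped by species
    in order of first appearance."""
    by_id = {r.specimen_id: r for r in records}
    missing = [c.specimen_id for c in configs if c.specimen_id not in by_id]
    if missing:
        raise ShellOntError(f"specimens without metadata: {missing[:5]}")
    grouped: dict[str, list] = {}
    for c in configs:
        r = by_id[c.specimen_id]
        grouped.setdefault(r.species, []).append((c, r))
    return [SpeciesDataset(sp, specs) for sp, specs in grouped.items()]


def _species_seed(global_seed: int, species: str, salt: str) -> int:
    return int(
        np.random.SeedSequence(
            [int(global_seed), zlib.crc32(f"{salt}:{species}".encode()) & 0x7FFFFFFF]
        ).generate_state(1)[0]
        % (2**31)
    )


def run_pipeline(
    config: PipelineConfig, stages: tuple[str, ...] = ALL_STAGES
) -> PipelineResult:
    """Run the analysis end to end and write all outputs to
    ``config.out_dir``; returns the tables in memory as well."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    configs = read_landmarks(config.landmarks_path, format=config.landmark_format)
    records = read_metadata(config.metadata_path)
    max_table = read_max_size_table(config.max_size_path)
    datasets = build_datasets(configs, records)
    n_input = sum(ds.n for ds in datasets)

    datasets, filter_log = filter_ontogenetic_series(
        datasets,
        min_n=config.min_n,
        min_fold=config.min_fold,
        exclude_species=config.exclude_species,
        max_table=max_table,
        exclude_specimens=config.exclude_specimens,
        fill_scl_specimens=config.fill_scl_specimens,
    )
    if not datasets:
        raise ShellOntError("no species survive the dataset filters")

    # One GPA over the full dataset, as in the original analysis; species
    # subsets of the global alignment feed the per-species models.
    all_configs = [c for ds in datasets for c in ds.configs()]
    all_records = [r for ds in datasets for r in ds.records()]
    sample = gpa(all_configs)
    shapes = sample.flattened(tangent=config.tangent)
    log_cs = np.log10(sample.centroid_sizes)
    species_of = np.array([r.species for r in all_records])
    ids = np.array([r.specimen_id for r in all_records])
    scl_all = np.array([r.scl_mm for r in all_records])
    sex_all = np.array([r.sex for r in all_records])
    pooled_pca = pca(sample, tangent=config.tangent)

    failures: list[dict] = []
    allo_rows, score_rows, sexmodel_rows = [], [], []
    thr_results: list[ThresholdResult] = []
    stage_rows: list[dict] = []

    for ds in datasets:
        sp = ds.species
        mask = species_of == sp
        y = shapes[mask]
        s = log_cs[mask]
        scl = scl_all[mask]
        sp_ids = ids[mask]
        sp_sex = sex_all[mask]
        try:
            fit = fit_allometry(
                y,
                s,
                n_perm=config.n_perm,
                seed=_species_seed(config.seed, sp, "allometry"),
                species=sp,
            )
        except ShellOntError as exc:
            failures.append({"species": sp, "stage": "allometry", "reason": str(exc)})
            continue
        allo_rows.append(
            {
                "species": sp,
                "n": fit.n,
                "r2": fit.r2,
                "f": fit.f_stat,
                "z": fit.z_score,
                "p": fit.p_value,
            }
        )
        proxy_scores = {"cac": fit.cac_scores, "multivariate": fit.predline_scores}
        for sid, cacv, plv, lc, sc in zip(
            sp_ids, fit.cac_scores, fit.predline_scores, s, scl
        ):
            score_rows.append(
                {
                    "specimen_id": sid,
                    "species": sp,
                    "cac": cacv,
                    "predline": plv,
                    "log_cs": lc,
                    "scl_mm": sc,
                }
            )

        if config.run_sex_models:
            n_f = int(np.sum(sp_sex == "female"))
            n_m = int(np.sum(sp_sex == "male"))
            if n_f >= 2 and n_m >= 2:
                try:
                    import warnings

                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        sm = fit_allometry_with_sex(
                            y,
                            s,
                            sp_sex,
                            n_perm=config.n_perm,
                            seed=_species_seed(config.seed, sp, "sex"),
                            species=sp,
                        )
                    sexmodel_rows.append(
                        {
                            "species": sp,
                            "n": sm.n,
                            "z_size": sm.z_size,
                            "z_sex": sm.z_sex,
                            "p_size": sm.p_size,
                            "p_sex": sm.p_sex,
                            "delta_z": sm.delta_z,
                        }
                    )
                except ShellOntError as exc:
                    failures.append(
                        {"species": sp, "stage": "sex_model", "reason": str(exc)}
                    )

        dimorphic = sp in config.dimorphic_species
        larger_sex = config.dimorphic_species.get(sp)
        if "thresholds" in stages:
            for proxy, scores in proxy_scores.items():
                try:
                    sex_for_max = larger_sex if dimorphic else "both"
                    max_scl = max_table.max_for(sp, sex_for_max)
                    gfit = fit_gompertz(
                        scl,
                        scores,
                        seed=_species_seed(config.seed, sp, f"gompertz-{proxy}"),
                    )
                    asym = None
                    if gfit.converged:
                        asym = asymptote_threshold(gfit, ci_level=config.ci_level)
                    d85 = distance85_threshold(
                        scl,
                        scores,
                        y,
                        max_scl_mm=max_scl,
                        n_grid=config.n_grid,
                        ratio=config.ratio,
                        trajectory=config.trajectory,
                        seed=_species_seed(config.seed, sp, f"d85-{proxy}"),
                    )
                    pf, pm, sex_used = pct_of_max(
                        d85, sp, max_table, dimorphic=dimorphic, larger_sex=larger_sex
                    )
                    thr_results.append(
                        ThresholdResult(
                            species=sp,
                            proxy=proxy,
                            asymptote_threshold_mm=asym,
                            distance85_threshold_mm=d85,
                            pct_of_max_female=pf,
                            pct_of_max_male=pm,
                            sex_used=sex_used,
                        )
                    )
                except ShellOntError as exc:
                    failures.append(
                        {
                            "species": sp,
                            "stage": f"thresholds-{proxy}",
                            "reason": str(exc),
                        }
                    )

        if "staging" in stages:
            for proxy, scores in proxy_scores.items():
                if len(scores) < config.cluster_k:
                    failures.append(
                        {
                            "species": sp,
                            "stage": f"staging-{proxy}",
                            "reason": f"n={len(scores)} < k={config.cluster_k}",
                        }
                    )
                    continue
                for a in stage_clusters(
                    scores, scl, specimen_ids=sp_ids, k=config.cluster_k
                ):
                    stage_rows.append(
                        {
                            "specimen_id": a.specimen_id,
                            "species": sp,
                            "proxy": proxy,
                            "stage": a.stage,
                        }
                    )

    allometry_df = pd.DataFrame(allo_rows)
    scores_df = pd.DataFrame(score_rows)
    sex_df = pd.DataFrame(sexmodel_rows)
    stages_df = pd.DataFrame(stage_rows)

    thresholds_df = pd.DataFrame(
        [
            {
                "species": r.species,
                "proxy": r.proxy,
                "asymptote_threshold_mm": r.asymptote_threshold_mm,
                "distance85_mm": r.distance85_threshold_mm,
                "pct_female": r.pct_of_max_female,
                "pct_male": r.pct_of_max_male,
                "sex_used": r.sex_used,
            }
            for r in thr_results
        ]
    )
    summary = summarize_thresholds(thr_results) if thr_results else {}

    # Pooled disparity across the CAC-based ontogenetic stages.
    disparity_df = pd.DataFrame()
    zou_df = pd.DataFrame()
    if "disparity" in stages and not stages_df.empty:
        cac_stages = stages_df[stages_df["proxy"] == "cac"].set_index("specimen_id")[
            "stage"
        ]
        in_stage = np.array([sid in cac_stages.index for sid in ids])
        labels = np.array([cac_stages.get(sid, "") for sid in ids])
        pc_scores = pooled_pca.scores[in_stage]
        shp = shapes[in_stage]
        lab = labels[in_stage]
        order = [s for s in STAGE_NAMES if s in set(lab)]
        sizes = {g: int(np.sum(lab == g)) for g in order}
        rarefy_n = min(sizes.values()) if config.rarefy else None
        disp_rows, zou_rows = [], []
        for metric, data in (("sor", pc_scores), ("pv", shp)):
            res = bootstrap_disparity(
                data,
                lab,
                metric=metric,
                n_boot=config.n_boot,
                rarefy_n=rarefy_n if metric == "sor" else None,
                ci=config.boot_ci,
                seed=_species_seed(config.seed, metric, "disparity"),
            )
            for g in order:
                r = res[g]
                disp_rows.append(
                    {
                        "stage": g,
                        "n": r.n,
                        "metric": metric,
                        "observed": r.observed,
                        "ci_lo": r.ci[0] if r.ci else math.nan,
                        "ci_hi": r.ci[1] if r.ci else math.nan,
                        "n_boot": r.n_boot,
                        "rarefy_n": r.rarefy_n,
                    }
                )
            pairs = [
                (order[i], order[j])
                for i in range(len(order))
                for j in range(i + 1, len(order))
            ]
            tests = [
                zou_ci_test(
                    res[a].ci, res[b].ci, ci_level=config.boot_ci, pair=f"{a}-{b}"
                )
                for a, b in pairs
                if res[a].ci and res[b].ci
            ]
            adj = bonferroni([max(t.p_raw, 1e-300) for t in tests]) if tests else []
            for t, p_adj in zip(tests, adj):
                zou_rows.append(
                    {
                        "metric": metric,
                        "pair": t.pair,
                        "statistic": t.statistic,
                        "p_raw": t.p_raw,
                        "p_bonferroni": p_adj,
                    }
                )
        disparity_df = pd.DataFrame(disp_rows)
        zou_df = pd.DataFrame(zou_rows)

    used_ids = set(ids)
    manifest = {
        "shellont_version": __version__,
        "seed": config.seed,
        "n_input_specimens": n_input,
        "n_used_specimens": len(used_ids),
        "n_species": len(datasets),
        "filtered": filter_log.to_dict("records"),
        "failures": failures,
        "config": {
            k: v for k, v in asdict(config).items() if not isinstance(v, (dict, list))
        },
    }

    # write outputs
    allometry_df.to_csv(out_dir / "allometry.tsv", sep="\t", index=False)
    scores_df.to_csv(out_dir / "scores.tsv", sep="\t", index=False)
    thresholds_df.to_csv(out_dir / "thresholds.tsv", sep="\t", index=False)
    stages_df.to_csv(out_dir / "stages.tsv", sep="\t", index=False)
    disparity_df.to_csv(out_dir / "disparity.tsv", sep="\t", index=False)
    zou_df.to_csv(out_dir / "zou_tests.tsv", sep="\t", index=False)
    sex_df.to_csv(out_dir / "sex_models.tsv", sep="\t", index=False)
    filter_log.to_csv(out_dir / "filter_log.tsv", sep="\t", index=False)
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2))
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))

    return PipelineResult(
        allometry=allometry_df,
        scores=scores_df,
        thresholds=thresholds_df,
        threshold_results=thr_results,
        summary=summary,
        stages=stages_df,
        disparity=disparity_df,
        zou_tests=zou_df,
        sex_models=sex_df,
        filter_log=filter_log,
        manifest=manifest,
    )
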