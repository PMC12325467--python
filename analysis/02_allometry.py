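#!/usr/bin/env python
"""Superimpose the panel and fit per-species allometric regressions.

One generalized Procrustes analysis over all specimens, then for each
species a permutation (RRPP) regression of shape on log10 centroid size,
with the CAC and multivariate-shape trajectory scores.  Writes
results/pipeline/allometry.tsv and scores.tsv and reports how many species
show statistically detectable ontogenetic shape change.
"""

import sys

from shellont.pipeline import PipelineConfig, run_pipeline

SEED = 1


def panel_config(seed: int) -> PipelineConfig:
    return PipelineConfig(
        landmarks_path="results/panel/landmarks.tps",
        metadata_path="results/panel/metadata.tsv",
        max_size_path="results/panel/max_sizes.tsv",
        out_dir="results/pipeline",
        min_n=1,
        min_fold=1.0,
        n_perm=999,
        n_boot=1000,
        seed=seed,
    )


def main() -> None:
    seed = int(sys.argv[1]) if len(sys.argv) > 1 else SEED
    result = run_pipeline(panel_config(seed), stages=("allometry",))
    allo = result.allometry
    sig = (allo["p"] <= 0.05).sum()
    print(f"allometric regressions: {sig}/{len(allo)} species significant at 0.05")
    print(
        f"R2 range {allo['r2'].min():.2f}-{allo['r2'].max():.2f}, "
        f"Z range {allo['z'].min():.2f}-{allo['z'].max():.2f}"
    )
    if not result.sex_models.empty:
        sm = result.sex_models
        print(
            f"sex models ({len(sm)} species): median Z(size) "
            f"{sm['z_size'].median():.2f} vs median Z(sex) {sm['z_sex'].median():.2f}"
        )
    print("tables: results/pipeline/allometry.tsv, scores.tsv, sex_models.tsv")


if __name__ == "__main__":
    main()
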