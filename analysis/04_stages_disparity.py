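#!/usr/bin/env python
"""Cluster specimens into ontogenetic stages and compare stage disparity.

Within each species, Ward clustering of the (standardised) CAC score and
carapace length defines 'small', 'intermediate' and 'large' stages.  Pooled
across species, stage disparity is measured as the sum of ranges over PC
axes (bootstrapped and rarefied to the smallest stage) and as Procrustes
variance, and pairwise stage differences are tested with the
overlapping-confidence-interval z statistic, Bonferroni-adjusted.
"""

import importlib.util
import sys
from pathlib import Path

_spec = importlib.util.spec_from_file_location(
    "allometry_driver", Path(__file__).parent / "02_allometry.py"
)
_driver = importlib.util.module_from_spec(_spec)
_spec.loader.exec_module(_driver)

from shellont.pipeline import run_pipeline

SEED = 1


def main() -> None:
    seed = int(sys.argv[1]) if len(sys.argv) > 1 else SEED
    result = run_pipeline(
        _driver.panel_config(seed), stages=("allometry", "staging", "disparity")
    )
    counts = (
        result.stages.query("proxy == 'cac'")["stage"].value_counts().to_dict()
    )
    print(f"stage sizes (CAC clustering): {counts}")
    print("disparity per stage (observed [95% bootstrap CI]):")
    for _, row in result.disparity.iterrows():
        print(
            f"  {row['metric']:3s} {row['stage']:12s} "
            f"{row['observed']:.4g} [{row['ci_lo']:.4g}-{row['ci_hi']:.4g}]"
        )
    print("overlapping-CI tests (statistic, Bonferroni-adjusted p):")
    for _, row in result.zou_tests.iterrows():
        flag = "*" if row["p_bonferroni"] < 0.05 else " "
        print(
            f"  {row['metric']:3s} {row['pair']:22s} "
            f"{row['statistic']:6.2f}  p={row['p_bonferroni']:.3g} {flag}"
        )
    print("tables: results/pipeline/stages.tsv, disparity.tsv, zou_tests.tsv")


if __name__ == "__main__":
    main()
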