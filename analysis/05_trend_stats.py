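#!/usr/bin/env python
"""Trend statistics over the sensitivity tables.

Computes the ensemble summaries for each model — PCA of sensitivity
strengths and of positive-set parameter values, per-set z-scores across
reactions, pairwise dominance percentages (signed and magnitude), and the
integral-sensitivity Pearson correlations — and prints which reaction pairs
keep an invariant order across all reproducible sets.
"""
import json
import sys

import pandas as pd

import hubsens as hs
from hubsens.trend_stats import pairwise_dominance

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1


def main():
    cfg = hs.RunConfig.from_profile("quick", SEED, outdir="results")
    for mid in cfg.models:
        paths = hs.pipeline.stage_analyze(cfg, mid)
        summary = json.loads((cfg.model_dir(mid) / "summary.json").read_text())
        print(f"{mid}: {summary['n_positive']} positive sets; "
              f"{summary['n_invariant_dominance_pairs']} invariant and "
              f"{summary['n_split_dominance_pairs']} parameter-dependent "
              f"dominance pairs; max |r|(q, s) = {summary['max_abs_pearson_r']}")
        tab = pd.read_csv(cfg.model_dir(mid) / "sensitivity.csv")
        try:
            dom = pairwise_dominance(tab, "S3", use_magnitude=True)
        except ValueError:
            continue
        inv = dom[(dom["pct_greater"] == 100.0)]
        for _, row in inv.iterrows():
            print(f"   S3: |s({row['upper']})| > |s({row['left']})| "
                  f"in all positive sets")


if __name__ == "__main__":
    main()
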