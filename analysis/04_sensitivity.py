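#!/usr/bin/env python
"""Local sensitivity analysis of the output time integral.

For every labeled (non-excluded) parameter set, every signal pattern and
every reaction rate constant, the log-sensitivity of q = ∫ X* dt is computed
by a one-sided 0.1% forward difference.  Writes
results/<model>/sensitivity.csv and reports the sign structure.
"""
import sys

import pandas as pd

import hubsens as hs
from hubsens.pipeline import NEGATIVE_REACTIONS

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1


def main():
    cfg = hs.RunConfig.from_profile("quick", SEED, outdir="results")
    for mid in cfg.models:
        paths = hs.pipeline.stage_sensitivity(cfg, mid)
        tab = pd.read_csv(paths[0])
        pos = tab[tab["label"] == "positive"]
        neg_rxn = pos[pos["reaction"].isin(NEGATIVE_REACTIONS)]
        if len(neg_rxn):
            pct = 100.0 * (neg_rxn["s_log"] < 0).mean()
            print(f"{mid}: {len(tab)} records; deactivation-type reactions "
                  f"negative in {pct:.1f}% of positive records")
        else:
            print(f"{mid}: {len(tab)} records")


if __name__ == "__main__":
    main()
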