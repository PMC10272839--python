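"""Which NF-kB subunit's expression controls the response to TME stimuli?

Simulates 25-cell heterogeneous populations (11% CV on expression and
degradation parameters) of the core multi-dimer model at baseline and with
10-fold increased RelA, cRel or RelB expression, under a TME-driven
NEMO-IKK step. Summarises nuclear RelA:p50 and cRel:p50.

Expected picture: only the RelA-overexpressing population shows a
stimulated nuclear RelA:p50 excursion that clearly exceeds the inherent
cell-to-cell variability of the baseline population; the cRel:p50 response
is essentially unchanged by any of the expression changes.

Writes results/tenfold_expression/{summaries.csv, run_manifest.json}.
"""

import argparse
from pathlib import Path

import pandas as pd

from nfkbfp.config import RunConfig
from nfkbfp.recipes import run_experiment


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/tenfold_expression"))
    ap.add_argument("--n-cells", type=int, default=25)
    args = ap.parse_args()

    cfg = RunConfig(
        recipe="tenfold_expression", seed=args.seed, outdir=str(args.out),
        population={"n_cells": args.n_cells},
    )
    run_experiment(cfg)

    s = pd.read_csv(args.out / "summaries.csv")
    print("stimulated response (peak mean - basal mean), by population:")
    for rep in ("nRelAp50", "ncRelp50"):
        b = s[(s.population == "baseline") & (s.reporter == rep)]
        basal_sd = b["sd"].iloc[0]
        base_delta = b["mean"].max() - b["mean"].iloc[0]
        print(f"  {rep} (baseline response {base_delta:.2f}, basal SD {basal_sd:.2f}):")
        for popn, grp in s[s.reporter == rep].groupby("population"):
            delta = grp["mean"].max() - grp["mean"].iloc[0]
            amplified = popn != "baseline" and delta - base_delta > 2 * basal_sd
            flag = " <-- response amplified beyond baseline variability" if amplified else ""
            print(f"    {popn:10s} delta {delta:6.2f}{flag}")


if __name__ == "__main__":
    main()
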