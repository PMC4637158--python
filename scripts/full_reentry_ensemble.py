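#!/usr/bin/env python
"""Full-scale reentry ensemble: P(phi) on the 1 cm tissue, Bondarenko.

This is the cluster-profile experiment: 100 seeded fibrosis
realizations per phi from 0.40 to 0.55 in steps of 0.01, each a
120 ms (LP) or 300 ms (TP) monodomain run of ~4.7e4 cells with the
41-variable Bondarenko kinetics at a 0.1 us reaction substep.  Expect
on the order of a core-year in total; shard it by phi/seed across a
cluster (every run is independent and fully determined by
(--seed, phi index, repetition)).

    python scripts/full_reentry_ensemble.py --direction LP --seed 0 \
        --phi-index 8 --reps 0:10 --out runs_phi48.csv

writes the per-run outcome table for repetitions 0..9 of phi = 0.48.
Concatenate shards and feed them to `fibrosim analyze reentry` /
`analyze classes` / `cv_vs_phi`.
"""

from __future__ import annotations

import argparse

import numpy as np


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--direction", choices=["LP", "TP"], default="LP")
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--phi-index", type=int, required=True,
                    help="index into 0.40..0.55 step 0.01")
    ap.add_argument("--reps", default="0:100", help="start:stop repetition range")
    ap.add_argument("--out", required=True)
    args = ap.parse_args()

    from fibrosim.microstructure import build_template, tile_to_extent
    from fibrosim.discrete import reduce_to_network
    from fibrosim.ionic import BondarenkoModel

    phis = tuple(np.round(np.arange(0.40, 0.551, 0.01), 3))
    phi = phis[args.phi_index]
    lo, hi = (int(x) for x in args.reps.split(":"))

    import pandas as pd

    from fibrosim.analysis import classify_run, default_check_time, detect_reentry, ensemble_cv
    from fibrosim.discrete import network_plane_protocol, simulate_discrete
    from fibrosim.fibrosis import apply_fibrosis_network, realization_seed
    from fibrosim.monodomain import MonodomainParams

    net = reduce_to_network(tile_to_extent(build_template(), 1e4, 1e4))
    ionic = BondarenkoModel()
    params = MonodomainParams()
    side = "left" if args.direction == "LP" else "bottom"
    check = default_check_time(args.direction, net)   # 120 / 300 ms
    rows = []
    for rep in range(lo, hi):
        # per-run seeds derive from (base, phi index, rep): any shard
        # reproduces exactly the runs it names
        seed = realization_seed(args.seed, args.phi_index, rep)
        fib, real = apply_fibrosis_network(net, phi, seed)
        res = simulate_discrete(fib, ionic, params,
                                network_plane_protocol(fib, ionic, side),
                                T_end=check, stop_when_quiet=20.0)
        row = {"phi": phi, "rep": rep, "seed": seed,
               "n_removed": real.n_removed,
               "reentry": detect_reentry(res, args.direction, check_time=check),
               "cv": ensemble_cv(res, fib, args.direction),
               "max_ap": int(res.tracker.ap_count.max())}
        row.update(classify_run(res, fib))
        rows.append(row)
        print(f"phi={phi} rep={rep}: reentry={row['reentry']}", flush=True)
    pd.DataFrame(rows).to_csv(args.out, index=False)
    print(f"wrote {args.out}: {len(rows)} runs at phi={phi}")


if __name__ == "__main__":
    main()
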