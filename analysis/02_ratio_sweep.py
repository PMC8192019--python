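"""Acetylcholine/dopamine ratio sweep (heat-map slice).

At a fixed dopamine learning rate, sweeps the eta_ACh/eta_DA ratio through
the low-to-moderate regime and records days-to-criterion per stage.
Increasing acetylcholine in this regime quickens reversal learning while
leaving initial learning essentially unchanged.

Writes results/ratio_sweep.csv.
"""

import argparse
import pathlib
import sys

import pandas as pd

from snplast.config import build_components, load_config
from snplast.plasticity import PlasticityParams
from snplast.simulate import Network, run_session
from snplast.stats import days_to_criterion


def main(argv=None):
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--ratios", type=float, nargs="+",
                    default=[0.0, 0.1, 0.2, 0.3])
    ap.add_argument("--eta-da", type=float, default=0.00115)
    ap.add_argument("--seeds", type=int, default=10)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--config", default=None)
    ap.add_argument("--out-dir", default="results")
    args = ap.parse_args(argv)

    comp = build_components(load_config(args.config))
    net = Network.build(comp["arena"], comp["action"], comp["lateral_normalised"])
    out = pathlib.Path(args.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    rows = []
    for ratio in args.ratios:
        pp = PlasticityParams(eta_ach=ratio * args.eta_da, eta_da=args.eta_da)
        for k in range(args.seeds):
            c = run_session(pp, protocol=comp["protocol"],
                            seed=args.seed * 10_000 + k, network=net).daily_success
            rows.append((ratio, k, days_to_criterion(c[:8]), days_to_criterion(c[8:])))
    df = pd.DataFrame(rows, columns=["ratio", "agent", "days_initial", "days_reversal"])
    df.to_csv(out / "ratio_sweep.csv", index=False)

    print(f"eta_DA = {args.eta_da}, {args.seeds} agents per ratio")
    print("ratio  days-to-80% initial  days-to-80% reversal")
    for ratio, g in df.groupby("ratio"):
        print(f"{ratio:5.2f}  {g.days_initial.mean():8.2f}            "
              f"{g.days_reversal.mean():8.2f}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
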