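"""Policy preference maps across learning.

Runs one session with daily weight snapshots and exports the policy vector
field (the weight-averaged preferred direction at each place-field centre)
for selected days of each stage.  After initial learning the field points
toward the first well; early in reversal the old preference is still
visible and is progressively unlearned.

Writes results/policy_map_<stage>_day<k>.csv (columns x, y, vx, vy); with
--plot also renders a quiver figure per snapshot.
"""

import argparse
import pathlib
import sys

import numpy as np
import pandas as pd

from snplast.config import build_components, load_config
from snplast.plasticity import PlasticityParams
from snplast.simulate import Network, policy_map, run_session

SNAPSHOTS = [("initial", 8), ("reversal", 4), ("reversal", 8), ("reversal", 12)]


def main(argv=None):
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--eta-ach", type=float, default=0.000345)
    ap.add_argument("--eta-da", type=float, default=0.00115)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--config", default=None)
    ap.add_argument("--out-dir", default="results")
    ap.add_argument("--plot", action="store_true")
    args = ap.parse_args(argv)

    comp = build_components(load_config(args.config))
    net = Network.build(comp["arena"], comp["action"], comp["lateral_normalised"])
    pp = PlasticityParams(eta_ach=args.eta_ach, eta_da=args.eta_da)
    sess = run_session(pp, protocol=comp["protocol"], seed=args.seed,
                       network=net, snapshot_days=True)
    out = pathlib.Path(args.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    print(f"eta_ACh={args.eta_ach} eta_DA={args.eta_da} seed={args.seed}")
    print("daily success:", " ".join(f"{v:.0f}" for v in sess.daily_success))
    for stage, day in SNAPSHOTS:
        w = sess.day_weights[(stage, day)]
        pm = policy_map(w, net.cells, net.directions)
        df = pd.DataFrame(
            np.column_stack([net.cells.centers, pm]), columns=["x", "y", "vx", "vy"])
        path = out / f"policy_map_{stage}_day{day}.csv"
        df.to_csv(path, index=False)
        mean_norm = np.linalg.norm(pm, axis=1).mean()
        print(f"{stage} day {day}: mean |v| = {mean_norm:.4f} -> {path}")
        if args.plot:
            import matplotlib

            matplotlib.use("Agg")
            import matplotlib.pyplot as plt

            fig, ax = plt.subplots(figsize=(5, 5))
            ax.quiver(df.x, df.y, df.vx, df.vy, angles="xy")
            for c, colour in zip(net.arena.well_centers, ("tab:blue", "tab:gray")):
                ax.add_patch(plt.Circle(c, net.arena.well_radius,
                                        color=colour, alpha=0.4))
            ax.add_patch(plt.Circle((0, 0), net.arena.radius, fill=False))
            ax.set_aspect("equal")
            ax.set_title(f"{stage} day {day}")
            fig.savefig(out / f"policy_map_{stage}_day{day}.png", dpi=120)
            plt.close(fig)
    return 0


if __name__ == "__main__":
    sys.exit(main())
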