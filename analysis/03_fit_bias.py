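#!/usr/bin/env python
"""Fit the choice-model bias parameters per participant and condition.

Reads the per-pick display snapshots, reconstructs every choice step
(remaining targets, previous pick, previous heading) and maximizes the
sampling-without-replacement likelihood per participant x condition, and
additionally per set size and trial half ("bin") for the time-course model
of the proximity bias.  With a single target class per display, the class
preference and stickiness parameters are unidentifiable and pinned at 0.5
(flagged); the spatial parameters rho_d and rho_theta carry the signal.
Prints the recovery correlation against the generating rho_d.

Outputs (results/): bias_params.csv, bias_params_binned.csv.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from foragescan.bias_model import fit_bias_grouped
from foragescan.data_io import read_display_snapshots, read_trials


def _frame(rows, keys):
    df = pd.DataFrame(rows)
    df[keys] = pd.DataFrame(df.pop("group").tolist(), index=df.index)
    return df[keys + [c for c in df.columns if c not in keys]]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    snapshots = read_display_snapshots(args.results / "displays.csv")
    trials = read_trials(args.results / "trials.csv")
    truth = pd.read_csv(args.results / "truth.csv",
                        dtype={"participant": str})

    fits = _frame(fit_bias_grouped(snapshots),
                  ["participant", "condition"])
    fits.to_csv(args.results / "bias_params.csv", index=False)

    # per set size and trial half, for the time-course mixed models
    set_size = {(t.participant_id, t.condition, t.trial_index): t.set_size
                for t in trials}
    # small per-cell samples: weak MAP priors keep a handful of
    # nearest-target choices from sending rho_d to infinity
    binned = _frame(
        fit_bias_grouped(snapshots, split_halves=True,
                         group_fn=lambda key: (key[0], key[1],
                                               set_size[key]),
                         prior_sd={"rho_d": 5.0, "rho_theta": 2.0}),
        ["participant", "condition", "set_size", "bin"])
    binned.to_csv(args.results / "bias_params_binned.csv", index=False)

    per_part = fits.groupby("participant")["rho_d"].mean()
    merged = truth.set_index("participant").join(per_part,
                                                 rsuffix="_hat")
    r = np.corrcoef(merged["rho_d"], merged["rho_d_hat"])[0, 1]
    print(f"fitted {len(fits)} participant x condition cells "
          f"({fits.converged.mean():.0%} converged) and "
          f"{len(binned)} set-size x bin cells")
    print(f"rho_d recovery: corr(truth, estimate) = {r:.3f}")
    b = binned.groupby("bin")["rho_d"].mean()
    print(f"mean rho_d bin1 {b['bin1']:.2f} vs bin2 {b['bin2']:.2f} "
          "(proximity bias weakens as the patch depletes)")


if __name__ == "__main__":
    main()
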