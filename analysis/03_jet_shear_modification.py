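#!/usr/bin/env python
"""Solver analog of the angled-jet experiment: does the flux direction
feed back on the large-scale shear?

Runs the quasi-2D solver with a Kolmogorov shear band and a pulsed,
force-free jet dipole at theta_s = 0, pi/4, pi/2 to the band's
extensional strain eigenvector, paired with a no-jet reference from the
same initial state.  Reports the normalized mean velocity gradient
P~ = P_jet / P_ref: inverse flux (theta_s = 0) intensifies the shear
(P~ > 1), forward flux (theta_s = pi/2) attenuates it (P~ < 1), the
neutral angle leaves it nearly unchanged.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from shearflux.solver import (ForcingSpec, SolverConfig, laminar_shear_state,
                              run_case, run_geometry_experiment)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--n-seeds", type=int, default=1,
                    help="number of consecutive seeds to run")
    ap.add_argument("--duration", type=float, default=30.0)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    forcing = ForcingSpec(shear_amplitude=0.084)
    rows = []
    for seed in range(args.seed, args.seed + args.n_seeds):
        cfg = SolverConfig(n=128, domain_size=10.0, nu=0.01, alpha=0.08,
                           dt=0.01, seed=seed)
        init = laminar_shear_state(cfg, forcing, noise_amplitude=1e-6)
        ref = run_case(cfg, forcing, duration=args.duration, state=init)
        for theta, label in ((0.0, "0"), (np.pi / 4, "pi/4"),
                             (np.pi / 2, "pi/2")):
            res = run_geometry_experiment(cfg, forcing, theta,
                                          duration=args.duration,
                                          reference_field=ref)
            rows.append({"seed": seed, "theta_s": label,
                         "P": res.P_jet, "P_ref": res.P_ref,
                         "P_tilde": res.P_tilde})
            effect = ("intensified" if res.P_tilde > 1 else "attenuated")
            print(f"seed {seed}  theta_s = {label:>4}:  "
                  f"P~ = {res.P_tilde:.5f}  (shear {effect})")
    df = pd.DataFrame(rows)
    df.to_csv(args.out / "shear_modification.csv", index=False)
    print(f"table written to {args.out / 'shear_modification.csv'}")


if __name__ == "__main__":
    main()
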