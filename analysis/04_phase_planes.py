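#!/usr/bin/env python
"""Phase-plane portraits: nullclines, vector fields and stable nodes.

For each (miRNA, pathway) projection and each treatment arm, samples the
two nullclines and the direction field with the remaining six variables
frozen at their per-arm steady values, and reports the equilibrium
classification (all equilibria of this system are stable nodes: the
Jacobian spectrum equals the negated decay rates).
"""

from pathlib import Path

import numpy as np

from mirtgf.cli_io import RunConfig, run_subcommand
from mirtgf.dynamics import steady_state
from mirtgf.model_core import calibrated_parameters, calibrated_thresholds_dict
from mirtgf.phenotype import PhenotypeThresholds
from mirtgf.protocols import build_protocol

OUT = Path("results/phaseplanes")


def main() -> None:
    params = calibrated_parameters()
    cfg = RunConfig(params=params, protocol=build_protocol("bolus", dose=1.0),
                    thresholds=PhenotypeThresholds(**calibrated_thresholds_dict()),
                    out_dir=OUT)

    for arm in ("control", "antagomir"):
        for mirna in ("R1", "R2", "R3"):
            for pathway in ("T", "S"):
                run_subcommand("phaseplane", cfg, pair=(mirna, pathway),
                               arm=arm)
    print(f"wrote nullcline and field tables for 12 projections x 2 arms "
          f"under {OUT}/")

    for arm, A in (("control", 0.0), ("antagomir", 1.0)):
        eq = steady_state(params, A_const=A, se_phase=True)
        print(f"{arm} (A = {A}): equilibrium {eq.classification}, "
              f"T* = {eq.state[6]:.3f}, S* = {eq.state[7]:.3f}, "
              f"max |eig| = {np.max(np.abs(eq.eigenvalues)):.3f}")


if __name__ == "__main__":
    main()
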