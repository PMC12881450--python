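# Analysis drivers

Thin numbered scripts reproducing the study end to end; all computation
lives in the `mirtgf` package.  Run from the repository root; tables land
under `results/`.

1. `01_simulate_arms.py` — antagomir vs scrambled-control trajectories and
   phenotype summaries.
2. `02_mirna_variants.py` — single and pairwise miRNA model variants;
   pairwise suppression of T/S below both constituent singles.
3. `03_dose_strategies.py` — bolus/infusion dose scans, critical doses by
   bisection, multidose frequency ladder.
4. `04_phase_planes.py` — nullclines, vector fields and stable-node
   equilibria per arm.
5. `05_sensitivity.py` — eFAST S1/ST tables for every species and arm.
6. `06_synthetic_fit.py` — synthetic observations and parameter recovery.
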