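# saftscreen

Pure-prediction screening of drug–polymer compatibility for amorphous
solid dispersions, built on a from-scratch PC-SAFT equation of state.

Given pure-component parameters only (no binary interaction parameter:
`k_ij = 0`), the package

- evaluates the PC-SAFT residual Helmholtz energy (hard-chain,
  dispersion, association; copolymer-capable segments), densities,
  fugacity and activity coefficients (`saftscreen.saft_core`);
- solves crystalline-drug solubility curves in amorphous polymers
  (solid–liquid equilibrium) and amorphous–amorphous demixing binodals
  via an alternating-tangent construction robust to extreme molar-mass
  asymmetry (`saftscreen.phase_equilibria`);
- quantifies prediction error (AARD/ARD with pooled "ALL" margins),
  calibrates a one-point `k_ij` when needed, and ranks polymer carriers
  per drug with a demixing penalty (`saftscreen.screening`);
- estimates drug parameters from solubility data in small solvents by
  simulated annealing (`saftscreen.param_fitting`);
- generates seeded synthetic components and datasets so the entire
  pipeline is testable offline (`saftscreen.synthetic_data`).

Built-in data cover seven drugs (GSF, IBP, IMC, NPX, NIF, PCM, SIM):
molar masses, fusion properties (including linear-in-T heat-capacity
differences) and two parametrization strategies (`REF` for all seven,
`ALT` for IBP/IMC/NPX/PCM). Polymer PC-SAFT parameters are supplied by
the user through a documented YAML schema (see the
`saftscreen/parameters.py` module docstring); polymer molar masses and
monomer makeup for eleven common carriers ship with the package.

## Command line

```bash
saftscreen predict -c config.yaml   # phase-diagram TSVs per system
saftscreen screen  -c config.yaml   # AARD/ARD grid + polymer rankings
saftscreen synth   --seed 1 -o out  # synthetic study on disk
saftscreen fit     -c fitspec.yaml  # drug-parameter fit report
```

A `config.yaml` may set: `library` (parameter file), `data`
(experimental TSV: `system_id  api  polymer  T_K  w_api_exp`),
`systems` (list of `{api, polymer, strategy, kij}`), `strategy`
(`REF`/`ALT`), `pressure` (default 0.1 MPa), SLE grid (`sle_T_min`,
`sle_T_step`), demixing scan (`aaps_range`, default 200–600 K;
`aaps_step`; `aaps: false` to skip), `penalty`, `aggregation`
(`pool`/`mean`), `outdir`, `seed`. Every run writes a `manifest.json`
(config hash, seed, version); reruns are byte-identical.

Note: the default 1 K solubility grid and 2 K demixing scan are faithful
to the workflow but slow (minutes per system); coarser grids are fine
for exploration.

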