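# lignosim

Stochastic coarse-grained simulation of enzymatic lignocellulose
saccharification, with a closed-form characteristic-time (limiting-step)
analysis and a variance-based (Sobol) global sensitivity pipeline.

## What it does

* **Substrate** (`lignosim.substrate`) — a single microfibril resolved at
  monomer level: cellulose core chains on a concentric-ring lattice,
  optional hemicellulose sheath and lignin layer, crystalline/amorphous
  bond labelling with exact `round(X · bonds)` counts, and layered
  exposure (a bond is attackable once its covering monomers are removed).
* **Kinetics** (`lignosim.kinetics`) — a four-enzyme cocktail (EG, CBH,
  BGL, xylanase), the canonical 19-parameter registry, propensity
  calculus (crystalline bonds scaled by the digestibility ratio `r`),
  end-product inhibition of the cellulases by free glucose/cellobiose,
  and static non-productive enzyme adsorption on exposed lignin.
* **Engine** (`lignosim.engine`) — exact Gillespie SSA: exponential
  waiting times, stable-ordered channel selection, replicate-averaged
  conversion time-courses on an hourly (configurable) grid.
* **Analytic** (`lignosim.analytic`) — characteristic times
  `tau_EG, tau_CBHA, tau_CBHD, tau_BGL` with the crystallinity factor
  `1 + X(1/r − 1)` and inhibition corrections; limiting-step
  classification; the CBH-vs-EG regime quadratic (both the printed and
  the independently re-derived form, see module docstring) and the
  CBH-vs-BGL threshold rule; the `tau_CBHA` per-unit sensitivity report.
* **Sobol pipeline** (`lignosim.sobol`) — first/total-order cross-sampling
  design (`N_base · (p + 2)` sets; 21,504 at `p = 19`, `N_base = 1024`),
  the curve-difference objective `Y = Σ |sim − ref|` with the
  close/above/below classification, Jansen total-order estimator with
  bootstrap CIs, normalisation by the `K_CBHD` index, and a resumable
  campaign runner with a reproducibility manifest.
* **Fixtures** (`lignosim.fixtures`) — programmatic reference curves
  (simulated, or parametric two-phase curves anchored to 72-h yields),
  a packaged parameter-bounds table, uniform parameter samplers, the
  fully amorphous pure-cellulose *test sample*, and a parameter-recovery
  experiment.

## CLI

```sh
# replicate-averaged saccharification curve
lignosim simulate --config model.yaml --tmax 72 --reps 10 --seed 1 --out curve.csv

# characteristic-time / regime report
lignosim analytic --kr 1                 # regime roots only
lignosim analytic --params params.yaml --N 50 --report regimes.json

# reference curves and the test-sample configuration
lignosim fixtures make-ref --anchor 58.2 --out ref.csv
lignosim fixtures test-sample --out ts.yaml

# scaled-down sensitivity campaign (writes samples/objectives/indices/manifest)
lignosim sobol --ref ref.csv --nbase 64 --reps 3 --seed 1 --out campaign/

# objective scan against a reference curve
lignosim test-sample-scan --ref ref.csv --n 100 --seed 1 --out scan.csv

# parameter-recovery experiment
lignosim recover --x-true 0.3 --n 2000 --seed 1
```

`model.yaml` holds a `structure:` section (chains per ring, DP, sheath
and lignin content) and a `parameters:` section (any of the 19 registry
names); omitted keys take the documented defaults.

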