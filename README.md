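# peakfluo

Signal processing for real-time qPCR-based protein quantification with DNA
aptamers. In the underlying assay, the target protein displaces
aptamer–adaptor complexes, so *more* protein leaves *less* amplifiable
template: the 0 ng/mL negative control amplifies earliest and sample
amplification shifts later with concentration.

The package provides:

- **`peakfluo.ampsim`** — a four-phase amplification-curve simulator
  (background, exponential, linear, plateau) whose exponential phase follows
  the growth law `y_n = y_0 (1+E)^n`, with a hyperbolic
  concentration→template displacement map, shared per-plate process noise
  and per-well read noise.
- **`peakfluo.core`** — the streaming quantification algorithm: per-well
  background estimation over early cycles, negative-control subtraction,
  an early-stopping global-minimum ("peak") search over the cleaned signal,
  replicate averaging, an assay-validity gate (samples must not amplify
  before the control), standard curves of peak vs log10(concentration) and
  inversion of the fitted line to quantify unknowns.
- **`peakfluo.baselines`** — classical quantification points computed from a
  fitted 4-parameter logistic: scaled-threshold Ct, first/second-derivative
  maxima, the inflection-tangent intercept (Cy0) and back-projection of the
  early-cycle fit to cycle 0 (F0).
- **`peakfluo.classify`** — amplification curves rendered as fixed-axes
  grayscale images and a six-layer CNN (conv → max-pool → conv → max-pool →
  flatten → dense) classifying wells as high/low around a 5 ng/mL decision
  threshold, validated with stratified k-fold cross-validation. The CNN is
  implemented in pure NumPy (seeded, deterministic).
- **`peakfluo.io` / `peakfluo.pipeline` / `peakfluo.cli`** — plate/layout
  CSV formats, JSON configs and reports, and the command line.

## Command line

```bash
# simulate a plate from a layout that carries true concentrations
peakfluo simulate --layout layout.csv --out plate.csv --seed 17
ampsim simulate --layout layout.csv --out plate.csv --seed 17   # alias

# quantify with the streaming peak algorithm (or a classical baseline)
peakfluo quantify --plate plate.csv --layout layout.csv \
    --background-mode mean --persistence 3 --out results.json
peakfluo quantify --plate plate.csv --layout layout.csv --method cy0

# standard-curve R^2 per method, one column per plate
peakfluo compare-methods --plate exp1.csv --plate exp2.csv \
    --layout layout.csv --methods peakfluo,ct

# train/cross-validate the CNN on a directory of NAME.csv + NAME.layout.csv
peakfluo classify-train --plates plates/ --threshold 5 --folds 10 --seed 17
peakfluo classify-predict --model classifier_out/model.npz --plate plate.csv
```

File formats:

- **Plate CSV** (wide): header `cycle,<well_id_1>,...`, one row per cycle,
  6 significant digits.
- **Layout CSV**: `well_id,role,concentration_ng_ml,replicate_group` with
  roles `control` / `standard` / `unknown`; the concentration cell is empty
  for blinded unknowns.
- Configs and result reports are JSON; reports carry the package version and
  a hash of the semantic configuration, and identical config + seed yields
  byte-identical outputs.

## Library example

```python
from peakfluo import SimConfig, simulate_plate, run_peakfluo, triplicate_panel

panel = triplicate_panel(unknowns=(0.3, 3.0))       # control + standards + unknowns
traces = simulate_plate(panel, SimConfig(), seed=17)
result = run_peakfluo(traces, panel)
print(result.curve.r_squared, result.samples["unk1"].estimated_concentration)
```
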