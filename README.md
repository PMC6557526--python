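# dmt1flux

Kinetic models of DMT1 cycling and the mucosal block of intestinal iron
absorption in Caco-2 cells.

When intestinal epithelial cells receive an iron dose, a second dose given
shortly afterwards is absorbed markedly less — the *mucosal block*. A fast
candidate mechanism is the relocation of the apical iron importer DMT1
(Divalent Metal Transporter 1) away from the membrane by endocytosis.
`dmt1flux` implements two phenomenological ordinary-differential-equation
models of this process and everything needed to confront them with uptake
measurements:

* **Switch model** — endocytosis and exocytosis of DMT1 are mutually
  exclusive regimes, toggled with hysteresis when the endocyted fraction
  (threshold `alpha_E`) or the membrane fraction (`alpha_M`) is reached.
* **Swing model** — endocytosis and exocytosis run simultaneously, driven
  by three competitive autocatalytic reactions (a minimal chemical
  oscillator) on the internalized states, damped after repeated challenges
  by a kinetic correction factor ρ that encodes the observed block
  magnitude.

Both models track six DMT1 state fractions `P1..P6`, the apical iron
concentration `FeOUT` and the pooled intracellular + basolateral iron
`FeIN` through sequential 15-min apical iron challenges at 20 μM,
separated by an instantaneous ice-cold wash.

The package provides:

| Module | Contents |
| --- | --- |
| `dmt1flux.model_core` | model equations, parameter sets, cell geometry, ρ factor, hysteresis rule |
| `dmt1flux.simulation` | event-aware integration of challenge protocols, uptake observable |
| `dmt1flux.inference` | Nelder–Mead fitting in log space, jackknife resampling, R², AICc model comparison |
| `dmt1flux.sensitivity` | normalized local sensitivity coefficients (±10%) and influence classes |
| `dmt1flux.synthetic_data` | synthetic replicate uptake datasets, mucosal-block summaries, CSV/XLSX I/O |

## Quickstart

```python
import dmt1flux as dx

geom = dx.default_geometry()          # Caco-2 insert culture geometry
params = dx.default_swing_parameters()  # published kinetic constants
protocol = dx.default_protocol()      # two 15-min challenges at 20 uM

traj = dx.run_protocol("swing", params, geom, protocol, dt=0.1)
first = dx.uptake_series(traj, geom, challenge=1)
second = dx.uptake_series(traj, geom, challenge=2)
```

At the experimental sampling times (3, 6, 9, 12, 15 min) the swing model
predicts first-challenge cumulative uptake of about
`7.09, 7.79, 10.14, 15.73, 16.15` pmol/insert and second-challenge uptake
of about `2.12, 2.49, 5.08, 5.59, 8.54` pmol/insert — the reduction of the
second challenge relative to the first is the mucosal block:

```python
data = dx.generate_uptake_dataset("swing", params, geom, protocol,
                                  noise=dx.NoiseModel(cv=0.0))
block = dx.mucosal_block_summary(data)
block.reduction_pct(3.0)   # ~70% reduction at minute 3
```

Fitting and model comparison on (synthetic or measured) uptake data:

```python
noisy = dx.generate_uptake_dataset("swing", params, geom,
                                   dx.default_protocol(n_challenges=1),
                                   noise=dx.NoiseModel(cv=0.2, seed=7))
fit = dx.jackknife("swing", geom, dx.default_protocol(n_challenges=1),
                   noisy, params)
fit.estimates, fit.ci_halfwidth, fit.mse_jk, fit.r2, fit.aicc_train
```

Sensitivity analysis:

```python
records = dx.sensitivity_table("swing", params, geom)
for r in records:
    print(r.parameter, round(r.r_plus, 4), r.influence)
# k12 has r+ ~ 0.999 (high influence): iron binding to apical DMT1
# controls the predicted uptake almost linearly.
```

## Command-line interface

```bash
dmt1flux simulate --model swing --out run.csv --plot run.png
dmt1flux synth --model swing --cv 0.2 --seed 42 --out data.csv
dmt1flux fit --model swing --data data.csv --out fit_swing.json
dmt1flux fit --model switch --data data.csv --out fit_switch.json
dmt1flux compare --fit-a fit_switch.json --fit-b fit_swing.json
dmt1flux sensitivity --model swing --out sens.csv
```

## Documentation

`docs/methods.md` describes the model equations, parameter conventions,
numerical choices (event handling, tolerances, optimizer restarts) and
known limitations.
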