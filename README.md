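# flapsm

Single-molecule and ensemble FRET/PIFE analysis of flap-DNA dynamics and
flap endonuclease (Fen1) / sliding clamp (PCNA) kinetics.

5′-flap DNA — a duplex carrying an unannealed 5′ single-stranded branch —
is the substrate of Fen1, the structure-specific nuclease of lagging-strand
replication and long-patch base-excision repair, and its turnover is
stimulated by the PCNA sliding clamp. The conformational dynamics of the
free flap, the affinity and geometry of Fen1 and Fen1/PCNA complexes, and
the kinetics of binding and incision are all accessible by fluorescence:
intramolecular FRET between dyes on the two duplex arms reports the
junction geometry, protein-induced fluorescence enhancement (PIFE) of a
Cy3 probe reports clamp proximity, and real-time TIRF injection
experiments resolve binding, cleavage and clamp-departure events on
single immobilized molecules.

`flapsm` re-implements this inference machinery as a tested, reusable
library for experimentalists working with such data:

* **`flapsm.simulate`** — synthetic-data generator: exact (Gillespie)
  two-state telegraph paths, frame-averaged TIRF rendering with shot
  noise, state-dependent donor brightness (PIFE), acceptor blinking and
  single-step photobleaching; real-time injection profiles with
  exponential binding/cleavage waiting times; Hill and tight-binding
  titration curves; censored dwell samples.
* **`flapsm.fretcalc`** — E_app = I_A/(I_A + γI_D), the Förster relation
  R = R₀((1−E)/E)^(1/6), the PIFE quantum-yield correction, and the
  junction kink angle by the law of cosines.
* **`flapsm.ensemble_fit`** — global (shared-parameter) fits of the
  two-state Hill form y = b + a·xⁿ/(Kⁿ + xⁿ), the quadratic
  ligand-depletion isotherm f = ((P+D+K) − √((P+D+K)² − 4PD))/2D,
  monoexponential decays, and the censoring-aware exponential dwell MLE
  (rate = events / total observed time).
* **`flapsm.sm_analysis`** — trace filtering (photobleach truncation,
  blink masking), E_app histograms and Gaussian mixtures,
  donor–acceptor cross-correlation (the telegraph-process decay rate is
  k_forward + k_backward), two-state Gaussian HMMs, and change-point
  detection/classification of binding, cleavage and PIFE-loss events in
  injection traces.
* **`flapsm.structure_av`** — accessible-volume (AV) modelling of mean
  dye positions on atomic structures, for comparing model distances with
  FRET-derived ones.
* **`flapsm.io` / `flapsm.cli`** — TSV/HDF5 trace formats, YAML run
  configs, and the `flapsm` umbrella command line.

## Worked example

Recover a conformational exchange rate from simulated single-molecule
traces, exactly as one would from measured ones:

```python
import numpy as np
from flapsm import TwoStateKinetics, PhotophysicsModel, simulate_state_path, render_trace
from flapsm.sm_analysis import cross_correlate, fit_correlation

# flap switching between bent (E ~ 0.37) and extended (E ~ 0.6) conformers
kin = TwoStateKinetics(k_forward=7.9, k_backward=3.4, E_state1=0.37, E_state2=0.6)
phys = PhotophysicsModel(total_brightness=300, background_donor=10, background_acceptor=10)

rng = np.random.default_rng(0)
traces = []
for _ in range(15):
    path = simulate_state_path(kin, duration=60.0, seed=rng)
    traces.append(render_trace(path, kin, phys, frame_time=0.016, seed=rng))

curve = cross_correlate(traces, max_lag=1.0)
fit = fit_correlation(curve)
print(f"exchange rate: {fit.params['rate']:.1f} +/- {fit.stderr['rate']:.1f} s^-1")
```

```
exchange rate: 11.1 +/- 0.1 s^-1
```

The donor–acceptor cross-correlation of a two-state telegraph process
decays as exp(−(k_f + k_b)τ); the fitted 11.1 s⁻¹ recovers the simulated
summed rate of 11.3 s⁻¹ even though the 16 ms frames undersample the
dynamics.

The same pattern runs the full injection pipeline — simulate reaction
profiles, detect the binding/cleavage change-points, fit censored
exponentials:

```python
from flapsm.simulate import InjectionScheme
from flapsm.pipelines import injection_binding_rate

scheme = InjectionScheme(t_injection=15.0, k_bind=0.023, k_cleave=0.040,
                         E_unbound=0.6, E_bound=0.3, pife_bound=2.0)
res = injection_binding_rate(scheme, phys2, n_traces=100,
                             duration=600.0, frame_time=0.2, seed=0)
```

which prints (with `phys2` the 500-counts/frame camera model)

```
binding rate: 0.0273 +/- 0.0028 s^-1, cleavage rate: 0.0355 +/- 0.0036 s^-1 (96/100 molecules bound)
```

— the pseudo-first-order binding rate and the lumped
catalysis-plus-product-release rate with their standard errors, from 100
molecules. At the 300-molecule scale of a real dataset the estimates
tighten to a few percent.

## Command line

```sh
flapsm simulate traces|injection|titration|dwells --config cfg.yaml --seed 1 --out ...
flapsm calc efficiency|distance|kink ...
flapsm fit hill|binding|exp --data curves.csv ...
flapsm analyze filter|hist|xcorr|hmm|events|titrate ...
flapsm av --pdb model.pdb --atom "C1'" --linker 20 ...
flapsm run --config experiment.yaml --seed 1 --out results/
```

See `docs/methods.md` for the models, defaults and their rationale.
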