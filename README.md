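# clockarch

Why do real circadian clocks use *two* coupled transcriptional feedback
loops when a single negative feedback loop already oscillates? `clockarch`
is a simulation and analysis toolkit for comparing competing clock
architectures on two functional criteria: **robustness** of the circadian
oscillation to uncertainty in every kinetic parameter, and **entrainment**
to light–dark cycles.

It implements four competing ODE architectures over clock genes *X* and
*Y* (concentrations in nM, time in hours, transcription repressed with
Hill cooperativity h = 4):

| model | loops | output |
|---|---|---|
| `single` | X represses itself (m = 3 equations) | X(nuc) |
| `semi_dual` | X:Y heterodimer represses *X*; *Y* constitutive (m = 6) | X:Y(nuc) |
| `dual` | X:Y represses both *X* and *Y* (m = 6) | X:Y(nuc) |
| `redundant` | two independent single loops (m = 6) | X(nuc) + Y(nuc) |

and the analysis machinery around them:

* **Two-phase search (TPS)** — log-uniform random sampling of all kinetic
  parameters within 0.1–10 fold of the reference values, seeding a genetic
  algorithm that harvests every parameter set whose output oscillates with
  period 23–25 h and amplitude 2–6 nM.
* **Kinetic symmetry ρ** — for the two-loop dual/redundant models, each
  Y-loop parameter is searched inside the band `[x/(1+ρ), x·(1+ρ)]` around
  its X-loop counterpart: ρ = 0 forces identical loops, ρ ≥ 99 leaves them
  independent.
* **QMPS (quasi-multiparameter sensitivity)** — for a target q (period or
  amplitude), `QMPS = Σᵢ sᵢ²` with
  `sᵢ = ((q(pᵢ(1+Δ)) − q(p))/q(p))/Δ`, Δ = 0.001. Lower QMPS = more
  robust. Ensembles are compared by the cumulative frequency of their QMPS
  values and its median.
* **Loop balance γ** — `γ = mean[X(nuc)] / (mean[X(nuc)] + mean[Y(nuc)])`
  over the post-transient window; 0.5 means equally contributing loops.
* **Entrainment maps** — light multiplies the clock-protein degradation
  rate D2 (and the X:Y complex rate where it exists) by a factor δ during
  the light half of an LD cycle of period ζ; a parameter set is entrained
  when its forced cycles are constant (period deviation < 1%, amplitude
  < 10%) with period equal to ζ within 1%. The entrainment probability at
  each (ζ, δ) is the exact fraction of archive sets that entrain there.

## Worked example

Harvest ten single-model circadian parameter sets and measure their
robustness:

```sh
clockarch tps --model single --n 10 --trials 250 --population 40 \
    --generations 80 --seed 1 --out single.json
clockarch qmps --archive single.json --target period --out single_qmps.csv
```

which prints

```
archived 10 solutions -> single.json
QMPS(period): n=10, median=1.7, excluded=0
```

Every archived set oscillates inside the 23–25 h / 2–6 nM windows; the
median QMPS of the period, 1.7, is the robustness score of the
single-loop ensemble (the square sum of ~16 relative sensitivities — a
few parameters dominate). Repeating with `--model dual --rho 0` yields a
clearly smaller median: the kinetically symmetric dual feedback loop is
the more robust oscillator. The same archives feed the entrainment map:

```sh
clockarch entrain --archive single.json --zeta 16:32:9 --delta 1.1:11:7 \
    --out map.csv
```

The high-probability region sits at ζ ≈ 24 h for weak light and shrinks
as δ grows (strong light drives irregular oscillations).

Python API equivalent:

```python
import clockarch as ca

cfg = ca.SearchConfig(architecture="dual", rho=0.0, n_solutions=10,
                      random_phase_trials=250, population_size=40,
                      max_generations=80, seed=1)
archive = ca.run_tps(cfg)
table = ca.archive_qmps(archive)
print(ca.median_from_cf(table.values("period")))
```

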