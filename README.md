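# rwddm

A simulator for the **Rescorla–Wagner drift-diffusion model (RWDDM)** of
classical conditioning and interval timing, for researchers in associative
learning and timing who want to run the model on standard conditioning
protocols (acquisition/extinction, blocking, conditioned inhibition,
fixed/variable/mixed-interval schedules, peak procedures) and reduce the
output to the measures reported in the animal literature.

## The model

Each conditioned stimulus CS*i* owns three coupled pieces of state:

1. **A drift-diffusion timer.** An accumulator Ψ*i* starts at CS onset and
   steps every Δt as

   ΔΨ*i* = *A<sub>i</sub>*·Δt + *m*·√(*A<sub>i</sub>*·Δt)·N(0,1),

   with no ceiling. An interval is "remembered" as the slope *A<sub>i</sub>*
   that brings Ψ to a fixed threshold θ at the target time *t*\*: the slope
   is corrected once per timed occurrence by gradient descent,

   Δ*A<sub>i</sub>* = α<sub>t</sub>·*A<sub>i</sub>*·(θ − Ψ*i*(*t*\*)) / Ψ*i*(*t*\*),

   whose fixed point is *A* = θ/*t*\*. With θ = 1, 1/*A* stores an
   exponential moving **harmonic** average of the experienced intervals.
   The √(*A*Δt) diffusion noise makes first-crossing times inverse-Gaussian
   with CV = *m*/√θ — constant across durations, i.e. timescale invariant.

2. **A time-adaptive representation.** *x<sub>i</sub>* =
   exp(−(Ψ*i* − θ)² / 2σ²): a Gaussian receptive field over accumulator
   values that peaks exactly when the timer reaches the remembered time.

3. **A Rescorla–Wagner associative link** with a time-set asymptote.
   At US delivery (or CS offset when no US arrives),

   Δ*V<sub>i</sub>* = α<sub>V</sub>·(λ*i* − Σ*j* *V<sub>j</sub>x<sub>j</sub>*)·*x<sub>i</sub>*,  λ*i* = *H·A<sub>i</sub>* / Ψ*i*(*t*\*),

   which spreads the reinforcer's motivational value *H* hyperbolically
   over the signalled delay (λ ≈ *H*/*t*\*) and keeps the summed-prediction
   competition that yields blocking and conditioned inhibition.

The conditioned response is read out continuously as CR(*t*) =
*V·x*(Ψ(*t*)) (floored at 0). Timing and association have **independent**
update rules, which is what buys faster reacquisition, re-timing during
extinction, and timing learned by mere preexposure. Optional extensions:
a Pearce–Hall adaptive learning rate (latent inhibition) and a slowly
narrowing Gaussian width.

## Worked example

Ten classic experiment presets ship with the package (`rwddm list-designs`
shows the catalogue). The interstimulus-interval effect, for instance:

```python
from rwddm import build_design, run_experiment
from rwddm.analysis import average_curve, peak_time

design = build_design("isi_effect")          # FI 5 / 10 / 20 s, 150 trials each
result = run_experiment(design, seed=1)
for name in ("FI5", "FI10", "FI20"):
    curve = average_curve(result[name], last_n=50)
    print(f"{name}: peak height {curve.values.max():.3f} at {peak_time(curve):.2f} s")
```

prints

```
FI5: peak height 0.991 at 4.51 s
FI10: peak height 0.489 at 9.51 s
FI20: peak height 0.253 at 19.51 s
```

Response peaks sit just before each reinforcement time and their heights
fall roughly as 1/FI — the asymptote of learning is set by the remembered
reinforcement delay (V<sub>∞</sub> ≈ *H·A*<sub>∞</sub> = *H*/FI, here with
H = 5). Normalizing each curve by its peak and its FI superimposes them
(`analysis.superimposition_rmse` quantifies this), the timescale-invariance
signature.

The same machinery runs from the shell:

```
rwddm run --design isi_effect --seed 1 --out out/isi
rwddm run --design vi_vs_fi --seed 1 --record peak --out out/vi
```

writing tidy per-trial CSV traces (slope *A*, strength *V*, Ψ(*t*\*), per-step
CR on request) plus a JSON metadata record with the seed and config hash.

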