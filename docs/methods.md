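# Methods

## Model

The package simulates a real-time hybrid of Rescorla–Wagner associative
learning and drift-diffusion interval timing. Per conditioned stimulus
(CS) the state is a timer slope *A*, a Gaussian representation width σ and
an associative strength *V*; the unconditioned stimulus (US) contributes a
motivational magnitude *H*.

Within a trial, every present CS's accumulator is stepped each Δt:

    ΔΨ = A·Δt + m·√(A·Δt)·N(0,1)

and the conditioned response is emitted continuously as
CR(t) = V·x(Ψ(t)), x(Ψ) = exp(−(Ψ−θ)²/2σ²), floored at zero for reporting
(strengths themselves may be negative — conditioned inhibition).

At the end of a trial — US delivery on reinforced trials, CS offset on
non-reinforced ("extinction") trials — two independent updates fire:

* association: ΔV_i = α_V (λ_i − Σ_j V_j x_j) x_i with λ_i = H·A_i/Ψ_i(t*)
  (H = 0 encodes US absence, so extinction is λ = 0);
* timing: ΔA_i = α_t A_i (θ − Ψ_i(t*)) / Ψ_i(t*).

Peak trials (long non-reinforced probes) receive **neither** update: the
timing rule because infrequent probes should not re-time the CS, and the
associative rule because applying λ = 0 on hundreds of probes would
extinguish V and make probe-based tests (e.g. the conditioned-inhibition
summation test) meaningless. Probes are read-outs only.

### Noise form

A literal reading of the increment rule would scale the noise as
m·A·Δt·N(0,1). Only the diffusion scaling m·√(A·Δt) produces the
closed-form coefficient of variation CV = m/√θ for first-crossing times
(inverse-Gaussian first-passage), hence timescale invariance, which is the
point of the timer; it is therefore the default. The linear form is kept
behind `noise_form="linear"` for sensitivity checks.

### Units

Internal time is milliseconds with Δt = 10 ms; slopes are per ms. The
associative asymptote uses the slope in s⁻¹ (λ = H·A[s⁻¹]/Ψ), so that
H = 5 with a converged 5-s timer gives λ = V∞ ≈ 1. Protocol definitions
and all analysis outputs are in seconds.

### Degenerate early trials

A novel stimulus starts at A(1) = 10⁻⁶/ms — low enough to overestimate
any experimental duration. With diffusion noise this makes Ψ(t*) on the
first few trials a near-zero-mean random variable: it can reach zero, and
tiny positive values would make λ and the slope correction explode.
Two regularizations handle this: accumulator paths are reflected at zero
(a pulse count cannot be negative), and the Ψ(t*) entering the end-of-trial
updates is floored at `psi_update_floor`·θ (default 0.01). The floor caps
the per-trial slope growth at a factor 1 + 99·α_t and caps λ at 100·H·A;
it is inert once the timer is tuned (Ψ(t*) ≈ θ). Both behaviours are
confined to the first handful of trials of a novel CS.

## Parameters

| name | meaning | default / typical | units |
|---|---|---|---|
| m | accumulator noise factor | 0.15–0.25 | — |
| θ | crossing threshold | 1 | — |
| σ | representation width | 0.18–0.425 | accumulator units |
| α_t | timing adaptation rate | 0.08–0.75 | per interval occurrence |
| α_V | associative learning rate | 0.06–0.1 | per trial |
| H | US motivational magnitude | 4–40 | sets λ = H/t* (t* in s) |
| Δt | simulation step | 10 | ms |
| A(1) | novel-stimulus slope | 10⁻⁶ | ms⁻¹ |

Each experiment preset carries the parameter set used for the
corresponding published simulation; overrides are accepted everywhere.

Optional per-design flags:

* **Pearce–Hall rate** (latent inhibition only): α_V becomes per-CS state,
  α_V(n+1) = α_V(n) + γ(|δ| − α_V(n)) with δ = λ − V·x, initial value 0.4
  for a novel CS, γ = 0.03. Preexposure (δ = 0) decays the rate toward
  zero, producing the slower initial acquisition of a preexposed CS.
* **Adaptive width** (latent inhibition only): σ(n+1) = σ(n) +
  α_σ(0.35 − σ(n)), σ(1) = 0.6, α_σ = 0.025 — the representation sharpens
  with exposure.
* A **leaky-integrator trace** (x += (I − x)/τ) is provided as the
  early-training representation variant; no preset switches to it
  automatically because no principled switching rule exists — it is
  config-only.

## Compound stimuli

Three policies, selected per design:

* `sum` (default): CR is the summing-junction output Σ V_j x_j; each
  present CS updates with its own λ against the shared prediction. Used by
  blocking and conditioned inhibition; inhibitors time US *omission*
  exactly as excitors time the US (update at compound offset with H = 0).
* `faster_timer`: on simultaneous compounds responding is guided solely by
  the CS whose timer currently has the larger slope (ties: lexicographic
  label order, for reproducibility). This converts trial-to-trial slope
  noise into the left-shifted compound response curve of disinhibition of
  delay and the compound peak procedure. On reinforced compound trials
  each timer still updates from its **own** Ψ(t*).
* `average`: the compound is treated as a single representation with
  A = A_low/2 + A_high/2 and V = (V_low + V_high)/2 — harmonic averaging
  of the remembered intervals (temporal averaging). A strength-weighted
  variant (weights V_low/(V_low+V_high), …) is available.

A CS may own several timer/representation units (mixed-interval
schedules declare 2). At every instant behaviour is guided by the unit
with the highest activation; at reinforcement only the maximally active
unit is credited with both updates.

## Protocol generator

The ten presets encode the simulated designs (trial counts, durations,
US times, phase order) with their published parameter sets. Trials are
concatenated events: intertrial intervals are not simulated and the
context is not timed. Mixed phases shuffle their trial blocks with the
run's seeded generator; the variable-interval preset samples integer
durations from U{15..45} s with 135-s probes interleaved (375 probes per
1500 reinforced trials ≈ probability 0.25). Two deliberate deviations
from the tabulated designs: the compound-peak phase also interleaves
50 + 50 single-CS probes (the published peak-time comparison requires
single-CS probe curves), and the extinction-duration-change experiment
gains an unchanged 20→20 s control group (required by the first-window
extinction-rate comparison). The latent-inhibition conditioning phase is
250 trials (the running-text value; the design table prints 120).

What the generator does **not** emulate about real data: no intertrial or
context timing, no response packets or baseline responding, no
motivational drift, no generalisation between CSs, deterministic trial
counts. Passing tests therefore show that the *model mechanisms* produce
the published patterns under the published designs — not that the model
fits animal data.

## Analysis conventions

* Averaged response curves are pointwise means of per-step CR across
  selected trials of equal duration.
* Peak times: moving-average smoothing (window 1 s, exposed) before the
  argmax; ties resolve to the earliest time.
* Superimposition is quantified as RMSE between two peak-normalized,
  time-normalized curves interpolated onto a common 100-point grid; the
  0.05 acceptance threshold is package-defined (the literature says only
  "roughly superimpose").
* The first-window extinction measure sums CR over the first 10 s of each
  trial, averages adjacent trials pairwise (an odd final trial is
  dropped) and divides by 100.
* `empirical_cv` uses the population SD (ddof = 0).
* Trials-to-criterion: first trial with V ≥ criterion × asymptote, the
  asymptote defaulting to the mean of the final 10 trials.

## Randomness and sizes

A single seed drives everything: group g of a design runs on child seed
(seed·1000003 + 7919·(g+1)) mod 2³¹, replications likewise; one normal
draw per timer per step, in deterministic order. Problem sizes follow the
published designs throughout (e.g. 15 replications of the full 900-trial
compound-peak run; 1875-trial variable-interval sessions); the
Monte-Carlo check of the crossing-time CV uses 10,000 first passages at
1000 steps per mean crossing with linearly interpolated crossing times,
at each of 1, 5 and 50 s.

## Known limitations

* **Plateau bias.** Because Ψ(t*) enters both updates in the denominator,
  E[1/Ψ] > 1/E[Ψ] biases the converged slope ~2–4% above θ/t* and the
  V plateau ~10% above the H·A∞ arithmetic (at m = 0.15). These are
  properties of the update rules, not of the implementation.
* **Trial-averaged peak location.** Averaged probe curves peak near the
  *mode* of the skewed (inverse-Gaussian) crossing distribution, i.e.
  ~4–6% earlier than the remembered interval at m = 0.2–0.25. The
  variable-interval probe curve therefore peaks near 25 s — left of the
  27.1-s harmonic-average reference, and well left of the arithmetic mean.
* **Unequal-duration compounds are unstable.** Co-terminating CSs of
  different durations signal different λ, an inconsistent steady-state
  system: with prolonged compound training the V values diverge linearly
  (the blocked/control strength ratio settles near the model's own
  H(A_X−A_A) asymptote, about 1/3, rather than near zero). The model's
  blocking account is qualitative beyond the first trials.
* **Latent inhibition is transient.** At the published parameters the
  preexposed CS's acquisition deficit lasts ~20 trials, after which its
  pre-tuned timer and pre-narrowed width let it marginally overtake the
  still-adapting control before both converge.
* The Gaussian representation cannot express improved pre-US timing early
  in training (curves are sigmoidal from trial 1); the leaky-trace
  variant exists for this reason but has no switching rule.
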