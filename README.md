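# dona — single-trial neural interaction analysis

`dona` estimates **time-resolved interactions between simultaneously
recorded neurons within single trials**.  Trial-averaged correlograms hide
the moment-to-moment variability of neural coordination; this package
combines a latent dynamical model of the slow, shared population activity
with correlogram-derived transient corrections to ask, for every neuron,
trial and ~67 ms time bin: *how strongly did the rest of the population (or
one specific reference neuron) shape this neuron's spiking right now?*

It is aimed at systems neuroscientists analyzing spike-sorted population
recordings from epoch-structured behavioral tasks (e.g. sample / delay /
response designs in rodent or primate cortex).

## The method

1. **Shared neural activity (SNA).**  Binned spike counts are modeled with
   an epoch-switched linear dynamical system

   `x_T = A(s) x_{T-1} + w_T`,  `y_T = V(s) x_T + r_0 + v_T`,

   where the latent state `x` is low-dimensional, `s` is the behavioral
   epoch of bin `T` (parameters switch at the cued boundaries, the state is
   continuous across them), and `y = counts/S_bin`.  EM with a Kalman
   smoother yields per-trial rate estimates `r_i^T` (the SNA),
   with `S_bin = 67.4 ms`.

2. **Correlograms.**  For each ordered pair (reference `j`, target `i`) the
   spike-based CCG `C_ij(kτ)` is the trial-averaged per-reference-spike
   rate of target spikes in lag windows of width `τ = 25 ms`; the ECCG
   `C^E_ij(kτ)` is the same construction applied to the SNA instead of the
   target's spikes.  Their difference (DCCG) isolates transient pairwise
   effects from the shared slow dynamics.

3. **Transient SNA and optimized neural activity.**  Within each bin, on a
   fine grid `δt = S_bin/60`, the SNA is modulated by the population's
   spikes through locally estimated (20-bin × 20-trial windows) CCG/ECCG
   weights and renormalized to preserve the bin mean (TSNA).  The ONA is
   the mixture `α* · TSNA + (1−α*) · SNA`, with `α* = 1/(1+e^{−Q*})` and
   `Q*` maximizing the per-bin likelihood of the target's observed spikes.

4. **Interaction measures.**  `DONA` is the Kullback–Leibler divergence
   between the ONA- and SNA-implied per-step firing probabilities of a bin
   (ensemble interaction strength, nats).  `PDONA` is the KL divergence
   between the pattern distributions of the target firing in the step after
   each of the `n = 6` reference spikes nearest the bin, under ONA- vs
   SNA-derived rates (directed pairwise strength).

5. **Statistics.**  Neurons/pairs are classified by the epoch in which
   their interaction is largest (Wilcoxon rank-sum on the 20 bins per
   epoch), proportions are compared by χ² tests, behavioral choice is
   decoded by logistic regression with and without the interaction term
   (AIC comparison), and a normalized across-trial count-correlation
   (NCC, `ρ_i = sqrt(Σ_{j≠i} ρ_ij²/(N−1))`) serves as the conventional
   baseline.

A full ground-truth simulator (latent-driven rates, epoch-gated
multiplicative couplings on a 25 ms kernel, Bernoulli thinning on the fine
grid) makes every stage testable against known couplings.

## Worked example

Simulate a population with one known coupling (neuron 0 doubles neuron 4's
rate for 25 ms after each of its spikes, response epoch only), run the full
chain, and read off the interaction measures:

```python
from dona import (Coupling, SessionConfig, bin_spikes, compute_divergences,
                  compute_ona, estimate_sna, fit_edlds, generate_session)
from dona.edlds import FitConfig

session, truth = generate_session(
    SessionConfig(n_neurons=8, n_trials=60, n_latent=2,
                  couplings=(Coupling(ref=0, target=4, gain=3.0,
                                      epochs=("response",)),)),
    seed=3)
counts = bin_spikes(session)
params = fit_edlds(counts, n_latent=2, config=FitConfig(max_iter=40))
sna = estimate_sna(params, counts)
ona = compute_ona(session, sna)
series = compute_divergences(session, ona)
```

Running `python examples/04_single_trial_interactions.py` (the same
computation) prints:

```
mean mixture weight alpha*: 0.18 (0 = pure shared estimate, 1 = pure transient estimate)
target DONA in sample  : 0.0095 nats
target DONA in delay   : 0.0075 nats
target DONA in response: 0.0170 nats
PDONA 0->4 (coupled) in response : 0.00220 nats
PDONA 1->4 (uncoupled) in response: 0.00044 nats
```

The coupled target's ensemble interaction (DONA) roughly doubles in the
epoch where the coupling is active, and the coupled reference's directed
PDONA onto it is ~5× that of an uncoupled reference — the pipeline
rediscovers the injected interaction, localized to the correct epoch.

The other scripts in `examples/` walk through each capability separately
(simulation, latent-model fitting, correlograms, classification/decoding),
and the `dona` command line (`dona simulate`, `dona run-all --preset
recovery --out out/`) runs the same stages from a shell with a YAML config.

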