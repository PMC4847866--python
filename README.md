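# hrssm — home-range state-space modelling for passive acoustic telemetry

Arrays of omnidirectional acoustic receivers are the workhorse of coastal
fish tracking: a tagged fish pings once a minute, and each receiver either
hears the ping or not, with a probability that decays with distance.  The
raw data — counts of detections per receiver per time window — only
indirectly reflect where the fish was.  `hrssm` estimates home-range
behaviour from such data with a Bayesian state-space model, and ships the
simulation machinery to validate the whole pipeline end to end.

## Model

**Process model.**  Movement inside a stable home range is a biased random
walk: diffusion plus a linear restoring force toward an attraction center
*r*<sub>H</sub> — a bivariate Ornstein–Uhlenbeck process.  Over a time-step
Δt the exact discrete transition is

    r[n+1] = r_H + exp(−k Δt) (r[n] − r_H) + R[n],
    R[n] ~ N(0, σ²I),   σ² = ε (1 − e^(−2kΔt)) / (2k),

with exploration rate *k* (min⁻¹) and noise intensity ε (m²/min).  At
stationarity the fish is found 95% of the time inside a disc of radius

    radius = sqrt(−ε ln(0.05) / k),

the home-range radius.  Activity is diurnal: the animal moves during 14
daylight hours and holds position overnight.

**Observation model.**  A ping emitted at distance *d* from receiver *j* is
detected with probability `invlogit(α_day + β_day · d)`; the daily (α, β)
pair is estimated from a moored control tag by a binomial GLM
(`calibrate_control_tag`).  Counts pooled over a time-step are modelled as
Binomial(pings per step, detection probability at the latent position).

**Inference.**  Metropolis-within-Gibbs MCMC over (center, *k*, radius) and
the latent per-step positions (ε is derived from *k* and radius per draw);
3 chains, burn-in, thinning, and the Gelman–Rubin statistic (R̂ < 1.1) as
the convergence gate.  Priors default to nearly flat: *k* ~ U(0, 1),
radius ~ N(0, 10⁴ m) truncated at zero, center ~ N(0, 10⁶ m).

## Worked example

```python
import hrssm as H

# simulate a slow-exploring fish (k = 0.001/min, 245-m home range) tracked
# for 3 days on a 5x5 receiver grid at 300-m spacing, pooled at 15 min
cfg = H.SimulationConfig.canonical(1, step_minutes=15, days=3)
traj, calib, tensor, data = H.simulate_dataset(cfg, seed=11)
print(data.counts.shape)            # (168, 25) steps x receivers

res = H.fit_ssm(data, cfg.array, calib, config=H.MCMCConfig.scaled_down(seed=5))
print(res.summary().round(4))
```

Output (truth: center (0, 0), k = 0.001, radius = 245 m, ε = 20.04 m²/min):

```
              mean    median    bci_2.5   bci_97.5    rhat
parameter
center_x  -65.0205    9.6345 -1672.5113   609.3896  1.0292
center_y  -59.9727  -80.3355  -564.4585   749.5947  1.0088
k           0.0007    0.0006     0.0000     0.0024  1.0075
radius    612.9322  320.7849   162.9838  3623.3941  1.0263
epsilon    20.1659   19.5650    13.0749    30.0966  1.0237
```

Every 95% credibility interval brackets its true value.  ε — the product
radius²·k up to a constant — is far better identified than *k* or radius
separately on a 3-day series: a slow fish barely traverses its range in
three days, so the data pin down the diffusion intensity but not how it
factors into speed versus extent.  Longer tracks tighten *k* and radius
individually.

The same workflow is scriptable from the shell (`hrssm simulate`, `hrssm
calibrate`, `hrssm fit`, `hrssm experiment`, `hrssm summarize`); every run
writes a manifest with seeds and input hashes.

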