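# embc

Unsupervised behavioural annotation of animal movement trajectories by
**expectation-maximization binary clustering** (EMbC), with the classic
unconstrained EM clustering (EMC) baseline, a synthetic-trajectory
simulator, posterior-margin label smoothing, robustness experiments and
evaluation metrics.

## The problem and the model

Movement ecologists need to split GPS/Argos tracks into semantically
interpretable behavioural modes (resting, intensive search, travelling,
extensive search) without per-species supervision.  Plain Gaussian-mixture
EM finds statistically sound clusters that are often impossible to read in
behavioural terms.  EMbC constrains the mixture instead of the analyst:
with m input variables the model has at most k = 2^m components, one per
combination of Low/High values, and a set of m·2^(m−1) *delimiters* — per
variable, one splitting value for every L/H context of the other
variables.  At each EM iteration the delimiters are placed at the
empirical equiprobability frontier between adjacent clusters (the
projected data point where |w_a − w_b| is minimal), and each component
mean is estimated only from the points inside its binary region, so the
LL cluster stays low-low, HH stays high-high, and the labelling reads
directly as behaviour.  Per-point reliability weights u_i ∈ [0, 1]
(default: min(1, τ̃/τ_i) from the sampling-interval distribution)
down-weight poorly estimated values in the parameter updates.  Covariances
stay unbounded, variances are floored at a per-variable resolution σ_min
(0.01 m/s for velocity, 0.087 rad for turns).

See `docs/methods.md` for the full model, iteration, initialization,
cycle handling and design rationale.

## Worked example

```python
import embc

# a labelled synthetic track: 400 points, 4 behavioural modes,
# Markov state sequence, overlap gamma = 0.1
ds = embc.simulate(embc.SyntheticConfig(n=400, gamma=0.1, seed=7))

res = embc.fit(ds.features)          # deterministic, no random state
print(res.status, res.n_active)      # converged 4
print(res.delimiters)                # {'.L': 0.496, '.H': 0.468,
                                     #  'L.': 0.477, 'H.': 0.492}
print(embc.f_score(ds.state_labels, res.labels, labels=ds.codes))
# 0.9625
```

The fit converges in 14 iterations with all four clusters active; the
recovered means sit at the generating corners (e.g. LL at (0.248, 0.243),
HH at (0.714, 0.748)) and the delimiters near 0.5, the true partition of
the unit square.  The F-measure of 0.96 against the ground-truth states is
at the Bayes ceiling of this overlap level — with γ = 0.1 about 4% of
points fall on the wrong side of the optimal partition by construction.

Real tracks go through the same pipeline from a Movebank-style CSV:

```python
traj = embc.read_trajectory_csv("track.csv")     # timestamp, location-long, location-lat
fm = embc.compute_velocity_turn(traj)            # + interval-based reliability
res = embc.fit(fm)
labels = embc.smooth_labels(res.labels, res.W, res.codes,
                            embc.SmoothConfig(delta_w=0.2))
```

or through the CLI, including KML/GeoJSON export and burst segmentation:

```sh
embc annotate track.csv --out track.kml --format kml --mode burst --delta-w 0.2
embc simulate --n 400 --gamma 0.05 --seed 7 --out synth.csv
embc benchmark --ns 50,100,200 --gammas 0.1 --reps 20 --out bench.csv
embc robustness --kind jitter --factors 0:0.1:0.02 --reps 10 --out rob.csv
```

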