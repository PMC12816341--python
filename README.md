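# bim — coupling and causality in bivariate time series

`bim` quantifies how two simultaneously recorded, stationary time series
interact: how strongly they are coupled overall, in which direction
information flows, at which time scales (frequencies) the interaction
lives, and whether any of it is statistically significant.  Typical users
are physiologists relating heart period to systolic pressure
(baroreflex), climate scientists relating pressure and sea-surface
temperature indices, or anyone inferring pairwise links in a dynamic
network from time-resolved data.

## The measures

For two jointly stationary processes $Y_1, Y_2$, a bivariate VAR(p)
("full" model) describes each present value from $p$ past values of both
processes, with innovation covariance $\Sigma_U$; a "restricted" AR model
describes each process from its own past only, with innovation variance
$\lambda_i^2$.  Geweke's log-ratio measures follow:

- total dependence $F_{1;2}=\ln\frac{\lambda_1^2\lambda_2^2}{|\Sigma_U|}$
- Granger causality $F_{1\to2}=\ln\frac{\lambda_2^2}{\sigma_{2}^2}$ (and
  symmetrically $F_{2\to1}$)
- instantaneous causality
  $F_{1\cdot2}=\ln\frac{\sigma_1^2\sigma_2^2}{|\Sigma_U|}$

with the exact decomposition $F_{1;2}=F_{1\to2}+F_{2\to1}+F_{1\cdot2}$.
For jointly Gaussian processes each $F$ is twice an information measure
(nats): mutual information rate $I_{1;2}$, transfer entropies
$T_{1\to2}, T_{2\to1}$, instantaneous transfer $I_{1\cdot2}$.

In the frequency domain, the transfer matrix
$H(\bar f)=[I-\sum_k A_k e^{-j2\pi\bar f k}]^{-1}$ factorizes the
spectral matrix $P=H\Sigma_U H^*$, from which the package computes the
squared coherence, the directed coherence, and the Geweke spectral
profiles $f_{1;2}, f_{1\to2}, f_{2\to1}, f_{1\cdot2}$.  Each profile
satisfies the spectral integration property
$F = 2\int_0^{1/2} f(\bar f)\,d\bar f$, so integrating over a band (e.g.
LF 0.04–0.15 Hz, HF 0.15–0.4 Hz) yields band-specific information
measures.

The same information measures are also estimated model-free, by a
shared-radius k-nearest-neighbour estimator, by uniform amplitude
binning, and by ordinal (permutation) patterns — useful when linearity or
Gaussianity is in doubt.  Significance of any measure is assessed with
random time-shift surrogates, which destroy the coupling while preserving
each series' own dynamics.

## Worked example

Simulate two coupled stochastic oscillators (process 1 drives process 2
with gain 0.6 at lag 1) and analyse the realization:

```python
import bim

spec = bim.benchmark_physio(coupling_12=0.6, L=2000, seed=7)
pair = bim.simulate_arx(spec)
res = bim.BivariateInteractionModel.from_pair(pair).fit(
    max_order=8, bands=[(0.04, 0.15), (0.15, 0.4)])
print(res.summary())
```

```
Bivariate interaction analysis (linear parametric)
====================================================
series: y1, y2   L = 2000   fs = 1.0
VAR order p = 2   restriction = yw   stable = True
innovation covariance |Sigma_U| = 1.0017
----------------------------------------------------
measure                     F (log-ratio)   I (nats)
total dependence                   0.6404     0.3202
GC y1 -> y2                        0.6378     0.3189
GC y2 -> y1                        0.0012     0.0006
instantaneous                      0.0013     0.0007
band 0.04-0.15 Hz: I_mir=0.1998 T_12=0.2003 T_21=-0.0001 I_it=-0.0004
band 0.15-0.4 Hz: I_mir=0.0555 T_12=0.0519 T_21=0.0006 I_it=0.0030
```

The analysis recovers the one-way coupling: the transfer entropy
estimate $T_{1\to2}=0.3189$ nats is close to the population value 0.3221
computed analytically from the generating model
(`bim.population_measures(spec.model)`), while the reverse direction and
the instantaneous term are near zero.  Most of the directed information
sits in the LF band, where the driving oscillator lives.  A surrogate
test confirms significance:

```python
t = res.test_significance(which="T_12", n_s=100, seed=0)
# T_12 = 0.3189, surrogate threshold = 0.0024, significant = True
```

A command-line interface mirrors this workflow:

```sh
bim simulate --c12 0.6 --length 2000 --seed 7 --out pair.csv
bim analyze --input pair.csv --fs 1 --bands 0.04:0.15,0.15:0.4 \
    --surrogates 100 --seed 1 --out results/
```

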