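# metsizer

Analysis-based sample-size estimation for two-group metabolomic (and other
high-dimensional omics) experiments, with false-discovery-rate control.

## The problem

When planning an NMR or targeted-MS metabolomics experiment that will
compare two groups across hundreds of spectral bins or metabolites,
classical power calculations do not apply: the variables are many,
correlated, and unequal in variance, and experimental pilot data are
rarely available. `metsizer` answers the design question *"how many samples
do I need so that a moderated-t screen of all bins achieves a target false
discovery rate?"* — and it does so by simulating pseudo-pilot data from the
very model the analyst intends to fit afterwards (probabilistic PCA and its
relatives), so the answer reflects the planned analysis.

## The method

For a candidate total sample size `n` (balanced groups `n/2 + n/2`):

1. **Simulate pilot data** `X (n x p)` from the intended analysis model
   `x_i = W u_i + mu + eps_i`, `eps_i ~ N_p(0, sigma2 I)`:
   - **PPCA**: `u_i ~ N_q(0, I)`;
   - **PPCCA**: `u_i ~ N_q(B c_i, I)` with per-sample covariates `c_i`;
   - **DPPCA** (longitudinal designs, first time point): each latent
     dimension has variance `exp(h_l)` with `h_l` drawn from the
     stationary law of a stochastic-volatility process.

   Without pilot data, `(W, sigma2, ...)` are drawn from priors (loadings
   rows `N_q(0, I)`, `sigma2 ~ InvGamma(3, 4)`) fresh for every
   simulation; with pilot data, the model is fitted once (closed-form PPCA
   MLE or PPCCA EM) and the estimates are held fixed.
2. **Permutation null**: for `T = 20` random relabelings compute the
   moderated statistic per bin, `TS_j = (xbar_j1 - xbar_j2)/(S_j + cf)`,
   where `S_j` is the pooled standard error and `cf` (the 5th percentile
   of all `S_j`) guards near-zero-intensity bins.
3. **Spike** a random `p0 = m*p` of the statistics with an effect of
   `delta = 2.3` within-group standard deviations, calibrated at the
   design's baseline sample size; these play the role of truly
   significant bins.
4. **Score**: declare bins whose `|TS|` strictly exceed the `p0`-th
   largest value and record the false discovery rate among them; reduce
   `T` permutations to their median, repeat over `SIM = 20` simulations,
   and keep the 10th/50th/90th FDR percentiles.
5. **Search and interpolate**: sweep `n` upward from the minimum until the
   median FDR falls safely below the target, then place `n-hat` where the
   median curve crosses the target (two-point linear interpolation,
   rounded to the nearest even integer).

## Worked example

```python
from metsizer import MetSizeR

model = MetSizeR(model="ppca", p=300, prop_significant=0.2,
                 target_fdr=0.05, min_n=10)
res = model.fit(seed=1)
print(res.summary())
```

```
================================================================
      Sample-size estimation for a two-group omics design
================================================================
Analysis model:             PPCA    Spectral bins (p):     300
Prop. significant (m):       0.2    Target FDR:           0.05
Permutations:                 20    Simulations:            20
Effect size (delta):         2.3    Latent dim (q):          2
Pilot data:                   no    Seed:                    1
----------------------------------------------------------------
Estimated total sample size (n-hat):               28
Per-group allocation:                           14/14
Target FDR bracketed by grid:                     yes
----------------------------------------------------------------
FDR percentiles by candidate sample size
     n       p10    median       p90
    10    0.2797    0.3093    0.3398
    12    0.1864    0.2458    0.2898
    ...
    28    0.0339    0.0508    0.0695
    30    0.0169    0.0339    0.0508
================================================================
```

Reading: at the minimum design size (10 samples) the screen would declare
roughly 31% false positives among its top hits; by 28–30 samples the
median FDR reaches the 5% target, so the design calls for about 14–15
samples per group.  `res.curve` exposes the percentile table as a
DataFrame, `res.plot()` draws the FDR band, and `res.save(json, csv)`
writes a machine-readable run record.

With pilot data instead:

```python
model = MetSizeR.from_pilot_csv("pilot.csv", group_column="group")
res = model.fit(seed=1)
```

A CLI wraps the same functionality:

```bash
metsizer estimate --model ppca --bins 300 --prop-significant 0.2 \
    --target-fdr 0.05 --min-n 10 --seed 1 --out run/
metsizer sweep-m --bins 300 --props 0.1,0.2,0.3 --at-n 10,20,30 --out run/
metsizer fixture --n1 5 --n2 5 --bins 50 --out pilot.csv
```

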