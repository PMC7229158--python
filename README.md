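# burstfit

Bayesian inference of transcriptional burst kinetics from single-cell mRNA
count data, built around a three-state stochastic promoter model.

Many genes transcribe in bursts: the promoter switches between an active
state, in which mRNAs are made in quick succession, and inactive states in
which nothing happens. Single-molecule FISH experiments measure absolute
mRNA counts per cell; the shape of that count distribution carries the
burst kinetics. `burstfit` implements the full analysis path from a count
table to posterior estimates of burst size and burst frequency:

- **Model.** A promoter with a deep inactive state C, a primed inactive
  state B and an active state A (`C ⇌ B ⇌ A`, exchange rates α, β and
  λ, ν; transcription rate Κ in A; mRNA decay δ). When C⇌B exchange is slow
  compared with mRNA turnover, the steady-state count distribution is a
  zero-inflated negative binomial (ZINB): with probability ω = β/(α+β) a
  cell sits in C and shows zero counts; otherwise counts are negative
  binomial with shape r = λ/δ (bursts per mRNA lifetime, the **burst
  frequency**) and success probability p, with mean burst size
  p/(1−p) = Κ/ν (**burst size**).
- **Inference.** A Metropolis–Hastings sampler fits (ω, r, p) to the
  filtered counts with uniform priors on ω and p and a wide half-normal
  prior on r, reporting MAP estimates, 95% equal-tailed credible intervals,
  derived burst kinetics and convergence diagnostics.
- **Simulation.** Exact Gillespie simulation of the three-state model, for
  validating the ZINB approximation and generating synthetic datasets.
- **Summary statistics.** Noise CV² = σ²/μ² and Fano factor F = σ²/μ per
  condition, with bootstrap standard errors and the standard artifact
  filter that drops cells with more than 150 counts.
- **Scaling theory.** Closed-form noise-versus-mean laws distinguishing
  regulation by burst size (F → 1 at low expression, rising with the mean)
  from regulation by burst frequency (F ≫ 1 and nearly flat).

## Worked example

Fit burst kinetics to a synthetic dataset with known parameters
(ω = 0.3, r = 2, p = 0.9, i.e. burst size 9):

```python
from burstfit import BurstingModel
from burstfit.simulate import sample_zinb
from burstfit.zinb import ZINBParams

data = sample_zinb(ZINBParams(omega=0.3, r=2.0, p=0.9), 2000,
                   seed=11, condition="stress")
model = BurstingModel(data)           # applies the 150-count artifact filter
res = model.fit(n_samples=50_000, burn_in=10_000, thin=10, seed=12)
print(res.summary())
```

Output:

```text
Bursting model fit (zero-inflated negative binomial, MH MCMC)
==============================================================
condition: stress
cells used: 2000 (filtered out: 0, count cap: 150)
retained samples: 4000   acceptance rate: 0.031

       parameter        MAP   95% CI low    CI high
           omega     0.3165       0.2942     0.3386
               r      2.099        1.923      2.301
               p     0.8949        0.885      0.903
 burst_frequency      2.099        1.923      2.301
      burst_size      8.516        7.697      9.304
```

All generating parameters are recovered within the credible intervals.
`res.conf_int()`, `res.kinetics`, `res.chain_frame()` and `res.resume()`
give programmatic access to the posterior; `res.diagnostics` reports
effective sample sizes and split-R̂.

Descriptive statistics with bootstrap standard errors:

```python
from burstfit.data import CountData
from burstfit.stats import summarize_counts, summary_table

a = sample_zinb(ZINBParams(0.45, 1.0, 0.75), 400, seed=1, condition="basal")
b = sample_zinb(ZINBParams(0.10, 1.1, 0.95), 400, seed=2, condition="stress")
table = summary_table(summarize_counts(CountData.concat([a, b]),
                                       n_boot=10_000, seed=3))
print(table.round(3).to_string(index=False))
```

```text
condition  n_used  n_filtered     mu  sigma   cv2  sem_cv2   fano  sem_fano  sem_mu
    basal     400           0  1.762  3.181 3.258    0.329  5.743     0.478   0.160
   stress     400           0 16.538 17.806 1.159    0.095 19.173     1.668   0.892
```

## Command line

The `burstfit` entry point chains the same steps on CSV/TSV count tables
(columns `cell_id`, `condition`, `count`):

```bash
burstfit simulate  --config scenario.yaml --out counts.csv --seed 3
burstfit summarize --input counts.csv --out summary.csv --seed 1
burstfit fit       --input counts.csv --seed 2 --out-prefix results/stress
burstfit predict   --regime frequency --out curve.csv
burstfit pipeline  --config scenario.yaml --out-dir run1   # all of the above
```

`pipeline` writes a `manifest.json` with per-file SHA-256 digests; two runs
with the same config and seed produce byte-identical outputs.

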