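# powerpost

Log model evidence by **thermodynamic integration** (TI) over power
posteriors, with a population MCMC sampler, reference implementations of the
prior arithmetic-mean (AME) and posterior harmonic-mean (HME) estimators, and
two built-in model families: conjugate Bayesian linear regression (analytic
evidence available as an oracle) and a dynamic causal model (DCM) of fMRI
effective connectivity.

## The problem

Bayesian model comparison ranks hypotheses by the log model evidence
(marginal likelihood)

$$\ln p(y\mid m) = \ln \int p(y\mid\theta,m)\, p(\theta\mid m)\, d\theta ,$$

which is intractable for nonlinear generative models such as DCMs.
Variational approximations are fast but can be biased by local optima and by
the Gaussian assumption. TI instead builds a smooth path of *power
posteriors*

$$p_\beta(\theta\mid y,m) \propto p(y\mid\theta,m)^{\beta}\, p(\theta\mid m),
\qquad \beta \in [0,1],$$

from the prior ($\beta=0$) to the posterior ($\beta=1$) and uses the
thermodynamic identity

$$\ln p(y\mid m) = \int_0^1 \mathrm{E}\big[\ln p(y\mid\theta,m)\big]_{p_\beta}\, d\beta .$$

The inner expectation, the *accuracy* $A(\beta)$, is estimated by Monte
Carlo from an ensemble of Metropolis chains — one per inverse temperature
$\beta_j = (j/(N-1))^5$ — that exchange states through swap moves
(parallel tempering / population MCMC). The outer integral is the trapezoid
quadrature

$$\ln p(y\mid m) \approx \tfrac12 \sum_j (\beta_{j+1}-\beta_j)
\big(E_{MC}(\beta_{j+1}) + E_{MC}(\beta_j)\big).$$

AME ($\log$ mean of $e^{\ln p(y|\theta_k)}$ over prior draws) and HME (the
harmonic-mean analogue over posterior draws) are included because they are
popular and cheap but systematically biased — downward and upward,
respectively — which the benchmark below makes visible.

## Worked example

Estimate the evidence of a conjugate linear regression (p = 2 predictors,
M = 20 observations) and compare the three estimators with the closed form:

```python
import numpy as np
from powerpost import (generate_linreg_dataset, linreg_log_evidence,
                       make_power_schedule, run_population_mcmc,
                       ti_estimate, ame_estimate, hme_estimate)

model = generate_linreg_dataset(p=2, M=20, seed=3)
trace = run_population_mcmc(model, make_power_schedule(16, 5.0),
                            n_samples=1500, burn_in=500, seed=7)
print("analytic :", round(linreg_log_evidence(model), 3))
print("TI       :", round(ti_estimate(trace).lme, 3))
print("HME      :", round(hme_estimate(trace.loglik[-1]).lme, 3))
print("AME      :", round(ame_estimate(model, 6000, seed=7).lme, 3))
```

Output:

```
analytic : -60.237
TI       : -60.523
HME      : -55.027
AME      : -59.96
```

TI lands within a third of a nat of the truth while HME overshoots by more
than 5 nats. At p = 2 the prior arithmetic mean still works (here it happens
to land 0.3 nat high); both biases grow quickly with model dimension — at
p = 16 in the benchmark suite AME undershoots and HME overshoots by tens of
nats while TI stays within a nat.

The same machinery runs on simulated fMRI. From the shell:

```bash
powerpost simulate-dcm --model m5 --snr 1.0 --seed 4 --out sim/   # BOLD CSV + spec YAML
powerpost recover-dcm --models m1,m5 --n-datasets 5 --seed 0 --out recovery/
powerpost chi2 --a-correct 198 --a-total 200 --b-correct 199 --b-total 200
```

The last command prints `chi2 = 0.3359, p = 0.5622`: two estimators that
recover the generating model 198/200 and 199/200 times are statistically
indistinguishable.

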