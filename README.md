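# mmlsdm

Minimum-message-length model selection for species distribution modeling.

Ecologists modeling where a species occurs must usually decide two things
at once: which environmental features matter, and which model family to
use — a point process on the raw coordinates, a count regression on
gridded data, or an occupancy (presence/absence) regression. Classical
criteria such as AIC, AICc and BIC handle the first question within a
fixed family but offer no principled way to compare across families, and
they are fragile when the family is misspecified. `mmlsdm` implements a
minimum message length (MML87) framework in which every candidate —
inhomogeneous Poisson point process (IPPP), Poisson or negative-binomial
count GLM, logistic occupancy regression, hardcore process — is scored by
the length in nats of a two-part message:

    I = -ln pi(theta) + (1/2) ln |F(theta)| + (D/2)(ln kappa_D + 1)
        - ln f(Y | theta)

where the prior factorizes into a discrete subset code
ln(K+1) + ln C(K, D) and independent N(0, 10^2) coefficient priors (an
exponential prior covers the NB dispersion statistic and the hardcore
radius), F is the expected Fisher information over all continuous
parameters and kappa_D the optimal-quantizing-lattice constant. Message
lengths are directly comparable across families under equal family
priors, and the shortest message wins. A unimodal search over subset
sizes (start at floor(K/2), probe both neighbors, walk while the per-size
minimum keeps improving) finds the MML winner without enumerating all
2^K - 1 subsets.

The package also ships the stochastic machinery to validate all of this
from scratch: smoothed-Gaussian covariate fields with PCA, exact IPPP
simulation on gridded intensities, independent thinning, a hardcore
simulator, Gamma-mixed (Cox) clustering for overdispersed counts, and
the simulation protocols that measure selection accuracy by the
generalized Hamming distance d = |X Δ Y| between selected and generating
feature subsets.

## Worked example

```python
import numpy as np
from mmlsdm import (generate_raw_fields, standardize, pca_components,
                    intensity_surface, simulate_ippp, mml_search,
                    message_length)

# 12 orthogonal synthetic covariates on a 50x25 unit grid
grid = pca_components(standardize(
    generate_raw_fields(25, 50, 13, smoothness=3.0, seed=11)), 12)

# true intensity: first four components, 1/sigma weights, intercept -3
theta = np.concatenate([[-3.0], 1.0 / grid.sigmas[:4]])
lam = intensity_surface(grid, [0, 1, 2, 3], theta)
pattern = simulate_ippp(lam, grid, seed=23)

out = mml_search(pattern, grid, "ippp", K=8)
print(pattern.n, out.subset, round(out.score, 2), out.evaluated_count)
ml = message_length(out.best, K=8)
print({k: round(v, 2) for k, v in ml.parts().items()})
```

prints

```
353 (0, 1, 2, 3) 270.74 182
{'discrete_prior': 6.45, 'continuous_prior': 16.17,
 'fisher_half_logdet': 14.35, 'lattice_dim_term': -2.64,
 'neg_loglik': 236.41, 'family_cost': 0.0}
```

The simulated pattern has 353 points; the search fits 182 of the 255
possible subsets and returns exactly the four generating features with a
total message length of 270.74 nats, itemized into the subset code, the
coefficient priors, the Fisher and lattice (parameter-precision) terms,
and the data code -ln f(Y|theta).

The same selection is available from the shell:

```sh
mmlsdm simulate --seed 11 --out demo/
mmlsdm select demo/covariates.csv demo/pattern.csv --family ippp --k 8
mmlsdm experiment table1 --trials 20 --seed 0
```

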