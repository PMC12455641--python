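# carokin

Ensemble kinetic modelling of β-carotene production in recombinant
*Saccharomyces cerevisiae*: thermodynamically anchored kinetic model
particles of the mevalonate + carotenoid pathway, approximate-Bayesian
rejection fitting to multi-strain chemostat flux and transcript data,
metabolic control analysis with bootstrap inference, and simulation of
enzyme/metabolite perturbation scenarios.

## Who this is for

Metabolic engineers and systems biologists who want to locate flux
bottlenecks in a heterologous production pathway when enzyme kinetic
parameters are unknown. Instead of fitting one model, the pipeline samples
thousands of *model particles* — fully parameterised elementary-mechanism
kinetic models, each exactly consistent with reaction thermodynamics and
each exactly reproducing the measured fluxes of a reference strain — and
keeps the fraction that best explains additional strains. Questions about
control and interventions are then answered by the surviving ensemble, with
uncertainty carried through.

## The model

The packaged network covers the mevalonate pathway from acetyl-CoA through
IPP/DMAPP into the carotenoid branch (GGPP → phytoene → lycopene →
β-carotene) plus the native squalene branch: 29 metabolites, 14 enzymes and
22 reactions. At steady state only three fluxes are free — the lycopene and
β-carotene accumulation sinks `SK_lyc`, `SK_b_car` and the squalene-forming
flux `ERG9b` — and all three are measurable: the sinks from carotenoid
content × dilution rate in chemostat culture, `ERG9b` from the growth rate.

Each enzymatic reaction is an elementary mechanism (ordered sequential
binding). A particle draws, per catalytic cycle, step *reversibilities*
r_i ≥ 0, Σr_i = 1 (the fraction of ΔG_r each step dissipates) and enzyme
state abundances from flat Dirichlet priors; the elementary rate constants
then follow algebraically so that at the reference state the net rate
equals the measured flux exactly and the Haldane relationship
Π(k⁺_i/k⁻_i) = exp(−ΔG°/RT) holds by construction. Rates at new states are
evaluated by solving the steady-state enzyme-state balance (a numerical
King–Altman solve). Three structure levels are supported: **simple**
(substrates/products only), **regulated** (+ competitive dead-end
inhibition at ERG13 and ERG12, allosteric modulation of HMG2), and
**detailed** (+ the promiscuous CrtYB enzyme, whose phytoene-synthase and
lycopene-cyclase cycles share one free-enzyme pool).

Fitting is ABC rejection: each particle is simulated under every
non-reference strain (enzymes confined to transcript-derived 95% CI boxes,
metabolites to physiological windows), scored by a weighted Euclidean
discrepancy between simulated and measured free fluxes (weights 1/σ² from
the measurement CIs), and the most accurate cutoff fraction — 1% in the
full-scale design — forms the posterior ensemble.

## Worked example

```python
import numpy as np
from carokin import (load_network, load_thermo_table, ThermoSampler,
                     run_prior, reject, compare_prior_posterior)
from carokin.synthdata import make_study
from carokin.mca import ensemble_mca, mean_response_to_enzymes

model = load_network()                      # packaged reconstruction
study = make_study(model, "detailed", "crtyb_limited", seed=13)
sampler = ThermoSampler(model, load_thermo_table())

ens = run_prior(study.cm, sampler, study.v_ref, study.conditions,
                n_particles=400, seed=17)
reject(ens, cutoff_fraction=0.05)
print("feasible:", int((~np.isnan(ens.scores())).sum()),
      "posterior:", int(ens.posterior.sum()))
print("rank-sum p:", compare_prior_posterior(ens)[1])

posterior = [ens.particles[i] for i in np.flatnonzero(ens.posterior)]
resp = mean_response_to_enzymes(ensemble_mca(study.cm, posterior), "SK_b_car")
top = sorted(resp.items(), key=lambda kv: -abs(kv[1]))[:3]
print("top SK_b_car controllers:", [(e, float(round(v, 2))) for e, v in top])
```

prints

```
feasible: 349 posterior: 20
rank-sum p: 1.3235579692302532e-12
top SK_b_car controllers: [('CrtYB', 1.84), ('ERG13', -0.5), ('ERG9', 0.34)]
```

The synthetic study hides a ground truth in which CrtYB is saturated
(rate-limiting). After rejection against two noisy synthetic strains, the
posterior's mean flux response coefficients single out CrtYB as the
dominant positive controller of the β-carotene sink — the control
structure was recovered from flux and transcript data alone. A 67% CrtYB
upregulation simulated on the same posterior raises the median β-carotene
flux and shifts the β-carotene/lycopene ratio toward the product.

The same stages are scriptable from the shell:

```bash
carokin pipeline --level detailed --scenario crtyb_limited \
        --n 400 --cutoff 0.05 --seed 13 --out out/
carokin perturb --target CrtYB --factors 0.25,0.5,1,1.67,2,4 --n 200 --out out/
```

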