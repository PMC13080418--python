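# margirt

Compare patient self-report inventories as measures of a **general
internalizing factor**, using marginal (projective) item response theory.

Routine outcome monitoring in psychological therapies increasingly relies
on broadband measures of general psychopathology rather than
disorder-specific scores. When several inventories (here: CORE-OM with its
embedded CORE-10 short form, PHQ-9, OASIS, AUDIT-C) are administered
jointly, every item mixes variance from the general factor with variance
from specific factors (anxiety, depression, alcohol use, ...). This
package implements the isolate-and-analyse pipeline that separates those
sources and then asks which inventory tells you the most about the general
factor per item administered:

1. **Polychoric correlations** — two-step ML on pairwise-complete ordinal
   data, with sparse top categories merged (`margirt.polychoric`);
2. **Dimensionality** — share of covariance explained by the first
   principal component, and Horn-style parallel analysis against
   column-permuted nulls, on pretreatment scores and change scores
   (`margirt.dimensionality`);
3. **Bifactor EFA** — minres extraction plus *bi-geomin* rotation (geomin
   complexity on the specific columns, the general column unpenalized),
   with a stability screen for pathological items (`margirt.bifactor`);
4. **Marginalization** — the multidimensional normal-ogive graded model
   `P(X >= c | theta) = Phi((lambda' theta - tau_c) / sqrt(psi))` is
   integrated over the specific factors *exactly*, giving a
   unidimensional graded item in the general factor t alone with
   `a* = alpha / sigma`, `b*_c = tau_c / alpha`, where
   `alpha = lambda_g + lambda_s' Phi_21` and
   `sigma^2 = psi + lambda_s' (Phi_22 - Phi_21 Phi_12) lambda_s`
   (`margirt.projection`);
5. **Fisher information** — point and total (area under the curve) item
   and test information about t, per-item averages, StdEM = 1/sqrt(I),
   and nonparametric bootstrap percentile CIs with congruence-aligned
   factors (`margirt.information`, `margirt.pipeline`).

Because real psychotherapy-registry data cannot be redistributed, the
package ships a synthetic-cohort generator (`margirt.synthetic`) that
emulates the registry structure — 51 unique items, a dominant general
factor plus eight specific factors, an anxiety-specific factor under
OASIS, and alcohol/aggression items with zero general loading — and
exposes the generating parameters as a ground-truth oracle for every
estimation stage.

## Worked example

```bash
python analysis/01_simulate_cohort.py     # n = 5000 registry-like cohort
python analysis/03_bifactor_model.py      # stage 3 + recovery vs truth
python analysis/04_marginal_information.py
```

which prints (seeds as in the scripts):

```
fitted k=9 (converged=True); general factor explains 53.6% of factor covariance (truth: 54.3%)
general-loading RMSE vs truth (loading items): 0.0097
items not loading the general factor (|loading| < 0.20): ['AUDIT_C_1', 'AUDIT_C_2', 'AUDIT_C_3', 'CORE_OM_22', 'CORE_OM_6']

inventories ranked by averaged total test information (estimate vs generating truth):
  OASIS    total=  23.57 (true   24.11)  per-item=4.71
  CORE_OM  total= 113.57 (true  115.34)  per-item=3.34
  CORE_10  total=  31.92 (true   32.40)  per-item=3.19
  PHQ9     total=  22.34 (true   22.37)  per-item=2.48
all 51 items: total test information 159.5
```

Reading this: the externalizing items are correctly identified as not
measuring the general factor; the long form has by far the most *total*
information simply because it has 34 items, but per item the anxiety
screen and the embedded short form are the efficient measures, and the
depression inventory trails — the same qualitative ordering the method
produces on real registry data. Estimated totals sit within a few percent
of the generating model's true values.

`analysis/02_dimensionality.py` (first-component share and parallel
analysis), `analysis/05_bootstrap_cis.py` (percentile CIs at reduced
scale) and `analysis/06_core10_sensitivity.py` (re-run on the 27-item
reduced pool) cover the remaining stages. The same functionality is
available as a CLI (`margirt simulate|run|bootstrap|sensitivity`) for use
on your own response CSVs (header row, `person_id` first column, one
column per item, empty cell = missing).

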