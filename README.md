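# tausustain

Subtype and Stage Inference (SuStaIn, linear z-score variant) for regional
biomarker data, built for tau-PET subtyping in early-onset Alzheimer's
disease and for anyone who needs to cluster cross-sectional biomarker
profiles into *subtypes with their own event orderings* while placing every
scan on a discrete *stage* along its subtype's trajectory.

## The model

Regional values (e.g. mean [18F]Flortaucipir SUVR in 10 unilateral lobar
composites) are z-scored against controls. Region *i* crossing severity
threshold *z<sub>ir</sub>* is an **event**; with R thresholds per region and
B regions the model has N = ΣR<sub>i</sub> events (20 in the reference
setup). Subtype *c* is a permutation S<sub>c</sub> of all events (lower
thresholds first within a region) and a subject at stage k has completed the
first k events. Expected z per region is piecewise linear through the
threshold knots, and

P(x) = Σ<sub>c</sub> f<sub>c</sub> · (N+1)<sup>−1</sup> Σ<sub>k</sub>
Π<sub>i</sub> N(x<sub>i</sub>; g<sub>i</sub><sup>c</sup>(k), σ<sub>i</sub>)

is maximized over sequences and fractions by EM with greedy sequence
optimization and divisive subtype splitting; Metropolis MCMC over orderings
yields positional-variance diagrams, and 5-fold cross-validation (CVIC)
compares subtype counts. Scans are assigned to the highest-posterior subtype
and stage, poorly fitting scans (max subtype posterior < 50%) are flagged,
and follow-up scans restaged by the frozen baseline model feed a stability
analysis (confusion matrix, Cohen's κ, annualized stage change). A synthetic
cohort generator with known ground truth stands in for the access-restricted
study data. See `docs/methods.md` for the full model and its assumptions.

## Worked example

The numbered drivers under `analysis/` run the whole pipeline on a
simulated cohort that mirrors the study conditions (365 patients + 85
controls, 3 subtypes, 20 events, one scheduled follow-up PET per patient):

```sh
python analysis/01_simulate_cohort.py   --seed 1 --out-dir results
python analysis/02_prepare_inputs.py    --seed 1 --out-dir results
python analysis/03_fit_subtypes.py      --seed 1 --out-dir results
python analysis/04_assign_stages.py     --seed 1 --out-dir results
python analysis/05_longitudinal_stability.py --seed 1 --out-dir results
python analysis/06_evaluate_recovery.py --seed 1 --out-dir results
```

Output of the fitting and stability steps at seed 1:

```
C=1: log-likelihood -8360.9, fractions [1.]
C=2: log-likelihood -7545.7, fractions [0.54 0.46]
C=3: log-likelihood -7056.8, fractions [0.411 0.292 0.297]
CVIC: {1: 16912.7, 2: 15334.6, 3: 14006.8, 4: 13842.5}
...
assigned 365 baseline scans; 332/365 = 91% (95% CI: 88-94%) above the 50% certainty cut
  subtype 1: 142/332 = 43% (95% CI: 37-48%)
  subtype 2: 98/332 = 30% (95% CI: 25-34%)
  subtype 3: 92/332 = 28% (95% CI: 23-33%)
mean deviation from assigned sequence: 2.14 of 20 events
...
retained baseline subtype: 253/323 = 78% (95% CI: 74-83%)
Cohen's kappa: 0.67 (95% CI: 0.60-0.74)
annual stage change: mean 0.44 +/- 1.09 stages/year (n = 253)
```

Reading this: the training likelihood rises steeply to three subtypes and
the CVIC curve flattens after it; 91% of scans are assigned with ≥ 50%
certainty and split roughly 43/30/28% across subtypes; the typical scan
contradicts its assigned stage prefix on ~2 of 20 events; and when
follow-up scans are restaged blind by the frozen baseline model, 78% of
subjects keep their subtype (κ = 0.67) while advancing ~0.44 stages/year.
This demo derives event thresholds from per-region Gaussian mixtures, as
one would on real data; because those estimated thresholds differ from the
generating ones, recovery is intentionally harder than under the matched
fixed-threshold configuration the acceptance experiments use (step 06
prints both the sequence Kendall-τ and subtype accuracy against ground
truth, here 0.77 with misspecified thresholds vs ≥ 0.95 matched).

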