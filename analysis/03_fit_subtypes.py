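#!/usr/bin/env python
"""Fit the subtype hierarchy, select the subtype count, and sample MCMC.

Fits 1..C_max subtype models by divisive EM on baseline patient z-scores,
runs 5-fold cross-validation for the CVIC curve, draws Metropolis samples of
the event orderings for positional-variance diagrams, and saves the fitted
model bundle.
"""

import argparse
import warnings
from pathlib import Path

import numpy as np

import tausustain as ts

ap = argparse.ArgumentParser()
ap.add_argument("--seed", type=int, default=1)
ap.add_argument("--out-dir", type=Path, default=Path("results"))
ap.add_argument("--max-subtypes", type=int, default=3)
ap.add_argument("--cv-max-subtypes", type=int, default=4)
args = ap.parse_args()
warnings.filterwarnings("ignore")

cohort = ts.read_cohort_table(args.out_dir / "cohort.csv")
prep = ts.load_model(args.out_dir / "prep.json")
ref, event_set = prep["zscore_model"], prep["event_set"]

pmask = cohort.baseline_mask() & cohort.group_mask("patient")
Z = ts.apply_zscore(cohort, ref, mask=pmask)
print(f"fitting on {Z.shape[0]} baseline patient scans, "
      f"{event_set.n_events} events")

config = ts.RunConfig(regions=cohort.regions, seed=args.seed,
                      max_subtypes=args.max_subtypes)
rng = np.random.default_rng(args.seed)
models = ts.hierarchical_fit(Z, args.max_subtypes, event_set, config, rng)
for m in models:
    print(f"C={m.n_subtypes}: log-likelihood {m.log_likelihood:.1f}, "
          f"fractions {np.round(m.fractions, 3)}")
model = models[-1]

cv = ts.cross_validate(
    Z, list(range(1, args.cv_max_subtypes + 1)), config.cv_folds, event_set,
    ts.RunConfig(em_startpoints=5, seed=args.seed), seed=args.seed,
)
elbow = ts.cvic_elbow(cv.c_values, cv.cvic)
print("CVIC:", {c: round(float(v), 1) for c, v in zip(cv.c_values, cv.cvic)})
print(f"CVIC elbow at C = {elbow}")

mcmc = ts.run_mcmc(model, Z, n_iter=config.mcmc_iters, seed=args.seed)
print(f"MCMC acceptance rate: {mcmc.acceptance_rate:.3f}")

ts.save_model(
    args.out_dir / "model.json",
    event_set=event_set, subtype_model=model, zscore_model=ref,
    config=config, input_digest=ts.table_digest(cohort),
)
ts.render_report(args.out_dir, model=model, cv=cv, mcmc=mcmc)
print(f"saved fitted model to {args.out_dir / 'model.json'}")
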