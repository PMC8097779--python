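"""Evaluate a fitted model: bootstrap CIs, NPDE and prediction errors.

The bootstrap resamples subjects with replacement and refits (B kept small
here; 1000 is the conventional full run).  NPDE values should be standard
normal under a correct model; the prediction-error table compares
population predictions with the observations.
"""

import numpy as np

from vancopk import CohortDesign, bootstrap, final_model_spec, fit_model, make_cohort, npde, pk
from vancopk.evaluation import prediction_errors

# proportional residual matches the fitted model's error distribution, so
# the NPDE calibration below is a clean "true model" check
ds = make_cohort(CohortDesign(seed=5), residual="proportional")
spec = final_model_spec()
res = fit_model(ds, spec)

bs = bootstrap(ds, spec, B=50, seed=1, init=res)
print(f"bootstrap: {bs.converged}/{bs.attempted} replicates converged")
for name in ("theta_cl", "theta_v", "beta_cl_weight"):
    lo, hi = bs.interval(name)
    print(f"  {name:<16} median {bs.percentiles[name][50.0]:8.3f}   2.5-97.5% ({lo:.3f}, {hi:.3f})")

nr = npde(ds, spec, res.estimates, K=1000, seed=2)
print(f"npde: mean {nr.npde.mean():+.3f} var {nr.npde.var(ddof=1):.3f} | "
      f"t p={nr.t_test_p:.3f} var p={nr.variance_test_p:.3f} normality p={nr.normality_test_p:.3f} "
      f"-> {'accepted' if nr.passed else 'rejected'}")

obs, pred = [], []
for sid, subject in ds.subjects.items():
    events = ds.subject_events(sid)
    doses = [e for e in events if e.kind == "dose"]
    ind = pk.typical_params(subject, res.population_params)
    for o in (e for e in events if e.kind == "observation" and not e.below_loq):
        obs.append(o.concentration)
        pred.append(float(pk.concentration(ind, doses, o.time)))
pe = prediction_errors(obs, pred)
print(f"population prediction errors: MPE {pe.mpe:+.1f}% MAE {pe.mae:.1f}% "
      f"RMSE {pe.rmse:.1f}% MDPE {pe.mdpe:+.1f}% MDAE {pe.mdae:.1f}%")
# Bootstrap medians should sit near the point estimates with intervals well
# away from zero; MAE/RMSE reflect between-subject + residual variability
# because population (not individual) predictions are used.
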