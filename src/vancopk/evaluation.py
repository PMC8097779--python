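"""Internal model evaluation: bootstrap, NPDE and prediction-error metrics.

*Nonparametric bootstrap*: subjects are resampled with replacement (cohort
size preserved), each replicate is refitted starting from the original
estimates, and parameter percentiles are summarised over the converged
replicates.  A 2.5-97.5% interval that excludes 0 supports the reliability
of an estimate.

*Normalized prediction distribution errors (NPDE)*: the fitted model
simulates K replicate datasets; within each subject the observed and
simulated vectors are decorrelated with the Cholesky factor of the
empirical simulation covariance; each observation's pd is the fraction of
decorrelated simulations below the decorrelated observation and npde is its
standard-normal quantile.  Under the true model the npde sample is iid
N(0, 1), checked with a t test (mean 0), a Fisher variance test (variance
1) and Shapiro-Wilk normality.

*Prediction errors*: PE_j = 100 (pred_j - obs_j) / obs_j, summarised by
mean (MPE), mean absolute (MAE), root mean square (RMSE), medians
(MDPE/MDAE) and the SD of PE.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .data import Event, PKDataset
from .fit import FitResult, ModelSpec, _Engine, fit
from .pk import PopulationParams

logger = logging.getLogger(__name__)

__all__ = [
    "BootstrapSummary",
    "NpdeResult",
    "PredictionErrorReport",
    "bootstrap",
    "npde",
    "prediction_errors",
]

PERCENTILES = (0.5, 2.5, 5.0, 50.0, 95.0, 97.5, 99.5)


@dataclass
class BootstrapSummary:
    """Percentile table over converged bootstrap replicates."""

    percentiles: dict[str, dict[float, float]]  # parameter (and "ofv") -> {pct: value}
    attempted: int
    converged: int
    replicates: dict[str, np.ndarray] = field(default_factory=dict)

    def interval(self, name: str, lo: float = 2.5, hi: float = 97.5) -> tuple[float, float]:
        return self.percentiles[name][lo], self.percentiles[name][hi]

    def to_dict(self) -> dict:
        return {
            "percentiles": {k: {str(p): v for p, v in d.items()} for k, d in self.percentiles.items()},
            "attempted": self.attempted,
            "converged": self.converged,
        }


def bootstrap(
    ds: PKDataset,
    spec: ModelSpec,
    B: int = 1000,
    seed: int = 0,
    init: FitResult | Mapping[str, float] | None = None,
    keep_replicates: bool = True,
) -> BootstrapSummary:
    """Nonparametric bootstrap of the population fit (subjects resampled).

    ``init`` (a previous fit or its estimates) seeds every replicate fit;
    if omitted the original dataset is fitted first.  Replicates that fail
    to converge are excluded and counted.  Deterministic given ``seed``.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if init is None:
        init = fit(ds, spec, compute_se=False)
    init_values = init.estimates if isinstance(init, FitResult) else dict(init)
    rng = np.random.default_rng(seed)
    ids = list(ds.subjects)
    events_by_subject = {sid: [] for sid in ids}
    for e in ds.events:
        events_by_subject[e.subject_id].append(e)

    names = spec.parameter_names
    rows: list[dict[str, float]] = []
    attempted = 0
    for b in range(B):
        attempted += 1
        draw = rng.integers(0, len(ids), size=len(ids))
        subjects = {}
        events: list[Event] = []
        for j, idx in enumerate(draw):
            sid = ids[idx]
            new_id = str(j + 1)
            rec = ds.subjects[sid]
            subjects[new_id] = type(rec)(**{**rec.__dict__, "subject_id": new_id})
            for e in events_by_subject[sid]:
                events.append(Event(new_id, e.time, e.kind, e.amount, e.infusion_duration,
                                    e.concentration, e.observation_label, e.below_loq))
        ds_b = PKDataset(subjects=subjects, events=events)
        try:
            res = fit(ds_b, spec, init=init_values, compute_se=False)
        except Exception as exc:
            logger.warning("bootstrap replicate %d failed: %s", b, exc)
            continue
        if not res.converged:
            continue
        row = dict(res.estimates)
        row["ofv"] = res.ofv
        rows.append(row)
    if not rows:
        raise RuntimeError("all bootstrap replicates failed")

    table: dict[str, dict[float, float]] = {}
    reps: dict[str, np.ndarray] = {}
    for name in names + ["ofv"]:
        vals = np.array([r[name] for r in rows])
        reps[name] = vals
        table[name] = {p: float(np.percentile(vals, p)) for p in PERCENTILES}
    return BootstrapSummary(
        percentiles=table,
        attempted=attempted,
        converged=len(rows),
        replicates=reps if keep_replicates else {},
    )


@dataclass
class NpdeResult:
    """Per-observation npde values and the three calibration tests."""

    npde: np.ndarray
    pd: np.ndarray
    t_test_p: float
    variance_test_p: float
    normality_test_p: float
    alpha: float = 0.05

    @property
    def passed(self) -> bool:
        """Global decision with a Bonferroni correction over the three tests."""
        bonf = self.alpha / 3.0
        return min(self.t_test_p, self.variance_test_p, self.normality_test_p) > bonf

    def to_dict(self) -> dict:
        return {
            "npde": self.npde.tolist(),
            "t_test_p": self.t_test_p,
            "variance_test_p": self.variance_test_p,
            "normality_test_p": self.normality_test_p,
            "passed": self.passed,
        }


def _fisher_variance_p(x: np.ndarray) -> float:
    """Two-sided test of Var(x) = 1 via (n-1) s^2 ~ chi2(n-1)."""
    n = len(x)
    stat = (n - 1) * np.var(x, ddof=1)
    cdf = stats.chi2.cdf(stat, df=n - 1)
    return float(2.0 * min(cdf, 1.0 - cdf))


def npde(
    ds: PKDataset,
    spec: ModelSpec,
    params: PopulationParams | Mapping[str, float],
    K: int = 1000,
    seed: int = 0,
    include_bql: bool = False,
) -> NpdeResult:
    """Normalized prediction distribution errors under the fitted model."""
    if K < 100:
        raise ValueError("K must be >= 100 for a usable simulation distribution")
    eng = _Engine(ds, spec, include_bql=include_bql)
    x = eng.encode(params)
    rng = np.random.default_rng(seed)
    sims = eng.simulate(x, rng, K)  # (K, n_obs)
    y = eng.y
    npde_vals = np.empty(eng.n_obs)
    pd_vals = np.empty(eng.n_obs)
    for i in range(eng.n_sub):
        idx = np.where(eng.obs_sub == i)[0]
        if len(idx) == 0:
            continue
        sim = sims[:, idx]  # (K, n_i)
        mean = sim.mean(axis=0)
        centred = sim - mean
        cov = centred.T @ centred / (K - 1)
        try:
            L = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError:
            ridge = 1e-8 * np.trace(cov) / len(idx)
            logger.info("subject %s: singular simulation covariance, ridge %g added",
                        eng.subject_ids[i], ridge)
            L = np.linalg.cholesky(cov + ridge * np.eye(len(idx)))
        y_dec = np.linalg.solve(L, y[idx] - mean)
        sim_dec = np.linalg.solve(L, centred.T).T  # (K, n_i)
        pd = (sim_dec < y_dec[None, :]).mean(axis=0)
        pd = np.clip(pd, 1.0 / (2.0 * K), 1.0 - 1.0 / (2.0 * K))
        pd_vals[idx] = pd
        npde_vals[idx] = stats.norm.ppf(pd)
    t_p = float(stats.ttest_1samp(npde_vals, 0.0).pvalue)
    var_p = _fisher_variance_p(npde_vals)
    norm_p = float(stats.shapiro(npde_vals).pvalue)
    return NpdeResult(npde=npde_vals, pd=pd_vals, t_test_p=t_p,
                      variance_test_p=var_p, normality_test_p=norm_p)


@dataclass(frozen=True)
class PredictionErrorReport:
    """Percent prediction-error family: PE = 100 (pred - obs)/obs."""

    mpe: float  # mean PE
    mae: float  # mean |PE|
    rmse: float  # root mean square PE
    mdpe: float  # median PE
    mdae: float  # median |PE|
    sd_pe: float  # SD of PE
    pe: tuple[float, ...]

    def to_dict(self) -> dict:
        return {
            "MPE_percent": self.mpe,
            "MAE_percent": self.mae,
            "RMSE_percent": self.rmse,
            "MDPE_percent": self.mdpe,
            "MDAE_percent": self.mdae,
            "SD_PE_percent": self.sd_pe,
        }


def prediction_errors(observed: Sequence[float], predicted: Sequence[float]) -> PredictionErrorReport:
    """Percent prediction errors of ``predicted`` against ``observed``."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1:
        raise ValueError("observed and predicted must be equal-length vectors")
    if np.any(obs == 0):
        raise ValueError("observed values must be non-zero")
    pe = 100.0 * (pred - obs) / obs
    return PredictionErrorReport(
        mpe=float(np.mean(pe)),
        mae=float(np.mean(np.abs(pe))),
        rmse=float(np.sqrt(np.mean(pe**2))),
        mdpe=float(np.median(pe)),
        mdae=float(np.median(np.abs(pe))),
        sd_pe=float(np.std(pe, ddof=1)) if len(pe) > 1 else 0.0,
        pe=tuple(pe),
    )
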