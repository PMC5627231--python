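"""Parameter estimation against replicated batch observations.

Observables are the six measured quantities of the batch experiment: DOC,
DIC, NO3- and NO2- concentrations (mM, three replicates) and the two
functional-enzyme pools (pmol/g soil): E1 is the nitrate-reductase class
(NarG/NapA) tracking pathway 1, E2 the nitrous-oxide-reductase class
(NosZ1/NosZ2) tracking pathway 2.

Fitting minimises the sum of squared residuals between the simulated
observables and the per-timepoint observation means.  Because the
observables span three orders of magnitude, each residual is normalised by
the maximum observed mean of its observable, making the six series
commensurate; switch ``weighting='sd'`` to weight by per-point standard
deviations instead.

Confidence intervals use a resampling scheme: each synthetic dataset draws
every (time, observable) value uniformly from [mean - SD, mean + SD], the
fit is repeated per dataset, parameter sets containing a value outside the
per-parameter 2.5-97.5% quantile band for at least one parameter are
removed, and the min/max of each parameter over the retained sets are the
reported 95% confidence limits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares

from .core import (
    DomainError,
    IntegrationError,
    ModelParameters,
    ModelState,
    _params_tuple,
    rhs_array,
)

__all__ = [
    "OBSERVABLES",
    "FREE_PARAMETERS",
    "FitFailureError",
    "BootstrapFailureError",
    "ObservationSet",
    "FitResult",
    "read_observations",
    "write_observations",
    "model_observables",
    "residuals",
    "fit",
    "trim_parameter_sets",
    "bootstrap_ci",
]

logger = logging.getLogger(__name__)

#: Observable name -> index into the 12-component state vector.
OBSERVABLES: dict[str, int] = {
    "DOC": 0, "DIC": 4, "NO3": 1, "NO2": 2, "E1": 10, "E2": 11,
}

#: Parameters eligible for fitting (the identifiable set for batch data;
#: half-saturation constants and constitutive/degradation rates stay fixed
#: at literature values).
FREE_PARAMETERS = ("k1", "k2", "kR1", "kR2", "kT1", "kT2", "kE1", "kE2", "kdeg", "f1")

#: Default search bounds per free parameter.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    name: (1e-3, 100.0) for name in FREE_PARAMETERS
}
DEFAULT_BOUNDS["f1"] = (0.01, 0.999)

#: Solver tolerances for calibration trial simulations (looser than the
#: production defaults; see docs/methods.md).
FIT_RTOL = 1e-6
FIT_ATOL = 1e-8


class FitFailureError(RuntimeError):
    """No optimisation start converged; carries the best attempt."""

    def __init__(self, message: str, best: "FitResult | None" = None):
        super().__init__(message)
        self.best = best


class BootstrapFailureError(RuntimeError):
    """Every resampled dataset failed to fit."""


class ObservationSet:
    """Replicated measurements of the six batch observables.

    Wraps a long-format table with columns ``time`` (days), ``observable``
    (one of DOC, DIC, NO3, NO2, E1, E2), ``replicate`` (integer index) and
    ``value``.  Derived per (time, observable): the replicate mean and the
    sample standard deviation (0 for singletons).
    """

    def __init__(self, records: pd.DataFrame):
        required = {"time", "observable", "replicate", "value"}
        missing = required - set(records.columns)
        if missing:
            raise DomainError(f"observation table missing columns: {sorted(missing)}")
        bad = set(records["observable"].unique()) - set(OBSERVABLES)
        if bad:
            raise DomainError(f"unknown observables: {sorted(bad)}")
        if records.empty:
            raise DomainError("observation table is empty")
        records = records.reset_index(drop=True).astype(
            {"time": float, "replicate": int, "value": float})
        self.records = records

    def summary(self) -> pd.DataFrame:
        """Per (time, observable) mean and SD, in canonical sorted order."""

        def _mean(v: pd.Series) -> float:
            a = v.to_numpy(dtype=float)
            # exact replicate ties (noise-free data) must not pick up
            # 1-ulp summation error
            return float(a[0]) if np.all(a == a[0]) else float(a.mean())

        def _sd(v: pd.Series) -> float:
            a = v.to_numpy(dtype=float)
            if a.size < 2 or np.all(a == a[0]):
                return 0.0
            return float(np.std(a, ddof=1))

        g = self.records.groupby(["time", "observable"], sort=True)["value"]
        out = g.agg(mean=_mean, sd=_sd)
        return out.reset_index()

    @property
    def times(self) -> np.ndarray:
        return np.sort(self.records["time"].unique())

    def __len__(self) -> int:
        return len(self.records)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ObservationSet):
            return NotImplemented
        a = self.records.sort_values(["time", "observable", "replicate"]).reset_index(drop=True)
        b = other.records.sort_values(["time", "observable", "replicate"]).reset_index(drop=True)
        return a.equals(b)


def read_observations(path: str | Path) -> ObservationSet:
    """Read a tab- or comma-separated observation table."""
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    # round_trip parsing: the writer emits 17 significant digits
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    return ObservationSet(df)


def write_observations(obs: ObservationSet, path: str | Path) -> None:
    # 17 significant digits: values survive a write/read cycle bit-exactly
    obs.records.to_csv(path, sep="\t", index=False, float_format="%.17g")


@dataclass(frozen=True)
class FitResult:
    """Outcome of a least-squares fit, optionally with bootstrap CIs."""

    names: tuple[str, ...]
    estimates: dict[str, float]
    objective: float
    converged: bool
    ci: dict[str, tuple[float, float]] | None = None
    n_boot_total: int = 0
    n_boot_retained: int = 0
    message: str = ""
    boot_estimates: np.ndarray | None = field(default=None, repr=False, compare=False)

    def to_text(self) -> str:
        lines = [f"objective = {self.objective!r}", f"converged = {self.converged}"]
        for name in self.names:
            lines.append(f"estimate.{name} = {self.estimates[name]!r}")
        if self.ci is not None:
            for name in self.names:
                lo, hi = self.ci[name]
                lines.append(f"ci_lower.{name} = {lo!r}")
                lines.append(f"ci_upper.{name} = {hi!r}")
            lines.append(f"bootstrap.n_total = {self.n_boot_total}")
            lines.append(f"bootstrap.n_retained = {self.n_boot_retained}")
        return "\n".join(lines) + "\n"


def _simulate_at(params: ModelParameters, init: ModelState, times: np.ndarray,
                 rtol: float, atol: float) -> np.ndarray:
    """State matrix at the requested times (must include only t >= 0)."""
    times = np.asarray(times, dtype=float)
    horizon = float(times.max())
    pv = _params_tuple(params)
    sol = solve_ivp(lambda t, y: rhs_array(y, pv), (0.0, max(horizon, 1e-12)),
                    init.to_array(), method="LSODA", t_eval=times,
                    rtol=rtol, atol=atol)
    if not sol.success or not np.all(np.isfinite(sol.y)):
        reached = float(sol.t[-1]) if sol.t.size else 0.0
        raise IntegrationError(
            f"trial simulation failed at t={reached:.4g} d: {sol.message}", time=reached)
    return sol.y.T


def model_observables(params: ModelParameters, init: ModelState,
                      summary: pd.DataFrame,
                      rtol: float = FIT_RTOL, atol: float = FIT_ATOL) -> np.ndarray:
    """Simulated observable values aligned to a summary table's rows."""
    times = np.sort(summary["time"].unique())
    states = _simulate_at(params, init, times, rtol, atol)
    row_of_time = {t: i for i, t in enumerate(times)}
    idx = summary["observable"].map(OBSERVABLES).to_numpy()
    rows = summary["time"].map(row_of_time).to_numpy()
    return states[rows, idx]


def residuals(
    free: Mapping[str, float],
    fixed: ModelParameters,
    init: ModelState,
    obs: ObservationSet,
    weighting: str = "max",
    rtol: float = FIT_RTOL,
    atol: float = FIT_ATOL,
) -> np.ndarray:
    """Weighted residual vector (model minus observed mean) over all records.

    ``free`` overrides fields of ``fixed``.  With ``weighting='max'`` each
    residual is divided by the maximum observed mean of its observable; with
    ``'sd'`` by the per-point SD (points with SD 0 fall back to the max
    scale).  Residual order follows the canonical (time, observable) sort,
    so the objective is invariant to record order.
    """
    params = fixed.with_updates(**dict(free)) if free else fixed
    summary = obs.summary()
    model = model_observables(params, init, summary, rtol=rtol, atol=atol)
    mean = summary["mean"].to_numpy(dtype=float)
    scale_of = summary.groupby("observable")["mean"].transform("max").to_numpy(dtype=float)
    if np.any(scale_of <= 0):
        raise DomainError("an observable has non-positive maximum mean; cannot scale")
    if weighting == "max":
        scale = scale_of
    elif weighting == "sd":
        sd = summary["sd"].to_numpy(dtype=float)
        scale = np.where(sd > 0, sd, scale_of)
    else:
        raise DomainError(f"unknown weighting {weighting!r}")
    return (model - mean) / scale


def fit(
    obs: ObservationSet,
    free: Sequence[str],
    bounds: Mapping[str, tuple[float, float]] | None = None,
    start: Mapping[str, float] | None = None,
    fixed: ModelParameters | None = None,
    init: ModelState | None = None,
    weighting: str = "max",
    n_starts: int = 1,
    seed: int = 0,
    rtol: float = FIT_RTOL,
    atol: float = FIT_ATOL,
) -> FitResult:
    """Bounded nonlinear least-squares fit of the named free parameters.

    Parameters
    ----------
    free
        Names drawn from :data:`FREE_PARAMETERS`.  An empty set evaluates
        the objective at the fixed parameters without searching.
    bounds, start
        Per-parameter (lower, upper) bounds and starting values; defaults
        are :data:`DEFAULT_BOUNDS` and the ``fixed`` parameter values.
    fixed, init
        Baseline parameters (fields not in ``free`` stay at these values)
        and initial state; packaged defaults when omitted.
    n_starts, seed
        Optional multi-start: additional starts are log-uniform
        perturbations of ``start`` within bounds, drawn from a seeded
        generator, and the best converged attempt wins.

    Trial simulations that fail return penalty residuals (10x the largest
    clean residual magnitude seen so far) instead of aborting the search,
    since the bounded search may probe stiff corners of parameter space.
    """
    fixed = fixed if fixed is not None else ModelParameters()
    init = init if init is not None else ModelState()
    free = tuple(free)
    unknown = set(free) - set(FREE_PARAMETERS)
    if unknown:
        raise DomainError(f"not fittable: {sorted(unknown)}; "
                          f"choose from {FREE_PARAMETERS}")
    if len(set(free)) != len(free):
        raise DomainError("duplicate names in free parameter list")

    summary = obs.summary()
    if len(free) == 0:
        res = residuals({}, fixed, init, obs, weighting=weighting, rtol=rtol, atol=atol)
        return FitResult(names=(), estimates={}, objective=float(res @ res),
                         converged=True, message="no free parameters")

    bnds = dict(DEFAULT_BOUNDS)
    if bounds:
        bnds.update(bounds)
    lo = np.array([bnds[n][0] for n in free])
    hi = np.array([bnds[n][1] for n in free])
    if not np.all(np.isfinite(lo)) or not np.all(np.isfinite(hi)):
        raise DomainError("bounds must be finite")
    x0_base = np.array([
        (start[n] if start and n in start else getattr(fixed, n)) for n in free
    ])
    x0_base = np.clip(x0_base, lo, hi)

    n_rows = len(summary)
    clean_max = {"value": 1.0}

    def objective_vec(x: np.ndarray) -> np.ndarray:
        overrides = dict(zip(free, x))
        try:
            r = residuals(overrides, fixed, init, obs,
                          weighting=weighting, rtol=rtol, atol=atol)
        except (IntegrationError, DomainError) as exc:
            logger.warning("trial simulation failed (%s); penalty residuals used", exc)
            return np.full(n_rows, 10.0 * clean_max["value"])
        clean_max["value"] = max(clean_max["value"], float(np.max(np.abs(r))))
        return r

    rng = np.random.default_rng(seed)
    starts = [x0_base]
    for _ in range(n_starts - 1):
        factor = np.exp(rng.uniform(np.log(0.5), np.log(2.0), size=len(free)))
        starts.append(np.clip(x0_base * factor, lo, hi))

    best: FitResult | None = None
    for x0 in starts:
        sol = least_squares(objective_vec, x0, bounds=(lo, hi),
                            method="trf", x_scale=np.maximum(np.abs(x0), 1e-3))
        result = FitResult(
            names=free,
            estimates=dict(zip(free, map(float, sol.x))),
            objective=float(2.0 * sol.cost),
            converged=bool(sol.success),
            message=sol.message,
        )
        if best is None or (result.converged and not best.converged) or (
            result.converged == best.converged and result.objective < best.objective
        ):
            best = result
    assert best is not None
    if not best.converged:
        raise FitFailureError("no optimisation start converged", best=best)
    return best


def trim_parameter_sets(estimates: np.ndarray,
                        lower_q: float = 0.025,
                        upper_q: float = 0.975) -> np.ndarray:
    """Boolean mask of parameter sets retained by per-parameter quantile trimming.

    A row (one fitted parameter set) is removed when at least one of its
    values lies strictly below the per-parameter ``lower_q`` quantile or
    strictly above the ``upper_q`` quantile (linear-interpolation sample
    quantiles).
    """
    estimates = np.asarray(estimates, dtype=float)
    if estimates.ndim != 2 or estimates.shape[0] < 1:
        raise DomainError("estimates must be a non-empty (n_sets, n_params) matrix")
    q_lo = np.quantile(estimates, lower_q, axis=0, method="linear")
    q_hi = np.quantile(estimates, upper_q, axis=0, method="linear")
    return np.all((estimates >= q_lo) & (estimates <= q_hi), axis=1)


def _resample(summary: pd.DataFrame, rng: np.random.Generator) -> ObservationSet:
    """One synthetic dataset: each value uniform in [mean - SD, mean + SD]."""
    mean = summary["mean"].to_numpy(dtype=float)
    sd = summary["sd"].to_numpy(dtype=float)
    values = rng.uniform(mean - sd, mean + sd)
    return ObservationSet(pd.DataFrame({
        "time": summary["time"],
        "observable": summary["observable"],
        "replicate": 0,
        "value": values,
    }))


def bootstrap_ci(
    obs: ObservationSet,
    free: Sequence[str],
    bounds: Mapping[str, tuple[float, float]] | None = None,
    start: Mapping[str, float] | None = None,
    n_sets: int = 500,
    seed: int = 0,
    fixed: ModelParameters | None = None,
    init: ModelState | None = None,
    weighting: str = "max",
    rtol: float = FIT_RTOL,
    atol: float = FIT_ATOL,
) -> FitResult:
    """Point fit plus resampling-based 95% confidence limits.

    For each of ``n_sets`` synthetic datasets (values drawn uniformly within
    one SD of each observation mean) the fit is repeated, started from the
    point estimates for speed.  Per-parameter 2.5%/97.5% quantile trimming
    removes outlying parameter sets; the min and max of each parameter over
    the retained sets are the confidence limits.

    Each resample *j* draws from an independent substream keyed by
    ``(seed, j)``, so any subset of resamples is reproducible on its own.
    """
    if n_sets < 2:
        raise DomainError(f"n_sets must be >= 2, got {n_sets}")
    free = tuple(free)
    point = fit(obs, free, bounds=bounds, start=start, fixed=fixed, init=init,
                weighting=weighting, rtol=rtol, atol=atol)
    summary = obs.summary()
    rows = []
    for j in range(n_sets):
        rng = np.random.default_rng([seed, j])
        resampled = _resample(summary, rng)
        try:
            r = fit(resampled, free, bounds=bounds, start=point.estimates,
                    fixed=fixed, init=init, weighting=weighting, rtol=rtol, atol=atol)
        except FitFailureError:
            logger.warning("bootstrap resample %d failed to converge; dropped", j)
            continue
        rows.append([r.estimates[n] for n in free])
    if not rows:
        raise BootstrapFailureError("every bootstrap resample failed to converge")
    estimates = np.array(rows)
    keep = trim_parameter_sets(estimates)
    retained = estimates[keep]
    ci = {n: (float(retained[:, i].min()), float(retained[:, i].max()))
          for i, n in enumerate(free)}
    return FitResult(
        names=free,
        estimates=point.estimates,
        objective=point.objective,
        converged=point.converged,
        ci=ci,
        n_boot_total=len(rows),
        n_boot_retained=int(keep.sum()),
        message=point.message,
        boot_estimates=estimates,
    )
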