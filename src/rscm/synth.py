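"""Synthetic observation sets with the batch experiment's measurement design.

No machine-readable dataset of the sediment batch experiment is deposited,
so calibration and lag analysis are exercised against synthetic data that
copy its structure: a ~20-day anoxic incubation sampled daily, nutrient
concentrations measured in three replicates, and each enzyme class measured
as two effective replicates (the average of two signature peptides, each
from two replicates).  Noise is multiplicative Gaussian by default because
the observables span three orders of magnitude, keeping relative error
comparable across them; additive noise is available for sensitivity checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibrate import OBSERVABLES, ObservationSet
from .core import DomainError, ModelParameters, ModelState
from .simulate import Trajectory, simulate

__all__ = ["NoiseSpec", "default_design", "generate"]

NUTRIENT_OBSERVABLES = ("DOC", "DIC", "NO3", "NO2")
ENZYME_OBSERVABLES = ("E1", "E2")


@dataclass(frozen=True)
class NoiseSpec:
    """Measurement design: sampling times, replication and noise scales.

    ``noise`` maps each observable to its relative (multiplicative) noise
    scale; a missing key falls back to ``default_noise``.
    """

    times: tuple[float, ...]
    nutrient_replicates: int = 3
    enzyme_replicates: int = 2
    default_noise: float = 0.05
    noise: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.times) == 0:
            raise DomainError("at least one sampling time required")
        if any(t < 0 for t in self.times):
            raise DomainError("sampling times must be >= 0")
        if self.nutrient_replicates < 1 or self.enzyme_replicates < 1:
            raise DomainError("replicate counts must be >= 1")
        if self.default_noise < 0 or any(v < 0 for v in self.noise.values()):
            raise DomainError("noise scales must be >= 0")
        bad = set(self.noise) - set(OBSERVABLES)
        if bad:
            raise DomainError(f"unknown observables in noise spec: {sorted(bad)}")

    def noise_for(self, observable: str) -> float:
        return self.noise.get(observable, self.default_noise)

    def replicates_for(self, observable: str) -> int:
        return (self.nutrient_replicates if observable in NUTRIENT_OBSERVABLES
                else self.enzyme_replicates)


def default_design(noise: float = 0.05, seed: int = 0) -> NoiseSpec:
    """The batch design: daily sampling over 20 days, 3/2 replicates, 5% noise."""
    return NoiseSpec(times=tuple(float(t) for t in range(21)),
                     default_noise=noise, seed=seed)


def generate(
    params: ModelParameters | None = None,
    init: ModelState | None = None,
    spec: NoiseSpec | None = None,
    noise_law: str = "multiplicative",
    horizon: float | None = None,
    with_truth: bool = False,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> ObservationSet | tuple[ObservationSet, Trajectory]:
    """Simulate a truth trajectory and draw noisy replicated observations.

    Each replicate is ``truth * (1 + eps)`` with ``eps ~ Normal(0, scale)``
    truncated at -1 (redrawn) so values stay non-negative; with
    ``noise_law='additive'`` the perturbation is ``eps`` times the
    observable's maximum truth value, clipped at zero.  Deterministic given
    ``spec.seed``.  With ``with_truth=True`` the truth
    :class:`~rscm.simulate.Trajectory` is returned alongside.
    """
    params = params if params is not None else ModelParameters()
    init = init if init is not None else ModelState()
    spec = spec if spec is not None else default_design()
    t_max = max(spec.times)
    horizon = horizon if horizon is not None else max(t_max, 1e-6)
    if t_max > horizon:
        raise DomainError(
            f"sampling time {t_max} d exceeds the simulation horizon {horizon} d")
    if noise_law not in ("multiplicative", "additive"):
        raise DomainError(f"unknown noise law {noise_law!r}")

    traj = simulate(params, init, horizon=horizon, grid_step=0.01,
                    rtol=rtol, atol=atol)
    rng = np.random.default_rng(spec.seed)
    rows: list[tuple[float, str, int, float]] = []
    for obs_name, state_idx in OBSERVABLES.items():
        series = traj.states[:, state_idx]
        series_max = float(series.max())
        scale = spec.noise_for(obs_name)
        n_rep = spec.replicates_for(obs_name)
        for t in spec.times:
            # depleted species can sit O(atol) below zero in the raw
            # trajectory; measurements are of non-negative concentrations
            truth = max(float(np.interp(t, traj.times, series)), 0.0)
            for rep in range(n_rep):
                eps = rng.normal(0.0, scale) if scale > 0 else 0.0
                while eps <= -1.0:  # truncation keeps concentrations >= 0
                    eps = rng.normal(0.0, scale)
                value = truth * (1.0 + eps) if noise_law == "multiplicative" \
                    else max(truth + series_max * eps, 0.0)
                rows.append((float(t), obs_name, rep, value))
    obs = ObservationSet(pd.DataFrame(rows, columns=["time", "observable",
                                                     "replicate", "value"]))
    return (obs, traj) if with_truth else obs
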