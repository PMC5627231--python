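"""Peak detection, lag tables, depletion times and phase alignment."""

import math

import numpy as np
import pytest

from rscm import (
    DomainError,
    InconclusivePeakError,
    InsufficientOverlapError,
    ModelParameters,
    NOT_DEPLETED,
    Trajectory,
    align_and_correlate,
    depletion_time,
    lag_table,
    peak_time,
    simulate,
)


def make_regulatory_trajectory(times, rho, tau, e):
    """Trajectory stub carrying prescribed regulatory series on both pathways."""
    states = np.zeros((len(times), 12))
    states[:, 6] = states[:, 7] = rho
    states[:, 8] = states[:, 9] = tau
    states[:, 10] = states[:, 11] = e
    return Trajectory(times=np.asarray(times, dtype=float), states=states,
                      derived=np.zeros((len(times), 5)), params=ModelParameters())


def test_peak_time_parabola_and_ties():
    t = np.linspace(0, 10, 101)
    assert peak_time(t, -(t - 4.0) ** 2) == pytest.approx(4.0)
    assert peak_time(t, np.ones_like(t)) == 0.0   # tie broken to earliest


def test_peak_time_input_errors():
    with pytest.raises(DomainError):
        peak_time(np.array([]), np.array([]))
    with pytest.raises(DomainError):
        peak_time(np.array([0.0, 1.0]), np.array([1.0]))
    with pytest.raises(DomainError):
        peak_time(np.array([0.0, 0.0, 1.0]), np.array([1.0, 2.0, 3.0]))


def test_lag_table_known_shifts():
    """Series built as g(t), g(t-a), g(t-a-b) must show lags (a, b, a+b)."""
    a, b = 1.3, 0.7
    t = np.arange(0.0, 15.0, 0.01)
    g = lambda x: np.exp(-((x - 4.0) ** 2))
    traj = make_regulatory_trajectory(t, g(t), g(t - a), g(t - a - b))
    table = lag_table(traj)
    for i in (1, 2):
        assert table.lag("RT", i) == pytest.approx(a, abs=0.011)
        assert table.lag("TE", i) == pytest.approx(b, abs=0.011)
        assert table.lag("RE", i) == pytest.approx(a + b, abs=0.011)


def test_lag_table_identical_series_zero_lags():
    t = np.arange(0.0, 10.0, 0.01)
    g = np.exp(-((t - 3.0) ** 2))
    table = lag_table(make_regulatory_trajectory(t, g, g, g))
    for i in (1, 2):
        for kind in ("RT", "TE", "RE"):
            assert table.lag(kind, i) == 0.0


def test_lag_table_additivity_exact(default_traj):
    table = lag_table(default_traj)
    for i in (1, 2):
        assert table.lag("RE", i) == table.lag("RT", i) + table.lag("TE", i)


def test_lag_table_amplitude_invariance(default_traj):
    """Lags only depend on peak locations, not on series amplitude."""
    scaled_states = default_traj.states.copy()
    scaled_states[:, 6:] *= 37.5
    scaled = Trajectory(times=default_traj.times, states=scaled_states,
                        derived=default_traj.derived, params=default_traj.params)
    assert lag_table(scaled) == lag_table(default_traj)


def test_lag_table_inconclusive_peak():
    t = np.arange(0.0, 10.0, 0.01)
    rising = t ** 2
    g = np.exp(-((t - 3.0) ** 2))
    with pytest.raises(InconclusivePeakError, match="tau"):
        lag_table(make_regulatory_trajectory(t, g, rising, g))


def test_lag_report_resolution(default_traj):
    df = lag_table(default_traj).to_frame()
    assert set(df.columns) == {"quantity", "pathway", "value_days"}
    # every reported value sits on the 0.1-day lattice
    assert np.allclose(np.round(df["value_days"] / 0.1), df["value_days"] / 0.1)


def test_depletion_time_exponential_closed_form():
    t = np.linspace(0, 10, 10001)
    v = np.exp(-t)
    assert depletion_time(t, v, 0.01) == pytest.approx(math.log(100.0), abs=1e-3)


def test_depletion_time_never_crossed():
    t = np.linspace(0, 10, 101)
    assert depletion_time(t, t + 1.0, 0.01) is NOT_DEPLETED


def test_depletion_time_monotone_in_fraction():
    t = np.linspace(0, 10, 1001)
    v = np.exp(-t)
    fractions = [0.005, 0.01, 0.02, 0.05, 0.1]
    times = [depletion_time(t, v, f) for f in fractions]
    assert times == sorted(times, reverse=True)


def test_depletion_time_reference_modes():
    t = np.linspace(0, 20, 2001)
    v = np.exp(-((t - 5.0) ** 2))       # transient: starts at ~0
    by_max = depletion_time(t, v, 0.01, "max")
    assert by_max == pytest.approx(5.0 + math.sqrt(math.log(100.0)), abs=0.02)
    assert depletion_time(t, v, 0.01, "auto") == by_max
    with pytest.raises(DomainError):
        depletion_time(t, v, 1.5)


def test_align_and_correlate_shift_identity():
    t = np.arange(0.0, 20.0, 0.01)
    base = np.exp(-((t - 8.0) ** 2) / 4.0)
    shifted = np.exp(-((t - 9.5) ** 2) / 4.0)   # same pulse 1.5 d later
    assert align_and_correlate(base, base, 0.0, 0.01) == pytest.approx(1.0)
    assert align_and_correlate(base, shifted, 1.5, 0.01) == pytest.approx(1.0, abs=1e-9)


def test_align_and_correlate_overlap_guard():
    t = np.arange(0.0, 1.0, 0.01)
    v = np.sin(t)
    with pytest.raises(InsufficientOverlapError):
        align_and_correlate(v, v, 0.95, 0.01)
    with pytest.raises(InsufficientOverlapError):
        align_and_correlate(v, v, 5.0, 0.01)


def test_peak_time_grid_refinement(default_params, default_init):
    """Peak location of the enzyme series is stable under a 10x finer
    re-simulation grid."""
    coarse = simulate(default_params, default_init, horizon=20.0, grid_step=0.1)
    fine = simulate(default_params, default_init, horizon=20.0, grid_step=0.01)
    for name in ("e1", "e2"):
        t_coarse = peak_time(coarse.times, coarse.series(name))
        t_fine = peak_time(fine.times, fine.series(name))
        assert abs(t_coarse - t_fine) <= 0.1


def test_pathway1_transcription_is_the_slow_step(default_traj):
    table = lag_table(default_traj)
    assert table.lag_RT1 > table.lag_TE1
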