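"""Shared fixtures: small simulated systems reused across test modules."""

import numpy as np
import pytest

from autoxkin import (AntioxidantSpec, ExperimentSystem, ReactionParameters,
                      Trace, closed_form_uptake, simulate)


@pytest.fixture(scope="session")
def strong_inhibitor_run():
    """Liposomal run with a strong tocopherol-like inhibitor (ledger kept).

    k_inh [ArOH] = 1.4e-2 >> 10 sqrt(R_i 2k_t): the strong-inhibitor
    regime of the induction-period relation.
    """
    ax = AntioxidantSpec(name="PMHC", conc0=1e-6, k_inh=1.4e4, k_cross=1e8)
    system = ExperimentSystem(medium="liposome", R_i=2.3e-9,
                              antioxidants=[ax])
    params = ReactionParameters(k_p=41.0, two_kt=150.0)
    result = simulate(system, params, t_end=2000.0, dt_out=2.0,
                      return_ledger=True)
    return system, params, result


@pytest.fixture(scope="session")
def uninhibited_run():
    """Uninhibited micellar run at the default calibration."""
    system = ExperimentSystem(medium="micelle", R_i=4.63e-9)
    params = ReactionParameters(k_p=36.0, two_kt=150.0)
    result = simulate(system, params, t_end=4500.0, dt_out=5.0,
                      return_ledger=True)
    return system, params, result


def make_closed_form_trace(tau=432.0, k_inh=5.0e4, k_p=36.0, LH=2.74e-3,
                           r_ox=5.5e-7, dt=2.0, t_end_factor=1.8,
                           cutoff=None):
    """Noiseless trace: integrated inhibited uptake up to ``cutoff*tau``,
    then the uninhibited slope (default cutoff: slope-continuous join)."""
    t = np.arange(0.0, t_end_factor * tau + dt / 2, dt)
    if cutoff is None:
        cutoff = min(1.0 - (k_p * LH / k_inh) / (r_ox * tau), 0.995)
    t_b = cutoff * tau
    y = np.empty_like(t)
    pre = t < t_b
    y[pre] = closed_form_uptake(t[pre], tau, k_inh, k_p, LH)
    y_b = closed_form_uptake(t_b, tau, k_inh, k_p, LH)
    y[~pre] = y_b + r_ox * (t[~pre] - t_b)
    return Trace(times=t, o2_consumed=y, injection_time=0.0,
                 metadata={"medium": "micelle", "pH": 6.0, "LH0": LH,
                           "k_p": k_p, "compounds": "X:1e-06"})


@pytest.fixture
def closed_form_trace():
    return make_closed_form_trace()


def make_piecewise_trace(slope1=20e-9, slope2=200e-9, tau=600.0,
                         injection=100.0, dt=5.0, t_end=1500.0):
    """Exact two-segment trace with the break ``tau`` after injection."""
    t = np.arange(0.0, t_end + dt / 2, dt)
    t_rel = np.maximum(t - injection, 0.0)
    y = slope1 * t_rel + (slope2 - slope1) * np.maximum(t_rel - tau, 0.0)
    return Trace(times=t, o2_consumed=y, injection_time=injection,
                 metadata={"medium": "micelle", "pH": 7.0,
                           "compounds": "X:1e-06"})


@pytest.fixture
def piecewise_trace():
    return make_piecewise_trace()
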