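import pytest

from pumpdecay import (
    DepletionParams,
    InactivationParams,
    PumpParams,
    make_protocol,
)


@pytest.fixture
def pump():
    return PumpParams(Imax=1.6, Kn1=0.5, Kn2=4.0)


@pytest.fixture
def inact_params(pump):
    return InactivationParams(pump=pump)


@pytest.fixture
def depl_params(pump):
    return DepletionParams(pump=pump, NaB=25.0)


@pytest.fixture
def standard_protocol():
    return make_protocol("standard_k_pulse")


def bisect_depletion_root(params: DepletionParams, rel_tol: float = 1e-13) -> float:
    """Independent bisection oracle for the steady-state depletion balance.

    Pure interval halving on [0, NaB] of the monotone residual
    Ipeak(Na) - (NaB - Na)*Kdiff; shares no code path with the Newton
    solver beyond the forward current law.
    """
    p = params.pump
    lo, hi = 0.0, params.NaB

    def resid(na):
        f = p.Imax * (na / (na + p.Kn1)) ** 2 * (na / (na + p.Kn2))
        return f - (params.NaB - na) * params.Kdiff

    while (hi - lo) > rel_tol * max(params.NaB, 1.0):
        mid = 0.5 * (lo + hi)
        if resid(mid) > 0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)
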