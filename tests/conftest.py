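import numpy as np
import pytest

from bmpdiversity.synthetic import SyntheticDesign, default_truth


@pytest.fixture
def zero_noise_design():
    return SyntheticDesign(noise_sd_counts=0.0, noise_sd_intensity=0.0, seed=11)


@pytest.fixture
def zero_noise_truth(zero_noise_design):
    return default_truth(zero_noise_design)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def method2_ode_oracle(params, t_grid, rtol=1e-12, atol=1e-12):
    """Independent numerical integration of the 4-ODE Heaviside-pulse system.

    Integrates piecewise across the light-off discontinuity so the adaptive
    solver never steps over it; used to validate the closed-form evaluator.
    Returns a (4, len(t_grid)) array ordered (Pe, Po, Te, To).
    """
    from scipy.integrate import solve_ivp

    p = params
    t_grid = np.asarray(t_grid, dtype=float)
    assert (t_grid >= 0).all()

    def rhs(t, y, light):
        Pe, Po, Te, To = y
        return [
            p.k1 - p.k2 * Pe,
            p.k3 * light - p.k2 * Po,
            p.k4 * Pe - p.k5 * Te,
            p.sigma * Po - p.lam * To,
        ]

    y0 = [
        p.dPe + p.k1 / p.k2,
        p.dPo,
        p.dTe + p.k1 * p.k4 / (p.k2 * p.k5),
        p.dTo,
    ]
    out = np.empty((4, t_grid.size))
    during = t_grid <= p.t_L
    sol_on = solve_ivp(
        rhs, (0.0, p.t_L), y0, args=(1.0,), dense_output=True, rtol=rtol, atol=atol
    )
    assert sol_on.success
    if during.any():
        out[:, during] = sol_on.sol(t_grid[during])
    if (~during).any():
        t_end = float(t_grid.max())
        sol_off = solve_ivp(
            rhs, (p.t_L, t_end), sol_on.sol(p.t_L), args=(0.0,),
            dense_output=True, rtol=rtol, atol=atol,
        )
        assert sol_off.success
        out[:, ~during] = sol_off.sol(t_grid[~during])
    return out
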