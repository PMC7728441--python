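"""Induction-decay kinetics of transcriptional responses to optogenetic
BMP signaling pulses.

Blue light applied to Opto-BMP-injected embryos produces a square pulse of
extra pSmad1/5/9; uninjected siblings report the endogenous signal.  The
optogenetically induced components H(t) (pSmad) and L(t) (transcripts) are
isolated by sibling subtraction: injected minus uninjected.

Two fitting strategies estimate each gene's induction rate constant sigma
(1/s) and decay rate constant lambda (1/s):

Method 1 — the scalar induction-decay model dTo/dt = sigma*Po - lambda*To,
where Po(t) is the measured pSmad pulse H(t) smoothed with a degree-5
polynomial; the ODE is integrated numerically and (To(0), sigma, lambda)
are fitted per repeat by bounded Nelder-Mead.

Method 2 — the full linear system with a Heaviside light input of length
t_L (1800 s),

    dPe/dt = k1 - k2*Pe
    dPo/dt = k3*(theta(t) - theta(t - t_L)) - k2*Po
    dTe/dt = k4*Pe - k5*Te
    dTo/dt = sigma*Po - lambda*To

solved in closed form and fitted in two stages: pSmad parameters
(dPe, dPo, k1, k2, k3) against the two pSmad arms, then gene parameters
(dTe, dTo, k4, k5, sigma, lambda) against the two transcript arms with the
pSmad stage fixed.  Method-2 fits are unconstrained in sign.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares

from ._optim import nelder_mead_box
from .errors import (
    DegenerateSolutionError,
    GridMismatchError,
    InsufficientDataError,
    IntegrationError,
    InvalidInputError,
)

__all__ = [
    "PULSE_LENGTH_S",
    "PulsePair",
    "InducedSeries",
    "PSmadPolyInput",
    "Method1Fit",
    "Method2Params",
    "minutes_post_exposure_to_seconds",
    "subtract_sibling",
    "fit_psmad_polynomial",
    "simulate_induction",
    "fit_method1",
    "summarize_repeats",
    "eval_method2_analytic",
    "fit_psmad_method2",
    "fit_gene_method2",
]

#: Light pulse length used in all experiments: 30 min.
PULSE_LENGTH_S = 1800.0

# Method-1 fit settings: bounds are the biologically plausible boxes for the
# rate constants and the initial transcript offset; per-repeat fits run at
# most 500 Nelder-Mead iterations from zero initial guesses (clipped onto
# the boxes).
METHOD1_BOUNDS_RATE = (0.00001, 0.1)  # 1/s, sigma and lambda
METHOD1_BOUNDS_TO0 = (-100.0, 100.0)  # a.u.
METHOD1_MAXITER = 500

# Method-2 settings: unconstrained least squares, iteration caps and the
# optimality tolerance as configured in the original analysis.
METHOD2_PSMAD_X0 = {"dPe": 0.0, "dPo": 0.0, "k1": 0.0, "k2": 0.00167, "k3": 0.0}
METHOD2_GENE_X0 = {
    "dTe": 0.0, "dTo": 0.0, "k4": 0.0, "k5": 0.00167, "sigma": 0.0, "lam": 0.00167,
}
METHOD2_PSMAD_MAXFEV = 20000
METHOD2_GENE_MAXFEV = 10000
METHOD2_OPT_TOL = 0.3981071706e-14

_EXP_CLIP = 700.0  # guard: exp overflow only matters far outside plausible rates


def _exp(x):
    return np.exp(np.clip(x, -_EXP_CLIP, _EXP_CLIP))


def minutes_post_exposure_to_seconds(minutes, pulse_length_s: float = PULSE_LENGTH_S):
    """Convert 'min post-exposure' timestamps to model time (s after light ON).

    The light pulse occupies model time [0, t_L]; 'post-exposure' clocks
    start at light OFF, so t = 60*minutes + t_L.
    """
    return 60.0 * np.asarray(minutes, dtype=float) + pulse_length_s


@dataclass
class PulsePair:
    """Paired injected/uninjected measurements of one signal in one repeat."""

    signal: str  # 'psmad' or a gene name
    repeat: int
    times_s: np.ndarray  # model time, s relative to light onset
    uninjected: np.ndarray  # a.u.; G(t) for pSmad, K(t) for transcripts
    injected: np.ndarray  # a.u.; I(t) = G + H, or M(t) = K + L

    def __post_init__(self):
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.uninjected = np.asarray(self.uninjected, dtype=float)
        self.injected = np.asarray(self.injected, dtype=float)
        if not (self.times_s.size == self.uninjected.size == self.injected.size):
            raise GridMismatchError("arms and time grid differ in length")
        if not (np.isfinite(self.uninjected).all() and np.isfinite(self.injected).all()):
            raise InvalidInputError("arm values must be finite")


@dataclass
class InducedSeries:
    """Optogenetically induced component: injected minus uninjected."""

    signal: str
    repeat: int
    times_s: np.ndarray
    values: np.ndarray  # H(t) for pSmad, L(t) for transcripts


@dataclass
class PSmadPolyInput:
    """Degree-5 polynomial smoothing of the measured pSmad pulse H(t).

    Coefficients are highest-degree-first (numpy polyval convention) in
    seconds; evaluation outside the fitted window is clamped to the window
    endpoints because high-degree polynomials diverge immediately outside
    their data support.
    """

    coefficients: np.ndarray  # 6 values, a.u. vs s
    window: tuple[float, float]  # [t_min, t_max], s

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.size != 6:
            raise InvalidInputError("degree-5 polynomial needs exactly 6 coefficients")

    def __call__(self, t):
        t = np.clip(np.asarray(t, dtype=float), self.window[0], self.window[1])
        return np.polyval(self.coefficients, t)


@dataclass
class Method1Fit:
    sigma: float  # 1/s
    lam: float  # 1/s
    To0: float  # a.u.
    ssd_min: float  # a.u.^2
    r2: float  # NaN when the data have zero variance
    converged: bool
    gene: str = ""
    repeat: int = 0


@dataclass
class Method2Params:
    """Parameters of the 4-ODE Heaviside-pulse system (one gene)."""

    k1: float = 0.0  # a.u./s, endogenous pSmad activation rate
    k2: float = 1e-3  # 1/s, pSmad decay rate constant
    k3: float = 0.0  # a.u./s, optogenetic pSmad activation rate
    k4: float = 0.0  # 1/s, endogenous transcript activation rate constant
    k5: float = 1e-3  # 1/s, endogenous transcript decay rate constant
    sigma: float = 0.0  # 1/s, induction rate constant of the induced gene
    lam: float = 1e-3  # 1/s, decay rate constant of the induced gene
    dPe: float = 0.0  # a.u., initial-condition offsets
    dPo: float = 0.0
    dTe: float = 0.0
    dTo: float = 0.0
    t_L: float = PULSE_LENGTH_S  # s
    r2: float = float("nan")
    gene: str = ""

    def validate(self, rel_tol: float = 1e-12):
        if self.t_L <= 0:
            raise InvalidInputError("pulse length t_L must be positive")
        if self.k2 <= 0:
            raise DegenerateSolutionError("closed forms require k2 > 0")
        scale = abs(self.k2)
        if abs(self.k2 - self.lam) <= rel_tol * scale:
            raise DegenerateSolutionError("lambda = k2 is a removable singularity")
        if abs(self.k2 - self.k5) <= rel_tol * scale:
            raise DegenerateSolutionError("k5 = k2 is a removable singularity")
        if self.lam == 0.0 or self.k5 == 0.0:
            raise DegenerateSolutionError("lambda and k5 must be nonzero")


def subtract_sibling(pair: PulsePair) -> InducedSeries:
    """Isolate the induced component: injected minus uninjected, element-wise."""
    return InducedSeries(
        signal=pair.signal, repeat=pair.repeat,
        times_s=pair.times_s.copy(), values=pair.injected - pair.uninjected,
    )


def fit_psmad_polynomial(induced: InducedSeries, degree: int = 5) -> PSmadPolyInput:
    """Least-squares degree-5 polynomial smoothing of the pSmad pulse."""
    if induced.times_s.size < degree + 1:
        raise InsufficientDataError(f"need at least {degree + 1} timepoints")
    coeffs = np.polyfit(induced.times_s, induced.values, degree)
    return PSmadPolyInput(
        coefficients=coeffs,
        window=(float(induced.times_s[0]), float(induced.times_s[-1])),
    )


def simulate_induction(
    psmad_input: PSmadPolyInput,
    sigma: float,
    lam: float,
    To0: float,
    times: np.ndarray,
) -> np.ndarray:
    """Integrate dTo/dt = sigma*Po(t) - lambda*To from To(times[0]) = To0.

    Adaptive integration (LSODA, rtol 1e-10) evaluated at the measurement
    times; Po(t) is the clamped polynomial input.
    """
    times = np.asarray(times, dtype=float)
    if not (np.diff(times) > 0).all():
        raise InvalidInputError("times must be strictly increasing")

    def rhs(t, y):
        return sigma * psmad_input(t) - lam * y

    sol = solve_ivp(
        rhs, (times[0], times[-1]), [float(To0)],
        t_eval=times, method="LSODA", rtol=1e-10, atol=1e-10,
    )
    if not sol.success:
        raise IntegrationError(f"induction-decay ODE failed: {sol.message}")
    return sol.y[0]


def _exp_poly_integrals(lam: float, h: float, kmax: int = 5) -> np.ndarray:
    """I_k = integral_0^h exp(-lam*(h-u)) u^k du for k = 0..kmax.

    Upward recurrence I_k = (h^k - k*I_{k-1})/lam for moderate lam*h; a
    beta-function series for small lam*h where the recurrence cancels.
    """
    z = lam * h
    out = np.empty(kmax + 1)
    if abs(z) < 0.5:
        # I_k = h^(k+1) * sum_j (-z)^j * k!/(k+j+1)!
        for k in range(kmax + 1):
            term = 1.0 / (k + 1)  # j = 0
            total = term
            for j in range(1, 30):
                term *= -z / (k + j + 1)
                total += term
                if abs(term) < 1e-18 * abs(total):
                    break
            out[k] = h ** (k + 1) * total
        return out
    out[0] = (1.0 - np.exp(-z)) / lam
    for k in range(1, kmax + 1):
        out[k] = (h**k - k * out[k - 1]) / lam
    return out


def _induction_exact(
    psmad_input: PSmadPolyInput, sigma: float, lam: float, To0: float, times: np.ndarray
) -> np.ndarray:
    """Closed-form solution of dTo/dt = sigma*Po(t) - lambda*To on ``times``.

    Po is piecewise: the degree-5 polynomial inside its window, constant
    (clamped) outside, so the exponential-integrator update
    T(t+h) = exp(-lam*h)*T(t) + sigma * integral exp(-lam*(h-u))*Po du
    is evaluated exactly segment by segment.  Used as the forward model in
    Method-1 fitting, where an adaptive solver per objective evaluation
    would dominate the run time; agrees with :func:`simulate_induction` to
    solver tolerance.
    """
    times = np.asarray(times, dtype=float)
    w0, w1 = psmad_input.window
    # split integration at window endpoints so each segment has a single rule
    breaks = np.unique(np.concatenate([times, [b for b in (w0, w1) if times[0] < b < times[-1]]]))
    coeffs = psmad_input.coefficients
    # derivative coefficients for the Taylor shift P(t0 + u)
    derivs = [coeffs]
    for _ in range(5):
        derivs.append(np.polyder(derivs[-1]))
    factorial = np.array([1.0, 1.0, 2.0, 6.0, 24.0, 120.0])

    T = float(To0)
    values = {times[0]: T}
    for t0, t1 in zip(breaks[:-1], breaks[1:]):
        h = t1 - t0
        decay = np.exp(-lam * h)
        mid = 0.5 * (t0 + t1)
        if mid < w0 or mid > w1:
            # clamped region: constant input
            const = psmad_input(mid)
            integral = const * _exp_poly_integrals(lam, h, kmax=0)[0]
        else:
            a = np.array([np.polyval(d, t0) for d in derivs]) / factorial
            integral = float(a @ _exp_poly_integrals(lam, h, kmax=5))
        T = decay * T + sigma * integral
        values[t1] = T
    return np.array([values[t] for t in times])


def fit_method1(
    induced_counts: InducedSeries,
    psmad_input: PSmadPolyInput,
    maxiter: int = METHOD1_MAXITER,
) -> Method1Fit:
    """Per-repeat bounded fit of (To(0), sigma, lambda) to one induced series.

    Nelder-Mead on box-transformed parameters — sigma, lambda in
    [1e-5, 0.1] 1/s (log-spaced), To(0) in [-100, 100] a.u. — from zero
    initial guesses clipped onto the boxes, with at most ``maxiter``
    iterations.  R^2 = 1 - SSD_min / sum (L - mean L)^2.
    """
    if induced_counts.times_s.size < 4:
        raise InsufficientDataError("need at least 4 timepoints")
    t, L = induced_counts.times_s, induced_counts.values

    def ssd(params):
        To0, sigma, lam = params
        model = _induction_exact(psmad_input, sigma, lam, To0, t)
        return float(np.sum((L - model) ** 2))

    res = nelder_mead_box(
        ssd,
        x0=(0.0, 0.0, 0.0),
        bounds=(METHOD1_BOUNDS_TO0, METHOD1_BOUNDS_RATE, METHOD1_BOUNDS_RATE),
        log_scale=[False, True, True],
        maxiter=maxiter, maxfev=4 * maxiter,
    )
    To0, sigma, lam = (float(v) for v in res.x)
    sstot = float(np.sum((L - L.mean()) ** 2))
    r2 = 1.0 - res.fun / sstot if sstot > 0 else float("nan")
    return Method1Fit(
        sigma=sigma, lam=lam, To0=To0, ssd_min=res.fun, r2=r2,
        converged=res.converged,
        gene=induced_counts.signal, repeat=induced_counts.repeat,
    )


def summarize_repeats(fits: Sequence[Method1Fit]) -> pd.DataFrame:
    """Across-repeat mean and n-1 sample SD of sigma, lambda, To(0) per gene."""
    df = pd.DataFrame(
        {"gene": f.gene, "sigma": f.sigma, "lam": f.lam, "To0": f.To0} for f in fits
    )
    counts = df.groupby("gene").size()
    if (counts < 2).any():
        bad = counts[counts < 2].index.tolist()
        raise InsufficientDataError(f"genes with fewer than 2 repeats: {bad}")
    out = df.groupby("gene").agg(
        sigma_mean=("sigma", "mean"), sigma_sd=("sigma", lambda v: v.std(ddof=1)),
        lambda_mean=("lam", "mean"), lambda_sd=("lam", lambda v: v.std(ddof=1)),
        To0_mean=("To0", "mean"), To0_sd=("To0", lambda v: v.std(ddof=1)),
        n=("sigma", "count"),
    ).reset_index()
    return out


def eval_method2_analytic(params: Method2Params, t) -> tuple[np.ndarray, ...]:
    """Closed-form (Pe, Po, Te, To) of the Heaviside-pulse system at times t.

    The system is linear with a piecewise-constant input, so each component
    is a sum of exponentials assembled branch-wise: before the pulse
    (t < 0, no light), during (0 <= t <= t_L) and after (t > t_L, relaxation
    from the pulse-end state).  theta(0) = 1: the light is on at t = 0, and
    both Po and To are continuous across the branch points.  Initial
    conditions: Pe(0) = dPe + k1/k2, Po(0) = dPo, Te(0) = dTe + k1*k4/(k2*k5),
    To(0) = dTo.
    """
    params.validate()
    p = params
    t = np.asarray(t, dtype=float)
    scalar = t.ndim == 0
    t = np.atleast_1d(t)

    e_k2t = _exp(-p.k2 * t)
    e_k5t = _exp(-p.k5 * t)
    e_lt = _exp(-p.lam * t)

    # Endogenous channels are light-independent on the whole axis.
    Pe = p.k1 / p.k2 + p.dPe * e_k2t
    Te = (
        p.k1 * p.k4 / (p.k2 * p.k5)
        + p.k4 * p.dPe * (e_k2t - e_k5t) / (p.k5 - p.k2)
        + p.dTe * e_k5t
    )

    # Optogenetic channels, branch by branch.
    a = p.k3 / p.k2  # forced steady state of Po while the light is on
    b = p.dPo - a
    Po_on = a + b * e_k2t
    C_on = p.dTo - p.sigma * a / p.lam - p.sigma * b / (p.lam - p.k2)
    To_on = (
        p.sigma * a / p.lam
        + p.sigma * b * e_k2t / (p.lam - p.k2)
        + C_on * e_lt
    )

    # State at light OFF seeds the post-pulse relaxation.
    e_k2L = _exp(-p.k2 * p.t_L)
    e_lL = _exp(-p.lam * p.t_L)
    Po_L = a + b * e_k2L
    To_L = (
        p.sigma * a / p.lam + p.sigma * b * e_k2L / (p.lam - p.k2) + C_on * e_lL
    )
    s = t - p.t_L
    e_k2s = _exp(-p.k2 * s)
    e_ls = _exp(-p.lam * s)
    Po_off = Po_L * e_k2s
    To_off = (
        p.sigma * Po_L * (e_k2s - e_ls) / (p.lam - p.k2) + To_L * e_ls
    )

    # Before light onset there is no optogenetic input at all.
    Po_pre = p.dPo * e_k2t
    To_pre = (
        p.sigma * p.dPo * (e_k2t - e_lt) / (p.lam - p.k2) + p.dTo * e_lt
    )

    during = (t >= 0) & (t <= p.t_L)
    after = t > p.t_L
    Po = np.where(after, Po_off, np.where(during, Po_on, Po_pre))
    To = np.where(after, To_off, np.where(during, To_on, To_pre))

    if scalar:
        return float(Pe[0]), float(Po[0]), float(Te[0]), float(To[0])
    return Pe, Po, Te, To


def _lsq_tols():
    # least_squares rejects tolerances below machine epsilon; the configured
    # optimality tolerance is tighter, so clamp to eps.
    return max(METHOD2_OPT_TOL, np.finfo(float).eps)


def fit_psmad_method2(
    pair: PulsePair,
    t_L: float = PULSE_LENGTH_S,
    x0: dict | None = None,
    max_nfev: int = METHOD2_PSMAD_MAXFEV,
) -> Method2Params:
    """Stage 1: fit (dPe, dPo, k1, k2, k3) to the paired pSmad arms.

    Simultaneous unconstrained least squares of uninjected data against
    Pe(t) and injected data against Pe(t) + Po(t).  The fitted parameters
    are subsequently held fixed for every gene fit.
    """
    guesses = dict(METHOD2_PSMAD_X0)
    if x0:
        guesses.update(x0)
    theta0 = [guesses[k] for k in ("dPe", "dPo", "k1", "k2", "k3")]

    def residuals(theta):
        dPe, dPo, k1, k2, k3 = theta
        p = Method2Params(k1=k1, k2=k2, k3=k3, dPe=dPe, dPo=dPo, t_L=t_L)
        try:
            p.validate()
        except DegenerateSolutionError:
            return np.full(2 * pair.times_s.size, 1e12)
        Pe, Po, _, _ = eval_method2_analytic(p, pair.times_s)
        return np.concatenate([pair.uninjected - Pe, pair.injected - (Pe + Po)])

    tol = _lsq_tols()
    res = least_squares(
        residuals, theta0, method="trf", x_scale="jac",
        max_nfev=max_nfev, ftol=tol, xtol=tol, gtol=tol,
    )
    dPe, dPo, k1, k2, k3 = res.x
    y = np.concatenate([pair.uninjected, pair.injected])
    sstot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(res.fun**2)) / sstot if sstot > 0 else float("nan")
    return Method2Params(
        k1=float(k1), k2=float(k2), k3=float(k3),
        dPe=float(dPe), dPo=float(dPo), t_L=t_L, r2=r2, gene="psmad",
    )


def fit_gene_method2(
    pair: PulsePair,
    psmad: Method2Params,
    x0: dict | None = None,
    max_nfev: int = METHOD2_GENE_MAXFEV,
    multistart: bool = True,
) -> Method2Params:
    """Stage 2: fit (dTe, dTo, k4, k5, sigma, lambda) to the transcript arms.

    Unconstrained (negative rate constants are admissible and must survive
    reporting); the pSmad parameters come fixed from stage 1.  R^2 is
    computed over the concatenated two-arm residuals, analogous to the
    Method-1 formula.

    The six-parameter surface has local minima; with ``multistart`` the
    default initial guess is supplemented by a small deterministic grid of
    alternative (k5, lambda) starting rates and the lowest-SSD solution is
    returned.
    """
    guesses = dict(METHOD2_GENE_X0)
    if x0:
        guesses.update(x0)
    theta0 = [guesses[k] for k in ("dTe", "dTo", "k4", "k5", "sigma", "lam")]

    def residuals(theta):
        dTe, dTo, k4, k5, sigma, lam = theta
        p = replace(
            psmad, k4=k4, k5=k5, sigma=sigma, lam=lam, dTe=dTe, dTo=dTo,
            gene=pair.signal,
        )
        try:
            p.validate()
        except DegenerateSolutionError:
            return np.full(2 * pair.times_s.size, 1e12)
        _, _, Te, To = eval_method2_analytic(p, pair.times_s)
        return np.concatenate([pair.uninjected - Te, pair.injected - (Te + To)])

    starts = [theta0]
    if multistart:
        for k5_0 in (0.0005, 0.005):
            for lam_0 in (0.0005, 0.005):
                alt = dict(guesses, k5=k5_0, lam=lam_0)
                starts.append(
                    [alt[k] for k in ("dTe", "dTo", "k4", "k5", "sigma", "lam")]
                )

    tol = _lsq_tols()
    res = None
    for start in starts:
        cand = least_squares(
            residuals, start, method="trf", x_scale="jac",
            max_nfev=max_nfev, ftol=tol, xtol=tol, gtol=tol,
        )
        if res is None or cand.cost < res.cost:
            res = cand
    dTe, dTo, k4, k5, sigma, lam = res.x
    y = np.concatenate([pair.uninjected, pair.injected])
    sstot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(res.fun**2)) / sstot if sstot > 0 else float("nan")
    return replace(
        psmad,
        k4=float(k4), k5=float(k5), sigma=float(sigma), lam=float(lam),
        dTe=float(dTe), dTo=float(dTo), r2=r2, gene=pair.signal,
    )
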