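"""Temporal transcript time courses: erf-CDF regression and activation times.

Normalized transcript counts sampled every 30 min across late blastula and
gastrula stages rise sigmoidally; the shape is well approximated by a scaled
normal CDF

    c(t) = (A/2) * (1 + erf((t - nu) / (tau * sqrt(2)))) + b

with amplitude A, inflection point nu (hpf), width tau (hpf) and baseline b.
The activation time of a gene is the point where the rising curve is about
two mean average deviations before the inflection, t_act = nu - 1.5*tau.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import erf

from ._optim import nelder_mead_box
from .errors import InsufficientDataError, InvalidInputError

__all__ = [
    "TemporalSeries",
    "CdfFit",
    "cdf_model",
    "fit_cdf",
    "activation_time",
    "summarize_activation",
]

# Fit settings: initial guesses (A, nu, tau, b) and box bounds.
CDF_X0 = (1000.0, 5.0, 1.0, 100.0)
CDF_BOUNDS = ((100.0, 10000.0), (3.0, 7.0), (0.05, 3.0), (0.0, 1000.0))
CDF_MAXFEV = 10000
CDF_MAXITER = 5000

#: Multiple of tau subtracted from nu to define the activation time
#: (about two mean average deviations of a normal, 2*MAD/sigma ~ 1.6).
ACTIVATION_TAU_FACTOR = 1.5


@dataclass
class TemporalSeries:
    """Transcript counts over developmental time for one gene/condition/repeat."""

    gene: str
    condition: str
    repeat: int
    time_hpf: np.ndarray
    count: np.ndarray  # normalized counts, a.u.

    def __post_init__(self):
        self.time_hpf = np.asarray(self.time_hpf, dtype=float)
        self.count = np.asarray(self.count, dtype=float)
        if self.time_hpf.size != self.count.size:
            raise InvalidInputError("time and count differ in length")
        if not (np.diff(self.time_hpf) > 0).all():
            raise InvalidInputError("times must be strictly increasing")
        if not np.isfinite(self.count).all():
            raise InvalidInputError("counts must be finite")


@dataclass
class CdfFit:
    A: float  # a.u.
    nu: float  # hpf, inflection point
    tau: float  # hpf, width
    b: float  # a.u., baseline
    t_act: float  # hpf, nu - 1.5*tau
    ssd: float
    converged: bool
    gene: str = ""
    condition: str = ""
    repeat: int = 0


def cdf_model(t, A, nu, tau, b):
    """(A/2)(1 + erf((t - nu)/(tau*sqrt(2)))) + b."""
    t = np.asarray(t, dtype=float)
    return 0.5 * A * (1.0 + erf((t - nu) / (tau * np.sqrt(2.0)))) + b


def fit_cdf(series: TemporalSeries) -> CdfFit:
    """Bounded Nelder-Mead least-squares fit of the erf-CDF model.

    Initial guesses (1000, 5 h, 1 h, 100) inside boxes A in [100, 10000],
    nu in [3, 7] hpf, tau in [0.05, 3] hpf, b in [0, 1000]; at most 10000
    function evaluations and 5000 iterations.  A and tau are optimized in
    log space.
    """
    if series.time_hpf.size < 5:
        raise InsufficientDataError("need at least 5 timepoints")
    t, y = series.time_hpf, series.count

    def ssd(params):
        return float(np.sum((y - cdf_model(t, *params)) ** 2))

    # b's lower bound is 0, which log-space cannot represent; A/tau are the
    # decade-spanning parameters.
    res = nelder_mead_box(
        ssd, CDF_X0, CDF_BOUNDS,
        log_scale=[True, False, True, False],
        maxiter=CDF_MAXITER, maxfev=CDF_MAXFEV,
    )
    A, nu, tau, b = (float(v) for v in res.x)
    return CdfFit(
        A=A, nu=nu, tau=tau, b=b,
        t_act=activation_time(nu, tau),
        ssd=res.fun, converged=res.converged,
        gene=series.gene, condition=series.condition, repeat=series.repeat,
    )


def activation_time(nu_or_fit, tau: float | None = None) -> float:
    """Activation time t_act = nu - 1.5*tau (hpf).

    The early-side convention: rising curves cross the activation threshold
    1.5*tau *before* the inflection point.
    """
    if tau is None:
        fit = nu_or_fit
        nu, tau = fit.nu, fit.tau
    else:
        nu = nu_or_fit
    return float(nu - ACTIVATION_TAU_FACTOR * tau)


def summarize_activation(
    fits: Sequence[CdfFit],
    exclude_genes: Sequence[str] = (),
    compare_conditions: tuple[str, str] | None = None,
) -> pd.DataFrame:
    """Mean +/- standard error of t_act per gene x condition.

    ``exclude_genes`` removes maternally contributed genes whose early counts
    do not reflect zygotic activation.  With ``compare_conditions=(a, b)``,
    an equal-variance two-tailed t-test across repeats is added per gene
    (requires >= 2 repeats per arm).
    """
    rows = [
        {"gene": f.gene, "condition": f.condition, "repeat": f.repeat, "t_act": f.t_act}
        for f in fits
        if f.gene not in set(exclude_genes)
    ]
    if not rows:
        raise InsufficientDataError("no fits to summarize")
    df = pd.DataFrame(rows)
    out = (
        df.groupby(["gene", "condition"])["t_act"]
        .agg(mean_t_act="mean", sem_t_act="sem", n="count")
        .reset_index()
    )
    if compare_conditions is not None:
        from .stats import ttest_equal_var

        a, b = compare_conditions
        pvals = {}
        for gene, sub in df.groupby("gene"):
            xa = sub.loc[sub.condition == a, "t_act"].to_numpy()
            xb = sub.loc[sub.condition == b, "t_act"].to_numpy()
            if len(xa) < 2 or len(xb) < 2:
                raise InsufficientDataError(
                    f"gene {gene}: comparisons need >= 2 repeats per arm"
                )
            pvals[gene] = ttest_equal_var(xa, xb).p_value
        out[f"p_{a}_vs_{b}"] = out["gene"].map(pvals)
    return out
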