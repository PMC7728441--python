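"""Dorsal-ventral expression profiles: binning, background subtraction,
per-embryo affine normalization, Gaussian fitting, and expression ranges.

Positions run along the dorsal-ventral axis in percent embryo length
(ventral = 0, dorsal = 100).  Raw input is a per-embryo column-average
intensity trace; the pipeline averages it into 0.5%-wide bins, subtracts
background (a spatial control-embryo average for FISH, a scalar image or
dorsal-reference value for immunofluorescence), trims the unreliable outer
5% on each side, rescales each embryo onto the across-embryo mean shape
with an affine model I_n(x) = A_n*cbar(x) + b_n, and fits a Gaussian
A*exp(-(x-mu)^2/s) whose expression range is r = mu + sqrt(s/2) — the
position where the fitted curve has fallen to exp(-1/2) of its peak.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from ._optim import nelder_mead_box
from .errors import (
    DegenerateSolutionError,
    GridMismatchError,
    InsufficientDataError,
    InvalidInputError,
)

__all__ = [
    "BIN_WIDTH_PCT",
    "RawColumnProfile",
    "SpatialProfile",
    "BackgroundModel",
    "NormalizationFit",
    "GaussianFit",
    "standard_bin_centers",
    "bin_profile",
    "subtract_background",
    "dorsal_reference_value",
    "trim_edges",
    "fit_embryo_scaling",
    "normalize_profile",
    "gaussian_model",
    "fit_gaussian",
    "compute_range",
    "margin_expression",
    "mean_display_profile",
]

#: Bin width along the dorsal-ventral axis, in % embryo length.
BIN_WIDTH_PCT = 0.5

# Gaussian fit settings: initial guess (A, mu, s) and box bounds.
GAUSSIAN_X0 = (300.0, 20.0, 10000.0)
GAUSSIAN_BOUNDS = ((300.0, 100000.0), (-50.0, 50.0), (100.0, 100000.0))
GAUSSIAN_MAXFEV = 10000
GAUSSIAN_MAXITER = 5000


def standard_bin_centers(bin_width: float = BIN_WIDTH_PCT) -> np.ndarray:
    """Centers of the standard bin grid covering (0, 100]% embryo length."""
    n = int(round(100.0 / bin_width))
    return (np.arange(n) + 0.5) * bin_width


@dataclass
class RawColumnProfile:
    """Column-average intensities of one embryo before binning."""

    gene_or_signal: str
    embryo_id: str
    positions: np.ndarray  # % embryo length, ventral = 0
    intensities: np.ndarray  # a.u.
    orientation_known: bool = True

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.positions.size != self.intensities.size:
            raise InvalidInputError("positions and intensities differ in length")
        if self.positions.size < 2:
            raise InvalidInputError("need at least 2 columns")
        if ((self.positions < 0) | (self.positions > 100)).any():
            raise InvalidInputError("positions must lie in [0, 100]% embryo length")
        if not np.isfinite(self.intensities).all():
            raise InvalidInputError("intensities must be finite")


@dataclass
class SpatialProfile:
    """Binned dorsal-ventral profile; empty bins carry NaN, never zero."""

    gene_or_signal: str
    embryo_id: str
    bin_centers: np.ndarray  # % embryo length, strictly increasing
    bin_means: np.ndarray  # a.u.; NaN where no column contributed
    bin_counts: np.ndarray  # columns per bin

    def __post_init__(self):
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        self.bin_means = np.asarray(self.bin_means, dtype=float)
        self.bin_counts = np.asarray(self.bin_counts, dtype=int)
        if not (np.diff(self.bin_centers) > 0).all():
            raise InvalidInputError("bin centers must be strictly increasing")
        if not (self.bin_centers.size == self.bin_means.size == self.bin_counts.size):
            raise InvalidInputError("bin arrays differ in length")

    @property
    def valid(self) -> np.ndarray:
        return ~np.isnan(self.bin_means)

    def replace_means(self, means: np.ndarray) -> "SpatialProfile":
        return SpatialProfile(
            self.gene_or_signal, self.embryo_id,
            self.bin_centers.copy(), np.asarray(means, dtype=float),
            self.bin_counts.copy(),
        )


@dataclass
class BackgroundModel:
    """One of three background conventions.

    ``profile``: position-wise average of non-probe-exposed control embryos
    (FISH).  ``scalar``: mean of a small image-corner ROI (IF).
    ``dorsal_reference``: mean of the dorsal-most 5% at the earliest
    timepoint, subtracted uniformly (pSmad IF time courses).
    """

    mode: Literal["profile", "scalar", "dorsal_reference"]
    profile_background: np.ndarray | None = None  # a.u. per bin
    background_bin_centers: np.ndarray | None = None
    scalar_background: float | None = None  # a.u.
    dorsal_reference: float | None = None  # a.u.

    def __post_init__(self):
        provided = {
            "profile": self.profile_background is not None,
            "scalar": self.scalar_background is not None,
            "dorsal_reference": self.dorsal_reference is not None,
        }
        if not provided.get(self.mode, False):
            raise InvalidInputError(f"mode {self.mode!r} lacks its payload")
        if sum(provided.values()) != 1:
            raise InvalidInputError("exactly one background mode may carry a value")
        if self.mode == "profile":
            self.profile_background = np.asarray(self.profile_background, dtype=float)
            if self.background_bin_centers is not None:
                self.background_bin_centers = np.asarray(
                    self.background_bin_centers, dtype=float
                )


@dataclass
class NormalizationFit:
    """Across-embryo mean shape and per-embryo affine coefficients."""

    bin_centers: np.ndarray
    mean_profile: np.ndarray  # cbar(x), a.u.
    scale: dict = field(default_factory=dict)  # embryo_id -> A_n
    offset: dict = field(default_factory=dict)  # embryo_id -> b_n
    objective: float = 0.0  # summed squared residuals, a.u.^2


@dataclass
class GaussianFit:
    """Bounded Gaussian fit of one normalized profile.

    ``s`` is the width parameter of exp(-(x-mu)^2/s); it equals
    2*sigma^2 of the usual parameterization, hence range = mu + sqrt(s/2).
    """

    A: float  # a.u.
    mu: float  # % embryo length
    s: float  # (% embryo length)^2
    range: float  # % embryo length
    ssd: float  # a.u.^2
    converged: bool


def bin_profile(raw: RawColumnProfile, bin_width: float = BIN_WIDTH_PCT) -> SpatialProfile:
    """Average raw columns into half-open bins (lo, hi] of ``bin_width``.

    A column at exactly position 0 joins the first bin.  Bins receiving no
    column are NaN.
    """
    n_bins = int(round(100.0 / bin_width))
    idx = np.ceil(raw.positions / bin_width).astype(int) - 1
    idx[raw.positions <= 0] = 0
    idx = np.minimum(idx, n_bins - 1)
    sums = np.bincount(idx, weights=raw.intensities, minlength=n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return SpatialProfile(
        raw.gene_or_signal, raw.embryo_id,
        standard_bin_centers(bin_width), means, counts,
    )


def dorsal_reference_value(profile: SpatialProfile, dorsal_pct: float = 5.0) -> float:
    """Mean intensity over the dorsal-most ``dorsal_pct``% of the axis."""
    mask = profile.bin_centers >= 100.0 - dorsal_pct
    vals = profile.bin_means[mask & profile.valid]
    if vals.size == 0:
        raise InsufficientDataError("no populated bins in the dorsal window")
    return float(vals.mean())


def subtract_background(profile: SpatialProfile, bg: BackgroundModel) -> SpatialProfile:
    """Subtract background; values may legitimately go negative."""
    if bg.mode == "profile":
        if bg.profile_background.size != profile.bin_centers.size:
            raise GridMismatchError("background profile not on the target bin grid")
        if bg.background_bin_centers is not None and not np.allclose(
            bg.background_bin_centers, profile.bin_centers
        ):
            raise GridMismatchError("background bin centers differ from target grid")
        return profile.replace_means(profile.bin_means - bg.profile_background)
    value = bg.scalar_background if bg.mode == "scalar" else bg.dorsal_reference
    return profile.replace_means(profile.bin_means - value)


def trim_edges(profile: SpatialProfile, trim_pct: float = 5.0) -> SpatialProfile:
    """Drop bins whose centers fall in the outer ``trim_pct`` on either end."""
    if not 0 <= trim_pct < 50:
        raise InvalidInputError("trim_pct must lie in [0, 50)")
    keep = (profile.bin_centers >= trim_pct) & (profile.bin_centers <= 100.0 - trim_pct)
    return SpatialProfile(
        profile.gene_or_signal, profile.embryo_id,
        profile.bin_centers[keep], profile.bin_means[keep], profile.bin_counts[keep],
    )


def fit_embryo_scaling(profiles: Sequence[SpatialProfile]) -> NormalizationFit:
    """Fit I_n(x) = A_n*cbar(x) + b_n per embryo against the mean shape.

    cbar(x) is the across-embryo arithmetic mean at each bin (over embryos
    with data there).  The objective sum_i (I_n(x_i) - A_n*cbar(x_i) - b_n)^2
    is quadratic in (A_n, b_n), so the minimizer is computed in closed form
    (simple linear regression of I_n on cbar); missing bins are excluded.
    """
    if len(profiles) < 2:
        raise InsufficientDataError("need at least 2 embryos")
    grid = profiles[0].bin_centers
    for p in profiles[1:]:
        if p.bin_centers.size != grid.size or not np.allclose(p.bin_centers, grid):
            raise GridMismatchError("embryo profiles are not on a shared grid")
    stack = np.vstack([p.bin_means for p in profiles])
    with np.errstate(invalid="ignore"):
        cbar = np.nanmean(stack, axis=0)

    fit = NormalizationFit(bin_centers=grid.copy(), mean_profile=cbar)
    total = 0.0
    for p in profiles:
        ok = p.valid & ~np.isnan(cbar)
        if ok.sum() < 2:
            raise InsufficientDataError(
                f"embryo {p.embryo_id}: fewer than 2 bins overlap the mean shape"
            )
        x = cbar[ok]
        y = p.bin_means[ok]
        design = np.column_stack([x, np.ones_like(x)])
        (a_n, b_n), *_ = np.linalg.lstsq(design, y, rcond=None)
        fit.scale[p.embryo_id] = float(a_n)
        fit.offset[p.embryo_id] = float(b_n)
        total += float(np.sum((y - a_n * x - b_n) ** 2))
    fit.objective = total
    return fit


def normalize_profile(profile: SpatialProfile, fit: NormalizationFit) -> SpatialProfile:
    """Invert the affine model: (I_n(x) - b_n) / A_n."""
    if profile.embryo_id not in fit.scale:
        raise InvalidInputError(f"no normalization entry for embryo {profile.embryo_id}")
    a_n = fit.scale[profile.embryo_id]
    b_n = fit.offset[profile.embryo_id]
    if a_n == 0:
        raise DegenerateSolutionError("embryo scale A_n = 0 cannot be inverted")
    return profile.replace_means((profile.bin_means - b_n) / a_n)


def gaussian_model(x, A: float, mu: float, s: float):
    """A * exp(-(x - mu)^2 / s); s = 2*sigma^2 in the usual notation."""
    x = np.asarray(x, dtype=float)
    return A * np.exp(-((x - mu) ** 2) / s)


def fit_gaussian(profile: SpatialProfile) -> GaussianFit:
    """Bounded Nelder-Mead Gaussian fit of a normalized profile.

    Starts from (A, mu, s) = (300, 20, 10000) inside the boxes
    A in [300, 1e5], mu in [-50, 50], s in [100, 1e5]; at most 10000
    function evaluations and 5000 iterations.  A and s are optimized in
    log space (their boxes span decades).
    """
    ok = profile.valid
    if ok.sum() < 4:
        raise InsufficientDataError("need at least 4 populated bins")
    x = profile.bin_centers[ok]
    y = profile.bin_means[ok]

    def ssd(params):
        return float(np.sum((y - gaussian_model(x, *params)) ** 2))

    res = nelder_mead_box(
        ssd, GAUSSIAN_X0, GAUSSIAN_BOUNDS,
        log_scale=[True, False, True],
        maxiter=GAUSSIAN_MAXITER, maxfev=GAUSSIAN_MAXFEV,
    )
    A, mu, s = res.x
    return GaussianFit(
        A=float(A), mu=float(mu), s=float(s),
        range=compute_range(mu, s), ssd=res.fun, converged=res.converged,
    )


def compute_range(mu_or_fit, s: float | None = None) -> float:
    """Expression range r = mu + sqrt(s/2), in % embryo length.

    This is the dorsal position where the fitted Gaussian drops to
    exp(-1/2) of its peak (one sigma beyond the peak when s = 2*sigma^2).
    """
    if s is None:
        fit = mu_or_fit
        mu, s = fit.mu, fit.s
    else:
        mu = mu_or_fit
    return float(mu + np.sqrt(s / 2.0))


def margin_expression(profile: SpatialProfile, lo: float = 5.0, hi: float = 10.0) -> float:
    """Mean normalized intensity over bins with centers in [lo, hi]%."""
    if not lo < hi:
        raise InvalidInputError("window requires lo < hi")
    mask = (profile.bin_centers >= lo) & (profile.bin_centers <= hi) & profile.valid
    if not mask.any():
        raise InsufficientDataError("no populated bins in the margin window")
    return float(profile.bin_means[mask].mean())


def mean_display_profile(profiles: Sequence[SpatialProfile]) -> SpatialProfile:
    """Position-wise average of normalized profiles, scaled to peak 1.

    Display-layer convention only; statistics operate on the un-max-scaled
    normalized profiles.
    """
    grid = profiles[0].bin_centers
    for p in profiles[1:]:
        if not np.allclose(p.bin_centers, grid):
            raise GridMismatchError("profiles are not on a shared grid")
    stack = np.vstack([p.bin_means for p in profiles])
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(stack, axis=0)
    peak = np.nanmax(mean)
    if not np.isfinite(peak) or peak == 0:
        raise DegenerateSolutionError("mean profile has no positive peak")
    counts = np.sum(~np.isnan(stack), axis=0)
    return SpatialProfile(
        profiles[0].gene_or_signal, "mean", grid.copy(), mean / peak, counts
    )
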