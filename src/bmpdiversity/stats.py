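"""Cross-gene diversity statistics, significance testing, housekeeping
normalization, and report assembly.

The spatial coefficient of variation quantifies how diverse the normalized
expression profiles of different genes are at each dorsal-ventral position:
cv(x) = sigma(x)/mu(x) with the across-gene mean mu(x) and n-1 sample SD
sigma(x).  A condition that homogenizes target-gene patterns (e.g. joint
FGF/Nodal inhibition) lowers cv(x) across the axis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import GridMismatchError, InsufficientDataError, InvalidInputError
from .spatial import SpatialProfile

__all__ = [
    "CvProfile",
    "TTestResult",
    "spatial_cv",
    "ttest_equal_var",
    "significance_table",
    "housekeeping_normalize",
    "build_report",
]

ALPHA = 0.05  # significance threshold on raw p-values (no multiplicity correction)


@dataclass
class CvProfile:
    """Position-wise across-gene coefficient of variation for one condition."""

    condition: str
    bin_centers: np.ndarray  # % embryo length
    mu_x: np.ndarray  # a.u., across-gene mean
    sigma_x: np.ndarray  # a.u., across-gene n-1 SD
    cv_x: np.ndarray  # dimensionless; NaN where mu_x <= 0


@dataclass
class TTestResult:
    t: float
    df: int
    p_value: float
    degenerate_variance: bool = False


def spatial_cv(mean_profiles: Sequence[SpatialProfile], condition: str) -> CvProfile:
    """cv(x) = sigma(x)/mu(x) across one mean profile per gene.

    Positions where the across-gene mean is non-positive carry NaN rather
    than a signed or infinite ratio.
    """
    if len(mean_profiles) < 2:
        raise InsufficientDataError("need at least 2 genes")
    grid = mean_profiles[0].bin_centers
    for p in mean_profiles[1:]:
        if p.bin_centers.size != grid.size or not np.allclose(p.bin_centers, grid):
            raise GridMismatchError("gene profiles are not on a shared grid")
    stack = np.vstack([p.bin_means for p in mean_profiles])
    mu = stack.mean(axis=0)
    sigma = stack.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mu > 0, sigma / mu, np.nan)
    return CvProfile(
        condition=condition, bin_centers=grid.copy(),
        mu_x=mu, sigma_x=sigma, cv_x=cv,
    )


def ttest_equal_var(a, b) -> TTestResult:
    """Unpaired two-tailed Student's t-test assuming equal variance.

    Degenerate zero-pooled-variance input yields p = 1 for equal means and
    p = 0 (flagged) for unequal means.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("each sample needs n >= 2")
    df = a.size + b.size - 2
    pooled = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / df
    if pooled == 0:
        if a.mean() == b.mean():
            return TTestResult(t=0.0, df=df, p_value=1.0, degenerate_variance=True)
        return TTestResult(
            t=float("inf") if a.mean() > b.mean() else float("-inf"),
            df=df, p_value=0.0, degenerate_variance=True,
        )
    res = sps.ttest_ind(a, b, equal_var=True)
    return TTestResult(t=float(res.statistic), df=df, p_value=float(res.pvalue))


def significance_table(rows: Sequence[Mapping]) -> pd.DataFrame:
    """Assemble (contrast, gene, timepoint, p_value) rows; flags p <= 0.05."""
    df = pd.DataFrame(rows, columns=["contrast", "gene", "timepoint", "p_value"])
    if ((df["p_value"] < 0) | (df["p_value"] > 1)).any():
        raise InvalidInputError("p-values must lie in [0, 1]")
    df["significant"] = df["p_value"] <= ALPHA
    return df


def _geomean(values: np.ndarray) -> float:
    return float(np.exp(np.mean(np.log(values))))


def housekeeping_normalize(
    raw_counts: pd.DataFrame,
    housekeeping: Sequence[str],
    positive_controls: Sequence[str],
) -> pd.DataFrame:
    """Lane-wise geometric-mean normalization of a lane x gene count table.

    Each lane is scaled by (grand geometric mean / lane geometric mean) of
    the reference gene set — positive spike-in controls first, then the
    housekeeping genes — so that afterwards every lane has the same
    reference geometric mean.  The composition is order-insensitive up to a
    global scale; the control-first order is the documented convention.
    """
    table = raw_counts.astype(float).copy()
    for refs in (positive_controls, housekeeping):
        refs = list(refs)
        missing = [g for g in refs if g not in table.columns]
        if missing:
            raise InvalidInputError(f"reference genes absent from table: {missing}")
        ref_vals = table[refs].to_numpy()
        if (ref_vals <= 0).any():
            raise InvalidInputError("reference counts must be positive in every lane")
        lane_gm = np.exp(np.mean(np.log(ref_vals), axis=1))
        grand_gm = _geomean(lane_gm)
        table = table.mul(grand_gm / lane_gm, axis=0)
    return table


def build_report(
    out_dir,
    tables: Mapping[str, pd.DataFrame] | None = None,
    cv_profiles: Sequence[CvProfile] = (),
    manifest_extra: Mapping | None = None,
) -> Path:
    """Write result tables as CSV plus a provenance manifest JSON.

    Returns the manifest path.  Optional sections that are absent are listed
    as such in the manifest so a report is self-describing.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = {}
    for name, df in (tables or {}).items():
        path = out_dir / f"{name}.csv"
        df.to_csv(path, index=False)
        written[name] = path.name
    if cv_profiles:
        rows = []
        for cp in cv_profiles:
            for x, m, s, c in zip(cp.bin_centers, cp.mu_x, cp.sigma_x, cp.cv_x):
                rows.append((cp.condition, x, m, s, c))
        cv_df = pd.DataFrame(
            rows, columns=["condition", "position_pct", "mu", "sigma", "cv"]
        )
        cv_path = out_dir / "spatial_cv.csv"
        cv_df.to_csv(cv_path, index=False)
        written["spatial_cv"] = cv_path.name

    import bmpdiversity

    manifest = {
        "package": "bmpdiversity",
        "version": bmpdiversity.__version__,
        "tables": written or "absent",
        "cv_profiles": [cp.condition for cp in cv_profiles] or "absent",
    }
    if manifest_extra:
        manifest.update(manifest_extra)
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest_path
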