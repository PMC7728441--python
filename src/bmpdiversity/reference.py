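"""Bundled reference tables from the optogenetic zebrafish BMP study.

``method1_repeat_fits`` holds the published per-repeat induction-decay fits
(sigma, lambda, To(0), R^2) for the 14 high-confidence BMP target genes
across the three experimental repeats.  Averaging these per-repeat values
gene-wise (mean and n-1 sample SD) yields the study's across-repeat summary
table; see :func:`bmpdiversity.kinetics.summarize_repeats`.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["method1_repeat_fits", "method1_repeat_fits_as_method1"]


def method1_repeat_fits() -> pd.DataFrame:
    """Per-repeat Method-1 fitted values: gene, repeat, sigma, lam, To0, r2."""
    with resources.files("bmpdiversity.data").joinpath(
        "method1_repeat_fits.csv"
    ).open() as fh:
        return pd.read_csv(fh)


def method1_repeat_fits_as_method1():
    """The same table as a list of :class:`~bmpdiversity.kinetics.Method1Fit`."""
    from .kinetics import Method1Fit

    return [
        Method1Fit(
            sigma=row.sigma, lam=row.lam, To0=row.To0,
            ssd_min=float("nan"), r2=row.r2, converged=True,
            gene=row.gene, repeat=int(row.repeat),
        )
        for row in method1_repeat_fits().itertuples()
    ]
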