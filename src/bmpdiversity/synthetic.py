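"""Synthetic datasets with the statistical structure the analysis assumes.

Three dataset families mirror the study designs:

* spatial — bell-shaped dorsal-ventral FISH/IF profiles with embryo-specific
  affine scaling I_n(x) = A_n*G(x) + b_n plus additive Gaussian noise;
* temporal — sigmoidal (erf-CDF) transcript onsets sampled every 30 min from
  2.75 to 7.25 hpf, one series per experimental repeat;
* pulse — sibling-paired pSmad and transcript responses to a 30-min light
  pulse, generated from the closed-form 4-ODE Heaviside-pulse model on the
  10-point post-exposure grid.

Every dataset is generated from an explicit :class:`GroundTruth`, which
travels with the data so estimator-recovery tests can compare fitted
parameters against the values that produced the observations.  All noise
derives from one root seed via spawned substreams, so identical
(truth, design, seed) triples give bit-identical datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .errors import InvalidParameterError
from .kinetics import (
    PULSE_LENGTH_S,
    Method2Params,
    PulsePair,
    eval_method2_analytic,
    minutes_post_exposure_to_seconds,
)
from .spatial import SpatialProfile, gaussian_model, standard_bin_centers
from .temporal import TemporalSeries, cdf_model

__all__ = [
    "DEFAULT_TEMPORAL_GRID_HPF",
    "DEFAULT_PULSE_GRID_MIN",
    "SyntheticDesign",
    "SpatialTruth",
    "CdfTruth",
    "GeneKineticTruth",
    "PSmadTruth",
    "GroundTruth",
    "PulseExperiment",
    "default_truth",
    "gen_spatial_embryos",
    "gen_temporal_series",
    "gen_pulse_experiment",
]

#: Developmental sampling grid: every 30 min from 2.75 to 7.25 hpf.
DEFAULT_TEMPORAL_GRID_HPF = tuple(np.arange(2.75, 7.26, 0.5))
#: Pulse sampling grid in minutes post-exposure (light OFF at 0).
DEFAULT_PULSE_GRID_MIN = (-30.0, -20.0, -10.0, 0.0, 10.0, 20.0, 35.0, 55.0, 80.0, 110.0)


@dataclass
class SyntheticDesign:
    """Experimental design shared by the three synthetic dataset families.

    Noise SDs are additive Gaussian standard deviations in the same arbitrary
    units as the signals; 20 a.u. is about 2% of a typical ~1000 a.u. peak.
    """

    timepoints_temporal: tuple = DEFAULT_TEMPORAL_GRID_HPF  # hpf
    timepoints_pulse: tuple = DEFAULT_PULSE_GRID_MIN  # min post-exposure
    pulse_length_s: float = PULSE_LENGTH_S
    n_repeats: int = 3
    n_embryos: int = 10
    noise_sd_counts: float = 20.0  # a.u.
    noise_sd_intensity: float = 20.0  # a.u.
    seed: int = 0

    def __post_init__(self):
        for grid, name in (
            (self.timepoints_temporal, "timepoints_temporal"),
            (self.timepoints_pulse, "timepoints_pulse"),
        ):
            if len(grid) < 2 or not (np.diff(grid) > 0).all():
                raise InvalidParameterError(f"{name} must be strictly increasing")
        if self.pulse_length_s <= 0:
            raise InvalidParameterError("pulse_length_s must be positive")
        if self.n_repeats < 1 or self.n_embryos < 1:
            raise InvalidParameterError("n_repeats and n_embryos must be >= 1")
        if self.noise_sd_counts < 0 or self.noise_sd_intensity < 0:
            raise InvalidParameterError("noise SDs must be non-negative")

    @property
    def pulse_times_s(self) -> np.ndarray:
        """Model time (s after light onset) of the pulse grid."""
        return minutes_post_exposure_to_seconds(
            np.asarray(self.timepoints_pulse), self.pulse_length_s
        )


@dataclass
class SpatialTruth:
    A: float  # a.u. peak amplitude
    mu: float  # % embryo length
    s: float  # (% embryo length)^2, width parameter (2*sigma^2)


@dataclass
class CdfTruth:
    A: float  # a.u.
    nu: float  # hpf
    tau: float  # hpf
    b: float  # a.u.


@dataclass
class GeneKineticTruth:
    k4: float  # 1/s
    k5: float  # 1/s
    sigma: float  # 1/s
    lam: float  # 1/s
    dTe: float  # a.u.
    dTo: float  # a.u.


@dataclass
class PSmadTruth:
    k1: float  # a.u./s
    k2: float  # 1/s
    k3: float  # a.u./s
    dPe: float  # a.u.
    dPo: float  # a.u.


@dataclass
class GroundTruth:
    """Everything needed to simulate the three dataset families."""

    spatial: dict[str, SpatialTruth] = field(default_factory=dict)
    embryo_scale: tuple = ()  # A_n per embryo, dimensionless
    embryo_offset: tuple = ()  # b_n per embryo, a.u.
    cdf: dict[str, CdfTruth] = field(default_factory=dict)
    kinetics: dict[str, GeneKineticTruth] = field(default_factory=dict)
    psmad: PSmadTruth = field(
        default_factory=lambda: PSmadTruth(
            k1=0.1429, k2=0.000900, k3=0.954, dPe=-76.19, dPo=264.1
        )
    )

    def method2_params(self, gene: str, t_L: float = PULSE_LENGTH_S) -> Method2Params:
        g = self.kinetics[gene]
        p = self.psmad
        return Method2Params(
            k1=p.k1, k2=p.k2, k3=p.k3, k4=g.k4, k5=g.k5,
            sigma=g.sigma, lam=g.lam,
            dPe=p.dPe, dPo=p.dPo, dTe=g.dTe, dTo=g.dTo,
            t_L=t_L, gene=gene,
        )

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PulseExperiment:
    """Sibling-paired pulse-response dataset with repeat structure."""

    psmad: list[PulsePair]  # one pair per repeat
    genes: dict[str, list[PulsePair]]  # gene -> one pair per repeat
    times_s: np.ndarray
    pulse_length_s: float
    truth: GroundTruth | None = None


def default_truth(design: SyntheticDesign) -> GroundTruth:
    """Study-condition ground truth.

    pSmad pulse parameters are the best-fit values of the optogenetic
    experiments (k1 = 0.1429 a.u./s, k2 = 0.000900/s, k3 = 0.954 a.u./s,
    dPe = -76.19, dPo = 264.1); the reference gene's induction-decay
    parameters follow the bambia closed-form fit (sigma = 0.000327/s,
    lambda = 0.000671/s, dTe = 520.4, dTo = 16.01).  k4 and k5 are set to
    plausible transcript activation/decay rates (0.001/s, 0.0005/s) that
    put endogenous counts on the NanoString scale of hundreds of a.u.
    Embryo-specific spatial scales A_n are log-normal around 1 (sd 0.2 in
    log space) and offsets b_n are N(0, 10 a.u.), drawn once from the
    design seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence(design.seed).spawn(1)[0])
    scale = np.exp(rng.normal(0.0, 0.2, size=design.n_embryos))
    offset = rng.normal(0.0, 10.0, size=design.n_embryos)
    return GroundTruth(
        spatial={
            "sizzled": SpatialTruth(A=2000.0, mu=20.0, s=8000.0),
            "bambia": SpatialTruth(A=1500.0, mu=10.0, s=3000.0),
            "foxi1": SpatialTruth(A=800.0, mu=15.0, s=1200.0),
        },
        embryo_scale=tuple(scale),
        embryo_offset=tuple(offset),
        cdf={
            "sizzled": CdfTruth(A=2000.0, nu=5.5, tau=0.5, b=50.0),
            "bambia": CdfTruth(A=3000.0, nu=4.5, tau=0.8, b=100.0),
            "ved": CdfTruth(A=1500.0, nu=4.0, tau=0.4, b=80.0),
        },
        kinetics={
            "bambia": GeneKineticTruth(
                k4=0.001, k5=0.0005, sigma=0.000327, lam=0.000671,
                dTe=520.4, dTo=16.01,
            ),
        },
    )


def _streams(seed: int, n: int):
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def gen_spatial_embryos(
    truth: GroundTruth, design: SyntheticDesign, genes: Sequence[str] | None = None
) -> list[SpatialProfile]:
    """Per-embryo spatial profiles on the standard 0.5% bin grid.

    Embryo n of gene g has expected intensity A_n * G_g(x) + b_n with
    additive N(0, noise_sd_intensity) noise; one RNG substream per
    (gene, embryo) in fixed order.
    """
    genes = list(genes) if genes is not None else sorted(truth.spatial)
    if len(truth.embryo_scale) != design.n_embryos:
        raise InvalidParameterError(
            "truth carries embryo scales for a different n_embryos"
        )
    for g in genes:
        st = truth.spatial[g]
        if st.s <= 0:
            raise InvalidParameterError(f"{g}: width parameter s must be positive")
        if not 0 <= st.mu <= 100:
            raise InvalidParameterError(f"{g}: mu must lie within the position domain")
    if any(a <= 0 for a in truth.embryo_scale):
        raise InvalidParameterError("embryo scales A_n must be positive")

    x = standard_bin_centers()
    rngs = iter(_streams(design.seed, len(genes) * design.n_embryos))
    profiles = []
    for g in genes:
        st = truth.spatial[g]
        shape = gaussian_model(x, st.A, st.mu, st.s)
        for n in range(design.n_embryos):
            rng = next(rngs)
            noise = rng.normal(0.0, design.noise_sd_intensity, size=x.size)
            profiles.append(
                SpatialProfile(
                    gene_or_signal=g, embryo_id=f"embryo{n + 1:02d}",
                    bin_centers=x.copy(),
                    bin_means=truth.embryo_scale[n] * shape
                    + truth.embryo_offset[n] + noise,
                    bin_counts=np.ones(x.size, dtype=int),
                )
            )
    return profiles


def gen_temporal_series(
    truth: GroundTruth,
    design: SyntheticDesign,
    condition: str = "untreated",
) -> list[TemporalSeries]:
    """Per-repeat erf-CDF transcript time courses with additive count noise."""
    genes = sorted(truth.cdf)
    for g in genes:
        ct = truth.cdf[g]
        if ct.tau <= 0 or ct.A <= 0:
            raise InvalidParameterError(f"{g}: need tau > 0 and A > 0")
    t = np.asarray(design.timepoints_temporal, dtype=float)
    rngs = iter(_streams(design.seed, len(genes) * design.n_repeats))
    out = []
    for g in genes:
        ct = truth.cdf[g]
        expect = cdf_model(t, ct.A, ct.nu, ct.tau, ct.b)
        for r in range(design.n_repeats):
            rng = next(rngs)
            noise = rng.normal(0.0, design.noise_sd_counts, size=t.size)
            out.append(
                TemporalSeries(
                    gene=g, condition=condition, repeat=r + 1,
                    time_hpf=t.copy(), count=expect + noise,
                )
            )
    return out


def gen_pulse_experiment(
    truth: GroundTruth, design: SyntheticDesign
) -> PulseExperiment:
    """Sibling-paired pulse dataset from the closed-form 4-ODE model.

    Uninjected arms follow the endogenous channels Pe(t)/Te(t); injected
    arms follow Pe+Po and Te+To.  pSmad arms get N(0, noise_sd_intensity)
    noise, transcript arms N(0, noise_sd_counts), independently per repeat
    and arm.  Counts may go negative after noise or sibling subtraction; no
    clipping is applied.
    """
    genes = sorted(truth.kinetics)
    t = design.pulse_times_s
    # validate() raises for degenerate (k2 = lambda, k2 = k5) combinations
    params = {g: truth.method2_params(g, design.pulse_length_s) for g in genes}
    for p in params.values():
        p.validate()

    psmad_ref = Method2Params(
        k1=truth.psmad.k1, k2=truth.psmad.k2, k3=truth.psmad.k3,
        dPe=truth.psmad.dPe, dPo=truth.psmad.dPo, t_L=design.pulse_length_s,
    )
    Pe, Po, _, _ = eval_method2_analytic(psmad_ref, t)

    rngs = iter(_streams(design.seed, (1 + len(genes)) * design.n_repeats * 2))
    psmad_pairs = []
    for r in range(design.n_repeats):
        noise_u = next(rngs).normal(0.0, design.noise_sd_intensity, size=t.size)
        noise_i = next(rngs).normal(0.0, design.noise_sd_intensity, size=t.size)
        psmad_pairs.append(
            PulsePair(
                signal="psmad", repeat=r + 1, times_s=t.copy(),
                uninjected=Pe + noise_u, injected=Pe + Po + noise_i,
            )
        )

    gene_pairs: dict[str, list[PulsePair]] = {}
    for g in genes:
        _, _, Te, To = eval_method2_analytic(params[g], t)
        pairs = []
        for r in range(design.n_repeats):
            noise_u = next(rngs).normal(0.0, design.noise_sd_counts, size=t.size)
            noise_i = next(rngs).normal(0.0, design.noise_sd_counts, size=t.size)
            pairs.append(
                PulsePair(
                    signal=g, repeat=r + 1, times_s=t.copy(),
                    uninjected=Te + noise_u, injected=Te + To + noise_i,
                )
            )
        gene_pairs[g] = pairs

    return PulseExperiment(
        psmad=psmad_pairs, genes=gene_pairs, times_s=t,
        pulse_length_s=design.pulse_length_s, truth=truth,
    )
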