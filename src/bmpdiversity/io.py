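"""Shared long-format CSV dialects and ground-truth serialization.

Column names are part of the public contract:

* profiles:  gene, embryo_id, position_pct, intensity
* temporal:  gene, condition, repeat, time_hpf, count
* pulse:     signal, condition, repeat, time_post_exposure_min, value
  (condition is 'uninjected' or 'injected'; timestamps are minutes after
  light OFF)

All files are UTF-8 comma-separated with a header row.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .kinetics import PulsePair, minutes_post_exposure_to_seconds
from .spatial import RawColumnProfile, SpatialProfile
from .synthetic import GroundTruth, PulseExperiment
from .temporal import TemporalSeries

__all__ = [
    "PROFILE_COLUMNS",
    "TEMPORAL_COLUMNS",
    "PULSE_COLUMNS",
    "write_profiles_csv",
    "read_profiles_csv",
    "write_temporal_csv",
    "read_temporal_csv",
    "write_pulse_csv",
    "read_pulse_csv",
    "write_truth_json",
]

PROFILE_COLUMNS = ["gene", "embryo_id", "position_pct", "intensity"]
TEMPORAL_COLUMNS = ["gene", "condition", "repeat", "time_hpf", "count"]
PULSE_COLUMNS = ["signal", "condition", "repeat", "time_post_exposure_min", "value"]


def _require_columns(df: pd.DataFrame, columns: Sequence[str], path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise InvalidInputError(f"{path}: missing column(s) {', '.join(missing)}")


def write_profiles_csv(profiles: Sequence[SpatialProfile], path) -> None:
    rows = []
    for p in profiles:
        for x, v in zip(p.bin_centers, p.bin_means):
            rows.append((p.gene_or_signal, p.embryo_id, x, v))
    pd.DataFrame(rows, columns=PROFILE_COLUMNS).to_csv(path, index=False)


def read_profiles_csv(path) -> list[RawColumnProfile]:
    df = pd.read_csv(path)
    _require_columns(df, PROFILE_COLUMNS, path)
    df = df.dropna(subset=["intensity"])
    out = []
    for (gene, embryo), sub in df.groupby(["gene", "embryo_id"], sort=True):
        sub = sub.sort_values("position_pct")
        out.append(
            RawColumnProfile(
                gene_or_signal=str(gene), embryo_id=str(embryo),
                positions=sub["position_pct"].to_numpy(),
                intensities=sub["intensity"].to_numpy(),
            )
        )
    return out


def write_temporal_csv(series: Sequence[TemporalSeries], path) -> None:
    rows = []
    for s in series:
        for t, c in zip(s.time_hpf, s.count):
            rows.append((s.gene, s.condition, s.repeat, t, c))
    pd.DataFrame(rows, columns=TEMPORAL_COLUMNS).to_csv(path, index=False)


def read_temporal_csv(path) -> list[TemporalSeries]:
    df = pd.read_csv(path)
    _require_columns(df, TEMPORAL_COLUMNS, path)
    out = []
    for (gene, cond, rep), sub in df.groupby(["gene", "condition", "repeat"], sort=True):
        sub = sub.sort_values("time_hpf")
        out.append(
            TemporalSeries(
                gene=str(gene), condition=str(cond), repeat=int(rep),
                time_hpf=sub["time_hpf"].to_numpy(),
                count=sub["count"].to_numpy(),
            )
        )
    return out


def write_pulse_csv(experiment: PulseExperiment, path) -> None:
    minutes = (experiment.times_s - experiment.pulse_length_s) / 60.0
    rows = []

    def emit(pairs):
        for p in pairs:
            for m, u, i in zip(minutes, p.uninjected, p.injected):
                rows.append((p.signal, "uninjected", p.repeat, m, u))
                rows.append((p.signal, "injected", p.repeat, m, i))

    emit(experiment.psmad)
    for gene in sorted(experiment.genes):
        emit(experiment.genes[gene])
    pd.DataFrame(rows, columns=PULSE_COLUMNS).to_csv(path, index=False)


def read_pulse_csv(path, pulse_length_s: float) -> PulseExperiment:
    df = pd.read_csv(path)
    _require_columns(df, PULSE_COLUMNS, path)
    psmad: list[PulsePair] = []
    genes: dict[str, list[PulsePair]] = {}
    times_s = None
    for (signal, rep), sub in df.groupby(["signal", "repeat"], sort=True):
        arms = {}
        for cond in ("uninjected", "injected"):
            arm = sub[sub.condition == cond].sort_values("time_post_exposure_min")
            if arm.empty:
                raise InvalidInputError(f"{path}: {signal} repeat {rep} lacks {cond} arm")
            arms[cond] = arm
        t_min = arms["uninjected"]["time_post_exposure_min"].to_numpy()
        if not np.array_equal(t_min, arms["injected"]["time_post_exposure_min"].to_numpy()):
            raise InvalidInputError(f"{path}: {signal} repeat {rep}: arm grids differ")
        t_s = minutes_post_exposure_to_seconds(t_min, pulse_length_s)
        pair = PulsePair(
            signal=str(signal), repeat=int(rep), times_s=t_s,
            uninjected=arms["uninjected"]["value"].to_numpy(),
            injected=arms["injected"]["value"].to_numpy(),
        )
        if str(signal) == "psmad":
            psmad.append(pair)
        else:
            genes.setdefault(str(signal), []).append(pair)
        times_s = t_s
    if times_s is None:
        raise InvalidInputError(f"{path}: no pulse data found")
    return PulseExperiment(
        psmad=psmad, genes=genes, times_s=times_s, pulse_length_s=pulse_length_s
    )


def write_truth_json(truth: GroundTruth, path) -> None:
    Path(path).write_text(json.dumps(truth.to_dict(), indent=2, sort_keys=True))
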