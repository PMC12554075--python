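"""Kinetic trace containers and stable on-disk formats.

A *kinetic trace* is one well's time-stamped BRET ratio series (the 530/470 nm
emission ratio, dimensionless) together with its experiment, well and
treatment-condition labels and the stimulation time.  Traces travel on disk as
long-format CSV with a fixed column order; analysis outputs travel as JSON
(full entropy spectrum per trace) plus long-format CSV.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: fixed CSV column order for trace files
TRACE_COLUMNS = ["experiment_id", "well_id", "condition", "time_s", "ratio", "stim_time_s"]

#: a trace must carry at least this many samples to be analyzable
MIN_SAMPLES = 10


class TraceFormatError(ValueError):
    """A trace file is structurally invalid (missing column, bad dialect)."""


class TraceValidationError(ValueError):
    """Trace content violates an invariant (non-monotone times, too short...)."""


@dataclass(frozen=True)
class KineticTrace:
    """One well's BRET ratio time series.

    Parameters
    ----------
    experiment_id, well_id, condition
        Labels identifying the independent experiment, the plate well and the
        treatment condition.
    times
        Sample times in seconds, strictly increasing.
    values
        BRET ratios (dimensionless), same length as ``times``, all finite.
    stim_time
        Ligand-addition time in seconds; samples at ``t >= stim_time`` form
        the post-stimulation segment.
    """

    experiment_id: str
    well_id: str
    condition: str
    times: np.ndarray
    values: np.ndarray
    stim_time: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.times.ndim != 1 or self.values.ndim != 1:
            raise TraceValidationError("times and values must be 1-D")
        if len(self.times) != len(self.values):
            raise TraceValidationError(
                f"times ({len(self.times)}) and values ({len(self.values)}) differ in length"
            )
        if len(self.times) < MIN_SAMPLES:
            raise TraceValidationError(
                f"trace ({self.experiment_id}, {self.well_id}) has {len(self.times)} "
                f"samples; at least {MIN_SAMPLES} required"
            )
        if not np.all(np.isfinite(self.values)) or not np.all(np.isfinite(self.times)):
            raise TraceValidationError(
                f"trace ({self.experiment_id}, {self.well_id}) contains non-finite entries"
            )
        if not np.all(np.diff(self.times) > 0):
            raise TraceValidationError(
                f"times not strictly increasing in well ({self.experiment_id}, {self.well_id})"
            )
        if not (0.0 <= self.stim_time <= float(self.times[-1])):
            raise TraceValidationError(
                f"stim_time {self.stim_time} outside [0, {self.times[-1]}] "
                f"for well ({self.experiment_id}, {self.well_id})"
            )

    def __len__(self) -> int:
        return len(self.times)

    def segment(self, which: str = "post_stim") -> np.ndarray:
        """Return the values of the requested segment.

        ``post_stim`` keeps samples at t >= stim_time, ``baseline`` keeps
        t < stim_time, ``full`` keeps everything.
        """
        if which == "full":
            return self.values
        if which == "post_stim":
            return self.values[self.times >= self.stim_time]
        if which == "baseline":
            return self.values[self.times < self.stim_time]
        raise ValueError(f"unknown segment {which!r}")

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.experiment_id, self.well_id, self.condition)


@dataclass
class ExperimentSet:
    """A collection of traces with the ordered condition/experiment label sets."""

    traces: list[KineticTrace]
    conditions: list[str] = field(default_factory=list)
    experiments: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.conditions:
            self.conditions = _ordered_unique(t.condition for t in self.traces)
        if not self.experiments:
            self.experiments = _ordered_unique(t.experiment_id for t in self.traces)
        present = {t.condition for t in self.traces}
        for cond in self.conditions:
            if self.traces and cond not in present:
                raise TraceValidationError(f"condition {cond!r} listed but has no traces")
        for t in self.traces:
            if t.condition not in self.conditions:
                raise TraceValidationError(f"trace condition {t.condition!r} not in condition set")
            if t.experiment_id not in self.experiments:
                raise TraceValidationError(
                    f"trace experiment {t.experiment_id!r} not in experiment set"
                )

    def __len__(self) -> int:
        return len(self.traces)

    def by_condition(self, condition: str) -> list[KineticTrace]:
        return [t for t in self.traces if t.condition == condition]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.traces:
            rows.append(
                pd.DataFrame(
                    {
                        "experiment_id": t.experiment_id,
                        "well_id": t.well_id,
                        "condition": t.condition,
                        "time_s": t.times,
                        "ratio": t.values,
                        "stim_time_s": t.stim_time,
                    }
                )
            )
        if not rows:
            return pd.DataFrame(columns=TRACE_COLUMNS)
        return pd.concat(rows, ignore_index=True)[TRACE_COLUMNS]


def _ordered_unique(items: Iterable[str]) -> list[str]:
    seen: dict[str, None] = {}
    for x in items:
        seen.setdefault(x, None)
    return list(seen)


def read_traces(path: str | Path) -> ExperimentSet:
    """Read a long-format trace CSV into an :class:`ExperimentSet`.

    Rows are grouped by (experiment_id, well_id, condition) and sorted by
    time within each well; every trace invariant is validated on the way in.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise TraceFormatError(f"{path}: missing required column(s): {', '.join(missing)}")
    if df.empty:
        return ExperimentSet(traces=[])

    traces = []
    for (exp, well, cond), grp in df.groupby(
        ["experiment_id", "well_id", "condition"], sort=False
    ):
        grp = grp.sort_values("time_s")
        times = grp["time_s"].to_numpy(dtype=float)
        if len(np.unique(times)) != len(times):
            raise TraceValidationError(
                f"{path}: duplicated time point in well ({exp}, {well}, {cond})"
            )
        stim = grp["stim_time_s"].to_numpy(dtype=float)
        if not np.all(stim == stim[0]):
            raise TraceValidationError(
                f"{path}: inconsistent stim_time_s within well ({exp}, {well}, {cond})"
            )
        traces.append(
            KineticTrace(
                experiment_id=str(exp),
                well_id=str(well),
                condition=str(cond),
                times=times,
                values=grp["ratio"].to_numpy(dtype=float),
                stim_time=float(stim[0]),
            )
        )
    return ExperimentSet(traces=traces)


def write_traces(exp_set: ExperimentSet, path: str | Path) -> None:
    """Write an :class:`ExperimentSet` as long-format CSV (inverse of read)."""
    df = exp_set.to_frame()
    if not df.empty and not np.all(np.isfinite(df["ratio"].to_numpy(dtype=float))):
        raise TraceValidationError("refusing to write non-finite BRET ratios")
    df.to_csv(path, index=False, float_format="%.17g")


def metrics_to_frame(spectra: Sequence["EntropySpectrum"]) -> pd.DataFrame:  # noqa: F821
    """Long-format table: one row per (trace, tau, metric)."""
    rows = []
    for s in spectra:
        base = {
            "experiment_id": s.experiment_id,
            "well_id": s.well_id,
            "condition": s.condition,
            "tau": s.tau,
        }
        rows.append({**base, "metric": "sampen", "alpha": math.nan, "value": s.sampen})
        rows.append({**base, "metric": "H0", "alpha": 0.0, "value": s.h0})
        for a, raw, norm in zip(s.alpha_grid, s.h_raw, s.h_norm):
            rows.append({**base, "metric": "H_raw", "alpha": a, "value": raw})
            rows.append({**base, "metric": "H_norm", "alpha": a, "value": norm})
    cols = ["experiment_id", "well_id", "condition", "tau", "metric", "alpha", "value"]
    return pd.DataFrame(rows, columns=cols)


def comparisons_to_frame(comparisons: Sequence["ConditionComparison"]) -> pd.DataFrame:  # noqa: F821
    rows = [c.to_dict() for c in comparisons]
    cols = [
        "metric",
        "condition_a",
        "condition_b",
        "n",
        "mean_diff",
        "sd_diff",
        "t_stat",
        "df",
        "p_value",
        "ci_low",
        "ci_high",
        "n_boot",
        "seed",
    ]
    return pd.DataFrame(rows, columns=cols)


def write_metrics(
    spectra: Sequence["EntropySpectrum"],  # noqa: F821
    comparisons: Sequence["ConditionComparison"],  # noqa: F821
    out_prefix: str | Path,
) -> dict[str, Path]:
    """Write the metrics table and comparisons as JSON + CSV.

    ``out_prefix`` is extended to ``<prefix>_metrics.json``,
    ``<prefix>_metrics.csv`` and ``<prefix>_comparisons.csv``.  The JSON keeps
    the full alpha grid per trace; numbers are serialized with 17 significant
    digits so a round-trip is exact to double precision.
    """
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "metrics_json": out_prefix.with_name(out_prefix.name + "_metrics.json"),
        "metrics_csv": out_prefix.with_name(out_prefix.name + "_metrics.csv"),
        "comparisons_csv": out_prefix.with_name(out_prefix.name + "_comparisons.csv"),
    }
    payload = {
        "schema": "bretropy-metrics-v1",
        "traces": [s.to_dict() for s in spectra],
        "comparisons": [c.to_dict() for c in comparisons],
    }
    with open(paths["metrics_json"], "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1, allow_nan=True, default=_json_default)
        fh.write("\n")
    metrics_to_frame(spectra).to_csv(paths["metrics_csv"], index=False, float_format="%.17g")
    comparisons_to_frame(comparisons).to_csv(
        paths["comparisons_csv"], index=False, float_format="%.17g"
    )
    return paths


def read_metrics(path: str | Path) -> dict:
    """Read back a metrics JSON document written by :func:`write_metrics`."""
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
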