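"""File formats: activity tables, DSM matrices, configs, results.

Activity table CSV columns: ``id,label,bcv,mlv,wcv,rework_impact,
improvement_curve`` with the improvement curve as semicolon-separated
multipliers.  The matrix CSV is square with identical row and column
labels and rework probabilities in the cells (blank or 0 = no
dependency; the diagonal is blank).  Matrix orientation is explicit:
under the default ``"columns-are-inputs"`` convention, reading down
column j gives the inputs of activity j, i.e. a cell at (row i, col j)
is the edge i -> j; ``"rows-are-inputs"`` is the transpose.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import yaml

from .estimation import DurationSample, ObservationCounts
from .model import DSM, Activity, Edge, TriangularDuration, build_dsm
from .simulation import SimulationConfig, SimulationResult

__all__ = [
    "read_activity_table",
    "write_activity_table",
    "read_dsm_matrix",
    "write_dsm_matrix",
    "read_dsm",
    "write_dsm_json",
    "read_dsm_json",
    "load_config",
    "write_result",
    "read_observations",
    "read_duration_samples",
]

Orientation = Literal["columns-are-inputs", "rows-are-inputs"]


def _parse_ic(raw) -> tuple[float, ...]:
    if raw is None or (isinstance(raw, float) and np.isnan(raw)) or raw == "":
        return (1.0,)
    if isinstance(raw, (int, float)):
        return (float(raw),)
    return tuple(float(x) for x in str(raw).split(";") if x.strip() != "")


def read_activity_table(path: str | Path) -> list[Activity]:
    df = pd.read_csv(path, comment="#", dtype={"id": str}, float_precision="round_trip")
    required = {"id", "bcv", "mlv", "wcv", "rework_impact"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"activity table {path}: missing columns {sorted(missing)}")
    acts = []
    for _, row in df.iterrows():
        acts.append(
            Activity(
                id=str(row["id"]),
                label=str(row.get("label", "")) if "label" in df.columns else "",
                duration=TriangularDuration(
                    float(row["bcv"]), float(row["mlv"]), float(row["wcv"])
                ),
                rework_impact=float(row["rework_impact"]),
                improvement_curve=_parse_ic(row.get("improvement_curve")),
            )
        )
    return acts


def write_activity_table(activities: list[Activity], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "id": [a.id for a in activities],
            "label": [a.label for a in activities],
            "bcv": [a.duration.bcv for a in activities],
            "mlv": [a.duration.mlv for a in activities],
            "wcv": [a.duration.wcv for a in activities],
            "rework_impact": [a.rework_impact for a in activities],
            "improvement_curve": [
                ";".join(str(x) for x in a.improvement_curve) for a in activities
            ],
        }
    )
    df.to_csv(path, index=False)


def read_dsm_matrix(
    path: str | Path,
    orientation: Orientation = "columns-are-inputs",
) -> tuple[list[str], list[Edge]]:
    """Read a square probability matrix; returns (ids, edges)."""
    df = pd.read_csv(path, index_col=0, comment="#", float_precision="round_trip")
    ids = [str(c) for c in df.columns]
    row_ids = [str(r) for r in df.index]
    if ids != row_ids:
        raise ValueError(
            f"matrix {path}: row labels {row_ids} != column labels {ids}"
        )
    m = df.to_numpy(dtype=float)
    m = np.nan_to_num(m, nan=0.0)
    if orientation == "rows-are-inputs":
        m = m.T
    elif orientation != "columns-are-inputs":
        raise ValueError(f"unknown orientation {orientation!r}")
    edges = []
    for i, provider in enumerate(ids):
        for j, consumer in enumerate(ids):
            if i != j and m[i, j] > 0.0:
                edges.append(Edge(provider, consumer, float(m[i, j])))
    return ids, edges


def write_dsm_matrix(
    dsm: DSM,
    path: str | Path,
    orientation: Orientation = "columns-are-inputs",
) -> None:
    ids = list(dsm.ids)
    m = np.zeros((dsm.n, dsm.n))
    for e in dsm.edges:
        m[dsm.index(e.provider), dsm.index(e.consumer)] = e.rework_probability
    if orientation == "rows-are-inputs":
        m = m.T
    elif orientation != "columns-are-inputs":
        raise ValueError(f"unknown orientation {orientation!r}")
    pd.DataFrame(m, index=ids, columns=ids).to_csv(path)


def read_dsm(
    activities_path: str | Path,
    matrix_path: str | Path,
    orientation: Orientation = "columns-are-inputs",
) -> DSM:
    """Assemble a DSM from an activity table CSV and a matrix CSV."""
    acts = read_activity_table(activities_path)
    ids, edges = read_dsm_matrix(matrix_path, orientation)
    declared = [a.id for a in acts]
    if set(ids) != set(declared):
        raise ValueError(
            f"matrix ids {ids} do not match activity table ids {declared}"
        )
    # activity-table order defines the execution sequence
    return build_dsm(acts, edges)


def write_dsm_json(dsm: DSM, path: str | Path) -> None:
    Path(path).write_text(json.dumps(dsm.to_dict(), indent=2))


def read_dsm_json(path: str | Path) -> DSM:
    return DSM.from_dict(json.loads(Path(path).read_text()))


def load_config(path: str | Path) -> SimulationConfig:
    """Load a simulation config from YAML or JSON (by extension)."""
    p = Path(path)
    raw = p.read_text()
    data = json.loads(raw) if p.suffix == ".json" else yaml.safe_load(raw)
    return SimulationConfig(**data)


def write_result(
    result: SimulationResult,
    summary_path: str | Path,
    totals_path: str | Path | None = None,
    histogram_path: str | Path | None = None,
    n_bins: int = 30,
) -> None:
    """Write the JSON summary, optional per-run totals CSV and histogram CSV."""
    Path(summary_path).write_text(json.dumps(result.summary, indent=2))
    if totals_path is not None:
        pd.DataFrame(
            {
                "run": np.arange(len(result.totals)),
                "total_min": result.totals,
                "first_trial_min": result.first_trial_totals,
            }
        ).to_csv(totals_path, index=False)
    if histogram_path is not None:
        counts, edges = np.histogram(result.totals, bins=n_bins)
        pd.DataFrame(
            {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
        ).to_csv(histogram_path, index=False)


def read_observations(path: str | Path) -> dict[tuple[str, str], list[ObservationCounts]]:
    """Observation CSV -> per-dependency (possibly per-class) counts.

    Columns: ``input_id,consumer_id,class,n_o,n_oc,n_ic,n_ir``.
    """
    df = pd.read_csv(path, comment="#", dtype={"input_id": str, "consumer_id": str})
    out: dict[tuple[str, str], list[ObservationCounts]] = {}
    for _, row in df.iterrows():
        key = (str(row["input_id"]), str(row["consumer_id"]))
        out.setdefault(key, []).append(
            ObservationCounts(
                n_o=int(row["n_o"]),
                n_oc=int(row["n_oc"]),
                n_ic=int(row["n_ic"]),
                n_ir=int(row["n_ir"]),
            )
        )
    return out


def read_duration_samples(path: str | Path) -> list[DurationSample]:
    """Long-format duration CSV (``activity_id,duration_min``) -> samples."""
    df = pd.read_csv(path, comment="#", dtype={"activity_id": str})
    samples = []
    for aid, grp in df.groupby("activity_id", sort=False):
        samples.append(
            DurationSample(
                activity_id=str(aid),
                durations=tuple(float(x) for x in grp["duration_min"]),
            )
        )
    return samples
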