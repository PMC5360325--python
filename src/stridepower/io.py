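"""Reading stride-interval files and writing result tables.

Stride series are plain one-column text or CSV files (one stride interval
per line, seconds), the de facto interchange format for gait interval data
(e.g. the PhysioNet gait databases).  A manifest CSV with columns
``subject_id, condition, trial_index, path`` maps files to the experimental
design.  Results are written as JSON or TSV with a provenance block carrying
the configuration and seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .dfa import DFAEstimate, StrideSeries
from .empirical import EmpiricalPowerCurve, StrideDataset
from .exceptions import InvalidInputError
from .fgn import TrialSDTable
from .power import PowerSurface

__all__ = [
    "read_stride_series",
    "read_manifest",
    "load_dataset",
    "write_results",
    "write_stride_series",
]

logger = logging.getLogger("stridepower")

MANIFEST_COLUMNS = ("subject_id", "condition", "trial_index", "path")


def read_stride_series(
    path,
    subject_id: str = "",
    condition: str = "",
    trial_index: int = 0,
) -> StrideSeries:
    """Read one stride series from a one-column text/CSV file.

    A single non-numeric header line is skipped; any other non-numeric line
    raises a parse error naming the line number.
    """
    path = Path(path)
    values = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            token = line.strip().rstrip(",")
            if not token:
                continue
            try:
                values.append(float(token))
            except ValueError:
                if lineno == 1:  # header
                    continue
                raise InvalidInputError(
                    f"{path}: non-numeric value {token!r} at line {lineno}"
                ) from None
    if not values:
        raise InvalidInputError(f"{path}: no numeric values found")
    arr = np.asarray(values)
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError(f"{path}: non-finite values present")
    logger.info(
        "%s: %d strides, mean %.4f s, SD %.4f s",
        path.name, arr.size, arr.mean(), arr.std(),
    )
    return StrideSeries(
        values=arr,
        subject_id=subject_id,
        condition=condition,
        trial_index=trial_index,
    )


def read_manifest(path) -> pd.DataFrame:
    """Read and validate a manifest CSV; paths are resolved relative to it."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"subject_id": str, "condition": str})
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise InvalidInputError(f"manifest missing columns: {sorted(missing)}")
    keys = df[["subject_id", "condition", "trial_index"]]
    if keys.duplicated().any():
        raise InvalidInputError(
            "manifest rows must be unique in (subject_id, condition, trial_index)"
        )
    df = df.copy()
    df["path"] = [
        str((path.parent / p).resolve()) if not Path(p).is_absolute() else p
        for p in df["path"]
    ]
    for p in df["path"]:
        if not Path(p).exists():
            raise InvalidInputError(f"manifest references missing file: {p}")
    return df


def load_dataset(manifest_path) -> StrideDataset:
    """Load a two-condition dataset through a manifest.

    Multiple trials for the same subject and condition are concatenated in
    trial order into one long series.
    """
    manifest = read_manifest(manifest_path)
    records = []
    for (subject, condition), group in manifest.groupby(
        ["subject_id", "condition"], sort=True
    ):
        group = group.sort_values("trial_index")
        chunks = [
            read_stride_series(row.path, subject, condition, int(row.trial_index))
            for row in group.itertuples()
        ]
        values = np.concatenate([c.values for c in chunks])
        records.append(
            StrideSeries(values=values, subject_id=subject, condition=condition)
        )
    return StrideDataset(records=tuple(records))


def write_stride_series(series: StrideSeries, path) -> None:
    """Write one series as one value per line (6 significant digits)."""
    Path(path).write_text(
        "\n".join(f"{v:.6g}" for v in series.values) + "\n"
    )


def _sig6(x):
    if isinstance(x, float):
        return float(f"{x:.6g}")
    return x


def _result_payload(obj) -> tuple[str, dict, pd.DataFrame]:
    """(kind, scalar fields, long-format table) for a result object."""
    if isinstance(obj, DFAEstimate):
        fields = {
            "alpha": obj.alpha,
            "intercept": obj.intercept,
            "r_squared": obj.r_squared,
            "n_windows_used": obj.n_windows_used,
            "window_min": obj.window_range[0],
            "window_max": obj.window_range[1],
        }
        table = pd.DataFrame([fields])
        return "dfa_estimate", fields, table
    if isinstance(obj, TrialSDTable):
        fields = {"hurst": obj.hurst, "n_replicates": obj.n_replicates}
        table = pd.DataFrame(
            {"length": obj.lengths, "sd_alpha": obj.sd_alpha}
        )
        return "trial_sd_table", fields, table
    if isinstance(obj, PowerSurface):
        fields = {
            **dataclasses.asdict(obj.design),
            **dataclasses.asdict(obj.variance),
        }
        fields.pop("n_subjects_grid", None)
        fields.pop("trials_grid", None)
        table = pd.DataFrame(
            obj.to_records(), columns=["n_subjects", "trials", "power"]
        )
        return "power_surface", fields, table
    if isinstance(obj, EmpiricalPowerCurve):
        fields = {
            "n_resamples": obj.n_resamples,
            "window_length": obj.window_length,
            "n_windows": obj.n_windows,
            "test_level": obj.test_level,
            "seed": obj.seed,
        }
        table = pd.DataFrame(
            {
                "sample_size": obj.sample_sizes,
                "observed_power": obj.observed_power,
            }
        )
        return "empirical_power_curve", fields, table
    raise InvalidInputError(f"cannot serialise object of type {type(obj)!r}")


def write_results(obj, path, fmt: str = "json", config: dict | None = None) -> None:
    """Write a result object as JSON or TSV with a provenance block.

    Field order is deterministic and floats are rendered at 6 significant
    digits.  ``config`` (typically the resolved run configuration including
    the seed) is embedded for provenance.
    """
    kind, fields, table = _result_payload(obj)
    path = Path(path)
    fields = {k: _sig6(v) for k, v in fields.items()}
    config = {k: _sig6(v) for k, v in (config or {}).items()}
    if fmt == "json":
        payload = {
            "kind": kind,
            **fields,
            "table": [
                {k: _sig6(v) for k, v in row.items()}
                for row in table.to_dict(orient="records")
            ],
            "provenance": config,
        }
        path.write_text(json.dumps(payload, indent=2, sort_keys=False) + "\n")
    elif fmt == "tsv":
        lines = [f"# kind: {kind}"]
        lines += [f"# {k}: {v}" for k, v in fields.items()]
        lines += [f"# config.{k}: {v}" for k, v in config.items()]
        lines.append("\t".join(table.columns))
        for row in table.itertuples(index=False):
            lines.append(
                "\t".join(
                    f"{v:.6g}" if isinstance(v, float) else str(v) for v in row
                )
            )
        path.write_text("\n".join(lines) + "\n")
    else:
        raise InvalidInputError(f"unknown format {fmt!r} (use 'json' or 'tsv')")
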