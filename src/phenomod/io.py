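"""Table ingestion, validation and result/manifest writing.

Input is plain delimited text with a header row; the delimiter follows
the file extension (.csv comma, .tsv/.txt tab) unless overridden.  Rows
with missing values are dropped with a logged count.  Writers emit tidy
CSVs and a JSON run manifest (config, seeds, package version, input
checksums) sufficient to regenerate every output bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from .embedding.embed import DataMatrix
from .exceptions import ValidationError
from .growth.fit import GrowthTrajectory
from .prediction.registry import SupervisedTable

log = logging.getLogger("phenomod")

__all__ = [
    "read_table",
    "read_growth_trajectories",
    "read_supervised_table",
    "read_data_matrix",
    "write_manifest",
    "file_checksum",
]


def _delimiter_for(path, override=None):
    if override:
        return override
    suffix = Path(path).suffix.lower()
    if suffix == ".csv":
        return ","
    if suffix in (".tsv", ".txt"):
        return "\t"
    raise ValidationError(
        f"cannot infer delimiter from extension {suffix!r}; pass one explicitly"
    )


def read_table(path, delimiter=None) -> pd.DataFrame:
    """Read a delimited text table with a mandatory header row."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"input file does not exist: {path}")
    if path.stat().st_size == 0:
        raise ValidationError(f"input file is empty: {path}")
    df = pd.read_csv(path, sep=_delimiter_for(path, delimiter))
    if df.empty:
        raise ValidationError(f"no data rows in {path}")
    return df


def _drop_missing(df, context):
    n0 = len(df)
    df = df.dropna()
    dropped = n0 - len(df)
    if dropped:
        log.info("%s: dropped %d row(s) with missing values", context, dropped)
    return df, dropped


def _require_columns(df, required, path):
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing mandatory column(s) {missing}; "
                              f"found {list(df.columns)}")


def _numeric_or_die(df, cols, path):
    for c in cols:
        coerced = pd.to_numeric(df[c], errors="coerce")
        bad = df.index[coerced.isna() & df[c].notna()]
        if len(bad):
            raise ValidationError(
                f"{path}: non-numeric value {df.loc[bad[0], c]!r} "
                f"at row {bad[0]}, column {c!r}"
            )
        df[c] = coerced
    return df


def read_growth_trajectories(path, delimiter=None, plant_col="plant",
                             day_col="day", value_col="value",
                             group_col=None, condition_col=None):
    """Long-format growth table → list of :class:`GrowthTrajectory`."""
    df = read_table(path, delimiter)
    _require_columns(df, [plant_col, day_col, value_col], path)
    df, _ = _drop_missing(df[[c for c in (plant_col, day_col, value_col,
                                          group_col, condition_col) if c]],
                          str(path))
    df = _numeric_or_die(df, [day_col, value_col], path)
    trajectories = []
    for plant, sub in df.groupby(plant_col, sort=True):
        sub = sub.sort_values(day_col)
        if sub[day_col].duplicated().any():
            raise ValidationError(f"{path}: duplicate day for plant {plant!r}")
        group = str(sub[group_col].iloc[0]) if group_col else ""
        condition = str(sub[condition_col].iloc[0]) if condition_col else "control"
        trajectories.append(GrowthTrajectory(
            str(plant), sub[day_col].to_numpy(float),
            sub[value_col].to_numpy(float), group, condition,
        ))
    return trajectories


def pool_group_trajectories(trajectories):
    """Pool replicate (t, y) pairs per group into one trajectory each."""
    pooled = []
    by_group = {}
    for tr in trajectories:
        by_group.setdefault(tr.group_id or tr.plant_id, []).append(tr)
    for group, members in sorted(by_group.items()):
        t = np.concatenate([m.times for m in members])
        y = np.concatenate([m.values for m in members])
        order = np.argsort(t, kind="stable")
        t, y = t[order], y[order]
        # pooled replicates share time points; jitter-free strict ordering is
        # restored by averaging duplicates
        ut, inv = np.unique(t, return_inverse=True)
        uy = np.zeros_like(ut)
        counts = np.zeros_like(ut)
        np.add.at(uy, inv, y)
        np.add.at(counts, inv, 1)
        pooled.append(GrowthTrajectory(group, ut, uy / counts, group,
                                       members[0].condition))
    return pooled


def read_supervised_table(path, target, delimiter=None, id_col=None,
                          task=None) -> SupervisedTable:
    """Wide table with a designated target column → :class:`SupervisedTable`."""
    df = read_table(path, delimiter)
    _require_columns(df, [target] + ([id_col] if id_col else []), path)
    df, _ = _drop_missing(df, str(path))
    if id_col and df[id_col].duplicated().any():
        dup = df[id_col][df[id_col].duplicated()].iloc[0]
        raise ValidationError(f"{path}: duplicate id {dup!r}")
    feature_cols = [c for c in df.columns if c not in (target, id_col)]
    df = _numeric_or_die(df, feature_cols, path)
    return SupervisedTable.from_dataframe(df, target, task=task, id_col=id_col)


def read_data_matrix(path, delimiter=None, annotation_path=None) -> DataMatrix:
    """Wide matrix, first column = row ids → :class:`DataMatrix`."""
    df = read_table(path, delimiter)
    df = df.set_index(df.columns[0])
    if df.index.duplicated().any():
        raise ValidationError(f"{path}: duplicate row id {df.index[df.index.duplicated()][0]!r}")
    df, _ = _drop_missing(df, str(path))
    df = _numeric_or_die(df, list(df.columns), path)
    annotations = {}
    if annotation_path:
        ann = read_table(annotation_path, delimiter)
        ann = ann.set_index(ann.columns[0]).reindex(df.index.astype(str))
        annotations = {c: ann[c].tolist() for c in ann.columns}
    return DataMatrix.from_dataframe(df, annotations)


def file_checksum(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(outdir, config: dict, inputs=(), extra=None):
    """Write manifest.json recording config, seeds, versions and checksums."""
    from . import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package": "phenomod",
        "version": __version__,
        "python": platform.python_version(),
        "config": config,
        "inputs": {str(p): file_checksum(p) for p in inputs},
    }
    if extra:
        manifest.update(extra)
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return path
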