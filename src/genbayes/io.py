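"""File formats: survival tables, data matrices, result bundles.

TSV is the lingua franca for tables, JSON for run metadata.  Readers validate
eagerly and report the offending row or cell; writers are deterministic so a
rerun with the same config and seed reproduces byte-identical tables.
"""

from __future__ import annotations

import json
import logging
import pathlib

import numpy as np
import pandas as pd

from .survival import SurvivalDataset

logger = logging.getLogger(__name__)

__all__ = ["read_survival_table", "write_survival_table", "read_matrix",
           "write_matrix", "write_results"]


def _read_table(path) -> pd.DataFrame:
    path = pathlib.Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    return pd.read_csv(path, sep=sep)


def read_survival_table(path) -> SurvivalDataset:
    """Read a `time,event,marker_1..marker_p` table (CSV or TSV by suffix).

    Row numbers in error messages are 1-based data rows (excluding the
    header).  Missing genotypes are not supported.
    """
    df = _read_table(path)
    cols = list(df.columns)
    if cols[:2] != ["time", "event"]:
        raise ValueError(
            f"{path}: header must start with 'time,event', got {cols[:2]}"
        )
    if len(cols) < 3:
        raise ValueError(f"{path}: no covariate columns found")
    for col in cols:
        bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
        if len(bad):
            raise ValueError(
                f"{path}: non-numeric value in column {col!r} at row {bad[0] + 1}"
            )
    times = df["time"].to_numpy(float)
    events = df["event"].to_numpy()
    badt = np.flatnonzero(times <= 0)
    if badt.size:
        raise ValueError(f"{path}: non-positive time at row {badt[0] + 1}")
    bade = np.flatnonzero(~np.isin(events, [0, 1]))
    if bade.size:
        raise ValueError(
            f"{path}: event must be 0 or 1, got {events[bade[0]]} at row {bade[0] + 1}"
        )
    X = df[cols[2:]].to_numpy(float)
    ds = SurvivalDataset(times=times, events=events, X=X)
    logger.info("read %d subjects, %d markers from %s", ds.n, ds.p, path)
    return ds


def write_survival_table(dataset: SurvivalDataset, path) -> None:
    path = pathlib.Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    dataset.to_frame().to_csv(path, sep=sep, index=False)


def read_matrix(path) -> pd.DataFrame:
    """Read a TSV matrix with row and column headers; column order preserved."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] < 1:
        raise ValueError(f"{path}: matrix needs at least one column")
    na = df.isna()
    if na.to_numpy().any():
        i, j = np.argwhere(na.to_numpy())[0]
        raise ValueError(
            f"{path}: missing cell at row {df.index[i]!r}, column {df.columns[j]!r}"
        )
    return df.astype(float)


def write_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t")


def write_results(tables: dict, metadata: dict, outdir) -> list:
    """Write TSV tables plus a metadata.json; returns the paths written."""
    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, table in tables.items():
        p = outdir / f"{name}.tsv"
        if isinstance(table, pd.DataFrame):
            table.to_csv(p, sep="\t", index=False)
        else:
            np.savetxt(p, np.asarray(table), delimiter="\t")
        written.append(p)
    try:
        from importlib.metadata import version
        pkg_version = version("genbayes")
    except Exception:  # pragma: no cover
        pkg_version = "unknown"
    meta = dict(metadata)
    meta.setdefault("package_version", pkg_version)
    mp = outdir / "metadata.json"
    mp.write_text(json.dumps(meta, indent=2, sort_keys=True, default=str))
    written.append(mp)
    logger.info("wrote %d files to %s", len(written), outdir)
    return written
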