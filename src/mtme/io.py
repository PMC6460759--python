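"""Delimited-text readers/writers and the structured results directory.

Formats:

* phenotypes — CSV/TSV with columns ``line``, ``env`` then one column per
  trait; empty cells are missing values;
* kinship — square delimited matrix, line labels as header row and first
  column; realigned to the phenotype line order by label;
* markers — lines x markers numeric codes, optional header of marker names,
  first column = line labels.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datamodel import ChainConfig, MTMEDataset
from .kernels import Kinship

logger = logging.getLogger(__name__)

__all__ = ["read_phenotypes", "read_kinship", "read_markers",
           "write_phenotypes", "write_kinship", "write_report", "read_config"]


def _sep(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def read_phenotypes(path) -> MTMEDataset:
    df = pd.read_csv(path, sep=_sep(path), float_precision="round_trip")
    for col in df.columns:
        if col in ("line", "env"):
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            r = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(f"non-numeric trait cell at row {r}, column {col!r}")
        df[col] = coerced
    ds = MTMEDataset.from_frame(df)
    logger.info("read %d rows: %d environments, %d lines, %d traits",
                ds.n_rows, ds.n_env, ds.n_lines, ds.n_traits)
    return ds


def write_phenotypes(dataset: MTMEDataset, path) -> None:
    # shortest-repr floats + round_trip parsing on read give exact round trips
    dataset.to_frame().to_csv(path, sep=_sep(path), index=False)


def read_kinship(path, line_order=None) -> Kinship:
    df = pd.read_csv(path, sep=_sep(path), index_col=0,
                     float_precision="round_trip")
    labels = [str(c) for c in df.columns]
    if [str(i) for i in df.index] != labels:
        raise ValueError("kinship header row and first column disagree")
    kin = Kinship(df.to_numpy(dtype=float), labels)
    if line_order is not None:
        wanted = [str(l) for l in line_order]
        missing = [l for l in wanted if l not in set(labels)]
        if missing:
            raise ValueError(f"kinship labels missing for lines: {missing[:10]}")
        kin = kin.reorder(wanted)
    return kin


def write_kinship(kin: Kinship, path) -> None:
    pd.DataFrame(kin.G, index=kin.line_ids, columns=kin.line_ids).to_csv(
        path, sep=_sep(path))


def read_markers(path) -> tuple[np.ndarray, list]:
    """Returns (J x p marker matrix, line labels)."""
    df = pd.read_csv(path, sep=_sep(path), index_col=0)
    return df.to_numpy(dtype=float), [str(i) for i in df.index]


def read_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config file must hold a key-value mapping")
    return cfg


def chain_from_config(cfg: dict) -> ChainConfig:
    return ChainConfig(n_iter=int(cfg.get("n_iter", 60000)),
                       burn_in=int(cfg.get("burn_in", 20000)),
                       thin=int(cfg.get("thin", 5)),
                       seed=int(cfg.get("seed", 0)))


def write_report(outdir, manifest: dict, tables: dict[str, pd.DataFrame]) -> Path:
    """Write posterior-mean / prediction / summary CSVs plus a run manifest.

    ``tables`` maps file stems to DataFrames; numeric output is written at 6
    significant digits.  The manifest (config + seed + package versions) makes
    the run reproducible.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for stem, df in tables.items():
        df.to_csv(outdir / f"{stem}.csv", index=False, float_format="%.6g")
    import mtme
    manifest = dict(manifest)
    manifest["versions"] = {"mtme": mtme.__version__, "numpy": np.__version__,
                            "pandas": pd.__version__}
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return outdir
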