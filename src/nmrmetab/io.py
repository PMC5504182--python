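"""Delimited-text readers and writers for spectra, bins and feature matrices.

Spectra round-trip as a CSV matrix whose header row holds the ppm axis and
whose first column holds sample ids, with a companion metadata table
(sample id, group, tissue).  Feature matrices carry their processing-state
flags in a leading comment line so the pipeline state survives a round trip.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import BinTable, FeatureMatrix, SpectraSet

__all__ = [
    "write_spectra",
    "read_spectra",
    "write_feature_matrix",
    "read_feature_matrix",
    "write_bin_table",
    "read_bin_table",
    "write_json",
]


def write_spectra(spectra: SpectraSet, matrix_path, metadata_path) -> None:
    df = pd.DataFrame(
        spectra.intensities,
        index=pd.Index(spectra.sample_ids, name="sample_id"),
        columns=[repr(float(v)) for v in spectra.ppm],
    )
    df.to_csv(matrix_path)
    spectra.metadata.rename_axis("sample_id").to_csv(metadata_path)


def read_spectra(matrix_path, metadata_path) -> SpectraSet:
    """Read a spectra matrix + metadata pair written by :func:`write_spectra`.

    Accepts ascending ppm headers and reverses them to the descending
    convention; rejects duplicate or unmatched sample ids, non-numeric
    intensities and non-monotone axes.
    """
    df = pd.read_csv(matrix_path, index_col=0)
    try:
        ppm = np.array([float(c) for c in df.columns])
    except ValueError as exc:
        raise ValueError(f"ppm header does not parse as numbers: {exc}") from exc
    diffs = np.diff(ppm)
    if ppm.size > 1 and not (np.all(diffs < 0) or np.all(diffs > 0)):
        raise ValueError("ppm axis is not strictly monotone")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number) or np.isnan(values).any():
        raise ValueError("non-numeric intensities in spectra matrix")
    if ppm.size > 1 and diffs[0] > 0:  # ascending input: reverse
        ppm = ppm[::-1]
        values = values[:, ::-1]
    if df.index.has_duplicates:
        raise ValueError(f"duplicate sample ids: {df.index[df.index.duplicated()].tolist()}")
    metadata = pd.read_csv(metadata_path, index_col=0)
    missing = [s for s in df.index if s not in metadata.index]
    if missing:
        raise ValueError(f"metadata missing sample ids: {missing}")
    return SpectraSet(ppm=ppm, intensities=values, metadata=metadata.loc[df.index])


def write_feature_matrix(fm: FeatureMatrix, path) -> None:
    path = Path(path)
    flags = (
        f"# normalized={fm.normalized} glog={fm.glog} pareto={fm.pareto}"
    )
    with open(path, "w") as fh:
        fh.write(flags + "\n")
        fm.values.rename_axis("sample_id").to_csv(fh)
    if fm.feature_ppm is not None:
        pd.DataFrame(
            {"feature": fm.feature_names, "ppm": fm.feature_ppm}
        ).to_csv(path.with_suffix(".ppm.csv"), index=False)


def read_feature_matrix(path, metadata: pd.DataFrame) -> FeatureMatrix:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip()
        values = pd.read_csv(fh, index_col=0)
    flags = dict(
        kv.split("=") for kv in header.lstrip("# ").split() if "=" in kv
    )
    feature_ppm = None
    ppm_path = path.with_suffix(".ppm.csv")
    if ppm_path.exists():
        feature_ppm = pd.read_csv(ppm_path)["ppm"].to_numpy()
    return FeatureMatrix(
        values=values,
        metadata=metadata.loc[values.index],
        normalized=flags.get("normalized") == "True",
        glog=flags.get("glog") == "True",
        pareto=flags.get("pareto") == "True",
        feature_ppm=feature_ppm,
    )


def write_bin_table(bins: BinTable, definitions_path, integrals_path) -> None:
    bins.bin_definition_table().to_csv(definitions_path, index=False)
    bins.integrals.rename_axis("sample_id").to_csv(integrals_path)


def read_bin_table(definitions_path, integrals_path, metadata: pd.DataFrame) -> BinTable:
    defs = pd.read_csv(definitions_path)
    integrals = pd.read_csv(integrals_path, index_col=0)
    return BinTable(
        edges=defs[["left_ppm", "right_ppm"]].to_numpy(),
        integrals=integrals,
        metadata=metadata.loc[integrals.index],
    )


def write_json(obj: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, set):
        return sorted(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
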