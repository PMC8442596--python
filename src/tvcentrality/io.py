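"""File I/O: TSV/HDF5 exchange formats, PNG frame sequences, CIFTI-2.

Canonical exchange formats are TSV (UTF-8, LF, tab-delimited, '.'
decimal, 12 significant digits) for small tables and HDF5 for large
arrays.  Parcel time series are stored time-by-parcel with a header row
of parcel IDs and ``# key=value`` comment lines carrying the sampling
interval and run boundaries.  CIFTI-2 dtseries reading (with a dlabel
parcellation averaged per parcel) is optional and needs nibabel.
"""

from __future__ import annotations

import glob
import hashlib
import json
import os

import h5py
import numpy as np
import pandas as pd

from .connectome import (
    AdjacencyMatrix,
    CorrelationMatrix,
    ParcelTimeSeries,
    ValidationError,
)

__all__ = [
    "write_timeseries_tsv",
    "read_timeseries_tsv",
    "write_timeseries_hdf5",
    "read_timeseries_hdf5",
    "read_parcel_timeseries",
    "read_cifti_timeseries",
    "write_matrix_tsv",
    "read_matrix_tsv",
    "write_matrix_hdf5",
    "write_frames_png",
    "read_frames_png",
    "write_json",
    "file_sha256",
]

_FLOAT_FMT = "%.12g"


# ------------------------------------------------------------- timeseries

def write_timeseries_tsv(ts: ParcelTimeSeries, path: str) -> None:
    """Time-by-parcel TSV with a parcel-ID header and metadata comments."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"# tr_seconds={ts.tr_seconds!r}\n")
        fh.write("# run_boundaries="
                 + ",".join(map(str, ts.run_boundaries)) + "\n")
        fh.write("\t".join(ts.parcel_ids) + "\n")
        np.savetxt(fh, ts.values.T, fmt=_FLOAT_FMT, delimiter="\t")


def read_timeseries_tsv(path: str) -> ParcelTimeSeries:
    meta: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        line = fh.readline()
        while line.startswith("#"):
            key, _, val = line[1:].strip().partition("=")
            meta[key.strip()] = val.strip()
            line = fh.readline()
        # parse the header ourselves: pandas would mangle duplicates
        ids = line.rstrip("\n").split("\t")
        if len(set(ids)) != len(ids):
            raise ValidationError(f"duplicate parcel columns in {path}")
        df = pd.read_csv(fh, sep="\t", header=None, names=ids)
    try:
        values = df.to_numpy(dtype=float).T
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"non-numeric cell in {path}: {exc}") from exc
    tr = float(meta.get("tr_seconds", 1.0))
    bounds = [int(b) for b in meta.get("run_boundaries", "").split(",") if b]
    return ParcelTimeSeries(values=values, parcel_ids=ids, tr_seconds=tr,
                            run_boundaries=bounds)


def write_timeseries_hdf5(ts: ParcelTimeSeries, path: str) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=ts.values)
        f.create_dataset("parcel_ids",
                         data=np.array(ts.parcel_ids, dtype="S"))
        f.attrs["tr_seconds"] = ts.tr_seconds
        f.attrs["run_boundaries"] = np.array(ts.run_boundaries, dtype=int)


def read_timeseries_hdf5(path: str) -> ParcelTimeSeries:
    with h5py.File(path, "r") as f:
        return ParcelTimeSeries(
            values=f["values"][()],
            parcel_ids=[s.decode() for s in f["parcel_ids"][()]],
            tr_seconds=float(f.attrs["tr_seconds"]),
            run_boundaries=list(map(int, f.attrs["run_boundaries"])),
        )


def read_cifti_timeseries(
    dtseries_path: str, dlabel_path: str, tr_seconds: float | None = None
) -> ParcelTimeSeries:
    """Parcel time series from a CIFTI-2 dtseries + dlabel pair.

    Grayordinate series are averaged within each dlabel parcel
    ("averaged across vertices in each parcel"); the label table
    supplies parcel names.  Requires nibabel.
    """
    try:
        import nibabel as nib
    except ImportError as exc:  # pragma: no cover
        raise ImportError(
            "CIFTI-2 support requires nibabel (install the 'cifti' "
            "extra)") from exc
    dts = nib.load(dtseries_path)
    data = np.asarray(dts.get_fdata())  # time x grayordinates
    dlab = nib.load(dlabel_path)
    labels = np.asarray(dlab.get_fdata()).ravel().astype(int)
    if labels.size != data.shape[1]:
        raise ValidationError(
            f"dlabel covers {labels.size} grayordinates, dtseries has "
            f"{data.shape[1]}")
    label_axis = dlab.header.get_axis(0)
    name_of = {key: name for key, (name, _rgba)
               in label_axis.label[0].items()}
    keys = [k for k in sorted(np.unique(labels)) if k != 0]
    values = np.stack([data[:, labels == k].mean(axis=1) for k in keys])
    ids = [str(name_of.get(k, f"parcel_{k}")) for k in keys]
    if tr_seconds is None:
        series_axis = dts.header.get_axis(0)
        tr_seconds = float(getattr(series_axis, "step", 1.0) or 1.0)
    return ParcelTimeSeries(values=values, parcel_ids=ids,
                            tr_seconds=tr_seconds)


def read_parcel_timeseries(
    path: str,
    fmt: str | None = None,
    dlabel: str | None = None,
    tr_seconds: float | None = None,
) -> ParcelTimeSeries:
    """Read a parcel time-series file, dispatching on format/extension."""
    if fmt is None:
        if path.endswith((".h5", ".hdf5")):
            fmt = "hdf5"
        elif path.endswith(".dtseries.nii"):
            fmt = "cifti"
        else:
            fmt = "tsv"
    if fmt == "tsv":
        return read_timeseries_tsv(path)
    if fmt == "hdf5":
        return read_timeseries_hdf5(path)
    if fmt == "cifti":
        if dlabel is None:
            raise ValidationError(
                "CIFTI reading requires a dlabel parcellation file")
        return read_cifti_timeseries(path, dlabel, tr_seconds)
    raise ValidationError(f"unknown format {fmt!r}")


# ---------------------------------------------------------------- matrices

def write_matrix_tsv(mat, path: str, parcel_ids=None) -> None:
    values = mat.values if hasattr(mat, "values") else np.asarray(mat)
    ids = parcel_ids or getattr(mat, "parcel_ids", None) \
        or [f"P{i:03d}" for i in range(values.shape[0])]
    df = pd.DataFrame(values, index=ids, columns=ids)
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT, lineterminator="\n")


def read_matrix_tsv(path: str, kind: str = "correlation"):
    df = pd.read_csv(path, sep="\t", index_col=0)
    ids = [str(c) for c in df.columns]
    values = df.to_numpy(dtype=float)
    if kind == "correlation":
        return CorrelationMatrix(values=values, parcel_ids=ids)
    if kind == "adjacency":
        return AdjacencyMatrix(values=values.astype(np.int8), density=float(
            values.sum() / (values.shape[0] * (values.shape[0] - 1))),
            parcel_ids=ids)
    return values, ids


def write_matrix_hdf5(mat, path: str, name: str = "matrix") -> None:
    values = mat.values if hasattr(mat, "values") else np.asarray(mat)
    with h5py.File(path, "w") as f:
        f.create_dataset(name, data=values)
        ids = getattr(mat, "parcel_ids", None)
        if ids:
            f.create_dataset("parcel_ids", data=np.array(ids, dtype="S"))
        if hasattr(mat, "density"):
            f.attrs["density"] = mat.density


# ------------------------------------------------------------------ frames

def write_frames_png(frames: np.ndarray, directory: str,
                     prefix: str = "frame") -> list[str]:
    """Write an (n, H, W, 3) uint8 stack as zero-padded numbered PNGs."""
    import imageio.v3 as iio

    os.makedirs(directory, exist_ok=True)
    paths = []
    for i, frame in enumerate(frames):
        p = os.path.join(directory, f"{prefix}_{i:06d}.png")
        iio.imwrite(p, frame)
        paths.append(p)
    return paths


def read_frames_png(directory: str, pattern: str = "*.png") -> np.ndarray:
    import imageio.v3 as iio

    paths = sorted(glob.glob(os.path.join(directory, pattern)))
    if not paths:
        raise ValidationError(f"no PNG frames matching {pattern} in "
                              f"{directory}")
    return np.stack([iio.imread(p) for p in paths])


# -------------------------------------------------------------------- misc

def write_json(obj, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def file_sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
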