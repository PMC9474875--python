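"""Readers and writers for trace tables, barcode libraries and PWD stacks.

Trace tables are plain CSV/TSV with one row per detected barcode:

``nucleus_id, barcode_id, chrom, start, end, x_um, y_um, z_um, cohort,
embryo_id, rna_state``

An undetected barcode is simply an absent row — blank coordinates are never
emitted. A second dialect (``"fofct"``) maps the core columns of the 4DN
FOF-CT chromatin-trace convention (Trace_ID/Spot_ID/X/Y/Z/Chrom/
Chrom_Start/Chrom_End) onto this schema.

PWD stacks are stored in a small documented HDF5 container:
dataset ``pwd`` (N×B×B float64, NaN = missing), group ``nucleus_meta``
(one string dataset per column), group ``library`` (barcode table plus
``border_index`` and ``genome_build`` attributes).
"""

from __future__ import annotations

import os
from typing import Literal

import h5py
import numpy as np
import pandas as pd

from .model import (
    Barcode,
    BarcodeLibrary,
    FormatError,
    IntegrityError,
    Nucleus,
    PWDStack,
    TraceCollection,
)

TRACE_COLUMNS = [
    "nucleus_id",
    "barcode_id",
    "chrom",
    "start",
    "end",
    "x_um",
    "y_um",
    "z_um",
    "cohort",
    "embryo_id",
    "rna_state",
]

_REQUIRED = ["nucleus_id", "barcode_id", "x_um", "y_um", "z_um"]

# FOF-CT core column names -> internal schema
_FOFCT_MAP = {
    "Trace_ID": "nucleus_id",
    "Spot_ID": "barcode_id",
    "X": "x_um",
    "Y": "y_um",
    "Z": "z_um",
    "Chrom": "chrom",
    "Chrom_Start": "start",
    "Chrom_End": "end",
}


def _sep_for(path: str | os.PathLike) -> str:
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def read_trace_table(
    path: str | os.PathLike,
    library: BarcodeLibrary,
    dialect: Literal["simple", "fofct"] = "simple",
) -> TraceCollection:
    """Read a trace table into a :class:`TraceCollection`.

    Raises :class:`FormatError` when a required column is absent,
    :class:`ValueError` naming the offending row on a non-numeric coordinate,
    and :class:`IntegrityError` on a duplicate (nucleus, barcode) row.
    """
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)
    if dialect == "fofct":
        df = df.rename(columns=_FOFCT_MAP)
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(f"trace table missing required column(s): {missing}")
    for col in ("cohort", "embryo_id", "rna_state"):
        if col not in df.columns:
            df[col] = "NA"
        else:
            df[col] = df[col].replace("", "NA")

    for col in ("x_um", "y_um", "z_um"):
        for row_idx, raw in enumerate(df[col], start=1):
            try:
                float(raw)
            except ValueError:
                raise ValueError(
                    f"non-numeric {col} value {raw!r} at data row {row_idx}"
                ) from None
        df[col] = df[col].astype(float)

    dup = df.duplicated(subset=["nucleus_id", "barcode_id"])
    if dup.any():
        first = df.loc[dup, ["nucleus_id", "barcode_id"]].iloc[0]
        raise IntegrityError(
            f"duplicate row for nucleus {first.nucleus_id!r}, "
            f"barcode {first.barcode_id!r}"
        )

    nuclei: list[Nucleus] = []
    for nid, grp in df.groupby("nucleus_id", sort=False):
        coords = {
            str(r.barcode_id): np.array([r.x_um, r.y_um, r.z_um])
            for r in grp.itertuples()
        }
        nuclei.append(
            Nucleus(
                nucleus_id=str(nid),
                coords=coords,
                cohort=str(grp["cohort"].iloc[0]),
                embryo_id=str(grp["embryo_id"].iloc[0]),
                rna_state=str(grp["rna_state"].iloc[0]),
            )
        )
    return TraceCollection(nuclei, library)


def write_trace_table(tc: TraceCollection, path: str | os.PathLike) -> None:
    """Write a trace table with deterministic row order: nuclei in collection
    order, barcodes in library order. Undetected barcodes are omitted."""
    lib = tc.library
    interval = {b.barcode_id: b for b in lib.barcodes}
    rows = []
    for nuc in tc.nuclei:
        for bid in lib.barcode_ids:
            if bid not in nuc.coords:
                continue
            b = interval[bid]
            x, y, z = nuc.coords[bid]
            rows.append(
                (
                    nuc.nucleus_id,
                    bid,
                    b.chrom,
                    b.start,
                    b.end,
                    repr(float(x)),
                    repr(float(y)),
                    repr(float(z)),
                    nuc.cohort,
                    nuc.embryo_id,
                    nuc.rna_state,
                )
            )
    out = pd.DataFrame(rows, columns=TRACE_COLUMNS)
    out.to_csv(path, sep=_sep_for(path), index=False)


def write_library(lib: BarcodeLibrary, path: str | os.PathLike) -> None:
    df = lib.to_frame()
    df["border_index"] = lib.border_index
    df["genome_build"] = lib.genome_build
    df.to_csv(path, sep=_sep_for(path), index=False)


def read_library(path: str | os.PathLike) -> BarcodeLibrary:
    df = pd.read_csv(path, sep=_sep_for(path))
    required = {"barcode_id", "chrom", "start", "end", "tad_id", "border_index"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"library table missing column(s): {sorted(missing)}")
    build = str(df["genome_build"].iloc[0]) if "genome_build" in df else "dm6"
    return BarcodeLibrary.from_frame(
        df, border_index=int(df["border_index"].iloc[0]), genome_build=build
    )


def serialize_pwd_stack(stack: PWDStack, path: str | os.PathLike) -> None:
    """Write a PWD stack to the HDF5 container documented above."""
    with h5py.File(path, "w") as f:
        f.create_dataset("pwd", data=stack.values)
        meta = f.create_group("nucleus_meta")
        for col in ("nucleus_id", "cohort", "embryo_id", "rna_state"):
            meta.create_dataset(
                col, data=np.asarray(stack.meta[col], dtype=object), dtype=h5py.string_dtype()
            )
        lib = f.create_group("library")
        ldf = stack.library.to_frame()
        for col in ("barcode_id", "chrom", "tad_id"):
            lib.create_dataset(
                col, data=np.asarray(ldf[col], dtype=object), dtype=h5py.string_dtype()
            )
        lib.create_dataset("start", data=ldf["start"].to_numpy(dtype=np.int64))
        lib.create_dataset("end", data=ldf["end"].to_numpy(dtype=np.int64))
        lib.attrs["border_index"] = stack.library.border_index
        lib.attrs["genome_build"] = stack.library.genome_build


def read_pwd_stack(path: str | os.PathLike) -> PWDStack:
    """Read a PWD stack; raises :class:`IntegrityError` on shape/metadata
    mismatches (PWDStack construction re-validates)."""
    with h5py.File(path, "r") as f:
        values = f["pwd"][...]
        meta_cols = {}
        for col in ("nucleus_id", "cohort", "embryo_id", "rna_state"):
            meta_cols[col] = [s.decode() for s in f["nucleus_meta"][col][...]]
        lib_grp = f["library"]
        barcodes = tuple(
            Barcode(bid.decode(), chrom.decode(), int(s), int(e))
            for bid, chrom, s, e in zip(
                lib_grp["barcode_id"][...],
                lib_grp["chrom"][...],
                lib_grp["start"][...],
                lib_grp["end"][...],
            )
        )
        tads = {
            b.barcode_id: t.decode()
            for b, t in zip(barcodes, lib_grp["tad_id"][...])
        }
        library = BarcodeLibrary(
            barcodes,
            tads,
            int(lib_grp.attrs["border_index"]),
            str(lib_grp.attrs["genome_build"]),
        )
    meta = pd.DataFrame(meta_cols)
    return PWDStack(values, meta, library)
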