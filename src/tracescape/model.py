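"""Core domain types for single-nucleus chromatin-trace analysis.

The central objects are:

* :class:`BarcodeLibrary` — the ordered set of imaged genomic barcodes, their
  TAD membership and the index of the border barcode separating two adjacent
  TADs.
* :class:`TraceCollection` — per-nucleus 3D barcode localizations in µm with
  nucleus-level metadata (cohort, embryo, transcriptional state).
* :class:`PWDStack` — a stack of single-nucleus pairwise-distance (snPWD)
  matrices, the currency every downstream statistic consumes.

Missing observations (undetected barcodes, hence undefined distances) are
carried as ``NaN`` throughout; zero is never used as a missing marker.
"""

from __future__ import annotations

import dataclasses
import enum
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel for a distance or coordinate that was not observed.
MISSING = np.nan

RNA_STATES = ("ON", "OFF", "NA")


class IntegrityError(ValueError):
    """Raised when an input violates a structural invariant (duplicates,
    mismatched shapes, inconsistent metadata)."""


class FormatError(ValueError):
    """Raised when a file lacks required columns or has an unknown layout."""


@dataclass(frozen=True)
class Barcode:
    """One oligopaint-labeled genomic interval (0-based half-open)."""

    barcode_id: str
    chrom: str
    start: int
    end: int


@dataclass(frozen=True)
class BarcodeLibrary:
    """Ordered barcode set with TAD membership and a border barcode.

    Parameters
    ----------
    barcodes
        Barcodes sorted by (chrom, start); intervals 0-based half-open.
    tad_assignment
        Map ``barcode_id -> tad_id``; every barcode must appear exactly once.
    border_index
        Index (into ``barcodes``) of the barcode sitting at the ensemble TAD
        boundary. Must be an interior index: the border cannot be the first
        or last barcode of the chain.
    genome_build
        Free-text assembly label, e.g. ``"dm6"``.
    """

    barcodes: tuple[Barcode, ...]
    tad_assignment: Mapping[str, str]
    border_index: int
    genome_build: str = "dm6"

    def __post_init__(self) -> None:
        object.__setattr__(self, "barcodes", tuple(self.barcodes))
        object.__setattr__(self, "tad_assignment", dict(self.tad_assignment))

    @property
    def n_barcodes(self) -> int:
        return len(self.barcodes)

    @property
    def barcode_ids(self) -> list[str]:
        return [b.barcode_id for b in self.barcodes]

    @property
    def tad_ids(self) -> list[str]:
        """Distinct TAD ids in order of first appearance along the chain."""
        seen: list[str] = []
        for b in self.barcodes:
            t = self.tad_assignment.get(b.barcode_id)
            if t is not None and t not in seen:
                seen.append(t)
        return seen

    def index_of(self, barcode_id: str) -> int:
        try:
            return self.barcode_ids.index(barcode_id)
        except ValueError:
            raise KeyError(f"unknown barcode_id {barcode_id!r}") from None

    def tad_indices(self, tad_id: str) -> np.ndarray:
        """Indices of all barcodes assigned to ``tad_id`` (chain order)."""
        idx = [
            i
            for i, b in enumerate(self.barcodes)
            if self.tad_assignment.get(b.barcode_id) == tad_id
        ]
        if not idx:
            raise KeyError(f"unknown tad_id {tad_id!r}")
        return np.asarray(idx, dtype=int)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "barcode_id": self.barcode_ids,
                "chrom": [b.chrom for b in self.barcodes],
                "start": [b.start for b in self.barcodes],
                "end": [b.end for b in self.barcodes],
                "tad_id": [
                    self.tad_assignment.get(b.barcode_id) for b in self.barcodes
                ],
            }
        )

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        border_index: int,
        genome_build: str = "dm6",
    ) -> "BarcodeLibrary":
        barcodes = tuple(
            Barcode(str(r.barcode_id), str(r.chrom), int(r.start), int(r.end))
            for r in df.itertuples()
        )
        tads = {str(r.barcode_id): str(r.tad_id) for r in df.itertuples()}
        return cls(barcodes, tads, border_index, genome_build)


def validate_barcode_library(lib: BarcodeLibrary) -> list[str]:
    """Check all :class:`BarcodeLibrary` invariants; return human-readable
    violation messages (empty list iff the library is valid)."""
    report: list[str] = []
    ids = lib.barcode_ids
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        report.append(f"duplicate barcode_ids: {dupes}")
    for b in lib.barcodes:
        if not b.start < b.end:
            report.append(
                f"barcode {b.barcode_id}: start {b.start} not < end {b.end}"
            )
    keys = [(b.chrom, b.start) for b in lib.barcodes]
    if keys != sorted(keys):
        report.append("barcodes not sorted by (chrom, start)")
    # overlap check within each chromosome
    by_chrom: dict[str, list[Barcode]] = {}
    for b in lib.barcodes:
        by_chrom.setdefault(b.chrom, []).append(b)
    for chrom, bs in by_chrom.items():
        bs = sorted(bs, key=lambda b: b.start)
        for a, b in zip(bs, bs[1:]):
            if b.start < a.end:
                report.append(
                    f"overlapping intervals on {chrom}: "
                    f"{a.barcode_id} and {b.barcode_id}"
                )
    missing = [i for i in ids if i not in lib.tad_assignment]
    if missing:
        report.append(f"barcodes without TAD assignment: {missing}")
    extra = [k for k in lib.tad_assignment if k not in set(ids)]
    if extra:
        report.append(f"TAD assignment for unknown barcodes: {extra}")
    if not 0 < lib.border_index < lib.n_barcodes - 1:
        report.append(
            f"border at chain end: border_index {lib.border_index} "
            f"must satisfy 0 < i < {lib.n_barcodes - 1}"
        )
    return report


@dataclass
class Nucleus:
    """One nucleus's trace: detected barcode coordinates plus metadata."""

    nucleus_id: str
    coords: dict[str, np.ndarray] = field(default_factory=dict)
    cohort: str = "NA"
    embryo_id: str = "NA"
    rna_state: str = "NA"

    def __post_init__(self) -> None:
        if self.rna_state not in RNA_STATES:
            raise ValueError(
                f"rna_state must be one of {RNA_STATES}, got {self.rna_state!r}"
            )
        for bid, xyz in self.coords.items():
            arr = np.asarray(xyz, dtype=float)
            if arr.shape != (3,):
                raise ValueError(f"coords for {bid!r} must be a 3-vector")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite coordinate for barcode {bid!r}")
            self.coords[bid] = arr

    @property
    def n_detected(self) -> int:
        return len(self.coords)


@dataclass
class TraceCollection:
    """An ordered collection of single-nucleus traces bound to a library."""

    nuclei: list[Nucleus]
    library: BarcodeLibrary

    def __post_init__(self) -> None:
        known = set(self.library.barcode_ids)
        seen_ids = set()
        for nuc in self.nuclei:
            if nuc.nucleus_id in seen_ids:
                raise IntegrityError(f"duplicate nucleus_id {nuc.nucleus_id!r}")
            seen_ids.add(nuc.nucleus_id)
            unknown = set(nuc.coords) - known
            if unknown:
                raise IntegrityError(
                    f"nucleus {nuc.nucleus_id}: coords reference barcodes "
                    f"absent from library: {sorted(unknown)}"
                )

    def __len__(self) -> int:
        return len(self.nuclei)

    def __iter__(self):
        return iter(self.nuclei)


@dataclass
class PWDStack:
    """Stack of N single-nucleus B×B pairwise-distance matrices (µm).

    ``values[n, i, j]`` is the Euclidean distance between barcodes i and j in
    nucleus n, or ``NaN`` if either barcode was undetected. Matrices are
    stored dense with the symmetric half duplicated.
    """

    values: np.ndarray
    meta: pd.DataFrame
    library: BarcodeLibrary

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise IntegrityError("values must be N x B x B")
        n, b1, b2 = self.values.shape
        if b1 != b2 or b1 != self.library.n_barcodes:
            raise IntegrityError(
                f"matrix shape {b1}x{b2} does not match library "
                f"({self.library.n_barcodes} barcodes)"
            )
        required = {"nucleus_id", "cohort", "embryo_id", "rna_state"}
        missing = required - set(self.meta.columns)
        if missing:
            raise IntegrityError(f"meta missing columns: {sorted(missing)}")
        if len(self.meta) != n:
            raise IntegrityError(
                f"metadata lists {len(self.meta)} nuclei for {n} matrices"
            )
        self.meta = self.meta.reset_index(drop=True)

    @property
    def n_nuclei(self) -> int:
        return self.values.shape[0]

    @property
    def n_barcodes(self) -> int:
        return self.values.shape[1]

    def validate(self) -> list[str]:
        """Structural checks on the distance matrices themselves."""
        report: list[str] = []
        v = self.values
        finite = np.isfinite(v)
        if not np.array_equal(finite, np.transpose(finite, (0, 2, 1))):
            report.append("missingness is not symmetric")
        with np.errstate(invalid="ignore"):
            asym = np.nanmax(np.abs(v - np.transpose(v, (0, 2, 1))), initial=0.0)
        if asym > 1e-9:
            report.append(f"matrices not symmetric (max |v - v.T| = {asym:g})")
        if np.any(v[finite] < 0):
            report.append("negative distances present")
        diag = np.diagonal(v, axis1=1, axis2=2)
        dfin = np.isfinite(diag)
        if np.any(np.abs(diag[dfin]) > 1e-9):
            report.append("nonzero diagonal entries present")
        return report

    def detected_mask(self) -> np.ndarray:
        """Boolean N×B array: barcode counted as detected in a nucleus when it
        participates in at least one defined distance (diagonal included)."""
        return np.isfinite(self.values).any(axis=2)

    def subset(self, index: Sequence[int] | np.ndarray) -> "PWDStack":
        index = np.asarray(index)
        return PWDStack(
            self.values[index],
            self.meta.iloc[index].reset_index(drop=True),
            self.library,
        )

    def concat(self, other: "PWDStack") -> "PWDStack":
        if other.library.barcode_ids != self.library.barcode_ids:
            raise IntegrityError("cannot concatenate stacks over different libraries")
        return PWDStack(
            np.concatenate([self.values, other.values], axis=0),
            pd.concat([self.meta, other.meta], ignore_index=True),
            self.library,
        )


def traces_to_pwd_stack(
    tc: TraceCollection, lib: BarcodeLibrary | None = None
) -> PWDStack:
    """Compute the snPWD matrix stack from 3D traces.

    Entry (i, j) is the Euclidean distance between detected barcodes i and j;
    it is ``NaN`` if either barcode is undetected. A nucleus with fewer than
    two detected barcodes is retained (all off-diagonal entries missing) with
    a warning.
    """
    lib = lib or tc.library
    order = lib.barcode_ids
    b = len(order)
    n = len(tc.nuclei)
    values = np.full((n, b, b), np.nan)
    for k, nuc in enumerate(tc.nuclei):
        if nuc.n_detected < 2:
            logger.warning(
                "nucleus %s has %d detected barcode(s); distances undefined",
                nuc.nucleus_id,
                nuc.n_detected,
            )
        xyz = np.full((b, 3), np.nan)
        for bid, v in nuc.coords.items():
            xyz[order.index(bid)] = v
        diff = xyz[:, None, :] - xyz[None, :, :]
        values[k] = np.sqrt(np.sum(diff * diff, axis=-1))
    meta = pd.DataFrame(
        {
            "nucleus_id": [nuc.nucleus_id for nuc in tc.nuclei],
            "cohort": [nuc.cohort for nuc in tc.nuclei],
            "embryo_id": [nuc.embryo_id for nuc in tc.nuclei],
            "rna_state": [nuc.rna_state for nuc in tc.nuclei],
        }
    )
    return PWDStack(values, meta, lib)
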