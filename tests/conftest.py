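import numpy as np
import pandas as pd
import pytest

from tracescape.model import Barcode, BarcodeLibrary, Nucleus, PWDStack, TraceCollection


def make_two_tad_library(n: int = 20, border: int | None = None) -> BarcodeLibrary:
    """n-barcode library split into two equal TAD blocks."""
    border = border if border is not None else n // 2 - 1
    barcodes = tuple(
        Barcode(f"bc{i:03d}", "chr3L", 8_900_000 + 8000 * i, 8_900_000 + 8000 * i + 4000)
        for i in range(n)
    )
    tads = {f"bc{i:03d}": ("TAD1" if i <= border else "docTAD") for i in range(n)}
    return BarcodeLibrary(barcodes, tads, border_index=border)


def stack_from_matrices(matrices, library=None, cohorts=None, rna_states=None) -> PWDStack:
    """Build a PWDStack from a list of symmetric matrices (NaN = missing)."""
    matrices = np.asarray(matrices, dtype=float)
    n, b, _ = matrices.shape
    library = library or make_two_tad_library(b)
    meta = pd.DataFrame(
        {
            "nucleus_id": [f"n{i}" for i in range(n)],
            "cohort": cohorts if cohorts is not None else ["c"] * n,
            "embryo_id": ["e0"] * n,
            "rna_state": rna_states if rna_states is not None else ["NA"] * n,
        }
    )
    return PWDStack(matrices, meta, library)


def symmetric_matrix(b: int, fill: float) -> np.ndarray:
    m = np.full((b, b), float(fill))
    np.fill_diagonal(m, 0.0)
    return m


@pytest.fixture
def library20() -> BarcodeLibrary:
    return make_two_tad_library(20)


@pytest.fixture
def library3() -> BarcodeLibrary:
    return make_two_tad_library(3, border=1)


@pytest.fixture
def small_traces(library3) -> TraceCollection:
    nuclei = [
        Nucleus(
            "nucA",
            coords={
                "bc000": np.array([0.0, 0.0, 0.0]),
                "bc001": np.array([1.0, 0.0, 0.0]),
                "bc002": np.array([1.0, 1.0, 0.0]),
            },
            cohort="nc14",
            embryo_id="e1",
            rna_state="ON",
        ),
        Nucleus(
            "nucB",
            coords={
                "bc000": np.array([0.5, 0.5, 0.5]),
                "bc002": np.array([0.5, 0.5, 1.5]),
            },
            cohort="nc11/12",
            embryo_id="e2",
        ),
    ]
    return TraceCollection(nuclei, library3)
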