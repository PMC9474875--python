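"""Per-nucleus structural metrics of the traced locus.

* radius of gyration (Rg) of a barcode subset, computed from pairwise
  distances alone: Rg² = Σ_{i,j} d²_ij / (2N²) over ordered pairs, with the
  pair count adjusted for undetected distances and distances above 1.0 µm
  masked as outliers;
* single-nucleus insulation score (IS): a 2×2 window of inverse distances
  slid along the matrix diagonal; lower IS = stronger insulation between
  the upstream and downstream sides of the candidate border;
* intra-/inter-TAD median distances and the demixing score
  log2(intra/inter), where larger values mean stronger intermingling;
* inter-TAD contact counts at a 250 nm contact threshold;
* Welch's unequal-variance t-test for group comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .model import BarcodeLibrary, PWDStack

RG_MAX_DISTANCE = 1.0  # µm, outlier mask for Rg and TAD medians
RG_MIN_FRAC = 1.0 / 3.0
IS_CUTOFF = 3.5  # single-nucleus IS below this = strongly insulated border
CONTACT_THRESHOLD = 0.25  # µm
MIN_TAD_DISTANCES = 3


def _subset_indices(lib: BarcodeLibrary, subset) -> np.ndarray:
    if subset is None:
        return np.arange(lib.n_barcodes)
    subset = list(subset)
    if subset and isinstance(subset[0], str):
        return np.asarray([lib.index_of(s) for s in subset], dtype=int)
    idx = np.asarray(subset, dtype=int)
    if np.any(idx < 0) or np.any(idx >= lib.n_barcodes):
        raise ValueError("subset index out of range")
    return idx


def radius_of_gyration(
    m: np.ndarray,
    subset: np.ndarray | list | None = None,
    max_distance: float = RG_MAX_DISTANCE,
    min_frac: float = RG_MIN_FRAC,
    library: BarcodeLibrary | None = None,
) -> float:
    """Rg (µm) of a barcode subset from its pairwise distances.

    Distances above ``max_distance`` are masked as outliers; the ordered
    pair count N² in Rg² = Σ d² / (2N²) counts only pairs with a defined
    distance after masking. Returns NaN when fewer than ``min_frac`` of the
    subset's distinct pairs are defined.
    """
    m = np.asarray(m, dtype=float)
    if subset is not None or library is not None:
        idx = _subset_indices(library, subset) if library is not None else np.asarray(subset, int)
        m = m[np.ix_(idx, idx)]
    n = m.shape[0]
    if n < 2:
        raise ValueError("subset must contain at least 2 barcodes")
    with np.errstate(invalid="ignore"):
        masked = np.where(m > max_distance, np.nan, m)
    defined = np.isfinite(masked)
    iu = np.triu_indices(n, k=1)
    n_def_pairs = int(defined[iu].sum())
    if n_def_pairs < min_frac * len(iu[0]):
        return float("nan")
    n_sq = int(defined.sum())  # ordered pairs incl. diagonal
    if n_sq == 0:
        return float("nan")
    rg_sq = np.nansum(masked * masked) / (2.0 * n_sq)
    return float(np.sqrt(rg_sq))


def rg_scatter(
    stack: PWDStack,
    tad_a: str,
    tad_b: str,
    max_distance: float = RG_MAX_DISTANCE,
    min_frac: float = RG_MIN_FRAC,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Per-nucleus (Rg_a, Rg_b) for two TADs plus the Pearson r over nuclei
    where both are defined (NaN when fewer than 3 complete pairs)."""
    ia = stack.library.tad_indices(tad_a)
    ib = stack.library.tad_indices(tad_b)
    rg_a = np.array([
        radius_of_gyration(m, ia, max_distance, min_frac) for m in stack.values
    ])
    rg_b = np.array([
        radius_of_gyration(m, ib, max_distance, min_frac) for m in stack.values
    ])
    ok = np.isfinite(rg_a) & np.isfinite(rg_b)
    if ok.sum() < 3:
        return rg_a, rg_b, float("nan")
    r, _ = stats.pearsonr(rg_a[ok], rg_b[ok])
    return rg_a, rg_b, float(r)


def insulation_profile(m: np.ndarray, square_size: int = 2) -> np.ndarray:
    """Single-nucleus insulation-score profile (µm⁻¹).

    The score at border position i (the candidate boundary between barcodes
    i and i+1, with the border barcode assigned to the upstream side) sums
    the inverse distances in the square window
    rows {i−square_size+1, …, i} × columns {i+1, …, i+square_size}.
    Returned as a length-B vector, NaN at positions where the window does
    not fit or where any window distance is missing.
    """
    m = np.asarray(m, dtype=float)
    b = m.shape[0]
    if b < 2 * square_size:
        raise ValueError(f"need at least {2 * square_size} barcodes")
    out = np.full(b, np.nan)
    for i in range(square_size - 1, b - square_size):
        window = m[i - square_size + 1 : i + 1, i + 1 : i + square_size + 1]
        if np.all(np.isfinite(window)):
            with np.errstate(divide="ignore"):
                out[i] = np.sum(1.0 / window)
    return out


def insulation_profiles(stack: PWDStack, square_size: int = 2) -> np.ndarray:
    """Stacked IS profiles, shape (N, B)."""
    return np.array([insulation_profile(m, square_size) for m in stack.values])


def fraction_insulated(
    profiles: np.ndarray, border_index: int, cutoff: float = IS_CUTOFF
) -> float:
    """Fraction of nuclei whose border IS is strictly below ``cutoff``,
    among nuclei with a defined border IS."""
    border = np.asarray(profiles)[:, border_index]
    defined = np.isfinite(border)
    if not defined.any():
        raise ValueError("no nucleus has a defined insulation score at the border")
    return float(np.mean(border[defined] < cutoff))


def ensemble_is_profile(
    profiles: np.ndarray,
    n_boot: int = 1000,
    ci: float = 0.95,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Population-median IS profile with a bootstrap confidence band.

    Returns ``(median, lower, upper)``, each of length B; the band is the
    percentile interval of the per-position median over ``n_boot``
    resamples of nuclei with replacement.
    """
    profiles = np.asarray(profiles, dtype=float)
    if profiles.shape[0] < 2:
        raise ValueError("need at least 2 nuclei")
    with np.errstate(all="ignore"):
        median = np.nanmedian(profiles, axis=0)
    rng = np.random.default_rng(seed)
    n = profiles.shape[0]
    boots = np.empty((n_boot, profiles.shape[1]))
    for k in range(n_boot):
        take = rng.integers(0, n, size=n)
        with np.errstate(all="ignore"):
            boots[k] = np.nanmedian(profiles[take], axis=0)
    alpha = (1.0 - ci) / 2.0
    with np.errstate(all="ignore"):
        lower = np.nanpercentile(boots, 100 * alpha, axis=0)
        upper = np.nanpercentile(boots, 100 * (1 - alpha), axis=0)
    return median, lower, upper


@dataclass
class TadDistanceSummary:
    """Per-nucleus intra-/inter-TAD distance medians and demixing score."""

    intra_median: float
    inter_median: float
    demixing: float
    n_intra: int
    n_inter: int


def demixing_score(intra_median: float, inter_median: float) -> float:
    """log2(intra/inter); values near 0 or positive indicate intermingled
    TADs, strongly negative values indicate demixed TADs."""
    if not (np.isfinite(intra_median) and np.isfinite(inter_median)):
        return float("nan")
    if intra_median <= 0 or inter_median <= 0:
        return float("nan")
    return float(np.log2(intra_median / inter_median))


def intra_inter_medians(
    m: np.ndarray,
    library: BarcodeLibrary,
    intra_tad: str,
    tad_pair: tuple[str, str],
    max_distance: float = RG_MAX_DISTANCE,
    min_count: int = MIN_TAD_DISTANCES,
) -> TadDistanceSummary:
    """Median intra-TAD distance (within ``intra_tad``) and inter-TAD
    distance (across ``tad_pair``), each over defined distances at most
    ``max_distance`` and reported only when at least ``min_count`` such
    distances exist."""
    m = np.asarray(m, dtype=float)
    ia = library.tad_indices(intra_tad)
    pa = library.tad_indices(tad_pair[0])
    pb = library.tad_indices(tad_pair[1])

    intra_vals = m[np.ix_(ia, ia)][np.triu_indices(len(ia), k=1)]
    inter_vals = m[np.ix_(pa, pb)].ravel()

    def _summ(vals: np.ndarray) -> tuple[float, int]:
        with np.errstate(invalid="ignore"):
            vals = vals[np.isfinite(vals) & (vals <= max_distance)]
        if vals.size < min_count:
            return float("nan"), int(vals.size)
        return float(np.median(vals)), int(vals.size)

    intra_median, n_intra = _summ(intra_vals)
    inter_median, n_inter = _summ(inter_vals)
    return TadDistanceSummary(
        intra_median=intra_median,
        inter_median=inter_median,
        demixing=demixing_score(intra_median, inter_median),
        n_intra=n_intra,
        n_inter=n_inter,
    )


def inter_tad_contacts(
    m: np.ndarray,
    library: BarcodeLibrary,
    tad_pair: tuple[str, str],
    threshold: float = CONTACT_THRESHOLD,
) -> int:
    """Number of inter-TAD barcode pairs in contact (distance strictly
    below ``threshold``); each unordered pair counted once."""
    m = np.asarray(m, dtype=float)
    ia = library.tad_indices(tad_pair[0])
    ib = library.tad_indices(tad_pair[1])
    cross = m[np.ix_(ia, ib)]
    with np.errstate(invalid="ignore"):
        return int(np.sum(np.isfinite(cross) & (cross < threshold)))


def welch_t_test(x, y) -> tuple[float, float]:
    """Two-sided Welch's t-test (unequal variances, Welch–Satterthwaite
    degrees of freedom). Raises on degenerate samples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 values")
    if np.var(x) == 0 and np.var(y) == 0:
        if np.mean(x) == np.mean(y):
            return 0.0, 1.0
        raise ValueError("both samples have zero variance")
    res = stats.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.pvalue)
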