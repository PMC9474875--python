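"""Single-nucleus conformational similarity (pair correlation).

Two nuclei are compared by the Pearson correlation of their vectorized
*reciprocal* distance maps: the upper triangle of each snPWD matrix is
flattened, entries are inverted (1/d, emphasizing short-range changes), and
the correlation is computed over the entries detected in both nuclei. A
pair is skipped when that overlap covers less than half of the full
B(B−1)/2 complement of pairwise distances.

A shuffled reference destroys all structure by randomly reordering one
vector of each pair, giving the null band against which the observed
pair-correlation histogram is read.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import PWDStack

logger = logging.getLogger(__name__)

#: minimum detected barcodes for a nucleus to enter the pair correlation
#: (13 of 20 for the standard-resolution two-TAD library)
DEFAULT_MIN_DETECTED = 13
DEFAULT_MIN_OVERLAP_FRAC = 0.5
DEFAULT_N_SHUFFLES = 10


def vectorize_map(m: np.ndarray) -> np.ndarray:
    """Flatten the strict upper triangle of a B×B matrix, row-major.

    Missing entries stay NaN; the result has length B(B−1)/2.
    """
    m = np.asarray(m, dtype=float)
    iu = np.triu_indices(m.shape[0], k=1)
    return m[iu]


def _reciprocal(v: np.ndarray) -> np.ndarray:
    out = np.full_like(v, np.nan)
    ok = np.isfinite(v) & (v > 0)
    if np.any(np.isfinite(v) & (v == 0)):
        logger.warning("zero distance encountered; excluded from overlap")
    out[ok] = 1.0 / v[ok]
    return out


def pair_correlation(
    va: np.ndarray,
    vb: np.ndarray,
    min_overlap_frac: float = DEFAULT_MIN_OVERLAP_FRAC,
) -> float | None:
    """Pearson r of 1/va vs 1/vb over the jointly detected entries.

    Returns ``None`` (skipped) when the overlap is smaller than
    ``min_overlap_frac`` of the full vector length.
    """
    va = np.asarray(va, dtype=float)
    vb = np.asarray(vb, dtype=float)
    if va.shape != vb.shape:
        raise ValueError("vectors have different lengths")
    return _pearson_reciprocal(_reciprocal(va), _reciprocal(vb),
                               min_overlap=min_overlap_frac * va.size)


def _pearson_reciprocal(ra: np.ndarray, rb: np.ndarray,
                        min_overlap: float) -> float | None:
    m = np.isfinite(ra) & np.isfinite(rb)
    n = int(m.sum())
    if n < min_overlap or n < 2:
        return None
    x = ra[m]
    y = rb[m]
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:
        return None
    return float(np.clip((xc @ yc) / denom, -1.0, 1.0))


@dataclass
class PairCorrelationResult:
    """All-pairs pair-correlation distribution for one cohort."""

    correlations: pd.DataFrame  # columns nucleus_a, nucleus_b, r
    n_skipped: int
    median_r: float
    fraction_positive: float
    null_mean: float = np.nan
    null_sd: float = np.nan

    @property
    def r_values(self) -> np.ndarray:
        return self.correlations["r"].to_numpy()


def _admissible(stack: PWDStack, min_detected: int) -> np.ndarray:
    return np.flatnonzero(stack.detected_mask().sum(axis=1) >= min_detected)


def pair_correlation_distribution(
    stack: PWDStack,
    min_detected: int = DEFAULT_MIN_DETECTED,
    min_overlap_frac: float = DEFAULT_MIN_OVERLAP_FRAC,
) -> PairCorrelationResult:
    """Pair correlation over all unordered pairs of admissible nuclei.

    Nuclei with fewer than ``min_detected`` detected barcodes are excluded
    before pairing.
    """
    idx = _admissible(stack, min_detected)
    if idx.size < 2:
        raise ValueError(
            f"need >=2 nuclei with >= {min_detected} detected barcodes, "
            f"got {idx.size}"
        )
    recip = np.array([_reciprocal(vectorize_map(stack.values[i])) for i in idx])
    min_overlap = min_overlap_frac * recip.shape[1]
    ids = stack.meta["nucleus_id"].to_numpy()
    rows = []
    n_skipped = 0
    for a, b in itertools.combinations(range(idx.size), 2):
        r = _pearson_reciprocal(recip[a], recip[b], min_overlap)
        if r is None:
            n_skipped += 1
        else:
            rows.append((ids[idx[a]], ids[idx[b]], r))
    df = pd.DataFrame(rows, columns=["nucleus_a", "nucleus_b", "r"])
    rs = df["r"].to_numpy()
    return PairCorrelationResult(
        correlations=df,
        n_skipped=n_skipped,
        median_r=float(np.median(rs)) if rs.size else np.nan,
        fraction_positive=float(np.mean(rs > 0)) if rs.size else np.nan,
    )


def shuffled_null(
    stack: PWDStack,
    n_shuffles: int = DEFAULT_N_SHUFFLES,
    seed: int = 0,
    min_detected: int = DEFAULT_MIN_DETECTED,
    min_overlap_frac: float = DEFAULT_MIN_OVERLAP_FRAC,
) -> tuple[float, float]:
    """Shuffled-map reference: for each admissible pair, one vectorized map
    is randomly reordered ``n_shuffles`` times and the pair correlation
    recomputed; returns the mean and SD over all shuffled correlations."""
    idx = _admissible(stack, min_detected)
    if idx.size < 2:
        raise ValueError("need >=2 admissible nuclei")
    rng = np.random.default_rng(seed)
    recip = np.array([_reciprocal(vectorize_map(stack.values[i])) for i in idx])
    m = recip.shape[1]
    min_overlap = min_overlap_frac * m
    rs: list[float] = []
    for a, b in itertools.combinations(range(idx.size), 2):
        for _ in range(n_shuffles):
            perm = rng.permutation(m)
            r = _pearson_reciprocal(recip[a], recip[b][perm], min_overlap)
            if r is not None:
                rs.append(r)
    arr = np.asarray(rs)
    return float(arr.mean()), float(arr.std(ddof=1))
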