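"""Conformational-space analysis of single-nucleus distance maps.

Admitted nuclei (per-cohort dropout cutoffs) have their missing distances
imputed from the ensemble map, are vectorized, and are embedded in 2D with
UMAP (n_neighbors=50, min_dist=0.1, n_epochs=500, metric="canberra").
Cohort territories in the embedding are demarcated by density-difference
contours (Gaussian KDE, bandwidth 0.5; per-category density threshold 0.02;
difference threshold 0.02), and the embedding is partitioned into
communities by Leiden clustering of its k-nearest-neighbour graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
import shapely
import umap
from shapely.geometry import Polygon
from skimage import measure
from sklearn.neighbors import KernelDensity, kneighbors_graph

from .ensemble import EnsembleMap, ensemble_map
from .model import PWDStack
from .similarity import vectorize_map

UMAP_PARAMS = dict(n_neighbors=50, min_dist=0.1, n_epochs=500, metric="canberra")
KDE_BANDWIDTH = 0.5
DENSITY_THRESHOLD = 0.02
DIFF_THRESHOLD = 0.02
LEIDEN_RESOLUTION = 0.25
GRID_SIZE = 256


class ConfigError(ValueError):
    pass


def select_nuclei(
    stack: PWDStack, max_missing_per_category: Mapping[str, int]
) -> PWDStack:
    """Admit nuclei whose number of undetected barcodes is at most the
    cutoff configured for their cohort. A barcode counts as detected when
    it participates in at least one defined distance."""
    cohorts = stack.meta["cohort"]
    unknown = set(cohorts) - set(max_missing_per_category)
    if unknown:
        raise ConfigError(f"no dropout cutoff configured for cohort(s) {sorted(unknown)}")
    n_missing = stack.n_barcodes - stack.detected_mask().sum(axis=1)
    cutoffs = cohorts.map(max_missing_per_category).to_numpy()
    return stack.subset(np.flatnonzero(n_missing <= cutoffs))


def impute_with_ensemble(
    stack: PWDStack, emap: EnsembleMap
) -> tuple[PWDStack, np.ndarray]:
    """Replace missing snPWD entries by the ensemble-map value.

    Returns the completed stack and the boolean imputation mask (N×B×B).
    Raises when the ensemble map is itself undefined at a needed entry.
    """
    values = stack.values.copy()
    mask = ~np.isfinite(values)
    need = mask.any(axis=0)
    bad = need & ~np.isfinite(emap.values)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"ensemble map undefined at entry ({i}, {j}) required for imputation"
        )
    values[mask] = np.broadcast_to(emap.values, values.shape)[mask]
    out = PWDStack(values, stack.meta.copy(), stack.library)
    return out, mask


def impute_per_category(
    stack: PWDStack, method: str = "kde_mode"
) -> tuple[PWDStack, np.ndarray]:
    """Impute each cohort's nuclei from that cohort's own ensemble map."""
    values = stack.values.copy()
    mask = ~np.isfinite(values)
    for cohort in stack.meta["cohort"].unique():
        idx = np.flatnonzero((stack.meta["cohort"] == cohort).to_numpy())
        sub = stack.subset(idx)
        imputed, _ = impute_with_ensemble(sub, ensemble_map(sub, method=method))
        values[idx] = imputed.values
    return PWDStack(values, stack.meta.copy(), stack.library), mask


@dataclass
class EmbeddingResult:
    """2D embedding of vectorized snPWD maps with per-nucleus labels."""

    coords: np.ndarray  # N × 2
    categories: np.ndarray  # per-nucleus cohort label
    params: dict
    source_vectors: np.ndarray | None = None
    meta: pd.DataFrame | None = None


def stack_to_vectors(stack: PWDStack) -> np.ndarray:
    return np.array([vectorize_map(m) for m in stack.values])


def embed_conformations(
    vectors: np.ndarray,
    categories: Sequence[str],
    seed: int,
    n_neighbors: int = UMAP_PARAMS["n_neighbors"],
    min_dist: float = UMAP_PARAMS["min_dist"],
    n_epochs: int = UMAP_PARAMS["n_epochs"],
    metric: str = UMAP_PARAMS["metric"],
) -> EmbeddingResult:
    """UMAP embedding of imputed vectorized maps; deterministic given seed."""
    vectors = np.asarray(vectors, dtype=float)
    if not np.all(np.isfinite(vectors)):
        raise ValueError("vectors contain missing values; impute first")
    if vectors.shape[0] < n_neighbors + 1:
        raise ValueError(
            f"need at least n_neighbors+1={n_neighbors + 1} nuclei, "
            f"got {vectors.shape[0]}"
        )
    reducer = umap.UMAP(
        n_components=2,
        n_neighbors=n_neighbors,
        min_dist=min_dist,
        n_epochs=n_epochs,
        metric=metric,
        random_state=seed,
    )
    coords = reducer.fit_transform(vectors)
    return EmbeddingResult(
        coords=np.asarray(coords, dtype=float),
        categories=np.asarray(list(categories)),
        params=dict(
            n_neighbors=n_neighbors,
            min_dist=min_dist,
            n_epochs=n_epochs,
            metric=metric,
            seed=seed,
        ),
        source_vectors=vectors,
    )


@dataclass
class ClusterBoundary:
    """Density-difference cluster boundaries per category."""

    polygons: dict[str, list[Polygon]]
    kde_bandwidth: float
    density_threshold: float
    diff_threshold: float


def _grid(coords: np.ndarray, bandwidth: float, n: int = GRID_SIZE):
    lo = coords.min(axis=0) - 2 * bandwidth
    hi = coords.max(axis=0) + 2 * bandwidth
    xs = np.linspace(lo[0], hi[0], n)
    ys = np.linspace(lo[1], hi[1], n)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    return xs, ys, np.column_stack([gx.ravel(), gy.ravel()])


def _mask_to_polygons(mask: np.ndarray, xs: np.ndarray, ys: np.ndarray) -> list[Polygon]:
    # pad so regions touching the grid edge still yield closed contours
    padded = np.pad(mask.astype(float), 1)
    polys: list[Polygon] = []
    dx = xs[1] - xs[0]
    dy = ys[1] - ys[0]
    for contour in measure.find_contours(padded, 0.5):
        if len(contour) < 4:
            continue
        x = xs[0] + (contour[:, 0] - 1) * dx
        y = ys[0] + (contour[:, 1] - 1) * dy
        poly = Polygon(np.column_stack([x, y]))
        if not poly.is_valid:
            poly = poly.buffer(0)
        if poly.is_empty:
            continue
        if poly.geom_type == "MultiPolygon":
            polys.extend(list(poly.geoms))
        else:
            polys.append(poly)
    # keep outer shells only: drop any polygon contained in another
    keep = []
    for p in polys:
        if not any(q is not p and q.contains(p) for q in polys):
            keep.append(p)
    return keep


def density_boundaries(
    emb: EmbeddingResult,
    kde_bandwidth: float = KDE_BANDWIDTH,
    density_threshold: float = DENSITY_THRESHOLD,
    diff_threshold: float = DIFF_THRESHOLD,
) -> ClusterBoundary:
    """Per-category polygons enclosing embedding regions where that
    category's KDE exceeds the other's by ``diff_threshold`` while itself
    exceeding ``density_threshold``.

    Each category's density is normalized to unit peak before thresholding:
    embedding coordinates carry no absolute scale, so fixed thresholds are
    only meaningful relative to the density maximum.
    """
    cats = list(pd.unique(emb.categories))
    if len(cats) != 2:
        raise ValueError(f"density boundaries require exactly 2 categories, got {len(cats)}")
    xs, ys, grid_pts = _grid(emb.coords, kde_bandwidth)
    dens = {}
    for c in cats:
        pts = emb.coords[emb.categories == c]
        kde = KernelDensity(bandwidth=kde_bandwidth, kernel="gaussian").fit(pts)
        d = np.exp(kde.score_samples(grid_pts)).reshape(len(xs), len(ys))
        dens[c] = d / d.max()
    polygons: dict[str, list[Polygon]] = {}
    for c, other in ((cats[0], cats[1]), (cats[1], cats[0])):
        region = (dens[c] - dens[other] > diff_threshold) & (
            dens[c] >= density_threshold
        )
        polygons[c] = _mask_to_polygons(region, xs, ys)
    return ClusterBoundary(polygons, kde_bandwidth, density_threshold, diff_threshold)


def _inside(points: np.ndarray, polys: list[Polygon]) -> np.ndarray:
    out = np.zeros(len(points), dtype=bool)
    for p in polys:
        out |= shapely.intersects_xy(p, points[:, 0], points[:, 1])
    return out


def cluster_composition(emb: EmbeddingResult, cb: ClusterBoundary) -> pd.DataFrame:
    """For each category: % of its nuclei inside its own boundary, inside
    the other category's boundary, and outside both. Rows sum to 100;
    points falling in both polygon sets are credited to their own category."""
    cats = list(cb.polygons)
    rows = []
    for c in cats:
        other = [x for x in cats if x != c][0]
        pts = emb.coords[emb.categories == c]
        n = len(pts)
        in_own = _inside(pts, cb.polygons[c])
        in_other = _inside(pts, cb.polygons[other]) & ~in_own
        outside = ~in_own & ~in_other
        rows.append(
            dict(
                category=c,
                own_pct=100.0 * in_own.sum() / n,
                other_pct=100.0 * in_other.sum() / n,
                outside_pct=100.0 * outside.sum() / n,
                n=n,
            )
        )
    return pd.DataFrame(rows)


def leiden_partition(
    coords: np.ndarray,
    n_neighbors: int = UMAP_PARAMS["n_neighbors"],
    resolution: float = LEIDEN_RESOLUTION,
    seed: int = 0,
) -> np.ndarray:
    """Leiden community labels on the symmetrized k-nearest-neighbour graph
    (euclidean) of the 2D embedding coordinates."""
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if n <= n_neighbors:
        raise ValueError(f"need more than n_neighbors={n_neighbors} nuclei, got {n}")
    adj = kneighbors_graph(coords, n_neighbors=n_neighbors, mode="connectivity")
    adj = adj.maximum(adj.T).tocoo()
    edges = [(int(i), int(j)) for i, j in zip(adj.row, adj.col) if i < j]
    graph = ig.Graph(n=n, edges=edges)
    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=seed,
    )
    return np.asarray(part.membership, dtype=int)


def annotate_clusters(
    labels: np.ndarray, metrics: pd.DataFrame
) -> pd.DataFrame:
    """Per-cluster summary of per-nucleus metrics.

    Numeric columns yield count/mean/min/max; categorical columns (e.g.
    cohort) yield composition fractions.
    """
    labels = np.asarray(labels)
    if len(labels) != len(metrics):
        raise ValueError("labels and metrics are not aligned")
    df = metrics.copy()
    df["_cluster"] = labels
    rows = []
    for cluster, grp in df.groupby("_cluster"):
        row: dict = {"cluster": cluster, "count": len(grp)}
        for col in metrics.columns:
            if pd.api.types.is_numeric_dtype(metrics[col]):
                row[f"{col}_mean"] = grp[col].mean()
                row[f"{col}_min"] = grp[col].min()
                row[f"{col}_max"] = grp[col].max()
            else:
                frac = grp[col].value_counts(normalize=True)
                for val, f in frac.items():
                    row[f"{col}={val}_frac"] = f
        rows.append(row)
    return pd.DataFrame(rows).fillna(0.0)
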