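"""smFISH quantification and cell-to-cluster mapping.

Given a table of segmented cells (section, subregion, position, raw value
per marker gene) the module calls gene-positive cells, summarizes positive
fractions per BLA subregion, correlates subregions by their fraction
vectors, decomposes rasterized marker maps into eigen-images (PCA), and
assigns each cell to the transcriptomic cluster whose scaled profile its
marker vector correlates with best (Pearson, argmax).

Coordinates are in micrometres with the image convention: origin at the
section's top-left, y increasing downward.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree
from scipy.spatial.distance import squareform
from skimage.filters import threshold_otsu

from .simdata import AlignmentError, ParameterError

__all__ = [
    "SpatialConfig",
    "SubregionFractions",
    "EigenImageResult",
    "AssignmentResult",
    "call_positive_cells",
    "subregion_fractions",
    "subregion_correlation",
    "compute_eigen_images",
    "local_normalize",
    "assign_cells_to_clusters",
]

_META_COLS = ("cell_id", "section", "subregion", "x_um", "y_um")


def gene_columns(cells: pd.DataFrame) -> list[str]:
    """Marker-gene value columns of a cell table (everything that is not
    metadata or a pos_* flag)."""
    return [
        c
        for c in cells.columns
        if c not in _META_COLS and not str(c).startswith("pos_")
    ]


@dataclass(frozen=True)
class SpatialConfig:
    """Spatial-analysis knobs.

    neighbor_radius_um: radius of the local normalization neighborhood.
    pixel_size_um / smoothing_sigma_px: eigen-image raster resolution and
    Gaussian smoothing.  threshold_method: how per-gene positive thresholds
    are derived from log1p raw values (otsu | quantile | fixed).
    """

    neighbor_radius_um: float = 50.0
    pixel_size_um: float = 50.0
    smoothing_sigma_px: float = 1.0
    threshold_method: str = "otsu"
    quantile: float = 0.8
    fixed_thresholds: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.neighbor_radius_um <= 0 or self.pixel_size_um <= 0:
            raise ParameterError("radii and pixel size must be > 0")
        if self.threshold_method not in ("otsu", "quantile", "fixed"):
            raise ParameterError(f"unknown threshold method {self.threshold_method!r}")


def _gene_threshold(values: np.ndarray, gene: str, cfg: SpatialConfig) -> float:
    """Per-gene positive/negative threshold, in raw units."""
    if cfg.threshold_method == "fixed":
        if gene not in cfg.fixed_thresholds:
            raise ParameterError(f"no fixed threshold for gene {gene!r}")
        return float(cfg.fixed_thresholds[gene])
    logv = np.log1p(values)
    if cfg.threshold_method == "quantile":
        return float(np.expm1(np.quantile(logv, cfg.quantile)))
    # otsu on log1p values; degenerate (constant) input -> threshold 0
    if np.ptp(logv) == 0:
        warnings.warn(f"gene {gene!r}: constant values, Otsu threshold set to 0")
        return 0.0
    return float(np.expm1(threshold_otsu(logv)))


def call_positive_cells(cells: pd.DataFrame, cfg: SpatialConfig) -> pd.DataFrame:
    """Set per-gene positive flags (``pos_<gene>`` columns).

    The threshold is computed by ``cfg.threshold_method`` on log1p raw values
    and a cell is positive iff its raw value is strictly above it.  The
    thresholds used are recorded in ``result.attrs['thresholds']``.
    """
    out = cells.copy()
    thresholds = {}
    for g in gene_columns(cells):
        thr = _gene_threshold(out[g].to_numpy(float), g, cfg)
        thresholds[g] = thr
        out[f"pos_{g}"] = out[g].to_numpy(float) > thr
        if not out[f"pos_{g}"].any():
            warnings.warn(f"gene {g!r}: zero positive cells at threshold {thr:g}")
    out.attrs["thresholds"] = thresholds
    return out


@dataclass
class SubregionFractions:
    """Percentage of gene-positive cells per subregion.

    Cells positive for several genes count once per gene, so a subregion's
    row can sum to more than 100%.  Empty subregions are flagged undefined.
    """

    fractions: pd.DataFrame  # subregion x gene, percent
    cell_counts: pd.Series
    empty_subregions: list[str]


def subregion_fractions(cells: pd.DataFrame) -> SubregionFractions:
    genes = gene_columns(cells)
    flag_cols = [f"pos_{g}" for g in genes]
    missing = [c for c in flag_cols if c not in cells.columns]
    if missing:
        raise ParameterError("positive flags not set; run call_positive_cells first")
    counts = cells.groupby("subregion").size()
    frac = (
        cells.groupby("subregion")[flag_cols].mean().mul(100.0)
    )
    frac.columns = genes
    empty = [s for s in frac.index if counts.get(s, 0) == 0]
    return SubregionFractions(frac, counts, empty)


def subregion_correlation(fr: SubregionFractions):
    """Pearson r between subregion gene-fraction vectors, plus a leaf order
    from average-linkage clustering of 1 - r.

    Zero-variance subregion vectors yield undefined (NaN) correlations and
    are excluded from the clustering.
    """
    mat = fr.fractions.drop(index=fr.empty_subregions, errors="ignore")
    if len(mat) < 2:
        raise ParameterError("need >= 2 defined subregions")
    X = mat.to_numpy(float)
    sd = X.std(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        r = np.corrcoef(X)
    r[sd == 0, :] = np.nan
    r[:, sd == 0] = np.nan
    np.fill_diagonal(r, 1.0)
    corr = pd.DataFrame(r, index=mat.index, columns=mat.index)
    ok = sd > 0
    order = list(mat.index[ok])
    if ok.sum() >= 2:
        sub = r[np.ix_(ok, ok)]
        d = np.clip(1.0 - sub, 0.0, None)
        np.fill_diagonal(d, 0.0)
        Z = sch.linkage(squareform(d, checks=False), method="average")
        order = [mat.index[np.flatnonzero(ok)[i]] for i in sch.leaves_list(Z)]
    return corr, order


@dataclass
class EigenImageResult:
    """PCA decomposition of rasterized, smoothed positive-cell maps."""

    section: str
    origin_um: tuple[float, float]
    shape_px: tuple[int, int]
    pixel_size_um: float
    genes: list[str]
    loadings: np.ndarray  # genes x PCs
    variance_fraction: np.ndarray  # per PC, non-increasing, sums to 1
    score_maps: np.ndarray  # PCs x ny x nx

    @property
    def top4_variance(self) -> float:
        """Cumulative variance fraction of the top 4 PCs."""
        return float(self.variance_fraction[:4].sum())


def compute_eigen_images(
    cells: pd.DataFrame, cfg: SpatialConfig, section: str
) -> EigenImageResult:
    """Rasterize per-gene positive-cell counts for one section, smooth them,
    and decompose the pixels x genes matrix by PCA (columns centred).

    Variance fractions are reported over all PCs (they sum to 1); a section
    where only one gene has a nonzero map degenerates to a single PC at 100%
    of the variance, with a warning.
    """
    genes = gene_columns(cells)
    sec = cells[cells["section"] == section]
    if not len(sec):
        raise ParameterError(f"no cells in section {section!r}")
    flag_cols = [f"pos_{g}" for g in genes]
    if any(c not in sec.columns for c in flag_cols):
        raise ParameterError("positive flags not set; run call_positive_cells first")
    px = cfg.pixel_size_um
    x = sec["x_um"].to_numpy(float)
    y = sec["y_um"].to_numpy(float)
    x0 = np.floor(x.min() / px) * px
    y0 = np.floor(y.min() / px) * px
    nx = int(np.floor((x.max() - x0) / px)) + 1
    ny = int(np.floor((y.max() - y0) / px)) + 1
    ix = np.minimum(((x - x0) / px).astype(int), nx - 1)
    iy = np.minimum(((y - y0) / px).astype(int), ny - 1)
    maps = np.zeros((len(genes), ny, nx))
    for gi, g in enumerate(genes):
        pos = sec[f"pos_{g}"].to_numpy(bool)
        np.add.at(maps[gi], (iy[pos], ix[pos]), 1.0)
        if cfg.smoothing_sigma_px > 0:
            maps[gi] = gaussian_filter(maps[gi], cfg.smoothing_sigma_px)
    nonzero = maps.reshape(len(genes), -1).any(axis=1)
    if nonzero.sum() < 2:
        warnings.warn(
            f"section {section!r}: fewer than 2 genes with nonzero maps; "
            "PCA degenerates to a single component"
        )
    X = maps.reshape(len(genes), -1).T  # pixels x genes
    Xc = X - X.mean(axis=0, keepdims=True)
    if not np.any(Xc):
        raise ParameterError(f"section {section!r}: all maps empty or constant")
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = S**2
    var_frac = var / var.sum()
    scores = (U * S).T.reshape(-1, ny, nx)
    return EigenImageResult(
        section=section,
        origin_um=(x0, y0),
        shape_px=(ny, nx),
        pixel_size_um=px,
        genes=genes,
        loadings=Vt.T,
        variance_fraction=var_frac,
        score_maps=scores,
    )


def local_normalize(cells: pd.DataFrame, cfg: SpatialConfig) -> pd.DataFrame:
    """Per-cell feature vectors: neighborhood sums then per-gene z-scores.

    For every cell, raw values are summed over all cells of the same section
    within ``cfg.neighbor_radius_um`` (Euclidean, boundary inclusive, self
    included), then z-scored per gene across the cells of that section
    (population standard deviation).  Sections with fewer than two cells get
    NaN features and stay unassigned downstream.
    """
    genes = gene_columns(cells)
    feats = np.full((len(cells), len(genes)), np.nan)
    for section, idx in cells.groupby("section").groups.items():
        sub = cells.loc[idx]
        coords = sub[["x_um", "y_um"]].to_numpy(float)
        raw = sub[genes].to_numpy(float)
        if len(sub) < 2:
            continue
        tree = cKDTree(coords)
        neighbors = tree.query_ball_point(coords, cfg.neighbor_radius_um)
        sums = np.vstack([raw[nb].sum(axis=0) for nb in neighbors])
        mu = sums.mean(axis=0)
        sd = sums.std(axis=0)
        z = np.where(sd > 0, (sums - mu) / np.where(sd > 0, sd, 1.0), 0.0)
        feats[cells.index.get_indexer(idx)] = z
    out = pd.DataFrame(feats, index=cells.index, columns=genes)
    out.insert(0, "cell_id", cells["cell_id"].values)
    return out


@dataclass
class AssignmentResult:
    """Per-cell cluster assignment by highest Pearson correlation."""

    assignments: pd.DataFrame  # cell_id, cluster (may be NA), r
    r_matrix: pd.DataFrame  # cells x clusters

    @property
    def n_unassigned(self) -> int:
        return int(self.assignments["cluster"].isna().sum())


def assign_cells_to_clusters(features: pd.DataFrame, profile) -> AssignmentResult:
    """Assign each cell to the cluster with the highest Pearson r between the
    cell's gene feature vector and the cluster's scaled profile row.

    Ties break to the lowest cluster id; cells whose feature vector has zero
    variance (or NaNs) have undefined correlation and stay unassigned.
    """
    genes = [c for c in features.columns if c != "cell_id"]
    if list(genes) != list(profile.genes):
        if sorted(genes) != sorted(profile.genes):
            raise AlignmentError("feature genes do not match profile genes")
        features = features[["cell_id"] + list(profile.genes)]
        genes = list(profile.genes)
    order = np.argsort(np.asarray(profile.clusters, dtype=object))
    clusters = [profile.clusters[i] for i in order]
    P = profile.scaled[order]
    Pc = P - P.mean(axis=1, keepdims=True)
    pn = np.linalg.norm(Pc, axis=1)
    if (pn == 0).any():
        warnings.warn("constant cluster profile row(s): correlations undefined for them")
    Pz = np.where(pn[:, None] > 0, Pc / np.where(pn[:, None] > 0, pn[:, None], 1.0), np.nan)
    F = features[genes].to_numpy(float)
    Fc = F - np.nanmean(F, axis=1, keepdims=True)
    fn = np.linalg.norm(Fc, axis=1)
    valid = np.isfinite(F).all(axis=1) & (fn > 0)
    Fz = np.zeros_like(F)
    Fz[valid] = Fc[valid] / fn[valid, None]
    R = Fz @ Pz.T  # cells x clusters, Pearson r
    R[~valid] = np.nan
    best = np.full(len(F), -1)
    best_r = np.full(len(F), np.nan)
    if R.shape[1]:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            finite_any = np.isfinite(R).any(axis=1)
        ok = valid & finite_any
        best[ok] = np.nanargmax(R[ok], axis=1)  # first occurrence = lowest id
        best_r[ok] = R[ok, best[ok]]
    assigned = pd.DataFrame(
        {
            "cell_id": features["cell_id"].values,
            "cluster": [clusters[b] if b >= 0 else pd.NA for b in best],
            "r": best_r,
        }
    )
    r_matrix = pd.DataFrame(R, index=features["cell_id"].values, columns=clusters)
    return AssignmentResult(assigned, r_matrix)
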