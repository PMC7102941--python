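"""Single-molecule localization microscopy: I/O, rendering, Voronoi
density segmentation, multicolor overlap, and localization precision.

Localization tables (ThunderSTORM-style delimited text) are parsed into
DataFrames with nm coordinates.  Local density is the inverse Voronoi
first-rank cell area; partitioning the density distribution at a fixed
threshold separates *clustered* (high-density aggregates) from *diffuse*
(sparse, individual-molecule) pools — the diffuse ribosomal-protein pool
being the translationally engaged, puromycin-sensitive one.  Fractional
overlap between thresholded channel images follows the image-calculator
formulas

    2-color: (R*G) / (R + G - R*G)
    3-color: (R*G*B) / [R + G + B - R*B - R*G - G*B + R*G*B]

which, aggregated over pixels of {0,1} images, are exactly the Jaccard
index of the masks (intersection over union).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.spatial import QhullError, Voronoi

__all__ = [
    "DensityPartition",
    "PrecisionEstimate",
    "RoiTransferResult",
    "read_localizations",
    "write_localizations",
    "render_localizations",
    "local_density",
    "partition_by_density",
    "threshold_8bit",
    "fractional_overlap2",
    "fractional_overlap3",
    "roi_transfer",
    "estimate_localization_precision",
]

#: clustered/diffuse boundary in the units the source analysis used
#: ("localizations per nm^2"); configurable everywhere it is consumed.
DEFAULT_DENSITY_THRESHOLD = 40.0

_FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))

_X_ALIASES = {"x [nm]", "x_nm", "x (nm)", "x"}
_Y_ALIASES = {"y [nm]", "y_nm", "y (nm)", "y"}
_U_ALIASES = {"uncertainty [nm]", "uncertainty_nm", "uncertainty_xy [nm]", "uncertainty"}


def read_localizations(path) -> pd.DataFrame:
    """Read a delimited localization table (ThunderSTORM dialect accepted).

    Column headers are matched case-insensitively; ``x [nm]``/``y [nm]``,
    ``x_nm``/``y_nm`` and bare ``x``/``y`` all map onto the canonical
    ``x_nm``/``y_nm`` columns (coordinates are taken to be in nm).  Unknown
    columns are preserved.  Missing coordinate columns raise a
    ``ValueError`` listing the headers that were found.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    if df.columns.size and df.columns[0].startswith("Unnamed") and df.empty:
        pass
    rename = {}
    for col in df.columns:
        key = str(col).strip().strip('"').lower()
        if key in _X_ALIASES:
            rename[col] = "x_nm"
        elif key in _Y_ALIASES:
            rename[col] = "y_nm"
        elif key in _U_ALIASES:
            rename[col] = "uncertainty_nm"
        elif key == "frame":
            rename[col] = "frame"
        elif key == "id":
            rename[col] = "id"
        elif key == "channel":
            rename[col] = "channel"
    df = df.rename(columns=rename)
    missing = {"x_nm", "y_nm"} - set(df.columns)
    if missing:
        raise ValueError(
            f"missing coordinate column(s) {sorted(missing)}; headers found: "
            f"{list(df.columns)}")
    if "id" not in df.columns:
        df.insert(0, "id", np.arange(len(df)))
    if "frame" not in df.columns:
        df["frame"] = 0
    return df


def write_localizations(table: pd.DataFrame, path) -> None:
    """Write a localization table with ``id, frame, x [nm], y [nm], channel``
    headers (extra columns appended)."""
    out = table.copy()
    cols = {"x_nm": "x [nm]", "y_nm": "y [nm]", "uncertainty_nm": "uncertainty [nm]"}
    out = out.rename(columns=cols)
    lead = [c for c in ("id", "frame", "x [nm]", "y [nm]", "channel") if c in out.columns]
    rest = [c for c in out.columns if c not in lead]
    out[lead + rest].to_csv(path, index=False)


def render_localizations(
    table: pd.DataFrame,
    pixel_size_nm: float,
    mode: str = "histogram",
    extent_nm: tuple[float, float] | None = None,
    default_sigma_nm: float = 20.0,
) -> np.ndarray:
    """Render localizations onto a pixel grid.

    ``histogram`` mode gives integer counts per pixel (image sum = n);
    ``gaussian`` mode spreads each point with its own uncertainty (the
    ``uncertainty_nm`` column when present, else ``default_sigma_nm``),
    conserving total mass n.  ``extent_nm`` fixes the field of view
    (width, height); by default it covers the data.
    """
    if pixel_size_nm <= 0:
        raise ValueError("pixel_size_nm must be > 0")
    if len(table) < 1:
        raise ValueError("need at least one localization to render")
    x = table["x_nm"].to_numpy(dtype=float)
    y = table["y_nm"].to_numpy(dtype=float)
    if extent_nm is None:
        extent_nm = (float(x.max()) + pixel_size_nm, float(y.max()) + pixel_size_nm)
    w = int(math.ceil(extent_nm[0] / pixel_size_nm))
    h = int(math.ceil(extent_nm[1] / pixel_size_nm))
    ci = np.clip((x / pixel_size_nm).astype(int), 0, w - 1)
    ri = np.clip((y / pixel_size_nm).astype(int), 0, h - 1)
    if mode == "histogram":
        img = np.zeros((h, w), dtype=float)
        np.add.at(img, (ri, ci), 1.0)
        return img
    if mode != "gaussian":
        raise ValueError(f"mode must be 'histogram' or 'gaussian', got {mode!r}")
    if "uncertainty_nm" in table.columns:
        sig = table["uncertainty_nm"].to_numpy(dtype=float)
        sig = np.where(np.isfinite(sig) & (sig > 0), sig, default_sigma_nm)
    else:
        sig = np.full(len(table), default_sigma_nm)
    img = np.zeros((h, w), dtype=float)
    # render per unique sigma via a shared binned image + gaussian blur
    for s in np.unique(sig):
        sel = sig == s
        sub = np.zeros((h, w), dtype=float)
        np.add.at(sub, (ri[sel], ci[sel]), 1.0)
        img += gaussian_filter(sub, sigma=s / pixel_size_nm, mode="constant")
    # mass lost over the field border is redistributed so the image sums to n
    total = img.sum()
    if total > 0:
        img *= len(table) / total
    return img


def _polygon_area(pts: np.ndarray) -> float:
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def local_density(table: pd.DataFrame) -> pd.DataFrame:
    """Per-localization density as the inverse first-rank Voronoi cell area.

    Points whose Voronoi cell is unbounded (the convex-hull border) are
    flagged ``border=True`` and carry no density (NaN) rather than a
    clipped value.  Requires at least 4 non-collinear points; collinear
    input raises ``ValueError``.  Densities are in localizations per nm²
    when the coordinates are in nm.
    """
    pts = table[["x_nm", "y_nm"]].to_numpy(dtype=float)
    if pts.shape[0] < 4:
        raise ValueError(f"need >= 4 points for a Voronoi tessellation, got {pts.shape[0]}")
    try:
        vor = Voronoi(pts)
    except QhullError as exc:
        raise ValueError(f"degenerate point set (collinear?): {exc}") from exc
    dens = np.full(pts.shape[0], np.nan)
    border = np.zeros(pts.shape[0], dtype=bool)
    for i, reg_idx in enumerate(vor.point_region):
        region = vor.regions[reg_idx]
        if len(region) == 0 or -1 in region:
            border[i] = True
            continue
        area = _polygon_area(vor.vertices[region])
        if area <= 0:
            border[i] = True
            continue
        dens[i] = 1.0 / area
    return pd.DataFrame({"id": table["id"].to_numpy() if "id" in table.columns
                         else np.arange(pts.shape[0]),
                         "density": dens, "border": border})


@dataclass
class DensityPartition:
    """Clustered/diffuse partition of a localization set by local density.

    ``labels`` is per-point: 'clustered' (density >= threshold), 'diffuse'
    (below), or 'border' (unbounded Voronoi cell, excluded from
    classification).  ``hist_log10_edges``/``hist_counts`` describe the
    density histogram on a log scale for inspecting bimodality.
    """

    density: np.ndarray
    labels: np.ndarray
    threshold: float
    border: np.ndarray
    hist_log10_edges: np.ndarray
    hist_counts: np.ndarray

    @property
    def clustered_fraction(self) -> float:
        valid = ~self.border
        if valid.sum() == 0:
            return float("nan")
        return float((self.labels[valid] == "clustered").mean())


def automatic_density_threshold(densities: np.ndarray, n_bins: int = 50) -> float:
    """Threshold at the histogram minimum between the two largest modes of
    the log-density distribution."""
    d = densities[np.isfinite(densities) & (densities > 0)]
    if d.size < 4:
        raise ValueError("too few valid densities for automatic thresholding")
    logd = np.log10(d)
    counts, edges = np.histogram(logd, bins=n_bins)
    from scipy.signal import find_peaks
    smooth = np.convolve(counts, np.ones(3) / 3, mode="same")
    peaks, props = find_peaks(smooth, height=0)
    if peaks.size < 2:
        return float(10 ** np.median(logd))
    order = np.argsort(props["peak_heights"])[::-1]
    p1, p2 = sorted(peaks[order[:2]])
    valley = p1 + int(np.argmin(smooth[p1:p2 + 1]))
    mid = 0.5 * (edges[valley] + edges[valley + 1])
    return float(10 ** mid)


def partition_by_density(
    density_table: pd.DataFrame,
    threshold: float | str = DEFAULT_DENSITY_THRESHOLD,
    n_bins: int = 50,
) -> DensityPartition:
    """Partition localizations into clustered and diffuse pools.

    ``threshold`` is the density boundary (clustered at or above it); pass
    ``"auto"`` to place it at the minimum between the two largest modes of
    the log-density histogram.  Border points (no density) are excluded
    from classification.
    """
    dens = density_table["density"].to_numpy(dtype=float)
    border = density_table["border"].to_numpy(dtype=bool)
    if isinstance(threshold, str):
        if threshold != "auto":
            raise ValueError(f"threshold must be a number or 'auto', got {threshold!r}")
        thr = automatic_density_threshold(dens[~border])
    else:
        thr = float(threshold)
        if thr <= 0:
            raise ValueError("threshold must be > 0")
    labels = np.where(border, "border",
                      np.where(np.nan_to_num(dens, nan=-1.0) >= thr, "clustered", "diffuse"))
    valid = dens[np.isfinite(dens) & (dens > 0)]
    if valid.size:
        lo, hi = np.log10(valid.min()), np.log10(valid.max())
        if hi <= lo:
            hi = lo + 1e-9
        edges = np.linspace(lo, hi, n_bins + 1)
        counts, _ = np.histogram(np.log10(valid), bins=edges)
    else:
        edges = np.linspace(0, 1, n_bins + 1)
        counts = np.zeros(n_bins, dtype=int)
    return DensityPartition(density=dens, labels=labels, threshold=thr,
                            border=border, hist_log10_edges=edges, hist_counts=counts)


def threshold_8bit(image: np.ndarray, lo: int = 2, hi: int = 255) -> np.ndarray:
    """Fixed-point binary threshold on an 8-bit image: lo <= value <= hi.

    Images not representable in 0-255 (floats or wider integers) are
    rescaled min->0, max->255 (rounded) first; a constant image maps to 0.
    The 2-255 default captures everything above the lowest background
    count.
    """
    if lo > hi:
        raise ValueError(f"lo ({lo}) must be <= hi ({hi})")
    img = np.asarray(image)
    if not (np.issubdtype(img.dtype, np.integer) and img.min() >= 0 and img.max() <= 255):
        f = img.astype(float)
        rng = f.max() - f.min()
        if rng == 0:
            img = np.zeros(img.shape, dtype=np.uint8)
        else:
            img = np.round((f - f.min()) / rng * 255).astype(np.uint8)
    return (img >= lo) & (img <= hi)


def _check_masks(*masks: np.ndarray) -> list[np.ndarray]:
    out = [np.asarray(m, dtype=bool) for m in masks]
    shapes = {m.shape for m in out}
    if len(shapes) != 1:
        raise ValueError(f"mask shape mismatch: {sorted(shapes)}")
    return out


def fractional_overlap2(R: np.ndarray, G: np.ndarray) -> float:
    """Two-color fractional overlap (R*G)/(R + G - R*G) aggregated over
    pixels — the Jaccard index of the two masks.  NaN on an empty union."""
    R, G = _check_masks(R, G)
    inter = int((R & G).sum())
    denom = int(R.sum()) + int(G.sum()) - inter
    if denom == 0:
        warnings.warn("both masks empty; overlap undefined")
        return float("nan")
    return inter / denom


def fractional_overlap3(R: np.ndarray, G: np.ndarray, B: np.ndarray) -> float:
    """Three-color fractional overlap
    (R*G*B)/[R + G + B - R*B - R*G - G*B + R*G*B] — by inclusion-exclusion
    the triple intersection over the triple union."""
    R, G, B = _check_masks(R, G, B)
    rgb = int((R & G & B).sum())
    denom = (int(R.sum()) + int(G.sum()) + int(B.sum())
             - int((R & B).sum()) - int((R & G).sum()) - int((G & B).sum()) + rgb)
    if denom == 0:
        warnings.warn("all masks empty; overlap undefined")
        return float("nan")
    return rgb / denom


@dataclass
class RoiTransferResult:
    table: pd.DataFrame                 # roi id, area_px, one bool column per channel
    overlap_fraction: dict[str, float]  # fraction of ROIs overlapping each channel
    overlapping_areas: dict[str, np.ndarray]


def roi_transfer(
    roi_labels: np.ndarray,
    channels: dict[str, np.ndarray] | np.ndarray,
    areas_nm2: dict[int, float] | None = None,
) -> RoiTransferResult:
    """Transfer puncta ROIs onto thresholded channel images.

    ``roi_labels`` is a label image (0 = background, ROI ids > 0), e.g. the
    label image attached by puncta detection.  An ROI *overlaps* a channel
    when any of its pixels is nonzero in that channel's thresholded image.
    Returns the per-ROI flags, the fraction of overlapping ROIs per
    channel, and the areas of overlapping ROIs (nm² via ``areas_nm2`` when
    given, else pixel counts) for downstream size-distribution analysis.
    Channel images larger/smaller than the ROI image are compared on the
    common region, with a warning.
    """
    lab = np.asarray(roi_labels)
    if isinstance(channels, np.ndarray):
        channels = {"channel": channels}
    ids = np.unique(lab)
    ids = ids[ids > 0]
    area_px = {int(i): int((lab == i).sum()) for i in ids}
    recs: dict[str, np.ndarray] = {}
    for name, ch in channels.items():
        ch = np.asarray(ch)
        if ch.shape != lab.shape:
            warnings.warn(
                f"channel {name!r} shape {ch.shape} differs from ROI image "
                f"{lab.shape}; comparing the common region")
            h = min(ch.shape[0], lab.shape[0])
            w = min(ch.shape[1], lab.shape[1])
            chc, labc = ch[:h, :w], lab[:h, :w]
        else:
            chc, labc = ch, lab
        flags = np.zeros(ids.size, dtype=bool)
        hit = np.unique(labc[(chc != 0) & (labc > 0)])
        flags = np.isin(ids, hit)
        recs[name] = flags
    table = pd.DataFrame({"id": ids.astype(int),
                          "area_px": [area_px[int(i)] for i in ids]})
    overlap_fraction = {}
    overlapping_areas = {}
    for name, flags in recs.items():
        table[f"overlaps_{name}"] = flags
        overlap_fraction[name] = float(flags.mean()) if ids.size else float("nan")
        if areas_nm2 is not None:
            areas = np.array([areas_nm2.get(int(i), np.nan) for i in ids])
        else:
            areas = table["area_px"].to_numpy(dtype=float)
        overlapping_areas[name] = areas[flags]
    return RoiTransferResult(table=table, overlap_fraction=overlap_fraction,
                             overlapping_areas=overlapping_areas)


@dataclass
class PrecisionEstimate:
    sigma_nm: float
    fwhm_nm: float
    n_frames_used: int


def estimate_localization_precision(per_frame_centroids: np.ndarray) -> PrecisionEstimate:
    """Localization precision from repeated centroids of a fixed emitter.

    The per-frame centroid scatter of a bead imaged over many frames is
    modeled as an isotropic bi-dimensional Gaussian; the maximum-likelihood
    sigma is the RMS radial deviation divided by sqrt(2), and
    FWHM = 2 sqrt(2 ln 2) sigma.  Requires at least 100 centroids.
    """
    pts = np.asarray(per_frame_centroids, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("expected an (n, 2) array of centroids")
    if pts.shape[0] < 100:
        raise ValueError(f"need >= 100 centroids, got {pts.shape[0]}")
    centered = pts - pts.mean(axis=0)
    r2 = (centered ** 2).sum(axis=1)
    sigma = math.sqrt(float(r2.mean()) / 2.0)
    return PrecisionEstimate(sigma_nm=sigma, fwhm_nm=_FWHM_PER_SIGMA * sigma,
                             n_frames_used=pts.shape[0])
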