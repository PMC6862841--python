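"""Canopy coverage from plot RGB imagery.

Pipeline: Excess Green Index on chromaticity-normalized rgb, Otsu
thresholding of the ExG raster to separate canopy from soil, coverage as
the pixel fraction above the threshold, the median over replicate images of
a plot-date, and the average canopy coverage (ACC) as the mean of the
per-date medians.

ExG uses chromaticity coordinates (r = R/(R+G+B) etc.; a black pixel gets
r = g = b = 1/3), giving illumination invariance and a fixed [-1, 2] range
for stable histogramming.  The Otsu threshold is an equal-width bin edge
maximizing the between-class variance computed from exact per-bin sums, so
it agrees exactly with an exhaustive search over all candidate cuts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PlotImage",
    "CoverageObservation",
    "ACCRecord",
    "DegenerateImageError",
    "excess_green",
    "otsu_threshold",
    "coverage_from_image",
    "date_coverage",
    "average_canopy_coverage",
    "process_manifest",
    "acc_from_coverage",
]

DEFAULT_N_BINS = 256
#: ExG cutoff used when the raster is near-unimodal (all soil / all canopy)
GUARD_CUTOFF = 0.1
#: between-class variance below which Otsu is considered unstable
GUARD_VARIANCE_MIN = 1e-4


class DegenerateImageError(ValueError):
    """Raster has no contrast (constant ExG); no separable canopy."""


@dataclass
class PlotImage:
    """8-bit RGB raster of one plot at one sampling date."""

    pixels: np.ndarray  # (H, W, 3) uint8
    plot_id: str
    dap: int
    replicate_index: int = 0
    truth_mask: np.ndarray | None = None  # simulator ground truth, if any

    def __post_init__(self):
        p = np.asarray(self.pixels)
        if p.ndim != 3 or p.shape[2] != 3 or p.shape[0] < 1 or p.shape[1] < 1:
            raise ValueError("pixels must be an HxWx3 raster")
        if p.min() < 0 or p.max() > 255:
            raise ValueError("channel values must lie in [0, 255]")
        self.pixels = p


@dataclass
class CoverageObservation:
    plot_id: str
    dap: int
    coverage: float  # fraction in [0, 1]
    n_replicate_images: int
    threshold_used: float | None = None

    def __post_init__(self):
        if not 0.0 <= self.coverage <= 1.0:
            raise ValueError("coverage must lie in [0, 1]")
        if self.n_replicate_images < 1:
            raise ValueError("need at least one replicate image")


@dataclass
class ACCRecord:
    plot_id: str
    acc: float
    dates_used: tuple[int, ...]
    line_id: str | None = None


def excess_green(pixels: np.ndarray) -> np.ndarray:
    """Per-pixel ExG = 2g - r - b on chromaticity coordinates, in [-1, 2]."""
    p = np.asarray(pixels, dtype=float)
    total = p.sum(axis=-1, keepdims=True)
    chrom = np.where(total > 0, p / np.where(total > 0, total, 1.0), 1.0 / 3.0)
    return 2.0 * chrom[..., 1] - chrom[..., 0] - chrom[..., 2]


def _otsu_scan(values: np.ndarray, n_bins: int):
    """All candidate equal-width bin edges and their between-class variances.

    Class statistics use exact per-bin value sums (not bin centers); a value
    equal to an interior edge falls in the upper class, matching a raw
    partition at ``v < edge`` vs ``v >= edge``.
    """
    v = np.asarray(values, dtype=float).ravel()
    lo, hi = v.min(), v.max()
    if hi <= lo:
        raise DegenerateImageError("constant raster: no separable canopy")
    edges = np.linspace(lo, hi, n_bins + 1)
    idx = np.clip(np.searchsorted(edges, v, side="right") - 1, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins).astype(float)
    sums = np.bincount(idx, weights=v, minlength=n_bins)
    n = v.size
    c0 = np.cumsum(counts)[:-1]  # class 0 = bins 0..k for cut after bin k
    s0 = np.cumsum(sums)[:-1]
    c1 = n - c0
    s1 = v.sum() - s0
    w0 = c0 / n
    w1 = c1 / n
    with np.errstate(invalid="ignore", divide="ignore"):
        mu0 = np.where(c0 > 0, s0 / c0, 0.0)
        mu1 = np.where(c1 > 0, s1 / c1, 0.0)
    bcv = w0 * w1 * (mu0 - mu1) ** 2
    return edges[1:-1], bcv  # interior edges; edge k separates bins <=k from >k


def otsu_threshold(values: np.ndarray, n_bins: int = DEFAULT_N_BINS) -> float:
    """Equal-width-histogram Otsu threshold on an ExG raster.

    Returns the interior bin edge maximizing the between-class variance
    ``w0 w1 (mu0 - mu1)^2``; ties take the smallest edge.  Foreground is
    defined as values strictly greater than the returned threshold.
    Raises :class:`DegenerateImageError` on a constant raster.
    """
    edges, bcv = _otsu_scan(values, n_bins)
    return float(edges[int(np.argmax(bcv))])


def coverage_from_image(
    img: PlotImage | np.ndarray,
    n_bins: int = DEFAULT_N_BINS,
    guard_cutoff: float = GUARD_CUTOFF,
    guard_variance_min: float = GUARD_VARIANCE_MIN,
) -> tuple[float, float | None]:
    """Canopy pixel fraction of one image; returns (coverage, threshold).

    A constant ExG raster maps to coverage 0.  If the best between-class
    variance is below ``guard_variance_min`` the raster is near-unimodal
    (all soil or all canopy) and Otsu's split is meaningless; classification
    then falls back to the fixed cutoff ``ExG > guard_cutoff``.
    """
    pixels = img.pixels if isinstance(img, PlotImage) else np.asarray(img)
    exg = excess_green(pixels)
    try:
        edges, bcv = _otsu_scan(exg, n_bins)
    except DegenerateImageError:
        return 0.0, None
    k = int(np.argmax(bcv))
    if bcv[k] < guard_variance_min:
        return float(np.mean(exg > guard_cutoff)), None
    thr = float(edges[k])
    return float(np.mean(exg > thr)), thr


def date_coverage(
    plot_id: str, dap: int, replicate_coverages, threshold: float | None = None
) -> CoverageObservation:
    """Median over replicate-image coverages of one plot-date."""
    vals = np.asarray(list(replicate_coverages), dtype=float)
    if vals.size < 1:
        raise ValueError("need at least one replicate coverage")
    return CoverageObservation(
        plot_id=plot_id,
        dap=dap,
        coverage=float(np.median(vals)),
        n_replicate_images=int(vals.size),
        threshold_used=threshold,
    )


def average_canopy_coverage(per_date, line_id: str | None = None) -> ACCRecord:
    """ACC: unweighted mean of the per-date median coverages of one plot."""
    obs = list(per_date)
    if not obs:
        raise ValueError("need at least one date")
    plot_ids = {o.plot_id for o in obs}
    if len(plot_ids) != 1:
        raise ValueError("observations span multiple plots")
    return ACCRecord(
        plot_id=obs[0].plot_id,
        acc=float(np.mean([o.coverage for o in obs])),
        dates_used=tuple(sorted(o.dap for o in obs)),
        line_id=line_id,
    )


# ---------------------------------------------------------------------------
# batch pipeline over an image manifest
# ---------------------------------------------------------------------------

def process_manifest(
    manifest: pd.DataFrame,
    n_bins: int = DEFAULT_N_BINS,
    guard_cutoff: float = GUARD_CUTOFF,
    images: list[PlotImage] | None = None,
    base_dir=None,
) -> pd.DataFrame:
    """Per-plot-date coverage table from a manifest (or in-memory images).

    The manifest CSV has columns path, plot_id, dap, replicate, with paths
    resolved against ``base_dir`` (the manifest's own directory, typically);
    ``images`` bypasses file reading when the rasters are already in memory.
    """
    if images is None:
        from pathlib import Path

        import imageio.v3 as iio

        base = Path(base_dir) if base_dir is not None else Path(".")
        images = [
            PlotImage(
                pixels=np.asarray(iio.imread(base / r.path))[..., :3],
                plot_id=str(r.plot_id),
                dap=int(r.dap),
                replicate_index=int(r.replicate),
            )
            for r in manifest.itertuples(index=False)
        ]
    per = {}
    for im in images:
        cov, thr = coverage_from_image(im, n_bins=n_bins, guard_cutoff=guard_cutoff)
        per.setdefault((im.plot_id, im.dap), []).append((cov, thr))
    rows = []
    for (plot_id, dap), pairs in sorted(per.items()):
        covs = [c for c, _ in pairs]
        thrs = [t for _, t in pairs if t is not None]
        obs = date_coverage(plot_id, dap, covs)
        rows.append(
            {
                "plot_id": plot_id,
                "dap": dap,
                "coverage": obs.coverage,
                "n_images": obs.n_replicate_images,
                "threshold": float(np.median(thrs)) if thrs else np.nan,
            }
        )
    return pd.DataFrame(rows)


def acc_from_coverage(
    coverage: pd.DataFrame, line_map: pd.Series | None = None
) -> pd.DataFrame:
    """Aggregate the per-date coverage table to one ACC row per plot."""
    rows = []
    for plot_id, grp in coverage.groupby("plot_id", sort=True):
        obs = [
            CoverageObservation(
                plot_id=str(plot_id),
                dap=int(r.dap),
                coverage=float(r.coverage),
                n_replicate_images=int(r.n_images),
            )
            for r in grp.itertuples(index=False)
        ]
        rec = average_canopy_coverage(obs)
        rows.append(
            {
                "plot_id": rec.plot_id,
                "line_id": (
                    line_map.get(rec.plot_id, "") if line_map is not None else ""
                ),
                "acc": rec.acc,
                "n_dates": len(rec.dates_used),
            }
        )
    return pd.DataFrame(rows)
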