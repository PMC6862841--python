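"""Synthetic progeny-row experiment generator with known ground truth.

Emulates the data of an early-stage soybean breeding trial: a biparental
pedigree selfed to F4-type lines, correlated additive genetic values for
yield, average canopy coverage (ACC) and maturity (R8), an unreplicated
one-row-plot field with replicated checks and a smooth spatial trend, and
per-plot aerial RGB images whose green fraction tracks the true canopy
cover across early-season sampling dates.

Every generator is deterministic given its seed.  Ground truth (breeding
values, spatial field, residuals, true cover and canopy masks) is retained
so parameter recovery of every downstream stage can be tested.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .imaging import PlotImage
from .pedigree import AMatrix, build_a_matrix

__all__ = [
    "GeneticArchitecture",
    "FieldLayout",
    "SimTruth",
    "default_architecture",
    "simulate_pedigree",
    "terminal_lines",
    "simulate_breeding_values",
    "augmented_layout",
    "simulate_trial",
    "growth_curve",
    "assign_true_cover",
    "simulate_plot_images",
    "render_plot_image",
    "write_phenotype_csv",
    "write_images",
    "DATES_2015",
]

#: early-season sampling schedule (days after planting), first trial year
DATES_2015: tuple[int, ...] = (15, 29, 34, 37, 44, 47, 51, 54)

#: ground sampling distance of the imaging platform, cm per pixel
DEFAULT_GSD_CM = 1.5

#: one-row plot geometry, meters
PLOT_LENGTH_M = 1.83
ROW_SPACING_M = 0.76


# ---------------------------------------------------------------------------
# genetic architecture
# ---------------------------------------------------------------------------

@dataclass
class GeneticArchitecture:
    """Trait means, heritabilities, phenotypic SDs and genetic correlations.

    ``genetic_corr`` is the trait-by-trait additive correlation matrix; the
    additive SD of trait t is ``sqrt(h2[t]) * pheno_sd[t]``.
    """

    trait_names: tuple[str, ...]
    h2: np.ndarray
    genetic_corr: np.ndarray
    pheno_sd: np.ndarray
    trait_means: np.ndarray

    def __post_init__(self):
        self.trait_names = tuple(self.trait_names)
        self.h2 = np.asarray(self.h2, dtype=float)
        self.genetic_corr = np.asarray(self.genetic_corr, dtype=float)
        self.pheno_sd = np.asarray(self.pheno_sd, dtype=float)
        self.trait_means = np.asarray(self.trait_means, dtype=float)
        t = len(self.trait_names)
        if self.genetic_corr.shape != (t, t):
            raise ValueError("genetic_corr shape does not match trait_names")
        if not np.allclose(np.diag(self.genetic_corr), 1.0):
            raise ValueError("genetic_corr must have unit diagonal")
        if not np.allclose(self.genetic_corr, self.genetic_corr.T):
            raise ValueError("genetic_corr must be symmetric")
        if np.linalg.eigvalsh(self.genetic_corr).min() < -1e-10:
            raise ValueError("genetic_corr is not positive semidefinite")
        if np.any(self.h2 < 0) or np.any(self.h2 > 1):
            raise ValueError("h2 must lie in [0, 1]")
        if np.any(self.pheno_sd <= 0):
            raise ValueError("pheno_sd must be positive")

    @property
    def additive_sd(self) -> np.ndarray:
        return np.sqrt(self.h2) * self.pheno_sd

    @property
    def genetic_cov(self) -> np.ndarray:
        sa = self.additive_sd
        return self.genetic_corr * np.outer(sa, sa)

    def index(self, trait: str) -> int:
        return self.trait_names.index(trait)


def default_architecture(acc_yield_corr: float = 0.87) -> GeneticArchitecture:
    """Reference soybean scenario: yield (kg/ha), ACC (fraction), R8 (days).

    The ACC-yield additive correlation defaults to the high value reported
    for early-season canopy coverage in the literature this scenario mirrors.
    """
    return GeneticArchitecture(
        trait_names=("yield", "acc", "r8"),
        h2=np.array([0.25, 0.35, 0.50]),
        genetic_corr=np.array(
            [
                [1.0, acc_yield_corr, 0.30],
                [acc_yield_corr, 1.0, 0.00],
                [0.30, 0.00, 1.0],
            ]
        ),
        pheno_sd=np.array([400.0, 0.08, 5.0]),
        trait_means=np.array([3500.0, 0.45, 105.0]),
    )


# ---------------------------------------------------------------------------
# pedigree simulation
# ---------------------------------------------------------------------------

def simulate_pedigree(
    n_founders: int, n_crosses: int, selfing_generations: int, seed: int
) -> pd.DataFrame:
    """Founders, biparental crosses, then single-seed-descent selfing chains.

    Selfing is recorded as sire == dam == the single progenitor, so the
    tabular A-matrix accumulates inbreeding with no special cases.
    """
    if n_founders < 2:
        raise ValueError("need at least 2 founders")
    if n_crosses < 0 or selfing_generations < 0:
        raise ValueError("counts must be non-negative")
    rng = np.random.default_rng(seed)
    rows = [
        {"id": f"P{i:04d}", "sire": "", "dam": "", "generation": "founder"}
        for i in range(n_founders)
    ]
    founder_ids = [r["id"] for r in rows]
    for j in range(n_crosses):
        s, d = rng.choice(founder_ids, size=2, replace=False)
        prev = f"X{j:05d}"
        rows.append({"id": prev, "sire": s, "dam": d, "generation": "F1"})
        for t in range(1, selfing_generations + 1):
            cur = f"X{j:05d}S{t}"
            rows.append(
                {"id": cur, "sire": prev, "dam": prev, "generation": f"F{t + 1}"}
            )
            prev = cur
    return pd.DataFrame(rows, columns=["id", "sire", "dam", "generation"])


def terminal_lines(ped: pd.DataFrame) -> list[str]:
    """Ids never used as a parent — the finished (phenotyped) lines."""
    used = set(ped["sire"]) | set(ped["dam"])
    return [i for i in ped["id"] if i not in used]


# ---------------------------------------------------------------------------
# breeding values
# ---------------------------------------------------------------------------

def _psd_factor(m: np.ndarray) -> np.ndarray:
    """Symmetric square root with tiny negative eigenvalues clipped to 0."""
    w, v = np.linalg.eigh(m)
    if w.min() < -1e-8 * max(w.max(), 1.0):
        raise ValueError("matrix is not positive semidefinite")
    return v * np.sqrt(np.clip(w, 0.0, None))


@dataclass
class SimTruth:
    """Ground truth carried alongside the simulated observables."""

    breeding_values: pd.DataFrame
    spatial_field: dict = field(default_factory=dict)
    residuals: pd.DataFrame | None = None
    true_cover: pd.DataFrame | None = None


def simulate_breeding_values(
    ped: pd.DataFrame,
    arch: GeneticArchitecture,
    seed: int,
    amatrix: AMatrix | None = None,
) -> SimTruth:
    """Draw multitrait additive values ~ N(0, kron(G_trait, A)).

    Sampled as ``L_A Z L_G'`` with Z iid standard normal; traits with
    ``h2 == 0`` get exactly zero breeding values.
    """
    founders_only = amatrix is None and (
        (ped["sire"].fillna("") == "") & (ped["dam"].fillna("") == "")
    ).all()
    if amatrix is None and not founders_only:
        amatrix = build_a_matrix(ped)
    g_cov = arch.genetic_cov
    lg = _psd_factor(g_cov)
    if founders_only:  # A = I: skip the O(n^3) factorization
        ids = list(ped["id"])
        rng = np.random.default_rng(seed)
        z = rng.standard_normal((len(ids), len(arch.trait_names)))
        bv = z @ lg.T
        bv[:, arch.h2 == 0] = 0.0
        return SimTruth(
            breeding_values=pd.DataFrame(bv, index=ids,
                                         columns=list(arch.trait_names))
        )
    la = _psd_factor(amatrix.values)
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((len(amatrix.ids), len(arch.trait_names)))
    bv = la @ z @ lg.T
    bv[:, arch.h2 == 0] = 0.0
    return SimTruth(
        breeding_values=pd.DataFrame(
            bv, index=amatrix.ids, columns=list(arch.trait_names)
        )
    )


# ---------------------------------------------------------------------------
# field layout
# ---------------------------------------------------------------------------

@dataclass
class FieldLayout:
    """Grid of one-row plots: unreplicated lines plus replicated checks."""

    n_rows: int
    n_cols: int
    plot_assignments: np.ndarray  # (n_rows, n_cols) array of line/check ids
    check_ids: tuple[str, ...]
    plot_length_m: float = PLOT_LENGTH_M
    row_spacing_m: float = ROW_SPACING_M

    def __post_init__(self):
        self.plot_assignments = np.asarray(self.plot_assignments, dtype=object)
        if self.plot_assignments.shape != (self.n_rows, self.n_cols):
            raise ValueError("plot_assignments shape mismatch")
        flat = self.plot_assignments.ravel()
        counts = pd.Series(flat).value_counts()
        for c in self.check_ids:
            if counts.get(c, 0) < 2:
                raise ValueError(f"check {c} appears fewer than 2 times")
        lines = counts.drop(list(self.check_ids), errors="ignore")
        if (lines > 1).any():
            raise ValueError("experimental lines must be unreplicated")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        k = 0
        for r in range(self.n_rows):
            for c in range(self.n_cols):
                entry = self.plot_assignments[r, c]
                rows.append(
                    {
                        "plot_id": f"p{k:05d}",
                        "line_id": entry,
                        "is_check": entry in self.check_ids,
                        "field_row": r,
                        "field_col": c,
                    }
                )
                k += 1
        return pd.DataFrame(rows)


def augmented_layout(
    line_ids,
    check_ids,
    check_every: int = 10,
    n_cols: int = 40,
    seed: int = 0,
) -> FieldLayout:
    """Modified-augmented-design grid: a check every ``check_every`` plots.

    Lines are placed once each in randomized order; check cultivars cycle
    through the systematic check positions, and any tail cells left over in
    the last field row are filled with checks so every cell is assigned.
    """
    line_ids = list(line_ids)
    check_ids = tuple(check_ids)
    if not check_ids:
        raise ValueError("need at least one check cultivar")
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(line_ids))
    cells: list[str] = []
    ci = 0
    while order:
        if len(cells) % check_every == 0:
            cells.append(check_ids[ci % len(check_ids)])
            ci += 1
        else:
            cells.append(order.pop())
    n_rows = math.ceil(len(cells) / n_cols)
    while len(cells) < n_rows * n_cols:
        cells.append(check_ids[ci % len(check_ids)])
        ci += 1
    grid = np.array(cells, dtype=object).reshape(n_rows, n_cols)
    return FieldLayout(
        n_rows=n_rows, n_cols=n_cols, plot_assignments=grid, check_ids=check_ids
    )


# ---------------------------------------------------------------------------
# trial phenotypes
# ---------------------------------------------------------------------------

def _cosine_surface(n_rows: int, n_cols: int, rng: np.random.Generator) -> np.ndarray:
    """Smooth random surface: sum of 3 random-phase low-frequency cosines,
    rescaled to unit standard deviation."""
    r = np.arange(n_rows)[:, None]
    c = np.arange(n_cols)[None, :]
    surf = np.zeros((n_rows, n_cols))
    for _ in range(3):
        fr, fc = rng.uniform(0.5, 2.0, size=2)
        phase = rng.uniform(0, 2 * np.pi)
        amp = rng.uniform(0.5, 1.0)
        surf += amp * np.cos(
            2 * np.pi * (fr * r / max(n_rows, 1) + fc * c / max(n_cols, 1)) + phase
        )
    sd = surf.std()
    return surf / sd if sd > 0 else surf


def simulate_trial(
    layout: FieldLayout,
    truth: SimTruth,
    arch: GeneticArchitecture,
    spatial_sd,
    seed: int,
    residual_floor_frac: float = 1e-6,
) -> pd.DataFrame:
    """Plot phenotypes = mean + breeding value + spatial trend + residual.

    ``spatial_sd`` is in trait units (scalar broadcast to every trait, or a
    per-trait sequence).  One smooth surface is drawn for the whole field and
    scaled per trait: a fertility/moisture gradient raises (or lowers) every
    trait in the same plots, which induces the positive non-genetic
    correlation between canopy cover and yield seen in real trials.
    Residual variance is ``(1-h2)*sigma_p^2`` minus the spatial share,
    floored at ``residual_floor_frac * sigma_p^2``; a negative requested
    residual variance is an error.
    """
    plots = layout.to_frame()
    bv = truth.breeding_values
    missing = set(plots["line_id"]) - set(bv.index)
    if missing:
        raise ValueError(f"no breeding values for {sorted(missing)[:5]}")
    spatial_sd = np.broadcast_to(
        np.asarray(spatial_sd, dtype=float), (len(arch.trait_names),)
    )
    rng = np.random.default_rng(seed)
    rr = plots["field_row"].to_numpy()
    cc = plots["field_col"].to_numpy()
    bvals = bv.loc[plots["line_id"]].to_numpy()
    resid = np.empty((len(plots), len(arch.trait_names)))
    pheno = plots.copy()
    base_surf = _cosine_surface(layout.n_rows, layout.n_cols, rng)
    for t, name in enumerate(arch.trait_names):
        resid_var = (1.0 - arch.h2[t]) * arch.pheno_sd[t] ** 2 - spatial_sd[t] ** 2
        if resid_var < -1e-12 * arch.pheno_sd[t] ** 2:
            raise ValueError(
                f"trait {name}: spatial_sd exceeds the non-genetic variance"
            )
        resid_var = max(resid_var, residual_floor_frac * arch.pheno_sd[t] ** 2)
        surf = base_surf * spatial_sd[t]
        truth.spatial_field[name] = surf
        resid[:, t] = rng.normal(0.0, np.sqrt(resid_var), size=len(plots))
        pheno[name] = arch.trait_means[t] + bvals[:, t] + surf[rr, cc] + resid[:, t]
    truth.residuals = pd.DataFrame(
        resid, index=plots["plot_id"], columns=list(arch.trait_names)
    )
    return pheno


def write_phenotype_csv(pheno: pd.DataFrame, path, trial: str = "PR",
                        location: str = "LOC1", rep: int = 1, block: int = 1) -> None:
    """Write the standard phenotype CSV dialect (yield_kg_ha, r8_dap, ...)."""
    out = pd.DataFrame(
        {
            "plot_id": pheno["plot_id"],
            "line_id": pheno["line_id"],
            "trial": pheno.get("trial", trial),
            "location": pheno.get("location", location),
            "rep": pheno.get("rep", rep),
            "block": pheno.get("block", block),
            "field_row": pheno["field_row"],
            "field_col": pheno["field_col"],
            "yield_kg_ha": pheno.get("yield"),
            "r8_dap": pheno.get("r8"),
        }
    )
    out.to_csv(path, index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# canopy growth and plot images
# ---------------------------------------------------------------------------

def growth_curve(dap, cover_max: float, rate: float, midpoint: float):
    """Logistic canopy development: cover_max / (1 + exp(-rate*(dap - mid)))."""
    if not 0.0 < cover_max <= 1.0:
        raise ValueError("cover_max must be in (0, 1]")
    dap = np.asarray(dap, dtype=float)
    out = cover_max / (1.0 + np.exp(-rate * (dap - midpoint)))
    return float(out) if out.ndim == 0 else out


def assign_true_cover(
    truth: SimTruth,
    pheno: pd.DataFrame,
    dates=DATES_2015,
    rate: float = 0.16,
    midpoint: float = 33.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-plot true canopy-cover trajectories whose date-average equals the
    plot's simulated ACC phenotype (clipped to the feasible logistic range)."""
    dates = tuple(int(d) for d in dates)
    rng = np.random.default_rng(seed)
    n = len(pheno)
    rates = rate * rng.uniform(0.85, 1.15, n)
    mids = midpoint + rng.normal(0.0, 2.0, n)
    acc = np.clip(pheno["acc"].to_numpy(dtype=float), 0.02, 0.98)
    cover = np.empty((n, len(dates)))
    for i in range(n):
        unit = 1.0 / (1.0 + np.exp(-rates[i] * (np.asarray(dates) - mids[i])))
        cmax = min(1.0, acc[i] / unit.mean())
        cover[i] = cmax * unit
    truth.true_cover = pd.DataFrame(
        cover, index=pheno["plot_id"], columns=list(dates)
    )
    return truth.true_cover


def render_plot_image(
    cover: float,
    shape: tuple[int, int],
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """One synthetic aerial plot image and its ground-truth canopy mask.

    Canopy is a union of elliptical blobs centered on the planted row;
    blob scale is chosen so the mask covers exactly the requested pixel
    fraction (to within one pixel).  Canopy pixels are green-dominant with a
    per-blob margin; soil is brownish with R >= G.  Pixel-level brightness
    noise is multiplicative (shared across channels), so chromaticity stays
    tight within each class while the image still looks textured.
    """
    if not 0.0 <= cover <= 1.0:
        raise ValueError("cover must lie in [0, 1]")
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w].astype(float)

    if cover <= 0.0:
        mask = np.zeros((h, w), dtype=bool)
        blob = np.zeros((h, w), dtype=int)
    else:
        n_plants = max(4, w // 24)
        cx = (np.arange(n_plants) + 0.5) / n_plants * w
        cx = cx + rng.uniform(-0.25, 0.25, n_plants) * w / n_plants
        cy = h / 2.0 + rng.normal(0.0, 0.04 * h, n_plants)
        rx = (w / n_plants) * rng.uniform(0.7, 1.3, n_plants)
        ry = rx * rng.uniform(0.7, 1.2, n_plants)
        # normalized squared distance to the nearest blob center; thresholding
        # its quantile yields an ellipse-union mask at the exact target fraction
        d = np.full((h, w), np.inf)
        blob = np.zeros((h, w), dtype=int)
        for i in range(n_plants):
            di = ((xx - cx[i]) / rx[i]) ** 2 + ((yy - cy[i]) / ry[i]) ** 2
            closer = di < d
            d[closer] = di[closer]
            blob[closer] = i
        if cover >= 1.0:
            mask = np.ones((h, w), dtype=bool)
        else:
            mask = d <= np.quantile(d, cover)

    img = np.empty((h, w, 3))
    # soil: brownish, R >= G > B
    soil_r = 135.0 + rng.normal(0.0, 4.0)
    gap = rng.uniform(14.0, 18.0)
    img[..., 0] = soil_r
    img[..., 1] = soil_r - gap + rng.normal(0.0, 1.0, (h, w))
    img[..., 2] = 0.62 * soil_r + rng.normal(0.0, 1.0, (h, w))
    if mask.any():
        n_plants = blob.max() + 1
        g0 = 115.0 + rng.normal(0.0, 1.0, n_plants)
        margin = np.clip(rng.normal(52.0, 0.6, n_plants), 50.0, 54.0)
        gm = g0[blob]
        img[..., 1][mask] = gm[mask]
        img[..., 0][mask] = (gm - margin[blob])[mask] + rng.normal(
            0.0, 0.5, (h, w)
        )[mask]
        img[..., 2][mask] = (0.55 * gm)[mask] + rng.normal(0.0, 0.5, (h, w))[mask]
    # multiplicative brightness texture + per-image illumination gain
    gain = rng.uniform(0.9, 1.1) * (1.0 + 0.08 * rng.standard_normal((h, w)))
    img *= gain[..., None]
    return np.clip(img, 0, 255).astype(np.uint8), mask


def simulate_plot_images(
    truth: SimTruth,
    dates=None,
    image_px: tuple[int, int] = (256, 256),
    gsd_cm: float = DEFAULT_GSD_CM,
    n_replicate_images: int = 3,
    seed: int = 0,
    plots=None,
) -> list[PlotImage]:
    """Render replicate RGB images for every plot-date in ``truth.true_cover``.

    Replicates of the same plot-date re-jitter blob placement and
    illumination but share the target cover.  Ground-truth masks ride along
    on each :class:`PlotImage`.
    """
    if truth.true_cover is None:
        raise ValueError("truth has no true_cover; run assign_true_cover first")
    cover_tab = truth.true_cover
    if plots is not None:
        cover_tab = cover_tab.loc[list(plots)]
    if dates is not None:
        cover_tab = cover_tab[[int(d) for d in dates]]
    if (cover_tab.to_numpy() < 0).any() or (cover_tab.to_numpy() > 1).any():
        raise ValueError("true_cover must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    images = []
    for plot_id, row in cover_tab.iterrows():
        for dap, cov in row.items():
            for k in range(n_replicate_images):
                pixels, mask = render_plot_image(float(cov), image_px, rng)
                images.append(
                    PlotImage(
                        pixels=pixels,
                        plot_id=str(plot_id),
                        dap=int(dap),
                        replicate_index=k,
                        truth_mask=mask,
                    )
                )
    return images


def write_images(images: list[PlotImage], outdir) -> pd.DataFrame:
    """Write PNGs + parallel mask PNGs and an index manifest CSV."""
    import imageio.v3 as iio
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for im in images:
        stem = f"{im.plot_id}_{im.dap}_{im.replicate_index}"
        path = outdir / f"{stem}.png"
        iio.imwrite(path, im.pixels)
        mask_path = ""
        if im.truth_mask is not None:
            mask_path = f"{stem}_mask.png"
            iio.imwrite(outdir / mask_path, (im.truth_mask * 255).astype(np.uint8))
        rows.append(
            {
                # paths relative to the manifest so the directory is portable
                "path": path.name,
                "mask_path": mask_path,
                "plot_id": im.plot_id,
                "dap": im.dap,
                "replicate": im.replicate_index,
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(outdir / "manifest.csv", index=False)
    return manifest
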