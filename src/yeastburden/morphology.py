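"""Cell-elongation morphometry from labeled segmentation masks.

Segmentation is upstream (any tool producing an integer label mask, 0 =
background).  Each retained region is summarized by its equivalent ellipse —
the ellipse with the same normalized second central moments as the region —
and elongation is the axis ratio major/minor.  Strain-level statistics
follow the study design: subsample a fixed number of cells per biological
replicate, pool replicates, compare the axis-ratio dispersion against a
control strain with Levene's test, and Bonferroni-adjust over the family of
strain-vs-control comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from skimage import measure

__all__ = [
    "CellShape",
    "StrainMorphology",
    "extract_shapes",
    "sample_cells",
    "levene_test",
    "bonferroni_adjust",
    "strain_summary",
    "elongation_property_correlation",
    "dead_cell_fraction",
]


@dataclass(frozen=True)
class CellShape:
    """Equivalent-ellipse geometry of one segmented cell.

    Axis lengths are ``4 * sqrt(eigenvalue)`` of the normalized second
    central moment matrix (the convention of CellProfiler's
    AreaShape_MajorAxisLength / MinorAxisLength); pixel size is 1 unit, so
    the axis ratio is dimensionless.
    """

    label: int
    area: int
    centroid: tuple[float, float]
    major_axis_length: float
    minor_axis_length: float
    orientation: float
    axis_ratio: float
    border_touching: bool


@dataclass
class StrainMorphology:
    """Pooled per-strain axis-ratio sample and its statistics vs. a control."""

    strain_id: str
    ratios: np.ndarray
    areas: np.ndarray
    mean_axis_ratio: float
    mean_area: float
    n_cells: int
    levene_W: float | None = None
    p_raw: float | None = None
    p_adjusted: float | None = None
    mean_size_normalized: float | None = None


def extract_shapes(
    mask: np.ndarray,
    min_area: int = 50,
    exclude_border: bool = True,
) -> list[CellShape]:
    """Measure every labeled region of ``mask`` as an equivalent ellipse.

    Regions smaller than ``min_area`` pixels, regions touching the image
    border (when ``exclude_border``), and degenerate regions whose minor
    axis is zero (e.g. single-pixel-wide lines) are dropped; drops are
    reported via warnings.  A label split into several connected components
    triggers a warning but is still measured as one region.
    """
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError("mask must be a 2D integer label image")
    if not np.issubdtype(mask.dtype, np.integer):
        raise ValueError("mask must have an integer dtype")

    h, w = mask.shape
    shapes: list[CellShape] = []
    n_small = n_border = n_degenerate = 0
    for region in measure.regionprops(mask):
        if region.area < min_area:
            n_small += 1
            continue
        minr, minc, maxr, maxc = region.bbox
        touching = minr == 0 or minc == 0 or maxr == h or maxc == w
        if exclude_border and touching:
            n_border += 1
            continue
        if measure.label(region.image, connectivity=2).max() > 1:
            warnings.warn(
                f"label {region.label} is not a single connected region",
                stacklevel=2,
            )
        major = float(region.axis_major_length)
        minor = float(region.axis_minor_length)
        if minor <= 0:
            n_degenerate += 1
            continue
        shapes.append(
            CellShape(
                label=int(region.label),
                area=int(region.area),
                centroid=tuple(float(c) for c in region.centroid),
                major_axis_length=major,
                minor_axis_length=minor,
                orientation=float(region.orientation),
                axis_ratio=major / minor,
                border_touching=touching,
            )
        )
    dropped = n_small + n_border + n_degenerate
    if dropped:
        warnings.warn(
            f"dropped {dropped} regions ({n_small} below min_area, "
            f"{n_border} border-touching, {n_degenerate} degenerate)",
            stacklevel=2,
        )
    if not shapes:
        warnings.warn("no regions retained from mask", stacklevel=2)
    return shapes


def sample_cells(
    shapes: list[CellShape],
    n: int = 100,
    seed: int | np.random.Generator = 0,
) -> list[CellShape]:
    """Uniform subsample of ``n`` cells without replacement.

    Mirrors the sampling design of picking a fixed number of cells from the
    pooled images of one replicate.  If fewer than ``n`` cells are
    available, all are returned with a warning.
    """
    rng = np.random.default_rng(seed)
    if len(shapes) <= n:
        if len(shapes) < n:
            warnings.warn(
                f"only {len(shapes)} cells available, requested {n}",
                stacklevel=2,
            )
        return list(shapes)
    idx = rng.choice(len(shapes), size=n, replace=False)
    return [shapes[i] for i in idx]


def levene_test(
    groups: list[np.ndarray] | list[list[float]],
    center: str = "mean",
) -> tuple[float, float]:
    """Levene's test for equality of variances across ``groups``.

    ``center='mean'`` is the classic Levene statistic; ``'median'`` gives
    the Brown–Forsythe variant.  The W statistic is referred to an
    F(k-1, N-k) distribution.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group needs at least two observations")
    if center not in ("mean", "median"):
        raise ValueError("center must be 'mean' or 'median'")
    centerfun = np.mean if center == "mean" else np.median
    z = [np.abs(a - centerfun(a)) for a in arrays]
    denom = sum(float(np.sum((zi - zi.mean()) ** 2)) for zi in z)
    if denom == 0:
        raise ValueError("degenerate data: all within-group deviations identical")
    W, p = stats.levene(*arrays, center=center)
    return float(W), float(p)


def bonferroni_adjust(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni correction: ``min(1, p * m)`` for a family of ``m`` tests.

    ``m`` defaults to the number of p-values supplied (the family of
    strain-vs-control comparisons in one experiment).
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < 1:
        raise ValueError("family size must be >= 1")
    return np.minimum(1.0, p * m)


def strain_summary(
    strain_id: str,
    replicate_shapes: list[list[CellShape]],
    control: StrainMorphology | None = None,
    n_per_replicate: int = 100,
    seed: int = 0,
    family_size: int = 1,
    center: str = "mean",
) -> StrainMorphology:
    """Pool sampled cells across replicates and test dispersion vs. control.

    Each replicate contributes ``n_per_replicate`` randomly chosen cells
    (default 100 cells x 3 replicates = 300).  With a ``control`` summary,
    Levene's test compares the pooled axis-ratio samples and the p-value is
    Bonferroni-adjusted for ``family_size`` comparisons; mean cell size is
    normalized by the control's mean area.  With ``control=None`` the
    returned summary is itself usable as the control.
    """
    if not replicate_shapes or all(len(r) == 0 for r in replicate_shapes):
        raise ValueError(f"{strain_id}: no cells supplied")
    rng = np.random.default_rng(seed)
    pooled: list[CellShape] = []
    for rep in replicate_shapes:
        pooled.extend(sample_cells(rep, n=n_per_replicate, seed=rng))
    ratios = np.array([c.axis_ratio for c in pooled])
    areas = np.array([c.area for c in pooled], dtype=float)
    summary = StrainMorphology(
        strain_id=strain_id,
        ratios=ratios,
        areas=areas,
        mean_axis_ratio=float(ratios.mean()),
        mean_area=float(areas.mean()),
        n_cells=ratios.size,
    )
    if control is not None:
        W, p = levene_test([summary.ratios, control.ratios], center=center)
        summary.levene_W = W
        summary.p_raw = p
        summary.p_adjusted = float(bonferroni_adjust([p], m=family_size)[0])
        summary.mean_size_normalized = summary.mean_area / control.mean_area
    return summary


def elongation_property_correlation(
    mean_ratios,
    property_values,
) -> tuple[float, float]:
    """Pearson correlation between strain mean axis ratios and a per-strain
    protein property (e.g. cysteine count per molecule), with the two-sided
    p-value from the t transform."""
    x = np.asarray(mean_ratios, dtype=float)
    y = np.asarray(property_values, dtype=float)
    if x.size != y.size:
        raise ValueError("inputs must have equal length")
    if x.size < 3:
        raise ValueError("need at least three strains")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined: zero variance in an input")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def dead_cell_fraction(flags, min_cells: int = 300) -> float:
    """Percentage of dead cells from boolean alive/dead flags pooled across
    replicates.  Warns when fewer than ``min_cells`` cells are supplied."""
    f = np.asarray(flags, dtype=bool)
    if f.size == 0:
        raise ValueError("no cells supplied")
    if f.size < min_cells:
        warnings.warn(
            f"only {f.size} cells (< {min_cells}); dead-cell fraction may be noisy",
            stacklevel=2,
        )
    return 100.0 * float(f.sum()) / f.size
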