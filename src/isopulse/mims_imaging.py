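"""Multi-isotope imaging mass spectrometry (MIMS) ratio-image quantification.

NanoSIMS acquisition counts 12C14N-, 12C15N- and 31P- secondary ions per
pixel. The per-pixel 15N/14N count ratio R is expressed relative to the
natural-abundance baseline R0 (0.37% by the imaging convention) as

    P = 100 * (R/R0 - 1)   [percent above background]

so unlabeled material reads 0%. This module builds ratio images with a
low-count validity mask, renders the hue-saturation-intensity (HSI) view
(blue at the lower bound to magenta at the upper), stitches acquisition
tiles into mosaics, segments nuclei from the 31P channel, summarises regions
of interest, and computes the per-cell nuclear/cytoplasmic ratio-of-means
tested against a hypothetical value of 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as _ndi

from .constants import MIMS_BASELINE_RATIO
from .synthetic_data import IonImageStack
from .stats_report import TestResult, one_sample_test

DEFAULT_MIN_14N_COUNTS = 20  # pixels below this 14N count are masked invalid

# HSI hue path: blue at the lower display bound, magenta at the upper
HUE_BLUE = 2.0 / 3.0
HUE_MAGENTA = 5.0 / 6.0


@dataclass
class RatioImage:
    """Per-pixel 15N/14N ratio grid with validity mask and baseline."""

    ratio: np.ndarray
    valid: np.ndarray
    baseline: float = MIMS_BASELINE_RATIO
    total_counts: np.ndarray | None = None  # for HSI intensity scaling

    @property
    def percent_above(self) -> np.ndarray:
        """P = 100 * (R/R0 - 1); exactly 0 where R equals the baseline."""
        return percent_above_background(self.ratio, self.baseline)

    def valid_values(self) -> np.ndarray:
        return self.ratio[self.valid]


def ratio_image(
    stack: IonImageStack,
    min_14n_counts: int = DEFAULT_MIN_14N_COUNTS,
    baseline: float = MIMS_BASELINE_RATIO,
) -> RatioImage:
    """15N/14N ratio per pixel; low-count pixels are masked invalid."""
    n14 = np.asarray(stack.n14, dtype=float)
    n15 = np.asarray(stack.n15, dtype=float)
    if n14.shape != n15.shape:
        raise ValueError("channel shapes differ")
    valid = n14 >= max(min_14n_counts, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(valid, n15 / np.where(n14 > 0, n14, 1.0), np.nan)
    return RatioImage(
        ratio=r,
        valid=valid,
        baseline=baseline,
        total_counts=n14 + n15,
    )


def percent_above_background(ratio, baseline: float = MIMS_BASELINE_RATIO):
    """Percent above the natural-abundance baseline: 100 * (R/R0 - 1)."""
    if baseline <= 0:
        raise ValueError("baseline ratio must be positive")
    return 100.0 * (np.asarray(ratio, dtype=float) / baseline - 1.0)


# ---------------------------------------------------------------------------
# HSI rendering
# ---------------------------------------------------------------------------


@dataclass
class HsiRender:
    """RGB view of a ratio image; display-only, never used for statistics."""

    rgb: np.ndarray
    lower_percent: float
    upper_percent: float


def hsi_render(
    image: RatioImage,
    lower_percent: float = 0.0,
    upper_percent: float = 300.0,
    intensity: np.ndarray | None = None,
) -> HsiRender:
    """Hue-saturation-intensity transform of the percent-above map.

    Hue runs linearly from blue at ``lower_percent`` to magenta at
    ``upper_percent``, values clamped at the bounds. Brightness scales with
    total ion counts (or a supplied ``intensity`` array); invalid pixels are
    black. Rendering reads the ratio image and never modifies it.
    """
    if not (np.isfinite(lower_percent) and np.isfinite(upper_percent)):
        raise ValueError("HSI bounds must be finite")
    if lower_percent >= upper_percent:
        raise ValueError("lower bound must be below upper bound")
    from matplotlib.colors import hsv_to_rgb

    p = image.percent_above
    frac = np.clip((p - lower_percent) / (upper_percent - lower_percent), 0.0, 1.0)
    hue = HUE_BLUE + frac * (HUE_MAGENTA - HUE_BLUE)
    if intensity is None:
        intensity = (
            image.total_counts
            if image.total_counts is not None
            else np.ones_like(p)
        )
    intensity = np.asarray(intensity, dtype=float)
    vmax = np.nanmax(intensity[image.valid]) if image.valid.any() else 1.0
    value = np.clip(intensity / vmax, 0.0, 1.0) if vmax > 0 else np.zeros_like(p)
    hsv = np.stack(
        [np.nan_to_num(hue), np.ones_like(hue), np.nan_to_num(value)], axis=-1
    )
    rgb = hsv_to_rgb(hsv)
    rgb[~image.valid] = 0.0
    return HsiRender(rgb=rgb, lower_percent=lower_percent, upper_percent=upper_percent)


def save_hsi_png(render: HsiRender, path: str | Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    plt.imsave(path, np.clip(render.rgb, 0, 1))


# ---------------------------------------------------------------------------
# mosaics
# ---------------------------------------------------------------------------


def stitch_tiles(
    tiles: Sequence[IonImageStack],
    grid_shape: tuple[int, int],
    order: str = "row-major",
    edge_attenuation: np.ndarray | None = None,
) -> IonImageStack:
    """Abut acquisition tiles into a mosaic.

    ``edge_attenuation`` (same shape as a tile, values in [0, 1]) optionally
    scales each tile's counts, emulating the lower secondary-ion yield at
    field peripheries.
    """
    rows, cols = grid_shape
    if rows * cols != len(tiles):
        raise ValueError(f"{len(tiles)} tiles do not fill a {rows}x{cols} grid")
    shape = tiles[0].shape
    if any(t.shape != shape for t in tiles):
        raise ValueError("tiles differ in shape")
    if order not in ("row-major", "column-major"):
        raise ValueError(f"unknown order {order!r}")

    def channel(getter):
        parts = []
        for t in tiles:
            arr = np.asarray(getter(t), dtype=float)
            if edge_attenuation is not None:
                arr = np.rint(arr * edge_attenuation)
            parts.append(arr.astype(np.uint32))
        grid = np.empty((rows, cols), dtype=object)
        for k, arr in enumerate(parts):
            r, c = (k // cols, k % cols) if order == "row-major" else (k % rows, k // rows)
            grid[r, c] = arr
        return np.block([[grid[r, c] for c in range(cols)] for r in range(rows)])

    return IonImageStack(
        channel(lambda t: t.n14),
        channel(lambda t: t.n15),
        channel(lambda t: t.p31),
        pixel_size_um=tiles[0].pixel_size_um,
    )


# ---------------------------------------------------------------------------
# segmentation and ROI statistics
# ---------------------------------------------------------------------------


def segment_nuclei(
    p31: np.ndarray,
    method: str = "otsu",
    min_area: int = 20,
    median_size: int = 3,
) -> np.ndarray:
    """Label nuclei from the 31P channel (chromatin is phosphorus-rich).

    Median-filters the channel, thresholds (Otsu by default) and keeps
    connected components of at least ``min_area`` pixels. Returns an integer
    label image (0 = background).
    """
    from skimage.filters import threshold_otsu
    from skimage.measure import label as _label
    from skimage.morphology import remove_small_objects

    img = np.asarray(p31, dtype=float)
    if img.size == 0:
        raise ValueError("empty 31P channel")
    smoothed = _ndi.median_filter(img, size=median_size)
    if np.all(smoothed == smoothed.flat[0]):
        warnings.warn("blank 31P channel; empty nucleus mask")
        return np.zeros(img.shape, dtype=np.int32)
    if method != "otsu":
        raise ValueError(f"unknown method {method!r}")
    thr = threshold_otsu(smoothed)
    mask = smoothed > thr
    mask = remove_small_objects(mask, max_size=min_area - 1)
    return _label(mask).astype(np.int32)


@dataclass
class RoiSet:
    """Integer label mask with a class tag per label."""

    labels: np.ndarray
    class_tags: dict[int, str] = field(default_factory=dict)

    def label_ids(self) -> list[int]:
        ids = np.unique(self.labels)
        return [int(i) for i in ids if i > 0]


def roi_stats(image: RatioImage, rois: RoiSet) -> pd.DataFrame:
    """Mean ratio / percent-above per ROI over valid pixels only.

    ROIs whose pixels are all masked invalid are flagged ``excluded`` (low
    ion counts make the cell unquantifiable) and carry NaN statistics.
    """
    if rois.labels.shape != image.ratio.shape:
        raise ValueError("ROI mask shape does not match the ratio image")
    rows = []
    for lab in rois.label_ids():
        sel = (rois.labels == lab) & image.valid
        n = int(sel.sum())
        if n == 0:
            rows.append(
                {
                    "label": lab,
                    "class_tag": rois.class_tags.get(lab, ""),
                    "n_pixels": 0,
                    "mean_ratio": np.nan,
                    "mean_percent_above": np.nan,
                    "se_ratio": np.nan,
                    "se_percent_above": np.nan,
                    "excluded": True,
                }
            )
            continue
        vals = image.ratio[sel]
        mean_r = float(vals.mean())
        se_r = float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan
        rows.append(
            {
                "label": lab,
                "class_tag": rois.class_tags.get(lab, ""),
                "n_pixels": n,
                "mean_ratio": mean_r,
                "mean_percent_above": percent_above_background(mean_r, image.baseline),
                "se_ratio": se_r,
                "se_percent_above": 100.0 * se_r / image.baseline if n > 1 else np.nan,
                "excluded": False,
            }
        )
    return pd.DataFrame(rows)


def nuc_cyto_ratio(
    image: RatioImage,
    nucleus_labels: np.ndarray,
    cell_labels: np.ndarray,
) -> tuple[pd.DataFrame, TestResult | None]:
    """Per-cell (mean nuclear R)/(mean cytoplasmic R), tested against 1.

    ``cell_labels`` labels whole cells; the cytoplasm of a cell is its area
    outside ``nucleus_labels``. Values above 1 signify greater 15N labeling
    in the nucleus than the cytoplasm. Cells with an empty (or fully masked)
    nuclear or cytoplasmic compartment are excluded with a reason. The group
    of per-cell values is compared to the hypothetical value 1 with a
    one-sample t-test (skipped with a warning when fewer than 2 cells
    remain).
    """
    if nucleus_labels.shape != image.ratio.shape or cell_labels.shape != image.ratio.shape:
        raise ValueError("mask shapes do not match the ratio image")
    nuc_any = nucleus_labels > 0
    rows = []
    for cell in np.unique(cell_labels):
        if cell == 0:
            continue
        cell_sel = cell_labels == cell
        nuc_sel = cell_sel & nuc_any & image.valid
        cyto_sel = cell_sel & ~nuc_any & image.valid
        if nuc_sel.sum() == 0 or cyto_sel.sum() == 0:
            rows.append(
                {
                    "cell": int(cell),
                    "nuc_mean_ratio": np.nan,
                    "cyto_mean_ratio": np.nan,
                    "nc_ratio": np.nan,
                    "n_nuc_pixels": int(nuc_sel.sum()),
                    "n_cyto_pixels": int(cyto_sel.sum()),
                    "excluded": True,
                    "reason": "empty nuclear or cytoplasmic compartment",
                }
            )
            continue
        mn = float(image.ratio[nuc_sel].mean())
        mc = float(image.ratio[cyto_sel].mean())
        rows.append(
            {
                "cell": int(cell),
                "nuc_mean_ratio": mn,
                "cyto_mean_ratio": mc,
                "nc_ratio": mn / mc if mc > 0 else np.nan,
                "n_nuc_pixels": int(nuc_sel.sum()),
                "n_cyto_pixels": int(cyto_sel.sum()),
                "excluded": False,
                "reason": "",
            }
        )
    table = pd.DataFrame(rows)
    values = table.loc[~table["excluded"], "nc_ratio"].dropna().to_numpy()
    if len(values) < 2:
        warnings.warn("fewer than 2 quantifiable cells; one-sample test skipped")
        return table, None
    return table, one_sample_test(values, 1.0)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def write_ratio_tiff(image: RatioImage, path: str | Path) -> None:
    """Ratio and percent-above maps as a 2-page 32-bit float TIFF."""
    import tifffile

    stack = np.stack(
        [
            np.where(image.valid, image.ratio, np.nan),
            np.where(image.valid, image.percent_above, np.nan),
        ]
    ).astype(np.float32)
    tifffile.imwrite(path, stack, photometric="minisblack")


def read_label_mask(path: str | Path) -> np.ndarray:
    """Read an integer ROI label image (16-bit PNG or TIFF)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        return tifffile.imread(path).astype(np.int32)
    import imageio.v3 as iio

    return iio.imread(path).astype(np.int32)


def write_roi_stats_tsv(path: str | Path, table: pd.DataFrame,
                        baseline: float = MIMS_BASELINE_RATIO,
                        min_14n_counts: int = DEFAULT_MIN_14N_COUNTS) -> None:
    with open(path, "w") as fh:
        fh.write(f"# baseline_ratio = {baseline}\n")
        fh.write(f"# min_14N_counts = {min_14n_counts}\n")
        table.to_csv(fh, sep="\t", index=False)
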