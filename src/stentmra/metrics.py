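"""Quantitative lumen-visibility measurements on a phantom image.

Three quantities are read off the middle longitudinal slice through the
tube axis, mirroring how stent artifacts obscure a vessel lumen:

1. **Relative signal intensity** (``si_percent``): mean lumen signal in
   the stented segment as a percentage of the mean lumen signal in the
   unstented reference segment of the same tube.
2. **Visible lumen diameter** (``vis_min_percent`` / ``vis_max_percent``):
   at each axial position inside the stent, the widest contiguous run of
   lumen pixels whose signal stays above a visibility threshold (default
   half the reference lumen mean — the full-width-half-maximum convention
   for vessel delineation), expressed as a percentage of the visible
   diameter measured identically on the unstented segment.  The minimum
   over the stent is the quantity that limits stenosis detection.
3. **Lumen homogeneity** (``sd_over_mean``): population standard
   deviation over mean of a fixed-size rectangular ROI centred in the
   stented lumen.

Percentages are reported as integers and the homogeneity ratio to two
decimals, the precision at which the downstream grades are defined.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .simulate import PhantomImage

__all__ = [
    "MeasurementConfig",
    "MeasurementResult",
    "MidSlice",
    "extract_mid_slice",
    "relative_signal_intensity",
    "visible_lumen_profile",
    "lumen_homogeneity",
    "measure_phantom",
]


@dataclass
class MeasurementConfig:
    roi_pixels: int = 120  # homogeneity ROI size, reconstructed pixels
    vis_threshold_frac: float = 0.5  # of reference lumen mean
    reference_margin: float = 5.0  # mm between stent end and reference segment
    slice_selection: str = "center"  # longitudinal plane through the tube axis
    si_erosion_mm: float = 0.8  # lumen-mask erosion for mean-signal ROIs

    def __post_init__(self) -> None:
        if not (0 < self.vis_threshold_frac < 1):
            raise ValueError("vis_threshold_frac must be in (0, 1)")
        if self.roi_pixels < 9:
            raise ValueError("roi_pixels must be >= 9")


@dataclass
class MeasurementResult:
    """One row of measured lumen-visibility quantities for one stent."""

    stent_id: int
    name: str
    si_percent: int
    vis_min_percent: int
    vis_max_percent: int
    sd_over_mean: float

    def __post_init__(self) -> None:
        if self.si_percent < 0 or self.sd_over_mean < 0:
            raise ValueError("si_percent and sd_over_mean must be >= 0")
        if not (0 <= self.vis_min_percent <= self.vis_max_percent):
            raise ValueError("require 0 <= vis_min <= vis_max")


@dataclass
class MidSlice:
    """Longitudinal mid-plane with lumen/segment annotations.

    ``data`` is indexed [row, column] = [across-tube x, along-tube z].
    """

    data: np.ndarray
    pixel_size: float  # mm
    axis_row: float  # fractional row index of the tube axis
    lumen_rows: np.ndarray  # bool, full lumen width
    core_rows: np.ndarray  # bool, eroded lumen (mean-signal ROIs)
    stented_cols: np.ndarray  # int indices
    reference_cols: np.ndarray  # int indices
    lumen_diameter_px: float  # geometric lumen diameter in pixels


def extract_mid_slice(
    image: PhantomImage, config: MeasurementConfig | None = None
) -> MidSlice:
    """Take the middle longitudinal slice and annotate its segments.

    The slice passes through the tube axis parallel to the stent's long
    axis.  Columns within the stent extent are "stented"; columns at least
    ``reference_margin`` away from either stent end are the unstented
    reference, pooled from both sides when available.
    """
    config = config or MeasurementConfig()
    data = image.mid_slice(axis=1)
    px = image.voxel_size
    nrow, ncol = data.shape

    z0, z1 = image.stent_extent
    if z0 <= 0 or z1 >= ncol:
        raise ValueError(
            "stent extent touches the volume boundary; no reference segment"
        )

    cx = image.axis_index[0]
    r_px = image.lumen_radius / px
    rows = np.arange(nrow)
    lumen_rows = np.abs(rows - cx) <= r_px
    core_rows = np.abs(rows - cx) <= max(r_px - config.si_erosion_mm / px, 1.0)

    margin_px = int(np.ceil(config.reference_margin / px))
    cols = np.arange(ncol)
    reference_cols = cols[(cols < z0 - margin_px) | (cols >= z1 + margin_px)]
    stented_cols = cols[z0:z1]
    return MidSlice(
        data=data,
        pixel_size=px,
        axis_row=cx,
        lumen_rows=lumen_rows,
        core_rows=core_rows,
        stented_cols=stented_cols,
        reference_cols=reference_cols,
        lumen_diameter_px=2 * r_px,
    )


def _round_half_up(v: float) -> int:
    return int(np.floor(v + 0.5))


def _reference_mean(sl: MidSlice) -> float:
    ref = sl.data[np.ix_(sl.core_rows, sl.reference_cols)]
    if ref.size < 20:
        raise ValueError("reference segment has fewer than 20 lumen pixels")
    mean = float(ref.mean())
    if mean <= 0:
        raise ValueError("reference lumen mean is zero")
    return mean


def relative_signal_intensity(
    sl: MidSlice, config: MeasurementConfig | None = None
) -> int:
    """In-stent lumen mean as integer percent of the reference lumen mean."""
    config = config or MeasurementConfig()
    ref_mean = _reference_mean(sl)
    stented = sl.data[np.ix_(sl.core_rows, sl.stented_cols)]
    return _round_half_up(100.0 * float(stented.mean()) / ref_mean)


def _longest_run(above: np.ndarray) -> int:
    """Length of the longest contiguous True run."""
    if not above.any():
        return 0
    padded = np.concatenate(([False], above, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return int((edges[1::2] - edges[::2]).max())


def visible_lumen_profile(
    sl: MidSlice, config: MeasurementConfig | None = None
) -> tuple[int, int]:
    """Minimal and maximal visible lumen diameter, percent of reference.

    The denominator is measured on the unstented segment with the same
    threshold-and-run procedure (median across reference columns), so an
    artifact-free stented segment scores exactly 100.  An axial position
    with no pixel above threshold contributes 0 — the signal-truncation
    pattern of severe susceptibility artifacts.
    """
    config = config or MeasurementConfig()
    if len(sl.stented_cols) < 3:
        raise ValueError("stented region shorter than 3 axial positions")
    threshold = config.vis_threshold_frac * _reference_mean(sl)
    lumen_line = sl.data[sl.lumen_rows, :]

    ref_runs = [
        _longest_run(lumen_line[:, c] >= threshold) for c in sl.reference_cols
    ]
    ref_diam = float(np.median(ref_runs))
    if ref_diam <= 0:
        ref_diam = sl.lumen_diameter_px  # geometric fallback

    runs = np.array(
        [_longest_run(lumen_line[:, c] >= threshold) for c in sl.stented_cols]
    )
    vis = 100.0 * runs / ref_diam
    return _round_half_up(float(vis.min())), _round_half_up(float(vis.max()))


def lumen_homogeneity(
    sl: MidSlice, config: MeasurementConfig | None = None, decimals: int | None = 2
) -> float:
    """SD/mean of a fixed-size rectangular ROI centred in the stented lumen.

    The ROI is ``roi_pixels`` pixels: width = min(lumen width - 2, 8)
    rows (reduced to the largest width that divides roi_pixels exactly),
    length along the stent adjusted to reach the pixel count.  Population
    (divisor N) standard deviation; reported to 2 decimals (pass
    ``decimals=None`` for the raw ratio).
    """
    config = config or MeasurementConfig()
    lumen_width = int(sl.lumen_rows.sum())
    w_max = min(lumen_width - 2, 8)
    if w_max < 2:
        raise ValueError("lumen too narrow for a homogeneity ROI")
    w = next((w for w in range(w_max, 1, -1) if config.roi_pixels % w == 0), w_max)
    length = config.roi_pixels // w
    n_cols = len(sl.stented_cols)
    if length > n_cols:
        warnings.warn(
            f"stented segment shorter than the {config.roi_pixels}-pixel ROI; "
            f"using {w * n_cols} pixels",
            stacklevel=2,
        )
        length = n_cols
    if w * length < 9:
        raise ValueError("ROI smaller than 9 pixels")

    lumen_idx = np.flatnonzero(sl.lumen_rows)
    mid = np.argmin(np.abs(lumen_idx - sl.axis_row))
    r0 = lumen_idx[mid] - w // 2
    rows = np.arange(r0, r0 + w)
    c_mid = n_cols // 2
    c0 = max(c_mid - length // 2, 0)
    cols = sl.stented_cols[c0 : c0 + length]

    roi = sl.data[np.ix_(rows, cols)]
    mean = float(roi.mean())
    if mean <= 0:
        raise ValueError("ROI mean is zero")
    ratio = float(roi.std()) / mean
    return ratio if decimals is None else float(np.round(ratio, decimals))


def measure_phantom(
    image: PhantomImage, config: MeasurementConfig | None = None
) -> MeasurementResult:
    """All three measurements for one phantom image."""
    config = config or MeasurementConfig()
    sl = extract_mid_slice(image, config)
    si = relative_signal_intensity(sl, config)
    vmin, vmax = visible_lumen_profile(sl, config)
    sd = lumen_homogeneity(sl, config)
    stent = (image.provenance or {}).get("stent") or {}
    return MeasurementResult(
        stent_id=int(stent.get("id", 0)),
        name=str(stent.get("name", "phantom")),
        si_percent=si,
        vis_min_percent=vmin,
        vis_max_percent=vmax,
        sd_over_mean=sd,
    )
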