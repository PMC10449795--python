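"""Pupil-iris contrast metrics and cross-device summaries.

The contrast statistic quantifies how segmentable an eye image is: the
difference in red-channel intensity between a 15x15 block of iris pixels and a
15x15 block of pupil pixels.  Comparing the same eye under far-red and
full-visible illumination gives the percent increase

    100 * (contrast_far_red - contrast_full) / |contrast_full|

which is the headline cross-device metric (it can be negative when the
full-visible contrast already exceeds the far-red one).  Iris colour is
characterised independently by the median CIELAB L* over an iris block of an
RGB image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage import color as skcolor

from .segmentation import PupilDetection, extract_red_channel

__all__ = [
    "BLOCK_SIZE",
    "PixelBlock",
    "ContrastMeasurement",
    "ContrastComparison",
    "IrisColorRecord",
    "BlockPlacementError",
    "ZeroContrastError",
    "select_pixel_blocks",
    "pupil_iris_contrast",
    "contrast_percent_increase",
    "iris_luminance",
    "CrossDeviceSummary",
    "cross_device_table",
    "spectral_contrast_comparison",
]

BLOCK_SIZE = 15  # 15 x 15 = 225 representative pixels

#: candidate diagonals for the iris block, degrees from image-horizontal,
#: upper-right quadrant first (row axis points down, so +angle is up-right)
_DIAGONALS_DEG = (45.0, 135.0, 225.0, 315.0)


class BlockPlacementError(ValueError):
    """No candidate block position fits inside the frame."""


class ZeroContrastError(ZeroDivisionError):
    """Percent increase is undefined when the full-spectrum contrast is zero."""


@dataclass(frozen=True)
class PixelBlock:
    """A 15x15 pixel block, addressed by its top-left corner (row, col)."""

    top_left: tuple[int, int]
    label: str = ""
    size: int = BLOCK_SIZE

    def slices(self) -> tuple[slice, slice]:
        r, c = self.top_left
        return slice(r, r + self.size), slice(c, c + self.size)

    def pixels(self, frame: np.ndarray) -> np.ndarray:
        sr, sc = self.slices()
        return frame[sr, sc]

    def in_frame(self, shape: tuple[int, ...]) -> bool:
        r, c = self.top_left
        return r >= 0 and c >= 0 and r + self.size <= shape[0] and c + self.size <= shape[1]


@dataclass(frozen=True)
class ContrastMeasurement:
    """Paired block statistics and their difference (iris minus pupil)."""

    pupil_intensity: float
    iris_intensity: float
    contrast: float
    condition: str = ""
    device: str = ""

    def __post_init__(self) -> None:
        if abs(self.contrast - (self.iris_intensity - self.pupil_intensity)) > 1e-9:
            raise ValueError("contrast must equal iris_intensity - pupil_intensity")


@dataclass(frozen=True)
class ContrastComparison:
    """Far-red vs full-visible contrast of the same eye, with Eq.-style percent increase."""

    contrast_far_red: float
    contrast_full: float
    percent_increase: float


@dataclass(frozen=True)
class IrisColorRecord:
    """Median CIELAB L* over an iris block, plus the self-reported colour label."""

    iris_luminance: float
    eye_color_label: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.iris_luminance <= 100.0:
            raise ValueError("CIELAB L* must lie in [0, 100]")


def _block_centered(center: tuple[float, float], label: str) -> PixelBlock:
    half = BLOCK_SIZE // 2
    return PixelBlock(top_left=(int(round(center[0])) - half, int(round(center[1])) - half), label=label)


def select_pixel_blocks(
    frame: np.ndarray,
    detection: PupilDetection,
    saturation_threshold: int = 240,
) -> tuple[PixelBlock, PixelBlock]:
    """Choose the pupil and iris 15x15 blocks for a detected pupil.

    The pupil block sits on the detection center.  The iris block sits at
    twice the pupil radius from the center, on one of the four diagonals
    (45-degree multiples); among in-frame candidates the one with minimum
    within-block intensity variance is chosen, which automatically steers away
    from specular glare.  If every candidate contains saturated pixels the
    candidates are re-generated with the radial distance shifted by
    +/- 0.25 pupil radius before falling back to plain minimum variance.
    """
    if not detection.valid:
        raise BlockPlacementError("cannot place blocks for an invalid detection")
    red = extract_red_channel(np.asarray(frame)).astype(float)
    center = detection.center
    radius = detection.diameter_px / 2.0

    pupil_block = _block_centered(center, "pupil")
    if not pupil_block.in_frame(red.shape):
        raise BlockPlacementError("pupil block does not fit inside the frame")

    def candidates(distance: float) -> list[PixelBlock]:
        out = []
        for ang in _DIAGONALS_DEG:
            th = np.deg2rad(ang)
            blk = _block_centered(
                (center[0] - distance * np.sin(th), center[1] + distance * np.cos(th)), "iris"
            )
            if blk.in_frame(red.shape):
                out.append(blk)
        return out

    base = candidates(2.0 * radius)
    if not base:
        raise BlockPlacementError("no iris block candidate fits inside the frame")

    def pick(blocks: list[PixelBlock]) -> tuple[PixelBlock, bool]:
        best, best_var, best_clean = None, np.inf, False
        for blk in blocks:
            px = blk.pixels(red)
            clean = not (px >= saturation_threshold).any()
            var = float(px.var())
            # prefer glare-free candidates; among equals, minimum variance
            key_better = (clean and not best_clean) or (clean == best_clean and var < best_var)
            if best is None or key_better:
                best, best_var, best_clean = blk, var, clean
        return best, best_clean

    chosen, clean = pick(base)
    if not clean:
        shifted = candidates(2.0 * radius + 0.25 * radius) + candidates(2.0 * radius - 0.25 * radius)
        if shifted:
            alt, alt_clean = pick(shifted)
            if alt_clean:
                chosen = alt
    return pupil_block, chosen


def pupil_iris_contrast(
    frame: np.ndarray,
    pupil_block: PixelBlock,
    iris_block: PixelBlock,
    statistic: str = "mean",
    condition: str = "",
    device: str = "",
) -> ContrastMeasurement:
    """Block statistic of each region and their difference (iris minus pupil).

    The frame must already be single-channel (red channel extracted by the
    caller).  ``statistic`` is ``"mean"`` (default) or ``"median"``.
    """
    frame = np.asarray(frame)
    if frame.ndim != 2:
        raise ValueError("pupil_iris_contrast requires a single-channel frame; extract the red channel first")
    for blk in (pupil_block, iris_block):
        if not blk.in_frame(frame.shape):
            raise BlockPlacementError(f"{blk.label or 'pixel'} block lies outside the frame")
    stat = {"mean": np.mean, "median": np.median}.get(statistic)
    if stat is None:
        raise ValueError(f"unknown block statistic {statistic!r}")
    pupil_i = float(stat(pupil_block.pixels(frame).astype(float)))
    iris_i = float(stat(iris_block.pixels(frame).astype(float)))
    return ContrastMeasurement(
        pupil_intensity=pupil_i,
        iris_intensity=iris_i,
        contrast=iris_i - pupil_i,
        condition=condition,
        device=device,
    )


def contrast_percent_increase(contrast_far_red: float, contrast_full: float) -> float:
    """Percent increase of far-red over full-visible contrast.

    ``100 * (far - full) / |full|``; the absolute value in the denominator
    preserves the sign of the numerator, so the result may be negative.
    """
    if contrast_full == 0:
        raise ZeroContrastError("percent increase undefined: full-spectrum contrast is zero")
    return float(100.0 * (contrast_far_red - contrast_full) / abs(contrast_full))


def iris_luminance(frame: np.ndarray, iris_block: PixelBlock, eye_color_label: str = "") -> IrisColorRecord:
    """Median CIELAB L* of the iris block of an RGB frame.

    Conversion uses the standard sRGB transfer function with D65 white point
    (2-degree observer), so uniform white maps to L* = 100 and black to 0.
    """
    frame = np.asarray(frame)
    if frame.ndim != 3 or frame.shape[-1] != 3:
        raise ValueError("iris_luminance requires a 3-channel RGB frame")
    if not iris_block.in_frame(frame.shape):
        raise BlockPlacementError("iris block lies outside the frame")
    block = iris_block.pixels(frame)
    lab = skcolor.rgb2lab(block.astype(np.float64) / 255.0)
    return IrisColorRecord(iris_luminance=float(np.median(lab[..., 0])), eye_color_label=eye_color_label)


@dataclass
class CrossDeviceSummary:
    """Per-participant device table with Mean/STD columns and cohort aggregates."""

    per_participant: pd.DataFrame  # index: participant; device columns + mean, std, eye_color

    def grand_mean(self, eye_color: str | None = None) -> float:
        """Grand mean of per-participant means, optionally within one colour label."""
        table = self.per_participant
        if eye_color is not None:
            table = table[table["eye_color"] == eye_color]
            if table.empty:
                raise ValueError(f"no participants with eye colour {eye_color!r}")
        return float(table["mean"].mean())

    @property
    def n_participants(self) -> int:
        return len(self.per_participant)


def cross_device_table(measurements: pd.DataFrame) -> CrossDeviceSummary:
    """Summarise per-participant, per-device contrast percent increases.

    ``measurements`` is long-format with columns ``participant``, ``device``,
    ``percent_increase`` and optionally ``eye_color``.  Each participant row
    gets the mean and sample standard deviation (n-1) across their devices;
    participants measured on a single device report the value itself as mean
    and an undefined (NaN) standard deviation.
    """
    required = {"participant", "device", "percent_increase"}
    missing = required - set(measurements.columns)
    if missing:
        raise ValueError(f"measurements missing columns: {sorted(missing)}")
    if measurements.empty:
        raise ValueError("measurements table is empty")

    wide = measurements.pivot_table(
        index="participant", columns="device", values="percent_increase", aggfunc="mean"
    )
    table = wide.copy()
    table["mean"] = wide.mean(axis=1)
    table["std"] = wide.std(axis=1, ddof=1)  # NaN for single-device rows
    if "eye_color" in measurements.columns:
        colors = measurements.groupby("participant")["eye_color"].first()
        table["eye_color"] = colors
    else:
        table["eye_color"] = ""
    return CrossDeviceSummary(per_participant=table)


def spectral_contrast_comparison(
    far_red_frame: np.ndarray,
    full_visible_frame: np.ndarray,
    detection: PupilDetection,
    statistic: str = "mean",
) -> ContrastComparison:
    """Compare the contrast of the same eye imaged in both bands.

    The block geometry is chosen once, on the far-red frame (where the pupil
    is detectable by design), and the identical blocks are applied to the red
    channel of the full-visible frame — mirroring a protocol where the eye and
    camera do not move between conditions.
    """
    far = extract_red_channel(np.asarray(far_red_frame))
    full = extract_red_channel(np.asarray(full_visible_frame))
    if far.shape != full.shape:
        raise ValueError("band frames must share geometry")
    pupil_blk, iris_blk = select_pixel_blocks(far, detection)
    c_far = pupil_iris_contrast(far, pupil_blk, iris_blk, statistic=statistic, condition="far_red")
    c_full = pupil_iris_contrast(full, pupil_blk, iris_blk, statistic=statistic, condition="full_visible")
    return ContrastComparison(
        contrast_far_red=c_far.contrast,
        contrast_full=c_full.contrast,
        percent_increase=contrast_percent_increase(c_far.contrast, c_full.contrast),
    )
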