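"""Classical pupil detection for far-red eye frames.

The far-red imaging condition makes the pupil the darkest compact region of
the frame by construction, so a learned detector is unnecessary for frames the
optics were designed to produce.  The default backend is:

red-channel extraction -> optional downscale -> glare in-painting of saturated
specks -> global threshold at the deepest valley of a smoothed intensity
histogram between the two darkest modes -> largest dark connected component ->
moment-ellipse fit -> diameter of the circle with the same area as the fitted
ellipse.

Detection failure is a state (``valid = False``), never an exception, so blink
frames and contrast-collapsed full-visible frames flow through the pipeline as
flagged samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.signal import find_peaks
from scipy.ndimage import gaussian_filter1d
from skimage import measure, morphology, transform

from .plr import PupilTrace

__all__ = ["DetectionConfig", "PupilDetection", "extract_red_channel", "detect_pupil", "process_video"]


@dataclass(frozen=True)
class DetectionConfig:
    """Tunables of the classical detector.

    ``downscale`` shrinks the frame by an integer factor before detection
    (results are mapped back to full-frame pixels); 1 means no downscaling.
    ``glare_intensity_threshold`` marks saturated specular pixels that are
    in-painted by a grayscale morphological operation before thresholding.
    The component checks reject regions that are too small, too large, not
    round enough, or not dark relative to their surround (e.g. a closed
    eyelid).
    """

    downscale: int = 1
    hist_smooth_sigma: float = 3.0
    peak_prominence_frac: float = 5e-4
    glare_intensity_threshold: int = 240
    glare_patch_radius: int = 5
    min_area_px: int = 50
    max_area_frac: float = 0.4
    min_circularity: float = 0.6
    relative_darkness_max: float = 0.6

    def __post_init__(self) -> None:
        if self.downscale < 1:
            raise ValueError("downscale must be >= 1")


@dataclass(frozen=True)
class PupilDetection:
    """Per-frame detection: center (row, col), diameter in pixels, confidence.

    When ``valid`` is False no geometric fields are defined (all None).
    Confidence is the circularity ``4*pi*area / perimeter**2`` of the selected
    component, clipped to [0, 1].
    """

    valid: bool
    center: tuple[float, float] | None = None
    diameter_px: float | None = None
    confidence: float = 0.0

    def __post_init__(self) -> None:
        if self.valid:
            if self.center is None or self.diameter_px is None or self.diameter_px <= 0:
                raise ValueError("valid detection requires a center and positive diameter")
        elif self.center is not None or self.diameter_px is not None:
            raise ValueError("invalid detection must not carry geometry")


_INVALID = PupilDetection(valid=False)


def extract_red_channel(frame: np.ndarray) -> np.ndarray:
    """Return the red channel of an RGB frame; single-channel input is identity."""
    if frame.ndim == 2:
        return frame
    if frame.ndim == 3 and frame.shape[-1] == 3:
        return frame[..., 0]
    raise ValueError(f"expected 1- or 3-channel frame, got shape {frame.shape}")


def _histogram_valley(img: np.ndarray, config: DetectionConfig) -> int | None:
    """Deepest valley between the two darkest modes of the smoothed histogram.

    The histogram is zero-padded on both sides before smoothing so a mode
    sitting at an end of the intensity range (a very dark pupil, a saturated
    surround) still registers as a genuine peak.
    """
    pad = int(np.ceil(4 * config.hist_smooth_sigma)) + 4
    hist = np.bincount(img.ravel().astype(np.int64), minlength=256).astype(float)
    padded = np.concatenate([np.zeros(pad), hist, np.zeros(pad)])
    smooth = gaussian_filter1d(padded, config.hist_smooth_sigma, mode="constant")
    prominence = max(1.0, config.peak_prominence_frac * img.size)
    peaks, _ = find_peaks(smooth, prominence=prominence)
    if len(peaks) < 2:
        return None
    p0, p1 = np.sort(peaks)[:2]
    valley = p0 + int(np.argmin(smooth[p0 : p1 + 1]))
    return int(np.clip(valley - pad, 0, 255))


def _inpaint_glare(img: np.ndarray, config: DetectionConfig) -> np.ndarray:
    """Replace saturated specular specks with local morphological background."""
    sat = img >= config.glare_intensity_threshold
    if not sat.any():
        return img
    footprint = morphology.disk(config.glare_patch_radius)
    opened = ndimage.grey_opening(img, footprint=footprint)
    region = ndimage.binary_dilation(sat, iterations=2)
    return np.where(region, opened, img)


def detect_pupil(frame: np.ndarray, config: DetectionConfig = DetectionConfig()) -> PupilDetection:
    """Detect the pupil in a single frame.

    Returns a valid detection when the frame contains one dark quasi-circular
    region on a brighter surround, otherwise ``valid = False``.  Deterministic
    for fixed input and configuration.
    """
    if frame.size == 0:
        raise ValueError("frame is empty")
    img = extract_red_channel(np.asarray(frame))
    scale = 1.0
    if config.downscale > 1:
        img = transform.downscale_local_mean(img.astype(float), (config.downscale, config.downscale))
        img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
        scale = float(config.downscale)

    work = _inpaint_glare(img, config)
    valley = _histogram_valley(work, config)
    if valley is None:
        return _INVALID

    mask = work <= valley
    mask = ndimage.binary_closing(mask, structure=morphology.disk(3))
    mask = ndimage.binary_fill_holes(mask)
    labels, n_labels = ndimage.label(mask)
    if n_labels == 0:
        return _INVALID
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n_labels + 1))
    component = labels == (1 + int(np.argmax(sizes)))

    area = float(component.sum())
    min_area = max(1, int(config.min_area_px / scale**2))
    if area < min_area or area > config.max_area_frac * component.size:
        return _INVALID
    inside = float(work[component].mean())
    outside = float(work[~component].mean()) if (~component).any() else 255.0
    if outside <= 0 or inside > config.relative_darkness_max * outside:
        return _INVALID

    props = measure.regionprops(component.astype(np.uint8))[0]
    perimeter = props.perimeter
    circularity = 4.0 * np.pi * area / perimeter**2 if perimeter > 0 else 0.0
    if circularity < config.min_circularity:
        return _INVALID

    major, minor = props.axis_major_length, props.axis_minor_length
    if major > 0 and minor > 0:
        diameter = float(np.sqrt(major * minor))  # equal-area circle of the moment ellipse
    else:
        diameter = float(props.equivalent_diameter_area)
    row, col = props.centroid
    return PupilDetection(
        valid=True,
        center=(float(row) * scale + (scale - 1) / 2.0, float(col) * scale + (scale - 1) / 2.0),
        diameter_px=diameter * scale,
        confidence=float(np.clip(circularity, 0.0, 1.0)),
    )


def process_video(
    frames: np.ndarray | list[np.ndarray],
    timestamps_s: np.ndarray,
    config: DetectionConfig = DetectionConfig(),
) -> PupilTrace:
    """Run detection frame-by-frame, producing a pixel-unit pupil trace.

    Samples where detection fails are flagged as blinks and carry NaN
    diameters; trace length always equals the frame count.
    """
    frames = list(frames)
    if len(frames) == 0:
        raise ValueError("no frames to process")
    timestamps_s = np.asarray(timestamps_s, dtype=float)
    if len(timestamps_s) != len(frames):
        raise ValueError("timestamps and frames must have equal length")

    n = len(frames)
    diameter = np.full(n, np.nan)
    blink = np.zeros(n, dtype=bool)
    confidence = np.zeros(n)
    center = np.full((n, 2), np.nan)
    for i, frame in enumerate(frames):
        det = detect_pupil(frame, config)
        if det.valid:
            diameter[i] = det.diameter_px
            center[i] = det.center
            confidence[i] = det.confidence
        else:
            blink[i] = True
    return PupilTrace(
        timestamps_s=timestamps_s,
        diameter=diameter,
        blink=blink,
        unit="px",
        confidence=confidence,
        center=center,
    )
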