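"""Synthetic eye frames and pupillary-light-reflex videos with known ground truth.

The generator emulates the optical effect that makes far-red (~630-700 nm)
imaging attractive for smartphone pupillometry: iris melanin absorbs weakly at
the far-red edge of the visible range, so even a heavily pigmented iris images
brightly against the dark pupil, whereas in the full visible spectrum a
dark-brown iris and the pupil are nearly indistinguishable.  Wavelength-resolved
absorption is collapsed to one effective Beer-Lambert coefficient per imaging
band (per colour channel for full-visible renders), which is sufficient to
reproduce the contrast ordering between bands.

Every rendered intensity is 8-bit (0-255) and every stochastic element (sensor
noise) flows from a single integer seed, so frames are a pure function of
(parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SpectralBand",
    "FAR_RED",
    "FULL_VISIBLE",
    "MELANIN_BLUE",
    "MELANIN_LIGHT_BROWN",
    "MELANIN_DARK_BROWN",
    "SpectralEyeParams",
    "PupilDynamicsParams",
    "PLRProtocol",
    "GroundTruthTrace",
    "iris_reflectance",
    "simulate_plr_diameter",
    "render_eye_frame",
    "render_plr_video",
    "default_glare_spots",
]


@dataclass(frozen=True)
class SpectralBand:
    """An imaging band reduced to an effective melanin absorption coefficient.

    Parameters
    ----------
    name
        ``"far_red"`` or ``"full_visible"``.
    effective_melanin_absorption
        Attenuation per unit melanin load (dimensionless).  For a 3-channel
        band this is the *red-channel* coefficient, because red-channel
        extraction is the first step of the downstream contrast calculation.
    channel_absorption
        Optional per-channel (R, G, B) coefficients; present only for
        3-channel (full visible) rendering.  Red must absorb least so that the
        iris is reddest in the red channel.
    """

    name: str
    effective_melanin_absorption: float
    channel_absorption: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if self.effective_melanin_absorption < 0:
            raise ValueError("effective_melanin_absorption must be >= 0")
        if self.channel_absorption is not None:
            if len(self.channel_absorption) != 3:
                raise ValueError("channel_absorption must have 3 entries (R, G, B)")
            r, g, b = self.channel_absorption
            if not (r <= g <= b):
                raise ValueError("channel absorption must satisfy red <= green <= blue")

    @property
    def n_channels(self) -> int:
        return 1 if self.channel_absorption is None else 3


#: Far-red band (~630-700 nm): weak melanin absorption, single channel.
FAR_RED = SpectralBand("far_red", 0.35)

#: Full visible spectrum as seen by an RGB sensor; the broadband red channel
#: still absorbs far more than the filtered far-red band.
FULL_VISIBLE = SpectralBand("full_visible", 0.9, channel_absorption=(0.9, 1.5, 2.0))

# Melanin-load presets spanning the iris colours of a typical cohort.
MELANIN_BLUE = 0.3
MELANIN_LIGHT_BROWN = 1.0
MELANIN_DARK_BROWN = 2.5

_EYELID_REFLECTANCE = (0.80, 0.62, 0.55)  # skin, per RGB channel


@dataclass(frozen=True)
class SpectralEyeParams:
    """Geometry and reflectance of one synthetic eye.

    Reflectances are in [0, 1]; intensities render as ``255 * reflectance``
    clipped to the 8-bit range.  ``melanin_load`` is dimensionless (0 = no
    melanin, ~2.5 = dark brown).
    """

    image_height_px: int = 240
    image_width_px: int = 320
    pupil_center: tuple[float, float] = (120.0, 160.0)  # (row, col)
    iris_radius_px: float = 110.0
    sclera_reflectance: float = 0.85
    iris_base_reflectance: float = 0.55
    melanin_load: float = 1.0
    pupil_reflectance: float = 0.02
    glare_spots: tuple[tuple[float, float, float, float], ...] = ()
    noise_sd: float = 0.0
    edge_softness_px: float = 1.0
    bit_depth: int = 8

    def __post_init__(self) -> None:
        if self.image_height_px <= 0 or self.image_width_px <= 0:
            raise ValueError("image dimensions must be positive")
        if self.iris_radius_px <= 0:
            raise ValueError("iris_radius_px must be positive")
        for name in ("sclera_reflectance", "iris_base_reflectance", "pupil_reflectance"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.melanin_load < 0:
            raise ValueError("melanin_load must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.bit_depth != 8:
            raise ValueError("only 8-bit rendering is supported")


def iris_reflectance(params: SpectralEyeParams, band: SpectralBand, channel: int | None = None) -> float:
    """Iris reflectance under Beer-Lambert melanin attenuation.

    ``iris_base_reflectance * exp(-melanin_load * absorption)``, strictly
    decreasing in melanin load; for any positive load the far-red value exceeds
    the full-visible one because melanin absorbs less at long wavelengths.
    """
    if channel is None:
        mu = band.effective_melanin_absorption
    else:
        if band.channel_absorption is None:
            mu = band.effective_melanin_absorption
        else:
            mu = band.channel_absorption[channel]
    return float(params.iris_base_reflectance * np.exp(-params.melanin_load * mu))


@dataclass(frozen=True)
class PupilDynamicsParams:
    """Piecewise latency + mono-exponential constriction/redilation kinetics.

    The diameter sits at ``baseline_diameter_px`` (D0) until the stimulus onset
    plus ``latency_s``, constricts exponentially toward ``D0 * (1 - A)`` with
    ``constriction_time_constant_s``, then after stimulus offset (plus the same
    latency) redilates along an exponential shape that recovers exactly
    ``redilation_fraction`` of the achieved constriction by the end of the
    recording.
    """

    baseline_diameter_px: float = 60.0
    constriction_amplitude: float = 0.3
    latency_s: float = 0.2
    constriction_time_constant_s: float = 0.2
    redilation_time_constant_s: float = 1.5
    redilation_fraction: float = 0.6

    def __post_init__(self) -> None:
        if self.baseline_diameter_px <= 0:
            raise ValueError("baseline_diameter_px must be positive")
        if not 0.0 <= self.constriction_amplitude < 1.0:
            raise ValueError("constriction_amplitude must be in [0, 1)")
        if self.latency_s < 0:
            raise ValueError("latency_s must be >= 0")
        if self.constriction_time_constant_s <= 0 or self.redilation_time_constant_s <= 0:
            raise ValueError("time constants must be positive")
        if not 0.0 <= self.redilation_fraction <= 1.0:
            raise ValueError("redilation_fraction must be in [0, 1]")


@dataclass(frozen=True)
class PLRProtocol:
    """Light-reflex stimulus schedule: dark / flash / dark, 5 s total."""

    pre_stimulus_s: float = 1.0
    stimulus_s: float = 1.0
    post_stimulus_s: float = 3.0
    frame_rate_hz: float = 60.0

    def __post_init__(self) -> None:
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")
        if min(self.pre_stimulus_s, self.stimulus_s, self.post_stimulus_s) < 0:
            raise ValueError("protocol phases must be non-negative")

    @property
    def total_duration_s(self) -> float:
        return self.pre_stimulus_s + self.stimulus_s + self.post_stimulus_s

    @property
    def n_frames(self) -> int:
        return int(round(self.total_duration_s * self.frame_rate_hz))


@dataclass
class GroundTruthTrace:
    """Time-stamped true pupil diameters with blink flags and centers."""

    timestamps_s: np.ndarray
    diameter_px: np.ndarray
    blink_flag: np.ndarray
    center_px: np.ndarray  # shape (n, 2): (row, col) per sample

    def __post_init__(self) -> None:
        n = len(self.timestamps_s)
        if not (len(self.diameter_px) == len(self.blink_flag) == len(self.center_px) == n):
            raise ValueError("trace arrays must have equal length")
        if n > 1 and not np.all(np.diff(self.timestamps_s) > 0):
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.timestamps_s)

    def as_trace(self):
        """View as a :class:`redpupil.plr.PupilTrace` (unit: pixels)."""
        from .plr import PupilTrace

        return PupilTrace(
            timestamps_s=self.timestamps_s.copy(),
            diameter=self.diameter_px.astype(float).copy(),
            blink=self.blink_flag.copy(),
            unit="px",
        )


def simulate_plr_diameter(
    dyn: PupilDynamicsParams,
    protocol: PLRProtocol,
    center_px: tuple[float, float] = (0.0, 0.0),
) -> GroundTruthTrace:
    """Simulate the true pupil-diameter trace for one PLR recording.

    Blink flags are all False here; :func:`render_plr_video` sets them when it
    occludes frames.
    """
    n = protocol.n_frames
    if n < 1:
        raise ValueError("protocol yields no frames")
    t = np.arange(n) / protocol.frame_rate_hz
    d0 = dyn.baseline_diameter_px
    a = dyn.constriction_amplitude
    t_on = protocol.pre_stimulus_s + dyn.latency_s
    t_off = protocol.pre_stimulus_s + protocol.stimulus_s + dyn.latency_s
    t_end = protocol.total_duration_s

    d = np.full(n, d0, dtype=float)
    constricting = (t >= t_on) & (t < t_off)
    d[constricting] = d0 - a * d0 * (1.0 - np.exp(-(t[constricting] - t_on) / dyn.constriction_time_constant_s))

    # diameter reached when the stimulus-driven constriction ends
    d_reached = d0 - a * d0 * (1.0 - np.exp(-(t_off - t_on) / dyn.constriction_time_constant_s))
    redilating = t >= t_off
    if np.any(redilating) and t_end > t_off:
        tau_r = dyn.redilation_time_constant_s
        # normalised so exactly redilation_fraction of (d0 - d_reached) is
        # recovered at t_end
        denom = 1.0 - np.exp(-(t_end - t_off) / tau_r)
        shape = (1.0 - np.exp(-(t[redilating] - t_off) / tau_r)) / denom
        d[redilating] = d_reached + dyn.redilation_fraction * (d0 - d_reached) * shape
    elif np.any(redilating):
        d[redilating] = d_reached

    centers = np.tile(np.asarray(center_px, dtype=float), (n, 1))
    return GroundTruthTrace(
        timestamps_s=t,
        diameter_px=d,
        blink_flag=np.zeros(n, dtype=bool),
        center_px=centers,
    )


def default_glare_spots(
    params: SpectralEyeParams, pupil_diameter_px: float, radius_px: float = 3.0, intensity: float = 250.0
) -> tuple[tuple[float, float, float, float], ...]:
    """Two specular LED reflections near the upper pupil boundary."""
    r = pupil_diameter_px / 2.0
    cr, cc = params.pupil_center
    spots = []
    for angle_deg in (70.0, 110.0):
        th = np.deg2rad(angle_deg)
        spots.append((cr - r * np.sin(th), cc + r * np.cos(th), radius_px, intensity))
    return tuple(spots)


def _soft_disc(rho: np.ndarray, radius: float, softness: float) -> np.ndarray:
    """Weight 1 inside the disc, 0 outside, linear ramp of width ``softness``."""
    h = max(softness, 1e-6) / 2.0
    return np.clip((radius + h - rho) / (2.0 * h), 0.0, 1.0)


def _render_channel(
    params: SpectralEyeParams, pupil_radius: float, iris_refl: float, rho: np.ndarray
) -> np.ndarray:
    h = params.edge_softness_px / 2.0
    xp = np.array(
        [pupil_radius - h, pupil_radius + h, params.iris_radius_px - h, params.iris_radius_px + h]
    )
    fp = np.array(
        [params.pupil_reflectance, iris_refl, iris_refl, params.sclera_reflectance]
    )
    if not np.all(np.diff(xp) > 0):
        raise ValueError("pupil and iris radii too close for the configured edge softness")
    img = 255.0 * np.interp(rho, xp, fp)
    for row, col, rad, inten in params.glare_spots:
        rr = np.hypot(
            np.arange(params.image_height_px)[:, None] - row,
            np.arange(params.image_width_px)[None, :] - col,
        )
        img = np.maximum(img, inten * _soft_disc(rr, rad, params.edge_softness_px))
    return img


def render_eye_frame(
    params: SpectralEyeParams, pupil_diameter_px: float, band: SpectralBand, seed: int
) -> np.ndarray:
    """Render one eye frame: concentric pupil disc, iris annulus, sclera.

    Returns a ``uint8`` array of shape ``(H, W)`` for a single-channel band or
    ``(H, W, 3)`` (RGB order) for ``full_visible``.  Identical arguments and
    seed give bit-identical frames.
    """
    if pupil_diameter_px <= 0:
        raise ValueError("pupil_diameter_px must be positive")
    if pupil_diameter_px / 2.0 >= params.iris_radius_px:
        raise ValueError("pupil must be strictly smaller than the iris")
    rng = np.random.default_rng(seed)
    rho = np.hypot(
        np.arange(params.image_height_px)[:, None] - params.pupil_center[0],
        np.arange(params.image_width_px)[None, :] - params.pupil_center[1],
    )
    r = pupil_diameter_px / 2.0
    if band.n_channels == 1:
        img = _render_channel(params, r, iris_reflectance(params, band), rho)
    else:
        img = np.stack(
            [_render_channel(params, r, iris_reflectance(params, band, ch), rho) for ch in range(3)],
            axis=-1,
        )
    if params.noise_sd > 0:
        img = img + rng.normal(0.0, params.noise_sd, size=img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def _occlude_eyelid(frame: np.ndarray, params: SpectralEyeParams, seed: int) -> np.ndarray:
    """Cover the eye region with a skin-toned eyelid band (blink)."""
    rng = np.random.default_rng(seed)
    out = frame.astype(float).copy()
    cr = params.pupil_center[0]
    r0 = max(0, int(np.floor(cr - params.iris_radius_px - 8)))
    r1 = min(params.image_height_px, int(np.ceil(cr + params.iris_radius_px + 8)))
    if frame.ndim == 2:
        out[r0:r1, :] = 255.0 * _EYELID_REFLECTANCE[0]
    else:
        for ch in range(3):
            out[r0:r1, :, ch] = 255.0 * _EYELID_REFLECTANCE[ch]
    if params.noise_sd > 0:
        shape = out[r0:r1].shape
        out[r0:r1] += rng.normal(0.0, params.noise_sd, size=shape)
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def render_plr_video(
    params: SpectralEyeParams,
    dyn: PupilDynamicsParams,
    protocol: PLRProtocol,
    band: SpectralBand = FAR_RED,
    blink_times_s: tuple[float, ...] = (),
    blink_duration_s: float = 0.15,
    seed: int = 0,
) -> tuple[np.ndarray, GroundTruthTrace]:
    """Render a full PLR recording: one frame per ground-truth sample.

    During each blink window ``[t, t + blink_duration_s)`` the eye is occluded
    by an eyelid band and the corresponding ground-truth ``blink_flag`` is set.
    Overlapping blink windows or windows outside the recording are rejected.
    """
    starts = sorted(float(t) for t in blink_times_s)
    for t in starts:
        if not 0.0 <= t <= protocol.total_duration_s:
            raise ValueError("blink times must lie within the recording")
    for t0, t1 in zip(starts, starts[1:]):
        if t1 < t0 + blink_duration_s:
            raise ValueError("blink windows must not overlap")

    truth = simulate_plr_diameter(dyn, protocol, center_px=params.pupil_center)
    for t0 in starts:
        inside = (truth.timestamps_s >= t0) & (truth.timestamps_s < t0 + blink_duration_s)
        truth.blink_flag |= inside

    rng = np.random.default_rng(seed)
    frame_seeds = rng.integers(0, 2**31 - 2, size=len(truth))
    frames = []
    for i in range(len(truth)):
        frame = render_eye_frame(params, truth.diameter_px[i], band, int(frame_seeds[i]))
        if truth.blink_flag[i]:
            frame = _occlude_eyelid(frame, params, int(frame_seeds[i]) + 1)
        frames.append(frame)
    return np.stack(frames), truth
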