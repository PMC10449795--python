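"""End-to-end validation chains: render -> segment -> normalise -> agree.

These helpers wire the stages together the way a device-validation study
does: the prototype-style trace (60 Hz, pixels, detector blink flags) is
downsampled to the 30 Hz reference base, both traces are normalised to
percent change from mean, aligned by cross-correlation, blink-excluded
jointly, and summarised by MAE / Pearson r / Bland-Altman statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .agreement import AgreementResult, ValidationSummary, agreement, summarize_cohort
from .plr import (
    AlignedTracePair,
    PupilTrace,
    align_traces,
    downsample_trace,
    exclude_blinks,
    flag_blink_spikes,
    percent_change_from_mean,
)
from .segmentation import DetectionConfig, process_video
from .simulate import (
    FAR_RED,
    MELANIN_BLUE,
    MELANIN_DARK_BROWN,
    PLRProtocol,
    PupilDynamicsParams,
    SpectralEyeParams,
    default_glare_spots,
    render_plr_video,
)

__all__ = ["analyze_pair", "validate_synthetic_subject", "synthetic_cohort", "CohortSpec"]


def analyze_pair(
    device: PupilTrace,
    reference: PupilTrace,
    target_rate_hz: float = 30.0,
    max_lag_s: float = 0.5,
    spike_threshold: float = 0.2,
) -> tuple[AgreementResult, AlignedTracePair]:
    """Full comparison chain for one device/reference trace pair.

    Dropout spikes in the device trace are flagged as blinks, both traces are
    brought to ``target_rate_hz``, normalised to percent change from mean,
    aligned within ``max_lag_s``, and jointly blink-excluded before the
    agreement statistics are computed.
    """
    device = flag_blink_spikes(device, threshold=spike_threshold)
    traces = []
    for tr in (device, reference):
        if tr.sample_rate_hz > target_rate_hz * (1 + 1e-6):
            tr = downsample_trace(tr, target_rate_hz)
        traces.append(percent_change_from_mean(tr))
    pair = align_traces(traces[0], traces[1], max_lag_s=max_lag_s)
    pair = exclude_blinks(pair)
    return agreement(pair), pair


def validate_synthetic_subject(
    eye: SpectralEyeParams,
    dyn: PupilDynamicsParams,
    protocol: PLRProtocol = PLRProtocol(),
    blink_times_s: tuple[float, ...] = (),
    seed: int = 0,
    detection: DetectionConfig = DetectionConfig(),
    max_lag_s: float = 0.5,
) -> AgreementResult:
    """Render one synthetic PLR recording and score the measured trace
    against the simulator's ground truth, processed identically."""
    frames, truth = render_plr_video(
        eye, dyn, protocol, band=FAR_RED, blink_times_s=blink_times_s, seed=seed
    )
    measured = process_video(frames, truth.timestamps_s, detection)
    result, _ = analyze_pair(measured, truth.as_trace(), max_lag_s=max_lag_s)
    return result


@dataclass(frozen=True)
class CohortSpec:
    """Sampling ranges for a synthetic validation cohort.

    Defaults span the physiology and optics of a device-validation study:
    baseline diameters 40-80 px, constriction amplitudes 0.15-0.4, melanin
    loads from light-blue to dark-brown irises, sensor noise up to 5 intensity
    units, and up to two blinks per recording.
    """

    n_subjects: int = 11
    baseline_diameter_px: tuple[float, float] = (40.0, 80.0)
    constriction_amplitude: tuple[float, float] = (0.15, 0.4)
    melanin_load: tuple[float, float] = (MELANIN_BLUE, MELANIN_DARK_BROWN)
    noise_sd: tuple[float, float] = (2.0, 5.0)
    max_blinks: int = 2
    protocol: PLRProtocol = field(default_factory=PLRProtocol)


def synthetic_cohort(spec: CohortSpec = CohortSpec(), seed: int = 0) -> ValidationSummary:
    """Simulate and validate a cohort of independent synthetic subjects.

    Subject parameters are drawn uniformly from the spec ranges with a single
    seeded generator, so the whole cohort is reproducible from one integer.
    """
    rng = np.random.default_rng(seed)
    results = []
    for _ in range(spec.n_subjects):
        d0 = float(rng.uniform(*spec.baseline_diameter_px))
        amp = float(rng.uniform(*spec.constriction_amplitude))
        melanin = float(rng.uniform(*spec.melanin_load))
        noise = float(rng.uniform(*spec.noise_sd))
        eye = SpectralEyeParams(melanin_load=melanin, noise_sd=noise)
        eye = SpectralEyeParams(
            melanin_load=melanin,
            noise_sd=noise,
            glare_spots=default_glare_spots(eye, d0),
        )
        dyn = PupilDynamicsParams(baseline_diameter_px=d0, constriction_amplitude=amp)
        n_blinks = int(rng.integers(0, spec.max_blinks + 1))
        # keep blinks clear of each other and of the recording edges
        candidates = np.linspace(0.4, spec.protocol.total_duration_s - 0.4, 8)
        blink_times = tuple(np.sort(rng.choice(candidates, size=n_blinks, replace=False)))
        subject_seed = int(rng.integers(0, 2**31 - 1))
        results.append(
            validate_synthetic_subject(
                eye, dyn, spec.protocol, blink_times_s=blink_times, seed=subject_seed
            )
        )
    return summarize_cohort(results)
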