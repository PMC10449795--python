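"""Bundled reference data.

``cross_device_means.csv`` is the published reference cohort of a
four-smartphone cross-device comparison: for each of 11 participants, the
pupil-iris contrast percent increase measured on a Samsung Galaxy A53,
iPhone 12, Moto G Power and Pixel 4, together with the study's reported
per-participant mean and standard deviation, a DSLR-derived contrast value,
the median CIELAB iris luminance, and the self-assessed eye-colour label.

The reported mean/STD columns are shipped exactly as printed — for some
participants they are not the plain arithmetic mean/sample-SD of the four
per-device cells — and cohort aggregates are defined on the reported means.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["DEVICES", "load_cross_device_reference", "reference_participant_means", "reference_long"]

DEVICES = ("a53", "iphone12", "moto_g", "pixel4")


def load_cross_device_reference() -> pd.DataFrame:
    """The reference cohort, wide format, one row per participant."""
    with resources.files("redpupil.data").joinpath("cross_device_means.csv").open() as fh:
        return pd.read_csv(fh)


def reference_participant_means() -> pd.DataFrame:
    """Long-format per-participant reported means, ready for cross_device_table.

    Each participant appears once with device ``"reported_mean"``, so the
    cross-device grand means aggregate the reported per-participant means.
    """
    wide = load_cross_device_reference()
    return pd.DataFrame(
        {
            "participant": wide["participant"],
            "device": "reported_mean",
            "percent_increase": wide["reported_mean"],
            "eye_color": wide["eye_color"],
        }
    )


def reference_long() -> pd.DataFrame:
    """Long-format per-device percent increases of the reference cohort."""
    wide = load_cross_device_reference()
    frames = []
    for dev in DEVICES:
        frames.append(
            pd.DataFrame(
                {
                    "participant": wide["participant"],
                    "device": dev,
                    "percent_increase": wide[dev],
                    "eye_color": wide["eye_color"],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
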