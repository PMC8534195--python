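"""The four standard acoustic parameters of a call contour.

* principal frequency — unweighted mean frequency over the call;
* change in frequency — max minus min frequency over the contour
  (the absolute convention: a trill that returns to its start frequency
  still shows its full modulation extent);
* sinuosity — contour path length divided by the straight-line distance
  between its endpoints, computed in grid coordinates (time in frame
  steps, frequency in bin steps) so the two axes are commensurate;
* duration — contour span plus one frame step, in ms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from usvkit.contour import Contour


@dataclass
class CallFeatures:
    principal_khz: float
    delta_khz: float
    sinuosity: float
    duration_ms: float

    def as_dict(self) -> dict[str, float]:
        return {
            "principal_khz": self.principal_khz,
            "delta_khz": self.delta_khz,
            "sinuosity": self.sinuosity,
            "duration_ms": self.duration_ms,
        }


FEATURE_COLUMNS = ["principal_khz", "delta_khz", "sinuosity", "duration_ms"]


def _check(contour: Contour) -> None:
    if len(contour) < 2:
        raise ValueError("contour must have at least 2 points")


def principal_frequency(contour: Contour) -> float:
    """Unweighted mean of the contour frequencies, kHz."""
    _check(contour)
    return float(np.mean(contour.freqs_khz))


def delta_frequency(contour: Contour) -> float:
    """Frequency extent (max - min) over the contour, kHz."""
    _check(contour)
    return float(np.max(contour.freqs_khz) - np.min(contour.freqs_khz))


def sinuosity(contour: Contour, normalization: str = "grid") -> float:
    """Path length over chord length of the contour, >= 1.

    ``normalization='grid'`` (default) measures both axes in analysis-grid
    units (frame steps, bin steps).  ``normalization='zscore'`` instead
    z-scores each axis; offered for sensitivity analysis.
    """
    _check(contour)
    if normalization == "grid":
        x = contour.times / contour.frame_step_s
        y = contour.freqs_khz / contour.bin_step_khz
    elif normalization == "zscore":
        x = _zscore(contour.times)
        y = _zscore(contour.freqs_khz)
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    dx = np.diff(x)
    dy = np.diff(y)
    path = float(np.sum(np.hypot(dx, dy)))
    chord = float(np.hypot(x[-1] - x[0], y[-1] - y[0]))
    if chord == 0:
        raise ValueError(
            f"degenerate contour (coincident endpoints after {normalization} "
            f"normalization) starting at t={contour.times[0]:.4f}s"
        )
    return path / chord


def _zscore(v: np.ndarray) -> np.ndarray:
    s = np.std(v)
    return (v - np.mean(v)) / s if s > 0 else v - np.mean(v)


def duration(contour: Contour) -> float:
    """Contour duration in ms: span plus one frame step.

    A k-frame contour thus has duration k * hop, avoiding a zero-duration
    edge case for minimal contours.
    """
    _check(contour)
    return contour.duration_ms


def compute_features(contour: Contour, normalization: str = "grid") -> CallFeatures:
    """All four parameters of one contour."""
    return CallFeatures(
        principal_khz=principal_frequency(contour),
        delta_khz=delta_frequency(contour),
        sinuosity=sinuosity(contour, normalization),
        duration_ms=duration(contour),
    )


def features_table(contours: list[Contour], normalization: str = "grid"):
    """Per-call feature DataFrame (one row per contour, indexed by call_id)."""
    import pandas as pd

    rows = []
    for c in contours:
        d = compute_features(c, normalization).as_dict()
        d["call_id"] = c.call_id
        d["onset_s"] = c.onset_s
        rows.append(d)
    return pd.DataFrame(rows, columns=["call_id", "onset_s"] + FEATURE_COLUMNS)
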