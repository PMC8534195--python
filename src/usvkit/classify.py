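"""Rule-based assignment of contours to the four call categories.

The decision cascade operationalizes the standard hand-labeling scheme:

1. principal frequency below 30 kHz -> **LF** (the 20-30 kHz "22 kHz-type"
   calls; 30 kHz exactly belongs to the high-frequency side);
2. otherwise, frequency extent below ``flat_threshold_khz`` -> **Flat**
   (no visible frequency modulation);
3. otherwise, duration >= 8 ms with >= 2 rapid oscillation cycles ->
   **Trill** (8 ms exactly is eligible);
4. otherwise -> **FM**.

"Visible" modulation and "rapid" oscillation are visual criteria in manual
labeling; the thresholds used here (3 kHz extent, 1.5 kHz minimum
excursion, 25 ms maximum cycle period) are explicit, configurable
operationalizations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from usvkit.contour import Contour
from usvkit.features import CallFeatures

LABELS = ("LF", "Flat", "FM", "Trill")


@dataclass
class ClassifierParams:
    lf_boundary_khz: float = 30.0
    flat_threshold_khz: float = 3.0
    trill_min_ms: float = 8.0
    trill_min_cycles: int = 2
    min_excursion_khz: float = 1.5
    max_cycle_ms: float = 25.0
    cycle_window_ms: float = 25.0


@dataclass
class CallLabel:
    label: str
    cycles: int
    modulation_extent_khz: float


def _moving_average(v: np.ndarray, win: int) -> np.ndarray:
    # centered moving average with edge shrinkage
    win = min(max(1, win), v.size)
    kernel = np.ones(win)
    num = np.convolve(v, kernel, mode="same")
    den = np.convolve(np.ones_like(v), kernel, mode="same")
    return num / den


def count_oscillation_cycles(contour: Contour, params: ClassifierParams | None = None) -> int:
    """Count rapid frequency-oscillation cycles in a contour.

    The frequency track is detrended with a centered moving average
    (``cycle_window_ms`` wide); sign changes of the residual are counted,
    keeping only changes between excursions whose peak-to-trough amplitude
    reaches ``min_excursion_khz``.  Cycles = ceil(valid sign changes / 2),
    so a track that completes n full oscillations (2n extrema) counts n
    regardless of its starting phase.  Returns 0 when the mean cycle period
    exceeds ``max_cycle_ms`` (oscillation too slow to be a trill) or the
    contour has fewer than 4 points.
    """
    params = params or ClassifierParams()
    if len(contour) < 4:
        return 0
    f = contour.freqs_khz
    win = int(round(params.cycle_window_ms / 1000.0 / contour.frame_step_s))
    resid = f - _moving_average(f, win)

    # split into sign segments; record each segment's extremum and its time
    sign = np.sign(resid)
    sign[sign == 0] = 1
    change = np.flatnonzero(np.diff(sign) != 0)
    if change.size == 0:
        return 0
    seg_bounds = np.r_[0, change + 1, resid.size]
    extrema = []
    for a, b in zip(seg_bounds[:-1], seg_bounds[1:]):
        k = a + int(np.argmax(np.abs(resid[a:b])))
        extrema.append((contour.times[k], resid[k]))
    # a sign change is valid if the flanking excursions differ by >= the gate
    valid_times = []
    for (t1, e1), (t2, e2) in zip(extrema[:-1], extrema[1:]):
        if abs(e1 - e2) >= params.min_excursion_khz:
            valid_times.append(0.5 * (t1 + t2))
    n_changes = len(valid_times)
    if n_changes == 0:
        return 0
    cycles = int(np.ceil(n_changes / 2))
    if n_changes >= 2:
        mean_period_ms = 2 * np.mean(np.diff(valid_times)) * 1000.0
        if mean_period_ms > params.max_cycle_ms:
            return 0
    return cycles


def classify_call(
    features: CallFeatures,
    contour: Contour,
    params: ClassifierParams | None = None,
) -> CallLabel:
    """Assign one of LF / Flat / FM / Trill by the decision cascade."""
    params = params or ClassifierParams()
    pf = features.principal_khz
    if not (20.0 <= pf <= 100.0):
        raise ValueError(
            f"principal frequency {pf:.1f} kHz outside the 20-100 kHz acceptance band; "
            "contour should have been filtered upstream"
        )
    extent = features.delta_khz
    if pf < params.lf_boundary_khz:
        return CallLabel("LF", 0, extent)
    if extent < params.flat_threshold_khz:
        return CallLabel("Flat", 0, extent)
    cycles = count_oscillation_cycles(contour, params)
    if features.duration_ms >= params.trill_min_ms and cycles >= params.trill_min_cycles:
        return CallLabel("Trill", cycles, extent)
    return CallLabel("FM", cycles, extent)


def label_accuracy(
    predicted: pd.Series, ground_truth: pd.Series
) -> tuple[pd.DataFrame, pd.Series, float]:
    """Confusion matrix (truth rows x predicted columns), per-class and
    overall accuracy for matched call sets (aligned by index)."""
    predicted = pd.Series(predicted)
    ground_truth = pd.Series(ground_truth)
    if not predicted.index.equals(ground_truth.index):
        missing = predicted.index.symmetric_difference(ground_truth.index)
        raise ValueError(f"unmatched call ids: {list(missing)[:10]}")
    cm = pd.crosstab(ground_truth, predicted, dropna=False).reindex(
        index=LABELS, columns=LABELS, fill_value=0
    )
    cm.index.name = "truth"
    cm.columns.name = "predicted"
    totals = cm.sum(axis=1)
    diag = pd.Series(np.diag(cm.values), index=cm.index)
    per_class = (diag / totals).where(totals > 0)
    overall = float(diag.sum() / totals.sum()) if totals.sum() else float("nan")
    return cm, per_class, overall
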