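"""Spectrogram computation, ridge-based call detection and noise rejection.

Detection is rule-based: per-frame adaptive thresholding of the band-limited
power spectrogram (median + k * scaled MAD), 8-connected component grouping,
gap merging, and magnitude-weighted ridge extraction.  Candidate contours
shorter than 2 ms or with a principal frequency outside the 20-100 kHz
acceptance band are discarded.  A separate rule set rejects broadband
clicks, weakly tonal components and over-long sounds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

from usvkit.contour import Contour


@dataclass
class Spectrogram:
    """Power spectrogram with frame-major orientation.

    ``power[i, j]`` is the power in frame ``i`` (center time ``times[i]``
    seconds) and frequency bin ``j`` (``freqs_khz[j]`` kHz).
    """

    times: np.ndarray
    freqs_khz: np.ndarray
    power: np.ndarray
    window_s: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.freqs_khz = np.asarray(self.freqs_khz, dtype=float)
        if self.power.shape != (self.times.size, self.freqs_khz.size):
            raise ValueError("power must be (n_frames, n_bins)")
        if np.any(np.diff(self.times) <= 0) or np.any(np.diff(self.freqs_khz) <= 0):
            raise ValueError("axes must be strictly increasing")

    @property
    def frame_step_s(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def bin_step_khz(self) -> float:
        return float(self.freqs_khz[1] - self.freqs_khz[0])


@dataclass
class DetectorParams:
    """Tunables of the rule-based detector.

    STFT defaults (512-sample Hann window, 75% overlap at 250 kHz) give
    ~0.49 kHz frequency and ~0.5 ms time resolution, enough to apply the
    2 ms minimum-duration rule and trace trill oscillations.
    """

    nperseg: int = 512
    overlap: float = 0.75
    window: str = "hann"
    threshold_k: float = 5.0
    gap_ms: float = 5.0
    min_pixels: int = 12
    min_duration_ms: float = 2.0  # contours must be strictly longer
    band_khz: tuple[float, float] = (18.0, 105.0)
    accept_band_khz: tuple[float, float] = (20.0, 100.0)
    merge_freq_tol_khz: float = 6.0
    merge_min_pixels: int = 10  # only substantial fragments are merged
    # noise-rejection rules
    max_click_bw_khz: float = 25.0
    min_tonality: float = 0.35
    tonality_halfwidth_khz: float = 3.0
    max_duration_s: float = 1.0

    def validate(self, sample_rate: float) -> None:
        if sample_rate / self.nperseg > 1000.0:
            raise ValueError("frequency resolution coarser than 1 kHz")
        hop = self.nperseg * (1 - self.overlap) / sample_rate
        if hop > 1e-3:
            raise ValueError("time resolution coarser than 1 ms")


def compute_spectrogram(
    waveform: np.ndarray,
    sample_rate: float,
    nperseg: int = 512,
    overlap: float = 0.75,
    window: str = "hann",
) -> Spectrogram:
    """One-sided power spectrogram (PSD scaling) of a mono waveform.

    With a rectangular window and no overlap the summed power times the
    bin width and frame duration reproduces the time-domain energy
    (Parseval), see :func:`total_energy`.
    """
    x = np.asarray(waveform)
    if x.size == 0:
        raise ValueError("empty waveform")
    if x.size < nperseg:
        raise ValueError(f"waveform shorter than one window ({x.size} < {nperseg})")
    noverlap = int(round(nperseg * overlap))
    f, t, sxx = signal.spectrogram(
        x,
        fs=sample_rate,
        window=window if window != "rect" else ("boxcar"),
        nperseg=nperseg,
        noverlap=noverlap,
        detrend=False,
        scaling="density",
        mode="psd",
    )
    return Spectrogram(times=t, freqs_khz=f / 1000.0, power=sxx.T, window_s=nperseg / sample_rate)


def total_energy(spec: Spectrogram) -> float:
    """Time-domain-equivalent energy implied by the spectrogram."""
    df_hz = spec.bin_step_khz * 1000.0
    return float(spec.power.sum() * df_hz * spec.window_s)


# ---------------------------------------------------------------------------
# Contour detection
# ---------------------------------------------------------------------------


#: components smaller than this are dropped before gap merging; single- and
#: two-pixel noise specks dominate the raw component count.
_MIN_FRAGMENT_PIXELS = 3


def detect_contours(spec: Spectrogram, params: DetectorParams | None = None) -> list[Contour]:
    """Extract candidate call contours from a power spectrogram.

    Pixels above a per-frame adaptive threshold (median + k * 1.4826 MAD of
    the band-limited power in that frame) are grouped into 8-connected
    components; components separated by gaps <= ``gap_ms`` with overlapping
    frequency extents are merged.  Each component's per-frame
    magnitude-weighted mean frequency forms the contour.  Components smaller
    than ``min_pixels``, contours lasting <= ``min_duration_ms`` or with a
    principal frequency outside the acceptance band are discarded.
    """
    params = params or DetectorParams()
    lo, hi = params.band_khz
    bsel = (spec.freqs_khz >= lo) & (spec.freqs_khz <= hi)
    p = spec.power[:, bsel]
    freqs = spec.freqs_khz[bsel]
    med = np.median(p, axis=1, keepdims=True)
    mad = np.median(np.abs(p - med), axis=1, keepdims=True)
    thresh = med + params.threshold_k * 1.4826 * mad
    active = p > thresh

    labels, n = ndimage.label(active, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return []

    ti, fi = np.nonzero(active)
    lab = labels[ti, fi] - 1
    sizes = np.bincount(lab, minlength=n)
    sel = sizes[lab] >= _MIN_FRAGMENT_PIXELS
    if not sel.any():
        return []
    ti, fi, lab = ti[sel], fi[sel], lab[sel]
    pw = p[ti, fi].astype(float)
    uniq, lab = np.unique(lab, return_inverse=True)
    m = uniq.size
    comp_sizes = np.bincount(lab, minlength=m)

    # component bounding boxes (frame/bin index space)
    big = np.iinfo(np.int64).max
    t0 = np.full(m, big)
    t1 = np.full(m, -1)
    np.minimum.at(t0, lab, ti)
    np.maximum.at(t1, lab, ti)
    # frequency extent of each component's first and last frame, for
    # continuity-based gap merging (a fragment of the same call resumes
    # near the frequency where the previous fragment stopped)
    first_lo = np.full(m, big)
    first_hi = np.full(m, -1)
    last_lo = np.full(m, big)
    last_hi = np.full(m, -1)
    at_first = ti == t0[lab]
    at_last = ti == t1[lab]
    np.minimum.at(first_lo, lab[at_first], fi[at_first])
    np.maximum.at(first_hi, lab[at_first], fi[at_first])
    np.minimum.at(last_lo, lab[at_last], fi[at_last])
    np.maximum.at(last_hi, lab[at_last], fi[at_last])

    # merge components separated by short gaps with continuous frequency
    gap_frames = max(1, int(round(params.gap_ms / 1000.0 / spec.frame_step_s)))
    tol_bins = int(math.ceil(params.merge_freq_tol_khz / spec.bin_step_khz))
    parent = list(range(m))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    order = np.argsort(t0, kind="stable")
    for ai in range(m):
        i = int(order[ai])
        for aj in range(ai + 1, m):
            j = int(order[aj])
            if t0[j] - t1[i] > gap_frames:
                break
            if t0[j] <= t1[i]:  # simultaneous sounds are not the same call
                continue
            if comp_sizes[i] < params.merge_min_pixels or comp_sizes[j] < params.merge_min_pixels:
                continue
            if last_lo[i] - tol_bins <= first_hi[j] and first_lo[j] <= last_hi[i] + tol_bins:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri

    root = np.array([find(i) for i in range(m)])
    group = root[lab]
    order = np.argsort(group, kind="stable")
    ti, fi, pw, group = ti[order], fi[order], pw[order], group[order]
    bounds = np.flatnonzero(np.r_[True, np.diff(group) > 0])
    bounds = np.r_[bounds, group.size]

    contours: list[Contour] = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        if b - a < params.min_pixels:
            continue
        tg, fg, wg = ti[a:b], fi[a:b], pw[a:b]
        fa, fb = int(tg.min()), int(tg.max())
        nspan = fb - fa + 1
        if nspan < 2:
            continue
        loc = tg - fa
        wsum = np.bincount(loc, weights=wg, minlength=nspan)
        wfreq = np.bincount(loc, weights=wg * freqs[fg], minlength=nspan)
        has = wsum > 0
        freq_tr = np.empty(nspan)
        freq_tr[has] = wfreq[has] / wsum[has]
        if not has.all():  # fill merged-gap frames by interpolation
            span = np.arange(nspan)
            freq_tr[~has] = np.interp(span[~has], span[has], freq_tr[has])
        mags = np.zeros(nspan)
        np.maximum.at(mags, loc, wg)
        fmin = np.full(nspan, np.iinfo(np.int64).max)
        fmax = np.full(nspan, -1)
        np.minimum.at(fmin, loc, fg)
        np.maximum.at(fmax, loc, fg)
        bw = np.where(fmax >= 0, (fmax - fmin + 1) * spec.bin_step_khz, 0.0)
        c = Contour(
            times=spec.times[fa : fb + 1],
            freqs_khz=freq_tr,
            mags=mags,
            frame_step_s=spec.frame_step_s,
            bin_step_khz=spec.bin_step_khz,
            frame_bw_khz=bw,
        )
        # discount the STFT window smear: a burst of true length L spans
        # roughly (L + window - hop) of frames, so subtract that excess
        smear_ms = (spec.window_s - spec.frame_step_s) * 1000.0
        if c.duration_ms - smear_ms <= params.min_duration_ms:
            continue
        pf = float(freq_tr.mean())
        if not (params.accept_band_khz[0] <= pf <= params.accept_band_khz[1]):
            continue
        contours.append(c)

    contours.sort(key=lambda c: c.times[0])
    for i, c in enumerate(contours):
        c.call_id = i
    return contours


def reject_noise(
    contours: list[Contour],
    spec: Spectrogram | None = None,
    params: DetectorParams | None = None,
) -> tuple[list[Contour], list[tuple[Contour, str]]]:
    """Split contours into (accepted, rejected-with-reason) by explicit rules.

    Rules: instantaneous bandwidth above ``max_click_bw_khz`` in any frame
    (broadband click); median tonality — the fraction of band power within
    ``tonality_halfwidth_khz`` of the ridge — below ``min_tonality``;
    duration above ``max_duration_s``.
    """
    params = params or DetectorParams()
    accepted: list[Contour] = []
    rejected: list[tuple[Contour, str]] = []
    for c in contours:
        reason = None
        if c.duration_ms / 1000.0 > params.max_duration_s:
            reason = "too_long"
        elif c.frame_bw_khz.size and float(np.max(c.frame_bw_khz)) > params.max_click_bw_khz:
            reason = "click"
        elif spec is not None:
            tone = _tonality(c, spec, params)
            if tone < params.min_tonality:
                reason = "low_tonality"
        if reason is None:
            accepted.append(c)
        else:
            rejected.append((c, reason))
    return accepted, rejected


def _tonality(c: Contour, spec: Spectrogram, params: DetectorParams) -> float:
    lo, hi = params.band_khz
    bsel = (spec.freqs_khz >= lo) & (spec.freqs_khz <= hi)
    freqs = spec.freqs_khz[bsel]
    idx = np.searchsorted(spec.times, c.times[0])
    fracs = []
    for k, t in enumerate(c.times):
        i = min(idx + k, spec.times.size - 1)
        row = spec.power[i, bsel]
        near = np.abs(freqs - c.freqs_khz[k]) <= params.tonality_halfwidth_khz
        tot = float(row.sum())
        fracs.append(float(row[near].sum()) / tot if tot > 0 else 0.0)
    return float(np.median(fracs))


def detect_session(
    waveform: np.ndarray,
    sample_rate: float,
    params: DetectorParams | None = None,
    apply_rejection: bool = True,
) -> list[Contour]:
    """Full detection chain on one waveform: spectrogram, contours, rejection."""
    params = params or DetectorParams()
    params.validate(sample_rate)
    x = np.asarray(waveform, dtype=np.float32)  # halves spectrogram memory
    spec = compute_spectrogram(
        x, sample_rate, nperseg=params.nperseg, overlap=params.overlap, window=params.window
    )
    contours = detect_contours(spec, params)
    if apply_rejection:
        contours, _ = reject_noise(contours, spec, params)
    return contours


def match_ground_truth(
    contours: list[Contour],
    truth_onsets_s: np.ndarray,
    onset_tol_ms: float = 5.0,
) -> tuple[float, float, list[tuple[int, int]]]:
    """Greedy one-to-one matching of detections to ground-truth onsets.

    Returns ``(recall, precision, matches)`` where matches are
    (truth_index, contour_index) pairs with onset distance within tolerance.
    """
    truth = np.asarray(truth_onsets_s, dtype=float)
    det = np.array([c.onset_s for c in contours])
    tol = onset_tol_ms / 1000.0
    pairs = []
    if truth.size and det.size:
        cand = [
            (abs(truth[i] - det[j]), i, j)
            for i in range(truth.size)
            for j in range(det.size)
            if abs(truth[i] - det[j]) <= tol
        ]
        cand.sort()
        used_t: set[int] = set()
        used_d: set[int] = set()
        for _, i, j in cand:
            if i in used_t or j in used_d:
                continue
            pairs.append((i, j))
            used_t.add(i)
            used_d.add(j)
    recall = len(pairs) / truth.size if truth.size else float("nan")
    precision = len(pairs) / det.size if det.size else float("nan")
    return recall, precision, pairs
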