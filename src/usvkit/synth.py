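"""Synthetic rat USV audio and experimental-session generation.

Generates single calls with parametric frequency trajectories, whole
recording sessions (audio + ground-truth table), and event-level
multi-animal experiments with the statistical structure of a chemogenetic
inhibition study: a declining 30-min baseline, a psychostimulant-induced
surge that is maximal in the first 20 min post-injection, multiplicative
suppression of FM and Trill (but not Flat/LF) call rates under the agonist
(CNO) condition, and a female > male Trill-rate effect.

Call trajectory shapes are the minimal ones consistent with the four-category
scheme: LF and Flat are constant tones, FM is a monotone (gently curved)
sweep, Trill is a sinusoidal frequency modulation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.io import wavfile

from usvkit.contour import Contour, DEFAULT_BIN_STEP_KHZ, DEFAULT_FRAME_STEP_S

CALL_TYPES = ("LF", "Flat", "FM", "Trill")
HIGH_TYPES = ("Flat", "FM", "Trill")

#: Frequency band (kHz) within which all rendered trajectories must stay.
BAND_KHZ = (20.0, 100.0)


@dataclass
class CallSpec:
    """Ground-truth description of one synthesized call.

    ``sweep_khz`` is the signed total frequency change of an FM sweep (the
    trajectory runs from ``base_khz`` to ``base_khz + sweep_khz``).
    ``trill_depth_khz`` is the half peak-to-trough amplitude of the Trill's
    sinusoidal modulation around ``base_khz``.
    """

    call_type: str
    onset_s: float
    duration_ms: float
    base_khz: float
    amplitude: float = 0.3
    sweep_khz: float = 0.0
    fm_curve_khz: float = 0.0
    trill_rate_hz: float = 0.0
    trill_depth_khz: float = 0.0

    def __post_init__(self) -> None:
        if self.call_type not in CALL_TYPES:
            raise ValueError(f"unknown call type {self.call_type!r}")
        if self.onset_s < 0:
            raise ValueError("onset must be >= 0")
        if self.duration_ms <= 0:
            raise ValueError("duration must be positive")
        if not (0 < self.amplitude <= 1):
            raise ValueError("amplitude must be in (0, 1]")
        if self.call_type == "LF":
            if not (20.0 <= self.base_khz < 30.0):
                raise ValueError(f"LF base frequency {self.base_khz} kHz outside [20, 30)")
        else:
            if not (30.0 <= self.base_khz <= 100.0):
                raise ValueError(
                    f"{self.call_type} base frequency {self.base_khz} kHz outside [30, 100]"
                )
        if self.call_type == "Trill":
            cycles = self.trill_rate_hz * self.duration_ms / 1000.0
            if self.duration_ms < 8.0 or cycles < 2.0:
                raise ValueError(
                    f"Trill must last >= 8 ms with >= 2 cycles (got {self.duration_ms} ms, "
                    f"{cycles:.2f} cycles)"
                )
        lo, hi = self.freq_range_khz()
        if lo < BAND_KHZ[0] - 1e-9 or hi > BAND_KHZ[1] + 1e-9:
            raise ValueError(
                f"trajectory spans [{lo:.1f}, {hi:.1f}] kHz, outside the {BAND_KHZ} kHz band"
            )

    def trajectory_khz(self, t_s: np.ndarray) -> np.ndarray:
        """Instantaneous frequency (kHz) at times ``t_s`` from call start."""
        t = np.asarray(t_s, dtype=float)
        if self.call_type in ("LF", "Flat"):
            return np.full_like(t, self.base_khz)
        if self.call_type == "FM":
            # gently curved sweep: a half-cycle arc rides on the linear ramp
            # (kept monotone, so the frequency extent stays |sweep_khz|)
            dur_s = self.duration_ms / 1000.0
            return (
                self.base_khz
                + self.sweep_khz * t / dur_s
                + self.fm_curve_khz * np.sin(np.pi * t / dur_s)
            )
        # Trill: sinusoidal modulation around the base frequency
        return self.base_khz + self.trill_depth_khz * np.sin(
            2 * np.pi * self.trill_rate_hz * t
        )

    def freq_range_khz(self) -> tuple[float, float]:
        """Min and max of the programmed trajectory."""
        if self.call_type in ("LF", "Flat"):
            return self.base_khz, self.base_khz
        if self.call_type == "FM" and self.fm_curve_khz == 0.0:
            end = self.base_khz + self.sweep_khz
            return min(self.base_khz, end), max(self.base_khz, end)
        t = np.linspace(0, self.duration_ms / 1000.0, 512)
        f = self.trajectory_khz(t)
        return float(f.min()), float(f.max())

    def nominal_features(self) -> dict[str, float]:
        """Principal frequency and extent of the programmed trajectory."""
        t = np.linspace(0, self.duration_ms / 1000.0, 512)
        f = self.trajectory_khz(t)
        return {
            "principal_khz": float(f.mean()),
            "extent_khz": float(f.max() - f.min()),
        }


def synthesize_call(spec: CallSpec, sample_rate: float, ramp_ms: float = 2.0) -> np.ndarray:
    """Render one call as a waveform at ``sample_rate`` Hz.

    The instantaneous frequency follows :meth:`CallSpec.trajectory_khz`; the
    amplitude envelope has raised-cosine onset/offset ramps (``ramp_ms`` each,
    capped at a quarter of the call) to avoid spectral splatter.
    """
    _, f_hi = spec.freq_range_khz()
    if sample_rate < 2 * f_hi * 1000:
        raise ValueError(
            f"sample rate {sample_rate} Hz violates Nyquist for a {f_hi} kHz trajectory"
        )
    if spec.call_type == "Trill":
        cycles = spec.trill_rate_hz * spec.duration_ms / 1000.0
        if cycles < 2.0:
            raise ValueError(f"Trill renders only {cycles:.2f} cycles (< 2)")
    n = max(2, round(spec.duration_ms / 1000.0 * sample_rate))
    t = np.arange(n) / sample_rate
    freq_hz = spec.trajectory_khz(t) * 1000.0
    phase = 2 * np.pi * np.cumsum(freq_hz) / sample_rate
    wave = spec.amplitude * np.sin(phase)

    ramp_n = min(int(ramp_ms / 1000.0 * sample_rate), n // 4)
    if ramp_n > 0:
        ramp = 0.5 * (1 - np.cos(np.pi * np.arange(ramp_n) / ramp_n))
        wave[:ramp_n] *= ramp
        wave[-ramp_n:] *= ramp[::-1]
    return wave


def contour_from_spec(
    spec: CallSpec,
    frame_step_s: float = DEFAULT_FRAME_STEP_S,
    bin_step_khz: float = DEFAULT_BIN_STEP_KHZ,
) -> Contour:
    """Ideal spectrotemporal contour of a call (no audio rendering).

    Samples the programmed trajectory on the analysis frame grid; used to
    attach noiseless features to event-level simulations and as a reference
    in detector evaluation.
    """
    dur_s = spec.duration_ms / 1000.0
    n = max(2, int(round(dur_s / frame_step_s)))
    t = spec.onset_s + np.arange(n) * frame_step_s
    f = spec.trajectory_khz(t - spec.onset_s)
    return Contour(
        times=t,
        freqs_khz=f,
        mags=np.full(n, spec.amplitude),
        frame_step_s=frame_step_s,
        bin_step_khz=bin_step_khz,
    )


# ---------------------------------------------------------------------------
# Per-type parameter priors
# ---------------------------------------------------------------------------

#: Sampling ranges for call parameters, chosen to keep every call well inside
#: the four-category decision boundaries (constant tones for LF/Flat, sweeps
#: of at least 8 kHz for FM, >= 3 modulation cycles for Trill).
DEFAULT_PRIORS: dict[str, dict[str, tuple[float, float]]] = {
    "LF": {"base_khz": (21.0, 27.0), "duration_ms": (30.0, 120.0)},
    "Flat": {"base_khz": (35.0, 75.0), "duration_ms": (20.0, 80.0)},
    "FM": {
        "base_khz": (40.0, 70.0),
        "duration_ms": (20.0, 80.0),
        "sweep_abs_khz": (6.0, 12.0),
    },
    # trill modulation spans its full peak-to-trough extent twice per cycle,
    # so depth 5-9 kHz makes trills the most frequency-modulated category
    "Trill": {
        "base_khz": (50.0, 75.0),
        "duration_ms": (50.0, 90.0),
        "trill_rate_hz": (60.0, 90.0),
        "trill_depth_khz": (5.0, 9.0),
    },
}


def sample_call_spec(
    call_type: str,
    rng: np.random.Generator,
    onset_s: float = 0.0,
    amplitude: float = 0.3,
    priors: dict | None = None,
) -> CallSpec:
    """Draw one call's parameters from the per-type priors."""
    p = (priors or DEFAULT_PRIORS)[call_type]
    base = rng.uniform(*p["base_khz"])
    dur = rng.uniform(*p["duration_ms"])
    kw: dict[str, float] = {}
    if call_type == "FM":
        extent = rng.uniform(*p["sweep_abs_khz"])
        sign = 1.0 if rng.random() < 0.5 else -1.0
        # keep the sweep inside the band
        if base + sign * extent > BAND_KHZ[1] - 2 or base + sign * extent < BAND_KHZ[0] + 2:
            sign = -sign
        kw["sweep_khz"] = sign * extent
        # curvature below sweep/pi keeps the trajectory monotone
        kw["fm_curve_khz"] = sign * rng.uniform(0.5, 0.9 * extent / math.pi)
    elif call_type == "Trill":
        depth = rng.uniform(*p["trill_depth_khz"])
        base = min(base, BAND_KHZ[1] - depth - 2)
        kw["trill_rate_hz"] = rng.uniform(*p["trill_rate_hz"])
        kw["trill_depth_khz"] = depth
    return CallSpec(
        call_type=call_type,
        onset_s=onset_s,
        duration_ms=dur,
        base_khz=base,
        amplitude=amplitude,
        **kw,
    )


# ---------------------------------------------------------------------------
# Session design and event simulation
# ---------------------------------------------------------------------------


def _default_base_rates() -> dict[str, float]:
    # events/min in the first baseline bin; absolute levels are a design
    # choice (see docs/methods.md), relative structure mirrors the study.
    return {"LF": 0.3, "Flat": 2.0, "FM": 3.0, "Trill": 2.0}


def _default_surge() -> dict[str, float]:
    return {"LF": 1.0, "Flat": 3.0, "FM": 8.0, "Trill": 8.0}


def _default_cno() -> dict[str, float]:
    return {"LF": 1.0, "Flat": 1.0, "FM": 0.5, "Trill": 0.5}


@dataclass
class SessionDesign:
    """Rate structure and rendering parameters for one recording session.

    The event-rate profile is piecewise constant over 10-min bins: the
    baseline profile starts at ``base_rates`` and decays by
    ``baseline_decay`` per bin; the post-injection profile jumps to
    ``surge x base_rates``, stays at its peak for the first two bins
    (maximal in the first 20 min) and then decays by ``post_decay`` per bin.
    Under ``drug == "CNO"`` every rate is multiplied by the per-type
    ``cno_multiplier``; females get ``sex_trill_multiplier`` on Trill.
    """

    rat_id: str = "rat00"
    sex: str = "F"
    drug: str = "VEH"
    baseline_minutes: float = 30.0
    post_minutes: float = 60.0
    base_rates: dict[str, float] = field(default_factory=_default_base_rates)
    baseline_decay: float = 0.6
    surge: dict[str, float] = field(default_factory=_default_surge)
    post_decay: float = 0.6
    cno_multiplier: dict[str, float] = field(default_factory=_default_cno)
    sex_trill_multiplier: float = 1.5
    rate_scale: dict[str, float] = field(default_factory=dict)
    snr_db: float = 20.0
    sample_rate: float = 250_000.0
    amplitude: float = 0.3
    refractory_ms: float = 50.0
    bin_minutes: float = 10.0
    priors: dict | None = None

    def __post_init__(self) -> None:
        if self.sex not in ("F", "M"):
            raise ValueError("sex must be 'F' or 'M'")
        if self.drug not in ("VEH", "CNO"):
            raise ValueError("drug must be 'VEH' or 'CNO'")
        for ct, r in self.base_rates.items():
            if r < 0:
                raise ValueError(f"negative rate for {ct}")

    def _type_multiplier(self, call_type: str) -> float:
        m = self.rate_scale.get(call_type, 1.0)
        if self.drug == "CNO":
            m *= self.cno_multiplier.get(call_type, 1.0)
        if self.sex == "F" and call_type == "Trill":
            m *= self.sex_trill_multiplier
        return m

    def bin_rates(self, call_type: str, epoch: str) -> np.ndarray:
        """Events/min in each 10-min bin of an epoch, multipliers applied."""
        base = self.base_rates.get(call_type, 0.0) * self._type_multiplier(call_type)
        if epoch == "baseline":
            nb = int(math.ceil(self.baseline_minutes / self.bin_minutes))
            return base * self.baseline_decay ** np.arange(nb)
        if epoch == "post_amph":
            nb = int(math.ceil(self.post_minutes / self.bin_minutes))
            peak = base * self.surge.get(call_type, 1.0)
            decay_steps = np.maximum(0, np.arange(nb) - 1)  # peak held for 2 bins
            return peak * self.post_decay ** decay_steps
        raise ValueError(f"unknown epoch {epoch!r}")

    def rate_profile(self, call_type: str, epoch: str):
        """Piecewise-constant rate function (events/min vs time-in-epoch, s)."""
        rates = self.bin_rates(call_type, epoch)
        bin_s = self.bin_minutes * 60.0

        def rate(t_s: np.ndarray) -> np.ndarray:
            idx = np.clip((np.asarray(t_s) // bin_s).astype(int), 0, len(rates) - 1)
            return rates[idx]

        return rate

    def epoch_minutes(self, epoch: str) -> float:
        return self.baseline_minutes if epoch == "baseline" else self.post_minutes


def _thinned_onsets(rate_fn, duration_s: float, rate_max_per_min: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Inhomogeneous-Poisson onsets on [0, duration_s) by thinning."""
    if rate_max_per_min <= 0:
        return np.empty(0)
    lam = rate_max_per_min / 60.0  # events/s
    n = rng.poisson(lam * duration_s)
    t = np.sort(rng.uniform(0, duration_s, n))
    keep = rng.uniform(0, rate_max_per_min, n) < rate_fn(t)
    return t[keep]


def simulate_events(design: SessionDesign, rng: np.random.Generator) -> pd.DataFrame:
    """Draw the call-event stream for one session.

    Onsets come from independent inhomogeneous Poisson processes per call
    type (thinning algorithm), durations from the per-type priors.  A
    refractory gap is then enforced by shifting colliding onsets forward to
    the first admissible time, which preserves expected counts; events pushed
    past the epoch end are dropped.  Raises if the offered load (total call
    time + gaps) exceeds the epoch duration.

    Returns a DataFrame with one row per call: ``call_type``, ``epoch``,
    ``time_s`` (in-epoch onset) and ``duration_ms``, sorted by epoch and time.
    """
    rows: list[pd.DataFrame] = []
    for epoch in ("baseline", "post_amph"):
        dur_min = design.epoch_minutes(epoch)
        if dur_min <= 0:
            continue
        dur_s = dur_min * 60.0
        onsets_all, types_all, durms_all = [], [], []
        for ct in CALL_TYPES:
            rates = design.bin_rates(ct, epoch)
            if rates.max() <= 0:
                continue
            onsets = _thinned_onsets(design.rate_profile(ct, epoch), dur_s, rates.max(), rng)
            if onsets.size == 0:
                continue
            lo, hi = (DEFAULT_PRIORS if design.priors is None else design.priors)[ct][
                "duration_ms"
            ]
            durms = rng.uniform(lo, hi, onsets.size)
            onsets_all.append(onsets)
            types_all.extend([ct] * onsets.size)
            durms_all.append(durms)
        if not onsets_all:
            continue
        onset = np.concatenate(onsets_all)
        durms = np.concatenate(durms_all)
        ctype = np.asarray(types_all, dtype=object)
        order = np.argsort(onset, kind="stable")
        onset, durms, ctype = onset[order], durms[order], ctype[order]

        gap_s = design.refractory_ms / 1000.0
        load = float(np.sum(durms / 1000.0 + gap_s))
        if load > dur_s:
            raise ValueError(
                f"offered call load {load:.0f} s exceeds the {dur_s:.0f} s {epoch} epoch; "
                "rates too high for the refractory constraint"
            )
        # enforce non-overlap by pushing colliding onsets forward
        t_free = 0.0
        keep = np.ones(onset.size, dtype=bool)
        for i in range(onset.size):
            start = max(onset[i], t_free)
            end = start + durms[i] / 1000.0
            if end > dur_s:
                keep[i] = False
                continue
            onset[i] = start
            t_free = end + gap_s
        rows.append(
            pd.DataFrame(
                {
                    "call_type": ctype[keep],
                    "epoch": epoch,
                    "time_s": onset[keep],
                    "duration_ms": durms[keep],
                }
            )
        )
    if not rows:
        return pd.DataFrame(columns=["call_type", "epoch", "time_s", "duration_ms"])
    return pd.concat(rows, ignore_index=True)


GROUND_TRUTH_COLUMNS = [
    "rat_id", "sex", "drug", "epoch", "call_type",
    "onset_s", "time_s", "duration_ms", "principal_khz", "extent_khz",
]


def synthesize_session(
    design: SessionDesign, rng: np.random.Generator | int
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render a full session: waveform plus ground-truth record table.

    The waveform covers baseline followed by the post-injection epoch;
    ``onset_s`` in the returned table is the absolute onset in the waveform,
    ``time_s`` the in-epoch onset.  Calls are rendered with
    :func:`synthesize_call` and summed with white Gaussian noise whose power
    in the 20-100 kHz band realizes ``design.snr_db`` relative to the mean
    power of a call at the design amplitude.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    fs = design.sample_rate
    events = simulate_events(design, rng)
    total_s = (design.baseline_minutes + design.post_minutes) * 60.0
    n_total = int(round(total_s * fs))
    wave = np.zeros(n_total)

    records = []
    for _, ev in events.iterrows():
        offset_s = 0.0 if ev.epoch == "baseline" else design.baseline_minutes * 60.0
        onset_abs = offset_s + ev.time_s
        spec = sample_call_spec(
            ev.call_type, rng, onset_s=onset_abs, amplitude=design.amplitude,
            priors=design.priors,
        )
        spec = replace(spec, duration_ms=float(ev.duration_ms))
        call = synthesize_call(spec, fs)
        i0 = int(round(onset_abs * fs))
        i1 = min(i0 + call.size, n_total)
        wave[i0:i1] += call[: i1 - i0]
        nf = spec.nominal_features()
        records.append(
            {
                "rat_id": design.rat_id,
                "sex": design.sex,
                "drug": design.drug,
                "epoch": ev.epoch,
                "call_type": ev.call_type,
                "onset_s": onset_abs,
                "time_s": ev.time_s,
                "duration_ms": spec.duration_ms,
                "principal_khz": nf["principal_khz"],
                "extent_khz": nf["extent_khz"],
            }
        )
    table = pd.DataFrame(records, columns=GROUND_TRUTH_COLUMNS)

    # white noise scaled so SNR over the 20-100 kHz band matches the design
    band_fraction = (BAND_KHZ[1] - BAND_KHZ[0]) * 1000.0 / (fs / 2)
    p_call = design.amplitude**2 / 2
    p_noise_band = p_call / 10 ** (design.snr_db / 10)
    sigma = math.sqrt(p_noise_band / band_fraction)
    wave += rng.normal(0.0, sigma, n_total)
    return wave, table


def write_session(
    waveform: np.ndarray,
    records: pd.DataFrame,
    wav_path,
    csv_path,
    sample_rate: float = 250_000.0,
) -> None:
    """Write a session to a 16-bit PCM mono WAV plus a ground-truth CSV.

    The CSV has the fixed column set :data:`GROUND_TRUTH_COLUMNS`; the
    waveform is clipped to [-1, 1] before quantization.
    """
    x = np.clip(np.asarray(waveform, dtype=float), -1.0, 1.0)
    pcm = np.round(x * 32767.0).astype(np.int16)
    wavfile.write(wav_path, int(sample_rate), pcm)
    records.reindex(columns=GROUND_TRUTH_COLUMNS).to_csv(csv_path, index=False)


def read_wav(path) -> tuple[float, np.ndarray]:
    """Read a mono WAV; returns (sample_rate, float waveform in [-1, 1])."""
    fs, data = wavfile.read(path)
    if data.ndim != 1:
        raise ValueError("expected mono audio")
    if data.dtype == np.int16:
        return float(fs), data.astype(float) / 32767.0
    return float(fs), data.astype(float)


# ---------------------------------------------------------------------------
# Event-level experiment simulation (no audio)
# ---------------------------------------------------------------------------


@dataclass
class ExperimentDesign:
    """A full within-subjects experiment: every rat tested on a vehicle day
    and a CNO day, half the rats per sex.

    ``rat_rate_sd`` and ``day_rate_sd`` are log-normal standard deviations of
    per-rat (shared across days) and per-day multiplicative rate
    heterogeneity, giving the counts realistic overdispersion relative to a
    pure Poisson process.
    """

    n_rats: int = 16
    session: SessionDesign = field(default_factory=SessionDesign)
    rat_rate_sd: float = 0.4
    day_rate_sd: float = 0.15

    def rats(self) -> list[tuple[str, str]]:
        half = self.n_rats // 2
        return [
            (f"rat{i:02d}", "F" if i < half else "M") for i in range(self.n_rats)
        ]


def simulate_experiment(
    design: ExperimentDesign,
    rng: np.random.Generator | int,
    with_features: bool = False,
) -> pd.DataFrame:
    """Simulate every session of an experiment at the event level.

    Returns a per-call table (columns of :data:`GROUND_TRUTH_COLUMNS` minus
    ``onset_s``; plus the four acoustic features when ``with_features``),
    ready for :func:`usvkit.stats.bin_counts`.  Feature values, when
    requested, are computed by running the real feature code on ideal
    contours of sampled call parameters.
    """
    from usvkit import features as feat

    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    tables = []
    for rat_id, sex in design.rats():
        rat_frailty = {
            ct: float(np.exp(rng.normal(0.0, design.rat_rate_sd))) for ct in CALL_TYPES
        }
        for drug in ("VEH", "CNO"):
            day = float(np.exp(rng.normal(0.0, design.day_rate_sd)))
            scale = {ct: rat_frailty[ct] * day for ct in CALL_TYPES}
            sess = replace(
                design.session, rat_id=rat_id, sex=sex, drug=drug, rate_scale=scale
            )
            events = simulate_events(sess, rng)
            events.insert(0, "rat_id", rat_id)
            events.insert(1, "sex", sex)
            events.insert(2, "drug", drug)
            if with_features:
                feats = []
                for _, ev in events.iterrows():
                    spec = sample_call_spec(ev.call_type, rng, priors=design.session.priors)
                    spec = replace(spec, duration_ms=float(ev.duration_ms))
                    c = contour_from_spec(spec)
                    feats.append(feat.compute_features(c).as_dict())
                fdf = pd.DataFrame(
                    feats, columns=["principal_khz", "delta_khz", "sinuosity", "duration_ms"]
                )
                events = pd.concat(
                    [events.drop(columns=["duration_ms"]).reset_index(drop=True), fdf],
                    axis=1,
                )
            tables.append(events)
    out = pd.concat(tables, ignore_index=True)
    out = out.rename(columns={"call_type": "label"})
    return out
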