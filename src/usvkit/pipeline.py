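"""End-to-end orchestration: generate -> detect -> featurize -> classify ->
analyze -> embed, with a single YAML-configurable RunConfig, one master
seed, and provenance headers on every output file."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from usvkit import __version__
from usvkit.analysis import analyze_experiment
from usvkit.classify import ClassifierParams, classify_call
from usvkit.detect import DetectorParams, detect_session
from usvkit.embed import cluster_composition, embed_table
from usvkit.features import FEATURE_COLUMNS, compute_features
from usvkit.synth import (
    ExperimentDesign,
    SessionDesign,
    read_wav,
    synthesize_session,
    write_session,
)

log = logging.getLogger("usvkit")


@dataclass
class GeneratorConfig:
    n_rats: int = 4
    baseline_minutes: float = 5.0
    post_minutes: float = 5.0
    snr_db: float = 20.0
    amplitude: float = 0.3


@dataclass
class EmbedConfig:
    k: int = 3
    n_neighbors: int = 15
    min_dist: float = 0.1


@dataclass
class RunConfig:
    """All tunables of a pipeline run; ``seed`` is mandatory."""

    seed: int
    sample_rate: float = 250_000.0
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    detector: DetectorParams = field(default_factory=DetectorParams)
    classifier: ClassifierParams = field(default_factory=ClassifierParams)
    embed: EmbedConfig = field(default_factory=EmbedConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        js = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(js.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "seed" not in raw:
            raise ValueError(f"config {path} must define a 'seed' key")
        kwargs = dict(raw)
        for key, sub in (
            ("generator", GeneratorConfig),
            ("detector", DetectorParams),
            ("classifier", ClassifierParams),
            ("embed", EmbedConfig),
        ):
            if key in kwargs and isinstance(kwargs[key], dict):
                d = kwargs[key]
                if key == "detector":
                    for tup in ("band_khz", "accept_band_khz"):
                        if tup in d:
                            d[tup] = tuple(d[tup])
                kwargs[key] = sub(**d)
        return cls(**kwargs)


def _write_csv(df: pd.DataFrame, path: Path, config: RunConfig) -> None:
    header = (
        f"# usvkit {__version__} config_hash={config.config_hash()} seed={config.seed}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False)


def read_output_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def stage_generate(config: RunConfig, outdir: Path) -> list[Path]:
    """Synthesize one WAV + ground-truth CSV per rat x drug session."""
    outdir.mkdir(parents=True, exist_ok=True)
    gen = config.generator
    design = ExperimentDesign(
        n_rats=gen.n_rats,
        session=SessionDesign(
            baseline_minutes=gen.baseline_minutes,
            post_minutes=gen.post_minutes,
            snr_db=gen.snr_db,
            sample_rate=config.sample_rate,
            amplitude=gen.amplitude,
        ),
    )
    rng = np.random.default_rng(config.seed)
    wavs = []
    for rat_id, sex in design.rats():
        for drug in ("VEH", "CNO"):
            sess = dataclasses.replace(
                design.session, rat_id=rat_id, sex=sex, drug=drug
            )
            wave, records = synthesize_session(sess, rng)
            stem = f"{rat_id}_{drug}"
            wav = outdir / f"{stem}.wav"
            write_session(wave, records, wav, outdir / f"{stem}_truth.csv",
                          config.sample_rate)
            wavs.append(wav)
            log.info("generated %s: %d calls", stem, len(records))
    return wavs


CONTOUR_COLUMNS = [
    "call_id", "time_s", "freq_khz", "magnitude", "frame_bw_khz",
    "frame_step_s", "bin_step_khz",
]


def stage_detect_one(wav_path: Path, config: RunConfig, outdir: Path) -> pd.DataFrame:
    """Detect calls in one WAV; writes the contour-point CSV."""
    fs, wave = read_wav(wav_path)
    contours = detect_session(wave, fs, config.detector)
    pts = []
    for c in contours:
        for t, f, m, bw in zip(c.times, c.freqs_khz, c.mags, c.frame_bw_khz):
            pts.append(
                {
                    "call_id": c.call_id,
                    "time_s": t,
                    "freq_khz": f,
                    "magnitude": m,
                    "frame_bw_khz": bw,
                    "frame_step_s": c.frame_step_s,
                    "bin_step_khz": c.bin_step_khz,
                }
            )
    pts_df = pd.DataFrame(pts, columns=CONTOUR_COLUMNS)
    _write_csv(pts_df, outdir / f"{wav_path.stem}_contours.csv", config)
    log.info("detected %d calls in %s", len(contours), wav_path.name)
    return pts_df


def _contours_from_csv(path: Path) -> list:
    from usvkit.contour import Contour

    df = read_output_csv(path)
    out = []
    for cid, sub in df.groupby("call_id"):
        out.append(
            Contour(
                times=sub["time_s"].to_numpy(),
                freqs_khz=sub["freq_khz"].to_numpy(),
                mags=sub["magnitude"].to_numpy(),
                frame_step_s=float(sub["frame_step_s"].iloc[0]),
                bin_step_khz=float(sub["bin_step_khz"].iloc[0]),
                frame_bw_khz=sub["frame_bw_khz"].to_numpy(),
                call_id=int(cid),
            )
        )
    return out


def stage_features(config: RunConfig, outdir: Path) -> None:
    """Compute the four acoustic parameters for every detected contour."""
    for path in sorted(outdir.glob("*_contours.csv")):
        stem = path.stem.rsplit("_contours", 1)[0]
        rows = []
        for c in _contours_from_csv(path):
            feats = compute_features(c)
            rows.append({"call_id": c.call_id, "onset_s": c.onset_s, **feats.as_dict()})
        df = pd.DataFrame(rows, columns=["call_id", "onset_s"] + FEATURE_COLUMNS)
        _write_csv(df, outdir / f"{stem}_calls.csv", config)
        log.info("featurized %d calls from %s", len(df), path.name)


def stage_classify(config: RunConfig, outdir: Path) -> None:
    """Append the call-category label to every per-call summary CSV."""
    for path in sorted(outdir.glob("*_calls.csv")):
        stem = path.stem.rsplit("_calls", 1)[0]
        calls = read_output_csv(path).set_index("call_id")
        contours = {
            c.call_id: c for c in _contours_from_csv(outdir / f"{stem}_contours.csv")
        }
        labels, cycles = [], []
        for cid, row in calls.iterrows():
            c = contours[int(cid)]
            feats = compute_features(c)
            lab = classify_call(feats, c, config.classifier)
            labels.append(lab.label)
            cycles.append(lab.cycles)
        calls["label"] = labels
        calls["cycles"] = cycles
        _write_csv(calls.reset_index(), path, config)


def _session_table(config: RunConfig, outdir: Path) -> pd.DataFrame:
    """Assemble the per-call SessionTable from the per-session call CSVs."""
    gen = config.generator
    base_s = gen.baseline_minutes * 60.0
    rows = []
    for path in sorted(outdir.glob("*_calls.csv")):
        rat_id, drug = path.stem.rsplit("_calls", 1)[0].rsplit("_", 1)
        truth = outdir / f"{rat_id}_{drug}_truth.csv"
        sex = None
        if truth.exists():
            tdf = pd.read_csv(truth)
            if len(tdf):
                sex = tdf["sex"].iloc[0]
        if sex is None:
            half = gen.n_rats // 2
            sex = "F" if int(rat_id.replace("rat", "")) < half else "M"
        calls = read_output_csv(path)
        calls["rat_id"] = rat_id
        calls["drug"] = drug
        calls["sex"] = sex
        calls["epoch"] = np.where(calls["onset_s"] < base_s, "baseline", "post_amph")
        calls["time_s"] = np.where(
            calls["onset_s"] < base_s, calls["onset_s"], calls["onset_s"] - base_s
        )
        rows.append(calls)
    if not rows:
        raise FileNotFoundError(f"no *_calls.csv files in {outdir}")
    return pd.concat(rows, ignore_index=True)


def stage_stats(config: RunConfig, outdir: Path) -> pd.DataFrame:
    table = _session_table(config, outdir)
    results = analyze_experiment(
        table,
        baseline_minutes=config.generator.baseline_minutes,
        post_minutes=config.generator.post_minutes,
    )
    _write_csv(results, outdir / "stats_results.csv", config)
    return results


def stage_embed(config: RunConfig, outdir: Path) -> pd.DataFrame:
    table = _session_table(config, outdir)
    emb = embed_table(table, seed=config.seed, n_neighbors=config.embed.n_neighbors,
                      min_dist=config.embed.min_dist)
    comp = cluster_composition(emb, k=config.embed.k, seed=config.seed)
    _write_csv(
        comp["assignments"][
            ["rat_id", "sex", "drug", "label", "x", "y", "cluster"]
        ].reset_index(drop=True),
        outdir / "embedding.csv",
        config,
    )
    for col in ("label", "sex"):
        if col in comp:
            _write_csv(
                comp[col].reset_index(), outdir / f"cluster_{col}_composition.csv", config
            )
    return comp["assignments"]


def run_pipeline(config: RunConfig, outdir) -> Path:
    """Run every stage end to end into ``outdir``; returns the directory.

    Identical config + seed produce identical CSV contents.  A stage
    failure aborts with the stage name in the raised error.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "run_config.yaml", "w") as fh:
        yaml.safe_dump(
            {"config_hash": config.config_hash(), **config.to_dict()}, fh, sort_keys=False
        )
    logging.basicConfig(level=logging.INFO)
    stages = [
        ("generate", lambda: stage_generate(config, outdir)),
        ("detect", lambda: [
            stage_detect_one(w, config, outdir) for w in sorted(outdir.glob("*.wav"))
        ]),
        ("features", lambda: stage_features(config, outdir)),
        ("classify", lambda: stage_classify(config, outdir)),
        ("stats", lambda: stage_stats(config, outdir)),
        ("embed", lambda: stage_embed(config, outdir)),
    ]
    for name, fn in stages:
        try:
            fn()
        except Exception as err:
            raise RuntimeError(f"pipeline stage {name!r} failed: {err}") from err
    return outdir
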