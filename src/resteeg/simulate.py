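"""Synthetic resting-state EEG with ground-truth manifests.

The generator builds band-limited stochastic oscillators (FIR-filtered
Gaussian noise, so spectral peaks have realistic width) at atlas ROI
locations, couples selected pairs by a shared phase-lagged carrier or a
shared amplitude modulator, projects them to the scalp through the
three-shell spherical forward model, and adds 1/f background plus white
sensor noise. Artifacts (flat spans, noisy channels, blinks with a VEOG
mirror, line noise, high-amplitude bursts) are injected afterwards with
their realized sample ranges recorded in the manifest, so every detector in
the preprocessing chain can be scored against known truth.

Defaults describe a plausible adult eyes-closed resting recording:
2 minutes of 40 standard 10-10 channels + VEOG at 250 Hz, a 10 Hz occipital
alpha source (2 Hz bandwidth) about 6x the white-sensor-noise RMS at its
best electrode, a weaker 6 Hz frontal theta source, and a spatially
correlated 1/f background with log-log slope ~ -1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import filters
from .model_io import RawRecording, write_brainvision
from .source_recon import load_atlas
from .sphere import ThreeShellModel, standard_positions

DEFAULT_CHANNELS = [
    "Fp1", "Fpz", "Fp2", "AF3", "AF4", "F7", "F3", "Fz", "F4", "F8",
    "FT7", "FC5", "FC1", "FCz", "FC2", "FC6", "FT8",
    "T7", "C3", "Cz", "C4", "T8",
    "TP7", "CP5", "CP1", "CPz", "CP2", "CP6", "TP8",
    "P7", "P3", "Pz", "P4", "P8", "PO3", "POz", "PO4",
    "O1", "Oz", "O2",
]


@dataclass
class SourceSpec:
    center_hz: float = 10.0
    bandwidth_hz: float = 2.0
    amplitude_uv: float = 6.0      # peak-electrode RMS contribution, µV
    roi: int = 0


@dataclass
class CouplingSpec:
    pair: tuple[int, int] = (0, 1)         # indices into cfg.sources
    kind: str = "phase_lag"                # "phase_lag" | "envelope"
    strength: float = 1.0                  # in [0, 1]
    lag_rad: float = np.pi / 2


@dataclass
class ArtifactSpec:
    flat_spans: list[tuple[int, float, float]] = field(default_factory=list)
    noisy_channels: list[int] = field(default_factory=list)
    blink_times_s: list[float] = field(default_factory=list)
    line_amp_uv: float = 0.0
    burst_spans_s: list[tuple[float, float]] = field(default_factory=list)


@dataclass
class SimulationConfig:
    channels: list[str] = field(default_factory=lambda: list(DEFAULT_CHANNELS))
    srate: float = 250.0
    duration_s: float = 120.0
    seed: int = 0
    line_freq: float = 50.0
    sources: list[SourceSpec] = field(default_factory=lambda: [
        SourceSpec(center_hz=10.0, bandwidth_hz=2.0, amplitude_uv=6.0, roi=97),
        SourceSpec(center_hz=6.0, bandwidth_hz=2.0, amplitude_uv=2.0, roi=2),
    ])
    couplings: list[CouplingSpec] = field(default_factory=list)
    artifacts: ArtifactSpec = field(default_factory=ArtifactSpec)
    sensor_noise_uv: float = 1.0
    background_1f_uv: float = 3.0
    add_veog: bool = True
    atlas: str = "atlas100_7networks_synthetic"

    def validate(self) -> None:
        problems = []
        n_src = len(self.sources)
        for c in self.couplings:
            if not (0 <= c.pair[0] < n_src and 0 <= c.pair[1] < n_src):
                problems.append(f"coupling pair {c.pair} references undefined "
                                f"sources (have {n_src})")
            if c.kind not in ("phase_lag", "envelope"):
                problems.append(f"unknown coupling kind '{c.kind}'")
            if not 0 <= c.strength <= 1:
                problems.append(f"coupling strength {c.strength} outside [0,1]")
        for ch, t0, t1 in self.artifacts.flat_spans:
            if not (0 <= t0 < t1 <= self.duration_s):
                problems.append(f"flat span ({t0},{t1}) outside recording")
            if not 0 <= ch < len(self.channels):
                problems.append(f"flat-span channel {ch} out of range")
        for t0, t1 in self.artifacts.burst_spans_s:
            if not (0 <= t0 < t1 <= self.duration_s):
                problems.append(f"burst span ({t0},{t1}) outside recording")
        for t in self.artifacts.blink_times_s:
            if not 0 <= t <= self.duration_s - 0.5:
                problems.append(f"blink at {t}s does not fit in the recording")
        if problems:
            raise ValueError("invalid simulation config: " + "; ".join(problems))


@dataclass
class SimulationManifest:
    """Realized ground truth of one synthetic recording."""
    seed: int
    srate: float
    n_samples: int
    sources: list[dict] = field(default_factory=list)
    couplings: list[dict] = field(default_factory=list)
    artifacts: dict = field(default_factory=dict)
    mixing: list[list[float]] | None = None     # (n_src, n_channels) patterns

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @property
    def bad_sample_spans(self) -> list[tuple[int, int]]:
        return [tuple(s) for s in self.artifacts.get("burst_spans", [])]


def _narrowband_noise(rng, n, srate, center, bw) -> np.ndarray:
    lo = max(0.5, center - bw / 2)
    hi = min(srate / 2 * 0.95, center + bw / 2)
    x = filters.bandpass(rng.standard_normal(n + 2 * int(srate)), srate, (lo, hi))
    x = x[int(srate):-int(srate)]
    return x / (np.std(x) + 1e-30)


def _one_over_f(rng, n, srate, exponent: float = 1.0) -> np.ndarray:
    """Unit-RMS noise with power ~ 1/f^exponent above 1 Hz (flat below)."""
    spec = np.fft.rfft(rng.standard_normal(n))
    f = np.fft.rfftfreq(n, 1 / srate)
    shape = np.ones_like(f)
    nz = f > 1.0
    shape[nz] = (f[nz]) ** (-exponent / 2)
    x = np.fft.irfft(spec * shape, n)
    return x / (np.std(x) + 1e-30)


def source_signals(cfg: SimulationConfig, rng: np.random.Generator,
                   n: int) -> np.ndarray:
    """(n_sources, n) unit-RMS band-limited source time courses with the
    configured phase-lag / envelope couplings applied."""
    from scipy.signal import hilbert

    if not cfg.sources:
        return np.zeros((0, n))
    sigs = np.stack([
        _narrowband_noise(rng, n, cfg.srate, s.center_hz, s.bandwidth_hz)
        for s in cfg.sources])
    for c in cfg.couplings:
        i, j = c.pair
        if c.kind == "phase_lag":
            z = hilbert(sigs[i])
            lagged = np.real(z * np.exp(-1j * c.lag_rad))
            lagged /= np.std(lagged) + 1e-30
            own = sigs[j]
            sigs[j] = c.strength * lagged + np.sqrt(1 - c.strength ** 2) * own
        else:  # envelope
            mod = filters.lowpass(rng.standard_normal(n), cfg.srate, 1.0)
            mod = np.exp(1.0 * mod / (np.std(mod) + 1e-30))    # log-normal AM
            mod /= np.mean(mod)
            env_i = 1 + c.strength * (mod - 1)
            sigs[i] = sigs[i] * env_i
            sigs[j] = sigs[j] * env_i
        sigs[j] /= np.std(sigs[j]) + 1e-30
        sigs[i] /= np.std(sigs[i]) + 1e-30
    return sigs


def simulate_recording(cfg: SimulationConfig | None = None
                       ) -> tuple[RawRecording, SimulationManifest]:
    """Generate a clean synthetic recording (no artifacts) with its manifest.

    Bit-identical for a fixed config (all randomness from ``cfg.seed``).
    """
    cfg = cfg or SimulationConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration_s * cfg.srate))
    std = standard_positions()
    unknown = [c for c in cfg.channels if c not in std]
    if unknown:
        raise ValueError(f"channels without standard positions: {unknown}")
    pos = np.array([std[c] for c in cfg.channels])
    model = ThreeShellModel(pos)
    atlas = load_atlas(cfg.atlas)

    sigs = source_signals(cfg, rng, n)
    data = np.zeros((len(cfg.channels), n))
    patterns = []
    for spec, sig in zip(cfg.sources, sigs):
        p = atlas.positions[spec.roi]
        ori = p / np.linalg.norm(p)            # radial orientation
        g = model.gain(p) @ ori
        g = g / np.max(np.abs(g))              # µV at the best electrode
        patterns.append(g)
        data += np.outer(g, sig) * spec.amplitude_uv

    # spatially correlated 1/f background: many weak dipole sources projected
    # through the same head model (real EEG background is smooth across the
    # scalp, which the bad-channel predictability criterion relies on)
    n_bg = 40
    bg = np.zeros_like(data)
    for _ in range(n_bg):
        d = rng.standard_normal(3)
        d /= np.linalg.norm(d)
        r = 0.03 + 0.045 * rng.random()
        p = r * d
        g = model.gain(p) @ d
        g = g / (np.max(np.abs(g)) + 1e-30)
        bg += np.outer(g, _one_over_f(rng, n, cfg.srate))
    bg *= cfg.background_1f_uv / (np.median(np.std(bg, axis=1)) + 1e-30)
    data += bg
    data += cfg.sensor_noise_uv * rng.standard_normal(data.shape)

    names = list(cfg.channels)
    types = ["EEG"] * len(names)
    positions = pos
    if cfg.add_veog:
        names = names + ["VEOG"]
        types = types + ["EOG"]
        data = np.vstack([data, cfg.sensor_noise_uv * rng.standard_normal(n)])
        positions = np.vstack([pos, np.full(3, np.nan)])

    rec = RawRecording(data=data, srate=cfg.srate, channel_names=names,
                       channel_types=types, positions=positions,
                       reference="average", line_freq=cfg.line_freq)
    manifest = SimulationManifest(
        seed=cfg.seed, srate=cfg.srate, n_samples=n,
        sources=[{**asdict(s), "roi_name": atlas.roi_names[s.roi]}
                 for s in cfg.sources],
        couplings=[asdict(c) for c in cfg.couplings],
        artifacts={}, mixing=[list(map(float, g)) for g in patterns])
    return rec, manifest


def inject_artifacts(rec: RawRecording, cfg: SimulationConfig,
                     manifest: SimulationManifest
                     ) -> tuple[RawRecording, SimulationManifest]:
    """Add the configured artifacts in place of clean data; the manifest gains
    the realized sample ranges."""
    art = cfg.artifacts
    rng = np.random.default_rng(cfg.seed + 10_000)
    rec = rec.copy()
    n = rec.n_samples
    sr = rec.srate
    realized: dict = {"flat_spans": [], "noisy_channels": [],
                      "blink_spans": [], "burst_spans": [],
                      "line_amp_uv": art.line_amp_uv}

    flat_samples: dict[int, set] = {}
    for ch, t0, t1 in art.flat_spans:
        a, b = int(round(t0 * sr)), int(round(t1 * sr))
        for t0b, t1b in art.burst_spans_s:
            ba, bb = int(round(t0b * sr)), int(round(t1b * sr))
            if a < bb and ba < b:
                raise ValueError("flat span overlaps a burst span on the same "
                                 "samples; artifacts contradict each other")
        rec.data[ch, a:b] = 0.0
        realized["flat_spans"].append([ch, a, b])
        flat_samples.setdefault(ch, set()).update(range(a, b))

    eeg = rec.eeg_picks()
    for ch in art.noisy_channels:
        sigma = float(np.median(np.std(rec.data[eeg], axis=1)))
        rec.data[ch] += 10.0 * sigma * rng.standard_normal(n)
        realized["noisy_channels"].append(int(ch))

    if art.blink_times_s:
        blink_len = int(round(0.5 * sr))
        pulse = np.hanning(blink_len) ** 2
        if rec.positions is not None:
            y = np.nan_to_num(rec.positions[:, 1])
            z = np.nan_to_num(rec.positions[:, 2])
            w = np.clip(y, 0, None) * np.clip(1 - z / np.max(np.abs(z) + 1e-12), 0.2, 1)
            w = np.where(np.asarray(rec.channel_types) == "EEG",
                         w / (w.max() + 1e-30), 0.0)
        else:
            w = np.ones(rec.n_channels) / rec.n_channels
        veog = rec.channel_names.index("VEOG") if "VEOG" in rec.channel_names \
            else None
        for t in art.blink_times_s:
            a = int(round(t * sr))
            b = min(a + blink_len, n)
            seg = pulse[: b - a]
            rec.data[:, a:b] += 120.0 * np.outer(w, seg)
            if veog is not None:
                rec.data[veog, a:b] += 120.0 * seg
            realized["blink_spans"].append([a, b])

    if art.line_amp_uv > 0:
        t = np.arange(n) / sr
        phase = rng.uniform(0, 2 * np.pi)
        per_ch = art.line_amp_uv * rng.uniform(0.5, 1.0, rec.n_channels)
        rec.data += np.outer(per_ch, np.sin(2 * np.pi * cfg.line_freq * t + phase))

    for t0, t1 in art.burst_spans_s:
        a, b = int(round(t0 * sr)), int(round(t1 * sr))
        rec.data[eeg, a:b] += 500.0 * rng.standard_normal((len(eeg), b - a))
        realized["burst_spans"].append([a, b])

    # re-flatten any flat spans touched by later artifacts
    for ch, spans in flat_samples.items():
        idx = np.fromiter(spans, int)
        rec.data[ch, idx] = 0.0

    manifest.artifacts = realized
    return rec, manifest


# ---------------------------------------------------------------------------
# BIDS output
# ---------------------------------------------------------------------------

def write_bids_recording(rec: RawRecording, root, subject: str, task: str,
                         manifest: SimulationManifest | None = None) -> Path:
    """Write one recording as BrainVision + BIDS sidecars; returns vhdr path."""
    root = Path(root)
    eeg_dir = root / f"sub-{subject}" / "eeg"
    eeg_dir.mkdir(parents=True, exist_ok=True)
    stem = f"sub-{subject}_task-{task}"
    vhdr = write_brainvision(rec, eeg_dir, f"{stem}_eeg")
    (eeg_dir / f"{stem}_eeg.json").write_text(json.dumps({
        "TaskName": task,
        "PowerLineFrequency": rec.line_freq,
        "EEGReference": rec.reference,
        "SamplingFrequency": rec.srate,
        "EEGChannelCount": int(np.sum(np.array(rec.channel_types) == "EEG")),
        "RecordingDuration": rec.duration_s,
    }, indent=2))
    pd.DataFrame({
        "name": rec.channel_names,
        "type": rec.channel_types,
        "units": ["µV"] * rec.n_channels,
        "status": ["good"] * rec.n_channels,
    }).to_csv(eeg_dir / f"{stem}_channels.tsv", sep="\t", index=False)
    if rec.positions is not None:
        mask = np.all(np.isfinite(rec.positions), axis=1)
        pd.DataFrame({
            "name": [n for n, m in zip(rec.channel_names, mask) if m],
            "x": rec.positions[mask, 0],
            "y": rec.positions[mask, 1],
            "z": rec.positions[mask, 2],
        }).to_csv(eeg_dir / f"sub-{subject}_electrodes.tsv", sep="\t",
                  index=False)
        (eeg_dir / f"sub-{subject}_coordsystem.json").write_text(json.dumps({
            "EEGCoordinateSystem": "RAS", "EEGCoordinateUnits": "m"}))
    if manifest is not None:
        manifest.to_json(eeg_dir / f"{stem}_manifest.json")
    return vhdr


def make_paired_dataset(out_dir, n_subjects: int = 30, alpha_ratio: float = 0.5,
                        cfg: SimulationConfig | None = None,
                        base_seed: int = 0) -> Path:
    """Paired eyes-closed / eyes-open dataset: per subject, two recordings
    identical except the alpha-band source amplitude is scaled by
    ``alpha_ratio`` in the EO condition. Inter-subject variability comes from
    per-subject seeds.
    """
    if alpha_ratio <= 0:
        raise ValueError("alpha_ratio must be positive")
    # default stated world: one broadband alpha source spanning the whole
    # 8-12.9 Hz band (the eyes-open attenuation affects the full band) plus a
    # condition-independent theta source; 60 s per recording
    base = cfg or SimulationConfig(
        duration_s=60.0,
        sources=[SourceSpec(center_hz=10.45, bandwidth_hz=4.9,
                            amplitude_uv=6.0, roi=97),
                 SourceSpec(center_hz=6.0, bandwidth_hz=2.0,
                            amplitude_uv=2.0, roi=2)])
    out_dir = Path(out_dir)
    for s in range(1, n_subjects + 1):
        label = f"{s:03d}"
        for task, ratio in (("EC", 1.0), ("EO", alpha_ratio)):
            scfg = SimulationConfig(
                channels=list(base.channels), srate=base.srate,
                duration_s=base.duration_s, seed=base_seed + s,
                line_freq=base.line_freq,
                sources=[SourceSpec(
                    center_hz=sp.center_hz, bandwidth_hz=sp.bandwidth_hz,
                    amplitude_uv=sp.amplitude_uv * (
                        ratio if 8 <= sp.center_hz <= 12.9 else 1.0),
                    roi=sp.roi) for sp in base.sources],
                couplings=list(base.couplings),
                sensor_noise_uv=base.sensor_noise_uv,
                background_1f_uv=base.background_1f_uv,
                add_veog=base.add_veog, atlas=base.atlas)
            rec, manifest = simulate_recording(scfg)
            write_bids_recording(rec, out_dir, label, task, manifest)
    (out_dir / "dataset_description.json").write_text(json.dumps({
        "Name": "synthetic paired EC/EO resting EEG", "BIDSVersion": "1.8.0"}))
    return out_dir
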