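"""Domain types, BIDS-style raw readers (BrainVision / EDF), parameter
handling and feature writers.

Conventions
-----------
* amplitudes are microvolts; positions are head RAS in meters
* sample indexing is 0-based; intervals are half-open ``[start, end)``
* a *boundary* is a sample index at which continuity breaks: the sample at
  the boundary index starts a new continuous segment
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator
from scipy import signal

from .sphere import standard_positions

DEFAULT_BANDS = {
    "theta": (4.0, 7.9),
    "alpha": (8.0, 12.9),
    "beta": (13.0, 30.0),
    "gamma": (30.1, 80.0),
}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class RawRecording:
    """Continuous multichannel EEG.

    data : (n_channels, n_samples) float array, microvolts
    positions : (n_channels, 3) array in meters or None; rows may be NaN for
        channels without a known position (e.g. bipolar EOG)
    events : list of (sample_index, label)
    boundaries : sorted sample indices where continuity breaks
    """

    data: np.ndarray
    srate: float
    channel_names: list[str]
    channel_types: list[str]
    positions: np.ndarray | None = None
    reference: str = "average"
    line_freq: float | None = None
    events: list[tuple[int, str]] = field(default_factory=list)
    boundaries: list[int] = field(default_factory=list)

    def __post_init__(self):
        self.data = np.asarray(self.data, float)
        if self.srate <= 0:
            raise ValueError("srate must be positive")
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channel_names):
            raise ValueError("data row count must equal channel count")
        if len(self.channel_types) != len(self.channel_names):
            raise ValueError("channel_types length mismatch")
        b = list(self.boundaries)
        if b != sorted(set(b)) or (b and (b[0] < 0 or b[-1] > self.n_samples)):
            raise ValueError("boundaries must be strictly increasing within "
                             "[0, n_samples]")
        if self.positions is not None:
            self.positions = np.asarray(self.positions, float)
            if self.positions.shape != (len(self.channel_names), 3):
                raise ValueError("positions must be (n_channels, 3)")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.srate

    def eeg_picks(self) -> np.ndarray:
        return np.array([i for i, t in enumerate(self.channel_types)
                         if t.upper() == "EEG"], dtype=int)

    def copy(self) -> "RawRecording":
        return replace(
            self, data=self.data.copy(),
            channel_names=list(self.channel_names),
            channel_types=list(self.channel_types),
            positions=None if self.positions is None else self.positions.copy(),
            events=list(self.events), boundaries=list(self.boundaries))

    def pick(self, idx) -> "RawRecording":
        idx = np.asarray(idx, dtype=int)
        return replace(
            self, data=self.data[idx],
            channel_names=[self.channel_names[i] for i in idx],
            channel_types=[self.channel_types[i] for i in idx],
            positions=None if self.positions is None else self.positions[idx],
            events=list(self.events), boundaries=list(self.boundaries))


def make_channel_table(names, types=None, units=None, status=None,
                       positions=None) -> pd.DataFrame:
    """BIDS channels.tsv mirror: columns name, type, units, status (+ x,y,z)."""
    n = len(names)
    if len(set(names)) != n:
        raise ValueError("channel names must be unique")
    tbl = pd.DataFrame({
        "name": list(names),
        "type": list(types) if types is not None else ["EEG"] * n,
        "units": list(units) if units is not None else ["µV"] * n,
        "status": list(status) if status is not None else ["good"] * n,
    })
    if positions is not None:
        positions = np.asarray(positions, float)
        tbl[["x", "y", "z"]] = positions
    return tbl


class ParamSet(BaseModel):
    """Pipeline parameters with the published defaults.

    Band intervals are closed on both ends; all durations are seconds.
    """

    downsample_hz: float | None = None
    hp_transition_band: tuple[float, float] = (0.25, 0.75)
    flat_max_s: float = 5.0
    noise_z_thresh: float = 4.0
    predictability_frac: float = 0.8
    ic_reject_classes: list[str] = Field(default_factory=lambda: ["Muscle", "Eye"])
    ic_reject_prob: float = 0.8
    n_ica_repetitions: int = 10
    asr_calib_noisy_frac: float = 0.075
    asr_rms_z: float = 5.5
    asr_cutoff: float = 20.0
    epoch_len_s: float = 2.0
    epoch_overlap: float = 0.5
    bands: dict[str, tuple[float, float]] = Field(
        default_factory=lambda: dict(DEFAULT_BANDS))
    pad_to_s: float = 10.0
    lcmv_reg: float = 0.05
    atlas: str = "atlas100_7networks_synthetic"
    graph_density: float = 0.2
    n_null: int = 10
    add_back_ref: bool = False
    seed: int = 0

    @field_validator("flat_max_s", "noise_z_thresh", "predictability_frac",
                     "ic_reject_prob", "asr_calib_noisy_frac", "asr_rms_z",
                     "asr_cutoff", "epoch_len_s", "pad_to_s", "lcmv_reg")
    @classmethod
    def _positive(cls, v, info):
        if v <= 0:
            raise ValueError(f"{info.field_name} must be strictly positive")
        return v

    @field_validator("graph_density", "epoch_overlap")
    @classmethod
    def _open_unit(cls, v, info):
        if not 0 < v < 1:
            raise ValueError(f"{info.field_name} must lie in (0, 1)")
        return v

    @field_validator("n_ica_repetitions")
    @classmethod
    def _pos_int(cls, v):
        if v < 1:
            raise ValueError("n_ica_repetitions must be >= 1")
        return v

    @model_validator(mode="after")
    def _bands_ordered(self):
        prev_hi = -np.inf
        for name, (lo, hi) in self.bands.items():
            if not lo < hi:
                raise ValueError(f"band {name} has empty interval")
            if lo <= prev_hi:
                raise ValueError("band intervals must be ascending and "
                                 "non-overlapping")
            prev_hi = hi
        lo, hi = self.hp_transition_band
        if not 0 <= lo < hi:
            raise ValueError("hp_transition_band must be an ascending pair")
        return self


def load_params(path) -> ParamSet:
    """Read a params JSON file; unspecified fields take the defaults."""
    with open(path) as f:
        raw = json.load(f)
    if not isinstance(raw, dict):
        raise ValueError("params file must contain a JSON object")
    return ParamSet(**raw)


@dataclass
class FeatureBundle:
    """All extracted features of one recording plus the resolved parameters."""

    subject: str
    power: dict                      # frequencies, per-channel, global, n_epochs
    apf: dict                        # peak_maximum_hz (or None), cog_hz
    source_power: dict               # band -> (n_roi,) array
    connectivity: dict               # (measure, band) -> (n_roi, n_roi) matrix
    graph: dict                      # (measure, band) -> metrics dict
    params: ParamSet = field(default_factory=ParamSet)
    roi_names: list[str] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# BrainVision
# ---------------------------------------------------------------------------

def write_brainvision(rec: RawRecording, out_dir, stem: str) -> Path:
    """Write .vhdr/.vmrk/.eeg (IEEE float32, multiplexed). Returns vhdr path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    vhdr = out_dir / f"{stem}.vhdr"
    vmrk = out_dir / f"{stem}.vmrk"
    eeg = out_dir / f"{stem}.eeg"
    lines = [
        "Brain Vision Data Exchange Header File Version 1.0",
        "[Common Infos]",
        f"DataFile={eeg.name}",
        f"MarkerFile={vmrk.name}",
        "DataFormat=BINARY",
        "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={rec.n_channels}",
        f"SamplingInterval={1e6 / rec.srate:.6f}",
        "[Binary Infos]",
        "BinaryFormat=IEEE_FLOAT_32",
        "[Channel Infos]",
    ]
    for i, name in enumerate(rec.channel_names, start=1):
        lines.append(f"Ch{i}={name},,1,µV")
    vhdr.write_text("\n".join(lines) + "\n", encoding="utf-8")

    mlines = [
        "Brain Vision Data Exchange Marker File, Version 1.0",
        "[Common Infos]",
        f"DataFile={eeg.name}",
        "[Marker Infos]",
        "Mk1=New Segment,,1,1,0",
    ]
    k = 2
    for b in rec.boundaries:
        mlines.append(f"Mk{k}=New Segment,,{b + 1},1,0")
        k += 1
    for s, label in rec.events:
        mlines.append(f"Mk{k}=Stimulus,{label},{s + 1},1,0")
        k += 1
    vmrk.write_text("\n".join(mlines) + "\n", encoding="utf-8")

    rec.data.T.astype("<f4").tofile(eeg)
    return vhdr


def _parse_ini(text: str) -> dict[str, dict[str, str]]:
    sections: dict[str, dict[str, str]] = {}
    current = None
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith((";", "#")):
            continue
        if line.startswith("[") and line.endswith("]"):
            current = line[1:-1]
            sections.setdefault(current, {})
        elif "=" in line and current is not None:
            k, v = line.split("=", 1)
            sections[current][k.strip()] = v.strip()
    return sections


def read_brainvision(vhdr_path) -> RawRecording:
    vhdr_path = Path(vhdr_path)
    ini = _parse_ini(vhdr_path.read_text(encoding="utf-8", errors="replace"))
    common = ini.get("Common Infos", {})
    binary = ini.get("Binary Infos", {})
    if common.get("DataFormat", "BINARY").upper() != "BINARY":
        raise ValueError("only BINARY BrainVision data is supported")
    if binary.get("BinaryFormat", "IEEE_FLOAT_32") != "IEEE_FLOAT_32":
        raise ValueError("only IEEE_FLOAT_32 BrainVision data is supported")
    if common.get("DataOrientation", "MULTIPLEXED").upper() != "MULTIPLEXED":
        raise ValueError("only MULTIPLEXED orientation is supported")
    n_ch = int(common["NumberOfChannels"])
    srate = 1e6 / float(common["SamplingInterval"])
    names, scales = [], []
    for i in range(1, n_ch + 1):
        entry = ini["Channel Infos"][f"Ch{i}"]
        parts = entry.split(",")
        names.append(parts[0])
        scales.append(float(parts[2]) if len(parts) > 2 and parts[2] else 1.0)
    data = np.fromfile(vhdr_path.with_suffix(".eeg"), dtype="<f4")
    data = data.reshape(-1, n_ch).T.astype(float) * np.asarray(scales)[:, None]

    events: list[tuple[int, str]] = []
    boundaries: list[int] = []
    vmrk = vhdr_path.with_suffix(".vmrk")
    if vmrk.exists():
        mk = _parse_ini(vmrk.read_text(encoding="utf-8", errors="replace"))
        for key, val in sorted(mk.get("Marker Infos", {}).items(),
                               key=lambda kv: int(kv[0][2:])):
            parts = val.split(",")
            mtype, desc, pos = parts[0], parts[1], int(parts[2]) - 1
            if mtype == "New Segment":
                if pos > 0:
                    boundaries.append(pos)
            else:
                events.append((pos, desc))
    return RawRecording(data=data, srate=srate, channel_names=names,
                        channel_types=["EEG"] * n_ch,
                        events=events, boundaries=sorted(set(boundaries)))


# ---------------------------------------------------------------------------
# EDF (read; minimal write used for fixtures)
# ---------------------------------------------------------------------------

def read_edf(path) -> RawRecording:
    """Minimal EDF reader: continuous 16-bit records with physical scaling."""
    with open(path, "rb") as f:
        hdr = f.read(256)
        n_rec = int(hdr[236:244].decode().strip())
        rec_dur = float(hdr[244:252].decode().strip())
        ns = int(hdr[252:256].decode().strip())
        sig = f.read(ns * 256)
        # field layout (per signal): label16 transducer80 dim8 physmin8 physmax8
        # digmin8 digmax8 prefilter80 nsamp8 reserved32
        off = 0
        def take(width):
            nonlocal off
            vals = [sig[off + i * width: off + (i + 1) * width]
                    .decode("ascii", "replace").strip() for i in range(ns)]
            off += ns * width
            return vals
        labels = take(16)
        take(80)            # transducer
        units = take(8)
        pmin = [float(v) for v in take(8)]
        pmax = [float(v) for v in take(8)]
        dmin = [float(v) for v in take(8)]
        dmax = [float(v) for v in take(8)]
        take(80)            # prefilter
        nsamp = [int(v) for v in take(8)]
        raw = np.frombuffer(f.read(), dtype="<i2")

    if len(set(nsamp)) != 1:
        raise ValueError("EDF with per-signal sampling rates is not supported")
    spr = nsamp[0]
    srate = spr / rec_dur
    total = n_rec * spr
    data = np.empty((ns, total))
    raw = raw[: n_rec * ns * spr].reshape(n_rec, ns, spr)
    for i in range(ns):
        gain = (pmax[i] - pmin[i]) / (dmax[i] - dmin[i])
        data[i] = (raw[:, i, :].reshape(-1) - dmin[i]) * gain + pmin[i]
        if units[i].lower() in ("mv",):
            data[i] *= 1e3
        elif units[i].lower() in ("v",):
            data[i] *= 1e6
    return RawRecording(data=data, srate=srate, channel_names=labels,
                        channel_types=["EEG"] * ns)


def _write_edf(rec: RawRecording, path) -> Path:
    """Minimal EDF writer (one data-record per second), for fixtures/tests."""
    path = Path(path)
    spr = int(round(rec.srate))
    n_rec = rec.n_samples // spr
    data = rec.data[:, : n_rec * spr]
    ns = rec.n_channels
    pmin, pmax = data.min(axis=1), data.max(axis=1)
    span = np.where(pmax - pmin < 1e-9, 1.0, pmax - pmin)
    with open(path, "wb") as f:
        h = bytearray()
        def put(s, w):
            b = str(s).encode("ascii")[:w]
            h.extend(b + b" " * (w - len(b)))
        put("0", 8); put("X", 80); put("X", 80)
        put("01.01.00", 8); put("00.00.00", 8)
        put(256 * (1 + ns), 8); put("", 44); put(n_rec, 8); put("1", 8); put(ns, 4)
        f.write(bytes(h))
        sh = bytearray()
        def puts(vals, w):
            for v in vals:
                b = str(v).encode("ascii")[:w]
                sh.extend(b + b" " * (w - len(b)))
        puts(rec.channel_names, 16)
        puts([""] * ns, 80)
        puts(["uV"] * ns, 8)
        puts([f"{v:.3f}"[:8] for v in pmin], 8)
        puts([f"{v:.3f}"[:8] for v in pmax], 8)
        puts([-32768] * ns, 8)
        puts([32767] * ns, 8)
        puts([""] * ns, 80)
        puts([spr] * ns, 8)
        puts([""] * ns, 32)
        f.write(bytes(sh))
        pminf = np.array([float(f"{v:.3f}"[:8]) for v in pmin])
        pmaxf = np.array([float(f"{v:.3f}"[:8]) for v in pmax])
        spanf = np.where(pmaxf - pminf < 1e-9, 1.0, pmaxf - pminf)
        dig = ((data - pminf[:, None]) / spanf[:, None] * 65535 - 32768)
        dig = np.clip(np.round(dig), -32768, 32767).astype("<i2")
        for r in range(n_rec):
            f.write(dig[:, r * spr:(r + 1) * spr].tobytes())
    return path


# ---------------------------------------------------------------------------
# BIDS
# ---------------------------------------------------------------------------

def _find_one(d: Path, pattern: str, required: bool = True) -> Path | None:
    hits = sorted(d.glob(pattern))
    if not hits:
        if required:
            raise FileNotFoundError(f"required BIDS file matching '{pattern}' "
                                    f"not found in {d}")
        return None
    return hits[0]


def read_raw_bids(dataset_root, subject_label: str,
                  task: str | None = None) -> RawRecording:
    """Load one subject's EEG from a BIDS-style tree.

    Sidecars populate line frequency, reference and channel metadata. By
    default only channels with standard 10-5 positions are retained, unless
    electrodes.tsv supplies coordinates for them. EOG/ECG/EMG channels are
    kept as auxiliaries (position may be absent).
    """
    root = Path(dataset_root)
    eeg_dir = root / f"sub-{subject_label}" / "eeg"
    if not eeg_dir.is_dir():
        raise FileNotFoundError(f"no eeg directory for sub-{subject_label} "
                                f"under {root}")
    taskpat = f"task-{task}" if task else "*"
    vhdr = sorted(eeg_dir.glob(f"sub-{subject_label}_{taskpat}_eeg.vhdr"))
    edf = sorted(eeg_dir.glob(f"sub-{subject_label}_{taskpat}_eeg.edf"))
    other = [p for p in eeg_dir.glob(f"sub-{subject_label}_{taskpat}_eeg.*")
             if p.suffix not in (".vhdr", ".vmrk", ".eeg", ".edf", ".json")]
    if vhdr:
        rec = read_brainvision(vhdr[0])
        stem = vhdr[0].name[:-len("_eeg.vhdr")]
    elif edf:
        rec = read_edf(edf[0])
        stem = edf[0].name[:-len("_eeg.edf")]
    elif other:
        raise ValueError(f"unsupported EEG data format '{other[0].suffix}'; "
                         "only BrainVision (.vhdr) and EDF are supported")
    else:
        raise FileNotFoundError(f"no BrainVision or EDF recording for "
                                f"sub-{subject_label}")

    sidecar = _find_one(eeg_dir, f"{stem}_eeg.json")
    meta = json.loads(sidecar.read_text())
    rec.line_freq = meta.get("PowerLineFrequency")
    rec.reference = meta.get("EEGReference", "n/a")

    chans_path = _find_one(eeg_dir, f"{stem}_channels.tsv", required=False) \
        or _find_one(eeg_dir, f"sub-{subject_label}_channels.tsv")
    chans = pd.read_csv(chans_path, sep="\t")
    if len(chans) != rec.n_channels:
        raise ValueError(
            f"channels.tsv lists {len(chans)} channels but the data file has "
            f"{rec.n_channels}")
    order = {n: i for i, n in enumerate(rec.channel_names)}
    chans = chans.sort_values("name", key=lambda s: s.map(order)).reset_index(drop=True)
    rec.channel_types = [str(t).upper() for t in chans["type"]]

    elec_path = _find_one(eeg_dir, f"sub-{subject_label}*_electrodes.tsv",
                          required=False)
    coords: dict[str, np.ndarray] = {}
    if elec_path is not None:
        elec = pd.read_csv(elec_path, sep="\t")
        scale = 1.0
        cs_path = _find_one(eeg_dir, f"sub-{subject_label}*_coordsystem.json",
                            required=False)
        flip_als = False
        if cs_path is not None:
            cs = json.loads(cs_path.read_text())
            unit = str(cs.get("EEGCoordinateUnits", "m")).lower()
            scale = {"m": 1.0, "cm": 1e-2, "mm": 1e-3}.get(unit, 1.0)
            system = str(cs.get("EEGCoordinateSystem", "RAS")).upper()
            if system in ("CTF", "ALS"):
                flip_als = True
            elif system not in ("RAS", "CAPTRAK", "OTHER", "HEAD"):
                raise ValueError(f"unsupported electrode coordinate system "
                                 f"'{system}'")
        for _, row in elec.iterrows():
            p = np.array([row["x"], row["y"], row["z"]], float) * scale
            if flip_als:                     # ALS (x anterior, y left) -> RAS
                p = np.array([-p[1], p[0], p[2]])
            coords[str(row["name"])] = p

    std = standard_positions()
    keep, positions = [], []
    for i, (name, ctype) in enumerate(zip(rec.channel_names, rec.channel_types)):
        if ctype != "EEG":
            keep.append(i)
            positions.append(coords.get(name, np.full(3, np.nan)))
        elif name in coords:
            keep.append(i)
            positions.append(coords[name])
        elif name in std:
            keep.append(i)
            positions.append(std[name])
        # else: EEG channel without any known position -> dropped
    rec = rec.pick(keep)
    rec.positions = np.asarray(positions)
    bad = [rec.channel_names[i] for i, s in enumerate(
        chans["status"].iloc[keep] if "status" in chans else [])
        if str(s).lower() == "bad"]
    if bad:
        rec.events.append((0, "bads:" + ",".join(bad)))
    return rec


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------

def resample(rec: RawRecording, target_hz: float) -> RawRecording:
    """Polyphase resampling with anti-alias filtering; events/boundaries are
    remapped proportionally. Target must be below the native rate."""
    if target_hz >= rec.srate:
        raise ValueError(f"target rate {target_hz} Hz must be below the "
                         f"native rate {rec.srate} Hz")
    frac = Fraction(target_hz / rec.srate).limit_denominator(10000)
    up, down = frac.numerator, frac.denominator
    data = signal.resample_poly(rec.data, up, down, axis=1)
    ratio = target_hz / rec.srate
    n_out = data.shape[1]
    out = replace(
        rec, data=data, srate=target_hz,
        events=[(min(int(round(s * ratio)), n_out - 1), lab)
                for s, lab in rec.events],
        boundaries=sorted({min(int(round(b * ratio)), n_out)
                           for b in rec.boundaries}))
    return out


# ---------------------------------------------------------------------------
# feature writers
# ---------------------------------------------------------------------------

def write_feature_bundle(bundle: FeatureBundle, out_dir) -> list[Path]:
    """One file per feature, following the published naming scheme with HDF5
    containers for arrays and TSV/JSON for scalars. The resolved parameters
    are always written beside the features."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sub = f"sub-{bundle.subject}"
    written: list[Path] = []

    p = out_dir / f"{sub}_power.h5"
    with h5py.File(p, "w") as f:
        f["frequencies"] = bundle.power["frequencies"]
        f["power"] = bundle.power["power"]
        f["global_power"] = bundle.power["global_power"]
        f.attrs["n_epochs"] = bundle.power.get("n_epochs", 0)
    written.append(p)

    p = out_dir / f"{sub}_peakfrequency.tsv"
    peak = bundle.apf.get("peak_maximum_hz")
    cog = bundle.apf.get("cog_hz")
    pd.DataFrame([{
        "peak_maximum_hz": "n/a" if peak is None else f"{peak:.4f}",
        "cog_hz": "n/a" if cog is None else f"{cog:.4f}",
    }]).to_csv(p, sep="\t", index=False)
    written.append(p)

    if bundle.source_power:
        p = out_dir / f"{sub}_sourcepower.h5"
        with h5py.File(p, "w") as f:
            for band, vals in bundle.source_power.items():
                f[band] = np.asarray(vals)
            f.attrs["roi_names"] = json.dumps(bundle.roi_names)
        written.append(p)

    for (measure, band), mat in bundle.connectivity.items():
        p = out_dir / f"{sub}_{measure}_{band}.h5"
        with h5py.File(p, "w") as f:
            f["connectivity"] = np.asarray(mat)
            f.attrs["measure"] = measure
            f.attrs["band"] = band
            f.attrs["roi_names"] = json.dumps(bundle.roi_names)
        written.append(p)

    rows = []
    for (measure, band), gm in bundle.graph.items():
        p = out_dir / f"{sub}_graph_{measure}_{band}.h5"
        with h5py.File(p, "w") as f:
            f["degree"] = np.asarray(gm["degree"])
            f["clustering"] = np.asarray(gm["clustering"])
            f.attrs["global_clustering"] = gm["global_clustering"]
            f.attrs["global_efficiency"] = gm["global_efficiency"]
            f.attrs["smallworldness"] = gm["smallworldness"]
            f.attrs["n_null"] = gm.get("n_null", 0)
            f.attrs["null_seed"] = gm.get("null_seed", 0)
        written.append(p)
        rows.append({"measure": measure, "band": band,
                     "global_clustering": gm["global_clustering"],
                     "global_efficiency": gm["global_efficiency"],
                     "smallworldness": gm["smallworldness"]})
    if rows:
        p = out_dir / f"{sub}_graph_global.tsv"
        pd.DataFrame(rows).to_csv(p, sep="\t", index=False)
        written.append(p)

    p = out_dir / f"{sub}_params.json"
    payload = dict(bundle.params.model_dump())
    payload["_provenance"] = bundle.provenance
    p.write_text(json.dumps(payload, indent=2, default=str))
    written.append(p)
    return written


def read_feature_matrix(path) -> np.ndarray:
    with h5py.File(path, "r") as f:
        return f["connectivity"][()]
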