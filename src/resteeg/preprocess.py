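"""The seven-stage automated preprocessing chain.

Stages: (1) adaptive line-noise regression, (2) high-pass filtering and
bad-channel rejection by three criteria (flat / noisy / unpredictable),
(3) average re-referencing, (4) ICA with heuristic 7-class IC labelling and
rejection of confident Muscle/Eye components, (5) spherical-spline
interpolation of removed channels, (6) ASR-style bad-segment removal, and
(7) segmentation into overlapping epochs. Stages 4-6 are repeated
``n_ica_repetitions`` times and the repetition whose bad-segment mask is
closest (L1) to the mean mask is kept, which stabilizes the otherwise
rotation-dependent ICA outcome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal, stats
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from . import filters
from .model_io import ParamSet, RawRecording
from .sphere import spline_interp_weights

IC_CLASSES = ("Brain", "Muscle", "Eye", "Heart", "Line Noise",
              "Channel Noise", "Other")

FLAT_EPS_UV = 1e-8


# ---------------------------------------------------------------------------
# types
# ---------------------------------------------------------------------------

@dataclass
class BadChannelReport:
    channel_names: list[str]               # EEG channels, original order
    positions: np.ndarray | None           # matching positions
    flags: dict                            # criterion -> list of names
    removed: list[str]

    @classmethod
    def empty(cls) -> "BadChannelReport":
        return cls([], None, {"flat": [], "noisy": [], "unpredictable": []}, [])


@dataclass
class ICDecomposition:
    unmixing: np.ndarray                   # (k, n_ch)
    mixing: np.ndarray                     # (n_ch, k)
    sources: np.ndarray                    # (k, n_samples)
    mean: np.ndarray                       # (n_ch,)
    seed: int
    channel_names: list[str]
    converged: bool = True
    n_iter: int = 0


@dataclass
class ICClassification:
    probabilities: np.ndarray              # (k, 7), rows sum to 1
    classes: tuple = IC_CLASSES

    def prob(self, label: str) -> np.ndarray:
        return self.probabilities[:, self.classes.index(label)]


@dataclass
class SegmentMask:
    mask: np.ndarray                       # bool per sample, True = bad

    @property
    def intervals(self) -> list[tuple[int, int]]:
        m = np.asarray(self.mask, bool)
        if m.size == 0:
            return []
        d = np.diff(m.astype(int))
        starts = list(np.where(d == 1)[0] + 1)
        ends = list(np.where(d == -1)[0] + 1)
        if m[0]:
            starts = [0] + starts
        if m[-1]:
            ends = ends + [len(m)]
        return list(zip(starts, ends))

    @property
    def fraction(self) -> float:
        return float(np.mean(self.mask))


@dataclass
class EpochSet:
    data: np.ndarray                       # (n_epochs, n_channels, n_samples)
    srate: float
    epoch_len_s: float
    overlap: float
    starts: np.ndarray                     # start sample in the cleaned series
    channel_names: list[str] = field(default_factory=list)

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]


# ---------------------------------------------------------------------------
# 1. line noise
# ---------------------------------------------------------------------------

def remove_line_noise(rec: RawRecording, window_s: float = 2.0,
                      f_crit_p: float = 1e-4) -> RawRecording:
    """Regress out the line-frequency sinusoid (and harmonics below Nyquist)
    in sliding Hann windows with overlap-add.

    Amplitude and phase adapt per window, so no spectral notch is carved into
    broadband activity; a per-window, per-channel, per-harmonic F-test gates
    the subtraction so that noise-level energy at the line frequency is left
    untouched (signals without a line component pass through unchanged).
    """
    if rec.line_freq is None:
        raise ValueError("line_freq is not set; specify PowerLineFrequency in "
                         "the recording sidecar")
    rec = rec.copy()
    n = rec.n_samples
    sr = rec.srate
    win = int(round(window_s * sr))
    win = min(win if win % 2 == 0 else win + 1, n)
    hop = win // 2
    freqs = [h * rec.line_freq for h in range(1, 8)
             if h * rec.line_freq < 0.95 * sr / 2]
    if not freqs:
        return rec
    w = np.hanning(win)
    fitted = np.zeros_like(rec.data)
    norm = np.zeros(n)
    t_all = np.arange(n) / sr
    starts = list(range(0, max(n - win, 0) + 1, hop))
    if not starts:
        starts = [0]
    n_par = 2 * len(freqs)
    for s in starts:
        sl = slice(s, s + win)
        t = t_all[sl]
        nt = len(t)
        basis = np.empty((n_par, nt))
        for i, f in enumerate(freqs):
            basis[2 * i] = np.sin(2 * np.pi * f * t)
            basis[2 * i + 1] = np.cos(2 * np.pi * f * t)
        seg = rec.data[:, sl]
        coef, *_ = np.linalg.lstsq(basis.T, seg.T, rcond=None)  # (n_par, ch)
        coef = coef.T                                           # (ch, n_par)
        resid = seg - coef @ basis
        ss_resid = np.sum(resid ** 2, axis=1) + 1e-30
        df_resid = nt - n_par
        f_crit = stats.f.ppf(1 - f_crit_p, 2, df_resid)
        for i in range(len(freqs)):
            pair = coef[:, 2 * i:2 * i + 2]
            ss_harm = 0.5 * nt * np.sum(pair ** 2, axis=1)
            f_stat = (ss_harm / 2) / (ss_resid / df_resid)
            pair[f_stat < f_crit] = 0.0
        fitted[:, sl] += (coef @ basis) * w[:nt]
        norm[sl] += w[:nt]
    good = norm > 1e-6
    fitted[:, good] /= norm[good]
    rec.data = rec.data - fitted
    return rec


# ---------------------------------------------------------------------------
# 2. high pass + bad channels
# ---------------------------------------------------------------------------

def highpass(rec: RawRecording, params: ParamSet | None = None) -> RawRecording:
    params = params or ParamSet()
    rec = rec.copy()
    lo, hi = params.hp_transition_band
    rec.data = filters.highpass(rec.data, rec.srate, lo, hi)
    return rec


def _flat_runs(x: np.ndarray, max_run: int) -> bool:
    flat = np.abs(np.diff(x)) < FLAT_EPS_UV
    if not flat.any():
        return False
    # longest run of True
    d = np.diff(np.concatenate([[0], flat.astype(int), [0]]))
    starts = np.where(d == 1)[0]
    ends = np.where(d == -1)[0]
    return bool(np.max(ends - starts) > max_run)


def detect_bad_channels(rec: RawRecording, params: ParamSet | None = None,
                        rng: np.random.Generator | None = None,
                        raw: RawRecording | None = None) -> BadChannelReport:
    """Flag EEG channels that are flat, have extreme noise-to-signal ratio, or
    cannot be predicted from their neighbours.

    * flat: successive differences below 1e-8 µV for a contiguous run longer
      than ``flat_max_s``
    * noisy: noise-to-signal ratio std(>40 Hz)/std(<40 Hz), robust z-score
      (median / 1.4826 MAD) across channels above ``noise_z_thresh``
    * unpredictable: in 5-s windows, the channel's best spherical-spline
      prediction from 50 random subsets of 25 % of the other channels
      correlates >= 0.8 in fewer than ``predictability_frac`` of windows

    Flatness is evaluated on ``raw`` (the unfiltered recording) when given:
    any FIR stage smears neighbouring activity into a flat span, so exact
    flatness only survives on the signal as recorded.
    """
    params = params or ParamSet()
    rng = rng or np.random.default_rng(params.seed)
    eeg = rec.eeg_picks()
    names = [rec.channel_names[i] for i in eeg]
    x = rec.data[eeg]
    sr = rec.srate
    flags = {"flat": [], "noisy": [], "unpredictable": []}

    max_run = int(params.flat_max_s * sr)
    x_flat = raw.data[raw.eeg_picks()] if raw is not None else x
    for i, name in enumerate(names):
        if _flat_runs(x_flat[i], max_run):
            flags["flat"].append(name)

    low = filters.lowpass(x, sr, 40.0, transition_hz=5.0)
    nsr = np.std(x - low, axis=1) / (np.std(low, axis=1) + 1e-30)
    med = np.median(nsr)
    mad = stats.median_abs_deviation(nsr)
    z = (nsr - med) / (1.4826 * mad + 1e-30)
    for i, name in enumerate(names):
        if z[i] > params.noise_z_thresh:
            flags["noisy"].append(name)

    positions = rec.positions[eeg] if rec.positions is not None else None
    if positions is not None and np.all(np.isfinite(positions)):
        win = int(5 * sr)
        n_win = x.shape[1] // win
        n_sub = 50
        k = max(2, int(round(0.25 * (len(eeg) - 1))))
        if n_win >= 1 and len(eeg) > k:
            xw = x[:, : n_win * win].reshape(len(eeg), n_win, win)
            xw = xw - xw.mean(axis=-1, keepdims=True)
            denom = np.sqrt(np.sum(xw ** 2, axis=-1)) + 1e-30
            for i, name in enumerate(names):
                others = np.delete(np.arange(len(eeg)), i)
                best = np.full(n_win, -1.0)
                for _ in range(n_sub):
                    sub = rng.choice(others, size=k, replace=False)
                    w = spline_interp_weights(positions[sub],
                                              positions[i][None, :])[0]
                    pred = np.tensordot(w, xw[sub], axes=(0, 0))
                    pred = pred - pred.mean(axis=-1, keepdims=True)
                    pd_ = np.sqrt(np.sum(pred ** 2, axis=-1)) + 1e-30
                    r = np.sum(pred * xw[i], axis=-1) / (pd_ * denom[i])
                    best = np.maximum(best, r)
                if np.mean(best >= 0.8) < params.predictability_frac:
                    flags["unpredictable"].append(name)

    removed = sorted(set(flags["flat"]) | set(flags["noisy"])
                     | set(flags["unpredictable"]),
                     key=names.index)
    if len(names) - len(removed) < 8:
        raise ValueError(
            f"only {len(names) - len(removed)} good channels remain; "
            "bad-channel detection requires at least 8")
    return BadChannelReport(channel_names=names, positions=positions,
                            flags=flags, removed=removed)


def drop_bad_channels(rec: RawRecording, report: BadChannelReport
                      ) -> RawRecording:
    keep = [i for i, n in enumerate(rec.channel_names)
            if n not in report.removed]
    return rec.pick(keep)


# ---------------------------------------------------------------------------
# 3. re-referencing
# ---------------------------------------------------------------------------

def rereference_average(rec: RawRecording,
                        add_back_ref: bool = False) -> RawRecording:
    eeg = rec.eeg_picks()
    if len(eeg) < 2:
        raise ValueError("average reference needs at least 2 EEG channels")
    rec = rec.copy()
    mean = rec.data[eeg].mean(axis=0)
    rec.data[eeg] -= mean
    if add_back_ref and rec.reference not in ("average", "n/a", None):
        rec.data = np.vstack([rec.data, -mean])
        rec.channel_names = rec.channel_names + [rec.reference]
        rec.channel_types = rec.channel_types + ["EEG"]
        if rec.positions is not None:
            from .sphere import standard_positions
            std = standard_positions()
            p = std.get(rec.reference, np.full(3, np.nan))
            rec.positions = np.vstack([rec.positions, p])
        rec.data[rec.eeg_picks()] -= rec.data[rec.eeg_picks()].mean(axis=0)
    rec.reference = "average"
    return rec


# ---------------------------------------------------------------------------
# 4. ICA
# ---------------------------------------------------------------------------

def _rank(x: np.ndarray) -> int:
    s = np.linalg.svd(x - x.mean(axis=1, keepdims=True), compute_uv=False)
    tol = s.max() * max(x.shape) * np.finfo(float).eps * 100
    return int(np.sum(s > tol))


def fit_ica(rec: RawRecording, seed: int, max_iter: int = 200,
            tol: float = 1e-3, strict: bool = False) -> ICDecomposition:
    """FastICA on the EEG channels; component count equals the data rank
    (channel count minus one after average referencing). Reproducible for a
    fixed seed.

    Formal convergence of the parallel FastICA update routinely fails on
    rank-deficient EEG because the near-Gaussian background subspace has no
    identifiable rotation, while the non-Gaussian (artifact) components are
    recovered stably long before; by default the outcome is therefore kept
    with ``converged=False`` recorded, and ``strict=True`` raises instead.
    """
    eeg = rec.eeg_picks()
    x = rec.data[eeg]
    k = min(_rank(x), len(eeg))
    ica = FastICA(n_components=k, random_state=int(seed), max_iter=max_iter,
                  tol=tol, whiten="unit-variance")
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        S = ica.fit_transform(x.T)
    converged = not any(issubclass(w.category, ConvergenceWarning)
                        for w in caught)
    if strict and not converged:
        raise RuntimeError(
            f"ICA did not converge in {max_iter} iterations (tol={tol}, "
            f"seed={seed}, n_iter={ica.n_iter_})")
    return ICDecomposition(unmixing=ica.components_, mixing=ica.mixing_,
                           sources=S.T, mean=ica.mean_, seed=int(seed),
                           channel_names=[rec.channel_names[i] for i in eeg],
                           converged=converged, n_iter=int(ica.n_iter_))


def _ramp(v: float, lo: float, hi: float) -> float:
    return float(np.clip((v - lo) / (hi - lo), 0.0, 1.0))


def classify_ics(decomp: ICDecomposition, rec: RawRecording) -> ICClassification:
    """Heuristic 7-class IC scorer (stands behind the same interface as a
    trained classifier; scores are normalized to a probability vector).

    Evidence used per class: EOG correlation and frontal low-frequency
    dominance (Eye); positive 20-45 Hz log-spectral slope with high-frequency
    dominance (Muscle); line-frequency bin dominance (Line Noise); kurtosis of
    the channel loadings (Channel Noise); ~1 Hz periodic autocorrelation
    (Heart); 1/f-like spectrum with a 3-30 Hz peak (Brain); constant residual
    mass (Other).
    """
    sr = rec.srate
    eog = [i for i, t in enumerate(rec.channel_types) if t.upper() in
           ("EOG", "VEOG", "HEOG")]
    k = decomp.sources.shape[0]
    nper = int(min(4 * sr, decomp.sources.shape[1]))
    f, psd = signal.welch(decomp.sources, fs=sr, nperseg=nper, axis=-1)
    probs = np.zeros((k, len(IC_CLASSES)))

    eeg = rec.eeg_picks()
    pos = rec.positions[eeg] if rec.positions is not None else None
    for i in range(k):
        s = decomp.sources[i]
        a = decomp.mixing[:, i]
        p = psd[i]
        total = np.trapezoid(p, f) + 1e-30

        eog_r = 0.0
        for ch in eog:
            y = rec.data[ch]
            denom = np.std(s) * np.std(y) + 1e-30
            eog_r = max(eog_r, abs(np.mean((s - s.mean()) * (y - y.mean()))
                                   / denom))
        low_frac = np.trapezoid(p[f < 3], f[f < 3]) / total
        if pos is not None and np.all(np.isfinite(pos)):
            w = np.abs(a)
            frontal = float(np.sum(w[pos[:, 1] > 0.03]) / (np.sum(w) + 1e-30))
        else:
            frontal = 0.5
        sel = (f >= 20) & (f <= 45)
        slope = np.polyfit(f[sel], np.log10(p[sel] + 1e-30), 1)[0] \
            if sel.sum() > 3 else -1.0
        hf_frac = np.trapezoid(p[sel], f[sel]) / total
        line_frac = 0.0
        if rec.line_freq:
            lsel = np.abs(f - rec.line_freq) <= 1.0
            line_frac = np.trapezoid(p[lsel], f[lsel]) / total if lsel.any() else 0
        load_kurt = stats.kurtosis(a / (np.std(a) + 1e-30), fisher=False)
        # periodic ~1 Hz autocorrelation (heart)
        ac = signal.correlate(s - s.mean(), s - s.mean(), mode="full")
        ac = ac[len(ac) // 2:]
        ac /= ac[0] + 1e-30
        lag_lo, lag_hi = int(0.6 * sr), int(min(1.4 * sr, len(ac) - 1))
        heart_ac = float(np.max(ac[lag_lo:lag_hi])) if lag_hi > lag_lo else 0.0
        # band peak on a 1/f-corrected spectrum (brain); transient/eye
        # components are low-frequency dominated, so a genuine band peak is
        # only counted when the spectrum is not concentrated below 3 Hz
        bsel = (f >= 6) & (f <= 30)
        brain_peak = 0.0
        if bsel.sum() > 5:
            logf = np.log10(f[bsel] + 1e-30)
            logp = np.log10(p[bsel] + 1e-30)
            coef = np.polyfit(logf, logp, 1)
            resid = logp - np.polyval(coef, logf)
            brain_peak = float(np.max(resid))

        scores = {
            "Eye": max(_ramp(eog_r, 0.5, 0.85),
                       _ramp(low_frac, 0.4, 0.7) * _ramp(frontal, 0.5, 0.8)),
            "Muscle": _ramp(slope, 0.0, 0.01) * _ramp(hf_frac, 0.3, 0.6),
            "Line Noise": _ramp(line_frac, 0.3, 0.7),
            "Channel Noise": _ramp(load_kurt, 8.0, 18.0),
            "Heart": _ramp(heart_ac, 0.5, 0.8) * _ramp(low_frac, 0.2, 0.5),
            "Brain": (_ramp(brain_peak, 0.15, 0.5)
                      * (1 - _ramp(slope, 0, 0.01))
                      * (1 - _ramp(low_frac, 0.4, 0.7))),
            "Other": 0.15,
        }
        v = np.array([scores[c] for c in IC_CLASSES])
        probs[i] = v / v.sum()
    return ICClassification(probabilities=probs)


def reject_ics(rec: RawRecording, decomp: ICDecomposition,
               cls: ICClassification, params: ParamSet | None = None
               ) -> tuple[RawRecording, list[int]]:
    """Subtract ICs whose probability of any reject class exceeds the
    threshold (default: Muscle or Eye above 0.8)."""
    params = params or ParamSet()
    bad = set()
    for label in params.ic_reject_classes:
        bad |= set(np.where(cls.prob(label) > params.ic_reject_prob)[0])
    removed = sorted(bad)
    rec = rec.copy()
    if removed:
        eeg = rec.eeg_picks()
        contrib = decomp.mixing[:, removed] @ decomp.sources[removed]
        rec.data[eeg] = rec.data[eeg] - contrib
    return rec, removed


# ---------------------------------------------------------------------------
# 5. interpolation
# ---------------------------------------------------------------------------

def interpolate_channels(rec: RawRecording, report: BadChannelReport
                         ) -> RawRecording:
    """Reconstruct the channels removed in stage 2 by spherical-spline
    interpolation, restoring the original channel count and order."""
    if not report.removed:
        return rec.copy()
    if report.positions is None or not np.all(np.isfinite(report.positions)):
        raise ValueError("positions are required to interpolate channels")
    name_to_pos = {n: report.positions[i]
                   for i, n in enumerate(report.channel_names)}
    present = [n for n in report.channel_names if n not in report.removed]
    src_idx = [rec.channel_names.index(n) for n in present]
    src_pos = np.array([name_to_pos[n] for n in present])
    dst_pos = np.array([name_to_pos[n] for n in report.removed])
    W = spline_interp_weights(src_pos, dst_pos)
    interp = W @ rec.data[src_idx]

    # rebuild in the original EEG order, keeping non-EEG channels at the end
    out_names, out_types, out_rows, out_pos = [], [], [], []
    for i, n in enumerate(report.channel_names):
        if n in report.removed:
            out_rows.append(interp[report.removed.index(n)])
        else:
            out_rows.append(rec.data[rec.channel_names.index(n)])
        out_names.append(n)
        out_types.append("EEG")
        out_pos.append(name_to_pos[n])
    for i, n in enumerate(rec.channel_names):
        if rec.channel_types[i].upper() != "EEG":
            out_names.append(n)
            out_types.append(rec.channel_types[i])
            out_rows.append(rec.data[i])
            out_pos.append(rec.positions[i] if rec.positions is not None
                           else np.full(3, np.nan))
    return replace(rec, data=np.asarray(out_rows), channel_names=out_names,
                   channel_types=out_types, positions=np.asarray(out_pos))


# ---------------------------------------------------------------------------
# 6. ASR-style bad segments
# ---------------------------------------------------------------------------

@dataclass
class ASRCalibration:
    axes: np.ndarray                       # (n_ch, n_valid) principal axes
    variances: np.ndarray                  # per-axis variance of calib data
    kept_fraction: float
    window_spans: list = field(default_factory=list)   # (start, end) per window
    window_kept: np.ndarray | None = None              # bool per window


def _sliding_windows(n: int, win: int, hop: int) -> list[tuple[int, int]]:
    out = []
    s = 0
    while s + win <= n:
        out.append((s, s + win))
        s += hop
    if not out or out[-1][1] < n:
        out.append((max(0, n - win), n))
    return out


def asr_calibrate(rec: RawRecording, params: ParamSet | None = None
                  ) -> ASRCalibration:
    """Identify clean calibration data and fit its principal subspace.

    Per-channel RMS in sliding 1-s windows is robust z-scored across windows;
    a window enters the calibration set iff the fraction of channels with
    z above ``asr_rms_z`` (5.5) is below ``asr_calib_noisy_frac`` (7.5 %).
    """
    params = params or ParamSet()
    eeg = rec.eeg_picks()
    x = rec.data[eeg]
    sr = rec.srate
    win, hop = int(sr), int(sr // 2)
    spans = _sliding_windows(x.shape[1], win, hop)
    rms = np.stack([np.sqrt(np.mean(x[:, a:b] ** 2, axis=1))
                    for a, b in spans], axis=1)    # (n_ch, n_win)
    med = np.median(rms, axis=1, keepdims=True)
    mad = stats.median_abs_deviation(rms, axis=1)[:, None]
    z = (rms - med) / (1.4826 * mad + 1e-30)
    noisy_frac = np.mean(z > params.asr_rms_z, axis=0)
    keep = noisy_frac < params.asr_calib_noisy_frac
    kept_samples = np.zeros(x.shape[1], bool)
    for (a, b), k in zip(spans, keep):
        if k:
            kept_samples[a:b] = True
    if kept_samples.sum() < 5 * sr:
        raise ValueError("fewer than 5 s of clean calibration data; record a "
                         "longer or cleaner session")
    calib = x[:, kept_samples]
    calib = calib - calib.mean(axis=1, keepdims=True)
    cov = calib @ calib.T / (calib.shape[1] - 1)
    evals, evecs = np.linalg.eigh(cov)
    # drop the null subspace (average reference / interpolated channels make
    # the data rank deficient; deviations along zero-variance axes are
    # numerical noise, not artifacts)
    valid = evals > 1e-7 * evals.max()
    return ASRCalibration(axes=evecs[:, valid], variances=evals[valid],
                          kept_fraction=float(np.mean(keep)),
                          window_spans=spans, window_kept=keep)


def asr_flag_segments(rec: RawRecording, calib: ASRCalibration,
                      params: ParamSet | None = None) -> SegmentMask:
    """Flag sliding 0.5-s windows whose variance along any calibration axis
    exceeds ``asr_cutoff`` (20) times the calibration variance on that axis."""
    params = params or ParamSet()
    eeg = rec.eeg_picks()
    x = rec.data[eeg]
    sr = rec.srate
    win, hop = int(sr // 2), int(sr // 4)
    mask = np.zeros(x.shape[1], bool)
    for a, b in _sliding_windows(x.shape[1], win, hop):
        seg = x[:, a:b]
        seg = seg - seg.mean(axis=1, keepdims=True)
        proj = calib.axes.T @ seg
        v = np.mean(proj ** 2, axis=1)
        if np.any(v > params.asr_cutoff * calib.variances):
            mask[a:b] = True
    return SegmentMask(mask=mask)


# ---------------------------------------------------------------------------
# stages 4-6 with stabilization
# ---------------------------------------------------------------------------

def excise_bad_segments(rec: RawRecording, mask: SegmentMask) -> RawRecording:
    """Remove flagged samples; insert a boundary at every cut."""
    m = np.asarray(mask.mask, bool)
    if not m.any():
        return rec.copy()
    keep = ~m
    rec2 = rec.copy()
    rec2.data = rec.data[:, keep]
    cum_bad = np.cumsum(m)
    new_boundaries = set()
    for a, b in mask.intervals:
        new_idx = a - (cum_bad[a - 1] if a > 0 else 0)
        if 0 < new_idx < rec2.data.shape[1]:
            new_boundaries.add(int(new_idx))
    for bnd in rec.boundaries:
        if bnd <= 0 or bnd >= len(m):
            continue
        if m[bnd - 1] or (bnd < len(m) and m[bnd]):
            pass  # absorbed into a cut boundary
        nb = bnd - cum_bad[bnd - 1]
        if 0 < nb < rec2.data.shape[1]:
            new_boundaries.add(int(nb))
    rec2.boundaries = sorted(new_boundaries)
    rec2.events = [(s - (cum_bad[s - 1] if s > 0 else 0), lab)
                   for s, lab in rec.events if not m[min(s, len(m) - 1)]]
    return rec2


def stabilize_and_clean(rec: RawRecording, params: ParamSet | None = None,
                        report: BadChannelReport | None = None
                        ) -> tuple[RawRecording, SegmentMask, dict]:
    """Run stages 4 (ICA+rejection), 5 (interpolation), 6 (ASR) for
    ``n_ica_repetitions`` repetitions with seeds base+r, and keep the
    repetition whose bad-sample mask has minimum L1 distance to the
    per-sample mean mask (ties: lowest repetition index). Returns the
    selected repetition's cleaned continuous data with bad segments excised
    and boundaries at the cuts."""
    params = params or ParamSet()
    report = report or BadChannelReport.empty()
    masks, cleaned, diag_reps = [], [], []
    for r in range(1, params.n_ica_repetitions + 1):
        try:
            decomp = fit_ica(rec, seed=params.seed + r)
            cls = classify_ics(decomp, rec)
            rec_r, removed = reject_ics(rec, decomp, cls, params)
            rec_i = interpolate_channels(rec_r, report)
            calib = asr_calibrate(rec_i, params)
            m = asr_flag_segments(rec_i, calib, params)
        except Exception as e:
            raise RuntimeError(f"stabilization repetition {r} failed: {e}") from e
        masks.append(m.mask.astype(float))
        cleaned.append(rec_i)
        diag_reps.append({"seed": params.seed + r, "removed_ics": removed,
                          "bad_fraction": float(m.mask.mean()),
                          "calib_kept_fraction": calib.kept_fraction})
    mean_mask = np.mean(masks, axis=0)
    dists = [float(np.abs(m - mean_mask).sum()) for m in masks]
    sel = int(np.argmin(dists))
    mask = SegmentMask(mask=masks[sel].astype(bool))
    out = excise_bad_segments(cleaned[sel], mask)
    diagnostics = {"repetitions": diag_reps, "distances": dists,
                   "selected": sel,
                   "bad_seconds": float(mask.mask.sum() / rec.srate)}
    return out, mask, diagnostics


# ---------------------------------------------------------------------------
# 7. epoching
# ---------------------------------------------------------------------------

def epoch_data(rec: RawRecording, params: ParamSet | None = None) -> EpochSet:
    """Fixed-length overlapping epochs; epochs spanning a boundary are
    dropped (half-open interval test: a boundary strictly inside
    (start, end) invalidates the epoch)."""
    params = params or ParamSet()
    L = params.epoch_len_s * rec.srate
    if abs(L - round(L)) > 1e-9:
        raise ValueError("epoch_len_s times srate must be an integer")
    L = int(round(L))
    step = int(round(L * (1 - params.epoch_overlap)))
    if step < 1:
        raise ValueError("epoch overlap too large for this epoch length")
    bounds = np.asarray(rec.boundaries)
    epochs, starts = [], []
    for s in range(0, rec.n_samples - L + 1, step):
        if bounds.size and np.any((bounds > s) & (bounds < s + L)):
            continue
        epochs.append(rec.data[:, s:s + L])
        starts.append(s)
    if not epochs:
        raise ValueError("no epochs survive; recording too short or too "
                         "fragmented")
    return EpochSet(data=np.stack(epochs), srate=rec.srate,
                    epoch_len_s=params.epoch_len_s,
                    overlap=params.epoch_overlap,
                    starts=np.asarray(starts),
                    channel_names=list(rec.channel_names))


# ---------------------------------------------------------------------------
# full chain
# ---------------------------------------------------------------------------

def run_preprocessing(rec: RawRecording, params: ParamSet | None = None
                      ) -> tuple[EpochSet, RawRecording, dict]:
    """Stages 1-7 on a loaded recording; returns epochs, the cleaned
    continuous recording and a diagnostics dict."""
    params = params or ParamSet()
    diag: dict = {}
    raw = rec
    rec = remove_line_noise(rec)
    rec = highpass(rec, params)
    report = detect_bad_channels(rec, params, raw=raw)
    diag["bad_channels"] = {"flags": report.flags, "removed": report.removed}
    rec = drop_bad_channels(rec, report)
    rec = rereference_average(rec, add_back_ref=params.add_back_ref)
    rec, mask, stab = stabilize_and_clean(rec, params, report)
    diag["stabilization"] = stab
    epochs = epoch_data(rec, params)
    diag["n_epochs"] = epochs.n_epochs
    return epochs, rec, diag
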