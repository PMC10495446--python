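"""Atlas-based LCMV beamforming onto 100 ROI centroids.

The source model is a table of ROI centroids with 7 functional-network
labels. The packaged default atlas is a SYNTHETIC stand-in (quasi-uniform
cortical-shell points; see ``data/atlas100_7networks_synthetic.tsv``) —
any user TSV with columns roi_index, roi_name, network, x, y, z (meters,
head RAS) is accepted in its place.

The forward model is the analytic three-shell sphere (``sphere`` module),
or a user-supplied lead-field HDF5 with dataset "leadfield" of shape
(n_roi, n_channels, 3) and a "channel_names" attribute.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from . import filters
from .model_io import ParamSet, RawRecording
from .sphere import ThreeShellModel

NETWORKS_7 = ("Visual", "SomatoMotor", "DorsalAttention",
              "SalienceVentralAttention", "Limbic", "Control", "Default")


@dataclass
class SourceModel:
    """ROI centroids (meters, head RAS) with network labels."""
    positions: np.ndarray          # (n_roi, 3)
    roi_names: list[str]
    networks: list[str]

    def __post_init__(self):
        self.positions = np.asarray(self.positions, float)
        if self.positions.shape != (len(self.roi_names), 3):
            raise ValueError("positions must be (n_roi, 3)")

    @property
    def n_roi(self) -> int:
        return len(self.roi_names)


@dataclass
class LeadField:
    """Per-ROI free-orientation gain matrices bound to a channel order."""
    gain: np.ndarray               # (n_roi, n_channels, 3)
    channel_names: list[str]

    def __post_init__(self):
        self.gain = np.asarray(self.gain, float)
        if not np.all(np.isfinite(self.gain)):
            raise ValueError("lead field contains non-finite values")
        if self.gain.shape[1] != len(self.channel_names):
            raise ValueError("lead-field channel dimension mismatch")


@dataclass
class SpatialFilterSet:
    """Fixed-orientation LCMV filters for one band."""
    weights: np.ndarray            # (n_roi, n_channels)
    orientations: np.ndarray       # (n_roi, 3), unit norm
    band: tuple[float, float]
    reg: float
    channel_names: list[str]


def load_atlas(atlas: str | Path = "atlas100_7networks_synthetic") -> SourceModel:
    """Load an atlas TSV (packaged name or a path to a user file)."""
    p = Path(atlas)
    if not p.exists():
        res = resources.files("resteeg").joinpath(f"data/{atlas}.tsv")
        if not res.is_file():
            raise FileNotFoundError(f"atlas '{atlas}' not found")
        with resources.as_file(res) as f:
            tbl = pd.read_csv(f, sep="\t")
    else:
        tbl = pd.read_csv(p, sep="\t")
    required = {"roi_index", "roi_name", "network", "x", "y", "z"}
    if not required.issubset(tbl.columns):
        raise ValueError(f"atlas table must have columns {sorted(required)}")
    tbl = tbl.sort_values("roi_index")
    return SourceModel(positions=tbl[["x", "y", "z"]].to_numpy(float),
                       roi_names=[str(n) for n in tbl["roi_name"]],
                       networks=[str(n) for n in tbl["network"]])


def build_spherical_leadfield(model: SourceModel, channel_names: list[str],
                              positions: np.ndarray,
                              n_terms: int = 60) -> LeadField:
    """Analytic three-shell forward solution at the ROI centroids."""
    positions = np.asarray(positions, float)
    if positions.shape != (len(channel_names), 3) or \
            not np.all(np.isfinite(positions)):
        raise ValueError("electrode positions must be finite (n_channels, 3)")
    shell = ThreeShellModel(positions, n_terms=n_terms)
    gain = np.stack([shell.gain(p) for p in model.positions])
    return LeadField(gain=gain, channel_names=list(channel_names))


def load_leadfield_h5(path) -> LeadField:
    with h5py.File(path, "r") as f:
        gain = f["leadfield"][()]
        names = [n.decode() if isinstance(n, bytes) else str(n)
                 for n in f.attrs["channel_names"]]
    return LeadField(gain=gain, channel_names=names)


def _band_epochs(epochs: np.ndarray, srate: float,
                 band: tuple[float, float]) -> np.ndarray:
    taps = filters.bandpass_taps(srate, band)
    return filters.fir_apply(epochs, taps)


def lcmv_fit(epochs: np.ndarray, srate: float, lf: LeadField,
             band: tuple[float, float], params: ParamSet | None = None,
             already_filtered: bool = False) -> SpatialFilterSet:
    """Array-gain LCMV with fixed orientation.

    Covariance is computed from band-limited epochs and ridge-regularized as
    ``C + reg * (trace(C)/n) * I``. The free-orientation filter is
    ``W3 = (L^T C^-1 L)^-1 L^T C^-1``; the dipole orientation is the dominant
    eigenvector of the source covariance ``W3 C W3^T`` (maximum variance),
    sign-fixed by making its first nonzero component positive.
    """
    params = params or ParamSet()
    x = epochs if already_filtered else _band_epochs(epochs, srate, band)
    n_ep, n_ch, n_t = x.shape
    xc = x - x.mean(axis=-1, keepdims=True)
    C = np.einsum("eit,ejt->ij", xc, xc) / (n_ep * n_t - 1)
    C = C + params.lcmv_reg * (np.trace(C) / n_ch) * np.eye(n_ch)
    try:
        Ci = np.linalg.inv(C)
    except np.linalg.LinAlgError as e:
        raise np.linalg.LinAlgError(
            "regularized covariance is singular; increase lcmv_reg") from e

    n_roi = lf.gain.shape[0]
    weights = np.empty((n_roi, n_ch))
    oris = np.empty((n_roi, 3))
    for r in range(n_roi):
        L = lf.gain[r]                                # (n_ch, 3)
        CiL = Ci @ L
        W3 = np.linalg.solve(L.T @ CiL, CiL.T)        # (3, n_ch)
        src_cov = W3 @ C @ W3.T
        evals, evecs = np.linalg.eigh(src_cov)
        ori = evecs[:, -1]
        nz = np.nonzero(np.abs(ori) > 1e-12)[0]
        if len(nz) and ori[nz[0]] < 0:
            ori = -ori
        oris[r] = ori
        w = ori @ W3
        # enforce unit gain along the chosen orientation
        g = w @ (L @ ori)
        weights[r] = w / g
    return SpatialFilterSet(weights=weights, orientations=oris, band=tuple(band),
                            reg=params.lcmv_reg, channel_names=list(lf.channel_names))


def virtual_timeseries(epochs: np.ndarray, srate: float,
                       filters_: SpatialFilterSet,
                       channel_names: list[str] | None = None,
                       already_filtered: bool = False) -> np.ndarray:
    """Project band-passed sensor epochs through the ROI filters.

    Returns (n_epochs, n_roi, n_samples).
    """
    if channel_names is not None and list(channel_names) != list(
            filters_.channel_names):
        raise ValueError("channel order does not match the fitted filters")
    x = epochs if already_filtered else _band_epochs(epochs, srate, filters_.band)
    return np.einsum("rc,ect->ert", filters_.weights, x)


def source_band_power(vts: np.ndarray) -> np.ndarray:
    """Per-ROI variance pooled over epochs and samples."""
    centered = vts - vts.mean(axis=-1, keepdims=True)
    return np.mean(centered ** 2, axis=(0, 2))
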