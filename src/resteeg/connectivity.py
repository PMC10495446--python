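"""Band-wise functional connectivity between ROI virtual time series.

Two complementary measures, both insensitive to instantaneous (zero-lag,
volume-conducted) mixing:

* dwPLI — debiased weighted phase-lag index, built from the imaginary part
  of the cross-spectrum with epochs as observations, per 0.5 Hz bin,
  averaged over the band's bins.
* orthogonalized AEC — Pearson correlation of band-limited amplitude
  envelopes after removing, per pair and direction, the instantaneously
  shared component; the two directions are averaged, then epochs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import filters


@dataclass
class ConnectivityMatrix:
    values: np.ndarray               # (n_roi, n_roi), symmetric, zero diagonal
    measure: str                     # "dwpli" | "aec"
    band: tuple[float, float]

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        np.fill_diagonal(self.values, 0.0)


def band_bins(band: tuple[float, float], df: float = 0.5) -> np.ndarray:
    """All multiples of ``df`` within the closed band interval (the highest
    representable bin at or below the upper edge is the last one used)."""
    lo, hi = band
    k0 = int(np.ceil(lo / df - 1e-9))
    k1 = int(np.floor(hi / df + 1e-9))
    if k1 < k0:
        raise ValueError(f"band {band} contains no {df} Hz bins")
    return np.arange(k0, k1 + 1) * df


def dwpli_band(vts: np.ndarray, srate: float, band: tuple[float, float],
               df: float = 0.5) -> ConnectivityMatrix:
    """Debiased wPLI**2 per frequency bin, averaged across the band.

    vts : (n_epochs, n_roi, n_samples) band-limited virtual time series.
    Epochs are the observations: per bin, with X_i the cross-spectrum of an
    epoch, the estimator is
    [(sum_i Im X_i)^2 - sum_i (Im X_i)^2] / [(sum_i |Im X_i|)^2 - sum_i (Im X_i)^2].
    """
    vts = np.asarray(vts, float)
    n_ep, n_roi, n_t = vts.shape
    if n_ep < 2:
        raise ValueError("dwPLI needs at least 2 epochs")
    freqs = np.fft.rfftfreq(n_t, 1 / srate)
    native_df = freqs[1] - freqs[0]
    if abs(native_df - df) > 1e-9 and abs(round(df / native_df) - df / native_df) > 1e-6:
        raise ValueError(f"epoch length gives {native_df} Hz bins; cannot "
                         f"represent a {df} Hz grid")
    bins = band_bins(band, df)
    idx = np.round(bins / native_df).astype(int)
    idx = idx[idx < len(freqs)]
    if idx.size == 0:
        raise ValueError("no usable frequency bins in band")

    x = vts - vts.mean(axis=-1, keepdims=True)
    spec = np.fft.rfft(x, axis=-1)[:, :, idx]      # (ep, roi, nbins)
    out = np.zeros((n_roi, n_roi))
    for b in range(idx.size):
        z = spec[:, :, b]                          # (ep, roi)
        s_im = np.zeros((n_roi, n_roi))
        s_im2 = np.zeros((n_roi, n_roi))
        s_abs = np.zeros((n_roi, n_roi))
        for e in range(n_ep):
            im = np.imag(np.outer(z[e], np.conj(z[e])))
            s_im += im
            s_im2 += im ** 2
            s_abs += np.abs(im)
        num = s_im ** 2 - s_im2
        den = s_abs ** 2 - s_im2
        with np.errstate(invalid="ignore", divide="ignore"):
            w = np.where(den > 0, num / den, 0.0)
        out += w
    out /= idx.size
    out = 0.5 * (out + out.T)
    return ConnectivityMatrix(values=out, measure="dwpli", band=tuple(band))


def aec_band(vts: np.ndarray, band: tuple[float, float],
             chunk: int = 0) -> ConnectivityMatrix:
    """Orthogonalized amplitude-envelope correlation.

    Per epoch, with analytic signals Z_a: the component of A orthogonal to B
    at each sample has envelope |Im(Z_a conj(Z_b))| / |Z_b|; the entry is the
    mean of corr(|A_perp_B|, |B|) and corr(|B_perp_A|, |A|), averaged over
    epochs. Degenerate (zero-variance) envelopes give 0.
    """
    vts = np.asarray(vts, float)
    n_ep, n_roi, n_t = vts.shape
    acc = np.zeros((n_roi, n_roi))
    for e in range(n_ep):
        z = filters.analytic_epoch(vts[e])                 # (roi, t)
        env = (np.abs(z) + 1e-30).astype(np.float32)
        xr = z.real.astype(np.float32)
        xi = z.imag.astype(np.float32)
        # Im(Z_a conj(Z_b)) for all pairs, (roi_a, roi_b, t)
        cross = xi[:, None, :] * xr[None, :, :] - xr[:, None, :] * xi[None, :, :]
        env_orth = np.abs(cross, out=cross)
        env_orth /= env[None, :, :]                        # |A_perp_B|
        r = _rowwise_corr(env_orth, env)                   # corr with |B|
        acc += 0.5 * (r + r.T)
    acc /= n_ep
    return ConnectivityMatrix(values=acc, measure="aec", band=tuple(band))


def _rowwise_corr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """corr(a[i,j,:], b[j,:]) over the last axis; zero-variance pairs -> 0."""
    am = a - a.mean(axis=-1, keepdims=True)
    bm = b - b.mean(axis=-1, keepdims=True)
    num = np.einsum("ijt,jt->ij", am, bm, optimize=True).astype(float)
    va = np.einsum("ijt,ijt->ij", am, am, optimize=True).astype(float)
    vb = np.einsum("jt,jt->j", bm, bm).astype(float)
    den = np.sqrt(va * vb[None, :])
    # degenerate orthogonalization: residual envelope variance negligibly
    # small relative to the reference envelope -> entry 0
    valid = (den > 0) & (va > 1e-10 * vb[None, :])
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(valid, num / np.where(den > 0, den, 1.0), 0.0)
    return r
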