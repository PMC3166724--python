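"""Per-frame feature variables for activity classification.

Four feature families are computed from each data frame:

* DC component — mean of the raw samples per channel (discriminates static
  postures, where the accelerometer mostly reads the gravity projection).
* Energy — sum of squared non-DC magnitude-spectrum coefficients of the
  frame, normalized by the frame width (activity strength).
* Spectral entropy — Shannon entropy of a Gaussian kernel-density estimate
  over the unit-sum-normalized non-DC magnitude coefficients (frequency-
  domain complexity; a pure tone scores low, broadband motion high).
* Correlation coefficients — entries of the per-frame data covariance
  matrix: dot products of mean-removed channel pairs divided by the frame
  width, including self-pairs (movement coordination between body sites).

With all families enabled the dimension is d = 3*ch + ch*(ch+1)/2 for ch
channels: 85 features for a 10-channel setup (55 correlations), 15 for a
3-channel one (6 correlations).
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .io_windowing import FrameSet

__all__ = [
    "dc_component",
    "spectral_energy",
    "spectral_entropy",
    "correlation_features",
    "extract_features",
    "feature_dimension",
    "ALL_FAMILIES",
]

ALL_FAMILIES = ("dc", "energy", "entropy", "correlation")


def dc_component(frame_channel: np.ndarray) -> float:
    """Arithmetic mean of the samples in one channel of a frame."""
    x = np.asarray(frame_channel, dtype=float)
    if x.size == 0:
        raise ValueError("empty frame")
    return float(x.mean())


def spectral_energy(frame_channel: np.ndarray) -> float:
    """Sum of squared spectrum magnitudes over non-DC bins, / frame width.

    With N-point transform X and DC mean m, Parseval gives
    sum(x**2) = N*m**2 + spectral_energy(x), which tests rely on.
    """
    x = np.asarray(frame_channel, dtype=float)
    if x.size == 0:
        raise ValueError("empty frame")
    spectrum = np.fft.fft(x)
    return float(np.sum(np.abs(spectrum[1:]) ** 2) / x.size)


def _silverman_bandwidth(values: np.ndarray) -> float:
    n = values.size
    sd = float(values.std(ddof=1))
    q75, q25 = np.percentile(values, [75, 25])
    iqr = q75 - q25
    sigma = min(sd, iqr / 1.34) if iqr > 0 else sd
    return 0.9 * sigma * n ** (-0.2)


def spectral_entropy(frame_channel: np.ndarray, grid_size: int = 512) -> float:
    """KDE-based Shannon entropy (nats) of the normalized magnitude spectrum.

    The non-DC magnitude coefficients are normalized to unit sum (so the
    value is invariant to amplitude scaling of the frame), a Gaussian KDE
    with Silverman bandwidth is fitted to them, and the differential entropy
    of the estimate is computed by trapezoidal integration over its support.
    Degenerate spectra (all-zero, or identical coefficients) return 0.
    """
    x = np.asarray(frame_channel, dtype=float)
    if x.size < 4:
        raise ValueError("frame too short: need at least 2 non-DC bins")
    mags = np.abs(np.fft.rfft(x)[1:])
    total = mags.sum()
    if total == 0:
        return 0.0
    p = mags / total
    bw = _silverman_bandwidth(p)
    if not bw > 0:
        return 0.0
    # floor on the unit-sum scale keeps near-degenerate (pure-tone) spectra
    # at a finite, very negative entropy instead of diverging
    bw = max(bw, 1e-4)
    lo, hi = p.min() - 4 * bw, p.max() + 4 * bw
    n_grid = int(min(131072, max(grid_size, np.ceil(4 * (hi - lo) / bw))))
    grid = np.linspace(lo, hi, n_grid)
    # vectorized Gaussian KDE: mean kernel over the coefficient points
    z = (grid[:, None] - p[None, :]) / bw
    dens = np.exp(-0.5 * z**2).mean(axis=1) / (bw * np.sqrt(2 * np.pi))
    mask = dens > 0
    integrand = np.zeros_like(dens)
    integrand[mask] = dens[mask] * np.log(dens[mask])
    return float(-np.trapezoid(integrand, grid))


def correlation_features(frame: np.ndarray) -> np.ndarray:
    """Covariance entries of a multichannel frame, self-pairs included.

    For every unordered channel pair (i <= j): dot product of the
    mean-removed channels divided by the frame width. Returns
    ch*(ch+1)/2 values in row-major upper-triangular order.
    """
    f = np.atleast_2d(np.asarray(frame, dtype=float))
    centered = f - f.mean(axis=1, keepdims=True)
    cov = centered @ centered.T / f.shape[1]
    iu = np.triu_indices(f.shape[0])
    return cov[iu]


def feature_dimension(n_channels: int, families=ALL_FAMILIES) -> int:
    d = 0
    for fam in families:
        if fam == "correlation":
            d += n_channels * (n_channels + 1) // 2
        else:
            d += n_channels
    return d


def extract_features(frames, families=ALL_FAMILIES) -> pd.DataFrame:
    """One feature vector per frame, as a named-column DataFrame.

    ``frames`` is a FrameSet or an (n_frames, n_channels, width) array.
    Column order is deterministic: DC block, energy block, entropy block,
    correlation block, each in channel(-pair) order.
    """
    if isinstance(frames, FrameSet):
        blocks = frames.frames
    else:
        blocks = np.asarray(frames, dtype=float)
    if blocks.ndim != 3 or blocks.shape[0] == 0:
        raise ValueError("need a non-empty (n_frames, n_channels, width) array")
    unknown = set(families) - set(ALL_FAMILIES)
    if unknown:
        raise ValueError(f"unknown feature families {sorted(unknown)}")
    n, ch, width = blocks.shape
    cols: dict[str, np.ndarray] = {}
    if "dc" in families:
        dc = blocks.mean(axis=2)
        for c in range(ch):
            cols[f"dc_ch{c + 1}"] = dc[:, c]
    if "energy" in families:
        spec = np.fft.fft(blocks, axis=2)
        energy = np.sum(np.abs(spec[:, :, 1:]) ** 2, axis=2) / width
        for c in range(ch):
            cols[f"energy_ch{c + 1}"] = energy[:, c]
    if "entropy" in families:
        ent = np.empty((n, ch))
        for i in range(n):
            for c in range(ch):
                ent[i, c] = spectral_entropy(blocks[i, c])
        for c in range(ch):
            cols[f"entropy_ch{c + 1}"] = ent[:, c]
    if "correlation" in families:
        centered = blocks - blocks.mean(axis=2, keepdims=True)
        covs = np.einsum("ncw,ndw->ncd", centered, centered) / width
        iu, ju = np.triu_indices(ch)
        for a, b in zip(iu, ju):
            cols[f"corr_ch{a + 1}_ch{b + 1}"] = covs[:, a, b]
    out = pd.DataFrame(cols)
    if not np.isfinite(out.to_numpy()).all():
        raise ValueError("non-finite feature values")
    return out
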