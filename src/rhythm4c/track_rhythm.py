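"""Rhythmicity of binned genomic signal tracks and phase colouring.

Reads (or intervals) are binned into fixed-width bins (500 bp default),
library-size normalized, smoothed with a 7-bin running average, and each
bin's log2 signal across timepoints is fitted with a 24-h harmonic
regression.  Rhythmic bins are colour-encoded in HSV: hue from the peak
phase (blue at ZT0), saturation 1, and value from a Hill function of the
amplitude and of -log10(p), so bins below the thresholds fade to black.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from matplotlib.colors import hsv_to_rgb

from .harmonics import cosinor_test

__all__ = [
    "bin_and_normalize",
    "smooth_track",
    "fit_track_rhythm",
    "hill",
    "hsv_encode",
    "encode_track_colours",
]

DEFAULT_BIN_SIZE = 500
DEFAULT_SMOOTH_BINS = 7
DEFAULT_K_AMP = 1.0
DEFAULT_K_PVAL = 4.5
DEFAULT_HILL_N = 5.0
HUE_AT_ZT0 = 2.0 / 3.0  # blue


def bin_and_normalize(
    read_positions: dict[str, np.ndarray],
    region_start: int,
    region_end: int,
    bin_size: int = DEFAULT_BIN_SIZE,
    library_sizes: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Histogram read positions into fixed bins and rescale by library size.

    ``read_positions`` maps sample name -> array of read (midpoint)
    coordinates.  ``library_sizes`` defaults to each sample's total read
    count; normalized counts are ``raw * mean(library)/library(sample)``,
    so doubling one library halves its normalized values.

    Returns a DataFrame with ``start``, ``end`` and one column per sample.
    """
    if region_end <= region_start:
        raise ValueError("empty region")
    if not read_positions:
        raise ValueError("no samples given")
    edges = np.arange(region_start, region_end + bin_size, bin_size)
    if library_sizes is None:
        library_sizes = {k: float(len(v)) for k, v in read_positions.items()}
    libs = np.array([library_sizes[k] for k in read_positions])
    if np.any(libs <= 0):
        raise ValueError("library sizes must be positive")
    reference = libs.mean()
    out = pd.DataFrame({"start": edges[:-1], "end": edges[1:]})
    for name, pos in read_positions.items():
        counts, _ = np.histogram(np.asarray(pos), bins=edges)
        out[name] = counts * (reference / library_sizes[name])
    return out


def smooth_track(values: np.ndarray, k: int = DEFAULT_SMOOTH_BINS) -> np.ndarray:
    """Centered running average of ``k`` bins (default 3+1+3).

    Edge bins average over the available bins only (shrinking window),
    so the output has the same length as the input.
    """
    if k % 2 != 1 or k < 1:
        raise ValueError("k must be a positive odd integer")
    v = np.asarray(values, dtype=float)
    kernel = np.ones(k)
    num = np.convolve(v, kernel, mode="same")
    den = np.convolve(np.ones_like(v), kernel, mode="same")
    return num / den


def fit_track_rhythm(
    binned: pd.DataFrame,
    times: dict[str, float],
    smooth_k: int = DEFAULT_SMOOTH_BINS,
    log2_offset: float = 1.0,
    period: float = 24.0,
) -> pd.DataFrame:
    """Per-bin harmonic regression of smoothed log2 signal over time.

    ``times`` maps sample column -> hours.  Each sample column is
    smoothed, log2-transformed (with an offset to handle zeros) and the
    bins are fitted with an unweighted 24-h cosinor.

    Returns bins with ``amplitude`` (log2 units), ``phase`` (hours ZT),
    ``pvalue`` and ``mlog10p``.
    """
    samples = list(times)
    t = np.array([times[s] for s in samples], dtype=float)
    log_mat = np.column_stack(
        [np.log2(smooth_track(binned[s].to_numpy(), smooth_k) + log2_offset) for s in samples]
    )
    rows = []
    for y in log_mat:
        if np.allclose(y, y[0]):
            rows.append((0.0, 0.0, 1.0))
            continue
        fit = cosinor_test(t, y, period=period)
        rows.append((fit.amplitude, fit.phase, fit.pvalue))
    out = binned[["start", "end"]].copy()
    out[["amplitude", "phase", "pvalue"]] = rows
    out["mlog10p"] = -np.log10(np.maximum(out["pvalue"], 1e-300))
    return out


def hill(x: np.ndarray | float, k: float, n: float = DEFAULT_HILL_N):
    """Saturating Hill function ``x**n / (k**n + x**n)``; 0.5 at ``x = k``."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("Hill input must be non-negative")
    out = np.where(x > 0, x**n / (k**n + x**n), 0.0)
    return float(out) if out.ndim == 0 else out


def hsv_encode(
    amplitude: float,
    mlog10p: float,
    phase: float,
    k_amp: float = DEFAULT_K_AMP,
    k_pval: float = DEFAULT_K_PVAL,
    hill_n: float = DEFAULT_HILL_N,
    period: float = 24.0,
) -> tuple[tuple[float, float, float], tuple[float, float, float]]:
    """Map a bin's rhythm to an HSV colour and its RGB equivalent.

    Hue encodes the peak phase with blue (h = 2/3) at ZT0, advancing
    around the wheel over the 24 h; saturation is 1; value is the
    minimum of the two Hill scores of amplitude and -log10(p), so a bin
    is bright only when both exceed their thresholds and fades smoothly
    to black below them.
    """
    h = (HUE_AT_ZT0 + (phase % period) / period) % 1.0
    v = min(hill(amplitude, k_amp, hill_n), hill(mlog10p, k_pval, hill_n))
    hsv = (h, 1.0, float(v))
    rgb = tuple(float(c) for c in hsv_to_rgb(hsv))
    return hsv, rgb


def encode_track_colours(
    rhythm: pd.DataFrame,
    k_amp: float = DEFAULT_K_AMP,
    k_pval: float = DEFAULT_K_PVAL,
    hill_n: float = DEFAULT_HILL_N,
) -> pd.DataFrame:
    """Append HSV/RGB colour columns to a :func:`fit_track_rhythm` table."""
    out = rhythm.copy()
    cols = [
        hsv_encode(a, mp, ph, k_amp=k_amp, k_pval=k_pval, hill_n=hill_n)
        for a, mp, ph in zip(out["amplitude"], out["mlog10p"], out["phase"])
    ]
    out["hue"] = [hsv[0] for hsv, _ in cols]
    out["value"] = [hsv[2] for hsv, _ in cols]
    out["rgb"] = [
        ",".join(str(int(round(255 * c))) for c in rgb) for _, rgb in cols
    ]
    return out
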