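"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's structured solvers: the weighted
least-squares oracle materializes the full observation-level design
matrix and solves the constrained problem with SVD-based tools, and the
binning/counting oracles use explicit loops.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import null_space


def dense_wls_solve(
    positions: np.ndarray,
    Y: np.ndarray,
    w_s: np.ndarray,
    center: float,
    sigma_g: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Constrained WLS fit of Y_ijr = a_i + b_j via the full design matrix.

    Weights are w_g(position) * w_s[i, j]; the constraint
    sum_i w_g,i a_i = 0 is imposed through an orthonormal null-space
    basis.  Returns (a, b).
    """
    I, J, R = Y.shape
    w_g = np.exp(-((positions - center) ** 2) / (2.0 * sigma_g**2))
    rows, weights, ys = [], [], []
    for i in range(I):
        for j in range(J):
            for r in range(R):
                if np.isnan(Y[i, j, r]):
                    continue
                x = np.zeros(I + J)
                x[i] = 1.0
                x[I + j] = 1.0
                rows.append(x)
                weights.append(w_g[i] * w_s[i, j])
                ys.append(Y[i, j, r])
    X = np.asarray(rows)
    w = np.asarray(weights)
    y = np.asarray(ys)
    c = np.concatenate([w_g, np.zeros(J)])
    Zc = null_space(c[None, :])
    sw = np.sqrt(w)
    gamma, *_ = np.linalg.lstsq((X * sw[:, None]) @ Zc, y * sw, rcond=None)
    theta = Zc @ gamma
    return theta[:I], theta[I:]


def count_motif_brute(seq: str, motif: str) -> int:
    """Count (possibly overlapping) motif occurrences by sliding window."""
    return sum(
        1 for i in range(len(seq) - len(motif) + 1) if seq[i : i + len(motif)] == motif
    )


def bin_reads_brute(positions, edges) -> np.ndarray:
    """Per-bin read counts by explicit interval membership."""
    counts = np.zeros(len(edges) - 1, dtype=int)
    for p in positions:
        for k in range(len(edges) - 1):
            if edges[k] <= p < edges[k + 1]:
                counts[k] += 1
                break
    return counts


def running_mean_brute(values: np.ndarray, k: int) -> np.ndarray:
    """Shrinking-window centered running average by explicit slicing."""
    half = k // 2
    out = np.empty_like(values, dtype=float)
    for i in range(len(values)):
        lo = max(0, i - half)
        hi = min(len(values), i + half + 1)
        out[i] = values[lo:hi].mean()
    return out
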