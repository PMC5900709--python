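"""Locally weighted multilinear regression (LWMR) of 4C-seq profiles.

For every target restriction fragment, log-transformed fragment scores
``Y = log10(c/P + 1)`` in a Gaussian positional window are modelled as
``Y_ijr = a_i + b_j + eps`` with fragment effects ``a_i`` and condition
effects ``b_j`` (time, genotype or tissue), fitted by weighted least
squares with weights ``W_ij = w_g,i * w_s,j``: a Gaussian positional
kernel times a dropout-based condition weight ``w_s = n_nonzero + 0.5``.

Identifiability: ``a`` and ``b`` are confounded by a constant, resolved
with the constraint ``sum_i w_g,i * a_i = 0`` so that each ``b_j`` is
the local weighted mean signal of its condition and ``b_bar = mean(b)``
is the natural overall signal level used in the variance
regularization ``sigma2_reg = sigma2_hat + sigma_min**2 *
exp(-b_bar / log10(2))``.

Differential contacts are tested with regularized t statistics on
``n - p`` degrees of freedom; 24-h rhythmicity with a weighted harmonic
regression whose squared Fourier coefficient is referred to a
chi-square distribution with 2 degrees of freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .fourc_prep import CountMatrix
from .harmonics import phase_of

__all__ = [
    "DEFAULT_PSEUDOCOUNT",
    "DEFAULT_SIGMA_G",
    "LWMRData",
    "LWMRFit",
    "DifferentialResult",
    "RhythmResult",
    "log_transform",
    "gaussian_weights",
    "condition_weights",
    "prepare_lwmr_data",
    "fit_local_model",
    "regularize_variance",
    "estimate_sigma_min",
    "differential_test",
    "rhythm_test",
    "lwmr_profile",
]

DEFAULT_PSEUDOCOUNT = 500.0
DEFAULT_SIGMA_G = 2500.0
B_SHRINK_SCALE = float(np.log10(2.0))  # b_s in the variance regularization
WINDOW_TRUNCATION_SIGMAS = 4.0
EFFECTIVE_WEIGHT_FRACTION = 1e-3


def log_transform(c: np.ndarray | float, pseudocount: float = DEFAULT_PSEUDOCOUNT):
    """Variance-stabilizing transform ``Y = log10(c / P + 1)``."""
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("fragment scores must be non-negative")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    out = np.log10(c / pseudocount + 1.0)
    return float(out) if out.ndim == 0 else out


def gaussian_weights(
    positions: np.ndarray, center: float, sigma_g: float = DEFAULT_SIGMA_G
) -> np.ndarray:
    """Positional kernel ``w_g = exp(-(x - center)**2 / (2 sigma_g**2))``."""
    if sigma_g <= 0:
        raise ValueError("sigma_g must be positive")
    x = np.asarray(positions, dtype=float)
    return np.exp(-((x - center) ** 2) / (2.0 * sigma_g**2))


def condition_weights(n_nonzero: np.ndarray | int):
    """Dropout-based condition weight ``w_s = n_nonzero + 0.5``.

    0.5, 1.5, 2.5, 3.5, 4.5 for 0..4 replicates with nonzero counts in a
    4-replicate design; the rule generalizes to any replicate number.
    """
    n = np.asarray(n_nonzero)
    if np.any(n < 0):
        raise ValueError("replicate counts cannot be negative")
    out = n + 0.5
    return float(out) if out.ndim == 0 else out.astype(float)


@dataclass
class LWMRData:
    """Dense arrays prepared once per bait for repeated local fits.

    ``Y`` has shape (fragments, conditions, max replicates) with NaN for
    absent replicates; ``w_s`` is the per (fragment, condition) dropout
    weight; fragments are cis, unmasked, position-sorted.
    """

    fragment_ids: np.ndarray
    positions: np.ndarray
    conditions: list[str]
    times: np.ndarray | None
    Y: np.ndarray
    w_s: np.ndarray
    n_present: np.ndarray  # replicates present per (fragment, condition)


def prepare_lwmr_data(
    cm: CountMatrix,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    score_column: str = "norm_score",
    condition_column: str = "condition",
) -> LWMRData:
    """Assemble the per-bait arrays used by :func:`fit_local_model`.

    Uses cis, unmasked fragments only.  Dropout weights are derived from
    the *raw* scores (a fragment end observed at zero stays zero after
    rescaling, but this keeps the rule explicit).
    """
    frags = cm.fragments
    if "is_masked" not in frags:
        raise ValueError("CountMatrix must be bait-masked (mask_bait_adjacent)")
    keep = frags[(frags["chrom"] == cm.bait_chrom) & ~frags["is_masked"]]
    keep = keep.sort_values("start")
    fragment_ids = keep["fragment_id"].to_numpy()
    positions = ((keep["start"] + keep["end"]) / 2.0).to_numpy()

    meta = cm.samples.set_index("sample_id")
    conditions = list(dict.fromkeys(meta[condition_column]))
    times = None
    if "time" in meta:
        by_cond = meta.groupby(condition_column, sort=False)["time"].agg(["min", "max"])
        if (by_cond["min"] == by_cond["max"]).all():
            times = by_cond["min"].reindex(conditions).to_numpy(dtype=float)

    if score_column not in cm.counts:
        raise ValueError(f"counts table lacks {score_column!r}; run normalize_library")
    wide = cm.counts.pivot(index="fragment_id", columns="sample_id", values=score_column)
    wide_raw = cm.counts.pivot(index="fragment_id", columns="sample_id", values="score")
    wide = wide.reindex(fragment_ids)
    wide_raw = wide_raw.reindex(fragment_ids)

    n_frag, n_cond = len(fragment_ids), len(conditions)
    max_rep = int(meta.groupby(condition_column)[condition_column].count().max())
    Y = np.full((n_frag, n_cond, max_rep), np.nan)
    nonzero = np.zeros((n_frag, n_cond), dtype=int)
    n_present = np.zeros((n_frag, n_cond), dtype=int)
    for j, cond in enumerate(conditions):
        sample_ids = meta.index[meta[condition_column] == cond]
        for r, sid in enumerate(sample_ids):
            col = wide[sid].to_numpy(dtype=float)
            raw = wide_raw[sid].to_numpy(dtype=float)
            col = np.where(np.isnan(col), 0.0, col)
            raw = np.where(np.isnan(raw), 0.0, raw)
            Y[:, j, r] = log_transform(col, pseudocount)
            nonzero[:, j] += (raw > 0).astype(int)
            n_present[:, j] += 1
    w_s = condition_weights(nonzero)
    return LWMRData(
        fragment_ids=fragment_ids,
        positions=positions,
        conditions=conditions,
        times=times,
        Y=Y,
        w_s=w_s,
        n_present=n_present,
    )


@dataclass
class LWMRFit:
    """One local weighted fit centred on a target fragment."""

    fragment_id: int
    position: float
    conditions: list[str]
    window_fragment_ids: np.ndarray
    a: np.ndarray  # fragment effects, constrained to weighted mean 0
    b: np.ndarray  # condition effects (local mean signal per condition)
    cov_b_unit: np.ndarray  # Cov(b) / sigma2; scale by sigma2_reg for use
    sigma2_hat: float  # weighted residual variance
    n: int  # effective number of observations
    p: int  # number of parameters
    sigma_min: float = 0.0
    times: np.ndarray | None = None

    @property
    def ok(self) -> bool:
        return np.isfinite(self.sigma2_hat) and self.n > self.p

    @property
    def b_bar(self) -> float:
        return float(np.mean(self.b))

    @property
    def sigma2_reg(self) -> float:
        return regularize_variance(self.sigma2_hat, self.b_bar, self.sigma_min)

    @property
    def cov_b(self) -> np.ndarray:
        return self.sigma2_reg * self.cov_b_unit

    @property
    def se_b(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_b))

    def condition_index(self, condition: str) -> int:
        return self.conditions.index(condition)


def fit_local_model(
    data: LWMRData,
    center: float,
    sigma_g: float = DEFAULT_SIGMA_G,
    sigma_min: float = 0.0,
) -> LWMRFit | None:
    """Weighted least-squares fit of ``Y = a_i + b_j`` in one window.

    The window is truncated at ``center +/- 4 sigma_g``.  Returns None
    when the window holds fewer than two fragments or the design is
    degenerate.  The normal equations are solved exactly (the additive
    structure keeps them small: one fragment effect per window fragment
    and one effect per condition, under the gauge constraint
    ``sum_i w_g,i a_i = 0``).
    """
    half = WINDOW_TRUNCATION_SIGMAS * sigma_g
    lo, hi = np.searchsorted(data.positions, [center - half, center + half + 1])
    idx = np.arange(lo, hi)
    if idx.size < 2:
        return None
    x = data.positions[idx]
    w_g = gaussian_weights(x, center, sigma_g)
    w_s = data.w_s[idx]  # (I, J)
    Y = data.Y[idx]  # (I, J, R)
    present = ~np.isnan(Y)
    m = present.sum(axis=2)  # replicates per cell
    W = w_g[:, None] * w_s  # per-observation weight, (I, J)
    I, J = W.shape

    S = np.nansum(Y, axis=2)  # (I, J) replicate sums
    T = W * m
    Daa = T.sum(axis=1)
    Dbb = T.sum(axis=0)
    if np.any(Daa <= 0) or np.any(Dbb <= 0):
        return None
    rhs = np.concatenate([(W * S).sum(axis=1), (W * S).sum(axis=0)])
    ySS = float(np.nansum(W[:, :, None] * Y**2))

    # Full normal-equations matrix in (a_1..a_I, b_1..b_J) order.
    A = np.zeros((I + J, I + J))
    A[np.arange(I), np.arange(I)] = Daa
    A[I:, I:][np.arange(J), np.arange(J)] = Dbb
    A[:I, I:] = T
    A[I:, :I] = T.T

    # Null-space basis of the gauge constraint sum_i w_g,i a_i = 0.
    ref = int(np.argmax(w_g))
    free = [i for i in range(I) if i != ref]
    Z = np.zeros((I + J, I + J - 1))
    for col, i in enumerate(free):
        Z[i, col] = 1.0
        Z[ref, col] = -w_g[i] / w_g[ref]
    Z[I:, I - 1 :] = np.eye(J)

    G = Z.T @ A @ Z
    try:
        Ginv = np.linalg.inv(G)
    except np.linalg.LinAlgError:
        return None
    gamma = Ginv @ (Z.T @ rhs)
    theta = Z @ gamma
    a, b = theta[:I], theta[I:]

    # Sandwich covariance for smoothing weights: the kernel weights are
    # not inverse variances, so Cov(theta) = sigma2 * B (X'W^2X) B with
    # B the constrained solve operator and homoscedastic residuals.
    T2 = W**2 * m
    A2 = np.zeros((I + J, I + J))
    A2[np.arange(I), np.arange(I)] = T2.sum(axis=1)
    A2[I:, I:][np.arange(J), np.arange(J)] = T2.sum(axis=0)
    A2[:I, I:] = T2
    A2[I:, :I] = T2.T
    B = Z @ Ginv @ Z.T
    cov_unit = B @ A2 @ B
    cov_b_unit = cov_unit[I:, I:]

    ssr = ySS - float(theta @ rhs)
    ssr = max(ssr, 0.0)
    # effective residual DOF of the weighted smoother: E[sum W r^2] =
    # sigma2 * (tr W - tr(B A2)); gives an unbiased homoscedastic sigma2.
    dof_w = float(T.sum() - np.sum(B * A2))
    w_max = W.max()
    effective = (W[:, :, None] > EFFECTIVE_WEIGHT_FRACTION * w_max) & present
    n_eff = int(effective.sum())
    p = I + J - 1
    sigma2_hat = ssr / dof_w if (dof_w > 0 and n_eff > p) else np.nan

    return LWMRFit(
        fragment_id=int(data.fragment_ids[idx[np.argmin(np.abs(x - center))]]),
        position=float(center),
        conditions=list(data.conditions),
        window_fragment_ids=data.fragment_ids[idx],
        a=a,
        b=b,
        cov_b_unit=cov_b_unit,
        sigma2_hat=sigma2_hat,
        n=n_eff,
        p=p,
        sigma_min=sigma_min,
        times=data.times,
    )


def regularize_variance(
    sigma2_hat: float, b_bar: float, sigma_min: float
) -> float:
    """``sigma2_reg = sigma2_hat + sigma_min**2 * exp(-b_bar / log10(2))``.

    The floor term prevents artificially small variances at positions
    with high dropout (low mean signal); it vanishes as the mean signal
    grows.
    """
    if sigma2_hat < 0 or sigma_min < 0:
        raise ValueError("variances must be non-negative")
    return float(sigma2_hat + sigma_min**2 * np.exp(-b_bar / B_SHRINK_SCALE))


def estimate_sigma_min(
    sigma2_hats: np.ndarray,
    b_bars: np.ndarray,
    quantile: float = 0.10,
    min_fragments: int = 100,
) -> float:
    """Noise-floor scale from the residual-variance distribution.

    Taken as the square root of a low quantile (default 10th percentile)
    of the residual variances among fragments whose mean signal exceeds
    the median: high-signal fragments have little dropout, so their
    residual variance approximates the intrinsic noise floor.  The exact
    quantile is a tuning parameter, not a published constant.
    """
    s2 = np.asarray(sigma2_hats, dtype=float)
    bb = np.asarray(b_bars, dtype=float)
    ok = np.isfinite(s2) & np.isfinite(bb)
    s2, bb = s2[ok], bb[ok]
    if s2.size < min_fragments:
        raise ValueError(
            f"need >= {min_fragments} fitted fragments to estimate sigma_min, got {s2.size}"
        )
    high = bb >= np.median(bb)
    return float(np.sqrt(np.quantile(s2[high], quantile)))


@dataclass
class DifferentialResult:
    """Two-condition contrast on one fragment."""

    fragment_id: int
    delta_b: float
    z: float
    pvalue: float

    @property
    def signed_mlog10p(self) -> float:
        return float(np.sign(self.z) * -np.log10(max(self.pvalue, 1e-300)))


def differential_test(
    fit: LWMRFit,
    contrast: tuple[str, str],
    use_covariance: bool = True,
) -> DifferentialResult:
    """Regularized t test of ``b_j1 - b_j2`` with ``n - p`` DOF.

    ``use_covariance`` subtracts the (shared fragment-effect) covariance
    of the two condition estimates from the contrast variance; with
    ``False`` the variance is the plain sum ``se_j1**2 + se_j2**2``.
    """
    j1 = fit.condition_index(contrast[0])
    j2 = fit.condition_index(contrast[1])
    cov = fit.cov_b
    delta = float(fit.b[j1] - fit.b[j2])
    var = cov[j1, j1] + cov[j2, j2]
    if use_covariance:
        var -= 2.0 * cov[j1, j2]
    if not fit.ok or var <= 0:
        return DifferentialResult(fit.fragment_id, delta, np.nan, np.nan)
    z = delta / np.sqrt(var)
    p = 2.0 * stats.t.sf(abs(z), df=fit.n - fit.p)
    return DifferentialResult(fit.fragment_id, delta, float(z), float(min(p, 1.0)))


@dataclass
class RhythmResult:
    """Weighted 24-h harmonic regression on the condition effects."""

    fragment_id: int
    coefficient: complex
    amplitude: float
    phase: float  # hours ZT of peak, in [0, 24)
    chi2: float
    pvalue: float

    @property
    def log2_fold_change(self) -> float:
        """Peak-to-trough fold change of the fitted cosine, in log2."""
        return float(2.0 * self.amplitude / np.log10(2.0))

    @property
    def mlog10p(self) -> float:
        return float(-np.log10(max(self.pvalue, 1e-300)))


def rhythm_test(
    fit: LWMRFit,
    times: np.ndarray | None = None,
    period: float = 24.0,
) -> RhythmResult:
    """Chi-square (2 DOF) test on the 24-h Fourier coefficient of ``b_j``.

    ``F = (2/sum u) * sum_j u_j b_j exp(-i omega t_j)`` with inverse-
    variance weights ``u_j = 1/Var(b_j)``.  The uncertainty of the
    ``b_j`` is propagated to the real and imaginary parts of ``F``
    (including their covariance) and the squared coefficient referred to
    a chi-square distribution with two degrees of freedom.
    """
    if times is None:
        times = fit.times
    if times is None:
        raise ValueError("timepoints required: pass times= or provide a 'time' column")
    times = np.asarray(times, dtype=float)
    if len(times) != len(fit.conditions):
        raise ValueError("times must align with fit.conditions")
    if np.unique(times).size < 4:
        raise ValueError("need >= 4 distinct timepoints for the rhythm test")
    cov = fit.cov_b
    var_b = np.diag(cov)
    if not fit.ok or np.any(~np.isfinite(var_b)) or np.any(var_b <= 0):
        return RhythmResult(fit.fragment_id, 0j, np.nan, np.nan, np.nan, np.nan)
    omega = 2.0 * np.pi / period
    u = 1.0 / var_b
    scale = 2.0 / u.sum()
    vc = scale * u * np.cos(omega * times)
    vs = -scale * u * np.sin(omega * times)
    re = float(vc @ fit.b)
    im = float(vs @ fit.b)
    sig = np.array(
        [
            [vc @ cov @ vc, vc @ cov @ vs],
            [vc @ cov @ vs, vs @ cov @ vs],
        ]
    )
    try:
        stat = float(np.array([re, im]) @ np.linalg.solve(sig, np.array([re, im])))
    except np.linalg.LinAlgError:
        return RhythmResult(fit.fragment_id, 0j, np.nan, np.nan, np.nan, np.nan)
    F = complex(re, im)
    return RhythmResult(
        fragment_id=fit.fragment_id,
        coefficient=F,
        amplitude=abs(F),
        phase=phase_of(F, period),
        chi2=max(stat, 0.0),
        pvalue=float(stats.chi2.sf(max(stat, 0.0), df=2)),
    )


def lwmr_profile(
    cm: CountMatrix,
    sigma_g: float = DEFAULT_SIGMA_G,
    region: tuple[float, float] | None = None,
    contrast: tuple[str, str] | None = None,
    rhythm: bool = False,
    sigma_min: float | None = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    score_column: str = "norm_score",
    use_covariance: bool = True,
) -> pd.DataFrame:
    """Fit LWMR at every unmasked cis fragment and tabulate the results.

    Two passes: the first collects residual variances to estimate
    ``sigma_min`` from the window set (unless given), the second applies
    the regularized variance to standard errors and tests.  Masked
    (bait-adjacent) fragments never appear in the output.

    Returns a DataFrame indexed by target fragment with the condition
    effects ``b_<condition>``, their standard errors, the fit
    diagnostics, and optional differential (``delta_b``, ``z``,
    ``p_diff``, ``signed_mlog10p``) and rhythm (``amplitude``,
    ``phase``, ``p_rhythm``) columns.
    """
    data = prepare_lwmr_data(cm, pseudocount=pseudocount, score_column=score_column)
    targets = np.arange(data.positions.size)
    if region is not None:
        lo, hi = region
        targets = targets[(data.positions >= lo) & (data.positions <= hi)]

    fits: list[LWMRFit | None] = [
        fit_local_model(data, data.positions[i], sigma_g=sigma_g) for i in targets
    ]
    if sigma_min is None:
        s2 = np.array([f.sigma2_hat if f else np.nan for f in fits])
        bb = np.array([f.b_bar if f else np.nan for f in fits])
        try:
            sigma_min = estimate_sigma_min(s2, bb)
        except ValueError:
            warnings.warn(
                "too few fragments to estimate sigma_min; using 0", stacklevel=2
            )
            sigma_min = 0.0

    rows = []
    for i, fit in zip(targets, fits):
        row: dict = {
            "fragment_id": int(data.fragment_ids[i]),
            "position": float(data.positions[i]),
        }
        if fit is None:
            rows.append(row)
            continue
        fit.sigma_min = sigma_min
        se = fit.se_b
        for j, cond in enumerate(fit.conditions):
            row[f"b_{cond}"] = fit.b[j]
            row[f"se_{cond}"] = se[j]
        row.update(
            n=fit.n,
            p=fit.p,
            sigma2_hat=fit.sigma2_hat,
            sigma2_reg=fit.sigma2_reg,
            b_bar=fit.b_bar,
        )
        if contrast is not None:
            d = differential_test(fit, contrast, use_covariance=use_covariance)
            row.update(
                delta_b=d.delta_b,
                z=d.z,
                p_diff=d.pvalue,
                signed_mlog10p=d.signed_mlog10p if np.isfinite(d.z) else np.nan,
            )
        if rhythm:
            r = rhythm_test(fit)
            row.update(
                amplitude=r.amplitude,
                phase=r.phase,
                chi2_rhythm=r.chi2,
                p_rhythm=r.pvalue,
                log2_fold_change=r.log2_fold_change if np.isfinite(r.amplitude) else np.nan,
            )
        rows.append(row)
    out = pd.DataFrame(rows)
    out.attrs["sigma_min"] = sigma_min
    return out
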