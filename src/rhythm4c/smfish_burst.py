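"""smRNA-FISH transcription-site quantification and burst statistics.

Spots (nascent transcription sites) are detected as local maxima of a
Laplacian-filtered maximum projection; their intensities are integrated
in a 3x3 mask on the sum projection of the nine best-focused slices.
Nuclei are segmented from the counterstain channel (smoothing, Otsu
threshold, watershed) and assigned a ploidy (2N/4N/8N) by a
four-component Gaussian mixture over nuclear diameters; nuclei whose
posterior membership in one of the three smallest-mean components does
not exceed 0.7, or that fall in the broad outlier component, are
discarded.  Burst fraction is active sites per nucleus divided by
ploidy, pooled over nuclei.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import regionprops
from skimage.segmentation import watershed

__all__ = [
    "SpotCall",
    "PloidyModel",
    "detect_spots",
    "best_focus_sum_projection",
    "site_intensity",
    "segment_nuclei",
    "fit_ploidy_mixture",
    "assign_ploidy",
    "assign_ploidy_table",
    "burst_statistics",
    "lrt_genotype_effect",
]

SPOT_SUPPRESSION_RADIUS = 3  # px
PLOIDY_OF_RANK = {0: 2, 1: 4, 2: 8}


@dataclass
class SpotCall:
    """One candidate transcription site."""

    y: int
    x: int
    total_intensity: float = np.nan
    nucleus_id: int | None = None


def detect_spots(
    stack: np.ndarray,
    threshold: float | None = None,
    threshold_sigmas: float = 5.0,
    laplace_sigma: float = 1.0,
    min_distance: int = SPOT_SUPPRESSION_RADIUS,
) -> list[SpotCall]:
    """Local maxima of the Laplacian-filtered maximum projection.

    ``threshold`` is applied to the filtered image; by default it is
    ``mean + threshold_sigmas * sd`` of the filtered projection.  Maxima
    closer than ``min_distance`` pixels are merged (non-maximum
    suppression), so two spots 1 px apart yield a single call.
    """
    raw = np.asarray(stack)
    if np.issubdtype(raw.dtype, np.integer) and raw.size:
        if raw.max() >= np.iinfo(raw.dtype).max:
            warnings.warn("stack contains saturated pixels", stacklevel=2)
    stack = raw.astype(float)
    if stack.ndim == 2:
        stack = stack[None]
    proj = stack.max(axis=0)
    filtered = -ndimage.gaussian_laplace(proj, sigma=laplace_sigma)
    if filtered.std() == 0:
        return []
    if threshold is None:
        threshold = float(filtered.mean() + threshold_sigmas * filtered.std())
    peaks = peak_local_max(
        filtered, min_distance=min_distance, threshold_abs=threshold
    )
    return [SpotCall(y=int(py), x=int(px)) for py, px in peaks]


def best_focus_sum_projection(stack: np.ndarray, n_best: int = 9) -> np.ndarray:
    """Sum projection of the ``n_best`` best-focused slices.

    Focus is measured per slice by the variance of its Laplacian (a
    standard autofocus metric).  If the stack has fewer slices, all are
    used with a warning.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim == 2:
        stack = stack[None]
    if stack.shape[0] < n_best:
        warnings.warn(
            f"stack has {stack.shape[0]} < {n_best} slices; using all", stacklevel=2
        )
        return stack.sum(axis=0)
    focus = np.array([ndimage.laplace(s).var() for s in stack])
    best = np.sort(np.argsort(focus)[::-1][:n_best])
    return stack[best].sum(axis=0)


def site_intensity(
    stack: np.ndarray, spot: SpotCall, n_best: int = 9, projection: np.ndarray | None = None
) -> float:
    """Total signal in a 3x3 mask on the best-focus sum projection.

    Pass a precomputed ``projection`` when quantifying many spots on the
    same stack.  Masks overhanging the image border are clipped.
    """
    if projection is None:
        projection = best_focus_sum_projection(stack, n_best=n_best)
    h, w = projection.shape
    y0, y1 = max(spot.y - 1, 0), min(spot.y + 2, h)
    x0, x1 = max(spot.x - 1, 0), min(spot.x + 2, w)
    total = float(projection[y0:y1, x0:x1].sum())
    spot.total_intensity = total
    return total


def segment_nuclei(
    image: np.ndarray,
    pixel_size: float,
    smooth_sigma: float = 2.0,
    min_area_px: int = 50,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Threshold + watershed nucleus segmentation of a counterstain image.

    Returns the labelled mask and a table with ``nucleus_id``,
    centroid, area and equivalent-circle ``diameter`` in micrometres
    (``2 * sqrt(area/pi) * pixel_size``).
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive (um per pixel)")
    img = ndimage.gaussian_filter(np.asarray(image, dtype=float), smooth_sigma)
    if np.allclose(img, img.flat[0]):
        return np.zeros(img.shape, dtype=int), _empty_nucleus_table()
    mask = img > threshold_otsu(img)
    if not mask.any():
        return np.zeros(img.shape, dtype=int), _empty_nucleus_table()
    distance = ndimage.distance_transform_edt(mask)
    peaks = peak_local_max(
        distance, labels=mask, min_distance=7, exclude_border=False
    )
    markers = np.zeros(img.shape, dtype=int)
    for i, (py, px) in enumerate(peaks, start=1):
        markers[py, px] = i
    labels = watershed(-distance, markers, mask=mask)
    rows = []
    for prop in regionprops(labels):
        if prop.area < min_area_px:
            labels[labels == prop.label] = 0
            continue
        diameter = 2.0 * np.sqrt(prop.area / np.pi) * pixel_size
        rows.append(
            (prop.label, prop.centroid[0], prop.centroid[1], prop.area, diameter)
        )
    table = pd.DataFrame(
        rows, columns=["nucleus_id", "centroid_y", "centroid_x", "area_px", "diameter"]
    )
    return labels, table


def _empty_nucleus_table() -> pd.DataFrame:
    return pd.DataFrame(
        columns=["nucleus_id", "centroid_y", "centroid_x", "area_px", "diameter"]
    )


@dataclass
class PloidyModel:
    """Four-component univariate Gaussian mixture over nuclear diameters.

    Components are sorted by mean; the three smallest-mean components
    map to ploidies 2N, 4N and 8N and the remaining (largest-variance in
    practice) component captures diameter outliers.
    """

    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray
    log_likelihood: float
    ll_trajectory: np.ndarray

    @property
    def outlier_component(self) -> int:
        return int(np.argmax(self.sds))

    def responsibilities(self, diameters: np.ndarray) -> np.ndarray:
        d = np.asarray(diameters, dtype=float)[:, None]
        logp = stats.norm.logpdf(d, self.means[None, :], self.sds[None, :]) + np.log(
            self.weights[None, :]
        )
        logp -= logp.max(axis=1, keepdims=True)
        p = np.exp(logp)
        return p / p.sum(axis=1, keepdims=True)


def fit_ploidy_mixture(
    diameters: np.ndarray,
    n_components: int = 4,
    n_restarts: int = 10,
    max_iter: int = 500,
    tol: float = 1e-8,
    sd_floor: float = 1e-3,
    seed: int = 0,
) -> PloidyModel:
    """EM fit of a univariate Gaussian mixture to nuclear diameters.

    Best of ``n_restarts`` k-means++-style initializations by final log
    likelihood; component standard deviations are floored at
    ``sd_floor`` to survive degenerate inputs.  The log-likelihood
    trajectory of the winning run is retained (it is non-decreasing up
    to floating-point rounding).
    """
    d = np.asarray(diameters, dtype=float)
    if d.size < n_components:
        raise ValueError("need at least one diameter per component")
    rng = np.random.default_rng(seed)
    best: PloidyModel | None = None
    for _ in range(n_restarts):
        means = _kmeanspp_init(d, n_components, rng)
        sds = np.full(n_components, max(d.std(), sd_floor))
        weights = np.full(n_components, 1.0 / n_components)
        lls = []
        for _ in range(max_iter):
            logp = stats.norm.logpdf(d[:, None], means[None, :], sds[None, :]) + np.log(
                weights[None, :]
            )
            mx = logp.max(axis=1, keepdims=True)
            lse = mx[:, 0] + np.log(np.exp(logp - mx).sum(axis=1))
            ll = float(lse.sum())
            resp = np.exp(logp - lse[:, None])
            nk = resp.sum(axis=0)
            nk = np.maximum(nk, 1e-12)
            means = (resp * d[:, None]).sum(axis=0) / nk
            var = (resp * (d[:, None] - means[None, :]) ** 2).sum(axis=0) / nk
            sds = np.maximum(np.sqrt(var), sd_floor)
            weights = nk / d.size
            lls.append(ll)
            if len(lls) > 1 and abs(lls[-1] - lls[-2]) < tol * abs(lls[-2] + 1.0):
                break
        order = np.argsort(means)
        model = PloidyModel(
            means=means[order],
            sds=sds[order],
            weights=weights[order],
            log_likelihood=lls[-1],
            ll_trajectory=np.asarray(lls),
        )
        if best is None or model.log_likelihood > best.log_likelihood:
            best = model
    assert best is not None
    return best


def _kmeanspp_init(d: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    centers = [d[rng.integers(d.size)]]
    for _ in range(k - 1):
        dist2 = np.min(
            np.abs(d[:, None] - np.asarray(centers)[None, :]) ** 2, axis=1
        )
        total = dist2.sum()
        if total <= 0:
            centers.append(d[rng.integers(d.size)])
            continue
        centers.append(d[rng.choice(d.size, p=dist2 / total)])
    return np.sort(np.asarray(centers, dtype=float))


def assign_ploidy(
    diameter: float, model: PloidyModel, p_min: float = 0.7
) -> int | None:
    """Ploidy of one nucleus, or None when discarded.

    Assignment requires posterior probability > ``p_min`` for one of the
    three smallest-mean components (which map to 2N, 4N and 8N);
    everything else — ambiguous nuclei and outlier-component-dominated
    ones — is discarded.
    """
    resp = model.responsibilities(np.array([diameter]))[0]
    smallest3 = np.argsort(model.means)[:3]
    j = smallest3[np.argmax(resp[smallest3])]
    if resp[j] > p_min:
        return PLOIDY_OF_RANK[int(np.flatnonzero(smallest3 == j)[0])]
    return None


def assign_ploidy_table(
    diameters: np.ndarray, model: PloidyModel, p_min: float = 0.7
) -> pd.Series:
    """Vectorized :func:`assign_ploidy`; NaN marks discarded nuclei."""
    resp = model.responsibilities(np.asarray(diameters, dtype=float))
    smallest3 = np.argsort(model.means)[:3]
    sub = resp[:, smallest3]
    j = np.argmax(sub, axis=1)
    post = sub[np.arange(len(sub)), j]
    ploidy = np.array([PLOIDY_OF_RANK[int(i)] for i in j], dtype=float)
    ploidy[post <= p_min] = np.nan
    return pd.Series(ploidy, name="ploidy")


def burst_statistics(nuclei: pd.DataFrame, condition_column: str = "condition") -> dict:
    """Per-condition burst fraction / site intensity with Welch t-tests.

    ``nuclei`` needs ``ploidy`` (NaN rows are discarded),
    ``n_active_sites`` and optionally ``mean_site_intensity``.  Burst
    fraction is pooled over nuclei (sites/ploidy averaged across the
    population).  Nuclei with more sites than ploidy are kept but
    counted in ``n_overloaded``.

    Returns ``{"summary": DataFrame, "tests": DataFrame}``.
    """
    df = nuclei.dropna(subset=["ploidy"]).copy()
    conditions = list(dict.fromkeys(df[condition_column]))
    if len(conditions) < 2:
        raise ValueError("need >= 2 conditions for comparisons")
    df["burst_fraction"] = df["n_active_sites"] / df["ploidy"]
    has_intensity = "mean_site_intensity" in df

    rows = []
    for cond in conditions:
        sub = df[df[condition_column] == cond]
        if len(sub) < 2:
            raise ValueError(f"condition {cond!r} has fewer than 2 nuclei")
        bf = sub["burst_fraction"]
        row = {
            "condition": cond,
            "n_nuclei": len(sub),
            "burst_fraction": bf.mean(),
            "burst_fraction_se": bf.std(ddof=1) / np.sqrt(len(sub)),
            "n_overloaded": int((sub["n_active_sites"] > sub["ploidy"]).sum()),
        }
        if has_intensity:
            inten = sub["mean_site_intensity"].dropna()
            row["site_intensity"] = inten.mean()
            row["site_intensity_se"] = (
                inten.std(ddof=1) / np.sqrt(len(inten)) if len(inten) > 1 else np.nan
            )
        rows.append(row)
    summary = pd.DataFrame(rows)

    tests = []
    for i, c1 in enumerate(conditions):
        for c2 in conditions[i + 1 :]:
            s1 = df.loc[df[condition_column] == c1]
            s2 = df.loc[df[condition_column] == c2]
            t_bf = stats.ttest_ind(
                s1["burst_fraction"], s2["burst_fraction"], equal_var=False
            )
            rec = {
                "condition_1": c1,
                "condition_2": c2,
                "burst_fraction_t": t_bf.statistic,
                "burst_fraction_p": t_bf.pvalue,
            }
            if has_intensity:
                i1 = s1["mean_site_intensity"].dropna()
                i2 = s2["mean_site_intensity"].dropna()
                if len(i1) > 1 and len(i2) > 1:
                    t_in = stats.ttest_ind(i1, i2, equal_var=False)
                    rec["site_intensity_t"] = t_in.statistic
                    rec["site_intensity_p"] = t_in.pvalue
            tests.append(rec)
    return {"summary": summary, "tests": pd.DataFrame(tests)}


def lrt_genotype_effect(
    nuclei: pd.DataFrame,
    genotype_column: str = "genotype",
) -> dict:
    """Likelihood-ratio tests for a genotype effect on bursting.

    Counts: ``n_active_sites ~ ploidy`` with genotype-dependent slopes
    versus a shared slope.  Intensities: ``mean_site_intensity`` with
    genotype-dependent intercepts versus a single intercept.  Both are
    Gaussian fixed-effect models compared with chi-square(1) LRTs (the
    nested reduced model guarantees a non-negative statistic).

    Returns ``{"counts": {...}, "intensity": {...}}`` with the LRT
    statistic, p-value and per-genotype estimates.
    """
    df = nuclei.dropna(subset=["ploidy"]).copy()
    genotypes = list(dict.fromkeys(df[genotype_column]))
    if len(genotypes) != 2:
        raise ValueError("exactly two genotypes required")
    g = (df[genotype_column] == genotypes[1]).to_numpy(dtype=float)
    ploidy = df["ploidy"].to_numpy(dtype=float)
    sites = df["n_active_sites"].to_numpy(dtype=float)

    # Counts: slope-per-genotype (through the origin, slope = burst prob).
    X_full = np.column_stack([ploidy * (1 - g), ploidy * g])
    X_red = ploidy[:, None]
    lrt_counts, slopes = _gaussian_lrt(X_full, X_red, sites)
    counts_res = {
        "lrt": lrt_counts,
        "pvalue": float(stats.chi2.sf(lrt_counts, df=1)),
        "slopes": dict(zip(genotypes, slopes)),
    }

    intensity_res = None
    if "mean_site_intensity" in df:
        sub = df.dropna(subset=["mean_site_intensity"])
        if len(sub) > 3 and sub[genotype_column].nunique() == 2:
            gi = (sub[genotype_column] == genotypes[1]).to_numpy(dtype=float)
            inten = sub["mean_site_intensity"].to_numpy(dtype=float)
            X_full = np.column_stack([1 - gi, gi])
            X_red = np.ones((len(sub), 1))
            lrt_inten, intercepts = _gaussian_lrt(X_full, X_red, inten)
            intensity_res = {
                "lrt": lrt_inten,
                "pvalue": float(stats.chi2.sf(lrt_inten, df=1)),
                "intercepts": dict(zip(genotypes, intercepts)),
            }
    return {"counts": counts_res, "intensity": intensity_res}


def _gaussian_lrt(
    X_full: np.ndarray, X_reduced: np.ndarray, y: np.ndarray
) -> tuple[float, np.ndarray]:
    """2*(ll_full - ll_reduced) for nested Gaussian linear models."""
    n = y.size

    def rss(X: np.ndarray) -> tuple[float, np.ndarray]:
        beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r), beta

    rss_f, beta_f = rss(X_full)
    rss_r, _ = rss(X_reduced)
    rss_f = max(rss_f, 1e-300)
    lrt = n * np.log(max(rss_r, rss_f) / rss_f)
    return float(max(lrt, 0.0)), beta_f
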