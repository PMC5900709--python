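"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators are provided:

* :func:`simulate_4c` — negative-binomial 4C-seq end counts around a
  bait with power-law distance decay, an optional rhythmic Gaussian
  "loop" bump and replicate dropout;
* :func:`simulate_fish_nuclei` — nuclei whose diameters follow a
  4-component Gaussian mixture and whose alleles burst binomially, with
  optional rendering of image Z-stacks;
* :func:`simulate_actogram` — square-wave locomotor-activity traces of
  known period in Poisson counts.

Every generator returns the noiseless ground truth alongside the
samples, and fixing the seed reproduces outputs bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fourc_prep import CountMatrix, annotate_bait, mask_bait_adjacent, score_fragments

__all__ = [
    "FourCSimConfig",
    "FourCGroundTruth",
    "FishSimConfig",
    "ActogramSimConfig",
    "ActivityTrace",
    "simulate_4c",
    "simulate_fish_nuclei",
    "render_spot_stack",
    "render_nuclei_image",
    "simulate_actogram",
]


# ---------------------------------------------------------------------------
# 4C-seq
# ---------------------------------------------------------------------------

@dataclass
class FourCSimConfig:
    """Parameters of the synthetic 4C-seq contact profile.

    The per-end mean at fragment midpoint ``x`` and time ``t`` is::

        mu(x, t) = background_rate
                 + decay_amp * (max(|x - bait|, mean_fragment_length) / decay_ref) ** -decay_exponent
                 + loop_base_amp * exp(-(x - loop_center)**2 / (2 * loop_sigma**2))
                   * (1 + rhythm_relamp * cos(2*pi*(t - rhythm_peaktime)/24))

    Counts per fragment end are negative-binomial with this mean and
    shape ``nb_dispersion`` (Poisson in the ``inf`` limit); each
    (fragment, sample) is zeroed with probability ``dropout_prob``.
    Fragment boundaries are drawn as a Poisson process with mean spacing
    ``mean_fragment_length`` (the in-silico digestion statistics of a
    4-cutter on random sequence, without materializing the sequence).
    """

    chrom_length: int = 2_000_000
    bait_pos: int = 1_000_000
    decay_exponent: float = 1.0
    decay_amp: float = 0.0  # mean reads/end contributed at decay_ref from the bait
    decay_ref: float = 10_000.0
    background_rate: float = 50.0
    loop_center: int = 1_050_000
    loop_sigma: float = 5_000.0
    loop_base_amp: float = 0.0
    rhythm_relamp: float = 0.0
    rhythm_peaktime: float = 20.0
    timepoints: tuple[float, ...] = (0.0, 4.0, 8.0, 12.0, 16.0, 20.0)
    n_replicates: int = 4
    dropout_prob: float = 0.0
    nb_dispersion: float = 10.0
    mean_fragment_length: float = 256.0
    chrom: str = "chrS"
    seed: int = 0

    def validate(self) -> None:
        if self.loop_sigma <= 0:
            raise ValueError("loop_sigma must be > 0")
        if self.decay_exponent <= 0:
            raise ValueError("decay_exponent must be > 0")
        if not 0.0 <= self.rhythm_relamp <= 1.0:
            raise ValueError("rhythm_relamp must be in [0, 1]")
        if not 0.0 <= self.dropout_prob < 1.0:
            raise ValueError("dropout_prob must be in [0, 1)")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if min(self.background_rate, self.decay_amp, self.loop_base_amp) < 0:
            raise ValueError("rates and amplitudes must be non-negative")
        if not 0 <= self.bait_pos < self.chrom_length:
            raise ValueError("bait_pos must lie on the chromosome")


@dataclass
class FourCGroundTruth:
    """Noiseless mean surface behind a simulated 4C dataset."""

    fragments: pd.DataFrame
    timepoints: np.ndarray
    mean: np.ndarray  # per-end mean, shape (n_fragments, n_timepoints)
    config: FourCSimConfig

    def mean_at(self, time: float) -> np.ndarray:
        idx = int(np.flatnonzero(np.isclose(self.timepoints, time))[0])
        return self.mean[:, idx]


def _draw_fragments(cfg: FourCSimConfig, rng: np.random.Generator) -> pd.DataFrame:
    n_expect = int(np.ceil(2.0 * cfg.chrom_length / cfg.mean_fragment_length)) + 16
    gaps = rng.exponential(cfg.mean_fragment_length, size=n_expect)
    cuts = np.unique(np.floor(np.cumsum(gaps)).astype(np.int64))
    cuts = cuts[(cuts > 0) & (cuts < cfg.chrom_length)]
    bounds = np.concatenate([[0], cuts, [cfg.chrom_length]])
    return pd.DataFrame(
        {
            "fragment_id": np.arange(len(bounds) - 1),
            "chrom": cfg.chrom,
            "start": bounds[:-1],
            "end": bounds[1:],
        }
    )


def mean_surface(
    cfg: FourCSimConfig, positions: np.ndarray, times: np.ndarray
) -> np.ndarray:
    """Noiseless per-end mean for fragment midpoints x timepoints."""
    positions = np.asarray(positions, dtype=float)[:, None]
    times = np.asarray(times, dtype=float)[None, :]
    dist = np.abs(positions - cfg.bait_pos)
    dist = np.maximum(dist, cfg.mean_fragment_length)  # truncate at one fragment
    decay = cfg.decay_amp * (dist / cfg.decay_ref) ** (-cfg.decay_exponent)
    loop_shape = np.exp(-((positions - cfg.loop_center) ** 2) / (2.0 * cfg.loop_sigma**2))
    modulation = 1.0 + cfg.rhythm_relamp * np.cos(
        2.0 * np.pi * (times - cfg.rhythm_peaktime) / 24.0
    )
    mu = cfg.background_rate + decay + cfg.loop_base_amp * loop_shape * modulation
    if np.any(mu < 0):
        raise ValueError("configuration produces negative mean counts")
    return mu


def _nb_counts(
    rng: np.random.Generator, mu: np.ndarray, dispersion: float
) -> np.ndarray:
    if np.isinf(dispersion):
        return rng.poisson(mu)
    p = dispersion / (dispersion + mu)
    return rng.negative_binomial(dispersion, p)


def simulate_4c(cfg: FourCSimConfig) -> tuple[CountMatrix, FourCGroundTruth]:
    """Simulate a bait-anchored 4C-seq count matrix with ground truth.

    Returns a bait-annotated, bait-masked :class:`CountMatrix` (raw
    scores; call :func:`rhythm4c.fourc_prep.normalize_library` for
    normalized scores) and the :class:`FourCGroundTruth` mean surface.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    frags = _draw_fragments(cfg, rng)
    mids = ((frags["start"] + frags["end"]) / 2.0).to_numpy()
    times = np.asarray(cfg.timepoints, dtype=float)
    mu = mean_surface(cfg, mids, times)

    sample_rows = []
    count_frames = []
    n_frag = len(frags)
    for j, t in enumerate(times):
        for r in range(1, cfg.n_replicates + 1):
            sample_id = f"ZT{t:04.1f}_rep{r}"
            sample_rows.append((sample_id, f"ZT{t:g}", t, r))
            end1 = _nb_counts(rng, mu[:, j], cfg.nb_dispersion)
            end2 = _nb_counts(rng, mu[:, j], cfg.nb_dispersion)
            if cfg.dropout_prob > 0:
                drop = rng.random(n_frag) < cfg.dropout_prob
                end1 = np.where(drop, 0, end1)
                end2 = np.where(drop, 0, end2)
            count_frames.append(
                pd.DataFrame(
                    {
                        "fragment_id": frags["fragment_id"],
                        "sample_id": sample_id,
                        "end1": end1,
                        "end2": end2,
                    }
                )
            )
    counts = score_fragments(pd.concat(count_frames, ignore_index=True))
    samples = pd.DataFrame(
        sample_rows, columns=["sample_id", "condition", "time", "replicate"]
    )
    frags = annotate_bait(frags, cfg.chrom, cfg.bait_pos)
    cm = CountMatrix(
        fragments=frags,
        counts=counts,
        samples=samples,
        bait_chrom=cfg.chrom,
        bait_pos=cfg.bait_pos,
    )
    cm = mask_bait_adjacent(cm)
    truth = FourCGroundTruth(
        fragments=cm.fragments, timepoints=times, mean=mu, config=cfg
    )
    return cm, truth


# ---------------------------------------------------------------------------
# smRNA-FISH nuclei
# ---------------------------------------------------------------------------

DEFAULT_DIAMETER_MEANS = (7.0, 9.5, 12.5, 17.0)  # 2N, 4N, 8N, outliers (um)
DEFAULT_DIAMETER_SDS = (0.7, 0.8, 1.0, 2.5)
DEFAULT_MIXING_PROPS = (0.40, 0.35, 0.20, 0.05)


@dataclass
class FishSimConfig:
    """Parameters for synthetic smRNA-FISH nucleus populations.

    Diameters follow a 4-component Gaussian mixture (2N, 4N, 8N plus a
    broad outlier component); each allele of a nucleus bursts
    independently with the condition's ``burst_prob_per_allele``, and
    active-site intensities are log-normal with the given natural-scale
    mean and sd.
    """

    n_nuclei: int = 1000
    diameter_means: tuple[float, ...] = DEFAULT_DIAMETER_MEANS
    diameter_sds: tuple[float, ...] = DEFAULT_DIAMETER_SDS
    mixing_props: tuple[float, ...] = DEFAULT_MIXING_PROPS
    burst_prob_per_allele: dict[str, float] = field(
        default_factory=lambda: {"WT": 0.2}
    )
    site_intensity_mean: float = 100.0
    site_intensity_sd: float = 40.0
    image_shape: tuple[int, int] = (256, 256)
    n_slices: int = 12
    psf_sigma: float = 1.2
    pixel_size: float = 0.103  # um per pixel
    seed: int = 0

    def validate(self) -> None:
        if len(self.diameter_means) != 4 or len(self.diameter_sds) != 4:
            raise ValueError("diameter_means and diameter_sds need 4 components")
        if len(self.mixing_props) != 4:
            raise ValueError("mixing_props needs 4 components")
        if abs(sum(self.mixing_props) - 1.0) > 1e-9:
            raise ValueError("mixing_props must sum to 1")
        for cond, p in self.burst_prob_per_allele.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"burst probability for {cond!r} outside [0, 1]")
        if self.n_nuclei < 1:
            raise ValueError("n_nuclei must be >= 1")


_PLOIDY_OF_COMPONENT = {0: 2, 1: 4, 2: 8, 3: 8}  # outliers behave like 8N


def simulate_fish_nuclei(cfg: FishSimConfig) -> pd.DataFrame:
    """Draw nuclei with known ploidy, diameter, burst state and intensities.

    Returns one row per nucleus: ``condition, nucleus_id,
    true_component, true_ploidy, diameter, n_active_sites,
    site_intensities (list), mean_site_intensity``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    log_sigma2 = np.log1p(cfg.site_intensity_sd**2 / cfg.site_intensity_mean**2)
    log_mu = np.log(cfg.site_intensity_mean) - log_sigma2 / 2.0
    log_sigma = np.sqrt(log_sigma2)

    rows = []
    for cond, p_burst in cfg.burst_prob_per_allele.items():
        comps = rng.choice(4, size=cfg.n_nuclei, p=np.asarray(cfg.mixing_props))
        diam = rng.normal(
            np.take(cfg.diameter_means, comps), np.take(cfg.diameter_sds, comps)
        )
        for i in range(cfg.n_nuclei):
            ploidy = _PLOIDY_OF_COMPONENT[int(comps[i])]
            n_active = int(rng.binomial(ploidy, p_burst))
            intens = rng.lognormal(log_mu, log_sigma, size=n_active)
            rows.append(
                {
                    "condition": cond,
                    "nucleus_id": f"{cond}_{i}",
                    "true_component": int(comps[i]),
                    "true_ploidy": ploidy,
                    "diameter": float(diam[i]),
                    "n_active_sites": n_active,
                    "site_intensities": list(np.round(intens, 6)),
                    "mean_site_intensity": float(intens.mean()) if n_active else np.nan,
                }
            )
    return pd.DataFrame(rows)


def render_spot_stack(
    shape: tuple[int, int],
    n_slices: int,
    spots: pd.DataFrame,
    psf_sigma: float = 1.2,
    z_sigma: float = 1.5,
    background: float = 10.0,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """Render point sources as 3-D Gaussian spots in a Z-stack.

    ``spots`` needs columns ``y, x, z, intensity`` (total integrated
    signal per spot).  Returns a float ``(n_slices, *shape)`` array.
    """
    rng = np.random.default_rng(seed)
    stack = np.full((n_slices, *shape), background, dtype=float)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    for _, s in spots.iterrows():
        lateral = np.exp(
            -((yy - s["y"]) ** 2 + (xx - s["x"]) ** 2) / (2.0 * psf_sigma**2)
        ) / (2.0 * np.pi * psf_sigma**2)
        axial = np.exp(
            -((np.arange(n_slices) - s["z"]) ** 2) / (2.0 * z_sigma**2)
        )
        axial = axial / axial.sum()
        stack += s["intensity"] * axial[:, None, None] * lateral[None, :, :]
    if noise_sd > 0:
        stack += rng.normal(0.0, noise_sd, size=stack.shape)
    return stack


def render_nuclei_image(
    shape: tuple[int, int],
    centers: np.ndarray,
    radii: np.ndarray,
    intensity: float = 100.0,
    noise_sd: float = 2.0,
    seed: int = 0,
) -> np.ndarray:
    """Render nuclei as filled discs in a 2-D counterstain image."""
    rng = np.random.default_rng(seed)
    img = np.zeros(shape, dtype=float)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    for (cy, cx), r in zip(np.atleast_2d(centers), np.atleast_1d(radii)):
        img[(yy - cy) ** 2 + (xx - cx) ** 2 <= r**2] = intensity
    if noise_sd > 0:
        img += rng.normal(0.0, noise_sd, size=shape)
    return img


# ---------------------------------------------------------------------------
# Actograms
# ---------------------------------------------------------------------------

@dataclass
class ActogramSimConfig:
    """Square-wave locomotor-activity simulation of known period."""

    true_period: float = 23.75  # hours
    n_days: int = 21
    bin_minutes: int = 5
    active_fraction: float = 0.5
    active_rate: float = 10.0  # mean counts/bin during activity
    noise_rate: float = 0.0  # mean counts/bin during rest
    seed: int = 0

    def validate(self) -> None:
        if 60 % self.bin_minutes != 0:
            raise ValueError("bin_minutes must divide 60")
        if not 0.0 < self.active_fraction <= 1.0:
            raise ValueError("active_fraction must be in (0, 1]")
        if self.true_period <= 0:
            raise ValueError("true_period must be positive")
        if self.active_rate < 0 or self.noise_rate < 0:
            raise ValueError("rates must be non-negative")


@dataclass
class ActivityTrace:
    """Binned locomotor counts with sampling interval metadata."""

    counts: np.ndarray
    bin_minutes: int
    regime: str = "DD"

    @property
    def hours(self) -> np.ndarray:
        return np.arange(self.counts.size) * self.bin_minutes / 60.0

    @property
    def duration_hours(self) -> float:
        return self.counts.size * self.bin_minutes / 60.0


def simulate_actogram(cfg: ActogramSimConfig) -> tuple[ActivityTrace, np.ndarray]:
    """Poisson activity counts on a square-wave rate of known period.

    The rate is ``active_rate`` during the last ``active_fraction`` of
    each cycle ("subjective night") and ``noise_rate`` otherwise.
    Returns the trace and the noiseless rate per bin.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n_bins = cfg.n_days * 24 * 60 // cfg.bin_minutes
    t = np.arange(n_bins) * cfg.bin_minutes / 60.0
    phase = (t % cfg.true_period) / cfg.true_period
    active = phase >= 1.0 - cfg.active_fraction
    rate = np.where(active, cfg.active_rate, cfg.noise_rate)
    counts = rng.poisson(rate)
    return ActivityTrace(counts=counts, bin_minutes=cfg.bin_minutes), rate
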