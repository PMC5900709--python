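"""Organism-level circadian statistics.

Chi-square periodogram period estimation from binned locomotor traces,
genotype period comparison, and expression-phase analysis: per-gene
harmonic regression, circular phase differences between genotypes, a
sign/binomial test for systematic phase advances and a replicate
bootstrap for per-gene phase shifts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .harmonics import circular_phase_difference, cosinor_test
from .synthgen import ActivityTrace

__all__ = [
    "PeriodEstimate",
    "chi2_periodogram",
    "compare_periods",
    "expression_phases",
    "phase_advance_binomial",
    "phase_bootstrap",
]


@dataclass
class PeriodEstimate:
    """Chi-square periodogram over a grid of candidate periods."""

    periods: np.ndarray  # hours
    qp: np.ndarray  # Sokolove-Bushell statistic per period
    significance: np.ndarray  # chi-square quantile line per period
    best_period: float | None  # argmax of qp above the line, hours

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"period": self.periods, "qp": self.qp, "significance": self.significance}
        )


def chi2_periodogram(
    trace: ActivityTrace | np.ndarray,
    min_period: float = 20.0,
    max_period: float = 28.0,
    bin_minutes: int | None = None,
    alpha: float = 0.001,
) -> PeriodEstimate:
    """Sokolove-Bushell chi-square periodogram on a binned activity trace.

    For each candidate period of ``P`` bins (the grid step equals the
    bin resolution) the trace is folded into ``K = floor(N/P)`` complete
    rows and ``Qp = K * N * sum_h (M_h - M)^2 / sum_i (x_i - M)^2`` is
    computed from the column means ``M_h``; under a flat null ``Qp`` is
    approximately chi-square with ``P - 1`` degrees of freedom.  The
    best period is the grid maximum of ``Qp`` above the
    ``1 - alpha`` chi-square quantile line (None when nothing clears
    it, e.g. white noise or a constant trace).
    """
    if isinstance(trace, ActivityTrace):
        counts = np.asarray(trace.counts, dtype=float)
        bin_minutes = trace.bin_minutes
    else:
        counts = np.asarray(trace, dtype=float)
        if bin_minutes is None:
            raise ValueError("bin_minutes required for a bare array")
    bins_per_hour = 60.0 / bin_minutes
    p_lo = int(np.ceil(min_period * bins_per_hour))
    p_hi = int(np.floor(max_period * bins_per_hour))
    if counts.size < 2 * p_hi:
        raise ValueError("trace must span at least two cycles of the longest period")
    total_var = float(((counts - counts.mean()) ** 2).sum())

    periods, qps, lines = [], [], []
    for p_bins in range(p_lo, p_hi + 1):
        k = counts.size // p_bins
        folded = counts[: k * p_bins].reshape(k, p_bins)
        col_means = folded.mean(axis=0)
        grand = folded.mean()
        num = k * counts.size * float(((col_means - grand) ** 2).sum())
        qp = num / total_var if total_var > 0 else 0.0
        periods.append(p_bins / bins_per_hour)
        qps.append(qp)
        lines.append(float(stats.chi2.ppf(1.0 - alpha, df=p_bins - 1)))
    periods = np.asarray(periods)
    qps = np.asarray(qps)
    lines = np.asarray(lines)
    above = qps - lines
    best = float(periods[np.argmax(above)]) if np.any(above > 0) else None
    # among significant periods pick the global Qp maximum
    if best is not None:
        sig = above > 0
        best = float(periods[np.flatnonzero(sig)[np.argmax(qps[sig])]])
    return PeriodEstimate(periods=periods, qp=qps, significance=lines, best_period=best)


def compare_periods(
    periods_a: np.ndarray, periods_b: np.ndarray
) -> dict[str, float]:
    """Two-sample t-test on per-animal period estimates.

    Returns the group means (hours), their difference ``a - b`` in
    minutes, and the two-sided t-test p-value.
    """
    a = np.asarray(periods_a, dtype=float)
    b = np.asarray(periods_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 animals per group")
    res = stats.ttest_ind(a, b, equal_var=False)
    pvalue = float(res.pvalue)
    if a.std() == 0 and b.std() == 0:
        pvalue = 1.0 if a.mean() == b.mean() else 0.0
    return {
        "mean_a": float(a.mean()),
        "mean_b": float(b.mean()),
        "delta_minutes": float((a.mean() - b.mean()) * 60.0),
        "pvalue": pvalue,
    }


def expression_phases(
    expression: pd.DataFrame,
    meta: pd.DataFrame,
    genotype_column: str = "genotype",
    period: float = 24.0,
    rhythm_alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene, per-genotype harmonic regression on log expression.

    ``expression`` is gene x sample (values already on log scale or any
    scale appropriate for cosinor fitting); ``meta`` has one row per
    sample with ``time`` and the genotype column, indexed by or
    containing ``sample_id``.

    Returns one row per gene with per-genotype ``phase_<g>``,
    ``amplitude_<g>``, ``pvalue_<g>``, the circular phase difference
    ``delta_phase`` (second genotype minus first, hours in (-12, 12]),
    and ``rhythmic_both`` (both genotype fits below ``rhythm_alpha``).
    ``delta_phase`` is NaN for genes that are not rhythmic in both.
    """
    if "sample_id" in meta.columns:
        meta = meta.set_index("sample_id")
    meta = meta.loc[expression.columns]
    genotypes = list(dict.fromkeys(meta[genotype_column]))
    if len(genotypes) != 2:
        raise ValueError("exactly two genotypes required")

    rows = []
    for gene, values in expression.iterrows():
        row: dict = {"gene": gene}
        fits = {}
        for g in genotypes:
            cols = meta.index[meta[genotype_column] == g]
            t = meta.loc[cols, "time"].to_numpy(dtype=float)
            y = values[cols].to_numpy(dtype=float)
            fit = cosinor_test(t, y, period=period)
            fits[g] = fit
            row[f"phase_{g}"] = fit.phase
            row[f"amplitude_{g}"] = fit.amplitude
            row[f"pvalue_{g}"] = fit.pvalue
        rhythmic = all(fits[g].pvalue < rhythm_alpha for g in genotypes)
        row["rhythmic_both"] = rhythmic
        row["delta_phase"] = (
            circular_phase_difference(
                fits[genotypes[1]].phase, fits[genotypes[0]].phase, period
            )
            if rhythmic
            else np.nan
        )
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene")


def phase_advance_binomial(
    phase_table: pd.DataFrame,
    gene_set: list | None = None,
) -> dict[str, float]:
    """Sign/binomial test for a systematic phase advance.

    Counts rhythmic genes with negative circular ``delta_phase``
    (advance, mutant peaking earlier) against those with positive
    (delay) and tests the split against 0.5 with a two-sided binomial
    test.  Genes with ``delta_phase`` of exactly 0 or NaN are excluded.
    """
    df = phase_table
    if gene_set is not None:
        df = df.loc[df.index.intersection(gene_set)]
    d = df["delta_phase"].dropna()
    d = d[d != 0]
    if d.empty:
        raise ValueError("no rhythmic genes with a nonzero phase difference")
    n_advanced = int((d < 0).sum())
    res = stats.binomtest(n_advanced, len(d), p=0.5, alternative="two-sided")
    return {
        "n_genes": int(len(d)),
        "n_advanced": n_advanced,
        "n_delayed": int(len(d)) - n_advanced,
        "mean_delta_phase": float(d.mean()),
        "pvalue": float(res.pvalue),
    }


def phase_bootstrap(
    expression: pd.DataFrame,
    meta: pd.DataFrame,
    gene,
    genotype_column: str = "genotype",
    n_boot: int = 1000,
    period: float = 24.0,
    seed: int = 0,
) -> dict[str, float]:
    """Replicate bootstrap for a per-gene phase difference.

    Within each (genotype, timepoint) cell, samples are resampled with
    replacement; the circular phase difference is recomputed per
    resample and ``p = 2 * min(frac(delta* >= 0), frac(delta* <= 0))``.
    At least 100 bootstrap rounds are required.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    if "sample_id" in meta.columns:
        meta = meta.set_index("sample_id")
    meta = meta.loc[expression.columns]
    genotypes = list(dict.fromkeys(meta[genotype_column]))
    if len(genotypes) != 2:
        raise ValueError("exactly two genotypes required")
    values = expression.loc[gene]
    cells: dict[str, list[np.ndarray]] = {}
    for g in genotypes:
        sub = meta[meta[genotype_column] == g]
        groups = [sub.index[sub["time"] == t].to_numpy() for t in np.unique(sub["time"])]
        if any(len(c) < 2 for c in groups):
            raise ValueError("need >= 2 replicates per timepoint per genotype")
        cells[g] = groups

    rng = np.random.default_rng(seed)

    def one_phase(g: str, resample: bool) -> float:
        cols: list = []
        for cell in cells[g]:
            take = rng.choice(cell, size=len(cell), replace=True) if resample else cell
            cols.extend(take)
        t = meta.loc[cols, "time"].to_numpy(dtype=float)
        y = values[cols].to_numpy(dtype=float)
        return cosinor_test(t, y, period=period).phase

    observed = circular_phase_difference(
        one_phase(genotypes[1], False), one_phase(genotypes[0], False), period
    )
    deltas = np.array(
        [
            circular_phase_difference(
                one_phase(genotypes[1], True), one_phase(genotypes[0], True), period
            )
            for _ in range(n_boot)
        ]
    )
    frac_pos = float((deltas >= 0).mean())
    frac_neg = float((deltas <= 0).mean())
    pvalue = min(2.0 * min(frac_pos, frac_neg), 1.0)
    pvalue = max(pvalue, 2.0 / n_boot)
    return {
        "delta_phase": float(observed),
        "pvalue": float(pvalue),
        "n_boot": n_boot,
    }
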