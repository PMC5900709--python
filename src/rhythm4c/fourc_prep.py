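"""Restriction-fragment preparation and normalization of 4C-seq counts.

The pipeline is: in-silico digestion of the genome into restriction
fragments (:func:`digest_genome`), per-fragment scoring as the mean of
the two fragment-end read counts (:func:`score_fragments`), sample-level
QC on the fraction of empty fragments around the bait
(:func:`qc_sample`), masking of the bait fragment and its immediate
neighbours (:func:`mask_bait_adjacent`) and library-size rescaling on
the cis chromosome (:func:`normalize_library`).

Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FRAGMENT_COLUMNS",
    "CountMatrix",
    "digest_genome",
    "annotate_bait",
    "score_fragments",
    "qc_sample",
    "mask_bait_adjacent",
    "normalize_library",
    "cis_fraction",
]

FRAGMENT_COLUMNS = ["fragment_id", "chrom", "start", "end"]

DEFAULT_QC_WINDOW = 1_000_000
DEFAULT_MASK_K = 5


@dataclass
class CountMatrix:
    """Fragment-by-sample 4C-seq scores plus sample metadata.

    Attributes
    ----------
    fragments:
        Restriction-fragment table (``fragment_id, chrom, start, end``
        and, after :func:`annotate_bait` / :func:`mask_bait_adjacent`,
        ``distance_to_bait, is_bait, is_masked``).
    counts:
        Long table with one row per (fragment, sample):
        ``fragment_id, sample_id, end1, end2, score`` and, after
        :func:`normalize_library`, ``norm_score``.
    samples:
        One row per sample: ``sample_id`` plus free-form condition
        metadata (``condition``, ``time``, ``genotype``, ``replicate``).
    """

    fragments: pd.DataFrame
    counts: pd.DataFrame
    samples: pd.DataFrame
    bait_chrom: str | None = None
    bait_pos: int | None = None
    norm_factors: dict[str, float] = field(default_factory=dict)

    def copy(self) -> "CountMatrix":
        return CountMatrix(
            fragments=self.fragments.copy(),
            counts=self.counts.copy(),
            samples=self.samples.copy(),
            bait_chrom=self.bait_chrom,
            bait_pos=self.bait_pos,
            norm_factors=dict(self.norm_factors),
        )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.samples["sample_id"])

    def score_table(self, column: str = "score") -> pd.DataFrame:
        """Wide fragment x sample table of the requested score column."""
        return self.counts.pivot(
            index="fragment_id", columns="sample_id", values=column
        )


def digest_genome(
    sequences: dict[str, str] | str,
    site: str = "GATC",
) -> pd.DataFrame:
    """In-silico restriction digestion into a fragment map.

    Fragment boundaries are placed at every occurrence (start offset) of
    the recognition ``site``; the first fragment begins at 0 and the
    last ends at the sequence length, so fragments tile each chromosome
    exactly.  Overlapping motif occurrences are honoured.

    Parameters
    ----------
    sequences:
        Either ``{chrom: sequence}`` or a single sequence string (named
        ``"chr"``).  ``pyfaidx.Fasta`` objects work via their mapping
        interface.
    site:
        Non-degenerate DNA motif (default DpnII, ``GATC``).

    Returns
    -------
    DataFrame with columns ``fragment_id, chrom, start, end``.
    """
    site = site.upper()
    if not site or any(b not in "ACGT" for b in site):
        raise ValueError(f"restriction site must be a non-degenerate DNA motif, got {site!r}")
    if isinstance(sequences, str):
        sequences = {"chr": sequences}

    rows = []
    fragment_id = 0
    for chrom in sequences:
        seq = str(sequences[chrom]).upper()
        if not seq:
            raise ValueError(f"empty sequence for {chrom!r}")
        cuts = _find_motif(seq, site)
        if cuts.size == 0:
            warnings.warn(
                f"no {site!r} site on {chrom}; emitting a single whole-chromosome fragment",
                stacklevel=2,
            )
        bounds = np.concatenate([[0], cuts, [len(seq)]])
        bounds = np.unique(bounds)
        for start, end in zip(bounds[:-1], bounds[1:]):
            rows.append((fragment_id, chrom, int(start), int(end)))
            fragment_id += 1
    return pd.DataFrame(rows, columns=FRAGMENT_COLUMNS)


def _find_motif(seq: str, motif: str) -> np.ndarray:
    """Start offsets of all (possibly overlapping) motif occurrences."""
    hits = []
    pos = seq.find(motif)
    while pos != -1:
        hits.append(pos)
        pos = seq.find(motif, pos + 1)
    return np.asarray(hits, dtype=np.int64)


def annotate_bait(
    fragments: pd.DataFrame,
    bait_chrom: str,
    bait_pos: int,
) -> pd.DataFrame:
    """Mark the bait fragment and record signed distances to it.

    ``distance_to_bait`` is midpoint-to-midpoint, in bp, signed (negative
    upstream of the bait), and NaN on trans chromosomes.
    """
    frags = fragments.copy()
    on_cis = frags["chrom"] == bait_chrom
    hit = on_cis & (frags["start"] <= bait_pos) & (bait_pos < frags["end"])
    if not hit.any():
        raise ValueError(f"bait position {bait_chrom}:{bait_pos} not covered by any fragment")
    bait_mid = frags.loc[hit, ["start", "end"]].mean(axis=1).iloc[0]
    mid = (frags["start"] + frags["end"]) / 2.0
    frags["distance_to_bait"] = np.where(on_cis, mid - bait_mid, np.nan)
    frags["is_bait"] = hit
    return frags


def score_fragments(end_counts: pd.DataFrame) -> pd.DataFrame:
    """Per-fragment score: mean of the two fragment-end read counts.

    Each restriction fragment carries two mapping sites (its ends); the
    fragment score ``c`` is ``(end1 + end2) / 2``.  Missing end counts
    are treated as 0 (dropout).
    """
    counts = end_counts.copy()
    for col in ("end1", "end2"):
        if col not in counts:
            raise ValueError(f"end_counts must have an {col!r} column")
        counts[col] = counts[col].fillna(0)
        if (counts[col] < 0).any():
            raise ValueError("negative end counts are not allowed")
    counts["score"] = (counts["end1"] + counts["end2"]) / 2.0
    return counts


def qc_sample(
    cm: CountMatrix,
    window: int = DEFAULT_QC_WINDOW,
    zero_threshold: float = 0.75,
) -> pd.DataFrame:
    """Per-sample QC on empty-fragment fraction around the bait.

    A sample fails when the fraction of fragments with zero score inside
    ``bait +/- window`` is at or above ``zero_threshold`` (>= 75% by
    default; the boundary counts as failing).

    Returns one row per sample: ``sample_id, zero_fraction, pass``.
    """
    frags = _require_bait(cm)
    mid = (frags["start"] + frags["end"]) / 2.0
    in_window = (
        (frags["chrom"] == cm.bait_chrom)
        & (np.abs(mid - cm.bait_pos) <= window)
    )
    window_ids = frags.loc[in_window, "fragment_id"]
    if window_ids.empty:
        raise ValueError("no fragments inside the QC window around the bait")
    sub = cm.counts[cm.counts["fragment_id"].isin(window_ids)]
    rows = []
    for sample_id in cm.sample_ids:
        scores = sub.loc[sub["sample_id"] == sample_id, "score"]
        n = len(window_ids)  # fragments with no row at all count as zero
        n_zero = n - int((scores > 0).sum())
        zero_fraction = n_zero / n
        rows.append((sample_id, zero_fraction, zero_fraction < zero_threshold))
    return pd.DataFrame(rows, columns=["sample_id", "zero_fraction", "pass"])


def mask_bait_adjacent(cm: CountMatrix, k: int = DEFAULT_MASK_K) -> CountMatrix:
    """Flag the bait fragment and its ``k`` nearest neighbours per side.

    The flagged fragments (``is_masked``) are excluded from
    normalization and from all downstream fits; with the default
    ``k = 5`` this masks 10 fragments plus the bait itself for an
    interior bait.  Near a chromosome edge only the existing fragments
    are masked (with a warning).
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    out = cm.copy()
    frags = _require_bait(out)
    frags = frags.sort_values(["chrom", "start"]).reset_index(drop=True)
    bait_idx = int(np.flatnonzero(frags["is_bait"].to_numpy())[0])
    chrom = frags.loc[bait_idx, "chrom"]
    same = np.flatnonzero((frags["chrom"] == chrom).to_numpy())
    lo, hi = same.min(), same.max()
    n_up = bait_idx - max(lo, bait_idx - k)
    n_down = min(hi, bait_idx + k) - bait_idx
    if n_up < k or n_down < k:
        warnings.warn(
            f"bait within {k} fragments of a chromosome edge; masking {n_up}+{n_down} neighbours",
            stacklevel=2,
        )
    masked = np.zeros(len(frags), dtype=bool)
    masked[bait_idx - n_up : bait_idx + n_down + 1] = True
    frags["is_masked"] = masked
    out.fragments = frags
    return out


def normalize_library(cm: CountMatrix) -> CountMatrix:
    """Library-size rescaling on the cis chromosome.

    Each sample's scores are multiplied by
    ``mean_over_samples(cis_sum) / cis_sum(sample)``, where ``cis_sum``
    is the total score on the bait chromosome excluding masked
    fragments; afterwards every sample has the same (unmasked) cis sum.
    Rank order within a sample is preserved.
    """
    out = cm.copy()
    frags = _require_bait(out)
    if "is_masked" not in frags:
        raise ValueError("call mask_bait_adjacent before normalize_library")
    cis_ids = frags.loc[(frags["chrom"] == out.bait_chrom) & ~frags["is_masked"], "fragment_id"]
    sub = out.counts[out.counts["fragment_id"].isin(cis_ids)]
    cis_sums = sub.groupby("sample_id")["score"].sum().reindex(out.sample_ids)
    if cis_sums.isna().any() or (cis_sums <= 0).any():
        bad = cis_sums.index[cis_sums.isna() | (cis_sums <= 0)].tolist()
        raise ValueError(f"zero or missing cis-chromosome signal for samples {bad}")
    target = float(cis_sums.mean())
    factors = target / cis_sums
    out.norm_factors = factors.to_dict()
    out.counts = out.counts.copy()
    out.counts["norm_score"] = out.counts["score"] * out.counts["sample_id"].map(factors)
    return out


def cis_fraction(
    cm: CountMatrix,
    window: int = DEFAULT_QC_WINDOW,
    column: str = "norm_score",
) -> pd.Series:
    """Fraction of cis-chromosome signal within ``bait +/- window``.

    Both numerator and denominator exclude masked fragments.  Indexed by
    sample_id.
    """
    frags = _require_bait(cm)
    if "is_masked" not in frags:
        raise ValueError("call mask_bait_adjacent before cis_fraction")
    if column not in cm.counts:
        raise ValueError(f"counts table lacks column {column!r}")
    cis = frags[(frags["chrom"] == cm.bait_chrom) & ~frags["is_masked"]]
    mid = (cis["start"] + cis["end"]) / 2.0
    in_window = np.abs(mid - cm.bait_pos) <= window
    cis_ids = set(cis["fragment_id"])
    win_ids = set(cis.loc[in_window, "fragment_id"])
    sub = cm.counts[cm.counts["fragment_id"].isin(cis_ids)]
    denom = sub.groupby("sample_id")[column].sum()
    num = (
        sub[sub["fragment_id"].isin(win_ids)]
        .groupby("sample_id")[column]
        .sum()
        .reindex(denom.index, fill_value=0.0)
    )
    if (denom <= 0).any():
        raise ValueError("zero cis signal for at least one sample")
    frac = (num / denom).reindex(cm.sample_ids)
    frac.name = "cis_fraction"
    return frac


def _require_bait(cm: CountMatrix) -> pd.DataFrame:
    if cm.bait_chrom is None or cm.bait_pos is None or "is_bait" not in cm.fragments:
        raise ValueError("CountMatrix has no bait annotation; call annotate_bait first")
    return cm.fragments
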