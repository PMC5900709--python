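from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from rhythm4c.fourc_prep import (
    CountMatrix,
    annotate_bait,
    mask_bait_adjacent,
    score_fragments,
)


def build_count_matrix(
    scores: np.ndarray,
    fragment_length: int = 1000,
    chrom: str = "chr1",
    bait_index: int | None = None,
    sample_meta: pd.DataFrame | None = None,
    mask: bool = True,
) -> CountMatrix:
    """Assemble a CountMatrix from a fragment x sample score array.

    Fragments are contiguous equal-length intervals; end counts are set
    to the score on both ends (so score == (end1+end2)/2 holds exactly).
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    n_frag, n_samp = scores.shape
    frags = pd.DataFrame(
        {
            "fragment_id": np.arange(n_frag),
            "chrom": chrom,
            "start": np.arange(n_frag) * fragment_length,
            "end": (np.arange(n_frag) + 1) * fragment_length,
        }
    )
    if sample_meta is None:
        sample_meta = pd.DataFrame(
            {
                "sample_id": [f"s{k}" for k in range(n_samp)],
                "condition": [f"c{k}" for k in range(n_samp)],
                "replicate": 1,
            }
        )
    records = []
    for k, sid in enumerate(sample_meta["sample_id"]):
        records.append(
            pd.DataFrame(
                {
                    "fragment_id": frags["fragment_id"],
                    "sample_id": sid,
                    "end1": scores[:, k],
                    "end2": scores[:, k],
                }
            )
        )
    counts = score_fragments(pd.concat(records, ignore_index=True))
    bait_pos = None
    bait_chrom = None
    if bait_index is not None:
        bait_pos = bait_index * fragment_length + fragment_length // 2
        bait_chrom = chrom
        frags = annotate_bait(frags, chrom, bait_pos)
    cm = CountMatrix(
        fragments=frags,
        counts=counts,
        samples=sample_meta,
        bait_chrom=bait_chrom,
        bait_pos=bait_pos,
    )
    if bait_index is not None and mask:
        cm = mask_bait_adjacent(cm)
    return cm


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240905)
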