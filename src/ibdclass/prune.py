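"""Pruning of strong normal-tissue discriminator genes.

Normal-tissue biopsies in the two diseases come predominantly from
different gut segments (terminal ileum in Crohn's disease, rectum in
ulcerative colitis), so the genes that best separate normal CD from normal
UC largely track anatomy rather than disease. Removing the top-scoring
fraction of the pruning statistic before fitting the inflamed-tissue
classifier strips this confound from the feature set.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

__all__ = ["prune_top_fraction"]


def prune_top_fraction(scores: pd.Series, fraction: float) -> list[str]:
    """Drop the top ``floor(fraction * n)`` genes by pruning score.

    Scores are sorted descending with ties broken by gene identifier
    (lexicographic, ascending); the kept genes are returned in their
    original matrix order. ``fraction`` must lie in [0, 1): pruning
    everything would empty the gene universe.
    """
    if len(scores) == 0:
        raise ValueError("scores must be non-empty")
    if not (0.0 <= fraction < 1.0):
        raise ValueError(f"fraction must be in [0, 1), got {fraction}")
    if (scores.to_numpy(float) < 0).any():
        raise ValueError("pruning scores must be non-negative")
    n_remove = math.floor(fraction * len(scores))
    order = sorted(scores.index, key=lambda g: (-float(scores[g]), str(g)))
    removed = set(order[:n_remove])
    return [g for g in scores.index if g not in removed]
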