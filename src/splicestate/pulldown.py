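"""RNA pull-down proteomics normalization and enrichment filtering.

Identifies proteins enriched for binding the bait RNA from LC-MS intensity
tables with two bait (target) pull-down replicates, a scramble-RNA control,
and an empty-beads control.  Intensities are normalized to each sample's
total; a protein is enriched when it has at least one unique peptide in
both target replicates and its minimum log2 ratio of normalized target
intensity over each control exceeds 2 (i.e. >4-fold over both the scramble
and the beads pull-down, for the weaker target replicate).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["normalize_total", "enrich_filter"]

TARGET_COLS = ("intensity_target1", "intensity_target2")
CONTROL_COLS = ("intensity_scramble", "intensity_beads")
PEPTIDE_COLS = ("peptides_target1", "peptides_target2")
LOG2_THRESHOLD = 2.0


def normalize_total(table: pd.DataFrame, intensity_cols=None) -> pd.DataFrame:
    """Divide each intensity column by its sample total (columns sum to 1)."""
    out = table.copy()
    cols = intensity_cols or [c for c in table.columns if c.startswith("intensity_")]
    for c in cols:
        total = float(table[c].sum())
        if total <= 0:
            raise ValueError(f"sample column {c!r} has zero total intensity")
        out[c] = table[c] / total
    return out


def enrich_filter(
    normalized: pd.DataFrame,
    target_cols=TARGET_COLS,
    control_cols=CONTROL_COLS,
    peptide_cols=PEPTIDE_COLS,
    threshold: float = LOG2_THRESHOLD,
    use_mean: bool = False,
) -> pd.DataFrame:
    """Apply the enrichment filter to a normalized intensity table.

    The ratio statistic is min over controls of log2(target / control) using
    the per-replicate minimum target intensity (``use_mean=True`` switches
    both reductions to means).  Zero control intensities are floored to the
    smallest nonzero normalized value in that control column before taking
    logs.  Adds columns ``min_log2_ratio`` and ``enriched``.
    """
    out = normalized.copy()
    tgt = out[list(target_cols)].to_numpy(dtype=float)
    ctl = out[list(control_cols)].to_numpy(dtype=float)
    for j, c in enumerate(control_cols):
        col = ctl[:, j]
        nonzero = col[col > 0]
        if nonzero.size == 0:
            raise ValueError(f"control column {c!r} is all zero")
        ctl[:, j] = np.where(col > 0, col, nonzero.min())
    tgt_stat = tgt.mean(axis=1) if use_mean else tgt.min(axis=1)
    with np.errstate(divide="ignore"):
        ratios = np.log2(tgt_stat[:, None] / ctl)
    min_ratio = ratios.mean(axis=1) if use_mean else ratios.min(axis=1)
    peptides_ok = (out[list(peptide_cols)].to_numpy(dtype=float) >= 1).all(axis=1)
    out["min_log2_ratio"] = min_ratio
    out["enriched"] = peptides_ok & (min_ratio > threshold)
    return out
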