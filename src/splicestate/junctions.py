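"""U2 snRNP junction-residency scoring and eCLIP count normalization.

Crosslinking-IP coverage around every 3' intron-exon junction is binned into
100 bins of 10 bp spanning 500 bp on each side of the splice site, oriented
5'->3' in transcript direction (bins 0-49 intron side, 50-99 exon side).
The residency score is -log10 of the minimum strict-tail Poisson p-value
over the 5 intron-side bins adjacent to the junction (bins 45-49), with the
per-bin expectation taken as the maximum of the window's intron-side mean,
exon-side mean, and the global all-junction mean bin count.

The eCLIP enrichment survey quantile-normalizes per-entry read counts across
experiments and computes fold enrichment against the more conservative of a
matched control and the mean of all controls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .tracks import CoverageTrack

__all__ = [
    "bin_junction",
    "residency_score",
    "score_junctions",
    "quantile_normalize",
    "fold_enrichment",
    "ResidencyModel",
    "N_BINS",
    "BIN_BP",
    "JUNCTION_BINS",
]

N_BINS = 100
BIN_BP = 10
FLANK = N_BINS * BIN_BP // 2  # 500 bp each side
JUNCTION_BINS = slice(45, 50)  # 5 intron-side bins adjacent to the 3' splice site
_TINY = np.nextafter(0.0, 1.0)


def bin_junction(track: CoverageTrack, chrom: str, pos: int, strand: str = "+") -> np.ndarray:
    """Bin coverage around a 3' splice site into 100 x 10 bp bins.

    ``pos`` is the 3' splice-site coordinate; the window is
    [pos - 500, pos + 500).  For minus-strand junctions the bin vector is
    reversed so that bins run 5'->3' in transcript orientation (intron side
    first).  Returns None if the window falls off the contig.
    """
    if chrom not in track.data:
        raise KeyError(f"contig {chrom!r} not in track")
    lo, hi = pos - FLANK, pos + FLANK
    if lo < 0 or hi > track.contig_length(chrom):
        return None
    bins = np.array([
        track.weighted_sum(chrom, lo + i * BIN_BP, lo + (i + 1) * BIN_BP)
        for i in range(N_BINS)
    ])
    if strand == "-":
        bins = bins[::-1]
    return bins


@dataclass(frozen=True)
class ResidencyModel:
    """Per-junction Poisson residency model and score."""

    lambda_up: float
    lambda_down: float
    lambda_whole: float
    p_bins: tuple[float, ...]
    score: float

    @property
    def lam(self) -> float:
        return max(self.lambda_up, self.lambda_down, self.lambda_whole)


def residency_score(bins: np.ndarray, global_mean_bin: float) -> ResidencyModel:
    """Residency score for one junction's 100-bin vector.

    ``global_mean_bin`` is the mean bin count over the full window across
    all junctions.  Expected per-bin count lambda is the maximum of the
    intron-side mean (bins 0-49), exon-side mean (bins 50-99), and the
    global mean; per-bin p = P(X > k) for the 5 junction-adjacent
    intron-side bins; score = -log10(min p).  With lambda exactly zero a
    zero count is unremarkable (p = 1) while any positive count is floored
    to the smallest representable p.
    """
    bins = np.asarray(bins, dtype=float)
    if bins.size != N_BINS:
        raise ValueError(f"expected {N_BINS} bins, got {bins.size}")
    lam_up = float(bins[: N_BINS // 2].mean())
    lam_down = float(bins[N_BINS // 2 :].mean())
    lam = max(lam_up, lam_down, float(global_mean_bin))
    k = np.floor(bins[JUNCTION_BINS])
    if lam == 0.0:
        p = np.where(k > 0, _TINY, 1.0)
    else:
        p = stats.poisson.sf(k, lam)
        p = np.maximum(p, _TINY)
    score = float(-np.log10(p.min()))
    return ResidencyModel(lam_up, lam_down, float(global_mean_bin), tuple(p), score)


def score_junctions(bin_matrix: np.ndarray) -> pd.DataFrame:
    """Residency scores for a (junctions x 100) bin-count matrix, using the
    all-junction global mean bin count for the lambda-whole component."""
    bin_matrix = np.asarray(bin_matrix, dtype=float)
    global_mean = float(bin_matrix.mean()) if bin_matrix.size else 0.0
    lam_up = bin_matrix[:, : N_BINS // 2].mean(axis=1)
    lam_down = bin_matrix[:, N_BINS // 2 :].mean(axis=1)
    lam = np.maximum(np.maximum(lam_up, lam_down), global_mean)
    k = np.floor(bin_matrix[:, JUNCTION_BINS])
    with np.errstate(divide="ignore"):
        p = stats.poisson.sf(k, lam[:, None])
    p = np.where(lam[:, None] == 0.0, np.where(k > 0, _TINY, 1.0), np.maximum(p, _TINY))
    min_p = p.min(axis=1)
    return pd.DataFrame({
        "lambda_up": lam_up,
        "lambda_down": lam_down,
        "lambda_whole": global_mean,
        "min_p": min_p,
        "score": -np.log10(min_p),
    })


def quantile_normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """Classic rank-mean quantile normalization across experiment columns.

    After normalization every column's sorted value vector equals the
    reference (mean of the per-column sorted vectors); ties within a column
    receive the mean reference value of their shared rank block.
    """
    if counts.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 experiments")
    mat = counts.to_numpy(dtype=float)
    ref = np.sort(mat, axis=0).mean(axis=1)
    out = np.empty_like(mat)
    for j in range(mat.shape[1]):
        col = mat[:, j]
        order = np.argsort(col, kind="mergesort")
        assigned = np.empty(col.size)
        assigned[order] = ref
        # ties share the mean reference value of their rank block
        out[:, j] = pd.Series(assigned).groupby(col).transform("mean").to_numpy()
    return pd.DataFrame(out, index=counts.index, columns=counts.columns)


def fold_enrichment(
    normalized: pd.DataFrame,
    control_map: dict[str, str],
    all_controls: list[str],
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Fold enrichment of each entry per experiment against controls.

    The denominator is the maximum of the matched control value and the mean
    over all control experiments, plus a pseudocount; the numerator is the
    experiment value plus the same pseudocount.
    """
    if not all_controls:
        raise ValueError("all-control set must be nonempty")
    missing = set(all_controls) - set(normalized.columns)
    if missing:
        raise ValueError(f"control columns absent from table: {sorted(missing)}")
    ctrl_mean = normalized[all_controls].mean(axis=1)
    out = {}
    for exp, matched in control_map.items():
        matched_vals = normalized[matched] if matched in normalized.columns else ctrl_mean
        denom = np.maximum(matched_vals, ctrl_mean) + pseudocount
        out[exp] = (normalized[exp] + pseudocount) / denom
    return pd.DataFrame(out, index=normalized.index)
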