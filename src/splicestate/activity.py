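"""Poisson local-background gene-activity (ON/OFF) calling.

Small-gene activity is inferred from chromatin-accessibility coverage: the
observed read count k over a gene is compared against the expected count
under a local Poisson background.  The background rate is estimated in
windows of 1 kb, 10 kb, and 100 kb centered on the gene midpoint plus the
whole genome, each converted to an expected count lambda = rate x gene
length; the test uses the most conservative (maximum) lambda.  P-values are
the strict upper tail P(X > k) and are adjusted globally (all gene x sample
pairs jointly) with Benjamini-Hochberg.

Gene-level classes follow the median-p rule: short genes (<1000 bp) with a
global median p < 0.05 are "always ON"; remaining genes with a median p
< 0.05 in at least one cancer subtype are "ON/OFF"; otherwise "OFF".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .tracks import CoverageTrack, GenomicInterval

__all__ = [
    "BackgroundModel",
    "poisson_tail",
    "local_lambda",
    "downsample_track",
    "call_activity",
    "classify_gene_states",
]

DEFAULT_WINDOWS = (1_000, 10_000, 100_000)


@dataclass(frozen=True)
class BackgroundModel:
    """Expected gene-interval counts under each local background window."""

    lambda_1k: float
    lambda_10k: float
    lambda_100k: float
    lambda_genome: float

    @property
    def lambda_max(self) -> float:
        return max(self.lambda_1k, self.lambda_10k, self.lambda_100k, self.lambda_genome)


def poisson_tail(k, lam):
    """Strict upper-tail Poisson probability P(X > k).

    Note the strict inequality: many libraries' "survival function at k-1"
    convention equals P(X >= k); here the printed-formula convention
    P(X > k) is used, so ``poisson_tail(0, lam) = 1 - exp(-lam)``.
    Stable in log-space for large lambda and extreme tails.
    """
    k_arr = np.asarray(k)
    if np.any(k_arr < 0) or not np.issubdtype(k_arr.dtype, np.integer) and np.any(k_arr != np.floor(k_arr)):
        raise ValueError("k must be a nonnegative integer")
    lam_arr = np.asarray(lam, dtype=float)
    if np.any(lam_arr < 0):
        raise ValueError("lambda must be nonnegative")
    p = stats.poisson.sf(k_arr, lam_arr)
    return p if p.shape else float(p)


def local_lambda(
    track: CoverageTrack,
    gene: GenomicInterval,
    windows=DEFAULT_WINDOWS,
    include_gene: bool = False,
) -> BackgroundModel:
    """Local-background model for one gene on one coverage track.

    Windows are centered on the gene midpoint and clipped at contig ends;
    per window, rate = window count / effective window width and
    lambda = rate x gene length.  The genome-wide component uses
    total_reads / total assembly length.  By default the gene's own reads
    (and its footprint) are excluded from the windowed background so that a
    truly active gene does not inflate its own expectation; pass
    ``include_gene=True`` for the inclusive variant.
    """
    if gene.chrom not in track.data:
        raise KeyError(f"gene {gene.id} on unknown contig {gene.chrom!r}")
    clen = track.contig_length(gene.chrom)
    mid = (gene.start + gene.end) / 2
    lams = []
    gene_count = track.weighted_sum(gene.chrom, gene.start, gene.end)
    for w in windows:
        lo = int(max(0, mid - w / 2))
        hi = int(min(clen, mid + w / 2))
        width = hi - lo
        count = track.weighted_sum(gene.chrom, lo, hi)
        if not include_gene:
            ov = max(0, min(hi, gene.end) - max(lo, gene.start))
            count -= gene_count * (ov / gene.length)
            width -= ov
        if width <= 0:
            raise ValueError(f"zero-width effective window ({w} bp) for gene {gene.id}")
        lams.append(count / width * gene.length)
    total_len = track.genome_length
    lam_genome = track.total_reads / total_len * gene.length
    return BackgroundModel(lams[0], lams[1], lams[2], lam_genome)


def downsample_track(track: CoverageTrack, target_total: int = 250_000_000, seed: int | None = None) -> CoverageTrack:
    """Binomial thinning of bin counts to a target sequencing depth.

    Sample depths are equalized before calling so that statistical power is
    comparable across samples.  If the track is already at or below the
    target it is returned unchanged.
    """
    if target_total <= 0:
        raise ValueError("target_total must be positive")
    total = track.total_reads
    if total <= target_total:
        return track
    p = target_total / total
    rng = np.random.default_rng(seed)
    data = {c: rng.binomial(np.asarray(a, dtype=np.int64), p) for c, a in track.data.items()}
    return CoverageTrack(bin_width=track.bin_width, data=data)


def call_activity(
    tracks: dict[str, CoverageTrack],
    genes: list[GenomicInterval],
    windows=DEFAULT_WINDOWS,
    include_gene: bool = False,
    on_alpha: float = 0.05,
    off_p: float = 0.5,
    global_bh: bool = True,
) -> pd.DataFrame:
    """Per (gene, sample) Poisson enrichment calls with global BH adjustment.

    Returns a DataFrame with columns gene, sample, k, lambda_max, p_raw,
    p_adj, state.  BH is applied once over all (gene, sample) pairs jointly
    (``global_bh=False`` adjusts within each sample instead).  Per-sample
    states: ``confident_ON`` iff p_adj < on_alpha, ``confident_OFF`` iff
    p_raw > off_p, otherwise ``indeterminate``.
    """
    if not tracks or not genes:
        raise ValueError("need at least one sample track and one gene")
    rows = []
    for sample, track in tracks.items():
        for gene in genes:
            bg = local_lambda(track, gene, windows=windows, include_gene=include_gene)
            k = int(np.floor(track.weighted_sum(gene.chrom, gene.start, gene.end) + 0.5))
            rows.append((gene.id, sample, k, bg.lambda_max))
    df = pd.DataFrame(rows, columns=["gene", "sample", "k", "lambda_max"])
    df["p_raw"] = poisson_tail(df["k"].to_numpy(), df["lambda_max"].to_numpy())
    if global_bh:
        df["p_adj"] = multipletests(df["p_raw"], method="fdr_bh")[1]
    else:
        df["p_adj"] = df.groupby("sample")["p_raw"].transform(
            lambda p: multipletests(p, method="fdr_bh")[1]
        )
    state = np.where(df["p_adj"] < on_alpha, "confident_ON",
                     np.where(df["p_raw"] > off_p, "confident_OFF", "indeterminate"))
    df["state"] = state
    return df


def classify_gene_states(
    calls: pd.DataFrame,
    genes: list[GenomicInterval],
    subtype_map: dict[str, str],
    alpha: float = 0.05,
    short_length: int = 1_000,
) -> pd.DataFrame:
    """Gene-level ON / ON-OFF / OFF classes from per-sample raw p-values.

    A gene shorter than ``short_length`` whose median p across all samples is
    below ``alpha`` is ``always_ON``; of the remaining genes, those with a
    median p below ``alpha`` within at least one subtype are ``ON_OFF``;
    all others are ``OFF``.
    """
    lengths = {g.id: g.length for g in genes}
    missing = set(calls["sample"]) - set(subtype_map)
    if missing:
        raise ValueError(f"samples without subtype assignment: {sorted(missing)}")
    df = calls.copy()
    df["subtype"] = df["sample"].map(subtype_map)
    rows = []
    for gene, sub in df.groupby("gene", sort=False):
        global_med = float(sub["p_raw"].median())
        sub_med = sub.groupby("subtype")["p_raw"].median()
        if lengths[gene] < short_length and global_med < alpha:
            cls = "always_ON"
        elif (sub_med < alpha).any():
            cls = "ON_OFF"
        else:
            cls = "OFF"
        rows.append({"gene": gene, "global_median_p": global_med, "class": cls,
                     **{f"median_p_{s}": float(v) for s, v in sub_med.items()}})
    return pd.DataFrame(rows)
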