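"""Transcript-centric intron-retention (IR) statistics.

Per-intron IR ratios (unspliced / total, as produced by IR quantifiers such
as IRFinder) for one control and three knockdown replicates are scored with
a Dixon-style Q outlier test asking whether the control separates from the
treatment distribution; the intron IR score is -log10 of a Monte-Carlo
Q-test p-value.  Overlapping (nested/parent) intron annotations are
collapsed to single entities by median score.  Transcript-level significance
is assessed by comparing the mean intron score against an empirical null of
equally many scores drawn from the global score pool, under two frameworks:
[1] positive-score introns only and [2] all introns.  A transcript is called
sensitive when the BH-adjusted permutation p is below 0.05 in both
frameworks.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from ._sampling import subset_means

__all__ = [
    "filter_introns",
    "q_test_score",
    "score_introns",
    "collapse_nested",
    "transcript_significance",
    "delta_ir_z",
    "gel_psi",
    "DeltaIRSummary",
]

MIN_CPM = 1.0
MIN_FLANK = 10.0


def filter_introns(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read-quality filter on an intron table.

    An intron is retained iff gene expression CPM > 1 in every sample and
    both 5' and 3' flanking-exon read supports are > 10 in every sample,
    taken individually (strict inequalities).  Returns (retained, rejection
    log); the log names the first failed criterion per rejected intron.
    """
    cpm_cols = [c for c in records.columns if c.startswith("cpm_")]
    f5_cols = [c for c in records.columns if c.startswith("flank5_")]
    f3_cols = [c for c in records.columns if c.startswith("flank3_")]
    if not cpm_cols or not f5_cols or not f3_cols:
        raise ValueError("intron table must carry cpm_*, flank5_* and flank3_* columns")
    cpm_ok = (records[cpm_cols] > MIN_CPM).all(axis=1)
    f5_ok = (records[f5_cols] > MIN_FLANK).all(axis=1)
    f3_ok = (records[f3_cols] > MIN_FLANK).all(axis=1)
    keep = cpm_ok & f5_ok & f3_ok
    reason = np.where(~cpm_ok, "CPM", np.where(~f5_ok, "flank5", "flank3"))
    log = records.loc[~keep, ["transcript_id", "chrom", "start", "end"]].copy()
    log["reason"] = reason[~keep.to_numpy()]
    return records.loc[keep].reset_index(drop=True), log.reset_index(drop=True)


@lru_cache(maxsize=8)
def _q_null(n: int, mc_reps: int, seed: int) -> np.ndarray:
    """Sorted Monte-Carlo null of the suspect-designated Dixon Q statistic.

    Null draws are n i.i.d. standard Gaussians with the first position
    designated suspect; Q = gap-to-range if that position is an extreme,
    else 0.  Scale/location invariance of Q makes the standard Gaussian a
    canonical choice.
    """
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((mc_reps, n))
    q = _q_statistic(x[:, 0], x[:, 1:])
    q.sort()
    return q


def _q_statistic(suspect: np.ndarray, others: np.ndarray) -> np.ndarray:
    suspect = np.atleast_1d(np.asarray(suspect, dtype=float))
    others = np.atleast_2d(np.asarray(others, dtype=float))
    omin, omax = others.min(axis=1), others.max(axis=1)
    lo = np.minimum(suspect, omin)
    hi = np.maximum(suspect, omax)
    rng_ = hi - lo
    gap = np.where(suspect >= omax, suspect - omax, np.where(suspect <= omin, omin - suspect, 0.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        q = np.where(rng_ > 0, gap / rng_, 0.0)
    return q


def q_test_score(
    control_ir: float,
    treatment_irs,
    mc_reps: int = 100_000,
    seed: int = 0,
) -> tuple[float, float, float]:
    """Q-test of one control IR ratio against three treatment ratios.

    Returns (q_stat, p_q, score) where score = -log10(p_q).  The control is
    the designated suspect: Q = |control - nearest treatment| / range of all
    four values when the control is an extreme, 0 otherwise (a control
    inside the treatment range cannot separate from it).  The p-value is the
    add-one-smoothed Monte-Carlo tail P(Q_null >= q) under a Gaussian null
    at the same arity; a degenerate (zero-range) input yields p = 1.
    """
    treatment_irs = np.asarray(treatment_irs, dtype=float)
    if treatment_irs.size < 3:
        raise ValueError("need at least 3 treatment replicates")
    vals = np.concatenate([[control_ir], treatment_irs])
    if not np.isfinite(vals).all() or ((vals < 0) | (vals > 1)).any():
        raise ValueError("IR ratios must be finite and in [0, 1]")
    q = float(_q_statistic(np.array([control_ir]), treatment_irs[None, :])[0])
    if q == 0.0:
        return 0.0, 1.0, 0.0
    null = _q_null(vals.size, mc_reps, seed)
    n_ge = null.size - np.searchsorted(null, q, side="left")
    p = (1 + n_ge) / (1 + null.size)
    return q, float(p), float(-np.log10(p))


def score_introns(
    records: pd.DataFrame,
    treatment_cols=("ir_treat1", "ir_treat2", "ir_treat3"),
    control_col: str = "ir_control",
    mc_reps: int = 100_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Vectorized Q-test scores for every intron row of a filtered table."""
    ctrl = records[control_col].to_numpy(dtype=float)
    treat = records[list(treatment_cols)].to_numpy(dtype=float)
    q = _q_statistic(ctrl, treat)
    null = _q_null(1 + len(treatment_cols), mc_reps, seed)
    n_ge = null.size - np.searchsorted(null, q, side="left")
    p = (1 + n_ge) / (1 + null.size)
    p = np.where(q == 0.0, 1.0, p)
    out = records.copy()
    out["q_stat"] = q
    out["p_q"] = p
    out["score"] = -np.log10(p)
    return out


def collapse_nested(scores: pd.DataFrame) -> pd.DataFrame:
    """Collapse overlapping intron annotations into single intron entities.

    Introns of the same transcript on the same contig whose intervals
    overlap (larger parent / smaller nested annotations) are grouped into
    connected components; each component becomes one entity whose score is
    the median of member scores.  Output is order-independent.
    """
    req = {"transcript_id", "chrom", "start", "end", "score"}
    missing = req - set(scores.columns)
    if missing:
        raise ValueError(f"missing columns {sorted(missing)}")
    rows = []
    for (tid, chrom), grp in scores.groupby(["transcript_id", "chrom"], sort=False):
        grp = grp.sort_values(["start", "end"], kind="mergesort")
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        svals = grp["score"].to_numpy(dtype=float)
        i = 0
        while i < len(grp):
            j = i + 1
            comp_end = ends[i]
            while j < len(grp) and starts[j] < comp_end:
                comp_end = max(comp_end, ends[j])
                j += 1
            rows.append({
                "entity_id": f"{tid}:{chrom}:{starts[i]}-{comp_end}",
                "transcript_id": tid,
                "chrom": chrom,
                "start": int(starts[i]),
                "end": int(comp_end),
                "n_members": j - i,
                "score": float(np.median(svals[i:j])),
            })
            i = j
    return pd.DataFrame(rows)


def transcript_significance(
    entities: pd.DataFrame,
    B: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Permutation significance of transcript-wide IR score distributions.

    For each transcript and framework, the observed statistic is the mean of
    the relevant entity scores (framework 1: positive scores only;
    framework 2: all scores).  The null is B draws, without replacement, of
    the same number of scores from the framework-matched global pool;
    empirical p = (1 + #{null mean >= observed}) / (B + 1), BH-adjusted
    across transcripts within each framework.  ``sensitive`` requires
    adjusted p < alpha in both frameworks; a transcript with no qualifying
    introns in a framework is not evaluable there and is never sensitive.
    """
    if B < 1_000:
        raise ValueError("B must be at least 1000")
    scores_all = entities["score"].to_numpy(dtype=float)
    pool = {1: scores_all[scores_all > 0], 2: scores_all}
    rng = np.random.default_rng(seed)

    per_tx: dict[str, dict] = {}
    for tid, grp in entities.groupby("transcript_id", sort=False):
        s = grp["score"].to_numpy(dtype=float)
        pos = s[s > 0]
        per_tx[tid] = {
            "n_introns": s.size,
            "n_positive": pos.size,
            "stat_fw1": float(pos.mean()) if pos.size else np.nan,
            "stat_fw2": float(s.mean()),
        }

    for fw in (1, 2):
        key_n = "n_positive" if fw == 1 else "n_introns"
        key_stat = f"stat_fw{fw}"
        fw_pool = pool[fw]
        by_n: dict[int, list[str]] = {}
        for tid, rec in per_tx.items():
            if rec[key_n] > 0:
                by_n.setdefault(rec[key_n], []).append(tid)
        for n, tids in by_n.items():
            if n > fw_pool.size:
                for tid in tids:
                    per_tx[tid][f"p_fw{fw}"] = np.nan
                continue
            # batch transcripts sharing n; independent nulls per transcript
            chunk = max(1, int(4e6) // (B * n) or 1)
            for lo in range(0, len(tids), chunk):
                batch = tids[lo:lo + chunk]
                means = subset_means(fw_pool, n, B * len(batch), rng).reshape(len(batch), B)
                for tid, m in zip(batch, means):
                    obs = per_tx[tid][key_stat]
                    per_tx[tid][f"p_fw{fw}"] = (1 + int((m >= obs).sum())) / (B + 1)

    df = pd.DataFrame([{"transcript_id": t, **rec} for t, rec in per_tx.items()])
    for fw in (1, 2):
        p = df[f"p_fw{fw}"]
        adj = np.full(len(df), np.nan)
        ok = p.notna().to_numpy()
        if ok.any():
            adj[ok] = multipletests(p[ok], method="fdr_bh")[1]
        df[f"padj_fw{fw}"] = adj
    df["sensitive"] = (df["padj_fw1"] < alpha) & (df["padj_fw2"] < alpha)
    df.loc[df["padj_fw1"].isna() | df["padj_fw2"].isna(), "sensitive"] = False
    return df


@dataclass(frozen=True)
class DeltaIRSummary:
    transcript_id: str
    n_introns: int
    observed: float
    null_mean: float
    null_sd: float
    z: float


def delta_ir_z(
    ir_control,
    ir_treatment,
    transcripts,
    B: int = 10_000,
    seed: int = 0,
    eps: float = 0.01,
) -> pd.DataFrame:
    """Transcript-level delta-IR z-scores from standardized log2 fold changes.

    Per intron, delta = log2((IR_treatment + eps) / (IR_control + eps)) with
    pseudocount eps; deltas are standardized against the global delta
    distribution (z-units).  The transcript statistic is the mean of its
    standardized deltas, compared to B random same-size draws (without
    replacement) from the global pool: z = (obs - null mean) / null sd.
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    ir_c = np.asarray(ir_control, dtype=float)
    ir_t = np.asarray(ir_treatment, dtype=float)
    delta = np.log2((ir_t + eps) / (ir_c + eps))
    sd = delta.std(ddof=0)
    if sd == 0:
        raise ValueError("degenerate input: all log2 fold changes identical")
    std = (delta - delta.mean()) / sd
    rng = np.random.default_rng(seed)
    tx = pd.Series(transcripts)
    rows = []
    for tid, idx in tx.groupby(tx, sort=False).groups.items():
        vals = std[np.asarray(idx)]
        null = subset_means(std, vals.size, B, rng)
        nm, ns = float(null.mean()), float(null.std(ddof=0))
        obs = float(vals.mean())
        rows.append(DeltaIRSummary(tid, vals.size, obs, nm, ns,
                                   (obs - nm) / ns if ns > 0 else np.nan))
    return pd.DataFrame([r.__dict__ for r in rows])


def gel_psi(intensity_retained: float, intensity_spliced: float) -> float:
    """Percent-spliced-in from gel band intensities:
    retained / (retained + spliced)."""
    if intensity_retained < 0 or intensity_spliced < 0:
        raise ValueError("band intensities must be nonnegative")
    total = intensity_retained + intensity_spliced
    if total == 0:
        raise ValueError("both band intensities are zero; PSI undefined")
    return intensity_retained / total
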