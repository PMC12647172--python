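"""Randomization-based gene-set and event-overlap statistics.

The shared engine draws B uniform random subsets of a universe (without
replacement) to build an empirical null for a set-level statistic (median,
mean, or label frequency), reporting a z-score against the null and an
add-one-smoothed empirical p-value: p = (1 + #{null at least as extreme}) /
(B + 1), so p is never zero and the smallest attainable value is 1/(B+1).

Built on top of it: mean-correlation tests of marker gene sets against an
activity signature, prognostic-label frequency enrichment, and the ranked
triple-overlap permutation test for alternative-splicing event lists.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._sampling import subset_indices

__all__ = [
    "PermResult",
    "OverlapResult",
    "set_statistic_z",
    "mean_correlation_test",
    "overlap_permutation",
    "prognostic_frequency_test",
]

_STATS = {
    "median": lambda m: np.median(m, axis=-1),
    "mean": lambda m: np.mean(m, axis=-1),
    "frequency": lambda m: np.mean(m, axis=-1),
}


@dataclass(frozen=True)
class PermResult:
    observed: float
    B: int
    null_mean: float
    null_sd: float
    z: float
    p: float
    sided: str
    degenerate: bool = False


def _empirical_p(observed: float, null: np.ndarray, sided: str) -> float:
    B = null.size
    if sided == "greater":
        c = int((null >= observed).sum())
    elif sided == "less":
        c = int((null <= observed).sum())
    elif sided == "two-sided":
        center = null.mean()
        c = int((np.abs(null - center) >= abs(observed - center)).sum())
    else:
        raise ValueError(f"unknown sidedness {sided!r}")
    return (1 + c) / (B + 1)


def set_statistic_z(
    values,
    subset,
    stat: str = "median",
    B: int = 10_000,
    seed: int = 0,
    sided: str = "greater",
    ids=None,
) -> PermResult:
    """Permutation z-score for a set-level statistic.

    ``values`` holds the per-element statistic over the whole universe;
    ``subset`` selects the gene set of interest, either as integer positions
    or, if ``ids`` is given, as labels.  The null is B uniform same-size
    subsets drawn without replacement.
    """
    if B < 1_000:
        raise ValueError("B must be at least 1000")
    values = np.asarray(values, dtype=float)
    if ids is not None:
        lookup = {g: i for i, g in enumerate(ids)}
        subset_idx = np.array([lookup[g] for g in subset], dtype=np.intp)
    else:
        subset_idx = np.asarray(subset, dtype=np.intp)
    m = subset_idx.size
    if m < 1:
        raise ValueError("subset must contain at least one element")
    stat_fn = _STATS[stat]
    rng = np.random.default_rng(seed)
    observed = float(stat_fn(values[subset_idx]))
    null = stat_fn(values[subset_indices(values.size, m, B, rng)])
    nm, ns = float(null.mean()), float(null.std(ddof=0))
    if ns == 0.0:
        return PermResult(observed, B, nm, ns, float("nan"), 1.0, sided, degenerate=True)
    return PermResult(observed, B, nm, ns, (observed - nm) / ns,
                      _empirical_p(observed, null, sided), sided)


def mean_correlation_test(
    activity,
    expression: pd.DataFrame,
    markers,
    B: int = 10_000,
    seed: int = 0,
    sided: str = "greater",
) -> tuple[PermResult, pd.Series]:
    """Mean Spearman correlation of a marker gene set with an activity score.

    Per gene, Spearman rho between the per-sample activity vector and the
    gene's expression row; the observed statistic is the mean rho over the
    marker set, compared to B random same-size gene sets.  Returns the
    permutation result and the full per-gene rho series.
    """
    activity = np.asarray(activity, dtype=float)
    if activity.size < 3:
        raise ValueError("need at least 3 samples")
    if np.ptp(activity) == 0:
        raise ValueError("constant activity vector: correlation undefined")
    markers = list(markers)
    missing = set(markers) - set(expression.index)
    if missing:
        raise ValueError(f"marker genes absent from expression matrix: {sorted(missing)}")
    a_rank = stats.rankdata(activity)
    e_rank = np.apply_along_axis(stats.rankdata, 1, expression.to_numpy(dtype=float))
    a_c = a_rank - a_rank.mean()
    e_c = e_rank - e_rank.mean(axis=1, keepdims=True)
    denom = np.sqrt((a_c**2).sum() * (e_c**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(denom > 0, e_c @ a_c / denom, np.nan)
    rho_s = pd.Series(rho, index=expression.index, name="rho")
    res = set_statistic_z(np.nan_to_num(rho, nan=0.0), markers, stat="mean",
                          B=B, seed=seed, sided=sided, ids=list(expression.index))
    return res, rho_s


def prognostic_frequency_test(
    labels: pd.Series,
    subset,
    B: int = 10_000,
    seed: int = 0,
    classes=("negative", "positive"),
) -> dict[str, PermResult]:
    """Enrichment of prognostic-label frequencies within a gene subset.

    ``labels`` maps every universe gene to "negative", "positive", or
    "none".  For each prognostic class, the observed within-subset label
    frequency is compared one-sidedly (overrepresentation) against B random
    same-size subsets of the labeled universe.
    """
    labels = pd.Series(labels)
    out = {}
    for i, cls in enumerate(classes):
        indicator = (labels == cls).to_numpy(dtype=float)
        out[cls] = set_statistic_z(indicator, subset, stat="frequency",
                                   B=B, seed=seed + i, sided="greater",
                                   ids=list(labels.index))
    return out


@dataclass
class OverlapResult:
    """Ranked triple-overlap permutation result for one event partition."""

    event_type: str
    direction: str
    depths: np.ndarray
    observed: np.ndarray
    expected: np.ndarray
    p: np.ndarray
    k_star: int
    overlap_ids: list = field(default_factory=list)
    final_ids: list = field(default_factory=list)


def _rank_key(df: pd.DataFrame) -> np.ndarray:
    """Significance-weighted delta-PSI ranking key: -log10(FDR) x |dPSI|."""
    fdr = np.maximum(df["fdr"].to_numpy(dtype=float), 1e-300)
    return -np.log10(fdr) * np.abs(df["delta_psi"].to_numpy(dtype=float))


def overlap_permutation(
    lists: list[pd.DataFrame],
    B: int = 10_000,
    alpha: float = 0.05,
    seed: int = 0,
    final_fdr: float = 0.05,
    final_psi_spread: float = 0.1,
) -> list[OverlapResult]:
    """Permutation test for the ranked overlap of three splicing-event lists.

    The three tables share an event universe (same ``event_id`` sets) and
    are partitioned by (event type, direction), direction being the sign of
    delta_psi (zeros dropped).  Within a partition each list ranks events by
    -log10(FDR) x |delta PSI|; for every depth k the observed statistic is
    the size of the triple top-k intersection, compared against B
    independent random rankings.  k* is the largest depth with empirical
    p < alpha; the reported final set is the triple intersection at k*
    further filtered to FDR < ``final_fdr`` in all three lists and a PSI
    spread across samples > ``final_psi_spread``.
    """
    if len(lists) != 3:
        raise ValueError("exactly three event lists required")
    ids0 = set(lists[0]["event_id"])
    if any(set(l["event_id"]) != ids0 for l in lists[1:]):
        raise ValueError("event lists must share the same event universe")
    rng = np.random.default_rng(seed)
    base = lists[0]
    results = []
    psi_cols = [c for c in base.columns if c.startswith("psi_")]
    for (etype, direction), part in base.assign(
        direction=np.where(base["delta_psi"] > 0, "inclusion",
                           np.where(base["delta_psi"] < 0, "exclusion", "drop"))
    ).groupby(["event_type", "direction"], sort=True):
        if direction == "drop" or len(part) == 0:
            continue
        eids = part["event_id"].to_numpy()
        N = eids.size
        ranks = np.empty((3, N), dtype=np.intp)
        sub_tables = []
        for li, lst in enumerate(lists):
            sub = lst.set_index("event_id").loc[eids]
            sub_tables.append(sub)
            key = _rank_key(sub.reset_index())
            order = np.argsort(-key, kind="mergesort")
            r = np.empty(N, dtype=np.intp)
            r[order] = np.arange(1, N + 1)
            ranks[li] = r
        max_rank = ranks.max(axis=0)
        observed = np.bincount(max_rank, minlength=N + 1)[1:].cumsum()
        # null: independent uniform rankings per list
        null_counts = np.empty((B, N), dtype=np.int32)
        for b in range(B):
            m = np.maximum(rng.permutation(N) + 1,
                           np.maximum(rng.permutation(N) + 1, rng.permutation(N) + 1))
            null_counts[b] = np.bincount(m, minlength=N + 1)[1:].cumsum()
        expected = null_counts.mean(axis=0)
        p = (1 + (null_counts >= observed[None, :]).sum(axis=0)) / (B + 1)
        sig = np.nonzero(p < alpha)[0]
        k_star = int(sig[-1] + 1) if sig.size else 0
        overlap_mask = max_rank <= k_star
        overlap_ids = list(eids[overlap_mask])
        final_ids = []
        for eid in overlap_ids:
            fdr_ok = all(float(t.loc[eid, "fdr"]) < final_fdr for t in sub_tables)
            psis = np.concatenate([
                t.loc[eid, psi_cols].to_numpy(dtype=float) for t in sub_tables
            ]) if psi_cols else np.array([])
            spread_ok = psis.size > 0 and float(psis.max() - psis.min()) > final_psi_spread
            if fdr_ok and spread_ok:
                final_ids.append(eid)
        results.append(OverlapResult(
            event_type=etype, direction=direction,
            depths=np.arange(1, N + 1), observed=observed,
            expected=expected, p=p, k_star=k_star,
            overlap_ids=overlap_ids, final_ids=final_ids,
        ))
    return results
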