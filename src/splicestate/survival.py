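"""Per-gene proportional-hazards survival statistics over ON/OFF states.

Each small gene's per-tumor activity state (confident ON vs confident OFF)
enters a Cox proportional-hazards model as a binary covariate, stratified by
cancer subtype.  Subtype-restriction rules mirror the activity-calling
pipeline: subtypes with uniform predicted state are excluded (they carry no
within-subtype contrast and would import tissue effects), indeterminate
samples are dropped, and analyses are restricted to short genes (<400 bp).
Multi-copy gene families are collapsed to one per-sample family state via
the median p-value across members.  Gene "types" (all copies encoding one
RNA species) are ranked by their median Wald statistic against a
randomization null over equally many estimable genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter

from .permnull import PermResult, set_statistic_z

__all__ = [
    "CoxResult",
    "EligibilityMask",
    "restrict_samples",
    "cox_wald",
    "run_survival",
    "rank_gene_types",
]


@dataclass(frozen=True)
class CoxResult:
    gene: str
    n_samples: int
    coef: float
    se: float
    hazard_ratio: float
    wald: float
    estimable: bool = True


@dataclass
class EligibilityMask:
    gene: str
    eligible_subtypes: list[str]
    samples: pd.DataFrame  # columns: sample, subtype, state01


def _states_with_families(states: pd.DataFrame, families, on_alpha, off_p) -> pd.DataFrame:
    """Append family-level pseudo-genes whose per-sample state derives from
    the median p across family members."""
    if not families:
        return states
    extra = []
    for fam, members in families.items():
        sub = states[states["gene"].isin(members)]
        med = sub.groupby("sample")[["p_raw", "p_adj"]].median().reset_index()
        med["gene"] = fam
        med["state"] = np.where(med["p_adj"] < on_alpha, "confident_ON",
                                np.where(med["p_raw"] > off_p, "confident_OFF", "indeterminate"))
        extra.append(med)
    return pd.concat([states] + extra, ignore_index=True)


def restrict_samples(
    states: pd.DataFrame,
    subtype_map: dict[str, str],
    gene_lengths: dict[str, int],
    families: dict[str, list[str]] | None = None,
    max_length: int = 400,
    on_alpha: float = 0.05,
    off_p: float = 0.5,
) -> dict[str, EligibilityMask]:
    """Eligible (sample, subtype) sets per gene for survival analysis.

    Genes at or above ``max_length`` bp are dropped.  Indeterminate samples
    are removed, and subtypes lacking either a confident-ON or a
    confident-OFF sample are excluded for that gene.  ``families`` maps a
    family name to its member gene ids; the family is analyzed as one unit
    with per-sample state from the median member p-values (family length =
    median member length).
    """
    states = _states_with_families(states, families or {}, on_alpha, off_p)
    lengths = dict(gene_lengths)
    for fam, members in (families or {}).items():
        lengths[fam] = int(np.median([gene_lengths[m] for m in members]))
    out: dict[str, EligibilityMask] = {}
    for gene, sub in states.groupby("gene", sort=False):
        if lengths.get(gene, max_length) >= max_length:
            continue
        sub = sub[sub["state"] != "indeterminate"].copy()
        sub["subtype"] = sub["sample"].map(subtype_map)
        sub["state01"] = (sub["state"] == "confident_ON").astype(int)
        ok_subtypes = [
            st for st, grp in sub.groupby("subtype")
            if grp["state01"].nunique() == 2
        ]
        kept = sub[sub["subtype"].isin(ok_subtypes)]
        if not ok_subtypes:
            continue
        out[gene] = EligibilityMask(gene, sorted(ok_subtypes),
                                    kept[["sample", "subtype", "state01"]].reset_index(drop=True))
    return out


def cox_wald(df: pd.DataFrame, strata: str | None = "subtype") -> CoxResult | None:
    """Cox proportional-hazards fit of a binary state covariate.

    ``df`` needs columns time, event, state01 and (if stratified) the
    stratum column.  Efron tie handling; SE from the observed information.
    Returns None (non-estimable) for constant covariates, zero events in
    either state group, or a failed fit.
    """
    gene = str(df["gene"].iloc[0]) if "gene" in df.columns else ""
    if df["state01"].nunique() < 2:
        return None
    if df.groupby("state01")["event"].sum().min() < 1:
        return None
    cph = CoxPHFitter()
    cols = ["time", "event", "state01"] + ([strata] if strata else [])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df[cols], duration_col="time", event_col="event",
                    strata=[strata] if strata else None,
                    fit_options={"precision": 1e-13, "max_steps": 500})
    except Exception:
        return None
    coef = float(cph.params_["state01"])
    se = float(cph.standard_errors_["state01"])
    if not np.isfinite(coef) or not np.isfinite(se) or se == 0:
        return None
    return CoxResult(gene, len(df), coef, se, float(np.exp(coef)), coef / se)


def run_survival(
    states: pd.DataFrame,
    clinical: pd.DataFrame,
    gene_lengths: dict[str, int],
    families: dict[str, list[str]] | None = None,
    stratified: bool = True,
    **restrict_kwargs,
) -> pd.DataFrame:
    """Per-gene Cox results over eligible samples.

    ``clinical`` carries sample_id, time, event, subtype; ``states`` the
    per (gene, sample) activity calls.  Returns one row per estimable gene
    with coef, SE, hazard ratio and signed Wald statistic.
    """
    subtype_map = dict(zip(clinical["sample_id"], clinical["subtype"]))
    masks = restrict_samples(states, subtype_map, gene_lengths, families, **restrict_kwargs)
    clin = clinical.set_index("sample_id")
    rows = []
    for gene, mask in masks.items():
        df = mask.samples.join(clin[["time", "event"]], on="sample")
        df["gene"] = gene
        res = cox_wald(df, strata="subtype" if stratified else None)
        if res is not None:
            rows.append(res.__dict__)
    return pd.DataFrame(rows)


def rank_gene_types(
    cox_results: pd.DataFrame,
    type_map: dict[str, str],
    B: int = 10_000,
    seed: int = 0,
    sided: str = "greater",
) -> pd.DataFrame:
    """Median-Wald ranking of RNA gene types with permutation z-scores.

    For each type, the observed median Wald statistic over its estimable
    genes is compared against B random same-size draws from all estimable
    genes.
    """
    df = cox_results[cox_results["estimable"]] if "estimable" in cox_results else cox_results
    wald = df["wald"].to_numpy(dtype=float)
    genes = list(df["gene"])
    by_type: dict[str, list[str]] = {}
    for g in genes:
        if g in type_map:
            by_type.setdefault(type_map[g], []).append(g)
    rows = []
    for i, (rna_type, members) in enumerate(sorted(by_type.items())):
        res: PermResult = set_statistic_z(wald, members, stat="median",
                                          B=B, seed=seed + i, sided=sided, ids=genes)
        rows.append({"rna_type": rna_type, "n_genes": len(members),
                     "median_wald": res.observed, "z": res.z, "p": res.p})
    return pd.DataFrame(rows).sort_values("median_wald", ascending=False).reset_index(drop=True)
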