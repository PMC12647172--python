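"""Elastic-net logistic classification of splicing-disruption sensitivity.

Transcripts (or introns) significantly responsive to snaR-A depletion are a
small minority; the classifier learns to separate them from insensitive
rows using genomic features (length, G/C content, median intron length,
nuclear-speckle proximity score, RNA-binding-protein occupancy, ...).
Training runs as repeated bootstrap simulations: each simulation resamples
the rows, oversamples the minority class to parity, standardizes features
within the training set, selects the elastic-net mixing and strength by
cross-validation, and scores ROC AUC on the out-of-bootstrap rows.  A
reduced model over a handful of selected features produces a mean predicted
sensitivity probability per row across simulations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss, roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler

__all__ = ["assemble_features", "train_elastic_net", "predict_reduced", "ModelReport"]

DEFAULT_L1_RATIOS = (0.1, 0.5, 0.9)
DEFAULT_STRENGTHS = tuple(np.logspace(-3, 1, 5))  # penalty strength lambda; C = 1/lambda


def gc_content(seq: str) -> float:
    """Fraction of G/C bases in a sequence."""
    if not seq:
        raise ValueError("empty sequence")
    s = seq.upper()
    return (s.count("G") + s.count("C")) / len(s)


def assemble_features(
    annotation: pd.DataFrame,
    sequences: dict[str, str],
    speckle_scores: pd.Series | None = None,
    occupancy: pd.DataFrame | None = None,
    intron_lengths: dict[str, list[int]] | None = None,
    mode: str = "transcript",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Join feature sources into one numeric matrix indexed by row id.

    ``annotation`` needs columns row_id and length.  G/C content is computed
    from ``sequences``; speckle proximity and per-RBP occupancy columns are
    joined by id; transcript mode adds the median intron length.  Missing
    values are median-imputed and logged.  Returns (features, imputation
    log).
    """
    if mode not in ("transcript", "intron"):
        raise ValueError(f"unknown mode {mode!r}")
    ids = list(annotation["row_id"])
    absent = [i for i in ids if i not in sequences]
    if absent:
        raise ValueError(f"rows missing from sequence source: {absent[:5]}")
    fm = pd.DataFrame(index=pd.Index(ids, name="row_id"))
    fm["length"] = annotation.set_index("row_id")["length"]
    fm["gc_content"] = [gc_content(sequences[i]) for i in ids]
    if mode == "transcript" and intron_lengths is not None:
        fm["median_intron_length"] = [
            float(np.median(intron_lengths[i])) if intron_lengths.get(i) else np.nan
            for i in ids
        ]
    if speckle_scores is not None:
        fm["speckle_score"] = speckle_scores.reindex(ids)
    if occupancy is not None:
        fm = fm.join(occupancy.reindex(ids))
    log_rows = []
    for col in fm.columns:
        n_missing = int(fm[col].isna().sum())
        if n_missing:
            med = float(fm[col].median())
            fm[col] = fm[col].fillna(med)
            log_rows.append({"feature": col, "n_imputed": n_missing, "fill_value": med})
    return fm, pd.DataFrame(log_rows, columns=["feature", "n_imputed", "fill_value"])


@dataclass
class ModelReport:
    mean_auc: float
    aucs: np.ndarray
    coef_mean: pd.Series
    coef_sd: pd.Series
    mean_probability: pd.Series
    hyper_choices: list = field(default_factory=list)


def _oversample(X: np.ndarray, y: np.ndarray, rng: np.random.Generator):
    """Random-duplication oversampling of the minority class to parity."""
    n1, n0 = int(y.sum()), int((1 - y).sum())
    if n1 == n0:
        return X, y
    minority = 1 if n1 < n0 else 0
    idx_min = np.nonzero(y == minority)[0]
    extra = rng.choice(idx_min, size=abs(n0 - n1), replace=True)
    keep = np.concatenate([np.arange(y.size), extra])
    return X[keep], y[keep]


def _select_hyper(X, y, l1_ratios, strengths, rng, max_folds=3):
    """Pick (l1_ratio, C) by cross-validated log loss; stratified k-fold,
    falling back to leave-one-out on very small inputs."""
    n_splits = max_folds if y.size >= 6 * max_folds else max(2, min(int(y.sum()), int((1 - y).sum())))
    cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=int(rng.integers(2**31)))
    best, best_loss = None, np.inf
    for l1 in l1_ratios:
        for lam in strengths:
            losses = []
            for tr, te in cv.split(X, y):
                if len(np.unique(y[tr])) < 2:
                    continue
                clf = LogisticRegression(solver="saga", l1_ratio=l1, C=1.0 / lam,
                                         max_iter=3000, tol=1e-3, random_state=0)
                clf.fit(X[tr], y[tr])
                prob = clf.predict_proba(X[te])[:, 1]
                losses.append(log_loss(y[te], prob, labels=[0, 1]))
            loss = float(np.mean(losses)) if losses else np.inf
            if loss < best_loss:
                best, best_loss = (l1, lam), loss
    return best if best is not None else (l1_ratios[0], strengths[0])


def _fit_simulations(X_df: pd.DataFrame, y, B, seed, l1_ratios, strengths,
                     tune_every: int):
    X_all = X_df.to_numpy(dtype=float)
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    if min(int(y.sum()), int((1 - y).sum())) < 3:
        raise ValueError("minority class needs at least 3 rows")
    rng = np.random.default_rng(seed)
    n = y.size
    aucs, coefs, probs, hypers = [], [], [], []
    hyper = None
    sims = 0
    while sims < B:
        boot = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), boot)
        if oob.size == 0 or len(np.unique(y[oob])) < 2 or len(np.unique(y[boot])) < 2:
            continue
        Xb, yb = _oversample(X_all[boot], y[boot], rng)
        scaler = StandardScaler().fit(Xb)
        Xb_s = scaler.transform(Xb)
        if hyper is None or (tune_every and sims % tune_every == 0):
            hyper = _select_hyper(Xb_s, yb, l1_ratios, strengths, rng)
        l1, lam = hyper
        clf = LogisticRegression(solver="saga", l1_ratio=l1, C=1.0 / lam,
                                 max_iter=5000, tol=1e-4, random_state=0)
        clf.fit(Xb_s, yb)
        X_oob = scaler.transform(X_all[oob])
        aucs.append(roc_auc_score(y[oob], clf.predict_proba(X_oob)[:, 1]))
        coefs.append(clf.coef_[0])
        probs.append(clf.predict_proba(scaler.transform(X_all))[:, 1])
        hypers.append(hyper)
        sims += 1
    coefs = np.array(coefs)
    return ModelReport(
        mean_auc=float(np.mean(aucs)),
        aucs=np.array(aucs),
        coef_mean=pd.Series(coefs.mean(axis=0), index=X_df.columns),
        coef_sd=pd.Series(coefs.std(axis=0, ddof=0), index=X_df.columns),
        mean_probability=pd.Series(np.mean(probs, axis=0), index=X_df.index),
        hyper_choices=hypers,
    )


def train_elastic_net(
    features: pd.DataFrame,
    labels,
    B: int = 100,
    seed: int = 0,
    l1_ratios=DEFAULT_L1_RATIOS,
    strengths=DEFAULT_STRENGTHS,
    tune_every: int = 25,
) -> ModelReport:
    """Bootstrap-simulation training of the elastic-net classifier.

    Runs ``B`` simulations (bootstrap resample -> minority oversampling ->
    within-fold standardization -> elastic-net logistic fit) and reports the
    mean out-of-bootstrap AUC, coefficient stability, and the per-row mean
    predicted probability.  Hyperparameters are re-selected by internal
    cross-validation every ``tune_every`` simulations.
    """
    return _fit_simulations(features, labels, B, seed, l1_ratios, strengths, tune_every)


def predict_reduced(
    features_reduced: pd.DataFrame,
    labels,
    B: int = 100,
    seed: int = 0,
    l1_ratios=DEFAULT_L1_RATIOS,
    strengths=DEFAULT_STRENGTHS,
) -> pd.Series:
    """Mean predicted sensitivity probability per row from the reduced model.

    Fits ``B`` bootstrap simulations on the reduced feature set and averages
    the per-row predicted probabilities across simulations.
    """
    report = _fit_simulations(features_reduced, labels, B, seed, l1_ratios,
                              strengths, tune_every=50)
    return report.mean_probability
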