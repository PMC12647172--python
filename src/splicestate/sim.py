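"""Seeded synthetic-data generators with planted ground truth.

Every input the pipeline consumes can be generated here with known truth:
Poisson accessibility counts over a linear contig with a smoothly varying
local background and a planted active-gene set; replicate intron-retention
tables (one scramble control, three knockdown siRNAs) with planted
IR-reduced transcripts; junction-proximal crosslinking-IP bin counts with
planted enriched junctions; survival tables with a binary gene-state
covariate of known hazard ratio; ranked splicing-event lists with
controlled inter-list rank correlation; and pull-down proteomics intensity
tables with planted enriched proteins.

Each generator derives its own RNG stream from the master seed and a stable
hash of the generator name, so adding a generator never perturbs the
others, and identical configurations are byte-reproducible.
"""

from __future__ import annotations

import logging
import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special

from .tracks import CoverageTrack, GenomicInterval

logger = logging.getLogger(__name__)

__all__ = [
    "SimConfig",
    "TruthBundle",
    "simulate_accessibility",
    "simulate_ir_tables",
    "simulate_junction_bins",
    "simulate_survival",
    "simulate_event_lists",
    "simulate_proteomics",
]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the simulated study.

    Defaults mirror the designs the pipeline was built for: one scramble
    control against three knockdown siRNA replicates for the IR tables, a
    few hundred tumor samples split into six cancer subtypes (two of them
    state-uniform) for survival, short Pol III-scale genes (~200 bp) at a
    chromatin-accessibility background of ~0.01 reads/bp (expected gene
    count lambda ~ 2) with a five-fold accessibility gain when active, and a
    knockdown intron-retention shift of -0.3.
    """

    seed: int = 0
    # accessibility
    n_samples: int = 8
    n_genes: int = 1_000
    gene_length: int = 200
    gene_spacing: int = 2_000
    flank: int = 100_000
    bin_width: int = 10
    background_rate: float = 0.01  # reads per bp
    active_fraction: float = 0.05
    activity_fold: float = 5.0
    background_roughness: float = 0.2  # sd of log local-background multiplier
    # intron retention
    n_transcripts: int = 1_000
    n_introns_per_transcript: int = 5
    ir_effect: float = -0.3  # additive IR-ratio shift in treatments (negative = reduced IR)
    ir_noise_sd: float = 0.05  # sd of the Gaussian replicate noise on the logit scale
    sensitive_fraction: float = 0.02  # ~1-2% of expressed transcripts respond to knockdown
    filter_fail_fraction: float = 0.05
    # junctions
    n_junctions: int = 2_000
    junction_background: float = 1.0  # Poisson rate per 10 bp bin
    junction_fold: float = 10.0
    enriched_junction_fraction: float = 0.05
    # survival
    n_survival_samples: int = 328
    n_subtypes: int = 6
    true_log_hr: float = float(np.log(1.5))
    censor_rate: float = 0.3
    baseline_hazard: float = 0.1
    # splicing-event lists
    n_events: int = 500
    overlap_rho: float = 0.5
    # proteomics
    n_proteins: int = 1_000
    enriched_protein_fraction: float = 0.02

    def __post_init__(self):
        for name in ("active_fraction", "sensitive_fraction", "filter_fail_fraction",
                     "enriched_junction_fraction", "enriched_protein_fraction",
                     "censor_rate", "overlap_rho"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("background_rate", "baseline_hazard", "junction_background"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("activity_fold", "junction_fold"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not -1 <= self.ir_effect <= 1:
            raise ValueError("ir_effect must be in [-1, 1]")
        if not np.isfinite(self.true_log_hr):
            raise ValueError("true_log_hr must be finite")

    def rng(self, generator: str) -> np.random.Generator:
        """Independent RNG stream for one named generator."""
        return np.random.default_rng(
            np.random.SeedSequence([self.seed, zlib.crc32(generator.encode())])
        )


@dataclass
class TruthBundle:
    """Planted ground truth accompanying each generated dataset."""

    active_genes: list[str] = field(default_factory=list)
    active_pairs: list[tuple[str, str]] = field(default_factory=list)
    sensitive_transcripts: list[str] = field(default_factory=list)
    enriched_junctions: list[int] = field(default_factory=list)
    enriched_proteins: list[str] = field(default_factory=list)
    params: dict = field(default_factory=dict)


# --- accessibility ----------------------------------------------------------

def _smooth_multiplier(n_bins: int, bin_width: int, roughness: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Smooth positive background multiplier: log-normal nodes every 50 kb,
    linearly interpolated across bins."""
    node_bp = 50_000
    n_nodes = max(2, n_bins * bin_width // node_bp + 2)
    nodes = np.exp(rng.normal(0.0, roughness, size=n_nodes))
    x = np.linspace(0, n_bins - 1, n_nodes)
    return np.interp(np.arange(n_bins), x, nodes)


def simulate_accessibility(cfg: SimConfig):
    """Per-sample binned accessibility counts over one linear contig.

    Genes of ``gene_length`` bp are placed every ``gene_spacing`` bp between
    100 kb flanks.  Counts per bin are Poisson with rate background_rate x
    bin_width x smooth local multiplier; bins inside a planted active gene
    additionally get ``activity_fold`` in every sample (active genes are ON
    in all samples).  Returns (genes, {sample: CoverageTrack}, truth).
    """
    cfg_rng = cfg.rng("accessibility")
    bw = cfg.bin_width
    if cfg.gene_length % bw or cfg.gene_spacing % bw or cfg.flank % bw:
        raise ValueError("gene_length, gene_spacing and flank must be multiples of bin_width")
    if cfg.gene_spacing < cfg.gene_length:
        raise ValueError("contig sizing error: gene_spacing shorter than gene_length")
    contig_len = 2 * cfg.flank + cfg.n_genes * cfg.gene_spacing
    n_bins = contig_len // bw
    genes = [
        GenomicInterval("chrS", cfg.flank + i * cfg.gene_spacing,
                        cfg.flank + i * cfg.gene_spacing + cfg.gene_length,
                        "+", f"g{i:04d}")
        for i in range(cfg.n_genes)
    ]
    n_active = int(round(cfg.active_fraction * cfg.n_genes))
    active_idx = cfg_rng.choice(cfg.n_genes, size=n_active, replace=False)
    active = {genes[i].id for i in active_idx}
    mult = _smooth_multiplier(n_bins, bw, cfg.background_roughness, cfg_rng)
    base_rate = cfg.background_rate * bw * mult
    fold = np.ones(n_bins)
    for i in active_idx:
        g = genes[i]
        fold[g.start // bw : g.end // bw] = cfg.activity_fold
    samples = [f"s{j:02d}" for j in range(cfg.n_samples)]
    tracks = {}
    for s in samples:
        counts = cfg_rng.poisson(base_rate * fold)
        tracks[s] = CoverageTrack(bin_width=bw, data={"chrS": counts})
    truth = TruthBundle(
        active_genes=sorted(active),
        active_pairs=[(g, s) for g in sorted(active) for s in samples],
        params={"activity_fold": cfg.activity_fold, "background_rate": cfg.background_rate},
    )
    return genes, tracks, truth


# --- intron retention -------------------------------------------------------

def _logit_noise(mean: np.ndarray, sd_logit: float, rng: np.random.Generator) -> np.ndarray:
    """Replicate IR values as Gaussian noise on the logit scale around the
    logit of the mean, mapped back through the inverse logit.

    Working on the logit scale keeps ratios strictly inside (0, 1) with no
    hard clipping; the induced ratio-scale spread is about
    ``sd_logit * m * (1 - m)`` and shrinks toward the boundaries, matching
    the small replicate variability of deeply sequenced IR estimates.
    """
    mean = np.clip(mean, 1e-4, 1 - 1e-4)
    return special.expit(special.logit(mean) + rng.normal(0.0, sd_logit, size=mean.shape))


def simulate_ir_tables(cfg: SimConfig):
    """Per-intron IR table for 1 control + 3 treatment replicates.

    Sensitive transcripts shift every intron's treatment IR by ``ir_effect``
    (negative = reduced retention after knockdown); every replicate value
    carries Gaussian noise of sd ``ir_noise_sd`` on the logit scale.  CPM and
    flanking-exon read-support columns are included so the read-quality
    filters are exercisable; a ``filter_fail_fraction`` of introns is
    planted to fail one filter.  Returns (table, truth).
    """
    rng = cfg.rng("ir")
    n_tx, n_in = cfg.n_transcripts, cfg.n_introns_per_transcript
    n_rows = n_tx * n_in
    tx_ids = np.repeat([f"tx{i:05d}" for i in range(n_tx)], n_in)
    n_sens = int(round(cfg.sensitive_fraction * n_tx))
    sens_idx = rng.choice(n_tx, size=n_sens, replace=False)
    sensitive = np.zeros(n_tx, dtype=bool)
    sensitive[sens_idx] = True
    # base retention: background introns follow a low-retention Beta; introns
    # of responsive transcripts are partially retained (mid-range IR), the
    # regime where a knockdown-induced shift is biologically meaningful and
    # stays inside [0, 1]
    base = rng.beta(2, 5, size=n_rows)
    row_sens = np.repeat(sensitive, n_in)
    lo = max(0.05, abs(cfg.ir_effect) + 0.05)
    base[row_sens] = rng.uniform(lo, min(lo + 0.15, 0.95), size=int(row_sens.sum()))
    treat_mean = base.copy()
    shifted = base[row_sens] + cfg.ir_effect
    if ((shifted < 0) | (shifted > 1)).any():
        warnings.warn("ir_effect pushes some IR ratios outside [0, 1]; clipping", stacklevel=2)
    treat_mean[row_sens] = np.clip(shifted, 0.0, 1.0)

    starts = 1_000 + np.arange(n_rows) * 2_000
    df = pd.DataFrame({
        "transcript_id": tx_ids,
        "chrom": "chrI",
        "start": starts,
        "end": starts + rng.integers(200, 2_000, size=n_rows),
        "ir_control": _logit_noise(base, cfg.ir_noise_sd, rng),
    })
    for t in (1, 2, 3):
        df[f"ir_treat{t}"] = _logit_noise(treat_mean, cfg.ir_noise_sd, rng)
    samples = ("control", "treat1", "treat2", "treat3")
    for s in samples:
        df[f"cpm_{s}"] = rng.lognormal(2.0, 1.0, size=n_rows) + 1.01
        df[f"flank5_{s}"] = rng.integers(11, 200, size=n_rows)
        df[f"flank3_{s}"] = rng.integers(11, 200, size=n_rows)
    n_fail = int(round(cfg.filter_fail_fraction * n_rows))
    if n_fail:
        fail_rows = rng.choice(n_rows, size=n_fail, replace=False)
        mode = rng.integers(0, 3, size=n_fail)
        fail_sample = rng.choice(samples, size=n_fail)
        for r, m, s in zip(fail_rows, mode, fail_sample):
            col = ("cpm_", "flank5_", "flank3_")[m] + s
            df.loc[r, col] = 0.5 if m == 0 else 5
    truth = TruthBundle(
        sensitive_transcripts=sorted(f"tx{i:05d}" for i in sens_idx),
        params={"ir_effect": cfg.ir_effect, "ir_noise_sd": cfg.ir_noise_sd},
    )
    return df, truth


# --- junction bins ----------------------------------------------------------

def simulate_junction_bins(cfg: SimConfig):
    """(junction table, 100-bin count matrix, truth) for residency scoring.

    Background bins are Poisson(junction_background); enriched junctions
    receive ``junction_fold`` times the rate in the 5 intron-side bins
    adjacent to the 3' splice site (bins 45-49).
    """
    from .junctions import JUNCTION_BINS, N_BINS

    rng = cfg.rng("junctions")
    lam0 = cfg.junction_background
    rates = np.full((cfg.n_junctions, N_BINS), lam0)
    n_enr = int(round(cfg.enriched_junction_fraction * cfg.n_junctions))
    enr_idx = rng.choice(cfg.n_junctions, size=n_enr, replace=False) if n_enr else np.array([], dtype=int)
    rates[enr_idx, JUNCTION_BINS] = lam0 * cfg.junction_fold
    counts = rng.poisson(rates)
    junctions = pd.DataFrame({
        "junction_id": [f"j{i:05d}" for i in range(cfg.n_junctions)],
        "chrom": "chrJ",
        "pos": 1_000 + np.arange(cfg.n_junctions) * 2_000,
        "strand": "+",
    })
    truth = TruthBundle(enriched_junctions=sorted(int(i) for i in enr_idx),
                        params={"junction_fold": cfg.junction_fold, "lambda0": lam0})
    return junctions, counts, truth


# --- survival ---------------------------------------------------------------

def simulate_survival(cfg: SimConfig, n_genes: int = 1):
    """Survival table with binary per-gene states of known hazard ratio.

    Event times are exponential with hazard ``baseline_hazard`` x
    exp(true_log_hr x state); censoring is an independent exponential whose
    rate is solved numerically so the expected censored fraction equals
    ``censor_rate``.  Samples are split into ``n_subtypes`` subtypes, two of
    which are state-uniform (all-ON, all-OFF) to exercise the subtype
    exclusion rule; the rest assign ON with imbalanced probabilities.
    Returns (table, truth); the table has columns sample_id, time, event,
    subtype and one ``state_<gene>`` column per gene.
    """
    if cfg.censor_rate >= 1:
        raise ValueError("censor_rate = 1 leaves no events; refusing")
    rng = cfg.rng("survival")
    n = cfg.n_survival_samples
    subtypes = np.array([f"sub{j}" for j in rng.integers(0, cfg.n_subtypes, size=n)])
    df = pd.DataFrame({"sample_id": [f"t{i:04d}" for i in range(n)], "subtype": subtypes})
    on_prob = {f"sub{j}": p for j, p in enumerate(
        np.concatenate([[1.0, 0.0], 0.3 + 0.4 * rng.random(cfg.n_subtypes - 2)])
    )}
    h0, b = cfg.baseline_hazard, cfg.true_log_hr
    state_cols = {}
    hazards = np.zeros(n)
    for g in range(n_genes):
        state = (rng.random(n) < np.vectorize(on_prob.get)(subtypes)).astype(int)
        state_cols[f"state_gene{g:03d}"] = state
        if g == 0:
            hazards = h0 * np.exp(b * state)
    if cfg.censor_rate > 0:
        mean_censored = lambda c: float(np.mean(c / (c + hazards)))  # noqa: E731
        c_rate = optimize.brentq(lambda c: mean_censored(c) - cfg.censor_rate,
                                 1e-9, 1e6)
    else:
        c_rate = 0.0
    t_event = rng.exponential(1.0 / hazards)
    if c_rate > 0:
        t_cens = rng.exponential(1.0 / c_rate, size=n)
        df["time"] = np.minimum(t_event, t_cens)
        df["event"] = (t_event <= t_cens).astype(int)
    else:
        df["time"] = t_event
        df["event"] = 1
    for col, state in state_cols.items():
        df[col] = state
    truth = TruthBundle(params={"true_log_hr": b, "hazard_ratio": float(np.exp(b)),
                                "censor_rate": cfg.censor_rate,
                                "uniform_subtypes": ["sub0", "sub1"]})
    return df, truth


# --- splicing-event lists ---------------------------------------------------

_EVENT_TYPES = ("RI", "SE", "A5SS", "A3SS", "MXE")


def simulate_event_lists(cfg: SimConfig):
    """Three ranked splicing-event tables over a shared event universe.

    Per-list latent scores follow a Gaussian copula with inter-list
    correlation ``overlap_rho`` (rho = 1 gives identical rankings, rho = 0
    independent ones).  Within each (type, direction) partition, rank i of M
    maps to FDR = i / (M + 1) (monotone nondecreasing in rank) and
    |delta PSI| decreasing in rank, so the ranking key -log10(FDR) x |dPSI|
    reproduces the ranks.  Returns ([table1, table2, table3], truth).
    """
    rng = cfg.rng("events")
    N = cfg.n_events
    etype = rng.choice(_EVENT_TYPES, size=N, p=(0.4, 0.3, 0.1, 0.1, 0.1))
    sign = np.where(rng.random(N) < 0.5, 1.0, -1.0)
    base = rng.standard_normal(N)
    rho = cfg.overlap_rho
    tables = []
    psi_base = rng.uniform(0.1, 0.9, size=N)
    for li in range(3):
        if rho >= 1.0:
            score = base
        else:
            score = rho * base + np.sqrt(1 - rho**2) * rng.standard_normal(N)
        df = pd.DataFrame({
            "event_id": [f"e{i:05d}" for i in range(N)],
            "event_type": etype,
            "direction_sign": sign,
            "latent": score,
        })
        parts = []
        for (t, sg), part in df.groupby(["event_type", "direction_sign"], sort=True):
            part = part.sort_values("latent", ascending=False, kind="mergesort").copy()
            M = len(part)
            rank = np.arange(1, M + 1)
            part["fdr"] = rank / (M + 1)
            part["delta_psi"] = sg * (0.05 + 0.6 * (1 - rank / (M + 1)))
            parts.append(part)
        out = pd.concat(parts).drop(columns=["latent", "direction_sign"])
        out["psi_ctrl"] = psi_base
        out["psi_treat"] = np.clip(psi_base + out["delta_psi"], 0.0, 1.0)
        tables.append(out.sort_index().reset_index(drop=True))
    truth = TruthBundle(params={"overlap_rho": rho, "base_order": list(np.argsort(-base))})
    return tables, truth


# --- proteomics -------------------------------------------------------------

def simulate_proteomics(cfg: SimConfig):
    """Pull-down proteomics intensity table with a planted enriched set.

    Background proteins have comparable intensities in targets and controls
    (log2 ratios near 0); planted enriched proteins get >16x control
    intensity in both target replicates plus guaranteed unique peptides, so
    the downstream filter (>4x over both controls, >=1 peptide in both
    target replicates) recovers exactly the planted set.  A handful of
    decoys carry high ratios but zero peptides in one replicate.
    Returns (table, truth).
    """
    rng = cfg.rng("proteomics")
    n = cfg.n_proteins
    n_enr = int(round(cfg.enriched_protein_fraction * n))
    enr_idx = rng.choice(n, size=n_enr, replace=False) if n_enr else np.array([], dtype=int)
    enriched = np.zeros(n, dtype=bool)
    enriched[enr_idx] = True
    base = rng.lognormal(10, 1, size=n)
    tab = pd.DataFrame({"protein_id": [f"P{i:05d}" for i in range(n)]})
    jitter = lambda: rng.lognormal(0.0, 0.1, size=n)  # noqa: E731
    boost = np.where(enriched, rng.uniform(24.0, 64.0, size=n), 1.0)
    tab["intensity_target1"] = base * boost * jitter()
    tab["intensity_target2"] = base * boost * jitter()
    tab["intensity_scramble"] = base * jitter()
    tab["intensity_beads"] = base * jitter()
    peps = rng.integers(1, 20, size=(n, 2))
    # peptide-failing decoys: high ratio but no peptide in one target replicate
    n_decoy = max(1, n // 200)
    decoy_idx = rng.choice(np.nonzero(~enriched)[0], size=n_decoy, replace=False)
    tab.loc[decoy_idx, "intensity_target1"] *= 40.0
    tab.loc[decoy_idx, "intensity_target2"] *= 40.0
    peps[decoy_idx, rng.integers(0, 2, size=n_decoy)] = 0
    tab["peptides_target1"] = peps[:, 0]
    tab["peptides_target2"] = peps[:, 1]
    truth = TruthBundle(enriched_proteins=sorted(tab.loc[enriched, "protein_id"]),
                        params={"n_decoys": int(n_decoy)})
    return tab, truth
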