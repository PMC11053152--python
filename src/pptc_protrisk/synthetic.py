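"""Synthetic cohort generator.

Emulates the statistical structure of a TMT-labelled FFPE proteome study of
pediatric thyroid nodules: three biological groups (pediatric benign PB,
pediatric malignant PM, adult malignant AM) measured in multi-plex batches
with one pooled reference channel per batch and a handful of technical
replicate pairs; abundance-dependent missingness; a subset of proteins with
planted group differences; and recurrence outcomes for the PM patients drawn
from a proportional-hazards model driven by a small set of prognostic
("signal") proteins under heavy censoring.

The generative model, per protein p and biological sample i (log2 scale):

    y_pi = b_p + delta_p * 1[i in PM] + e_pi,          e ~ N(0, noise_sd^2)
    x_pi = y_pi + gamma_{p, batch(i)} + t_pi,          t ~ N(0, (noise_sd/2)^2)

where b_p is the protein baseline, delta_p the planted group effect (zero for
non-differential proteins), gamma the per-batch per-protein offset
(N(0, batch_sd^2)) and t technical noise.  Technical replicates re-measure
the same biological value y with fresh technical noise; pooled channels
measure the cohort-average profile plus their batch's offset.

Recurrence: each PM patient's log hazard is a linear combination of the
standardized biological abundances of the signal proteins; event times are
exponential, censoring uniform over a follow-up window.  The baseline hazard
is calibrated so the achieved event fraction matches a target (default ~14%,
i.e. ~85% censoring).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .containers import AbundanceMatrix, validate_clinical


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


# ----------------------------------------------------------------------
@dataclass
class SimConfig:
    """Parameters of the synthetic cohort.

    Defaults mirror the study layout: 85 PM + 83 PB + 66 AM biological
    samples, 6 technical replicate pairs (240 tissue channels), 16 batches
    each with one pooled reference, ~9k proteins, and ~14% recurrence among
    PM patients over a follow-up window with median ~71 months.
    """

    n_pb: int = 83
    n_pm: int = 85
    n_am: int = 66
    n_proteins: int = 9154
    n_batches: int = 16
    n_pooled_per_batch: int = 1
    n_replicate_pairs: int = 6
    n_dep: int = 200
    dep_log2fc: float = 1.0
    n_signal: int = 10
    signal_loghr: float = 1.0
    signal_corr: float = 0.7
    signal_in_dep_pool: bool = True
    baseline_hazard: float = 0.002          # events / month
    censor_time_dist: tuple = (29.0, 113.0)  # uniform window, median ~71 months
    target_event_fraction: float | None = 0.14
    batch_sd: float = 0.5
    noise_sd: float = 0.5
    n_modules: int = 25
    module_sd: float = 0.5
    baseline_mean: float = 20.0
    baseline_sd: float = 2.0
    mnar_slope: float = 8.0
    mnar_center: float = 0.05
    mcar_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        counts = dict(
            n_pb=self.n_pb, n_pm=self.n_pm, n_am=self.n_am,
            n_proteins=self.n_proteins, n_batches=self.n_batches,
            n_pooled_per_batch=self.n_pooled_per_batch,
            n_replicate_pairs=self.n_replicate_pairs,
            n_dep=self.n_dep, n_signal=self.n_signal,
        )
        for name, v in counts.items():
            if v < 0:
                raise ConfigurationError(f"{name} must be >= 0, got {v}")
        if self.n_dep + self.n_signal > self.n_proteins:
            raise ConfigurationError("n_dep + n_signal exceeds n_proteins")
        if not (0 <= self.mcar_rate < 1):
            raise ConfigurationError("mcar_rate must lie in [0, 1)")
        if self.mnar_slope < 0:
            raise ConfigurationError("mnar_slope must be >= 0")
        if self.target_event_fraction is not None and not (
            0 < self.target_event_fraction < 1
        ):
            raise ConfigurationError("target_event_fraction must lie in (0, 1)")
        lo, hi = self.censor_time_dist
        if lo <= 0 or hi < lo:
            raise ConfigurationError("censor window must satisfy 0 < min <= max")
        if self.n_modules < 0 or self.module_sd < 0:
            raise ConfigurationError("module parameters must be >= 0")
        if not (0 <= self.signal_corr < 1):
            raise ConfigurationError("signal_corr must lie in [0, 1)")
        if self.n_batches < 1:
            raise ConfigurationError("need at least one batch")


@dataclass
class SyntheticTruth:
    """Ground truth of a generated cohort, for recovery tests."""

    dep_effects: dict            # protein id -> signed log2 fold change (PM shift)
    signal_coefs: dict           # protein id -> true log hazard ratio per SD
    batch_offsets: pd.DataFrame  # proteins x batches
    masked_entries: pd.DataFrame  # columns protein, sample, value (pre-mask)
    linear_predictors: pd.Series  # per PM patient
    baseline_hazard_used: float
    achieved_event_fraction: float
    seed: int = 0


# ----------------------------------------------------------------------
def simulate_survival(linear_predictors, baseline_hazard, censor_times, seed=None, rng=None):
    """Exponential proportional-hazards outcome generator.

    Event time ``T_i ~ Exponential(rate = baseline_hazard * exp(lp_i))``;
    observed time is ``min(T_i, censor_i)`` and ``event = 1`` iff the event
    precedes censoring.

    Returns ``(event, time)`` integer / float arrays.
    """
    lp = np.asarray(linear_predictors, float)
    censor = np.asarray(censor_times, float)
    if not np.all(np.isfinite(lp)):
        raise ValueError("linear predictors must be finite")
    if baseline_hazard <= 0:
        raise ValueError("baseline hazard must be positive")
    if np.any(censor <= 0):
        raise ValueError("censor times must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)
    rate = baseline_hazard * np.exp(lp)
    t_event = rng.exponential(1.0 / rate)
    event = (t_event <= censor).astype(int)
    time = np.minimum(t_event, censor)
    return event, time


def calibrate_baseline_hazard(linear_predictors, censor_times, target_event_fraction,
                              bracket=(1e-10, 1e3)):
    """Solve for the baseline hazard whose *expected* event fraction hits the target.

    With exponential event times and known censor times the expected event
    fraction is ``mean_i(1 - exp(-h0 * exp(lp_i) * c_i))``, monotone in h0.
    """
    lp = np.asarray(linear_predictors, float)
    c = np.asarray(censor_times, float)

    def frac(h0):
        return float(np.mean(1.0 - np.exp(-h0 * np.exp(lp) * c)))

    lo, hi = bracket
    if frac(hi) < target_event_fraction:
        warnings.warn(
            f"target event fraction {target_event_fraction} unreachable; "
            f"achievable maximum ~{frac(hi):.3f}"
        )
        return hi
    return brentq(lambda h: frac(h) - target_event_fraction, lo, hi, xtol=1e-12)


# ----------------------------------------------------------------------
def inject_missingness(matrix: AbundanceMatrix, mnar_slope: float, mcar_rate: float,
                       seed=None, rng=None, mnar_center: float = 0.05):
    """Hide entries by an abundance-dependent (MNAR) plus uniform (MCAR) mechanism.

    The MNAR hide probability is logistic in the entry's overall abundance
    quantile u: ``expit(mnar_slope * (mnar_center - u))`` (zero when
    mnar_slope == 0), so low-abundance entries go missing preferentially.
    Returns ``(matrix_with_gaps, masked_entries)`` where masked_entries
    records (protein, sample, original value).
    """
    if not (0 <= mcar_rate < 1):
        raise ConfigurationError("mcar_rate must lie in [0, 1)")
    if mnar_slope < 0:
        raise ConfigurationError("mnar_slope must be >= 0")
    if matrix.values.isna().any().any():
        raise ValueError("inject_missingness expects a complete matrix")
    if rng is None:
        rng = np.random.default_rng(seed)

    vals = matrix.values.to_numpy(float)
    n = vals.size
    # overall abundance quantile of each entry
    order = np.argsort(vals, axis=None, kind="stable")
    u = np.empty(n)
    u[order] = np.arange(n) / max(n - 1, 1)
    u = u.reshape(vals.shape)

    p_mnar = expit(mnar_slope * (mnar_center - u)) if mnar_slope > 0 else np.zeros_like(u)
    p_hide = 1.0 - (1.0 - p_mnar) * (1.0 - mcar_rate)
    hide = rng.random(vals.shape) < p_hide

    out = matrix.copy()
    masked = np.where(hide)
    records = pd.DataFrame(
        {
            "protein": matrix.values.index[masked[0]],
            "sample": matrix.values.columns[masked[1]],
            "value": vals[masked],
        }
    )
    new_vals = vals.copy()
    new_vals[hide] = np.nan
    out.values = pd.DataFrame(new_vals, index=matrix.values.index,
                              columns=matrix.values.columns)
    return out, records


# ----------------------------------------------------------------------
def simulate_clinical_covariates(n: int, rng) -> pd.DataFrame:
    """Draw the eleven clinical covariates for n malignant pediatric patients.

    Forms are chosen to match printed cohort summaries: age ~ discretized
    N(15.6, 2.4) truncated to [8, 18]; nodule size ~ N(2.4, 1.3) truncated
    positive; lymph-node counts zero-inflated (about 80% node-positive);
    binary features Bernoulli.
    """
    age = np.clip(np.rint(rng.normal(15.6, 2.4, n)), 8, 18).astype(int)
    gender = rng.binomial(1, 62 / 85, n)              # 1 = female
    size = np.clip(rng.normal(2.4, 1.3, n), 0.3, None).round(1)
    multifocality = rng.binomial(1, 0.35, n)
    ete = rng.binomial(1, 0.35, n)

    node_positive = rng.binomial(1, 0.81, n)
    tlnn = node_positive * (1 + rng.poisson(4.5, n))
    lateral = rng.binomial(1, 0.45, n)
    llnn = rng.binomial(tlnn, 0.35) * lateral
    harvested_t = tlnn + rng.poisson(8.0, n)
    harvested_l = llnn + rng.poisson(5.0, n)
    with np.errstate(invalid="ignore"):
        tlnr = np.where(harvested_t > 0, tlnn / harvested_t, 0.0)
        llnr = np.where(harvested_l > 0, llnn / harvested_l, 0.0)

    surgery = rng.binomial(1, 0.5, n)                 # 1 = total thyroidectomy
    ht = rng.binomial(1, 0.25, n)
    return pd.DataFrame(
        {
            "age": age,
            "gender": gender,
            "max_nodule_size": size,
            "multifocality": multifocality,
            "ETE": ete,
            "TLNR": np.round(tlnr, 4),
            "LLNR": np.round(llnr, 4),
            "TLNN": tlnn,
            "LLNN": llnn,
            "surgery": surgery,
            "HT": ht,
        }
    )


# ----------------------------------------------------------------------
def generate_cohort(config: SimConfig):
    """Generate a full synthetic cohort.

    Returns ``(AbundanceMatrix, ClinicalTable, SyntheticTruth)``.  The matrix
    is on the log2 scale and contains biological tissue columns, technical
    replicate columns and pooled reference columns, each assigned to a batch;
    identical configs (same seed) give byte-identical outputs.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n_bio = cfg.n_pb + cfg.n_pm + cfg.n_am
    if cfg.n_replicate_pairs > n_bio:
        raise ConfigurationError("more replicate pairs than biological samples")

    protein_ids = pd.Index([f"P{i+1:05d}" for i in range(cfg.n_proteins)], name="protein")
    perm = rng.permutation(cfg.n_proteins)
    dep_idx = perm[: cfg.n_dep]
    signal_idx = perm[cfg.n_dep: cfg.n_dep + cfg.n_signal]

    baselines = rng.normal(cfg.baseline_mean, cfg.baseline_sd, cfg.n_proteins)

    # planted PM shifts: alternating signs for DEPs and (optionally) signal proteins
    delta = np.zeros(cfg.n_proteins)
    dep_signs = np.where(np.arange(cfg.n_dep) % 2 == 0, 1.0, -1.0)
    delta[dep_idx] = dep_signs * cfg.dep_log2fc
    signal_signs = np.where(np.arange(cfg.n_signal) % 2 == 0, 1.0, -1.0)
    if cfg.signal_in_dep_pool:
        delta[signal_idx] = signal_signs * cfg.dep_log2fc

    # biological sample ids and groups
    sample_ids = (
        [f"PB{i+1:03d}" for i in range(cfg.n_pb)]
        + [f"PM{i+1:03d}" for i in range(cfg.n_pm)]
        + [f"AM{i+1:03d}" for i in range(cfg.n_am)]
    )
    groups = ["PB"] * cfg.n_pb + ["PM"] * cfg.n_pm + ["AM"] * cfg.n_am
    is_pm = np.array([g == "PM" for g in groups])

    # biological (batch-free, technical-noise-free) log2 abundances
    y = (
        baselines[:, None]
        + delta[:, None] * is_pm[None, :]
        + rng.normal(0.0, cfg.noise_sd, (cfg.n_proteins, n_bio))
    )

    # co-expression structure: proteins fall into modules sharing a latent
    # per-sample factor, as complexes and pathways do in real proteomes
    if cfg.n_modules > 0 and cfg.module_sd > 0:
        module_of = rng.integers(0, cfg.n_modules, cfg.n_proteins)
        module_factors = rng.normal(0.0, cfg.module_sd, (cfg.n_modules, n_bio))
        y += module_factors[module_of]

    # prognostic proteins are co-regulated: their biological variation shares a
    # per-patient latent "aggressiveness" factor (loading signal_corr), which
    # also drives the hazard below.  Residual variance stays noise_sd^2.
    if cfg.n_signal > 0 and cfg.signal_corr > 0:
        latent = rng.normal(0.0, 1.0, n_bio)
        lam = cfg.signal_corr
        eps = rng.normal(0.0, 1.0, (cfg.n_signal, n_bio))
        y[signal_idx, :] = (
            baselines[signal_idx, None]
            + delta[signal_idx, None] * is_pm[None, :]
            + cfg.noise_sd
            * (lam * signal_signs[:, None] * latent[None, :]
               + np.sqrt(1.0 - lam**2) * eps)
        )

    # batch layout: tissues (biological + replicates) spread evenly over batches
    rep_targets = [sample_ids[i] for i in
                   rng.choice(n_bio, cfg.n_replicate_pairs, replace=False)]
    tissue_ids = sample_ids + [f"{sid}_rep" for sid in rep_targets]
    n_tissue = len(tissue_ids)
    shuffle = rng.permutation(n_tissue)
    batch_of = {}
    for pos, tidx in enumerate(shuffle):
        batch_of[tissue_ids[tidx]] = (pos % cfg.n_batches) + 1

    gamma = rng.normal(0.0, cfg.batch_sd, (cfg.n_proteins, cfg.n_batches))
    tech_sd = cfg.noise_sd / 2.0

    bio_index = {sid: j for j, sid in enumerate(sample_ids)}
    cols, col_ids, col_groups, col_batches, col_repof = [], [], [], [], []
    for tid in tissue_ids:
        base_sid = tid[:-4] if tid.endswith("_rep") else tid
        j = bio_index[base_sid]
        b = batch_of[tid]
        x = y[:, j] + gamma[:, b - 1] + rng.normal(0.0, tech_sd, cfg.n_proteins)
        cols.append(x)
        col_ids.append(tid)
        col_groups.append(groups[j])
        col_batches.append(b)
        col_repof.append(base_sid if tid.endswith("_rep") else None)

    # pooled reference channels: cohort mean profile + batch offset + technical noise
    pool_profile = y.mean(axis=1)
    for b in range(1, cfg.n_batches + 1):
        for k in range(cfg.n_pooled_per_batch):
            x = pool_profile + gamma[:, b - 1] + rng.normal(0.0, tech_sd, cfg.n_proteins)
            cols.append(x)
            suffix = f"_{k+1}" if cfg.n_pooled_per_batch > 1 else ""
            col_ids.append(f"POOL_B{b:02d}{suffix}")
            col_groups.append("POOL")
            col_batches.append(b)
            col_repof.append(None)

    values = pd.DataFrame(np.column_stack(cols), index=protein_ids, columns=col_ids)
    meta = pd.DataFrame(
        {"group": col_groups, "batch": col_batches, "replicate_of": col_repof},
        index=pd.Index(col_ids, name="sample"),
    )

    # ---------------- recurrence outcomes for PM patients ----------------
    pm_cols = [sid for sid, g in zip(sample_ids, groups) if g == "PM"]
    pm_j = [bio_index[s] for s in pm_cols]
    if cfg.n_signal > 0:
        z = y[np.ix_(signal_idx, pm_j)]
        z = (z - z.mean(axis=1, keepdims=True)) / z.std(axis=1, ddof=0, keepdims=True)
        beta = signal_signs * cfg.signal_loghr
        lp = beta @ z
    else:
        lp = np.zeros(len(pm_cols))

    cmin, cmax = cfg.censor_time_dist
    censor = rng.uniform(cmin, cmax, len(pm_cols))
    if cfg.target_event_fraction is not None:
        h0 = calibrate_baseline_hazard(lp, censor, cfg.target_event_fraction)
    else:
        h0 = cfg.baseline_hazard
    event, time = simulate_survival(lp, h0, censor, rng=rng)

    clinical = simulate_clinical_covariates(len(pm_cols), rng)
    clinical.insert(0, "patient_id", pm_cols)
    clinical["event"] = event
    clinical["time"] = np.round(time, 2)
    clinical.loc[clinical["time"] <= 0, "time"] = 0.01
    clinical = clinical.set_index("patient_id")
    validate_clinical(clinical)

    matrix = AbundanceMatrix(values, meta, scale="log2", history=["simulate"])
    matrix, masked = inject_missingness(
        matrix, cfg.mnar_slope, cfg.mcar_rate, rng=rng, mnar_center=cfg.mnar_center
    )

    truth = SyntheticTruth(
        dep_effects={protein_ids[i]: float(delta[i]) for i in dep_idx},
        signal_coefs={
            protein_ids[i]: float(s * cfg.signal_loghr)
            for i, s in zip(signal_idx, signal_signs)
        },
        batch_offsets=pd.DataFrame(
            gamma, index=protein_ids,
            columns=[f"batch{b}" for b in range(1, cfg.n_batches + 1)],
        ),
        masked_entries=masked,
        linear_predictors=pd.Series(lp, index=pm_cols),
        baseline_hazard_used=float(h0),
        achieved_event_fraction=float(np.mean(event)),
        seed=cfg.seed,
    )
    return matrix, clinical, truth


def config_to_dict(cfg: SimConfig) -> dict:
    d = asdict(cfg)
    d["censor_time_dist"] = list(cfg.censor_time_dist)
    return d
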