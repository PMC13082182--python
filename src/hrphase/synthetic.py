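"""Synthetic cohort generator.

Emulates the five input tables of a wearable-circadian study — raw
heart-rate samples, participant covariates, genotypes, condition
occurrences over a toy ontology, and HbA1c labs — with a known causal
structure: genotype -> phase -> disease, with an optional unobserved
confounder entering both phase and disease risk.  The generative truth
is retained so every downstream estimator can be checked for recovery.

Generative model
----------------
phase_i   = phase_mean + sum_v dosage_iv * effect_v / 60
            + confounding_strength * U_i + Normal(0, phase_sd)      [hours]
HR_i(t)   = A_i * sin(pi/720 * (t mod 1440 - 60*phase_i)) + b_i
            + Normal(0, hr_noise_sd)                                 [bpm]
logit P(D_ic) = intercept_c + beta_phase*(phase_i - phase_mean)
            + beta_steps*(steps_i - steps_mean) + beta_age*(age_i - age_mean)
            + beta_y*y_i + confounding_strength * U_i
with U_i ~ Normal(0,1).  Diagnosis ages for cases follow an exponential
waiting time from ``onset_age`` with rate proportional to
exp(covariate effects), truncated at each participant's censoring age,
so a higher linear predictor gives stochastically earlier diagnosis.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .config import SimConfig

__all__ = [
    "SyntheticCohort",
    "generate_cohort",
    "generate_hr_stream",
    "build_toy_ontology",
    "compute_sleep_duration",
    "average_sleep_duration",
    "simulate_survival_cohort",
]

_MINUTES_PER_DAY = 1440
_THIRD_ALLELES = {"A": "C", "C": "A", "G": "T", "T": "G"}


@dataclass
class SyntheticCohort:
    """Bundle of generated tables plus the generative truth."""

    hr: pd.DataFrame            # participant_id, timestamp, bpm
    covariates: pd.DataFrame    # participant_id, age, y_chromosome, pc1-5, ...
    genotypes: pd.DataFrame     # participant_id, snv_id, allele1, allele2
    conditions: pd.DataFrame    # participant_id, concept_id, age_at_occurrence
    ontology_edges: pd.DataFrame  # parent_id, child_id
    labs: pd.DataFrame          # participant_id, date, hba1c_pct
    truth: pd.DataFrame         # one row per participant

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "hr": self.hr,
            "covariates": self.covariates,
            "genotypes": self.genotypes,
            "conditions": self.conditions,
            "ontology_edges": self.ontology_edges,
            "labs": self.labs,
            "truth": self.truth,
        }


def build_toy_ontology(depth: int, branching: int) -> pd.DataFrame:
    """Rooted tree as a (parent_id, child_id) edge list.

    Node ids are deterministic breadth-first integers starting at 1
    (the root).  ``depth`` is the number of levels below the root.
    """
    if depth < 1 or branching < 1:
        raise ValueError("depth and branching must be >= 1")
    parents, children = [], []
    frontier = [1]
    next_id = 2
    for _ in range(depth):
        new_frontier = []
        for p in frontier:
            for _ in range(branching):
                parents.append(p)
                children.append(next_id)
                new_frontier.append(next_id)
                next_id += 1
        frontier = new_frontier
    return pd.DataFrame({"parent_id": parents, "child_id": children})


def _tree_closure(edges: pd.DataFrame) -> dict[int, list[int]]:
    """Full descendant closure (self included) for each node of a tree."""
    children: dict[int, list[int]] = {}
    for p, c in zip(edges["parent_id"], edges["child_id"]):
        children.setdefault(int(p), []).append(int(c))
    nodes = set(edges["parent_id"]).union(edges["child_id"])
    closure: dict[int, list[int]] = {}

    def descend(node: int) -> list[int]:
        if node in closure:
            return closure[node]
        out = [node]
        for ch in children.get(node, []):
            out.extend(descend(ch))
        closure[node] = out
        return out

    for n in nodes:
        descend(int(n))
    return closure


def compute_sleep_duration(light: float, deep: float, rem: float) -> float:
    """Total nightly sleep = light + deep + REM, in minutes."""
    if light < 0 or deep < 0 or rem < 0:
        raise ValueError("sleep stage durations must be non-negative")
    return light + deep + rem


def average_sleep_duration(nights: pd.DataFrame) -> float:
    """Mean total sleep over participant-nights.

    ``nights`` needs columns light, deep, rem (minutes).
    """
    if (nights[["light", "deep", "rem"]] < 0).any().any():
        raise ValueError("sleep stage durations must be non-negative")
    totals = nights["light"] + nights["deep"] + nights["rem"]
    return float(totals.mean())


def _hr_values(minutes: np.ndarray, amplitude: float, baseline: float,
               phase_h: float) -> np.ndarray:
    t = np.mod(minutes, _MINUTES_PER_DAY)
    return amplitude * np.sin(np.pi / 720.0 * (t - 60.0 * phase_h)) + baseline


def generate_hr_stream(truth_row: pd.Series | dict, config: SimConfig,
                       rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Raw heart-rate samples for one participant.

    Samples lie on a regular ``hr_sample_minutes`` grid over ``n_days``
    calendar days starting at ``monitoring_start`` (naive local time);
    each bin is independently dropped with probability
    ``missingness_rate``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    minutes = np.arange(0, config.n_days * _MINUTES_PER_DAY, config.hr_sample_minutes)
    keep = rng.random(minutes.size) >= config.missingness_rate
    minutes = minutes[keep]
    values = _hr_values(minutes, truth_row["amplitude"], truth_row["baseline"],
                        truth_row["phase"])
    if config.hr_noise_sd > 0:
        values = values + rng.normal(0.0, config.hr_noise_sd, minutes.size)
    start = pd.Timestamp(config.monitoring_start)
    return pd.DataFrame({
        "participant_id": truth_row["participant_id"],
        "timestamp": start + pd.to_timedelta(minutes, unit="m"),
        "bpm": values,
    })


def generate_cohort(config: SimConfig) -> SyntheticCohort:
    """Generate all input tables plus the truth table.

    Deterministic for a fixed ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_participants
    pid = np.arange(1, n + 1)

    # --- covariates ---------------------------------------------------
    age = np.clip(rng.normal(config.age_mean, config.age_sd, n), 21.0, 90.0)
    steps = np.clip(rng.normal(config.steps_mean_10k, config.steps_sd_10k, n), 0.2, None)
    y_chrom = rng.random(n) < config.y_chromosome_rate
    pcs = rng.normal(0.0, 1.0, (n, 5))
    confounder = rng.normal(0.0, 1.0, n)

    # --- genotypes ----------------------------------------------------
    geno_frames = []
    dosages: dict[str, np.ndarray] = {}
    for spec in config.snv_specs:
        is_alt = rng.random((n, 2)) < spec.alt_af
        alleles = np.where(is_alt, spec.alt_allele, spec.ref_allele).astype(object)
        if config.third_allele_rate > 0:
            third = _THIRD_ALLELES.get(spec.alt_allele, "N")
            if third in (spec.ref_allele, spec.alt_allele):
                third = next(a for a in "ACGT" if a not in (spec.ref_allele, spec.alt_allele))
            mask = rng.random((n, 2)) < config.third_allele_rate
            alleles[mask] = third
        dosages[spec.snv_id] = (alleles == spec.alt_allele).sum(axis=1).astype(int)
        geno_frames.append(pd.DataFrame({
            "participant_id": pid,
            "snv_id": spec.snv_id,
            "allele1": alleles[:, 0],
            "allele2": alleles[:, 1],
        }))
    genotypes = (pd.concat(geno_frames, ignore_index=True)
                 if geno_frames else
                 pd.DataFrame(columns=["participant_id", "snv_id", "allele1", "allele2"]))

    # --- true phase ---------------------------------------------------
    phase = np.full(n, config.phase_mean, dtype=float)
    for spec in config.snv_specs:
        phase = phase + dosages[spec.snv_id] * spec.phase_effect_min / 60.0
    phase = phase + config.confounding_strength * confounder
    phase = phase + rng.normal(0.0, config.phase_sd, n)
    amplitude = np.clip(rng.normal(config.hr_amplitude_mean, config.hr_amplitude_sd, n), 0.5, None)
    baseline = rng.normal(config.hr_baseline_mean, config.hr_baseline_sd, n)

    # --- diseases over the toy ontology -------------------------------
    ontology = build_toy_ontology(depth=3, branching=3)
    closure = _tree_closure(ontology)
    cond_rows: list[pd.DataFrame] = []
    truth = pd.DataFrame({
        "participant_id": pid,
        "phase": phase,
        "amplitude": amplitude,
        "baseline": baseline,
        "confounder": confounder,
        "age": age,
    })
    for spec in config.snv_specs:
        truth[f"dosage_{spec.snv_id}"] = dosages[spec.snv_id]

    for d in config.disease_specs:
        lp_effects = (d.log_or_per_hour * (phase - config.phase_mean)
                      + d.log_or_per_10k_steps * (steps - config.steps_mean_10k)
                      + d.log_or_per_year * (age - config.age_mean)
                      + d.log_or_y * y_chrom)
        lp = d.intercept + lp_effects + config.confounding_strength * confounder
        case = rng.random(n) < expit(lp)
        truth[f"disease_{d.concept_id}"] = case.astype(int)
        # diagnosis age: exponential waiting time from onset_age with
        # rate prop. to exp(covariate effects), truncated at censor age
        horizon = np.maximum(age - config.onset_age, 0.5)
        rate = config.diagnosis_base_rate * np.exp(lp_effects
                                                   + config.confounding_strength * confounder)
        u = rng.random(n)
        wait = -np.log1p(-u * -np.expm1(-rate * horizon)) / rate
        age_dx = np.where(case, config.onset_age + wait, np.nan)
        truth[f"age_dx_{d.concept_id}"] = age_dx
        members = closure.get(d.concept_id, [d.concept_id])
        concept_draw = rng.choice(members, size=n)
        idx = np.flatnonzero(case)
        cond_rows.append(pd.DataFrame({
            "participant_id": pid[idx],
            "concept_id": concept_draw[idx],
            "age_at_occurrence": age_dx[idx],
        }))
    conditions = (pd.concat(cond_rows, ignore_index=True) if cond_rows else
                  pd.DataFrame(columns=["participant_id", "concept_id", "age_at_occurrence"]))

    # --- monitoring window & covariate table ---------------------------
    start = pd.Timestamp(config.monitoring_start)
    monitoring_end = start + pd.Timedelta(days=config.n_days)
    gap_years = rng.uniform(0.0, 2.0, n)  # monitoring ends before study end
    covariates = pd.DataFrame({
        "participant_id": pid,
        "age": age,
        "y_chromosome": y_chrom,
        "pc1": pcs[:, 0], "pc2": pcs[:, 1], "pc3": pcs[:, 2],
        "pc4": pcs[:, 3], "pc5": pcs[:, 4],
        "weekly_steps": steps,
        "age_monitoring_end": age - gap_years,
        "monitoring_start": start,
        "monitoring_end": monitoring_end,
    })

    # --- HbA1c labs -----------------------------------------------------
    n_lab = int(round(config.hba1c_fraction * n))
    m = config.hba1c_model
    if n_lab:
        lab_pids = rng.choice(pid, size=n_lab, replace=False)
        k = 1 + rng.poisson(1.0, n_lab)  # >=1 measurement per sampled participant
        rep_pid = np.repeat(lab_pids, k)
        total = int(k.sum())
        ph = phase[rep_pid - 1]
        vals = (m.mean + m.slope_per_hour * (ph - config.phase_mean)
                + rng.normal(0.0, m.sd, total))
        junk = rng.random(total) < config.hba1c_outlier_rate
        vals[junk] = rng.choice([0.5, 32.0], size=int(junk.sum()))
        day_offsets = rng.uniform(0, config.n_days + 30, total)
        labs = pd.DataFrame({
            "participant_id": rep_pid,
            "date": start + pd.to_timedelta(day_offsets, unit="D"),
            "hba1c_pct": vals,
        })
    else:
        labs = pd.DataFrame(columns=["participant_id", "date", "hba1c_pct"])

    # --- raw HR stream --------------------------------------------------
    if config.generate_hr:
        minutes = np.arange(0, config.n_days * _MINUTES_PER_DAY, config.hr_sample_minutes)
        nbins = minutes.size
        keep = rng.random((n, nbins)) >= config.missingness_rate
        tgrid = np.mod(minutes, _MINUTES_PER_DAY)
        values = (amplitude[:, None]
                  * np.sin(np.pi / 720.0 * (tgrid[None, :] - 60.0 * phase[:, None]))
                  + baseline[:, None])
        if config.hr_noise_sd > 0:
            values = values + rng.normal(0.0, config.hr_noise_sd, (n, nbins))
        rows = np.flatnonzero(keep.ravel())
        pid_col = np.repeat(pid, nbins)[rows]
        min_col = np.tile(minutes, n)[rows]
        hr = pd.DataFrame({
            "participant_id": pid_col,
            "timestamp": start + pd.to_timedelta(min_col, unit="m"),
            "bpm": values.ravel()[rows],
        })
    else:
        hr = pd.DataFrame(columns=["participant_id", "timestamp", "bpm"])

    return SyntheticCohort(hr=hr, covariates=covariates, genotypes=genotypes,
                           conditions=conditions, ontology_edges=ontology,
                           labs=labs, truth=truth)


def mr_demo_config(n_participants: int, seed: int,
                   confounding_strength: float = 1.0,
                   causal_log_or_per_hour: float = 0.1,
                   instrument_effect_min: float = -30.0,
                   instrument_af: float = 0.2) -> SimConfig:
    """Study conditions for the Mendelian-randomization demonstration.

    One instrument (0.5 h earlier phase per allele, AF 0.20, so the
    stage-1 F is comfortably strong at the sizes used), a causal phase
    effect of 0.1 log-odds per hour on a single condition, and an
    unobserved standard-normal confounder entering both the phase and
    the outcome linear predictors with unit loading - strong enough
    that the naive (non-instrumented) logistic estimate is visibly
    biased relative to its sampling error.
    """
    from .config import DiseaseSpec, SNVSpec

    return SimConfig(
        n_participants=n_participants, seed=seed, generate_hr=False,
        confounding_strength=confounding_strength,
        snv_specs=[SNVSpec("rs_instr", alt_af=instrument_af,
                           phase_effect_min=instrument_effect_min)],
        disease_specs=[DiseaseSpec(concept_id=2, intercept=-1.9,
                                   log_or_per_hour=causal_log_or_per_hour,
                                   log_or_per_10k_steps=-0.1,
                                   log_or_per_year=0.04, log_or_y=0.2)],
    )


def simulate_survival_cohort(n: int, log_hr_per_hour: float, seed: int,
                             phase_mean: float = 9.48, phase_sd: float = 1.57,
                             log_hr_per_10k_steps: float = -0.05,
                             base_rate: float = 0.005,
                             onset_age: float = 20.0) -> pd.DataFrame:
    """Survival records under an exact exponential proportional-hazards truth.

    The diagnosis hazard from ``onset_age`` is
    ``base_rate * exp(log_hr_per_hour*(phase-phase_mean)
    + log_hr_per_10k_steps*(steps-mean))``, right-censored at the age at
    study end.  Used to check Cox-regression recovery of the log hazard
    ratio per hour of phase.
    """
    rng = np.random.default_rng(seed)
    phase = rng.normal(phase_mean, phase_sd, n)
    steps = np.clip(rng.normal(5.5, 2.0, n), 0.2, None)
    y_chrom = rng.random(n) < 0.32
    pcs = rng.normal(0.0, 1.0, (n, 5))
    censor_age = np.clip(rng.normal(55.0, 12.0, n), 21.0, 90.0)
    rate = base_rate * np.exp(log_hr_per_hour * (phase - phase_mean)
                              + log_hr_per_10k_steps * (steps - 5.5))
    t = onset_age + rng.exponential(1.0 / rate, n)
    event = t < censor_age
    out = pd.DataFrame({
        "participant_id": np.arange(1, n + 1),
        "phi": phase,
        "weekly_steps": steps,
        "y_chromosome": y_chrom,
        "age": np.where(event, t, censor_age),
        "event": event,
    })
    for j in range(5):
        out[f"pc{j+1}"] = pcs[:, j]
    return out
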