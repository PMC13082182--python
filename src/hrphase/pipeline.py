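"""End-to-end orchestration: phase -> filters -> genetics -> PheWAS ->
disease outcomes -> Mendelian randomization, with a provenance manifest.

All randomness flows from the single run seed, split per stage with
``numpy.random.SeedSequence`` so stages are individually reproducible.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig, SimConfig
from .genetics import run_snv_scan, compute_allele_frequencies, code_additive
from .mr import TwoStageResidualInclusion
from .outcomes import (build_survival_records, cox_age_at_diagnosis, flag_t2dm,
                       logistic_risk, max_hba1c_before_end)
from .phase import apply_inclusion_filters, fit_cohort, select_r2_threshold
from .phewas import ConditionOntology, build_phenotype_matrix, run_phewas
from .synthetic import SyntheticCohort, generate_cohort

logger = logging.getLogger("hrphase")

__all__ = ["PipelineResult", "run_pipeline", "manifest_hash"]


@dataclass
class PipelineResult:
    cohort: pd.DataFrame
    threshold_scan: object
    snv_results: pd.DataFrame
    phewas_results: pd.DataFrame
    t2dm_logistic: object
    hba1c_logistic: object
    cox: dict | None
    mr: object
    manifest: dict = field(default_factory=dict)


def manifest_hash(manifest: dict) -> str:
    payload = json.dumps(manifest, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()


def _stage_seeds(seed: int, n: int = 4) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def run_pipeline(tables: SyntheticCohort | dict, run_config: RunConfig | None = None,
                 mr_resamples: int | None = None) -> PipelineResult:
    """Run every analysis stage in order on a table bundle.

    ``tables`` is a :class:`~hrphase.synthetic.SyntheticCohort` or a
    dict with the same keys (hr, covariates, genotypes, conditions,
    ontology_edges, labs).  Any stage failure raises with the stage
    name; filter counts are logged and recorded in the manifest.
    """
    rc = run_config or RunConfig()
    t = tables.tables() if isinstance(tables, SyntheticCohort) else dict(tables)
    seeds = _stage_seeds(rc.seed)
    manifest: dict = {
        "package_version": __version__,
        "run_config": rc.to_dict(),
        "stage_seeds": seeds,
        "counts": {},
    }
    counts = manifest["counts"]

    # --- stage 1: phase extraction -----------------------------------
    stage = "phase"
    try:
        hr = t["hr"]
        counts["hr_samples"] = int(len(hr))
        fits = fit_cohort(hr)
        counts["participants_with_hr"] = int(len(fits))
        scan = select_r2_threshold(fits["r_squared"], grid_step=rc.r2_grid_step)
        filtered = apply_inclusion_filters(fits, scan.selected,
                                           min_days=rc.min_days,
                                           sd_limit=rc.phase_sd_limit)
        cohort = filtered.merge(t["covariates"], on="participant_id", how="left")
        included = cohort[cohort["included"]].reset_index(drop=True)
        counts["selected_r2_threshold"] = scan.selected
        counts["excluded_days"] = int((filtered["exclusion_reason"] == "days").sum())
        counts["excluded_r2"] = int((filtered["exclusion_reason"] == "r_squared").sum())
        counts["excluded_phase_outlier"] = int(
            (filtered["exclusion_reason"] == "phase_outlier").sum())
        counts["included"] = int(len(included))
        logger.info("phase: %d fitted, threshold %.1f, %d included",
                    len(fits), scan.selected, len(included))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    # --- stage 2: genetics -------------------------------------------
    stage = "genetics"
    try:
        genotypes = t["genotypes"]
        snv_results = run_snv_scan(included, genotypes,
                                   min_alt_af=rc.min_alt_af,
                                   cov_type=rc.robust_cov)
        counts["snvs_total"] = int(genotypes["snv_id"].nunique())
        counts["snvs_tested"] = int(len(snv_results))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    # --- stage 3: PheWAS ---------------------------------------------
    stage = "phewas"
    try:
        ontology = ConditionOntology(t["ontology_edges"])
        pheno = build_phenotype_matrix(t["conditions"], ontology,
                                       included["participant_id"],
                                       max_depth=rc.phewas_max_depth,
                                       min_cases=rc.min_cases)
        phewas_results = run_phewas(included, pheno, cov_type=rc.robust_cov)
        counts["phewas_concepts"] = int(pheno.shape[1])
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    # --- stage 4: T2DM outcomes --------------------------------------
    stage = "t2dm"
    try:
        t2dm = flag_t2dm(t["conditions"], ontology, rc.t2dm_concept_id,
                         included["participant_id"])
        counts["t2dm_cases"] = int(t2dm.sum())
        t2dm_logit = logistic_risk(included, t2dm, exposure="phi",
                                   cov_type=rc.robust_cov)
        labs = t["labs"]
        end = included.set_index("participant_id")["monitoring_end"] \
            if "monitoring_end" in included.columns else None
        hba1c_logit = None
        if end is not None and len(labs):
            hba = max_hba1c_before_end(labs, end, bounds=rc.hba1c_bounds,
                                       elevated_threshold=rc.hba1c_elevated_threshold)
            counts["hba1c_participants"] = int(len(hba))
            if len(hba) and hba["elevated"].nunique() > 1:
                age_col = ("age_monitoring_end"
                           if "age_monitoring_end" in included.columns else "age")
                hba1c_logit = logistic_risk(included, hba["elevated"].astype(int),
                                            exposure="phi", age_col=age_col,
                                            cov_type=rc.robust_cov)
        records = build_survival_records(included, t2dm, t["conditions"],
                                         ontology, rc.t2dm_concept_id)
        cox = None
        if t2dm.sum() > 0:
            try:
                cox = cox_age_at_diagnosis(records, exposure="phi")
                counts["cox_events"] = cox["n_events"]
            except Exception as exc:
                logger.warning("cox fit skipped: %s", exc)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    # --- stage 5: Mendelian randomization ----------------------------
    stage = "mr"
    mr_res = None
    try:
        snv_table = compute_allele_frequencies(genotypes, min_alt_af=rc.min_alt_af)
        usable = snv_table[~snv_table["excluded"]]
        if len(usable) and t2dm.sum() > 0:
            instrument_row = usable.iloc[0]
            dosage = code_additive(genotypes, instrument_row)
            df = included.set_index("participant_id").copy()
            df["t2dm"] = t2dm
            df["dosage"] = dosage.reindex(df.index)
            if df["dosage"].nunique() > 1:
                n_res = mr_resamples if mr_resamples is not None else rc.mr_resamples
                import warnings as _w
                try:
                    model = TwoStageResidualInclusion(df, outcome="t2dm",
                                                      exposure="phi",
                                                      instrument="dosage")
                    with _w.catch_warnings():
                        _w.simplefilter("ignore")
                        mr_res = model.fit(n_resamples=n_res, seed=seeds[3])
                    counts["mr_instrument"] = str(instrument_row["snv_id"])
                    counts["mr_stage1_F"] = round(mr_res.stage1_F, 6)
                except (np.linalg.LinAlgError, ValueError) as exc:
                    # too few cases for the stage-2 MLE: record, don't halt
                    counts["mr_skipped"] = str(exc)
                    logger.warning("mr stage skipped: %s", exc)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    manifest["hash_inputs"] = {
        name: int(pd.util.hash_pandas_object(df).sum()) % (2**63)
        for name, df in t.items() if isinstance(df, pd.DataFrame)
    }
    manifest["manifest_hash"] = manifest_hash(
        {k: v for k, v in manifest.items() if k != "manifest_hash"})
    return PipelineResult(cohort=cohort, threshold_scan=scan,
                          snv_results=snv_results,
                          phewas_results=phewas_results,
                          t2dm_logistic=t2dm_logit,
                          hba1c_logistic=hba1c_logit,
                          cox=cox, mr=mr_res, manifest=manifest)


def run_synthetic_pipeline(sim_config: SimConfig | None = None,
                           run_config: RunConfig | None = None,
                           mr_resamples: int = 500) -> PipelineResult:
    """Simulate a cohort and run the full pipeline on it."""
    sim = sim_config or SimConfig()
    rc = run_config or RunConfig(seed=sim.seed)
    tables = generate_cohort(sim)
    return run_pipeline(tables, rc, mr_resamples=mr_resamples)
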