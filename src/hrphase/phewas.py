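"""Phenome-wide association of phase with ontology-defined conditions.

Conditions live in a hierarchical clinical vocabulary (an OMOP-style
tree or DAG).  A participant counts as a case for a concept if they
have an occurrence of the concept or any descendant within two degrees
of separation (shortest-path distance <= 2); concepts with more than
100 cases are each modelled by logistic regression of case status on
phase, weekly steps, age, Y-chromosome presence and five ancestry PCs
with sandwich standard errors, Bonferroni-adjusted over the retained
concepts.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
import networkx as nx
import statsmodels.api as sm

from statsmodels.tools.sm_exceptions import PerfectSeparationError

__all__ = [
    "ConditionOntology",
    "descendant_closure",
    "build_phenotype_matrix",
    "run_phewas",
]

PHEWAS_COVARIATES = ["weekly_steps", "age", "y_chromosome",
                     "pc1", "pc2", "pc3", "pc4", "pc5"]


class ConditionOntology:
    """A concept hierarchy held as a directed graph (parent -> child).

    May be a tree or a DAG; cycles are rejected.  Descendant queries
    use shortest-path (breadth-first) distance.
    """

    def __init__(self, edges: pd.DataFrame):
        g = nx.DiGraph()
        g.add_edges_from(zip(edges["parent_id"], edges["child_id"]))
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("ontology edges contain a cycle")
        self.graph = g

    def __contains__(self, concept) -> bool:
        return concept in self.graph

    @property
    def nodes(self) -> list:
        return sorted(self.graph.nodes)

    @property
    def roots(self) -> list:
        return sorted(n for n in self.graph.nodes if self.graph.in_degree(n) == 0)

    def descendants(self, concept, max_depth: int | None = None) -> set:
        """{concept} union descendants at shortest-path depth <= max_depth."""
        if concept not in self.graph:
            raise KeyError(f"unknown concept {concept!r}")
        lengths = nx.single_source_shortest_path_length(self.graph, concept,
                                                        cutoff=max_depth)
        return set(lengths)

    def ancestors_within(self, concept, max_depth: int | None = None) -> set:
        """Concepts whose closure at ``max_depth`` contains ``concept``."""
        if concept not in self.graph:
            raise KeyError(f"unknown concept {concept!r}")
        rg = self.graph.reverse(copy=False)
        lengths = nx.single_source_shortest_path_length(rg, concept,
                                                        cutoff=max_depth)
        return set(lengths)


def descendant_closure(ontology: ConditionOntology, concept,
                       max_depth: int | None = 2) -> list:
    """Deterministically ordered closure of ``concept``.

    ``max_depth=None`` means unlimited depth (used for focused disease
    definitions); the PheWAS convention is depth 2.
    """
    return sorted(ontology.descendants(concept, max_depth=max_depth))


def build_phenotype_matrix(occurrences: pd.DataFrame,
                           ontology: ConditionOntology,
                           participant_ids: np.ndarray | pd.Series,
                           max_depth: int | None = 2,
                           min_cases: int = 100) -> pd.DataFrame:
    """Participant x concept case-indicator matrix.

    A participant is a case for a concept when they have at least one
    occurrence of the concept or of a member of its depth-bounded
    descendant closure.  Concepts with case counts of ``min_cases`` or
    fewer (i.e. not strictly more) are dropped.

    Parameters
    ----------
    occurrences : columns participant_id, concept_id.
    participant_ids : the analysis cohort; indicators are reported for
        exactly these participants, in this order.
    """
    unknown = set(occurrences["concept_id"]) - set(ontology.graph.nodes)
    if unknown:
        raise KeyError(f"occurrences reference unknown concepts: {sorted(unknown)[:5]}")
    pids = np.asarray(participant_ids)
    pid_index = pd.Index(pids)
    cols: dict = {}
    occ = occurrences[occurrences["participant_id"].isin(pid_index)]
    # propagate each occurrence up to the concepts whose closure holds it
    carriers: dict = {}
    for concept, grp in occ.groupby("concept_id"):
        members = ontology.ancestors_within(concept, max_depth=max_depth)
        pset = set(grp["participant_id"])
        for m in members:
            carriers.setdefault(m, set()).update(pset)
    for concept in sorted(carriers):
        cases = carriers[concept]
        if len(cases) > min_cases:
            cols[concept] = pid_index.isin(cases)
    out = pd.DataFrame(cols, index=pid_index)
    out.index.name = "participant_id"
    return out


def _fit_logit(y: np.ndarray, X: pd.DataFrame, cov_type: str = "HC1"):
    model = sm.Logit(y, X)
    try:
        fit = model.fit(disp=0, maxiter=100, cov_type=cov_type)
    except (PerfectSeparationError, np.linalg.LinAlgError):
        return None, "separation"
    if not fit.mle_retvals.get("converged", False):
        return fit, "not_converged"
    return fit, ""


def run_phewas(cohort: pd.DataFrame, phenotypes: pd.DataFrame,
               cov_type: str = "HC1") -> pd.DataFrame:
    """One logistic regression per retained concept.

    Exposure is phase in hours (column ``phi``); the reported effect is
    the odds ratio per hour with a robust 95% CI.  Bonferroni
    m = number of retained concepts.  Non-converging or separated fits
    are flagged, never silently dropped.
    """
    df = cohort.set_index("participant_id") if "participant_id" in cohort.columns else cohort
    df = df.loc[phenotypes.index]
    X = sm.add_constant(df[["phi"] + PHEWAS_COVARIATES].astype(float))
    m = phenotypes.shape[1]
    rows = []
    for concept in phenotypes.columns:
        y = phenotypes[concept].to_numpy(dtype=float)
        fit, flag = _fit_logit(y, X, cov_type=cov_type)
        if fit is None or flag == "separation":
            rows.append({"concept_id": concept, "beta_per_hour": np.nan,
                         "or_per_hour": np.nan, "se": np.nan, "p": np.nan,
                         "p_adj": np.nan, "or_ci_low": np.nan, "or_ci_high": np.nan,
                         "n_cases": int(y.sum()), "n": len(y),
                         "converged": False, "flag": flag or "separation"})
            continue
        beta = float(fit.params["phi"])
        se = float(fit.bse["phi"])
        p = float(fit.pvalues["phi"])
        ci = fit.conf_int().loc["phi"]
        rows.append({"concept_id": concept, "beta_per_hour": beta,
                     "or_per_hour": float(np.exp(beta)), "se": se, "p": p,
                     "p_adj": min(1.0, p * m),
                     "or_ci_low": float(np.exp(ci[0])),
                     "or_ci_high": float(np.exp(ci[1])),
                     "n_cases": int(y.sum()), "n": len(y),
                     "converged": flag == "", "flag": flag})
    out = pd.DataFrame(rows)
    return out.sort_values("p", na_position="last", ignore_index=True) if len(out) else out
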