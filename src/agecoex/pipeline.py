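"""End-to-end orchestration: one cohort, and the two-cohort comparison.

`analyze_cohort` chains the network stage, the young/old DEG screen, and
age-related module selection; `compare_cohorts` intersects two cohorts'
age-related module genes and DEG lists into a shared signature and ranks
shared hub genes on a PPI subnetwork.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .config import PipelineConfig
from .containers import ExpressionMatrix, TraitTable, align_samples
from .diffexpr import DEGSummary, differential_expression
from .hubs import rank_module_hubs
from .network import CoexpressionNetwork, CoexpressionResults
from .trajectory import SharedSignature, shared_signature

log = logging.getLogger("agecoex")


@dataclass
class CohortAnalysis:
    """Everything the pipeline derives from a single cohort."""

    network: CoexpressionResults
    deg_table: pd.DataFrame
    deg_summary: DEGSummary
    age_modules: list[str]
    age_module_genes: set[str]

    @property
    def significant_degs(self) -> set[str]:
        return set(self.deg_table.index[self.deg_table.significant])


def analyze_cohort(
    expression: ExpressionMatrix,
    traits: TraitTable,
    config: PipelineConfig | None = None,
    beta: int | None = None,
    group_column: str = "group",
    deg_method: str = "moderated",
    age_module_max_p: float = 0.05,
) -> CohortAnalysis:
    """Network stage + young/old DEG screen + age-module selection.

    The DEG contrast uses the `group_column` labels 'young' vs 'old'
    (other labels, e.g. 'middle', are simply excluded from the contrast).
    Age-related modules are those whose eigengene-age correlation has
    p < `age_module_max_p`.
    """
    config = config or PipelineConfig()
    traits = align_samples(expression, traits)
    results = CoexpressionNetwork(expression, traits, config).fit(beta=beta)
    groups = traits.data[group_column]
    deg_table, deg_summary = differential_expression(
        expression,
        groups,
        lfc_threshold=config.deg_lfc_threshold,
        fdr=config.deg_fdr,
        method=deg_method,
    )
    age_modules = results.age_related_modules(max_p=age_module_max_p)
    genes = {g for mod in age_modules for g in results.module_genes(mod)}
    log.info(
        "analyze_cohort: %d modules, %d age-related (%d genes), %d DEGs",
        len(results.partition.modules()), len(age_modules), len(genes), deg_summary.n_total,
    )
    return CohortAnalysis(results, deg_table, deg_summary, age_modules, genes)


@dataclass
class CohortComparison:
    signature: SharedSignature
    hubs: pd.DataFrame | None


def compare_cohorts(
    a: CohortAnalysis,
    b: CohortAnalysis,
    ppi: nx.Graph | None = None,
    top_k: int = 5,
) -> CohortComparison:
    """Shared signature across cohorts, optionally with shared-hub ranking.

    The gene universe for the overlap test is the union of both cohorts'
    analyzed genes; hub ranking runs on the PPI subnetwork induced by the
    shared genes when a PPI graph is supplied.
    """
    universe = set(a.network.partition.labels.index) | set(b.network.partition.labels.index)
    sig = shared_signature(
        a.age_module_genes,
        b.age_module_genes,
        a.significant_degs,
        b.significant_degs,
        len(universe),
    )
    hubs = None
    if ppi is not None and sig.shared:
        hubs = rank_module_hubs(ppi, sorted(sig.shared), k=top_k)
    return CohortComparison(signature=sig, hubs=hubs)
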