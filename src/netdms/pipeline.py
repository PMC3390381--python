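"""End-to-end bi-directional pipeline orchestration.

Chains gene-level summarisation, network construction, dense module search,
multi-layer assessment, combinatorial selection, cross-study evaluation and
consensus merging for a pair of GWAS datasets.  Each of the two studies is
used once for discovery and once for evaluation; the consensus subnetwork
is the union of both directions' surviving modules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import gwas_io
from .assessment import assess_all
from .dms import Module, search_all
from .errors import NetdmsError
from .network import build_weighted_network
from .selection import (
    ConsensusSubnetwork,
    SelectionCriteria,
    evaluate_in_second_study,
    merge_selected,
    select_evaluated,
    select_modules,
)

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineParams:
    """All tunables of the bi-directional pipeline (defaults as published
    for this family of analyses: r=0.1, d=2, flank=20 kb, B=1000 for
    assessment, alphas 0.05)."""

    r: float = 0.1
    d: int = 2
    flank: int = 20_000
    B: int = 1000
    n_strata: int = 10
    criteria: SelectionCriteria = field(default_factory=SelectionCriteria)
    max_missing_fraction: float = 0.2
    min_module_size: int = 1
    seed: int = 0


@dataclass
class DirectionResult:
    discovery: str
    evaluation: str
    modules: list[Module]
    assessed: pd.DataFrame
    evaluated: pd.DataFrame
    selected_idx: list[int]
    final_idx: list[int]
    funnel: dict

    @property
    def final_modules(self) -> list[Module]:
        return [self.modules[i] for i in self.final_idx]


@dataclass
class PipelineResult:
    directions: dict
    consensus: ConsensusSubnetwork
    gene_assoc: dict


def gene_level_from_snps(
    snps: pd.DataFrame, annotation: pd.DataFrame, flank: int = 20_000
) -> pd.DataFrame:
    """SNP table -> gene-wise association table (min-P summary)."""
    mapping = gwas_io.map_snps_to_genes(snps, annotation, flank)
    return gwas_io.gene_wise_p(snps, mapping, annotation)


def run_direction(
    name_disc: str,
    name_eval: str,
    assoc_disc: pd.DataFrame,
    assoc_eval: pd.DataFrame,
    edges,
    perm_disc: pd.DataFrame | None,
    perm_eval: pd.DataFrame | None,
    params: PipelineParams,
    seed: int,
) -> DirectionResult:
    """One discovery -> evaluation thread."""
    net_disc = build_weighted_network(edges, assoc_disc)
    net_eval = build_weighted_network(edges, assoc_eval)
    modules = search_all(net_disc, r=params.r, d=params.d)
    if params.min_module_size > 1:
        keep = [i for i, m in enumerate(modules) if m.k >= params.min_module_size]
        modules = [modules[i] for i in keep]
    assessed = assess_all(
        modules, net_disc, assoc_disc, perm_disc,
        B=params.B, seed=seed, n_strata=params.n_strata,
    )
    selected = select_modules(assessed, params.criteria)
    selected_idx = list(selected.index)
    evaluated = evaluate_in_second_study(
        modules, net_eval, perm_eval,
        max_missing_fraction=params.max_missing_fraction,
    )
    eval_pass = select_evaluated(evaluated, params.criteria)
    final_idx = sorted(set(selected_idx) & set(eval_pass.index))
    n_zm_eval = int(
        (
            evaluated.loc[selected_idx, "valid"]
            & (evaluated.loc[selected_idx, "p_zm_eval"] < params.criteria.alpha_zm_eval)
        ).sum()
    )
    funnel = {
        "modules": len(modules),
        "pass_combinatorial": len(selected_idx),
        "pass_zm_eval": n_zm_eval,
        "final": len(final_idx),
    }
    log.info(
        "%s->%s funnel: %d modules, %d pass combinatorial, %d pass eval score, %d final",
        name_disc, name_eval, *funnel.values(),
    )
    return DirectionResult(
        discovery=name_disc, evaluation=name_eval, modules=modules,
        assessed=assessed, evaluated=evaluated,
        selected_idx=selected_idx, final_idx=final_idx, funnel=funnel,
    )


def run_bidirectional(
    snp_tables: dict,
    annotation: pd.DataFrame,
    edges,
    perm_matrices: dict | None = None,
    params: PipelineParams = PipelineParams(),
) -> PipelineResult:
    """Run both discovery/evaluation threads and merge the survivors.

    ``snp_tables`` maps two study labels to SNP association tables;
    ``perm_matrices`` maps the same labels to gene x permutation P
    matrices.  The consensus gene union is symmetric in the two studies by
    construction (swapping them swaps direction labels only).
    """
    labels = sorted(snp_tables)
    if len(labels) != 2:
        raise NetdmsError("run_bidirectional needs exactly two studies")
    perm_matrices = perm_matrices or {}
    assoc = {
        lab: gene_level_from_snps(snp_tables[lab], annotation, params.flank)
        for lab in labels
    }
    ss = np.random.SeedSequence(params.seed)
    child = {lab: s for lab, s in zip(labels, ss.spawn(2))}
    directions = {}
    for disc, ev in ((labels[0], labels[1]), (labels[1], labels[0])):
        directions[f"{disc}->{ev}"] = run_direction(
            disc, ev, assoc[disc], assoc[ev], edges,
            perm_matrices.get(disc), perm_matrices.get(ev),
            params, seed=int(child[disc].generate_state(1)[0] % (2**31)),
        )
    keys = list(directions)
    consensus = merge_selected(
        directions[keys[0]].final_modules,
        directions[keys[1]].final_modules,
        edges,
        labels=(keys[0], keys[1]),
    )
    return PipelineResult(directions=directions, consensus=consensus, gene_assoc=assoc)


def recovery_metrics(consensus_genes, planted_genes) -> dict:
    """Recall and precision of a consensus gene set against planted truth."""
    consensus = set(consensus_genes)
    planted = set(planted_genes)
    tp = len(consensus & planted)
    return {
        "recall": tp / len(planted) if planted else float("nan"),
        "precision": tp / len(consensus) if consensus else float("nan"),
        "n_consensus": len(consensus),
        "n_planted": len(planted),
    }
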