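"""End-to-end domain assignment: configuration, orchestration, run report.

The pipeline steps are: parse and annotate the chain, build the contact
graph, decide single vs multi domain (classifier, unless the domain count
is forced or multi-domain is assumed), compute the diffusion kernel with
the Rg^2-scaled bandwidth, generate candidate partitionings over increasing
m with structure-aware post-processing, and select the domain count by the
hydrophobic-residue silhouette. The report captures everything needed to
reproduce the run (config, seed, realized bandwidth, per-m outcomes).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

from .classify import BaggingModel, extract_features, predict
from .clustering import DEFAULT_RESTARTS
from .contacts import build_contact_graph
from .kernels import ETA_DEFAULTS, default_bandwidth
from .partition import (
    DomainAssignment,
    LoopReportEntry,
    Params,
    candidate_loop,
    select_assignment,
)
from .structure import ProteinChain, annotate, parse_chain


@dataclass
class RunConfig:
    """Everything that determines one assignment run."""

    structure: str | None = None
    chain_id: str = "A"
    dssp: str | None = None
    kernel: str = "led"
    clusterer: str = "kernel-kmeans"
    eta: float | None = None  # None -> per (kernel, clusterer) default
    restarts: int = DEFAULT_RESTARTS
    seed: int = 0
    params: Params = field(default_factory=Params)
    num_domains: int | None = None  # force an exact domain count
    min_domains: int | None = None
    max_domains: int | None = None
    force_multi: bool = False
    model_path: str | None = None  # classifier; None -> assume multi
    cutoff: float = 4.0

    def realized_eta(self) -> float:
        return self.eta if self.eta is not None else ETA_DEFAULTS[
            (self.kernel, self.clusterer)
        ]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["params"] = dataclasses.asdict(self.params)
        return d


def assign_domains(
    chain: ProteinChain, config: RunConfig
) -> tuple[DomainAssignment, dict]:
    """Run the assignment pipeline on an already-annotated chain."""
    graph = build_contact_graph(chain, cutoff=config.cutoff)
    report: dict = {
        "config": config.to_dict(),
        "n_residues": chain.n,
        "radius_of_gyration": chain.rg,
        "graph_components": graph.n_components,
        "bandwidth": default_bandwidth(
            config.kernel, config.clusterer, chain.rg, config.eta
        ),
    }

    if config.num_domains is not None:
        verdict, vote = "forced", None
        report["classifier"] = "bypassed (domain count forced)"
    elif config.force_multi:
        verdict, vote = "multi", None
        report["classifier"] = "bypassed (--force-multi)"
    elif config.model_path is not None:
        model = BaggingModel.load(config.model_path)
        fv = extract_features(chain, graph, seed=config.seed)
        verdict, vote = predict(model, fv)
        report["classifier"] = {"verdict": verdict, "multi_vote_fraction": vote}
    else:
        verdict, vote = "multi", None
        report["classifier"] = "no model supplied; assuming multi-domain"

    if verdict == "single" or config.num_domains == 1:
        assignment = select_assignment([], "single", chain.n)
        if config.num_domains == 1:
            assignment.source = "forced"
        report["candidates"] = []
    else:
        if config.num_domains is not None:
            m_bounds = (config.num_domains, config.num_domains)
        elif config.min_domains or config.max_domains:
            m_bounds = (config.min_domains or 2, config.max_domains or chain.n)
        else:
            m_bounds = None
        loop_report: list[LoopReportEntry] = []
        candidates = candidate_loop(
            chain,
            graph,
            kernel_kind=config.kernel,
            clusterer=config.clusterer,
            eta=config.eta,
            restarts=config.restarts,
            seed=config.seed,
            params=config.params,
            m_bounds=m_bounds,
            report=loop_report,
        )
        report["candidates"] = [
            {
                "m": e.m,
                "accepted": e.accepted,
                "silhouette": e.silhouette,
                "m_effective": e.m_effective,
                "reason": e.reason,
            }
            for e in loop_report
        ]
        if config.num_domains is not None:
            assignment = select_assignment(
                candidates, "forced", chain.n, forced_m=config.num_domains
            )
        else:
            assignment = select_assignment(candidates, "multi", chain.n)

    report["n_domains"] = assignment.n_domains
    report["assignment"] = assignment.to_range_string()
    report["source"] = assignment.source
    report["silhouette"] = assignment.silhouette
    return assignment, report


def run(config: RunConfig) -> tuple[DomainAssignment, dict]:
    """Full pipeline from a structure file (with optional DSSP annotation)."""
    if config.structure is None:
        raise ValueError("config.structure is required")
    chain = parse_chain(config.structure, config.chain_id)
    annotate(chain, config.dssp)
    return assign_domains(chain, config)


def write_report(report: dict, path: str | Path | None) -> str:
    text = json.dumps(report, indent=2, sort_keys=True)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text
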