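"""End-to-end orchestration: config in, all stage outputs and a run log out.

``run`` is a pure composition of the stage operations — network
construction, complex detection, disease enrichment, comorbidity
filtering, pathway enrichment, shared-pathway flagging, artifact writing —
with no hidden state, so driving the stages by hand yields identical
results. Every threshold comes from :class:`RunConfig`, whose defaults are
the standard study settings (confidence >= 0.73, canonical MCODE
parameters, disease alpha 0.01, pathway alpha 0.05).
"""

from __future__ import annotations

import dataclasses
import logging
import sys
import warnings
from pathlib import Path

import yaml

from . import disease_enrichment, mcode, network_io, pathway_enrichment

logger = logging.getLogger("comorbnet")

__all__ = ["RunConfig", "RunReport", "PipelineError", "run", "load_config"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclasses.dataclass
class RunConfig:
    interactions: str
    annotations: str
    pathways: str
    comorbid: str
    out_dir: str
    min_confidence: float = 0.73
    mcode: mcode.McodeParams = dataclasses.field(
        default_factory=mcode.McodeParams)
    disease_alpha: float = 0.01
    disease_alternative: str = "greater"
    pathway_alpha: float = 0.05
    universe_mode: str = "network"  # or "annotated"
    rng_seed: int = 0  # used only by the synthetic subcommand

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def load_config(path, overrides: dict | None = None) -> RunConfig:
    """Load a YAML config; ``overrides`` maps dotted keys to values."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    for key, value in (overrides or {}).items():
        target = raw
        parts = key.split(".")
        for part in parts[:-1]:
            target = target.setdefault(part, {})
        target[parts[-1]] = value
    mcode_params = mcode.McodeParams(**raw.pop("mcode", {}))
    return RunConfig(mcode=mcode_params, **raw)


@dataclasses.dataclass(frozen=True)
class RunReport:
    n_input_records: int
    n_retained_proteins: int
    n_retained_edges: int
    n_clusters: int
    n_significant_diseases: int
    n_disease_subnetworks: int
    n_shared_pathways: int
    files: dict


def _log_stage(name: str, **counts) -> None:
    detail = " ".join(f"{k}={v}" for k, v in counts.items())
    logger.info("stage=%s %s", name, detail)


def run(config: RunConfig) -> RunReport:
    """Execute the whole pipeline; partial outputs are removed on failure."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_path = out_dir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    stderr_handler = logging.StreamHandler(sys.stderr)
    fmt = logging.Formatter("%(levelname)s %(message)s")
    handler.setFormatter(fmt)
    stderr_handler.setFormatter(fmt)
    logger.addHandler(handler)
    logger.addHandler(stderr_handler)
    logger.setLevel(logging.INFO)
    written: list = []
    stage = "setup"
    try:
        logger.info("config %s", config.to_dict())

        stage = "build_network"
        records = network_io.read_interactions(config.interactions)
        network, report = network_io.build_network(
            records, config.min_confidence)
        _log_stage(stage, records=report.n_input_records,
                   proteins=report.n_retained_proteins,
                   edges=report.n_retained_edges,
                   excluded=len(report.excluded_proteins))

        stage = "mcode"
        clusters = mcode.find_clusters(network, config.mcode)
        _log_stage(stage, clusters=len(clusters))

        stage = "disease_enrichment"
        annotation = network_io.read_disease_annotations(config.annotations)
        disease_results = disease_enrichment.enrich_clusters(
            clusters, annotation, network,
            alpha=config.disease_alpha,
            alternative=config.disease_alternative)
        n_significant = sum(r.significant for r in disease_results)
        _log_stage(stage, tested=len(disease_results),
                   significant=n_significant)

        stage = "comorbidity_filter"
        comorbid = network_io.read_comorbid_list(config.comorbid)
        if comorbid:
            filtered = disease_enrichment.comorbidity_filter(
                disease_results, comorbid)
        else:
            filtered = []
            warnings.warn("empty comorbid list: no disease subnetworks; "
                          "pathway stage skipped", stacklevel=2)
        subnetwork_ids = disease_enrichment.disease_subnetwork_ids(filtered)
        _log_stage(stage, comorbid_listed=len(comorbid),
                   kept=len(filtered), disease_subnetworks=len(subnetwork_ids))

        stage = "pathway_enrichment"
        pathway_results: list = []
        if subnetwork_ids:
            pathways = network_io.read_gene_sets(config.pathways)
            if config.universe_mode == "annotated":
                universe = set()
                for _, members in pathways.items():
                    universe |= members
                universe &= set(network.nodes)
            else:
                universe = set(network.nodes)
            for cluster in clusters:
                if cluster.rank in subnetwork_ids:
                    pathway_results += pathway_enrichment.enrich_pathways(
                        cluster, pathways, universe,
                        alpha=config.pathway_alpha)
            pathway_results = pathway_enrichment.flag_shared_pathways(
                pathway_results, filtered)
        else:
            logger.warning("stage=pathway_enrichment skipped: "
                           "no disease subnetworks")
        n_shared = sum(r.shared for r in pathway_results)
        _log_stage(stage, tested=len(pathway_results), shared=n_shared)

        stage = "write_results"
        # merge comorbid flags into the full disease table for reporting
        flagged = {(r.cluster_id, r.disease) for r in filtered if r.comorbid}
        disease_out = [
            dataclasses.replace(r, comorbid=(r.cluster_id, r.disease)
                                in flagged)
            for r in disease_results]
        files = network_io.write_results(
            out_dir, network, clusters, disease_out, pathway_results)
        written = list(files.values())
        files["run_log"] = log_path
        _log_stage(stage, files=len(files))

        return RunReport(
            n_input_records=report.n_input_records,
            n_retained_proteins=report.n_retained_proteins,
            n_retained_edges=report.n_retained_edges,
            n_clusters=len(clusters),
            n_significant_diseases=n_significant,
            n_disease_subnetworks=len(subnetwork_ids),
            n_shared_pathways=n_shared,
            files=files,
        )
    except Exception as exc:
        for path in written:
            Path(path).unlink(missing_ok=True)
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    finally:
        logger.removeHandler(handler)
        logger.removeHandler(stderr_handler)
        handler.close()
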