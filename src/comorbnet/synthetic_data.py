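"""Synthetic inputs with planted structure and a ground-truth manifest.

The generator emits exactly the dialects the readers consume — a scored
interaction TSV, a protein/disease annotation TSV, a GMT pathway file and a
plain-text comorbid list — plus a JSON manifest recording everything that
was planted, so every pipeline stage can be checked against known truth
without downloading any database.

The graph is a planted-partition model: within each planted module every
pair is an edge with probability ``p_within`` (default 0.9) and carries a
confidence drawn from Uniform(0.75, 0.99); every other pair is an edge
with probability ``p_background`` (default 0.01) with confidence from
Uniform(0.3, 0.95). At the standard 0.73 confidence threshold module edges
therefore survive essentially always while only about a third of
background edges do, making the filter an active step rather than a no-op.
Module sizes default to 18/25/5/29, the magnitudes of prominent
subnetworks in real runs of this kind of analysis.

Diseases annotate proteins independently: Bernoulli(``q_in``) inside the
host module, Bernoulli(``q_bg``) elsewhere (a disease with no host, or
with ``q_in == q_bg``, is a true null). Pathways cover a ``coverage``
fraction of their host module plus random background members.

All randomness flows through one :class:`numpy.random.Generator` seeded
from the spec, and every iteration runs in a fixed index order, so the
same seed yields byte-identical files on any platform.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .network_io import ScoredInteraction, build_network

__all__ = [
    "ModuleSpec",
    "DiseaseSpec",
    "PathwaySpec",
    "SyntheticSpec",
    "GroundTruthManifest",
    "SyntheticDataset",
    "generate",
    "make_null_spec",
]


@dataclasses.dataclass(frozen=True)
class ModuleSpec:
    size: int
    p_within: float = 0.9


@dataclasses.dataclass(frozen=True)
class DiseaseSpec:
    label: str
    host: int | None  # planted module index, or None for background-only
    q_in: float = 0.8
    q_bg: float = 0.05

    @property
    def is_null(self) -> bool:
        return self.host is None or self.q_in == self.q_bg


@dataclasses.dataclass(frozen=True)
class PathwaySpec:
    label: str
    host: int | None
    coverage: float = 0.7
    n_background: int = 15


def _default_modules() -> tuple:
    return tuple(ModuleSpec(size) for size in (18, 25, 5, 29))


def _default_diseases() -> tuple:
    return (
        DiseaseSpec("migraine", 0),
        DiseaseSpec("ovarian cancer", 1),
        DiseaseSpec("schizophrenia", 2),
        DiseaseSpec("hypertension", 3),
        DiseaseSpec("gout", None),
    )


def _default_pathways() -> tuple:
    return (
        PathwaySpec("ribosome", 0),
        PathwaySpec("long-term potentiation", 1),
        PathwaySpec("antigen processing and presentation", 2),
        PathwaySpec("mitophagy", 3),
        PathwaySpec("random background pathway", None),
    )


@dataclasses.dataclass(frozen=True)
class SyntheticSpec:
    """Full description of one synthetic study condition."""

    n_background: int = 400
    p_background: float = 0.01
    modules: tuple = dataclasses.field(default_factory=_default_modules)
    background_confidence: tuple = (0.3, 0.95)
    module_confidence: tuple = (0.75, 0.99)
    diseases: tuple = dataclasses.field(default_factory=_default_diseases)
    pathways: tuple = dataclasses.field(default_factory=_default_pathways)
    min_confidence: float = 0.73  # threshold used for manifest bookkeeping
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if any(m.size < 3 for m in self.modules):
            raise ValueError("module sizes must be >= 3")
        if sum(m.size for m in self.modules) > self.n_background:
            raise ValueError("module sizes exceed the number of proteins")
        if any(m.p_within <= self.p_background for m in self.modules):
            raise ValueError("p_within must exceed p_background")
        for d in self.diseases:
            if d.host is not None and not d.q_in >= d.q_bg:
                raise ValueError(f"disease {d.label!r}: q_in must be >= q_bg")
            if d.host is not None and d.host >= len(self.modules):
                raise ValueError(f"disease {d.label!r}: no module {d.host}")
        for p in self.pathways:
            if p.host is not None and p.host >= len(self.modules):
                raise ValueError(f"pathway {p.label!r}: no module {p.host}")


@dataclasses.dataclass(frozen=True)
class GroundTruthManifest:
    """Everything planted, plus expected post-threshold graph counts."""

    modules: tuple  # tuple of member tuples
    diseases: dict  # label -> {host, members, null}
    pathways: dict  # label -> {host, members}
    comorbid: tuple
    expected_nodes: int
    expected_edges: int

    def to_dict(self) -> dict:
        return {
            "modules": [list(m) for m in self.modules],
            "diseases": {k: {"host": v["host"],
                             "members": list(v["members"]),
                             "null": v["null"]}
                         for k, v in self.diseases.items()},
            "pathways": {k: {"host": v["host"], "members": list(v["members"])}
                         for k, v in self.pathways.items()},
            "comorbid": list(self.comorbid),
            "expected_nodes": self.expected_nodes,
            "expected_edges": self.expected_edges,
        }


@dataclasses.dataclass(frozen=True)
class SyntheticDataset:
    spec: SyntheticSpec
    interactions: tuple  # of ScoredInteraction
    annotations: tuple  # of (protein, disease)
    pathway_sets: dict  # label -> tuple of members
    comorbid: tuple
    manifest: GroundTruthManifest

    def write(self, out_dir) -> dict:
        """Write all four input files plus the manifest; returns paths."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {
            "interactions": out_dir / "interactions.tsv",
            "annotations": out_dir / "annotations.tsv",
            "pathways": out_dir / "pathways.gmt",
            "comorbid": out_dir / "comorbid.txt",
            "manifest": out_dir / "manifest.json",
        }
        lines = ["protein_a\tprotein_b\tconfidence"]
        lines += [f"{r.protein_a}\t{r.protein_b}\t{r.confidence:.4f}"
                  for r in self.interactions]
        paths["interactions"].write_text("\n".join(lines) + "\n")

        lines = ["protein\tdisease"]
        lines += [f"{p}\t{d}" for p, d in self.annotations]
        paths["annotations"].write_text("\n".join(lines) + "\n")

        lines = []
        for label in sorted(self.pathway_sets):
            members = self.pathway_sets[label]
            lines.append("\t".join([label, "synthetic gene set", *members]))
        paths["pathways"].write_text("\n".join(lines) + "\n")

        paths["comorbid"].write_text("\n".join(self.comorbid) + "\n")

        paths["manifest"].write_text(
            json.dumps(self.manifest.to_dict(), indent=1, sort_keys=True)
            + "\n")
        return paths


def _protein_id(i: int) -> str:
    return f"P{i:04d}"


def generate(spec: SyntheticSpec) -> SyntheticDataset:
    """Draw one dataset from the spec; deterministic given ``rng_seed``."""
    rng = np.random.default_rng(spec.rng_seed)
    n = spec.n_background
    names = [_protein_id(i) for i in range(n)]

    # planted modules occupy consecutive index blocks from the front
    block = np.full(n, -1, dtype=int)
    modules = []
    start = 0
    for idx, mod in enumerate(spec.modules):
        stop = start + mod.size
        block[start:stop] = idx
        modules.append(tuple(names[start:stop]))
        start = stop

    iu, ju = np.triu_indices(n, k=1)
    same = (block[iu] >= 0) & (block[iu] == block[ju])
    p_within = np.array([m.p_within for m in spec.modules] or [0.0])
    pair_p = np.where(same, p_within[np.where(same, block[iu], 0)],
                      spec.p_background)
    keep = rng.random(iu.size) < pair_p
    lo = np.where(same, spec.module_confidence[0], spec.background_confidence[0])
    hi = np.where(same, spec.module_confidence[1], spec.background_confidence[1])
    conf = lo + rng.random(iu.size) * (hi - lo)
    # round so in-memory confidences equal the 4-decimal file representation
    conf = np.round(conf, 4)
    interactions = tuple(
        ScoredInteraction(names[int(a)], names[int(b)], float(c))
        for a, b, c in zip(iu[keep], ju[keep], conf[keep]))

    annotations = []
    disease_truth = {}
    for disease in spec.diseases:
        in_host = (block == disease.host) if disease.host is not None \
            else np.zeros(n, dtype=bool)
        prob = np.where(in_host, disease.q_in, disease.q_bg)
        hit = rng.random(n) < prob
        members = tuple(names[i] for i in np.flatnonzero(hit))
        disease_truth[disease.label] = {
            "host": disease.host, "members": members, "null": disease.is_null}
        annotations.extend((m, disease.label) for m in members)
    annotations.sort()

    pathway_sets = {}
    pathway_truth = {}
    for pathway in spec.pathways:
        members: list = []
        if pathway.host is not None:
            host_members = modules[pathway.host]
            k = max(1, int(round(pathway.coverage * len(host_members))))
            picked = rng.choice(len(host_members), size=k, replace=False)
            members += [host_members[i] for i in sorted(picked)]
        outside = np.flatnonzero(block != (pathway.host if pathway.host
                                           is not None else -2))
        if pathway.n_background > 0 and outside.size:
            k = min(pathway.n_background, outside.size)
            picked = rng.choice(outside.size, size=k, replace=False)
            members += [names[outside[i]] for i in sorted(picked)]
        pathway_sets[pathway.label] = tuple(sorted(set(members)))
        pathway_truth[pathway.label] = {
            "host": pathway.host, "members": pathway_sets[pathway.label]}

    comorbid = tuple(d.label for d in spec.diseases
                     if d.host is not None and not d.is_null)

    graph, report = build_network(interactions, spec.min_confidence)
    manifest = GroundTruthManifest(
        modules=tuple(modules),
        diseases=disease_truth,
        pathways=pathway_truth,
        comorbid=comorbid,
        expected_nodes=report.n_retained_proteins,
        expected_edges=report.n_retained_edges,
    )
    return SyntheticDataset(
        spec=spec,
        interactions=interactions,
        annotations=tuple(annotations),
        pathway_sets=pathway_sets,
        comorbid=comorbid,
        manifest=manifest,
    )


def make_null_spec(spec: SyntheticSpec) -> SyntheticSpec:
    """Copy of the spec with every disease made a true null (q_in = q_bg)."""
    null_diseases = tuple(
        dataclasses.replace(d, q_in=d.q_bg) for d in spec.diseases)
    return dataclasses.replace(spec, diseases=null_diseases)
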