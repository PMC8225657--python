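"""Expansion of a module backbone into a gene-level regulatory network.

The GRN is built in four steps: (1) sample transcription factors and assign
them to modules, (2) wire TF-TF interactions following the module network,
(3) grow a target-gene subnetwork by sampling from a reference regulatory
network weighted by PageRank, and (4) attach an isolated housekeeping
subnetwork sampled by breadth-first search from the same reference.

The reference network stands in for a large experimentally derived
regulatory atlas; it can be generated synthetically (scale-free-ish, hub
regulators) or loaded from a user-supplied edge-list TSV.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .backbone import Backbone

__all__ = [
    "Gene",
    "GeneInteraction",
    "GeneRegulatoryNetwork",
    "ReferenceNetwork",
    "generate_reference_network",
    "sample_tfs",
    "generate_tf_interactions",
    "sample_target_subnetwork",
    "sample_housekeeping_subnetwork",
    "generate_grn",
]


@dataclass(frozen=True)
class Gene:
    name: str
    kind: str  # "tf" | "target" | "housekeeping"
    module: str | None = None
    burn: bool = True
    basal: float = 0.0

    def __post_init__(self) -> None:
        if self.kind == "tf" and self.module is None:
            raise ValueError(f"TF {self.name} must belong to a module")
        if self.kind in ("target", "housekeeping") and self.module is not None:
            raise ValueError(f"{self.kind} gene {self.name} cannot belong to a module")


@dataclass(frozen=True)
class GeneInteraction:
    regulator: str
    target: str
    effect: int
    strength: float


@dataclass
class GeneRegulatoryNetwork:
    genes: list[Gene]
    interactions: list[GeneInteraction]
    backbone: Backbone

    @property
    def gene_names(self) -> list[str]:
        return [g.name for g in self.genes]

    def genes_of_kind(self, kind: str) -> list[Gene]:
        return [g for g in self.genes if g.kind == kind]

    def regulators_of(self, target: str) -> list[GeneInteraction]:
        return [i for i in self.interactions if i.target == target]

    def to_graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for gene in self.genes:
            g.add_node(gene.name, kind=gene.kind, module=gene.module)
        for i in self.interactions:
            g.add_edge(i.regulator, i.target, effect=i.effect, strength=i.strength)
        return g

    # ------------------------------------------------------------------
    def gene_metadata(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene": [g.name for g in self.genes],
                "kind": [g.kind for g in self.genes],
                "module": [g.module or "" for g in self.genes],
                "burn": [g.burn for g in self.genes],
                "basal": [g.basal for g in self.genes],
            }
        )

    def interaction_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "regulator": [i.regulator for i in self.interactions],
                "target": [i.target for i in self.interactions],
                "effect": [i.effect for i in self.interactions],
                "strength": [i.strength for i in self.interactions],
            }
        )

    def write_tsv(self, edge_path: str | Path, gene_path: str | Path) -> None:
        self.interaction_table().to_csv(edge_path, sep="\t", index=False)
        self.gene_metadata().to_csv(gene_path, sep="\t", index=False)


class ReferenceNetwork:
    """A directed reference regulatory network (simple digraph, no self-loops)."""

    def __init__(self, graph: nx.DiGraph):
        graph.remove_edges_from(nx.selfloop_edges(graph))
        self.graph = graph

    @property
    def num_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def pagerank(self, damping: float = 0.85) -> dict:
        return nx.pagerank(self.graph, alpha=damping)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ReferenceNetwork":
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
        g = nx.DiGraph()
        g.add_edges_from(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))
        return cls(g)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for u, v in self.graph.edges():
                fh.write(f"{u}\t{v}\n")


def generate_reference_network(
    num_nodes: int,
    max_in_degree: int = 5,
    mean_in_degree: float = 2.0,
    rng: np.random.Generator | int | None = None,
) -> ReferenceNetwork:
    """Synthesize a reference network with hub regulators.

    Nodes are added sequentially; each new node receives regulators chosen
    among existing nodes with probability proportional to (out-degree + 1),
    a preferential-attachment rule that yields a heavy-tailed out-degree
    distribution while bounding every in-degree by ``max_in_degree``.
    """
    if num_nodes < 2:
        raise ValueError("num_nodes must be >= 2")
    rng = np.random.default_rng(rng)
    g = nx.DiGraph()
    names = [f"R{i}" for i in range(num_nodes)]
    g.add_node(names[0])
    out_deg = np.zeros(num_nodes)
    for i in range(1, num_nodes):
        g.add_node(names[i])
        k = int(min(1 + rng.poisson(mean_in_degree - 1), max_in_degree, i))
        w = out_deg[:i] + 1.0
        regs = rng.choice(i, size=k, replace=False, p=w / w.sum())
        for r in regs:
            g.add_edge(names[r], names[i])
            out_deg[r] += 1
    return ReferenceNetwork(g)


# ----------------------------------------------------------------------
# step 1: transcription factors
# ----------------------------------------------------------------------

def sample_tfs(
    backbone: Backbone,
    num_tfs: int,
    min_per_module: int = 1,
    rng: np.random.Generator | int | None = None,
) -> list[Gene]:
    """Sample TFs and assign each to a module (>= ``min_per_module`` per
    module); a TF inherits ``burn`` and basal expression from its module."""
    rng = np.random.default_rng(rng)
    modules = backbone.modules
    if num_tfs < min_per_module * len(modules):
        raise ValueError(
            f"num_tfs={num_tfs} too small for {len(modules)} modules "
            f"with at least {min_per_module} TFs each"
        )
    counts = {m.name: min_per_module for m in modules}
    extra = num_tfs - min_per_module * len(modules)
    for idx in rng.integers(0, len(modules), size=extra):
        counts[modules[idx].name] += 1
    tfs: list[Gene] = []
    for m in modules:
        for j in range(counts[m.name]):
            tfs.append(
                Gene(
                    name=f"{m.name}_TF{j + 1}",
                    kind="tf",
                    module=m.name,
                    burn=m.burn,
                    basal=m.basal,
                )
            )
    return tfs


# ----------------------------------------------------------------------
# step 2: TF-TF interactions
# ----------------------------------------------------------------------

def generate_tf_interactions(
    backbone: Backbone,
    tfs: list[Gene],
    rng: np.random.Generator | int | None = None,
) -> list[GeneInteraction]:
    """Wire TFs according to the module interactions: for each module edge
    A->B, every TF of B receives at least one regulator among the TFs of A,
    inheriting the edge's effect and strength."""
    rng = np.random.default_rng(rng)
    by_module: dict[str, list[Gene]] = {}
    for tf in tfs:
        by_module.setdefault(tf.module, []).append(tf)
    interactions: list[GeneInteraction] = []
    for mi in backbone.module_interactions:
        sources = by_module.get(mi.from_module)
        targets = by_module.get(mi.to_module)
        if not sources or not targets:
            raise ValueError(
                f"module interaction {mi.from_module}->{mi.to_module} touches a module with no TFs"
            )
        for t in targets:
            n_regs = int(rng.integers(1, len(sources) + 1))
            chosen = rng.choice(len(sources), size=n_regs, replace=False)
            for c in chosen:
                interactions.append(
                    GeneInteraction(sources[c].name, t.name, mi.effect, float(mi.strength))
                )
    return interactions


# ----------------------------------------------------------------------
# step 3: target subnetwork
# ----------------------------------------------------------------------

def _sampled_effect_strength(rng: np.random.Generator) -> tuple[int, float]:
    # induced edges: mostly activating, heavy-tailed integer strengths
    effect = 1 if rng.random() < 0.75 else -1
    strength = float(math.ceil(np.exp(rng.uniform(np.log(1.0), np.log(10.0)))))
    return effect, strength


def sample_target_subnetwork(
    grn: GeneRegulatoryNetwork,
    ref: ReferenceNetwork,
    num_targets: int,
    max_regs_per_target: int = 5,
    rng: np.random.Generator | int | None = None,
) -> GeneRegulatoryNetwork:
    """Grow the GRN with ``num_targets`` target genes.

    Existing TFs are mapped onto reference regulators; targets are drawn from
    the reference weighted by PageRank, and each receives at most
    ``max_regs_per_target`` regulators from the induced subnetwork, always
    ending up downstream of at least one TF.
    """
    rng = np.random.default_rng(rng)
    tfs = grn.genes_of_kind("tf")
    nodes = list(ref.graph.nodes())
    if len(nodes) < num_targets:
        raise ValueError("reference network too small for requested number of targets")
    # map TFs to high-out-degree reference regulators
    out_deg = np.array([ref.graph.out_degree(n) for n in nodes], dtype=float)
    w = out_deg + 1.0
    n_map = min(len(tfs), len(nodes))
    tf_img_idx = rng.choice(len(nodes), size=n_map, replace=False, p=w / w.sum())
    node_to_tf = {nodes[i]: tfs[j].name for j, i in enumerate(tf_img_idx)}
    # draw targets weighted by pagerank, excluding TF images
    pr = ref.pagerank()
    candidates = [n for n in nodes if n not in node_to_tf]
    if len(candidates) < num_targets:
        raise ValueError("reference network exhausted")
    pw = np.array([pr[n] for n in candidates])
    chosen = rng.choice(len(candidates), size=num_targets, replace=False, p=pw / pw.sum())
    target_nodes = [candidates[i] for i in chosen]

    new_genes: list[Gene] = []
    new_inter: list[GeneInteraction] = []
    placed: dict[str, str] = {}  # ref node -> gene name, for nodes downstream of TFs
    placed.update(node_to_tf)
    for i, node in enumerate(target_nodes):
        gname = f"Target{i + 1}"
        preds = [p for p in ref.graph.predecessors(node) if p in placed]
        if not preds:
            # not connected within the induced subnetwork: anchor to a random TF
            reg_names = [tfs[int(rng.integers(0, len(tfs)))].name]
        else:
            k = int(min(len(preds), max_regs_per_target))
            idx = rng.choice(len(preds), size=k, replace=False)
            reg_names = [placed[preds[j]] for j in idx]
        for reg in reg_names:
            effect, strength = _sampled_effect_strength(rng)
            new_inter.append(GeneInteraction(reg, gname, effect, strength))
        new_genes.append(Gene(gname, "target", None, burn=True, basal=0.0))
        placed[node] = gname
    new_genes = _assign_basal(new_genes, new_inter)
    return GeneRegulatoryNetwork(
        genes=grn.genes + new_genes,
        interactions=grn.interactions + new_inter,
        backbone=grn.backbone,
    )


def _assign_basal(genes: list[Gene], interactions: list[GeneInteraction]) -> list[Gene]:
    """Basal expression for non-TF genes: 1 with no activating regulator
    (otherwise they could never be transcribed), 0.5 with mixed regulation,
    0 when driven by activators only."""
    has_act: dict[str, bool] = {}
    has_rep: dict[str, bool] = {}
    for i in interactions:
        if i.effect > 0:
            has_act[i.target] = True
        else:
            has_rep[i.target] = True
    out = []
    for g in genes:
        act, rep = has_act.get(g.name, False), has_rep.get(g.name, False)
        if act and rep:
            basal = 0.5
        elif act:
            basal = 0.0
        else:
            basal = 1.0
        out.append(Gene(g.name, g.kind, g.module, g.burn, basal))
    return out


# ----------------------------------------------------------------------
# step 4: housekeeping subnetwork
# ----------------------------------------------------------------------

def sample_housekeeping_subnetwork(
    ref: ReferenceNetwork,
    num_hks: int,
    max_in_degree: int = 5,
    rng: np.random.Generator | int | None = None,
    max_root_retries: int = 10,
) -> tuple[list[Gene], list[GeneInteraction]]:
    """Sample a weakly connected housekeeping subnetwork by BFS from a random
    root of the (in-degree-capped) reference network. Housekeeping genes are
    regulatorily isolated from TFs and targets."""
    rng = np.random.default_rng(rng)
    if num_hks == 0:
        return [], []
    nodes = list(ref.graph.nodes())
    if len(nodes) < num_hks:
        raise ValueError("reference network has fewer nodes than requested housekeeping genes")
    # cap in-degrees by subsampling incoming edges
    capped = nx.DiGraph()
    capped.add_nodes_from(nodes)
    for n in nodes:
        preds = list(ref.graph.predecessors(n))
        if len(preds) > max_in_degree:
            idx = rng.choice(len(preds), size=max_in_degree, replace=False)
            preds = [preds[i] for i in idx]
        capped.add_edges_from((p, n) for p in preds)
    und = capped.to_undirected(as_view=True)
    selection: list[str] | None = None
    for _ in range(max_root_retries):
        root = nodes[int(rng.integers(0, len(nodes)))]
        order = [root] + [v for _, v in nx.bfs_edges(und, root)]
        if len(order) >= num_hks:
            selection = order[:num_hks]
            break
    if selection is None:
        raise ValueError(
            f"could not find a connected component with {num_hks} nodes "
            f"after {max_root_retries} BFS roots"
        )
    sub = capped.subgraph(selection)
    genes = [Gene(f"HK{i + 1}", "housekeeping", None, burn=True, basal=0.0)
             for i in range(num_hks)]
    name_of = dict(zip(selection, (g.name for g in genes)))
    inter = []
    for u, v in sub.edges():
        effect, strength = _sampled_effect_strength(rng)
        inter.append(GeneInteraction(name_of[u], name_of[v], effect, strength))
    genes = _assign_basal(genes, inter)
    return genes, inter


# ----------------------------------------------------------------------
# full pipeline
# ----------------------------------------------------------------------

def generate_grn(
    backbone: Backbone,
    num_tfs: int | None = None,
    num_targets: int = 20,
    num_hks: int = 10,
    ref: ReferenceNetwork | None = None,
    min_tfs_per_module: int = 1,
    max_regs_per_target: int = 5,
    rng: np.random.Generator | int | None = None,
) -> GeneRegulatoryNetwork:
    """Run GRN-generation steps 1-4 for a backbone.

    With ``num_tfs=None``, one TF per module is used. With ``ref=None``, a
    synthetic reference network is generated (sized to comfortably supply the
    requested targets and housekeeping genes).
    """
    rng = np.random.default_rng(rng)
    if num_tfs is None:
        num_tfs = len(backbone.modules) * min_tfs_per_module
    tfs = sample_tfs(backbone, num_tfs, min_tfs_per_module, rng)
    tf_inter = generate_tf_interactions(backbone, tfs, rng)
    grn = GeneRegulatoryNetwork(list(tfs), list(tf_inter), backbone)
    if ref is None:
        n_ref = max(2, 3 * (num_targets + num_hks) + num_tfs + 10)
        ref = generate_reference_network(n_ref, rng=rng)
    if num_targets:
        grn = sample_target_subnetwork(grn, ref, num_targets, max_regs_per_target, rng)
    if num_hks:
        hk_genes, hk_inter = sample_housekeeping_subnetwork(ref, num_hks, rng=rng)
        grn = GeneRegulatoryNetwork(
            grn.genes + hk_genes, grn.interactions + hk_inter, backbone
        )
    return grn
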