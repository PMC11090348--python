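"""Residue-residue contacts and persistency-weighted interaction networks.

The residue-residue distance D_ij is the shortest distance between any two
heavy (non-hydrogen) atoms of residues i and j.  A binary contact map puts
A_ij = 1 when D_ij is strictly below the cutoff (3.5 Å by default).  Summing
the binary adjacency matrices over all ensemble members yields a weighted
residue interaction network (RIN): the weight of edge (i, j) counts the
members in which the contact occurs, and the persistency w_ij / N classifies
each edge as

* persistent — occurs in more than 75% of members,
* transient  — occurs in fewer than 25% of members,
* medium     — anything in between.

A disordered ensemble is dominated by transient edges (contacts that appear
in one conformation and vanish in the next); a well-folded ensemble by
persistent ones.  Thresholds are strict inequalities and configurable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial.distance import cdist

from .structure_io import PAEMap, StructureEnsemble, StructureModel

__all__ = [
    "ResidueDistanceMap",
    "ContactMap",
    "WeightedRIN",
    "RINSummary",
    "RESIDUE_CLASSES",
    "residue_distance_map",
    "contact_map",
    "accumulate_rin",
    "rin_summary",
    "ensemble_mean_distance_map",
    "pae_distance_concordance",
    "persistency_histogram",
]

DEFAULT_CUTOFF = 3.5           # Å, heavy-atom shortest distance
DEFAULT_THRESHOLDS = (0.75, 0.25)  # (persistent >, transient <)

#: Residue classes used in interaction-frequency summaries.  Aromatic is
#: {His, Tyr, Phe}; Trp can be added via ``aromatic_with_trp``.  His counts
#: in both the aromatic and the Gly+His group.
RESIDUE_CLASSES: dict[str, frozenset[str]] = {
    "aromatic": frozenset({"HIS", "TYR", "PHE"}),
    "glycine": frozenset({"GLY"}),
    "charged": frozenset({"ASP", "GLU", "ARG", "LYS"}),
    "gly_his": frozenset({"GLY", "HIS"}),
}

RESIDUE_CLASSES_WITH_TRP = dict(
    RESIDUE_CLASSES, aromatic=frozenset({"HIS", "TYR", "PHE", "TRP"}))


@dataclass
class ResidueDistanceMap:
    """Shortest heavy-atom distance between every residue pair, in Å."""

    matrix: np.ndarray
    residues: tuple

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


@dataclass
class ContactMap:
    """Binary adjacency at a strict distance cutoff; zero diagonal."""

    matrix: np.ndarray
    cutoff: float
    residues: tuple

    @property
    def n_contacts(self) -> int:
        return int(np.sum(np.triu(self.matrix, k=1)))


def residue_distance_map(model: StructureModel) -> ResidueDistanceMap:
    """All-pairs minimum inter-atomic distance per residue pair.

    Atoms are residue-contiguous in a :class:`StructureModel`, so the atom
    distance matrix reduces to residue blocks with two ``minimum.reduceat``
    passes.
    """
    atom_d = cdist(model.coords, model.coords)
    starts = model.residue_starts
    by_rows = np.minimum.reduceat(atom_d, starts, axis=0)
    d = np.minimum.reduceat(by_rows, starts, axis=1)
    np.fill_diagonal(d, 0.0)
    return ResidueDistanceMap(matrix=d, residues=model.residues)


def contact_map(dmap: ResidueDistanceMap,
                cutoff: float = DEFAULT_CUTOFF) -> ContactMap:
    """Binary contacts: A_ij = 1 iff D_ij < cutoff (strict), diagonal 0."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    a = (dmap.matrix < cutoff).astype(np.uint8)
    np.fill_diagonal(a, 0)
    return ContactMap(matrix=a, cutoff=cutoff, residues=dmap.residues)


def _backbone_mask(residues: tuple) -> np.ndarray:
    """Boolean matrix marking sequence-neighbor pairs within one chain.

    "Backbone" edges are contacts between residues adjacent by author index
    (|Δindex| = 1, same chain, no insertion-code gap semantics beyond the
    index itself) — the peptide-bond neighbors whose contacts persist
    trivially.
    """
    n = len(residues)
    chains = np.array([r.chain_id for r in residues])
    idx = np.array([r.residue_index for r in residues])
    same_chain = chains[:, None] == chains[None, :]
    adjacent = np.abs(idx[:, None] - idx[None, :]) == 1
    mask = same_chain & adjacent
    np.fill_diagonal(mask, False)
    return mask


@dataclass
class WeightedRIN:
    """Ensemble-weighted residue interaction network.

    ``weights[i, j]`` counts the members in which residues i and j are in
    contact; ``member_contacts`` retains the per-member binary maps so that
    per-model statistics (residue-class interaction frequencies) can be
    computed downstream.  ``graph`` is a networkx view with node and edge
    attributes for export/analysis.
    """

    weights: np.ndarray
    n_members: int
    residues: tuple
    cutoff: float
    thresholds: tuple[float, float]
    member_contacts: np.ndarray
    graph: nx.Graph = field(init=False)

    def __post_init__(self) -> None:
        hi, lo = self.thresholds
        if not (0.0 < lo < hi < 1.0):
            raise ValueError(
                "persistency thresholds must satisfy 0 < lower < upper < 1; "
                f"got (upper={hi}, lower={lo})")
        self.graph = self._build_graph()

    def classify(self, persistency: float) -> str:
        hi, lo = self.thresholds
        if persistency > hi:
            return "persistent"
        if persistency < lo:
            return "transient"
        return "medium"

    def _build_graph(self) -> nx.Graph:
        from Bio.SeqUtils import seq1
        g = nx.Graph(n_members=self.n_members, cutoff=self.cutoff,
                     thresholds=self.thresholds)
        for i, r in enumerate(self.residues):
            aa = seq1(r.residue_name.capitalize(), undef_code="X")
            classes = sorted(name for name, members in RESIDUE_CLASSES.items()
                             if r.residue_name in members)
            g.add_node(i, chain=r.chain_id, index=r.residue_index,
                       name=r.residue_name, aa=aa, classes=classes)
        ii, jj = np.nonzero(np.triu(self.weights, k=1))
        for i, j in zip(ii.tolist(), jj.tolist()):
            w = int(self.weights[i, j])
            p = w / self.n_members
            g.add_edge(i, j, weight=w, persistency=p,
                       persistency_class=self.classify(p),
                       chain_pair="|".join(sorted(
                           {self.residues[i].chain_id,
                            self.residues[j].chain_id})))
        return g

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_persistencies(self, exclude_backbone: bool = False) -> np.ndarray:
        mask = np.triu(self.weights, k=1) > 0
        if exclude_backbone:
            mask &= ~_backbone_mask(self.residues)
        return self.weights[mask] / self.n_members

    def to_edge_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("chain_i\tres_i\taa_i\tchain_j\tres_j\taa_j\t"
                     "weight\tpersistency\tclass\n")
            for i, j, data in sorted(self.graph.edges(data=True)):
                ri, rj = self.residues[i], self.residues[j]
                ai = self.graph.nodes[i]["aa"]
                aj = self.graph.nodes[j]["aa"]
                fh.write(f"{ri.chain_id}\t{ri.residue_index}\t{ai}\t"
                         f"{rj.chain_id}\t{rj.residue_index}\t{aj}\t"
                         f"{data['weight']}\t{data['persistency']:.6f}\t"
                         f"{data['persistency_class']}\n")

    def to_graphml(self, path) -> None:
        g = nx.Graph()
        g.add_nodes_from(
            (i, {k: (",".join(v) if isinstance(v, list) else v)
                 for k, v in d.items()})
            for i, d in self.graph.nodes(data=True))
        g.add_edges_from((i, j, d) for i, j, d in self.graph.edges(data=True))
        g.graph.update(n_members=self.n_members, cutoff=self.cutoff)
        nx.write_graphml(g, path)


def accumulate_rin(ensemble: StructureEnsemble,
                   cutoff: float = DEFAULT_CUTOFF,
                   thresholds: tuple[float, float] = DEFAULT_THRESHOLDS
                   ) -> WeightedRIN:
    """Sum per-member binary contact maps into a weighted RIN."""
    ensemble.require_size(2, "a weighted RIN")
    n_res = ensemble.n_residues
    stack = np.zeros((len(ensemble), n_res, n_res), dtype=bool)
    for k, model in enumerate(ensemble):
        stack[k] = contact_map(residue_distance_map(model),
                               cutoff=cutoff).matrix.astype(bool)
    weights = stack.sum(axis=0).astype(np.int64)
    return WeightedRIN(weights=weights, n_members=len(ensemble),
                       residues=ensemble.layout, cutoff=cutoff,
                       thresholds=thresholds, member_contacts=stack)


@dataclass
class RINSummary:
    """Edge totals, persistency-class breakdown, and residue-class stats."""

    n_members: int
    thresholds: tuple[float, float]
    total_edges: int
    class_counts: dict[str, int]
    class_percent: dict[str, float]
    total_edges_no_backbone: int
    class_counts_no_backbone: dict[str, int]
    class_percent_no_backbone: dict[str, float]
    residue_class_frequencies: dict[str, dict[str, float]]

    def as_dict(self) -> dict:
        return {
            "n_members": self.n_members,
            "thresholds": {"persistent_gt": self.thresholds[0],
                           "transient_lt": self.thresholds[1]},
            "total_edges": self.total_edges,
            "class_counts": self.class_counts,
            "class_percent": self.class_percent,
            "total_edges_no_backbone": self.total_edges_no_backbone,
            "class_counts_no_backbone": self.class_counts_no_backbone,
            "class_percent_no_backbone": self.class_percent_no_backbone,
            "residue_class_frequencies": self.residue_class_frequencies,
        }


def _class_breakdown(persistencies: np.ndarray,
                     classify) -> tuple[dict[str, int], dict[str, float]]:
    counts = {"persistent": 0, "medium": 0, "transient": 0}
    for p in persistencies:
        counts[classify(p)] += 1
    total = max(len(persistencies), 1)
    percent = {k: 100.0 * v / total for k, v in counts.items()}
    return counts, percent


def rin_summary(rin: WeightedRIN, include_trp_aromatic: bool = False
                ) -> RINSummary:
    """Summarize a weighted RIN.

    Totals and class breakdowns are reported both over all edges and after
    removing backbone edges (sequence-adjacent residues of the same chain).
    Residue-class interaction frequencies are computed per ensemble member:
    the number of that member's contacts incident to a residue of the class,
    counting an edge once per class-member endpoint, then summarized as
    median±IQR across members.
    """
    classes = RESIDUE_CLASSES_WITH_TRP if include_trp_aromatic \
        else RESIDUE_CLASSES
    backbone = _backbone_mask(rin.residues)
    triu = np.triu(np.ones_like(rin.weights, dtype=bool), k=1)
    present = (rin.weights > 0) & triu

    p_all = rin.weights[present] / rin.n_members
    counts, percent = _class_breakdown(p_all, rin.classify)

    present_nb = present & ~backbone
    p_nb = rin.weights[present_nb] / rin.n_members
    counts_nb, percent_nb = _class_breakdown(p_nb, rin.classify)

    resnames = np.array([r.residue_name for r in rin.residues])
    freq_summary: dict[str, dict[str, float]] = {}
    for cname, members in classes.items():
        in_class = np.isin(resnames, sorted(members))
        # endpoint-incidence count per ensemble member, backbone excluded
        incidence = in_class[:, None].astype(np.int64) + \
            in_class[None, :].astype(np.int64)
        weight_mask = (triu & ~backbone).astype(np.int64) * incidence
        per_member = np.einsum("kij,ij->k", rin.member_contacts.astype(np.int64),
                               weight_mask)
        q1, med, q3 = np.percentile(per_member, [25, 50, 75])
        freq_summary[cname] = {"median": float(med), "iqr": float(q3 - q1),
                               "mean": float(np.mean(per_member)),
                               "sd": float(np.std(per_member))}

    return RINSummary(
        n_members=rin.n_members,
        thresholds=rin.thresholds,
        total_edges=int(present.sum()),
        class_counts=counts,
        class_percent=percent,
        total_edges_no_backbone=int(present_nb.sum()),
        class_counts_no_backbone=counts_nb,
        class_percent_no_backbone=percent_nb,
        residue_class_frequencies=freq_summary,
    )


def ensemble_mean_distance_map(ensemble: StructureEnsemble
                               ) -> ResidueDistanceMap:
    """Element-wise mean of per-member residue distance maps."""
    acc = np.zeros((ensemble.n_residues, ensemble.n_residues))
    for model in ensemble:
        acc += residue_distance_map(model).matrix
    return ResidueDistanceMap(matrix=acc / len(ensemble),
                              residues=ensemble.layout)


def pae_distance_concordance(pae: PAEMap, mean_dmap: ResidueDistanceMap,
                             min_separation: int = 2) -> float:
    """Pearson correlation between a symmetrized PAE map and a distance map.

    Computed over the upper triangle restricted to |i − j| >= min_separation
    (sequence neighbors carry no information — both maps are trivially small
    there).  Returns NaN with a warning when either map is constant on the
    selected entries.
    """
    if pae.n_residues != mean_dmap.n:
        raise ValueError(
            f"PAE is {pae.n_residues} residues but distance map is "
            f"{mean_dmap.n}")
    n = mean_dmap.n
    sym = pae.symmetrized()
    ii, jj = np.triu_indices(n, k=min_separation)
    x, y = sym[ii, jj], mean_dmap.matrix[ii, jj]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant map: PAE-distance correlation is undefined",
                      RuntimeWarning, stacklevel=2)
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def persistency_histogram(rin: WeightedRIN, bins: int = 20,
                          exclude_backbone: bool = False
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of per-edge persistency over [0, 1].

    Bin edges are half-open [lo, hi) with the final bin closed (numpy
    convention), so persistency 1.0 lands in the last bin.  Returns
    ``(counts, edges)``.
    """
    p = rin.edge_persistencies(exclude_backbone=exclude_backbone)
    counts, edges = np.histogram(p, bins=bins, range=(0.0, 1.0))
    return counts, edges
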