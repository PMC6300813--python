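"""Co-functional network construction, communities, topology and scores.

Called edges form an undirected simple graph over all tested genes with
weight |r| and distance 1 - |r|.  Communities come from the map equation
(Infomap) with |r| as flow; centrality is a local closeness computed within
each community's induced subgraph; each community is summarized per cell
line by the first principal component of its members' corrected profiles.
"""

from __future__ import annotations

import logging
import random
import warnings
from dataclasses import dataclass

import igraph as ig
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import EffectMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "GeneNetwork",
    "CommunityPartition",
    "CommunityScore",
    "build_network",
    "detect_communities",
    "community_closeness",
    "community_summary",
    "community_scores",
    "census_enrichment",
]


@dataclass
class GeneNetwork:
    """Undirected simple graph of co-functional edges over all tested genes."""

    graph: ig.Graph

    @property
    def node_names(self) -> list[str]:
        return list(self.graph.vs["name"])

    @property
    def n_nodes(self) -> int:
        return self.graph.vcount()

    @property
    def n_edges(self) -> int:
        return self.graph.ecount()


@dataclass
class CommunityPartition:
    """Gene -> community assignment; isolates are singleton communities."""

    assignment: dict[str, int]

    @property
    def sizes(self) -> dict[int, int]:
        sizes: dict[int, int] = {}
        for cid in self.assignment.values():
            sizes[cid] = sizes.get(cid, 0) + 1
        return sizes

    def community_ids(self) -> list[int]:
        return sorted(self.sizes)

    def members(self, cid: int) -> list[str]:
        return [g for g, c in self.assignment.items() if c == cid]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene": list(self.assignment), "community": list(self.assignment.values())}
        )


@dataclass
class CommunityScore:
    """Per-cell-line PC1 score of one community's corrected profiles."""

    scores: pd.Series  # one real per cell line
    loadings: pd.Series  # one real per member gene, unit norm, mean >= 0
    variance_explained_pc1: float


def build_network(edges: pd.DataFrame, all_genes: list[str]) -> GeneNetwork:
    """Build the weighted network from called edges.

    Node set is every tested gene (isolates included).  Edge weight is |r|
    and distance 1 - |r|; the correlation sign is kept as an attribute.  If
    the table has a ``significant`` column only significant rows are used.
    """
    genes = list(all_genes)
    if len(set(genes)) != len(genes):
        raise ValueError("all_genes contains duplicates")
    index = {g: i for i, g in enumerate(genes)}
    if "significant" in edges.columns:
        edges = edges[edges["significant"].astype(bool)]
    unknown = set(edges["gene_a"]).union(edges["gene_b"]) - set(genes)
    if unknown:
        raise ValueError(f"edges reference unknown genes: {sorted(unknown)[:5]}")
    pairs = [(index[a], index[b]) for a, b in zip(edges["gene_a"], edges["gene_b"])]
    g = ig.Graph(n=len(genes), edges=pairs, directed=False)
    g.vs["name"] = genes
    r = edges["r"].to_numpy(dtype=float)
    g.es["r"] = list(r)
    g.es["weight"] = list(np.abs(r))
    g.es["distance"] = list(1.0 - np.abs(r))
    g.es["sign"] = ["-" if x < 0 else "+" for x in r]
    return GeneNetwork(g)


def detect_communities(
    network: GeneNetwork, seed: int = 0, trials: int = 10
) -> CommunityPartition:
    """Infomap (map-equation) partition with |r| edge weights as flow.

    The best of ``trials`` runs by codelength is kept (handled inside
    igraph); the run is seeded for reproducibility.  Isolated genes become
    singleton communities.
    """
    if network.n_nodes == 0:
        raise ValueError("network has no nodes")
    ig.set_random_number_generator(random.Random(int(seed)))
    try:
        weights = network.graph.es["weight"] if network.n_edges else None
        clustering = network.graph.community_infomap(
            edge_weights=weights, trials=trials
        )
    finally:
        ig.set_random_number_generator(random)
    assignment = dict(zip(network.node_names, clustering.membership))
    return CommunityPartition(assignment)


def community_closeness(
    network: GeneNetwork, partition: CommunityPartition
) -> pd.Series:
    """Local closeness: 1 / sum of weighted shortest distances to co-members.

    Shortest paths use distance 1 - |r| and are confined to the induced
    subgraph of the gene's community.  Genes with no reachable co-member
    (isolates, or disconnected within their community) are reported missing
    rather than penalized with infinities.
    """
    names = network.node_names
    if set(partition.assignment) < set(names):
        raise ValueError("partition does not cover all network nodes")
    name_to_idx = {g: i for i, g in enumerate(names)}
    closeness = pd.Series(np.nan, index=pd.Index(names, name="gene"), dtype=float)
    by_comm: dict[int, list[str]] = {}
    for g in names:
        by_comm.setdefault(partition.assignment[g], []).append(g)
    for members in by_comm.values():
        if len(members) < 2:
            continue
        sub = network.graph.induced_subgraph([name_to_idx[m] for m in members])
        D = np.asarray(sub.distances(weights="distance"), dtype=float)
        np.fill_diagonal(D, np.nan)
        for row, gene in zip(D, sub.vs["name"]):
            finite = row[np.isfinite(row)]
            if finite.size:
                total = finite.sum()
                closeness[gene] = np.inf if total == 0 else 1.0 / total
    return closeness


def community_summary(
    network: GeneNetwork,
    partition: CommunityPartition,
    annotations: pd.DataFrame | None = None,
    matrix: EffectMatrix | None = None,
    min_size: int = 8,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-community statistics and inter-community edge frequencies.

    For every community of at least ``min_size`` members: size, internal edge
    density (edges present over pairs possible), mean member knockout effect
    (when a matrix is supplied), census-gene count (when annotations carry a
    ``census`` column), and a flag for communities above 100 genes with more
    than half their members on a single chromosome.  Between retained
    communities, edge frequency is observed inter-edges over size_a * size_b,
    flagged when it exceeds the network's global pair-calling rate.
    """
    sizes = partition.sizes
    retained = [cid for cid, s in sorted(sizes.items()) if s >= min_size]
    names = network.node_names
    n = network.n_nodes
    global_rate = (
        network.n_edges / (n * (n - 1) / 2) if n > 1 else 0.0
    )

    chrom = None
    if annotations is not None and "chromosome" in annotations.columns:
        chrom = annotations["chromosome"]
    elif annotations is not None:
        warnings.warn(
            "annotations lack a 'chromosome' column; chromosome flag disabled",
            stacklevel=2,
        )
    census = None
    if annotations is not None and "census" in annotations.columns:
        census = annotations["census"]

    name_to_idx = {g: i for i, g in enumerate(names)}
    # count internal and cross edges in one pass over the edge list
    internal: dict[int, int] = {cid: 0 for cid in sizes}
    cross: dict[tuple[int, int], int] = {}
    for e in network.graph.es:
        ca = partition.assignment[names[e.source]]
        cb = partition.assignment[names[e.target]]
        if ca == cb:
            internal[ca] += 1
        else:
            key = (min(ca, cb), max(ca, cb))
            cross[key] = cross.get(key, 0) + 1

    rows = []
    for cid in retained:
        members = partition.members(cid)
        s = len(members)
        possible = s * (s - 1) / 2
        density = internal[cid] / possible if possible else np.nan
        mean_effect = (
            float(matrix.subset_genes([m for m in members if m in set(matrix.gene_ids)]).values.mean())
            if matrix is not None
            else np.nan
        )
        census_count = (
            int((census.reindex(members).fillna("none") != "none").sum())
            if census is not None
            else np.nan
        )
        chrom_flag = False
        if chrom is not None and s > 100:
            counts = chrom.reindex(members).dropna().value_counts()
            if len(counts) and counts.iloc[0] > 0.5 * s:
                chrom_flag = True
        rows.append(
            {
                "community": cid,
                "size": s,
                "n_edges": internal[cid],
                "density": density,
                "mean_effect": mean_effect,
                "census_count": census_count,
                "chromosome_flagged": chrom_flag,
            }
        )
    per_comm = pd.DataFrame(rows)

    inter_rows = []
    for i, ca in enumerate(retained):
        for cb in retained[i + 1 :]:
            obs = cross.get((min(ca, cb), max(ca, cb)), 0)
            possible = sizes[ca] * sizes[cb]
            freq = obs / possible
            inter_rows.append(
                {
                    "community_a": ca,
                    "community_b": cb,
                    "n_edges": obs,
                    "frequency": freq,
                    "flagged": freq > global_rate,
                }
            )
    inter = pd.DataFrame(
        inter_rows,
        columns=["community_a", "community_b", "n_edges", "frequency", "flagged"],
    )
    return per_comm, inter


def community_scores(
    matrix: EffectMatrix,
    partition: CommunityPartition,
    min_size: int = 8,
) -> dict[int, CommunityScore]:
    """First-PC cell-line scores per community of corrected profiles.

    PCA runs with cell lines as observations and member genes as features,
    each gene's mean effect removed.  Scores are the PC1 coordinates of the
    cell lines; loadings (one per member, unit norm) are sign-fixed so their
    mean is nonnegative, so a coherent essential community gets loadings of
    one shared sign.
    """
    if min_size < 2:
        raise ValueError("communities need at least 2 members to score")
    present = set(matrix.gene_ids)
    out: dict[int, CommunityScore] = {}
    for cid, size in sorted(partition.sizes.items()):
        if size < min_size:
            continue
        members = [g for g in partition.members(cid) if g in present]
        if len(members) < 2:
            raise ValueError(f"community {cid} has fewer than 2 members in the matrix")
        M = matrix.subset_genes(members).values.T  # cells x genes
        M = M - M.mean(axis=0)
        U, s, Vt = np.linalg.svd(M, full_matrices=False)
        total = float(np.sum(s**2))
        varexp = float(s[0] ** 2 / total) if total > 0 else 0.0
        loadings = Vt[0]
        scores = U[:, 0] * s[0]
        if loadings.mean() < 0:
            loadings = -loadings
            scores = -scores
        out[cid] = CommunityScore(
            scores=pd.Series(scores, index=matrix.cell_line_ids, name=f"community_{cid}"),
            loadings=pd.Series(loadings, index=members, name=f"community_{cid}"),
            variance_explained_pc1=varexp,
        )
    return out


def census_enrichment(
    partition: CommunityPartition,
    annotations: pd.DataFrame,
    fdr: float = 0.10,
) -> pd.DataFrame:
    """Binomial upper-tail enrichment of census genes per community.

    Success probability is the global census fraction over the partitioned
    genes; per community the p-value is P(X >= observed | size, p0), with
    Benjamini-Hochberg across communities.
    """
    if "census" not in annotations.columns:
        raise ValueError("annotations need a 'census' column")
    genes = list(partition.assignment)
    status = annotations["census"].reindex(genes).fillna("none") != "none"
    p0 = float(status.mean())
    rows = []
    for cid, size in sorted(partition.sizes.items()):
        members = partition.members(cid)
        count = int(status.loc[members].sum())
        p = float(stats.binom.sf(count - 1, size, p0)) if count > 0 else 1.0
        rows.append({"community": cid, "size": size, "census_count": count, "p": min(p, 1.0)})
    out = pd.DataFrame(rows)
    _, q, _, _ = multipletests(out["p"], method="fdr_bh")
    out["q"] = q
    out["enriched"] = out["q"] <= fdr
    return out
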