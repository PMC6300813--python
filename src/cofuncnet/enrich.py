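"""Gene-set and reference-network enrichment statistics for called edges.

The centerpiece is a degree-matched permutation test: genes are binned by
their degree in the co-functional network, and each gene set is compared
against random sets redrawn from the same degree bins, so that enrichment is
judged against hub structure rather than against a naive uniform null.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import GeneSetCollection

logger = logging.getLogger(__name__)

__all__ = [
    "EnrichmentCounts",
    "aggregate_enrichment",
    "enrichment_counts",
    "degree_matched_set_test",
    "ora_hypergeometric",
    "rate_by_stratum",
    "path_length_strata",
    "complex_cofunc_expectation",
]


@dataclass
class EnrichmentCounts:
    """Pair counts for aggregate enrichment of co-annotated gene pairs."""

    e: int  # total gene pairs in the tested universe
    e_f: int  # co-functional pairs
    e_c: int  # co-annotated pairs
    e_fc: int  # pairs both co-functional and co-annotated

    def __post_init__(self) -> None:
        counts = (self.e, self.e_f, self.e_c, self.e_fc)
        if any(c < 0 for c in counts):
            raise ValueError("counts must be nonnegative")
        if self.e_fc > min(self.e_f, self.e_c):
            raise ValueError("e_fc cannot exceed min(e_f, e_c)")
        if max(self.e_f, self.e_c) > self.e:
            raise ValueError("component counts cannot exceed total pairs")


def aggregate_enrichment(counts: EnrichmentCounts) -> float:
    """log2 of (co-functional rate among co-annotated pairs / global rate).

    Returns ``log2((e_fc / e_c) / (e_f / e))``; zero when calls are
    independent of annotation.  When ``e_fc`` is zero the value is -inf and
    NaN is returned with a warning (missing, flagged by the caller's NaN
    check).
    """
    if counts.e_c == 0 or counts.e_f == 0 or counts.e == 0:
        raise ValueError("e, e_f and e_c must be positive")
    if counts.e_fc == 0:
        warnings.warn("e_fc is zero; aggregate enrichment undefined (-inf)", stacklevel=2)
        return float("nan")
    return float(np.log2((counts.e_fc / counts.e_c) / (counts.e_f / counts.e)))


def enrichment_counts(
    edges: pd.DataFrame, sets: GeneSetCollection, universe: Sequence[str]
) -> EnrichmentCounts:
    """Count co-functional / co-annotated pairs over a gene universe.

    A pair is co-annotated when both genes share at least one gene set.
    ``edges`` is a full tested-pair table with a ``significant`` column.
    """
    uni = set(universe)
    n = len(uni)
    e = n * (n - 1) // 2
    called = {
        frozenset((a, b))
        for a, b, s in zip(edges["gene_a"], edges["gene_b"], edges["significant"])
        if s and a in uni and b in uni
    }
    co_annot: set[frozenset] = set()
    for _, members in sets.items():
        inside = [g for g in members if g in uni]
        for i, a in enumerate(inside):
            for b in inside[i + 1 :]:
                co_annot.add(frozenset((a, b)))
    e_fc = len(called & co_annot)
    return EnrichmentCounts(e=e, e_f=len(called), e_c=len(co_annot), e_fc=e_fc)


def _degree_bins(
    edges: pd.DataFrame, n_bins: int
) -> tuple[pd.Series, dict[int, np.ndarray]]:
    """Assign every tested gene to a degree bin (zero-degree genes separate).

    Positive-degree genes go into up to ``n_bins`` equal-occupancy quantile
    bins; genes with no called edge form their own bin 0.
    """
    universe = pd.Index(sorted(set(edges["gene_a"]) | set(edges["gene_b"])))
    sig = edges[edges["significant"].astype(bool)] if "significant" in edges.columns else edges
    deg = pd.Series(0, index=universe, dtype=int)
    counts = pd.concat([sig["gene_a"], sig["gene_b"]]).value_counts()
    deg.loc[counts.index.intersection(universe)] = counts.reindex(
        counts.index.intersection(universe)
    ).astype(int)

    bins = pd.Series(0, index=universe, dtype=int)
    pos = deg[deg > 0]
    if len(pos):
        q = min(n_bins, len(pos))
        ranks = pos.rank(method="first")
        bins.loc[pos.index] = pd.qcut(ranks, q=q, labels=False).astype(int) + 1
    groups = {
        int(b): members.index.to_numpy(dtype=object)
        for b, members in bins.groupby(bins)
    }
    return bins, groups


def degree_matched_set_test(
    edges: pd.DataFrame,
    sets: GeneSetCollection,
    n_bins: int = 100,
    n_perm: int = 1000,
    min_edges: int = 5,
    fdr: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation enrichment of co-functional edges within gene sets.

    Each permutation replaces every set member with a uniform seeded draw
    from the member's degree bin (without replacement within a set), and the
    subgraph edge count of the redrawn set forms the null.  Sets with fewer
    than ``min_edges`` observed edges are excluded (logged).  p uses the
    add-one convention ``(1 + #{perm >= obs}) / (1 + n_perm)``, floored at
    ``0.5 / n_perm`` when no permutation reaches the observed count; BH
    across tested sets at ``fdr``.
    """
    if n_perm < 20:
        raise ValueError("n_perm must be >= 20")
    bins, groups = _degree_bins(edges, n_bins)
    universe = bins.index
    gene_idx = {g: i for i, g in enumerate(universe)}
    sig = edges[edges["significant"].astype(bool)] if "significant" in edges.columns else edges

    n_genes = len(universe)
    dense = n_genes <= 4000
    if dense:
        adj = np.zeros((n_genes, n_genes), dtype=bool)
        ia = [gene_idx[a] for a in sig["gene_a"]]
        ib = [gene_idx[b] for b in sig["gene_b"]]
        adj[ia, ib] = True
        adj[ib, ia] = True

        def count_edges(idx: np.ndarray) -> int:
            return int(adj[np.ix_(idx, idx)].sum() // 2)

    else:
        neighbor: dict[int, set[int]] = {}
        for a, b in zip(sig["gene_a"], sig["gene_b"]):
            neighbor.setdefault(gene_idx[a], set()).add(gene_idx[b])
            neighbor.setdefault(gene_idx[b], set()).add(gene_idx[a])

        def count_edges(idx: np.ndarray) -> int:
            chosen = set(idx.tolist())
            return sum(len(neighbor.get(i, set()) & chosen) for i in chosen) // 2

    group_index = {b: {g: i for i, g in enumerate(members)} for b, members in groups.items()}
    rng = np.random.default_rng(seed)
    rows = []
    n_excluded = 0
    for name, members in sets.items():
        inside = [g for g in dict.fromkeys(members) if g in gene_idx]
        absent = len(members) - len(inside)
        if absent:
            warnings.warn(
                f"set {name!r}: {absent} members absent from the network, dropped",
                stacklevel=2,
            )
        if len(inside) < 2:
            n_excluded += 1
            continue
        idx = np.fromiter((gene_idx[g] for g in inside), dtype=int)
        observed = count_edges(idx)
        if observed < min_edges:
            n_excluded += 1
            continue

        by_bin: dict[int, int] = {}
        for g in inside:
            b = int(bins[g])
            by_bin[b] = by_bin.get(b, 0) + 1

        n_ge = 0
        for _ in range(n_perm):
            drawn: list[int] = []
            for b, need in by_bin.items():
                pool = groups[b]
                picks = rng.choice(len(pool), size=need, replace=False)
                drawn.extend(gene_idx[pool[i]] for i in picks)
            if count_edges(np.asarray(drawn, dtype=int)) >= observed:
                n_ge += 1
        floored = n_ge == 0
        p = 0.5 / n_perm if floored else (1 + n_ge) / (1 + n_perm)
        rows.append(
            {
                "set": name,
                "n_members_used": len(inside),
                "observed_edges": observed,
                "p": p,
                "floored": floored,
                "n_perm": n_perm,
            }
        )
    if n_excluded:
        logger.info(
            "degree-matched test: %d sets excluded (min_edges=%d or too few members)",
            n_excluded,
            min_edges,
        )
    out = pd.DataFrame(
        rows, columns=["set", "n_members_used", "observed_edges", "p", "floored", "n_perm"]
    )
    if len(out):
        _, q, _, _ = multipletests(out["p"], method="fdr_bh")
        out["q"] = q
        out["significant"] = out["q"] <= fdr
    else:
        out["q"] = pd.Series(dtype=float)
        out["significant"] = pd.Series(dtype=bool)
    return out


def ora_hypergeometric(
    hits: Sequence[str], gene_set: Sequence[str], universe: Sequence[str]
) -> float:
    """Upper-tail hypergeometric over-representation p for a hit list."""
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    hit_set = set(hits)
    if not hit_set <= uni:
        raise ValueError("hits must be a subset of the universe")
    inside = set(gene_set) & uni
    k = len(hit_set & inside)
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, len(uni), len(inside), len(hit_set)))


def rate_by_stratum(
    edges: pd.DataFrame,
    pair_strata: Mapping[tuple[str, str], str] | pd.DataFrame,
) -> pd.DataFrame:
    """Co-functional call rates for gene pairs grouped into strata.

    One operation serves several groupings: reference-network path-length
    bins, annotation-confidence bins, genomic-distance bins, complex-size
    bins.  ``pair_strata`` maps unordered pairs to labels (mapping or a
    DataFrame with gene_a/gene_b/stratum columns).  Per stratum the table
    reports the number of pairs, the number called, the call rate, and the
    fraction of calls with negative correlation sign.
    """
    if isinstance(pair_strata, pd.DataFrame):
        strata_df = pair_strata[["gene_a", "gene_b", "stratum"]].copy()
    else:
        strata_df = pd.DataFrame(
            [(a, b, s) for (a, b), s in pair_strata.items()],
            columns=["gene_a", "gene_b", "stratum"],
        )
    lo = [min(a, b) for a, b in zip(strata_df["gene_a"], strata_df["gene_b"])]
    hi = [max(a, b) for a, b in zip(strata_df["gene_a"], strata_df["gene_b"])]
    strata_df = strata_df.assign(gene_a=lo, gene_b=hi)

    known = set(edges["gene_a"]) | set(edges["gene_b"])
    unknown = (set(strata_df["gene_a"]) | set(strata_df["gene_b"])) - known
    if unknown:
        raise ValueError(f"strata reference unknown genes: {sorted(unknown)[:5]}")

    merged = strata_df.merge(edges, on=["gene_a", "gene_b"], how="left", indicator=True)
    n_missing = int((merged["_merge"] != "both").sum())
    if n_missing:
        warnings.warn(
            f"{n_missing} stratified pairs not present in the tested-pair table; dropped",
            stacklevel=2,
        )
        merged = merged[merged["_merge"] == "both"]

    def _summarize(group: pd.DataFrame) -> pd.Series:
        n_pairs = len(group)
        called = group["significant"].fillna(False).astype(bool)
        n_called = int(called.sum())
        neg = int(((group["sign"] == "-") & called).sum())
        return pd.Series(
            {
                "n_pairs": n_pairs,
                "n_called": n_called,
                "rate": n_called / n_pairs if n_pairs else np.nan,
                "fraction_negative": neg / n_called if n_called else np.nan,
            }
        )

    out = merged.groupby("stratum").apply(_summarize, include_groups=False).reset_index()
    out["n_pairs"] = out["n_pairs"].astype(int)
    out["n_called"] = out["n_called"].astype(int)
    return out


def path_length_strata(
    pairs: Sequence[tuple[str, str]],
    reference_edges: Sequence[tuple[str, str]],
) -> dict[tuple[str, str], str]:
    """Label pairs by shortest-path length in a reference interaction graph.

    Pairs with genes in separate components (or absent from the reference)
    are labeled ``"Inf"``.
    """
    g = nx.Graph()
    g.add_edges_from(reference_edges)
    out: dict[tuple[str, str], str] = {}
    for a, b in pairs:
        if a in g and b in g:
            try:
                out[(a, b)] = str(nx.shortest_path_length(g, a, b))
            except nx.NetworkXNoPath:
                out[(a, b)] = "Inf"
        else:
            out[(a, b)] = "Inf"
    return out


def complex_cofunc_expectation(
    complex_sizes: Sequence[int],
    per_complex_called: Sequence[int],
    global_rate: float,
) -> pd.DataFrame:
    """Binomial expectation for called pairs per protein complex.

    A complex of n members has m = n(n-1)/2 pairs; under independent calls
    at the genome-wide rate the called-pair count is Binomial(m, rate).
    Returns per complex the pmf, the central 90% interval, and whether the
    observation falls outside it.
    """
    if not (0 < global_rate < 1):
        raise ValueError("global_rate must lie in (0, 1)")
    if len(complex_sizes) != len(per_complex_called):
        raise ValueError("complex_sizes and per_complex_called differ in length")
    rows = []
    for n, called in zip(complex_sizes, per_complex_called):
        if n < 2:
            raise ValueError("complexes need at least 2 members")
        m = n * (n - 1) // 2
        dist = stats.binom(m, global_rate)
        lo = int(dist.ppf(0.05))
        hi = int(dist.ppf(0.95))
        rows.append(
            {
                "n_members": n,
                "n_pairs": m,
                "n_called": called,
                "expected": m * global_rate,
                "interval_low": lo,
                "interval_high": hi,
                "outside_interval": called < lo or called > hi,
                "pmf": dist.pmf(np.arange(m + 1)),
            }
        )
    return pd.DataFrame(rows)
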