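"""Correlation of corrected profiles, empirical null, and edge calling.

Significance of a gene-pair Pearson correlation is judged against a zero-mean
Gaussian null whose standard deviation is the RMS of held-out control-pair
correlations from a cross-validated re-fit of the confounder basis.  Pairs
passing Benjamini-Hochberg at the target FDR (default 10%), in either sign,
are called co-functional.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .correction import (
    ConfounderBasis,
    PermutationReport,
    fit_confounder_basis,
    remove_confounders,
    select_num_components,
)
from .io import EffectMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "NullModel",
    "pairwise_correlations",
    "fit_empirical_null",
    "call_edges",
    "run_pipeline",
    "PipelineResult",
    "downsample_power_curve",
]


@dataclass
class NullModel:
    """Zero-mean Gaussian null for corrected-profile Pearson correlations."""

    sigma: float
    n_folds: int
    n_pairs_used: int
    control_set_name: str = "controls"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.sigma < 1):
            raise ValueError(f"sigma must lie in (0, 1); got {self.sigma}")
        if self.n_pairs_used < 2:
            raise ValueError("need at least 2 control pairs for a null")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "NullModel":
        return cls(**json.loads(Path(path).read_text()))


def _unit_rows(X: np.ndarray, gene_ids: Sequence[str]) -> np.ndarray:
    """Center rows and scale to unit norm so that Z @ Z.T yields Pearson r."""
    centered = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    zero = np.flatnonzero(norms == 0)
    if zero.size:
        raise ValueError(
            f"zero-variance profile for gene {gene_ids[zero[0]]!r}"
        )
    return centered / norms[:, None]


def pairwise_correlations(
    matrix: EffectMatrix,
    genes_a: Sequence[str] | None = None,
    genes_b: Sequence[str] | None = None,
    block_size: int = 2048,
) -> pd.DataFrame:
    """Pearson correlations for all requested unordered gene pairs.

    With only ``genes_a`` (default: all genes), every unordered pair within
    the subset is returned; with ``genes_b`` as well, all cross pairs.  Rows
    carry ``gene_a < gene_b`` lexicographically, each unordered pair once,
    no self-pairs.  Computed blockwise so large panels stay within bounded
    memory per block.
    """
    if matrix.n_cells < 3:
        raise ValueError("need at least 3 cell lines to correlate profiles")
    if genes_a is None:
        genes_a = matrix.gene_ids
    if not len(genes_a):
        raise ValueError("empty gene subset")

    if genes_b is None:
        genes = sorted(set(genes_a))
        sub = matrix.subset_genes(genes)
        Z = _unit_rows(sub.values, genes)
        n = len(genes)
        a_idx: list[np.ndarray] = []
        b_idx: list[np.ndarray] = []
        rs: list[np.ndarray] = []
        for start in range(0, n, block_size):
            stop = min(start + block_size, n)
            R = Z[start:stop] @ Z.T
            for i_local, i in enumerate(range(start, stop)):
                if i + 1 < n:
                    a_idx.append(np.full(n - i - 1, i))
                    b_idx.append(np.arange(i + 1, n))
                    rs.append(R[i_local, i + 1 :])
        ai = np.concatenate(a_idx)
        bi = np.concatenate(b_idx)
        r = np.concatenate(rs)
        names = np.asarray(genes, dtype=object)
        return pd.DataFrame(
            {"gene_a": names[ai], "gene_b": names[bi], "r": np.clip(r, -1.0, 1.0)}
        )

    if not len(genes_b):
        raise ValueError("empty gene subset")
    ga = sorted(set(genes_a))
    gb = sorted(set(genes_b))
    Za = _unit_rows(matrix.subset_genes(ga).values, ga)
    Zb = _unit_rows(matrix.subset_genes(gb).values, gb)
    R = Za @ Zb.T
    rows = []
    for i, a in enumerate(ga):
        for j, b in enumerate(gb):
            if a == b:
                continue
            lo, hi = (a, b) if a < b else (b, a)
            rows.append((lo, hi, float(np.clip(R[i, j], -1.0, 1.0))))
    out = pd.DataFrame(rows, columns=["gene_a", "gene_b", "r"])
    return out.drop_duplicates(subset=["gene_a", "gene_b"], ignore_index=True)


def fit_empirical_null(
    matrix: EffectMatrix,
    controls: Sequence[str],
    basis_k: int,
    n_folds: int = 5,
    seed: int = 0,
    control_set_name: str = "controls",
) -> NullModel:
    """Cross-validated empirical null from held-out control correlations.

    Controls are split into seeded folds; for each fold a confounder basis is
    fit on the remaining folds only, the held-out controls are corrected with
    it, and all their within-fold pairwise correlations are pooled.  The null
    standard deviation is the RMS of the pooled correlations (mean fixed at
    zero).  Cross-validation exists solely to avoid the overfitting deflation
    that correcting controls with their own basis would cause; the basis used
    for genome-wide correction is fit on all controls.

    ``matrix`` must be the raw (uncorrected) matrix.
    """
    controls = list(controls)
    if len(controls) < 2 * n_folds:
        raise ValueError(
            f"need at least {2 * n_folds} controls for {n_folds}-fold CV"
        )
    rng = np.random.default_rng(seed)
    shuffled = list(np.asarray(controls, dtype=object)[rng.permutation(len(controls))])
    folds = [list(f) for f in np.array_split(np.asarray(shuffled, dtype=object), n_folds)]
    for f in folds:
        if len(f) < 2:
            raise ValueError("a fold has fewer than 2 control genes")

    sq: list[np.ndarray] = []
    n_pairs = 0
    for i, held_out in enumerate(folds):
        train = [c for j, f in enumerate(folds) if j != i for c in f]
        basis = fit_confounder_basis(matrix, train, k=basis_k)
        V = basis.components
        Xh = matrix.subset_genes(held_out).values
        Xh = Xh - (Xh @ V) @ V.T
        Z = _unit_rows(Xh, held_out)
        R = Z @ Z.T
        iu = np.triu_indices(len(held_out), k=1)
        sq.append(R[iu] ** 2)
        n_pairs += iu[0].size

    sigma = float(np.sqrt(np.mean(np.concatenate(sq))))
    return NullModel(
        sigma=sigma,
        n_folds=n_folds,
        n_pairs_used=n_pairs,
        control_set_name=control_set_name,
        seed=seed,
    )


def call_edges(
    correlations: pd.DataFrame, null: NullModel, fdr: float = 0.10
) -> pd.DataFrame:
    """Assign two-sided normal p-values and call edges at the target FDR.

    ``p = 2 * (1 - Phi(|r| / sigma))``; q-values by Benjamini-Hochberg over
    all tested pairs; ``significant`` marks q <= fdr.  Both correlation signs
    are eligible; the sign is recorded.
    """
    if not (0 < fdr < 1):
        raise ValueError("fdr must lie in (0, 1)")
    if null.sigma <= 0:
        raise ValueError("null sigma must be positive")
    r = correlations["r"].to_numpy(dtype=float)
    p = 2.0 * stats.norm.sf(np.abs(r) / null.sigma)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    _, q, _, _ = multipletests(p, method="fdr_bh")
    out = correlations.copy()
    out["p"] = p
    out["q"] = q
    out["significant"] = q <= fdr
    out["sign"] = np.where(r < 0, "-", "+")
    return out


@dataclass
class PipelineResult:
    """Everything produced by one correction + null + calling run."""

    selection: PermutationReport | None
    basis: ConfounderBasis | None
    null: NullModel
    corrected: EffectMatrix
    edges: pd.DataFrame
    dropped_genes: list[str] = field(default_factory=list)

    @property
    def n_edges(self) -> int:
        return int(self.edges["significant"].sum())


def run_pipeline(
    matrix: EffectMatrix,
    controls: Sequence[str],
    n_perm: int = 100,
    n_folds: int = 5,
    fdr: float = 0.10,
    seed: int = 0,
    force_k: int | None = None,
    apply_correction: bool = True,
    genes: Sequence[str] | None = None,
) -> PipelineResult:
    """Full co-functional calling pipeline on one effect matrix.

    Steps: permutation selection of the component count (unless ``force_k``),
    confounder removal (skipped when ``apply_correction`` is False, which
    models the naive uncorrected analysis with a raw-control null), CV
    empirical null, pairwise correlation of the requested genes, and BH edge
    calling.  Genes whose corrected profile has zero variance are dropped
    with a warning before correlation.
    """
    controls = list(controls)
    selection = None
    if apply_correction:
        if force_k is None:
            selection = select_num_components(matrix, controls, n_perm=n_perm, seed=seed)
            k = selection.selected_k
        else:
            k = int(force_k)
        basis = fit_confounder_basis(matrix, controls, k=k)
        corrected = remove_confounders(matrix, basis)
    else:
        k = 0
        basis = None
        corrected = matrix

    null = fit_empirical_null(
        matrix, controls, basis_k=k, n_folds=n_folds, seed=seed
    )

    wanted = list(genes) if genes is not None else corrected.gene_ids
    sub = corrected.subset_genes(wanted)
    sd = sub.values.std(axis=1)
    dropped = [g for g, s in zip(wanted, sd) if s == 0]
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} zero-variance profiles before correlation",
            stacklevel=2,
        )
        wanted = [g for g in wanted if g not in set(dropped)]

    corr = pairwise_correlations(corrected, wanted)
    edges = call_edges(corr, null, fdr=fdr)
    return PipelineResult(
        selection=selection,
        basis=basis,
        null=null,
        corrected=corrected,
        edges=edges,
        dropped_genes=dropped,
    )


def downsample_power_curve(
    matrix: EffectMatrix,
    controls: Sequence[str],
    cell_counts: Sequence[int],
    reps: int = 1,
    seed: int = 0,
    n_perm: int = 100,
    n_folds: int = 5,
    fdr: float = 0.10,
) -> pd.DataFrame:
    """Re-run the full pipeline on subsampled cell-line panels.

    For each requested panel size, cell lines are subsampled (seeded, order
    preserved) and k-selection -> correction -> null -> calling re-run;
    the table reports the mean null sigma and mean significant-edge count
    over ``reps`` draws per size.  Larger panels tighten the null and
    increase discovery.
    """
    for c in cell_counts:
        if c < 10 or c > matrix.n_cells:
            raise ValueError(f"cell count {c} outside [10, {matrix.n_cells}]")
    rng = np.random.default_rng(seed)
    cells = np.asarray(matrix.cell_line_ids, dtype=object)
    records = []
    for count in cell_counts:
        for rep in range(reps):
            chosen = cells[np.sort(rng.choice(matrix.n_cells, size=count, replace=False))]
            sub = matrix.subset_cells(list(chosen))
            res = run_pipeline(
                sub, controls, n_perm=n_perm, n_folds=n_folds, fdr=fdr, seed=seed
            )
            records.append(
                {"n_cells": count, "rep": rep, "sigma": res.null.sigma, "n_edges": res.n_edges}
            )
    raw = pd.DataFrame(records)
    out = (
        raw.groupby("n_cells", as_index=False)
        .agg(mean_sigma=("sigma", "mean"), mean_n_edges=("n_edges", "mean"))
        .sort_values("n_cells", ignore_index=True)
    )
    return out
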