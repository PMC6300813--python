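"""Cell-line-level association utilities.

Drug response (Amax) vs. gene-knockout correlation, similarity-based label
prediction (same-lineage / same-disease AUC from cell-line profile
correlations), exact 1-D two-means binarization of drug response, and
Wilcoxon tests of mutation status against per-cell-line loadings.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve
from statsmodels.stats.multitest import multipletests

from .io import EffectMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "drug_gene_correlations",
    "similarity_auc",
    "SimilarityAUC",
    "kmeans_binarize",
    "mutation_loading_association",
]


def drug_gene_correlations(
    drugs: pd.DataFrame,
    matrix: EffectMatrix,
    top_n: int = 30,
    min_shared: int = 10,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson correlation of each drug's Amax profile with every gene.

    ``drugs`` is drugs x cell lines with missing values allowed; each drug
    uses complete-case pairing over cell lines shared with the matrix.
    Drugs with fewer than ``min_shared`` usable lines are skipped with a
    warning.  Returns the full long table and, per drug, the ``top_n`` genes
    by |r| (the network figure uses 4, the enrichment analysis 30).
    """
    shared_all = [c for c in drugs.columns if c in set(matrix.cell_line_ids)]
    records = []
    X = matrix.data
    for drug, row in drugs.iterrows():
        vals = row[shared_all].astype(float)
        mask = vals.notna()
        cells = list(vals.index[mask])
        if len(cells) < min_shared:
            warnings.warn(
                f"drug {drug!r}: only {len(cells)} shared non-missing lines; skipped",
                stacklevel=2,
            )
            continue
        y = vals[mask].to_numpy()
        G = X[cells].to_numpy()
        yc = y - y.mean()
        ynorm = np.linalg.norm(yc)
        Gc = G - G.mean(axis=1, keepdims=True)
        gnorm = np.linalg.norm(Gc, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (Gc @ yc) / (gnorm * ynorm)
        for gene, rv in zip(matrix.gene_ids, r):
            records.append({"drug": drug, "gene": gene, "r": rv, "n": len(cells)})
    full = pd.DataFrame(records, columns=["drug", "gene", "r", "n"])
    if len(full):
        full = full[np.isfinite(full["r"].astype(float))].reset_index(drop=True)
    top = (
        full.assign(abs_r=full["r"].abs())
        .sort_values(["drug", "abs_r"], ascending=[True, False])
        .groupby("drug", sort=False)
        .head(top_n)
        .drop(columns="abs_r")
        .reset_index(drop=True)
    )
    return full, top


@dataclass
class SimilarityAUC:
    auc: float
    roc: pd.DataFrame  # columns fpr, tpr, threshold
    n_pairs: int
    n_positive: int


def similarity_auc(matrix: EffectMatrix, labels: pd.Series) -> SimilarityAUC:
    """AUC for detecting shared labels from cell-line profile correlations.

    Every unordered pair of labeled cell lines is scored by the Pearson
    correlation of their profile columns; positives are same-label pairs.
    AUC uses the rank statistic with midrank tie handling.
    """
    labels = labels.dropna()
    cells = [c for c in matrix.cell_line_ids if c in labels.index]
    counts = labels.loc[cells].value_counts()
    keep_classes = set(counts[counts >= 2].index)
    cells = [c for c in cells if labels[c] in keep_classes]
    if len(set(labels.loc[cells])) < 2:
        raise ValueError("need at least 2 label classes with >= 2 cell lines each")
    sub = matrix.subset_cells(cells)
    X = sub.values.T  # cells x genes
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Xc, axis=1)
    if (norms == 0).any():
        raise ValueError("zero-variance cell-line profile")
    Z = Xc / norms[:, None]
    R = Z @ Z.T
    iu = np.triu_indices(len(cells), k=1)
    scores = R[iu]
    lab = labels.loc[cells].to_numpy()
    y = (lab[iu[0]] == lab[iu[1]]).astype(int)
    auc = float(roc_auc_score(y, scores))
    fpr, tpr, thr = roc_curve(y, scores)
    return SimilarityAUC(
        auc=auc,
        roc=pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr}),
        n_pairs=len(y),
        n_positive=int(y.sum()),
    )


def kmeans_binarize(values: np.ndarray | pd.Series) -> tuple[np.ndarray, float]:
    """Exact 1-D two-means split into sensitive / resistant groups.

    The optimal 2-means partition of a 1-D vector is an interval split, so
    it is found exactly by scanning boundaries between distinct sorted
    values and minimizing within-cluster sum of squares.  The lower-mean
    cluster is labeled ``"sensitive"``.  Returns (labels, boundary) where
    the boundary is the midpoint between the two clusters.
    """
    if isinstance(values, pd.Series):
        index = values.index
        x = values.to_numpy(dtype=float)
    else:
        index = None
        x = np.asarray(values, dtype=float)
    if np.unique(x).size < 2:
        raise ValueError("all values identical; cannot binarize")
    order = np.argsort(x, kind="stable")
    xs = x[order]
    n = len(xs)
    csum = np.cumsum(xs)
    csq = np.cumsum(xs**2)

    best = (np.inf, -1)
    for s in range(1, n):
        if xs[s] == xs[s - 1]:
            continue  # optimal split always falls between distinct values
        left_ss = csq[s - 1] - csum[s - 1] ** 2 / s
        right_n = n - s
        right_sum = csum[-1] - csum[s - 1]
        right_ss = (csq[-1] - csq[s - 1]) - right_sum**2 / right_n
        wcss = left_ss + right_ss
        if wcss < best[0] - 1e-12:
            best = (wcss, s)
    s = best[1]
    boundary = float((xs[s - 1] + xs[s]) / 2)
    labels = np.where(x <= boundary, "sensitive", "resistant")
    if index is not None:
        labels = pd.Series(labels, index=index)  # type: ignore[assignment]
    return labels, boundary


def mutation_loading_association(
    loadings: pd.Series,
    mutations: pd.DataFrame,
    fdr: float = 0.10,
    min_group: int = 3,
) -> pd.DataFrame:
    """Wilcoxon rank-sum of per-cell-line loadings by mutation status.

    ``mutations`` is cell lines x genes, binary (1 = mutant).  Genes with
    fewer than ``min_group`` mutant or wild-type lines are skipped (logged).
    Two-sided p (exact for small groups without ties, normal approximation
    with tie correction otherwise), BH across genes.
    """
    cells = [c for c in loadings.index if c in mutations.index]
    rows = []
    for gene in mutations.columns:
        status = mutations.loc[cells, gene].astype(bool)
        mut = loadings.loc[cells][status.to_numpy()].to_numpy(dtype=float)
        wt = loadings.loc[cells][~status.to_numpy()].to_numpy(dtype=float)
        if len(mut) < min_group or len(wt) < min_group:
            logger.info("gene %s skipped: group sizes %d/%d", gene, len(mut), len(wt))
            continue
        combined = np.concatenate([mut, wt])
        if np.unique(combined).size == 1:
            p = 1.0  # all tied
        else:
            p = float(
                stats.mannwhitneyu(mut, wt, alternative="two-sided").pvalue
            )
        rows.append({"gene": gene, "n_mut": len(mut), "n_wt": len(wt), "p": p})
    out = pd.DataFrame(rows, columns=["gene", "n_mut", "n_wt", "p"])
    if len(out):
        _, q, _, _ = multipletests(out["p"], method="fdr_bh")
        out["q"] = q
        out["significant"] = out["q"] <= fdr
    else:
        out["q"] = pd.Series(dtype=float)
        out["significant"] = pd.Series(dtype=bool)
    return out
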