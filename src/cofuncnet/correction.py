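"""Control-gene PCA correction of nonspecific cell-line signatures.

Parallel knockout screens carry technical variation (screen quality, Cas9
toxicity, library effects) that inflates correlations between unrelated gene
profiles.  Genes with no expected proliferation phenotype (olfactory
receptors, curated nonessential genes) should show no coherent structure, so
any principal components of their profiles that exceed a within-column
permutation null are treated as confounder signatures living in cell-line
space and projected out of every gene profile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .io import EffectMatrix

__all__ = [
    "ConfounderBasis",
    "PermutationReport",
    "ControlPCACorrector",
    "fit_confounder_basis",
    "select_num_components",
    "remove_confounders",
]


@dataclass
class ConfounderBasis:
    """Orthonormal confounder subspace in cell-line space.

    ``components`` has shape (n_cell_lines, k); columns are mutually
    orthonormal.  ``center`` holds the per-cell-line mean over control genes
    used to center the PCA; ``variance_explained`` the per-rank variance
    fractions of the control PCA at all ranks.
    """

    components: np.ndarray
    variance_explained: np.ndarray
    k: int
    center: np.ndarray
    cell_line_ids: list[str]

    def __post_init__(self) -> None:
        if self.components.shape[1] != self.k:
            raise ValueError("components column count must equal k")
        gram = self.components.T @ self.components
        if self.k and not np.allclose(gram, np.eye(self.k), atol=1e-8):
            raise ValueError("components are not orthonormal to 1e-8")
        if np.any(self.variance_explained < -1e-12):
            raise ValueError("variance_explained must be nonnegative")
        if self.variance_explained.sum() > 1 + 1e-8:
            raise ValueError("variance_explained sums to more than 1")


@dataclass
class PermutationReport:
    """Outcome of the permutation (parallel-analysis style) rank selection."""

    n_perm: int
    true_varexp: np.ndarray
    perm_varexp_max: np.ndarray
    selected_k: int
    seed: int


def _variance_fractions(control_matrix: np.ndarray) -> np.ndarray:
    """Per-rank variance fractions of the column-centered control matrix."""
    centered = control_matrix - control_matrix.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    total = float(np.sum(s**2))
    if total == 0.0:
        return np.zeros_like(s)
    return s**2 / total


def _fix_signs(components: np.ndarray) -> np.ndarray:
    """Make each column's largest-magnitude entry positive (signs arbitrary)."""
    out = components.copy()
    for j in range(out.shape[1]):
        i = int(np.argmax(np.abs(out[:, j])))
        if out[i, j] < 0:
            out[:, j] = -out[:, j]
    return out


class ControlPCACorrector(TransformerMixin, BaseEstimator):
    """Learn confounder signatures from control genes and remove them.

    Fit on the control submatrix with control genes as observations and cell
    lines as variables (each cell-line column centered by its mean over
    controls).  ``transform`` projects the learned subspace out of any
    genes x cell-lines matrix: ``x -> x - V (V^T x)`` per gene profile, on
    raw (uncentered) profiles.

    Parameters
    ----------
    n_components
        Number of components to keep, or ``"permutation"`` to select the
        count by comparing per-rank variance fractions against the maximum
        over within-column permutations (strict exceedance, prefix rule).
    n_permutations
        Permutations used when ``n_components="permutation"``.
    random_state
        Seed for the permutation draws.

    Attributes
    ----------
    components_ : ndarray of shape (n_cell_lines, n_components_)
    n_components_ : int
    variance_explained_ : ndarray, per-rank variance fractions (all ranks)
    center_ : ndarray, per-cell-line mean over control genes
    permutation_report_ : PermutationReport, when permutation selection ran
    """

    def __init__(
        self,
        n_components: int | str = "permutation",
        n_permutations: int = 100,
        random_state: int | None = None,
    ) -> None:
        self.n_components = n_components
        self.n_permutations = n_permutations
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (control genes x cell lines)")
        if not np.isfinite(X).all():
            raise ValueError("X contains non-finite values")
        if X.shape[0] < 3:
            raise ValueError("need at least 3 control genes to fit a basis")

        self.center_ = X.mean(axis=0)
        centered = X - self.center_
        _, s, vt = np.linalg.svd(centered, full_matrices=False)
        total = float(np.sum(s**2))
        self.variance_explained_ = (
            s**2 / total if total > 0 else np.zeros_like(s)
        )

        if self.n_components == "permutation":
            report = self._permutation_select(X)
            self.permutation_report_ = report
            k = report.selected_k
        else:
            k = int(self.n_components)
            if k < 0 or k > min(X.shape):
                raise ValueError(
                    f"n_components={k} exceeds rank bound {min(X.shape)}"
                )
            self.permutation_report_ = None
        self.n_components_ = k
        self.components_ = _fix_signs(vt[:k].T)
        self.n_features_in_ = X.shape[1]
        return self

    def _permutation_select(self, X: np.ndarray) -> PermutationReport:
        rng = np.random.default_rng(self.random_state)
        true_varexp = _variance_fractions(X)
        perm_max = np.zeros_like(true_varexp)
        for _ in range(self.n_permutations):
            # shuffle effect sizes independently within each cell-line column
            permuted = rng.permuted(X, axis=0)
            perm_max = np.maximum(perm_max, _variance_fractions(permuted))
        exceeds = true_varexp > perm_max
        selected_k = int(np.argmin(exceeds)) if not exceeds.all() else len(exceeds)
        return PermutationReport(
            n_perm=self.n_permutations,
            true_varexp=true_varexp,
            perm_varexp_max=perm_max,
            selected_k=selected_k,
            seed=self.random_state if self.random_state is not None else -1,
        )

    def transform(self, X):
        if not hasattr(self, "components_"):
            raise RuntimeError("corrector is not fitted")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} cell lines, corrector was fit with "
                f"{self.n_features_in_}"
            )
        V = self.components_
        return X - (X @ V) @ V.T


# ---------------------------------------------------------------------------
# EffectMatrix-level wrappers


def fit_confounder_basis(
    matrix: EffectMatrix, controls: list[str], k: int
) -> ConfounderBasis:
    """PCA on the control submatrix; return the top-k cell-line components."""
    if len(controls) < 3:
        raise ValueError("need at least 3 control genes")
    sub = matrix.subset_genes(controls)
    if k > min(sub.n_genes, sub.n_cells):
        raise ValueError(
            f"k={k} exceeds rank bound min({sub.n_genes}, {sub.n_cells})"
        )
    est = ControlPCACorrector(n_components=k).fit(sub.values)
    return ConfounderBasis(
        components=est.components_,
        variance_explained=est.variance_explained_,
        k=k,
        center=est.center_,
        cell_line_ids=matrix.cell_line_ids,
    )


def select_num_components(
    matrix: EffectMatrix,
    controls: list[str],
    n_perm: int = 100,
    seed: int = 0,
) -> PermutationReport:
    """Permutation test for the number of significant control components.

    Variance fractions of the true control PCA are compared, rank by rank,
    with the maximum over ``n_perm`` within-column permutations; the selected
    count is the longest prefix of ranks where the true fraction strictly
    exceeds every permutation.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    sub = matrix.subset_genes(controls)
    est = ControlPCACorrector(
        n_components="permutation", n_permutations=n_perm, random_state=seed
    ).fit(sub.values)
    return est.permutation_report_


def remove_confounders(matrix: EffectMatrix, basis: ConfounderBasis) -> EffectMatrix:
    """Project the confounder subspace out of every gene profile.

    Applies ``x -> x - V (V^T x)`` to all genes, controls included; the
    result is flagged corrected.  Cell-line order must match the basis.
    """
    if matrix.cell_line_ids != basis.cell_line_ids:
        for got, want in zip(matrix.cell_line_ids, basis.cell_line_ids):
            if got != want:
                raise ValueError(
                    f"cell-line mismatch with basis: matrix has {got!r} where "
                    f"basis expects {want!r}"
                )
        raise ValueError(
            f"cell-line count mismatch: matrix {matrix.n_cells}, "
            f"basis {len(basis.cell_line_ids)}"
        )
    V = basis.components
    X = matrix.values
    corrected = X - (X @ V) @ V.T
    data = matrix.data.copy()
    data.loc[:, :] = corrected
    return EffectMatrix(data, is_corrected=True)
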