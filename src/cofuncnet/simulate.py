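"""Synthetic parallel-screen generator with known confounders and modules.

The generator emulates a post-copy-number-corrected gene-effect matrix:
every gene profile is a per-gene baseline plus gene-specific loadings on a
small number of shared cell-line confounders (technical variation affecting
all genes, controls included), plus — for planted-module members only — a
shared biological factor, plus Gaussian noise:

    X[g, c] = mu_g + sum_j s_gj * L_j[c] + sum_m a_gm * B_m[c] + eps[g, c]

Confounder and module factors L_j, B_m are i.i.d. standard normal across
cell lines.  Control genes carry confounders and noise but no module effect,
which is what lets components learned from controls transfer genome-wide.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import EffectMatrix

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "simulate_screen",
    "planted_truth_edges",
    "evaluate_calls",
    "CallEvaluation",
]


@dataclass
class SimulationConfig:
    """Parameters of one synthetic screen.

    Defaults describe the standard study conditions used throughout the test
    suite: a 1,000-gene panel (250 of them controls) screened across 200
    cell lines, two technical confounders of unit strength, ten planted
    co-functional modules of ten genes at effect 0.8, and unit residual
    noise.
    """

    n_genes: int = 1000
    n_controls: int = 250
    n_cells: int = 200
    n_confounders: int = 2
    confounder_strength: float = 1.0  # s.d. of per-gene susceptibilities
    modules: Sequence[tuple[int, float]] = field(
        default_factory=lambda: tuple((10, 0.8) for _ in range(10))
    )
    gene_mean_sd: float = 0.5  # s.d. of per-gene baseline essentiality
    noise_sd: float = 1.0
    noise_df: float | None = None  # Student-t noise when set (robustness switch)
    seed: int = 0

    def validate(self) -> None:
        if min(self.confounder_strength, self.gene_mean_sd, self.noise_sd) < 0:
            raise ValueError("standard deviations must be nonnegative")
        if self.n_confounders < 0:
            raise ValueError("n_confounders must be nonnegative")
        if any(size < 2 for size, _ in self.modules):
            raise ValueError("module sizes must be at least 2")
        if sum(size for size, _ in self.modules) > self.n_genes - self.n_controls:
            raise ValueError("planted modules exceed the non-control gene budget")
        if self.n_controls < 0 or self.n_controls > self.n_genes:
            raise ValueError("n_controls must lie in [0, n_genes]")
        if self.n_cells < 2:
            raise ValueError("need at least 2 cell lines")


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated screen."""

    modules: dict[str, list[str]]  # module name -> member genes
    controls: list[str]
    confounder_loadings: np.ndarray  # n_confounders x n_cells
    susceptibilities: pd.DataFrame  # genes x confounders
    module_factors: np.ndarray  # n_modules x n_cells
    config: SimulationConfig


def simulate_screen(config: SimulationConfig) -> tuple[EffectMatrix, SyntheticTruth]:
    """Draw one synthetic screen; fully seeded and reproducible."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    n_module_genes = sum(size for size, _ in config.modules)
    n_background = config.n_genes - config.n_controls - n_module_genes

    controls = [f"CTRL{i:04d}" for i in range(config.n_controls)]
    module_map: dict[str, list[str]] = {}
    module_genes: list[str] = []
    for m, (size, _) in enumerate(config.modules):
        members = [f"M{m:02d}G{i:02d}" for i in range(size)]
        module_map[f"module_{m:02d}"] = members
        module_genes.extend(members)
    background = [f"BG{i:04d}" for i in range(n_background)]
    genes = controls + module_genes + background
    cells = [f"ACH-{i + 1:06d}" for i in range(config.n_cells)]

    mu = rng.normal(0.0, config.gene_mean_sd, size=config.n_genes)
    mu[: config.n_controls] = 0.0  # controls are phenotype-free: confounders + noise only
    L = rng.standard_normal((config.n_confounders, config.n_cells))
    S = rng.normal(
        0.0, config.confounder_strength, size=(config.n_genes, config.n_confounders)
    )
    B = rng.standard_normal((len(config.modules), config.n_cells))
    A = np.zeros((config.n_genes, len(config.modules)))
    offset = config.n_controls
    for m, (size, effect) in enumerate(config.modules):
        A[offset : offset + size, m] = effect
        offset += size

    if config.noise_df is not None:
        eps = rng.standard_t(config.noise_df, size=(config.n_genes, config.n_cells))
        eps *= config.noise_sd
    else:
        eps = rng.normal(0.0, config.noise_sd, size=(config.n_genes, config.n_cells))

    X = mu[:, None] + S @ L + A @ B + eps
    matrix = EffectMatrix(pd.DataFrame(X, index=genes, columns=cells))
    truth = SyntheticTruth(
        modules=module_map,
        controls=controls,
        confounder_loadings=L,
        susceptibilities=pd.DataFrame(
            S, index=genes, columns=[f"confounder_{j}" for j in range(config.n_confounders)]
        ),
        module_factors=B,
        config=config,
    )
    return matrix, truth


def planted_truth_edges(truth: SyntheticTruth) -> list[tuple[str, str]]:
    """All unordered within-module pairs (gene_a < gene_b)."""
    pairs: list[tuple[str, str]] = []
    for members in truth.modules.values():
        ordered = sorted(members)
        for i, a in enumerate(ordered):
            for b in ordered[i + 1 :]:
                pairs.append((a, b))
    return pairs


@dataclass
class CallEvaluation:
    precision: float
    recall: float
    realized_fdr: float
    n_calls: int
    n_true_calls: int
    n_truth_pairs: int


def evaluate_calls(
    edges: pd.DataFrame,
    truth_pairs: Sequence[tuple[str, str]],
    universe: Sequence[str] | None = None,
) -> CallEvaluation:
    """Precision / recall / realized FDR of called edges vs. planted truth.

    Precision is defined as 1 when nothing is called (no false discoveries
    were made); realized FDR is 1 - precision.
    """
    sig = edges[edges["significant"].astype(bool)] if "significant" in edges.columns else edges
    calls = {
        (min(a, b), max(a, b)) for a, b in zip(sig["gene_a"], sig["gene_b"])
    }
    if universe is not None:
        uni = set(universe)
        calls = {p for p in calls if p[0] in uni and p[1] in uni}
    truth = {(min(a, b), max(a, b)) for a, b in truth_pairs}
    n_true_calls = len(calls & truth)
    precision = n_true_calls / len(calls) if calls else 1.0
    recall = n_true_calls / len(truth) if truth else 0.0
    return CallEvaluation(
        precision=precision,
        recall=recall,
        realized_fdr=1.0 - precision,
        n_calls=len(calls),
        n_true_calls=n_true_calls,
        n_truth_pairs=len(truth),
    )
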