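"""Readers/writers for screen matrices, control lists, guide maps and gene sets.

The canonical in-memory orientation is genes x cell lines: each row is a gene
essentiality profile (knockout effect sizes across screens), each column a
cell-line profile.  The Achilles "gene_effect" CSV dialect ships the transpose
(cell lines as rows, ``"SYMBOL (Entrez)"`` column labels); orientation is
auto-detected and gene labels are reduced to the bare symbol.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_ACH_ID = re.compile(r"^ACH-\d+$")
_ENTREZ_SUFFIX = re.compile(r"\s*\(\d+\)$")

__all__ = [
    "EffectMatrix",
    "GeneSetCollection",
    "read_effect_matrix",
    "write_effect_matrix",
    "read_gene_list",
    "read_guide_map",
    "dedup_by_guides",
    "read_gene_sets",
    "read_annotations",
]


@dataclass
class EffectMatrix:
    """Gene x cell-line matrix of knockout effect sizes.

    Rows are gene essentiality profiles; columns are cell lines.  Effect sizes
    are unitless, with more negative values indicating a stronger growth
    defect upon knockout.  ``is_corrected`` flags whether confounder
    signatures have already been projected out of the profiles.
    """

    data: pd.DataFrame
    is_corrected: bool = False

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate cell-line ids: {dups}")
        if not np.isfinite(self.data.to_numpy(dtype=float)).all():
            raise ValueError(
                "effect matrix contains non-finite values; "
                "apply a missing-value policy before constructing an EffectMatrix"
            )

    # -- basic accessors -------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def cell_line_ids(self) -> list[str]:
        return self.data.columns.tolist()

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_cells(self) -> int:
        return self.data.shape[1]

    def subset_genes(self, genes: Sequence[str]) -> "EffectMatrix":
        missing = [g for g in genes if g not in self.data.index]
        if missing:
            raise KeyError(f"genes not in matrix: {missing[:5]}")
        return EffectMatrix(self.data.loc[list(genes)], is_corrected=self.is_corrected)

    def subset_cells(self, cells: Sequence[str]) -> "EffectMatrix":
        missing = [c for c in cells if c not in self.data.columns]
        if missing:
            raise KeyError(f"cell lines not in matrix: {missing[:5]}")
        return EffectMatrix(self.data[list(cells)], is_corrected=self.is_corrected)

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index_label="gene")


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT-style), symbols uppercase-normalized."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        empty = [name for name, members in self.sets.items() if not members]
        if empty:
            raise ValueError(f"empty gene sets: {empty[:5]}")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def items(self):
        return self.sets.items()


def _clean_gene_label(label: str) -> str:
    """Reduce ``"SYMBOL (Entrez)"`` labels to the bare uppercase symbol."""
    return _ENTREZ_SUFFIX.sub("", str(label).strip()).upper()


def _fraction_matching(ids: Iterable[str], pattern: re.Pattern) -> float:
    ids = [str(i) for i in ids]
    if not ids:
        return 0.0
    return sum(bool(pattern.match(i.strip())) for i in ids) / len(ids)


def read_effect_matrix(
    path: str | Path,
    orientation: str = "auto",
    missing: str = "drop",
) -> EffectMatrix:
    """Read a gene-effect CSV into canonical genes x cell lines orientation.

    Parameters
    ----------
    path
        CSV with one header row and one id column.  Both the Achilles
        dialect (cell-line rows, ``"SYMBOL (Entrez)"`` columns) and generic
        genes-as-rows matrices are supported.
    orientation
        ``"auto"`` decides from id patterns (cell-line ids look like
        ``ACH-______``) and falls back on a >5x shape ratio; ``"genes_rows"``
        and ``"cells_rows"`` force the layout.
    missing
        Policy for missing values: ``"drop"`` removes genes with any missing
        entry (logged); ``"mean"`` imputes the gene's mean effect.
    """
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"empty effect matrix: {path}")

    if orientation not in {"auto", "genes_rows", "cells_rows"}:
        raise ValueError(f"unknown orientation {orientation!r}")

    if orientation == "auto":
        row_cells = _fraction_matching(df.index, _ACH_ID)
        col_cells = _fraction_matching(df.columns, _ACH_ID)
        if row_cells > 0.5 and col_cells <= 0.5:
            orientation = "cells_rows"
        elif col_cells > 0.5 and row_cells <= 0.5:
            orientation = "genes_rows"
        elif df.shape[1] > 5 * df.shape[0]:
            # Achilles ships ~17k gene columns for a few hundred screens.
            orientation = "cells_rows"
        elif df.shape[0] > 5 * df.shape[1]:
            orientation = "genes_rows"
        else:
            raise ValueError(
                "ambiguous matrix orientation: could be "
                f"{df.shape[0]} genes x {df.shape[1]} cell lines or "
                f"{df.shape[1]} genes x {df.shape[0]} cell lines; "
                "pass orientation='genes_rows' or 'cells_rows'"
            )

    if orientation == "cells_rows":
        df = df.T

    df.index = [_clean_gene_label(g) for g in df.index]
    df.columns = [str(c).strip() for c in df.columns]

    if pd.Index(df.index).has_duplicates:
        collisions = pd.Index(df.index)[pd.Index(df.index).duplicated()].unique().tolist()
        raise ValueError(
            f"duplicate gene ids after symbol reduction: {collisions[:10]}"
        )

    df = df.astype(float)
    if df.isna().to_numpy().any():
        if missing == "drop":
            keep = ~df.isna().any(axis=1)
            logger.info(
                "dropping %d/%d genes with missing values", int((~keep).sum()), len(keep)
            )
            df = df.loc[keep]
            if df.shape[0] == 0:
                raise ValueError("all genes dropped by missing-value policy")
        elif missing == "mean":
            df = df.apply(lambda row: row.fillna(row.mean()), axis=1)
        else:
            raise ValueError(f"unknown missing-value policy {missing!r}")

    return EffectMatrix(df)


def write_effect_matrix(matrix: EffectMatrix, path: str | Path) -> None:
    matrix.to_csv(path)


def read_gene_list(path: str | Path, matrix: EffectMatrix) -> list[str]:
    """Read a one-symbol-per-line gene list, intersected with the matrix.

    Order follows the file; duplicates are removed; symbols are uppercased.
    Raises if no listed gene is present in the matrix.
    """
    raw: list[str] = []
    seen: set[str] = set()
    for line in Path(path).read_text().splitlines():
        sym = line.strip().upper()
        if sym and sym not in seen:
            seen.add(sym)
            raw.append(sym)
    present = set(matrix.gene_ids)
    kept = [g for g in raw if g in present]
    logger.info("gene list %s: kept %d/%d symbols", path, len(kept), len(raw))
    if not kept:
        raise ValueError(f"no genes from {path} are present in the matrix")
    return kept


def read_guide_map(path: str | Path) -> pd.DataFrame:
    """Read a TSV sgRNA->gene map with columns ``sgrna`` and ``gene``."""
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    if "sgrna" not in cols or "gene" not in cols:
        raise ValueError(f"guide map {path} needs 'sgrna' and 'gene' columns")
    out = pd.DataFrame(
        {
            "sgrna": df[cols["sgrna"]].astype(str).str.strip(),
            "gene": df[cols["gene"]].astype(str).str.strip().str.upper(),
        }
    )
    if (out["sgrna"] == "").any():
        raise ValueError("guide map contains empty sgRNA sequences")
    return out


def dedup_by_guides(
    controls: Sequence[str],
    guides: pd.DataFrame,
    seed: int,
) -> list[str]:
    """Collapse control genes that share sgRNA sequences to one survivor each.

    Control genes connected through shared guides (transitively) form a group;
    one member per group is retained by a seeded uniform draw, mirroring the
    rule of keeping a single gene and discarding its duplicate-guide partners.
    Controls absent from the guide map are kept with a warning (the filter is
    conservative).  Deterministic given ``seed`` and idempotent.
    """
    controls = list(controls)
    control_set = set(controls)
    known = set(guides["gene"])
    missing = [c for c in controls if c not in known]
    if missing:
        warnings.warn(
            f"{len(missing)} control genes absent from guide map; keeping them",
            stacklevel=2,
        )

    # union-find over controls sharing at least one guide sequence
    parent = {c: c for c in controls}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: str, b: str) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    sub = guides[guides["gene"].isin(control_set)]
    for _, group in sub.groupby("sgrna"):
        members = sorted(set(group["gene"]))
        for other in members[1:]:
            union(members[0], other)

    components: dict[str, list[str]] = {}
    for c in controls:
        components.setdefault(find(c), []).append(c)

    rng = np.random.default_rng(seed)
    survivors: set[str] = set()
    # deterministic iteration order: sort components by their sorted members
    for members in sorted((sorted(m) for m in components.values())):
        if len(members) == 1:
            survivors.add(members[0])
        else:
            survivors.add(members[int(rng.integers(len(members)))])

    kept = [c for c in controls if c in survivors]
    logger.info("guide dedup: kept %d/%d controls", len(kept), len(controls))
    return kept


def read_gene_sets(
    path: str | Path,
    min_size: int | None = None,
    max_size: int | None = None,
) -> GeneSetCollection:
    """Parse a GMT file (name, description, members per tab-separated line)."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    n_filtered = 0
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
        name, desc, *members = fields
        uniq: list[str] = []
        seen: set[str] = set()
        for m in members:
            sym = m.strip().upper()
            if sym and sym not in seen:
                seen.add(sym)
                uniq.append(sym)
        if min_size is not None and len(uniq) < min_size:
            n_filtered += 1
            continue
        if max_size is not None and len(uniq) > max_size:
            n_filtered += 1
            continue
        sets[name] = uniq
        descriptions[name] = desc
    if n_filtered:
        logger.info("gene sets: %d sets excluded by size filter", n_filtered)
    return GeneSetCollection(sets, descriptions)


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read a per-gene annotation TSV (first column = gene symbol).

    Returns a DataFrame indexed by uppercase gene symbol.  Typical columns:
    ``chromosome`` (string), ``census`` (none/germline/somatic/both), plus
    arbitrary binary or real attributes.
    """
    df = pd.read_csv(path, sep="\t")
    gene_col = df.columns[0]
    df[gene_col] = df[gene_col].astype(str).str.strip().str.upper()
    if df[gene_col].duplicated().any():
        dups = df.loc[df[gene_col].duplicated(), gene_col].unique().tolist()
        raise ValueError(f"duplicate gene symbols in annotations: {dups[:5]}")
    return df.set_index(gene_col)
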