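"""Proteome/transcriptome concordance.

Given a gene-level differential-expression table, apply fixed DEG
thresholds (p <= 0.05 and |logFC| >= 0.5, both inclusive), then intersect
(a) differentially abundant proteins, mapped to gene symbols, with the DEG
list, and (b) significant category lists from the two omics layers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "ConcordanceReport",
    "call_deg",
    "intersect_molecules",
    "intersect_categories",
    "concordance_report",
]


def _check_gene_table(table: pd.DataFrame) -> pd.DataFrame:
    required = {"gene", "logfc", "p"}
    if not isinstance(table, pd.DataFrame) or not required <= set(table.columns):
        raise ValidationError(f"gene table needs columns {sorted(required)}")
    if table["gene"].duplicated().any():
        dup = sorted(table.loc[table["gene"].duplicated(), "gene"].unique())
        raise ValidationError(f"duplicate gene symbols: {dup}")
    p = table["p"].to_numpy(float)
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValidationError("gene p-values must lie in [0, 1]")
    return table


def call_deg(table: pd.DataFrame, p_threshold: float = 0.05,
             logfc_threshold: float = 0.5) -> pd.DataFrame:
    """Differentially expressed genes at p <= threshold and |logFC| >= threshold.

    Returns the called rows with a ``direction`` column (sign of logFC).
    """
    _check_gene_table(table)
    hit = (table["p"] <= p_threshold) & (table["logfc"].abs() >= logfc_threshold)
    out = table.loc[hit, ["gene", "logfc", "p"]].copy()
    out["direction"] = np.where(out["logfc"] >= 0, "up", "down")
    return out.reset_index(drop=True)


def intersect_molecules(da_proteins, degs, id_map: dict):
    """Gene symbols hit in both omics layers.

    ``id_map`` maps protein accession -> gene symbol; protein ids without a
    mapping are returned in a side list rather than silently dropped.
    Returns (sorted shared symbols, sorted unmapped protein ids).
    """
    unmapped = sorted(p for p in da_proteins if p not in id_map)
    mapped = {id_map[p] for p in da_proteins if p in id_map}
    shared = sorted(mapped & set(degs))
    return shared, unmapped


def intersect_categories(protein_sig, gene_sig) -> list:
    """Category ids significant in both layers, sorted."""
    return sorted(set(protein_sig) & set(gene_sig))


@dataclass
class ConcordanceReport:
    shared_molecules: list
    unmapped_proteins: list
    shared_categories: list
    n_da_proteins: int
    n_degs: int

    @property
    def n_shared_molecules(self) -> int:
        return len(self.shared_molecules)

    @property
    def n_shared_categories(self) -> int:
        return len(self.shared_categories)


def concordance_report(da_proteins, gene_table: pd.DataFrame, id_map: dict,
                       protein_sig_categories=(), gene_sig_categories=(),
                       p_threshold: float = 0.05,
                       logfc_threshold: float = 0.5) -> ConcordanceReport:
    """Full cross-omics summary: DEG calling plus both intersections."""
    degs = call_deg(gene_table, p_threshold, logfc_threshold)["gene"]
    shared, unmapped = intersect_molecules(da_proteins, degs, id_map)
    return ConcordanceReport(
        shared_molecules=shared,
        unmapped_proteins=unmapped,
        shared_categories=intersect_categories(protein_sig_categories,
                                               gene_sig_categories),
        n_da_proteins=len(list(da_proteins)),
        n_degs=len(degs),
    )
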