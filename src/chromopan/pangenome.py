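"""Pan- and core-genome accounting at chromosome scale.

The pan set is the union of reference genes and genes assembled in the
panel but absent from the reference (counted when found in at least two
accessions).  Variable genes are those affected by PAV or CNV in at least
one accession; the core is the pan minus the variable set.  Percentages
are reported as integers rounded half away from zero, the way such counts
are printed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "PanGenomeSummary",
    "rounded_percent",
    "pan_core_accounting",
    "extrapolate_to_genome",
    "new_gene_accounting",
]


@dataclass(frozen=True)
class PanGenomeSummary:
    n_reference_genes: int
    n_new_genes: int
    n_pan: int
    n_variable: int
    n_core: int
    pct_core: int
    pct_variable: int

    def report(self) -> str:
        return (
            f"pan = {self.n_reference_genes} + {self.n_new_genes} = {self.n_pan} genes; "
            f"variable = {self.n_variable} ({self.pct_variable}%); "
            f"core = pan - variable = {self.n_core} ({self.pct_core}%)"
        )


def rounded_percent(part: float, whole: float) -> int:
    """Integer percentage, rounded half away from zero."""
    if whole == 0:
        raise ZeroDivisionError("whole must be non-zero")
    x = 100 * part / whole
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def pan_core_accounting(
    n_reference_genes: int,
    n_new_genes: int,
    variable_gene_ids,
) -> PanGenomeSummary:
    """Assemble the pan/core summary from counts and the variable-gene set.

    ``n_core`` is computed as pan minus variable, which keeps the
    conservation identity core + variable = pan exact by construction.
    """
    if n_reference_genes < 0 or n_new_genes < 0:
        raise ValueError("negative gene counts")
    variable = set(variable_gene_ids)
    n_pan = n_reference_genes + n_new_genes
    n_var = len(variable)
    if n_var > n_pan:
        raise ValueError(f"variable set ({n_var}) larger than pan ({n_pan})")
    n_core = n_pan - n_var
    return PanGenomeSummary(
        n_reference_genes=n_reference_genes,
        n_new_genes=n_new_genes,
        n_pan=n_pan,
        n_variable=n_var,
        n_core=n_core,
        pct_core=rounded_percent(n_core, n_pan),
        pct_variable=rounded_percent(n_var, n_pan),
    )


def extrapolate_to_genome(variable_rate: float, total_genes: int) -> tuple[int, int]:
    """Scale a per-chromosome variable-gene rate to a whole-genome gene count.

    Returns (variable_count, core_count) with the variable count rounded
    half away from zero and the core count as the exact complement.
    """
    if not 0.0 <= variable_rate <= 1.0:
        raise ValueError("rate must be in [0, 1]")
    if total_genes <= 0:
        raise ValueError("total_genes must be positive")
    variable = int(math.floor(variable_rate * total_genes + 0.5))
    return variable, total_genes - variable


def new_gene_accounting(cluster_table: pd.DataFrame, reference_flag: str = "in_reference") -> int:
    """Count novel gene clusters: absent from the reference, present in >= 2 accessions.

    ``cluster_table`` has one row per assembled gene cluster, a boolean
    column per accession and a boolean ``reference_flag`` column.
    """
    acc_cols = [c for c in cluster_table.columns if c != reference_flag]
    in_ref = cluster_table[reference_flag].astype(bool)
    n_acc = cluster_table[acc_cols].astype(bool).sum(axis=1)
    return int(((~in_ref) & (n_acc >= 2)).sum())
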