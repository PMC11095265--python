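"""Selection of the flagellar predictor gene panel.

Starting from a labeled gene-content matrix, counts are binarized to
presence/absence and genes are retained by a dual prevalence rule: a gene
enters the panel when it is present in more than ``min_prevalence_motile``
of empirically motile genomes and is *not* present in more than
``max_prevalence_nonmotile`` of nonmotile genomes.  With the default strict
semantics a gene with motile prevalence exactly at the threshold is
rejected, while one with nonmotile prevalence exactly at the threshold is
kept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from flagmet.errors import ValidationError
from flagmet.io import GeneContentMatrix, MOTILE, NONMOTILE

logger = logging.getLogger("flagmet")


@dataclass(frozen=True)
class PanelCriteria:
    """Dual prevalence thresholds for panel membership.

    ``strict`` controls the motile-side boundary: when true (default) a
    gene must exceed ``min_prevalence_motile``; when false, reaching it is
    enough.  The nonmotile side always retains genes whose prevalence does
    not exceed ``max_prevalence_nonmotile``.
    """

    min_prevalence_motile: float = 0.80
    max_prevalence_nonmotile: float = 0.50
    strict: bool = True

    def __post_init__(self) -> None:
        for name in ("min_prevalence_motile", "max_prevalence_nonmotile"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name}={v} outside [0, 1]")

    def retains(self, prevalence_motile: float, prevalence_nonmotile: float) -> bool:
        if self.strict:
            crit_i = prevalence_motile > self.min_prevalence_motile
        else:
            crit_i = prevalence_motile >= self.min_prevalence_motile
        crit_ii = not (prevalence_nonmotile > self.max_prevalence_nonmotile)
        return crit_i and crit_ii


@dataclass
class GenePanel:
    """Retained predictor genes with their per-class prevalences."""

    gene_ids: list[str]
    prevalences: pd.DataFrame  # per retained gene: prevalence_motile, prevalence_nonmotile
    criteria: PanelCriteria
    candidate_pool_size: int

    def __len__(self) -> int:
        return len(self.gene_ids)

    def to_frame(self) -> pd.DataFrame:
        return self.prevalences.loc[self.gene_ids]

    def write(self, path) -> None:
        df = self.to_frame().reset_index().rename(columns={"index": "gene_id"})
        df.to_csv(path, sep="\t", index=False)


def read_panel(path) -> list[str]:
    """Read the gene ids of a panel TSV written by :meth:`GenePanel.write`."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    return df["gene_id"].astype(str).tolist()


def binarize(matrix: GeneContentMatrix) -> GeneContentMatrix:
    """Collapse copy counts to presence/absence (1 iff count > 0)."""
    if matrix.is_binary:
        return matrix
    data = (matrix.data > 0).astype(int)
    return GeneContentMatrix(data, is_binary=True)


def gene_prevalence(matrix: GeneContentMatrix, phenotypes: pd.Series) -> pd.DataFrame:
    """Per-gene fraction of motile and of nonmotile genomes carrying the gene.

    Returns a DataFrame indexed by gene id with columns
    ``prevalence_motile`` and ``prevalence_nonmotile``.
    """
    if not matrix.is_binary:
        raise ValidationError("gene_prevalence requires a binarized matrix")
    missing = [g for g in matrix.genome_ids if g not in phenotypes.index]
    if missing:
        raise ValidationError(f"genomes without phenotype: {missing}")
    labels = phenotypes.loc[matrix.genome_ids]
    for cls in (MOTILE, NONMOTILE):
        if (labels == cls).sum() == 0:
            raise ValidationError(f"phenotype class {cls!r} has zero members")
    motile_mask = (labels == MOTILE).values
    prev_m = matrix.data.values[motile_mask].mean(axis=0)
    prev_n = matrix.data.values[~motile_mask].mean(axis=0)
    return pd.DataFrame(
        {"prevalence_motile": prev_m, "prevalence_nonmotile": prev_n},
        index=matrix.gene_ids,
    )


def select_panel(
    prevalences: pd.DataFrame,
    criteria: PanelCriteria | None = None,
    candidates: list[str] | None = None,
) -> GenePanel:
    """Apply the dual prevalence rule, preserving input gene order.

    ``candidates`` optionally restricts selection to a candidate pool (e.g.
    the flagellar-assembly gene families); otherwise every gene in
    ``prevalences`` is considered.
    """
    criteria = criteria or PanelCriteria()
    if candidates is not None:
        pool = [g for g in prevalences.index if g in set(candidates)]
    else:
        pool = list(prevalences.index)
    retained = [
        g for g in pool
        if criteria.retains(
            float(prevalences.at[g, "prevalence_motile"]),
            float(prevalences.at[g, "prevalence_nonmotile"]),
        )
    ]
    if not retained:
        logger.warning("panel selection retained no genes")
    return GenePanel(
        gene_ids=retained,
        prevalences=prevalences,
        criteria=criteria,
        candidate_pool_size=len(pool),
    )


def build_panel(
    matrix: GeneContentMatrix,
    phenotypes: pd.Series,
    criteria: PanelCriteria | None = None,
    candidates: list[str] | None = None,
) -> GenePanel:
    """Binarize, compute prevalences and select the panel in one call."""
    binary = binarize(matrix)
    prev = gene_prevalence(binary, phenotypes)
    return select_panel(prev, criteria, candidates)
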