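"""Gene-level collapsing of the adjusted variant matrix.

The gene-based representation is the per-sample sum of adjusted variant
values over all variants mapped to the same gene.  Sums are of signed values
(they can be negative); an absolute-value mode is offered as a flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .stratify import AdjustedMatrix

logger = logging.getLogger(__name__)


@dataclass
class GeneCountMatrix:
    """Samples x genes integer matrix of summed adjusted variant values."""

    sample_ids: list[str]
    gene_ids: list[str]
    values: np.ndarray
    adjusted_phenotype: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.sample_ids), len(self.gene_ids)):
            raise ValueError("values shape inconsistent with sample/gene ids")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.sample_ids, columns=self.gene_ids)
        df.insert(0, "label", self.labels)
        df.insert(0, "adjusted_phenotype", self.adjusted_phenotype)
        df.index.name = "sample_id"
        return df


def gene_counts(
    A: AdjustedMatrix,
    variant_to_gene: Mapping[str, str | list[str]] | None = None,
    on_unmapped: str = "error",
    multi_gene_policy: str = "error",
    absolute: bool = False,
) -> GeneCountMatrix:
    """Sum adjusted variant columns per gene.

    Gene order is lexicographic.  Genes whose column is all-zero are retained
    (and counted in a log line).  ``on_unmapped`` is ``'error'`` or ``'drop'``
    (drop logs a warning).  A variant annotated with several genes raises
    unless ``multi_gene_policy='first'``.
    """
    mapping = variant_to_gene if variant_to_gene is not None else A.variant_to_gene
    if on_unmapped not in ("error", "drop"):
        raise ValueError("on_unmapped must be 'error' or 'drop'")

    genes_per_variant: dict[str, str] = {}
    dropped = []
    for vid in A.feature_ids:
        g = mapping.get(vid)
        if g is None:
            if on_unmapped == "error":
                raise ValueError(f"variant {vid} has no gene mapping")
            dropped.append(vid)
            continue
        if isinstance(g, (list, tuple)):
            if len(g) > 1 and multi_gene_policy != "first":
                raise ValueError(f"variant {vid} maps to multiple genes: {list(g)}")
            g = g[0]
        genes_per_variant[vid] = g
    if dropped:
        logger.warning("dropped %d unmapped variants", len(dropped))

    gene_ids = sorted(set(genes_per_variant.values()))
    gcol = {g: j for j, g in enumerate(gene_ids)}
    X = np.abs(A.values) if absolute else A.values
    values = np.zeros((len(A.sample_ids), len(gene_ids)), dtype=np.int64)
    for i, vid in enumerate(A.feature_ids):
        if vid in genes_per_variant:
            values[:, gcol[genes_per_variant[vid]]] += X[:, i]

    n_zero = int((values == 0).all(axis=0).sum())
    if n_zero:
        logger.info("%d gene columns are all-zero after collapsing", n_zero)

    return GeneCountMatrix(
        sample_ids=list(A.sample_ids),
        gene_ids=gene_ids,
        values=values,
        adjusted_phenotype=np.asarray(A.adjusted_phenotype),
        labels=np.asarray(A.labels),
    )
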