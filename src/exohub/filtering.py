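"""Variant selection rules and assembly of the wide 0/1/2 genotype matrix.

Calls arrive as a long-format table (one row per sample x variant observation,
homozygous-reference calls absent).  Filtering keeps calls that satisfy the
annotation criteria (coding type, functional type, reference-population MAF)
and the per-individual evidence criteria (alt reads, depth, genotype quality).
All thresholds are inclusive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Recognized coding-consequence annotations.  "other" collects everything
#: outside the selected set (synonymous, unknown, ...).
CODING_TYPES = frozenset(
    {
        "frameshift_deletion",
        "frameshift_insertion",
        "frameshift_substitution",
        "nonsynonymous_SNV",
        "stopgain",
        "stoploss",
        "other",
    }
)

FUNCTIONAL_TYPES = frozenset({"exonic", "exonic_splicing", "intronic_splicing", "other"})

DEFAULT_CODING = frozenset(CODING_TYPES - {"other"})
DEFAULT_FUNCTIONAL = frozenset({"exonic", "exonic_splicing", "intronic_splicing"})

#: Documented column order of the long-format call table.
CALL_COLUMNS = [
    "sample_id",
    "variant_id",
    "rsid",
    "gene",
    "coding_type",
    "functional_type",
    "maf",
    "genotype",
    "alt_reads",
    "depth",
    "gq",
]

#: Criteria names used in rejection tallies, in evaluation order.
CRITERIA = ["coding_type", "functional_type", "maf", "alt_reads", "depth", "gq"]


@dataclass(frozen=True)
class FilterThresholds:
    """Inclusive selection thresholds for annotated calls."""

    allowed_coding_types: frozenset[str] = DEFAULT_CODING
    allowed_functional_types: frozenset[str] = DEFAULT_FUNCTIONAL
    max_maf: float = 0.01
    min_alt_reads: int = 4
    min_depth: int = 10
    min_gq: int = 90

    def __post_init__(self) -> None:
        unknown = set(self.allowed_coding_types) - CODING_TYPES
        if unknown:
            raise ValueError(f"unknown coding types in thresholds: {sorted(unknown)}")
        unknown = set(self.allowed_functional_types) - FUNCTIONAL_TYPES
        if unknown:
            raise ValueError(f"unknown functional types in thresholds: {sorted(unknown)}")


@dataclass
class GenotypeMatrix:
    """Samples x variants table in {0,1,2} with labels and a variant->gene map."""

    sample_ids: list[str]
    variant_ids: list[str]
    values: np.ndarray
    labels: np.ndarray
    variant_to_gene: dict[str, str]
    rsids: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.labels = np.asarray(self.labels)
        n, m = self.values.shape
        if n != len(self.sample_ids) or m != len(self.variant_ids):
            raise ValueError("values shape inconsistent with sample/variant ids")
        if len(self.labels) != n:
            raise ValueError("one label per sample required")
        bad = set(np.unique(self.values)) - {0, 1, 2}
        if bad:
            raise ValueError(f"genotype values outside {{0,1,2}}: {sorted(bad)}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.sample_ids, columns=self.variant_ids)
        df.insert(0, "label", self.labels)
        df.index.name = "sample_id"
        return df


def _validate_enums(calls: pd.DataFrame) -> None:
    for col, universe in (("coding_type", CODING_TYPES), ("functional_type", FUNCTIONAL_TYPES)):
        bad = ~calls[col].isin(universe)
        if bad.any():
            row = calls[bad].iloc[0]
            raise ValueError(
                f"unknown {col} {row[col]!r} in record "
                f"(sample={row['sample_id']}, variant={row['variant_id']})"
            )


def _criterion_masks(calls: pd.DataFrame, thresholds: FilterThresholds) -> dict[str, pd.Series]:
    """Boolean pass-mask per criterion (True = passes)."""
    return {
        "coding_type": calls["coding_type"].isin(thresholds.allowed_coding_types),
        "functional_type": calls["functional_type"].isin(thresholds.allowed_functional_types),
        "maf": calls["maf"] <= thresholds.max_maf,
        "alt_reads": calls["alt_reads"] >= thresholds.min_alt_reads,
        "depth": calls["depth"] >= thresholds.min_depth,
        "gq": calls["gq"] >= thresholds.min_gq,
    }


def rejection_counts(
    calls: pd.DataFrame, thresholds: FilterThresholds | None = None
) -> dict[str, int]:
    """Number of calls failing each criterion (a call may count toward several)."""
    thresholds = thresholds or FilterThresholds()
    _validate_enums(calls)
    masks = _criterion_masks(calls, thresholds)
    counts = {name: int((~mask).sum()) for name, mask in masks.items()}
    counts["input"] = len(calls)
    retained = np.logical_and.reduce([m.to_numpy() for m in masks.values()])
    counts["retained"] = int(retained.sum())
    return counts


def filter_calls(
    calls: pd.DataFrame, thresholds: FilterThresholds | None = None
) -> pd.DataFrame:
    """Retain exactly the calls satisfying every (inclusive) criterion.

    Per-criterion rejection counts are emitted to the module logger.
    """
    thresholds = thresholds or FilterThresholds()
    _validate_enums(calls)
    masks = _criterion_masks(calls, thresholds)
    keep = np.logical_and.reduce([m.to_numpy() for m in masks.values()])
    for name, mask in masks.items():
        logger.info("filter criterion %-15s rejected %d calls", name, int((~mask).sum()))
    logger.info("retained %d of %d calls", int(keep.sum()), len(calls))
    return calls.loc[keep].reset_index(drop=True)


def build_genotype_matrix(
    calls: pd.DataFrame,
    all_samples: Sequence[str],
    labels: Mapping[str, str],
) -> GenotypeMatrix:
    """Pivot filtered calls into the wide 0/1/2 matrix.

    One column per variant retained in at least one sample; cells default to 0
    (absent call = homozygous reference).  Sample and variant order are
    lexicographic for determinism; every sample in ``all_samples`` gets a row
    even with zero retained calls.
    """
    missing = set(calls["sample_id"]) - set(all_samples)
    if missing:
        raise ValueError(f"calls reference samples outside the sample universe: {sorted(missing)[:5]}")
    missing_labels = [s for s in all_samples if s not in labels]
    if missing_labels:
        raise ValueError(f"samples without a class label: {missing_labels[:5]}")

    dup = calls.groupby(["sample_id", "variant_id"])["genotype"].nunique()
    conflicts = dup[dup > 1]
    if len(conflicts):
        pair = conflicts.index[0]
        raise ValueError(f"conflicting genotypes for sample={pair[0]} variant={pair[1]}")
    calls = calls.drop_duplicates(subset=["sample_id", "variant_id"])

    sample_ids = sorted(all_samples)
    variant_ids = sorted(calls["variant_id"].unique())
    values = np.zeros((len(sample_ids), len(variant_ids)), dtype=np.int64)
    srow = {s: i for i, s in enumerate(sample_ids)}
    vcol = {v: j for j, v in enumerate(variant_ids)}
    values[
        calls["sample_id"].map(srow).to_numpy(),
        calls["variant_id"].map(vcol).to_numpy(),
    ] = calls["genotype"].to_numpy()

    v2g = dict(
        calls.drop_duplicates("variant_id").set_index("variant_id")["gene"]
    )
    ambiguous = calls.groupby("variant_id")["gene"].nunique()
    if (ambiguous > 1).any():
        vid = ambiguous[ambiguous > 1].index[0]
        raise ValueError(f"variant {vid} maps to multiple genes")
    rsids = dict(calls.drop_duplicates("variant_id").set_index("variant_id")["rsid"]) if "rsid" in calls else {}

    return GenotypeMatrix(
        sample_ids=sample_ids,
        variant_ids=variant_ids,
        values=values,
        labels=np.array([labels[s] for s in sample_ids]),
        variant_to_gene=v2g,
        rsids=rsids,
    )
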