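"""Synthetic two-cohort variant-call generator.

Produces a long-format annotated call table for two labeled cohorts (ASD vs.
SCZ) with:

* planted class-discriminative genes (allele frequency enriched in one class),
* a planted co-mutation "hub" module per class — a subset of that class's
  discriminative genes whose carrier union covers a target share of the
  class's cases, with partially overlapping per-gene carrier sets,
* background noise genes, a subset of whose variants carry ancestry-shifted
  allele frequencies (population structure confounded with class),
* deliberate filter failures: disjoint call subsets each failing exactly one
  selection criterion, so rejection tallies are exactly predictable,

plus a machine-readable truth record for parameter-recovery tests.

Distributional choices here are artifact conventions, not claims about any
real cohort: genotypes are Binomial(2, f) draws, read depth is gamma-Poisson,
and the annotated MAF is an independent reference-population annotation, not
the realized cohort frequency.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .filtering import CALL_COLUMNS

CLASSES = ("ASD", "SCZ")


class ConfigError(ValueError):
    """Raised for infeasible or inconsistent simulation configurations."""


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs for the synthetic cohort. Defaults are the planted default scenario."""

    n_cases_per_class: int = 600
    n_genes_total: int = 600
    n_discriminative_genes_per_class: int = 40
    n_hub_genes_per_class: int = 10
    hub_coverage_target: float = 0.9
    n_noise_genes: int = 520
    variants_per_gene: tuple[int, int] = (2, 4)
    maf_range: tuple[float, float] = (0.0005, 0.01)

    # planted allele frequencies (true cohort frequencies, per class)
    signal_case_freq: float = 0.008
    signal_bg_freq: float = 0.001
    noise_freq: float = 0.003

    # population structure: scores carry a class offset (confounding); the
    # frequency shift per score unit is ancestry_effect (0 = no structure)
    ancestry_axes: int = 4
    ancestry_effect: float = 0.12
    ancestry_class_offset: float = 0.3
    structure_variant_fraction: float = 0.2  # of noise-gene variants
    structure_base_freq: float = 0.15

    # read-support models
    mean_depth: float = 40.0
    depth_dispersion: float = 6.0

    # deliberate filter failures
    fail_coding_fraction: float = 0.04  # of calls: disallowed coding type
    common_variant_fraction: float = 0.05  # of variants: annotated MAF > 0.01
    fail_alt_fraction: float = 0.04  # of calls: alt_reads < 4
    fail_depth_fraction: float = 0.04  # of calls: depth < 10
    fail_gq_fraction: float = 0.05  # of calls: gq < 90

    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_cases_per_class": self.n_cases_per_class,
            "n_genes_total": self.n_genes_total,
            "n_discriminative_genes_per_class": self.n_discriminative_genes_per_class,
            "n_hub_genes_per_class": self.n_hub_genes_per_class,
            "n_noise_genes": self.n_noise_genes,
        }
        for name, value in counts.items():
            if value <= 0:
                raise ConfigError(f"{name} must be positive, got {value}")
        if self.n_hub_genes_per_class > self.n_discriminative_genes_per_class:
            raise ConfigError("hub genes must be a subset of discriminative genes")
        if self.n_hub_genes_per_class < 2:
            raise ConfigError("need >= 2 hub genes per class for overlapping carrier sets")
        if 2 * self.n_discriminative_genes_per_class + self.n_noise_genes != self.n_genes_total:
            raise ConfigError(
                "n_genes_total must equal 2 * n_discriminative_genes_per_class + n_noise_genes"
            )
        if not 0.0 < self.hub_coverage_target <= 1.0:
            raise ConfigError("hub_coverage_target must lie in (0, 1]")
        lo, hi = self.variants_per_gene
        if lo < 1 or hi < lo:
            raise ConfigError("variants_per_gene must be a range with 1 <= lo <= hi")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.01):
            raise ConfigError("maf_range must satisfy 0 < lo <= hi <= 0.01 for signal variants")
        if self.mean_depth < 11:
            raise ConfigError("mean_depth must be at least 11")
        fracs = (
            self.fail_coding_fraction,
            self.common_variant_fraction,
            self.fail_alt_fraction,
            self.fail_depth_fraction,
            self.fail_gq_fraction,
        )
        if any(not 0.0 <= f < 0.5 for f in fracs):
            raise ConfigError("failure fractions must lie in [0, 0.5)")
        if self.ancestry_axes < 1:
            raise ConfigError("ancestry_axes must be >= 1")


@dataclass
class TruthRecord:
    """Ground truth of a simulated cohort, for parameter-recovery tests."""

    sample_ids: list[str]
    class_labels: list[str]
    discriminative_genes: dict[str, list[str]]
    hub_genes: dict[str, list[str]]
    hub_carriers: dict[str, list[str]]
    ancestry_scores: list[list[float]]  # samples x axes
    structure_variants: list[str]
    common_variants: list[str]
    filter_fail_counts: dict[str, int]

    def __post_init__(self) -> None:
        for cls in self.hub_genes:
            if not set(self.hub_genes[cls]) <= set(self.discriminative_genes[cls]):
                raise ValueError(f"hub genes of {cls} not a subset of its discriminative genes")
        if len(self.class_labels) != len(self.sample_ids):
            raise ValueError("one class label per sample required")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthRecord":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class _VariantMeta:
    variant_id: str
    rsid: str
    gene: str
    maf: float
    kind: str  # signal_ASD | signal_SCZ | structure | noise | common
    axis: int = -1
    axis_sign: float = 0.0


_BASES = ("A", "C", "G", "T")


def _make_variants(cfg: SimulationConfig, rng: np.random.Generator) -> list[_VariantMeta]:
    n_disc = cfg.n_discriminative_genes_per_class
    genes = [f"G{i:04d}" for i in range(cfg.n_genes_total)]
    roles: dict[str, str] = {}
    for i, g in enumerate(genes):
        if i < n_disc:
            roles[g] = "disc_ASD"
        elif i < 2 * n_disc:
            roles[g] = "disc_SCZ"
        else:
            roles[g] = "noise"

    variants: list[_VariantMeta] = []
    pos = 1000
    for gi, g in enumerate(genes):
        nv = int(rng.integers(cfg.variants_per_gene[0], cfg.variants_per_gene[1] + 1))
        chrom = (gi % 22) + 1
        for _ in range(nv):
            pos += int(rng.integers(500, 5000))
            ref, alt = rng.choice(len(_BASES), size=2, replace=False)
            vid = f"{chrom}:{pos}:{_BASES[ref]}:{_BASES[alt]}"
            rsid = f"rs{int(rng.integers(10**6, 10**8))}"
            kind = {"disc_ASD": "signal_ASD", "disc_SCZ": "signal_SCZ", "noise": "noise"}[roles[g]]
            variants.append(_VariantMeta(vid, rsid, g, 0.0, kind))

    # annotated MAF: signal-range annotation everywhere, overwritten for the
    # common-variant subset below
    for v in variants:
        v.maf = float(rng.uniform(*cfg.maf_range))

    noise_idx = [i for i, v in enumerate(variants) if v.kind == "noise"]
    n_common = int(round(cfg.common_variant_fraction * len(variants)))
    if n_common > len(noise_idx):
        raise ConfigError("not enough noise-gene variants to host the common-variant fraction")
    common_pick = rng.choice(noise_idx, size=n_common, replace=False) if n_common else np.array([], int)
    for i in common_pick:
        variants[i].kind = "common"
        variants[i].maf = float(rng.uniform(0.02, 0.2))

    remaining = [i for i in noise_idx if variants[i].kind == "noise"]
    n_struct = int(round(cfg.structure_variant_fraction * len(noise_idx)))
    if n_struct > len(remaining):
        raise ConfigError("structure_variant_fraction too large after common-variant allocation")
    struct_pick = rng.choice(remaining, size=n_struct, replace=False) if n_struct else np.array([], int)
    for i in struct_pick:
        v = variants[i]
        v.kind = "structure"
        v.axis = int(rng.integers(cfg.ancestry_axes))
        v.axis_sign = float(rng.choice([-1.0, 1.0]))
    return variants


def simulate_cohorts(config: SimulationConfig) -> tuple[pd.DataFrame, TruthRecord]:
    """Generate the annotated call table and its truth record.

    Returns a DataFrame with the documented :data:`~exohub.filtering.CALL_COLUMNS`
    order, sorted by (sample_id, variant_id); only carrier calls (genotype > 0)
    are emitted.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_cases_per_class

    sample_ids = [f"ASD_{i:04d}" for i in range(n)] + [f"SCZ_{i:04d}" for i in range(n)]
    labels = ["ASD"] * n + ["SCZ"] * n
    is_asd = np.array([lab == "ASD" for lab in labels])

    # ancestry scores: axis-wise class offsets decaying with axis index
    offsets = cfg.ancestry_class_offset * 0.5 ** np.arange(cfg.ancestry_axes)
    scores = rng.standard_normal((2 * n, cfg.ancestry_axes))
    scores += np.where(is_asd[:, None], offsets[None, :], -offsets[None, :])

    variants = _make_variants(cfg, rng)
    n_samples = 2 * n

    # per-variant, per-sample allele frequency
    geno = np.zeros((n_samples, len(variants)), dtype=np.int64)
    for j, v in enumerate(variants):
        if v.kind == "signal_ASD":
            f = np.where(is_asd, cfg.signal_case_freq, cfg.signal_bg_freq)
        elif v.kind == "signal_SCZ":
            f = np.where(is_asd, cfg.signal_bg_freq, cfg.signal_case_freq)
        elif v.kind == "structure":
            f = cfg.structure_base_freq + cfg.ancestry_effect * v.axis_sign * scores[:, v.axis]
            f = np.clip(f, 0.01, 0.99)
        elif v.kind == "common":
            f = np.full(n_samples, float(rng.uniform(0.05, 0.2)))
        else:
            f = np.full(n_samples, cfg.noise_freq)
        geno[:, j] = rng.binomial(2, f)

    # plant hub carriers: each carrier gets het calls in two distinct hub genes
    by_gene: dict[str, list[int]] = {}
    for j, v in enumerate(variants):
        by_gene.setdefault(v.gene, []).append(j)
    gene_names = [f"G{i:04d}" for i in range(cfg.n_genes_total)]
    n_disc = cfg.n_discriminative_genes_per_class
    disc = {"ASD": gene_names[:n_disc], "SCZ": gene_names[n_disc : 2 * n_disc]}
    hubs = {cls: disc[cls][: cfg.n_hub_genes_per_class] for cls in CLASSES}

    hub_carriers: dict[str, list[str]] = {}
    planted_cells: set[tuple[int, int]] = set()
    for cls in CLASSES:
        class_rows = np.flatnonzero(is_asd if cls == "ASD" else ~is_asd)
        n_carriers = int(round(cfg.hub_coverage_target * n))
        carriers = rng.choice(class_rows, size=n_carriers, replace=False)
        hub_carriers[cls] = sorted(sample_ids[i] for i in carriers)
        for row in carriers:
            for g in rng.choice(hubs[cls], size=2, replace=False):
                col = int(rng.choice(by_gene[g]))
                if geno[row, col] == 0:
                    geno[row, col] = 1
                planted_cells.add((int(row), col))

    # assemble carrier calls
    rows, cols = np.nonzero(geno)
    n_calls = len(rows)
    gt = geno[rows, cols]

    lam = rng.gamma(cfg.depth_dispersion, (cfg.mean_depth - 10.0) / cfg.depth_dispersion, n_calls)
    depth = 10 + rng.poisson(lam)
    p_alt = np.where(gt == 1, 0.5, 0.95)
    alt = np.clip(rng.binomial(depth, p_alt), 4, depth)
    gq = rng.integers(90, 100, n_calls)

    # annotation consequences are a per-variant property (they live in VCF
    # INFO); the coding-type failure is therefore planted per variant, on
    # noise variants first, spilling into unplanted signal variants if needed
    variant_coding = rng.choice(
        np.array(["nonsynonymous_SNV", "frameshift_deletion", "frameshift_insertion",
                  "frameshift_substitution", "stopgain", "stoploss"]),
        size=len(variants),
        p=[0.70, 0.08, 0.08, 0.04, 0.06, 0.04],
    )
    variant_functional = rng.choice(
        np.array(["exonic", "exonic_splicing", "intronic_splicing"]),
        size=len(variants),
        p=[0.90, 0.05, 0.05],
    )

    kinds = np.array([variants[c].kind for c in cols])
    planted_mask = np.fromiter(
        ((int(r), int(c)) in planted_cells for r, c in zip(rows, cols)), bool, n_calls
    )
    planted_variants = {c for _, c in planted_cells}
    calls_per_variant = np.bincount(cols, minlength=len(variants))

    coding_target = int(round(cfg.fail_coding_fraction * n_calls))
    pool = [
        j for j, v in enumerate(variants)
        if v.kind == "noise" and j not in planted_variants and calls_per_variant[j] > 0
    ]
    spill = [
        j for j, v in enumerate(variants)
        if v.kind in ("signal_ASD", "signal_SCZ")
        and j not in planted_variants and calls_per_variant[j] > 0
    ]
    rng.shuffle(pool)
    rng.shuffle(spill)
    n_coding_fails = 0
    bad_coding_variants: set[int] = set()
    for j in pool + spill:
        if n_coding_fails >= coding_target:
            break
        bad_coding_variants.add(j)
        n_coding_fails += int(calls_per_variant[j])
    if n_coding_fails < coding_target:
        raise ConfigError("fail_coding_fraction exceeds the pool of sabotagable variants")
    for j in bad_coding_variants:
        variant_coding[j] = "other"

    coding = variant_coding[cols]
    functional = variant_functional[cols]

    # per-call evidence failures are mutually exclusive and exempt planted hub
    # calls, common variants, and coding-failed variants, so tallies stay exact
    coding_bad_mask = np.isin(cols, list(bad_coding_variants))
    eligible = np.flatnonzero((kinds != "common") & ~planted_mask & ~coding_bad_mask)
    sizes = {
        "alt_reads": int(round(cfg.fail_alt_fraction * n_calls)),
        "depth": int(round(cfg.fail_depth_fraction * n_calls)),
        "gq": int(round(cfg.fail_gq_fraction * n_calls)),
    }
    total_bad = sum(sizes.values())
    if total_bad > len(eligible):
        raise ConfigError("failure fractions exceed the pool of sabotagable calls")
    picked = rng.choice(eligible, size=total_bad, replace=False)
    off = 0
    sab: dict[str, np.ndarray] = {}
    for name, size in sizes.items():
        sab[name] = picked[off : off + size]
        off += size

    alt[sab["alt_reads"]] = rng.integers(1, 4, len(sab["alt_reads"]))
    depth[sab["depth"]] = rng.integers(4, 10, len(sab["depth"]))
    alt[sab["depth"]] = rng.integers(4, depth[sab["depth"]] + 1)
    gq[sab["gq"]] = rng.integers(20, 90, len(sab["gq"]))

    fail_counts = {
        "coding_type": n_coding_fails,
        "functional_type": 0,
        "maf": int((kinds == "common").sum()),
        "alt_reads": sizes["alt_reads"],
        "depth": sizes["depth"],
        "gq": sizes["gq"],
    }

    calls = pd.DataFrame(
        {
            "sample_id": [sample_ids[r] for r in rows],
            "variant_id": [variants[c].variant_id for c in cols],
            "rsid": [variants[c].rsid for c in cols],
            "gene": [variants[c].gene for c in cols],
            "coding_type": coding,
            "functional_type": functional,
            "maf": np.round([variants[c].maf for c in cols], 6),
            "genotype": gt,
            "alt_reads": alt,
            "depth": depth,
            "gq": gq,
        }
    )[CALL_COLUMNS]
    calls = calls.sort_values(["sample_id", "variant_id"], kind="mergesort").reset_index(drop=True)

    truth = TruthRecord(
        sample_ids=sample_ids,
        class_labels=labels,
        discriminative_genes={cls: list(disc[cls]) for cls in CLASSES},
        hub_genes={cls: list(hubs[cls]) for cls in CLASSES},
        hub_carriers=hub_carriers,
        ancestry_scores=scores.round(8).tolist(),
        structure_variants=sorted(v.variant_id for v in variants if v.kind == "structure"),
        common_variants=sorted(v.variant_id for v in variants if v.kind == "common"),
        filter_fail_counts=fail_counts,
    )
    return calls, truth
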