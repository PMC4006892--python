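"""Synthetic two-condition expression data with known ground truth.

Emulates a two-group (siRNA-treated vs scramble control) Illumina-style
expression experiment: per-probe log2 baselines, additive Gaussian
measurement noise, a subset of genes spiked at stated fold changes in the
treated group, a fraction of probes hard-shifted below the detection floor,
gene-set collections in which enriched sets concentrate true-DE genes, and
qPCR Ct tables with a group-independent reference gene. Every simulated
entity (probe, gene, gene set, qPCR target) has exactly one ground-truth
record, so downstream stages can be validated against known answers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, GeneSet, GroundTruth
from .errors import ConfigError

DEFAULT_PROBES_PER_GENE = {1: 0.5, 2: 0.3, 3: 0.2}


@dataclass
class SimulationConfig:
    """Generator settings.

    Defaults emulate a small two-arm knockdown array experiment: three
    replicates per condition, log2 baselines around 8 (sd 1.5), measurement
    noise sd 0.3 on the log2 scale, 10% of genes differentially expressed at
    1.2-2.0x, 1-3 probes per gene, and 5% of probes sitting below the
    detection floor.
    """

    n_genes: int = 500
    n_probes: int | None = None  # None: derive from probes_per_gene draws
    probes_per_gene: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_PROBES_PER_GENE)
    )
    n_per_group: int = 3
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    noise_sd: float = 0.3
    de_fraction: float = 0.1
    de_fold_changes: tuple[float, ...] = (1.2, 1.5, 2.0)
    de_down_fraction: float = 0.5
    undetected_fraction: float = 0.05
    detection_floor: float = 5.0
    n_gene_sets: int = 50
    set_size_range: tuple[int, int] = (10, 40)
    enriched_set_ids: tuple[str, ...] = ()
    enriched_de_fraction: float = 0.8
    group_names: tuple[str, str] = ("scramble", "sirna")  # (control, treated)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ConfigError(f"n_genes must be >= 1, got {self.n_genes}")
        if self.n_per_group < 2:
            raise ConfigError(
                f"n_per_group must be >= 2 (within-group scatter is required), got {self.n_per_group}"
            )
        if self.n_probes is not None and self.n_probes < self.n_genes:
            raise ConfigError(
                f"n_probes ({self.n_probes}) must be >= n_genes ({self.n_genes})"
            )
        if any(f <= 0 for f in self.de_fold_changes):
            raise ConfigError(f"de_fold_changes must be positive, got {self.de_fold_changes}")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ConfigError(f"de_fraction must lie in [0, 1], got {self.de_fraction}")
        if not 0.0 <= self.undetected_fraction < 1.0:
            raise ConfigError(
                f"undetected_fraction must lie in [0, 1), got {self.undetected_fraction}"
            )
        lo, hi = self.set_size_range
        if not 1 <= lo <= hi:
            raise ConfigError(f"set_size_range must satisfy 1 <= lo <= hi, got {self.set_size_range}")
        if hi > self.n_genes:
            raise ConfigError(
                f"set_size_range upper bound {hi} exceeds n_genes {self.n_genes}"
            )
        if any(p < 0 for p in self.probes_per_gene.values()) or sum(self.probes_per_gene.values()) <= 0:
            raise ConfigError("probes_per_gene must be a distribution with positive mass")

    def with_(self, **changes) -> "SimulationConfig":
        return replace(self, **changes)


def _stage_rng(seed: int, stage: int) -> np.random.Generator:
    """Independent stream per stage, all derived from the one root seed."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), stage]))


def _gene_ids(n: int) -> list[str]:
    return [f"GENE{i:05d}" for i in range(1, n + 1)]


def simulate_expression(config: SimulationConfig) -> tuple[ExpressionMatrix, GroundTruth]:
    """Generate a probes x samples log2 matrix and its ground truth.

    Differentially expressed genes get a group-mean log2 shift of exactly
    log2(fold) before noise; undetected probes (drawn from non-DE genes) sit
    entirely below the detection floor.
    """
    rng = _stage_rng(config.seed, 0)
    genes = _gene_ids(config.n_genes)

    # probe multiplicity per gene
    if config.n_probes is None:
        mult_values = np.array(sorted(config.probes_per_gene), dtype=int)
        weights = np.array([config.probes_per_gene[m] for m in mult_values], dtype=float)
        weights /= weights.sum()
        multiplicity = rng.choice(mult_values, size=config.n_genes, p=weights)
    else:
        multiplicity = np.ones(config.n_genes, dtype=int)
        extra = rng.choice(config.n_genes, size=config.n_probes - config.n_genes)
        np.add.at(multiplicity, extra, 1)
    probe_gene = np.repeat(np.arange(config.n_genes), multiplicity)
    n_probes = probe_gene.size
    probe_ids = [f"P{i:06d}" for i in range(1, n_probes + 1)]
    gene_of_probe = pd.Series([genes[g] for g in probe_gene], index=probe_ids, name="gene")

    # gene-level differential expression
    n_de = int(round(config.de_fraction * config.n_genes))
    de_genes = rng.choice(config.n_genes, size=n_de, replace=False) if n_de else np.array([], dtype=int)
    gene_log2fold = np.zeros(config.n_genes)
    if n_de:
        folds = rng.choice(np.asarray(config.de_fold_changes, dtype=float), size=n_de)
        down = rng.random(n_de) < config.de_down_fraction
        gene_log2fold[de_genes] = np.where(down, -np.log2(folds), np.log2(folds))
    gene_de = gene_log2fold != 0.0

    # sample layout: control block then treated block
    control, treated = config.group_names
    samples = [f"{control}_{i}" for i in range(1, config.n_per_group + 1)] + [
        f"{treated}_{i}" for i in range(1, config.n_per_group + 1)
    ]
    groups = pd.Series(
        [control] * config.n_per_group + [treated] * config.n_per_group,
        index=samples, name="group",
    )

    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=n_probes)
    effect = gene_log2fold[probe_gene]
    X = baseline[:, None] + rng.normal(0.0, config.noise_sd, size=(n_probes, 2 * config.n_per_group))
    X[:, config.n_per_group:] += effect[:, None]

    # hard-shift a fraction of non-DE-gene probes below the detection floor
    probe_log2fold = effect.copy()
    eligible = np.flatnonzero(~gene_de[probe_gene])
    n_undet = min(int(round(config.undetected_fraction * n_probes)), eligible.size)
    if n_undet:
        undet = rng.choice(eligible, size=n_undet, replace=False)
        X[undet] = config.detection_floor - rng.uniform(
            0.3, 1.5, size=(n_undet, 2 * config.n_per_group)
        )
        probe_log2fold[undet] = 0.0

    matrix = ExpressionMatrix(
        values=pd.DataFrame(X, index=probe_ids, columns=samples),
        genes=gene_of_probe,
        groups=groups,
    )
    truth = GroundTruth(
        probe_fold=pd.Series(np.exp2(probe_log2fold), index=probe_ids, name="true_fold"),
        probe_de=pd.Series(probe_log2fold != 0.0, index=probe_ids, name="true_de"),
        gene_fold=pd.Series(np.exp2(gene_log2fold), index=genes, name="true_fold"),
        gene_de=pd.Series(gene_de, index=genes, name="true_de"),
    )
    return matrix, truth


def simulate_gene_sets(config: SimulationConfig, truth: GroundTruth) -> tuple[list[GeneSet], GroundTruth]:
    """Generate a gene-set collection and record per-set enrichment truth.

    Sets named in ``enriched_set_ids`` draw ``enriched_de_fraction`` of their
    members from true-DE genes; all other sets draw members uniformly from
    all genes. Returns the collection and the truth updated in place.
    """
    rng = _stage_rng(config.seed, 1)
    genes = np.asarray(truth.gene_de.index)
    de_genes = genes[truth.gene_de.to_numpy(bool)]
    non_de = genes[~truth.gene_de.to_numpy(bool)]
    names = [f"SET{i:03d}" for i in range(1, config.n_gene_sets + 1)]
    unknown = set(config.enriched_set_ids) - set(names)
    if unknown:
        raise ConfigError(f"enriched_set_ids not among generated set names: {sorted(unknown)}")
    lo, hi = config.set_size_range
    sets: list[GeneSet] = []
    enriched_flags = {}
    for name in names:
        size = int(rng.integers(lo, hi + 1))
        enriched = name in config.enriched_set_ids
        if enriched:
            n_from_de = min(int(round(config.enriched_de_fraction * size)), de_genes.size)
            if n_from_de == 0:
                raise ConfigError(
                    f"enriched set {name} requested but no true-DE genes exist "
                    "(de_fraction too small)"
                )
            members = list(rng.choice(de_genes, size=n_from_de, replace=False))
            pool = non_de if non_de.size >= size - n_from_de else genes
            members += list(rng.choice(pool, size=size - n_from_de, replace=False))
        else:
            members = list(rng.choice(genes, size=size, replace=False))
        sets.append(GeneSet(name=name, members=tuple(members), description="synthetic"))
        enriched_flags[name] = enriched
    truth.set_enriched = pd.Series(enriched_flags, name="true_enriched")
    return sets, truth


def simulate_qpcr(
    targets: list[str],
    true_rq: dict[str, float] | float,
    n: int = 3,
    ct_sd: float = 0.2,
    seed: int = 0,
    reference: str = "GAPDH",
    group_names: tuple[str, str] = ("control", "treated"),
    reference_ct: float = 18.0,
    target_ct: float = 26.0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate a long-format qPCR Ct table with known relative quantities.

    The reference gene's Ct is group-independent; each target's Ct in the
    treated group is offset by -log2(true_rq), so perfect-doubling ddCt
    quantification recovers true_rq exactly when ct_sd = 0.
    """
    if n < 2:
        raise ConfigError(f"need n >= 2 replicates per group, got {n}")
    if not isinstance(true_rq, dict):
        true_rq = {t: float(true_rq) for t in targets}
    for t in targets:
        if t not in true_rq:
            raise ConfigError(f"true_rq missing target {t!r}")
        if not true_rq[t] > 0:
            raise ConfigError(f"true_rq must be positive, got {true_rq[t]} for {t!r}")
    rng = _stage_rng(seed, 2)
    control, treated = group_names
    rows = []
    for group in (control, treated):
        for i in range(1, n + 1):
            sample = f"{group}_{i}"
            rows.append((sample, group, reference, reference_ct + rng.normal(0.0, ct_sd)))
            for t in targets:
                ct = target_ct + rng.normal(0.0, ct_sd)
                if group == treated:
                    ct -= np.log2(true_rq[t])
                rows.append((sample, group, t, ct))
    table = pd.DataFrame(rows, columns=["sample_id", "group", "target", "ct"])
    truth = GroundTruth(
        probe_fold=pd.Series(dtype=float),
        probe_de=pd.Series(dtype=bool),
        gene_fold=pd.Series(dtype=float),
        gene_de=pd.Series(dtype=bool),
        target_rq=pd.Series(true_rq, name="true_rq"),
    )
    return table, truth
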