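"""End-to-end orchestration: simulate/load -> normalize -> detect -> SAM ->
collapse -> enrich (and qPCR), with a provenance manifest.

All randomness flows from one root seed, split per stage, so a fixed config
yields byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io
from .containers import ExpressionMatrix, GeneSet, GroundTruth
from .differential import SamConfig, differential_table, filter_de
from .enrichment import RankedGeneList, collapse_probes, enrich_collection, enrichment_frame
from .errors import ConfigError
from .preprocess import detect_probes, quantile_normalize, suggest_threshold
from .simulate import SimulationConfig, simulate_expression, simulate_gene_sets

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All stage parameters; defaults are the pipeline's standard settings
    (s0 percentile 75, >=1.2-fold with p <= 0.05, report at adjusted p <= 0.01)."""

    simulation: SimulationConfig | None = None  # simulate when set
    expression_path: str | None = None
    groups_path: str | None = None
    gmt_path: str | None = None
    log2_transform: bool = False  # apply log2(x+1) to raw-scale inputs
    detect_threshold: float | None = None  # explicit; None -> percentile rule
    detect_percentile: float = 20.0
    filter_before_normalization: bool = False
    s0_percentile: float = 75.0
    n_permutations: int | str = 1000
    min_fold: float = 1.2
    max_p: float = 0.05
    alpha: float = 0.01
    enrichment_variant: str = "top"  # or "literal"
    seed: int = 0

    def config_hash(self) -> str:
        payload = asdict(self)
        if self.simulation is not None:
            payload["simulation"] = asdict(self.simulation)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class PipelineResult:
    """Bundle of all stage outputs plus the run manifest."""

    normalized: ExpressionMatrix
    detected: ExpressionMatrix
    threshold: float
    de_table: pd.DataFrame
    de_filtered: pd.DataFrame
    ranked: RankedGeneList
    enrichment: pd.DataFrame
    manifest: dict
    truth: GroundTruth | None = None
    gene_sets: list[GeneSet] = field(default_factory=list)


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> PipelineResult:
    """Run the full analysis chain; optionally write all outputs to ``outdir``.

    Stage failures propagate wrapped with the stage name.
    """
    stages: list[tuple[str, dict]] = []
    truth = None
    gene_sets: list[GeneSet]
    try:
        if config.simulation is not None:
            sim = config.simulation
            matrix, truth = simulate_expression(sim)
            gene_sets, truth = simulate_gene_sets(sim, truth)
            stages.append(("simulate", {"n_probes": matrix.n_probes,
                                        "n_genes": sim.n_genes,
                                        "n_gene_sets": len(gene_sets)}))
        else:
            if not (config.expression_path and config.groups_path and config.gmt_path):
                raise ConfigError(
                    "either simulation or expression_path+groups_path+gmt_path must be set"
                )
            matrix = io.read_expression(config.expression_path, config.groups_path)
            gene_sets = io.read_gmt(config.gmt_path)
            stages.append(("load", {"n_probes": matrix.n_probes,
                                    "n_gene_sets": len(gene_sets)}))
        if config.log2_transform:
            matrix = ExpressionMatrix(
                values=np.log2(matrix.values + 1.0), genes=matrix.genes, groups=matrix.groups
            )
    except Exception as err:
        raise type(err)(f"[stage input] {err}") from err

    def _stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as err:
            raise type(err)(f"[stage {name}] {err}") from err

    def _detect(m):
        thr = (config.detect_threshold if config.detect_threshold is not None
               else suggest_threshold(m, config.detect_percentile))
        return thr, detect_probes(m, thr)

    if config.filter_before_normalization:
        threshold, det = _stage("detect", _detect, matrix)
        normalized = _stage("normalize", quantile_normalize, det.matrix)
        detected = normalized
    else:
        normalized = _stage("normalize", quantile_normalize, matrix)
        threshold, det = _stage("detect", _detect, normalized)
        detected = det.matrix
    stages.append(("normalize+detect", {"threshold": threshold,
                                        "probes_in": matrix.n_probes,
                                        "probes_detected": detected.n_probes}))

    sam_cfg = SamConfig(
        s0_percentile=config.s0_percentile,
        n_permutations=config.n_permutations,
        seed=int(np.random.SeedSequence([config.seed, 10]).generate_state(1)[0] % (2**31)),
    )
    de_table = _stage("differential", differential_table, detected, sam_cfg)
    de_filtered = _stage("filter", filter_de, de_table, config.min_fold, config.max_p)
    stages.append(("differential", {"s0": de_table.attrs.get("s0"),
                                    "probes_tested": len(de_table),
                                    "probes_passing_filter": len(de_filtered)}))

    ranked = _stage("collapse", collapse_probes, de_table)
    results = _stage("enrich", enrich_collection, ranked, gene_sets,
                     config.alpha, config.enrichment_variant)
    enrichment = enrichment_frame(results)
    stages.append(("enrichment", {"genes_ranked": ranked.n_genes,
                                  "sets_tested": int(enrichment["testable"].sum()),
                                  "sets_reported": int(enrichment["reported"].sum())}))

    manifest = {
        "tool": "mhgpipe",
        "version": __version__,
        "config_hash": config.config_hash(),
        "parameters": {
            "detect_threshold": threshold,
            "detect_percentile": config.detect_percentile,
            "filter_before_normalization": config.filter_before_normalization,
            "s0_percentile": config.s0_percentile,
            "n_permutations": config.n_permutations,
            "min_fold": config.min_fold,
            "max_p": config.max_p,
            "alpha": config.alpha,
            "enrichment_variant": config.enrichment_variant,
            "seed": config.seed,
        },
        "stages": [{"stage": name, **info} for name, info in stages],
    }
    result = PipelineResult(
        normalized=normalized, detected=detected, threshold=threshold,
        de_table=de_table, de_filtered=de_filtered, ranked=ranked,
        enrichment=enrichment, manifest=manifest, truth=truth, gene_sets=gene_sets,
    )
    if outdir is not None:
        write_bundle(result, outdir)
    return result


def write_bundle(result: PipelineResult, outdir: str | Path) -> None:
    """Write every stage output as TSV plus a JSON manifest; each file carries
    the provenance block."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    prov = {"tool": f"mhgpipe {__version__}",
            "config_hash": result.manifest["config_hash"]}
    io.write_expression(result.normalized, outdir / "normalized.tsv",
                        outdir / "groups.tsv", provenance=prov)
    io.write_table(result.de_table, outdir / "differential.tsv", provenance=prov)
    io.write_table(result.de_filtered, outdir / "differential_filtered.tsv", provenance=prov)
    io.write_table(result.ranked.ranks.rename("rank").rename_axis("gene").to_frame(),
                   outdir / "ranked_genes.tsv", provenance=prov)
    io.write_table(result.enrichment, outdir / "enrichment.tsv", provenance=prov)
    if result.gene_sets:
        io.write_gmt(result.gene_sets, outdir / "gene_sets.gmt")
    if result.truth is not None:
        io.write_table(result.truth.to_frame(), outdir / "ground_truth.tsv",
                       provenance=prov, index=False)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
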