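"""Generate the synthetic knockdown experiment used by the downstream steps.

Emulates a two-arm siRNA-vs-scramble array experiment (3 replicates per arm):
500 genes on 1-3 probes each, 10% of genes shifted 1.2-2.0x, one gene set
(SET001) spiked with true-DE genes, 5% of probes below the detection floor,
plus a noise-free qPCR plate with a 50% knockdown target. Writes all pipeline
inputs and the ground truth under results/experiment/.
"""

from pathlib import Path

from mhgpipe import io
from mhgpipe.simulate import SimulationConfig, simulate_expression, simulate_gene_sets, simulate_qpcr

SEED = 42
OUT = Path(__file__).resolve().parents[1] / "results" / "experiment"


def main() -> None:
    cfg = SimulationConfig(seed=SEED, enriched_set_ids=("SET001",))
    matrix, truth = simulate_expression(cfg)
    sets, truth = simulate_gene_sets(cfg, truth)
    qpcr, qpcr_truth = simulate_qpcr(["HOTAIR"], {"HOTAIR": 0.5}, n=3, ct_sd=0.0, seed=SEED)
    truth.target_rq = qpcr_truth.target_rq

    OUT.mkdir(parents=True, exist_ok=True)
    io.write_expression(matrix, OUT / "expression.tsv", OUT / "groups.tsv")
    io.write_gmt(sets, OUT / "gene_sets.gmt")
    io.write_qpcr(qpcr, OUT / "qpcr.tsv")
    io.write_table(truth.to_frame(), OUT / "ground_truth.tsv", index=False)

    n_de = int(truth.gene_de.sum())
    print(f"simulated {matrix.n_probes} probes / {cfg.n_genes} genes "
          f"x {matrix.n_samples} samples (seed {SEED})")
    print(f"  {n_de} genes truly differential; spiked set: SET001")
    print(f"  {len(sets)} gene sets; qPCR target HOTAIR at true RQ 0.5")
    print(f"wrote inputs to {OUT}")


if __name__ == "__main__":
    main()
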