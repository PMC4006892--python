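"""Quantify the qPCR plate by the comparative-Ct method.

Computes per-target ddCt against the GAPDH endogenous control, RQ = 2^-ddCt,
RQ-scale SEM per group, a Student t-test on per-sample dCt, and the
percent/fold rendering of the change.
"""

from pathlib import Path

from mhgpipe import io
from mhgpipe.qpcr import quantify_all

BASE = Path(__file__).resolve().parents[1] / "results" / "experiment"


def main() -> None:
    table = io.read_qpcr(BASE / "qpcr.tsv")
    result = quantify_all(table, reference="GAPDH")
    io.write_table(result, BASE / "qpcr_quantified.tsv")
    for target, row in result.iterrows():
        print(f"{target}: ddCt={row.ddct:.3f}, RQ={row.rq:.4g} "
              f"({row.change_text}), p={row.p:.3g}")
    print(f"wrote {BASE / 'qpcr_quantified.tsv'}")


if __name__ == "__main__":
    main()
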