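"""Re-derive the published shared-gene meta-analysis table.

Feeds the printed per-trait gene p-values and published GWAS sample sizes
through the package's probit + sqrt(N)-weighted Stouffer combination and
compares with the published meta p-values, then checks every row against
the novel-pleiotropic-gene predicate.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
import common

from pairmeta.worked_example import TABLE1, TRAIT_N, reproduce_meta


def main() -> None:
    alpha_gene = 2.7e-6
    rows = []
    for r in TABLE1:
        p_meta = reproduce_meta(r)
        retained = (
            r.p_meta_published < alpha_gene
            and r.p_sz < 0.05 and r.p_sud < 0.05
            and r.p_sz >= alpha_gene and r.p_sud >= alpha_gene
        )
        rows.append({
            "gene": r.gene, "pair": f"SZ+{r.partner}",
            "p_sz": r.p_sz, "p_sud": r.p_sud,
            "p_meta_published": r.p_meta_published,
            "p_meta_recomputed": p_meta,
            "rel_diff": p_meta / r.p_meta_published - 1,
            "novel_pleiotropic": retained,
        })
        print(f"{r.gene:8s} SZ+{r.partner:3s} published {r.p_meta_published:.2e}"
              f"  recomputed {p_meta:.3e}  ({rows[-1]['rel_diff']:+.1%})"
              f"  retained={retained}")
    out = common.RESULTS / "worked_example.tsv"
    out.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(out, sep="\t", index=False,
                              float_format="%.6g")
    print(f"wrote {out}; sample sizes used: "
          + ", ".join(f"{k}={v:,}" for k, v in TRAIT_N.items()))


if __name__ == "__main__":
    main()
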