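"""Pairwise gene-level meta-analysis and the novel-pleiotropic-gene filter.

For each anchor/partner pair: sqrt(N)-weighted Stouffer and Cauchy
combination of the per-gene probit Z-scores, Pearson concordance of the two
methods' -log10 p-values, the novel-signal filter (meta-Bonferroni AND
nominal in both traits AND sub-Bonferroni in both), and the cross-pair
recurrence table.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
import common

from pairmeta import meta as meta_mod
from pairmeta.genes import GeneResult


def load_gene_run(label):
    df = pd.read_csv(common.gene_results_path(label), sep="\t")
    import math

    return {
        r.gene_id: GeneResult(gene_id=r.gene_id, n_snps=r.n_snps,
                              stat=r.stat, p=r.p, log_p=math.log(r.p),
                              z=r.z)
        for r in df.itertuples(index=False)
    }


def main() -> None:
    out = common.RESULTS / "meta"
    out.mkdir(parents=True, exist_ok=True)
    alpha_gene = 0.05 / common.N_BLOCKS
    reports = {}
    for partner, spec in common.PARTNERS.items():
        anchor_run = load_gene_run(f"{common.ANCHOR}__{partner}")
        partner_run = load_gene_run(partner)
        metas = {}
        for method in ("stouffer", "cauchy"):
            metas[method] = meta_mod.combine_gene_tables(
                anchor_run, partner_run, common.N_ANCHOR, spec["n"],
                method=method,
            )
            pd.DataFrame(
                {
                    "gene_id": [m.gene_id for m in metas[method]],
                    "z_meta": [m.z_meta for m in metas[method]],
                    "p_meta": [m.p_meta for m in metas[method]],
                }
            ).to_csv(out / f"{partner}_{method}.tsv", sep="\t", index=False,
                     float_format="%.10g")
        r, lo, hi = meta_mod.method_concordance(
            [m.p_meta for m in metas["stouffer"]],
            [m.p_meta for m in metas["cauchy"]],
        )
        report = meta_mod.novel_signal_filter(
            anchor_run, partner_run, metas["stouffer"],
            alpha_gene=alpha_gene, nominal=0.05,
        )
        report.to_csv(out / f"{partner}_novel.tsv", sep="\t", index=False,
                      float_format="%.10g")
        reports[partner] = report
        n_meta_sig = int((report["p_meta"] < alpha_gene).sum())
        print(f"{common.ANCHOR}+{partner}: {n_meta_sig} meta-Bonferroni "
              f"genes, {int(report['retained'].sum())} novel pleiotropic; "
              f"Stouffer/Cauchy concordance r={r:.4f} "
              f"[{lo:.4f}, {hi:.4f}]")
    rec = meta_mod.count_recurrence(reports)
    rec.to_csv(out / "recurrence.tsv", sep="\t", index=False)
    n_multi = int((rec["n_pairs"] > 1).sum()) if len(rec) else 0
    print(f"{n_multi} novel genes recur in more than one pair")


if __name__ == "__main__":
    main()
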