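"""Genetic correlation (LD score regression) and causality (LCV) per pair.

Estimates per-trait SNP heritability, cross-trait rg with the sample-overlap
intercept, and — for pairs whose rg survives Bonferroni correction over the
pairs tested — the posterior-mean genetic causality proportion.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
import common

from pairmeta import io
from pairmeta.lcv import MIN_ABS_RG, run_lcv
from pairmeta.ldsc import estimate_rg


def main() -> None:
    _, ldscores = common.ld_panel()
    rows = []
    threshold = common.RG_ALPHA / common.N_RG_TESTS
    for partner, spec in common.PARTNERS.items():
        ss_a = io.read_sumstats(
            common.sumstats_path(f"{common.ANCHOR}__{partner}")
        )
        ss_p = io.read_sumstats(common.sumstats_path(partner))
        est = estimate_rg(ss_a, ss_p, ldscores)
        row = {
            "pair": f"{common.ANCHOR}+{partner}",
            "rg_truth": spec["rg"],
            "rg": est.rg,
            "rg_se": est.se,
            "rg_p": est.p,
            "h2_anchor": est.h2_1.h2,
            "h2_partner": est.h2_2.h2,
            "z_h2_partner": est.h2_2.z_h2,
            "cross_intercept": est.cross_intercept,
            "overlap_flagged": est.overlap_flagged,
        }
        if est.p < threshold and abs(est.rg) > MIN_ABS_RG:
            res = run_lcv(ss_a, ss_p, ldscores, est)
            row.update(gcp=res.gcp, gcp_se=res.gcp_se, gcp_p=res.p,
                       partial_causality=res.partial_causality_flag,
                       low_h2_warning=res.low_h2_warning)
            verdict = ("partial causality" if res.partial_causality_flag
                       else "no causal direction")
            print(f"{row['pair']}: rg={est.rg:.3f} (SE {est.se:.3f}, "
                  f"p={est.p:.2e}); GCP={res.gcp:.2f} (SE {res.gcp_se:.2f}, "
                  f"p={res.p:.2e}) -> {verdict}"
                  + (" [low h2 Z: interpret cautiously]"
                     if res.low_h2_warning else ""))
        else:
            print(f"{row['pair']}: rg={est.rg:.3f} (SE {est.se:.3f}, "
                  f"p={est.p:.2e}) below threshold {threshold:.3g} "
                  "-> LCV skipped")
        if est.overlap_flagged:
            print(f"  note: cross-trait intercept "
                  f"{est.cross_intercept:.3f} markedly non-zero "
                  f"(p={est.cross_intercept_p:.2e}) — sample overlap; "
                  "compare Cauchy meta-analysis")
        rows.append(row)
    out = common.RESULTS / "rg_lcv.tsv"
    pd.DataFrame(rows).to_csv(out, sep="\t", index=False,
                              float_format="%.6g")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
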