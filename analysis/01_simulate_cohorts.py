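"""Simulate the study's GWAS summary statistics with known ground truth.

Generates, for each partner trait, a jointly drawn (anchor, partner) pair of
summary-statistic tables over a shared 20,000-SNP panel of heterogeneous
AR(1) LD blocks.  The anchor files are independent realisations of the same
generative anchor trait — the joint draw per pair is what carries the
cross-trait correlation, so each downstream pair analysis uses its own
anchor realisation.  Also writes LD scores, gene locations (one gene per LD
block) and a small gene-set collection under results/sim_inputs/.
"""

import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parent))
import common

from pairmeta import io
from pairmeta.simulate import simulate_pair


def main() -> None:
    ld, ldscores = common.ld_panel()
    out = common.RESULTS / "sim_inputs"
    out.mkdir(parents=True, exist_ok=True)

    for partner in common.PARTNERS:
        truth, mode = common.truth_for(partner)
        ss_anchor, ss_partner = simulate_pair(ld, truth, mode=mode)
        io.write_sumstats(
            ss_anchor, common.sumstats_path(f"{common.ANCHOR}__{partner}")
        )
        io.write_sumstats(ss_partner, common.sumstats_path(partner))
        print(f"wrote pair {common.ANCHOR}+{partner}: "
              f"N=({truth.n1:,}, {truth.n2:,}), rg(truth)={truth.rg}, "
              f"mode={mode}, overlap={truth.n_overlap:,}")

    io.write_ld_scores(
        [f"rs{j+1}" for j in range(ld.M)], ldscores, out / "ldscores.tsv"
    )

    # one gene per LD block, plus a gene-set collection over those genes
    first = io.read_sumstats(common.sumstats_path(list(common.PARTNERS)[0]))
    pos = first.table["pos"].to_numpy()
    bs = common.BLOCK_SIZE
    with open(out / "genes.loc", "w") as fh:
        for b in range(common.N_BLOCKS):
            fh.write(f"GENE{b}\t1\t{pos[b*bs]}\t{pos[(b+1)*bs-1]}\n")
    rng = np.random.default_rng(common.SEED)
    with open(out / "sets.gmt", "w") as fh:
        for s in range(60):
            members = rng.choice(common.N_BLOCKS, size=40, replace=False)
            fh.write("\t".join(
                [f"SET{s}", "na", *[f"GENE{g}" for g in sorted(members)]]
            ) + "\n")
    print(f"panel: M={ld.M:,} SNPs in {common.N_BLOCKS:,} blocks; "
          f"mean LD score {ldscores.mean():.2f}")


if __name__ == "__main__":
    main()
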