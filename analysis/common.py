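"""Shared design for the synthetic pairwise-analysis study.

One anchor trait (a schizophrenia-like disorder, largest GWAS) and four
substance-dependence-like partner traits with heterogeneous genetic
correlations, one partner sharing cohort samples with the anchor (sample
overlap) and one partner whose genetic correlation is too weak to survive
multiple-testing correction.  Effects are sparse (point-normal latent
architecture) so gene-based aggregation and the pairwise meta-analysis have
something genuine to discover; the partner labelled ``AD`` is generated with
a causal architecture (its latent component drives the anchor).

Sample sizes are one tenth of the published GWAS they emulate, keeping the
per-gene power in a regime where single-trait tests are underpowered but
the pairwise meta-analysis is not — the phenomenon the study design exists
to demonstrate.

Every script rebuilds the LD panel deterministically from these parameters;
summary statistics and downstream tables travel between stages as TSV under
results/.
"""

from __future__ import annotations

import zlib
from pathlib import Path

from pairmeta.simulate import SimTruth, build_ld_structure, compute_ld_scores

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"

SEED = 20_260_928

N_BLOCKS = 2_000          # one gene per LD block
BLOCK_SIZE = 10
RHO_RANGE = (0.0, 0.9)
M = N_BLOCKS * BLOCK_SIZE

ANCHOR = "SZ"
N_ANCHOR = 13_064         # one tenth of the published GWAS

#: partner -> (N, rg with anchor, simulation mode, extras)
PARTNERS = {
    "AD": dict(n=2_876, rg=0.37, mode="lcv_latent", gcp=-0.6,
               n_overlap=1_500, pheno_corr=0.4),
    "CUD": dict(n=35_781, rg=0.31, mode="lcv_latent", gcp=0.0),
    "ND": dict(n=24_489, rg=0.12, mode="lcv_latent", gcp=0.0),
    "OD": dict(n=2_871, rg=0.05, mode="bivariate_normal"),
}

H2_ANCHOR = 0.4
H2_PARTNER = 0.3
P_CAUSAL = 0.05           # sparse architecture: 5% of SNPs causal

#: Bonferroni-corrected threshold for calling a genetic correlation
#: significant (and gating the causality model), over the 4 pairs tested.
RG_ALPHA = 0.05
N_RG_TESTS = len(PARTNERS)


def ld_panel():
    ld = build_ld_structure(N_BLOCKS, BLOCK_SIZE, RHO_RANGE, seed=SEED)
    return ld, compute_ld_scores(ld)


def truth_for(partner: str) -> tuple[SimTruth, str]:
    spec = PARTNERS[partner]
    common = dict(
        h2_1=H2_ANCHOR,
        h2_2=H2_PARTNER,
        n1=N_ANCHOR,
        n2=spec["n"],
        n_overlap=spec.get("n_overlap", 0),
        pheno_corr=spec.get("pheno_corr", 0.0),
        seed=SEED + (zlib.crc32(partner.encode()) % 10_000),
    )
    if spec["mode"] == "lcv_latent":
        truth = SimTruth.from_gcp(spec["gcp"], rg=spec["rg"],
                                  p_causal=P_CAUSAL, **common)
    else:
        truth = SimTruth(rg=spec["rg"], **common)
    return truth, spec["mode"]


def sumstats_path(label: str) -> Path:
    return RESULTS / "sim_inputs" / f"{label}.tsv"


def gene_results_path(label: str) -> Path:
    return RESULTS / "genes" / f"{label}.tsv"
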