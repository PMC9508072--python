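"""Competitive gene-set association with confounder adjustment and BH FDR.

The competitive test asks whether genes in a set carry more association
signal than the remaining genes: ordinary least squares of the per-gene
probit Z-score on set membership plus nuisance covariates (gene size as SNP
count, its log, aggregate minor-allele count, its log — the confounders
that inflate gene statistics irrespective of biology), with a one-sided
test of the membership coefficient (enrichment only).  Benjamini-Hochberg
FDR is applied within each collection, since significant-set counts are
reported per collection; a joint flag exists for correcting across
collections at once.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import GeneSetCollection

__all__ = [
    "GeneSetResult",
    "competitive_geneset_test",
    "run_geneset_collection",
    "default_covariates",
]


@dataclass
class GeneSetResult:
    set_id: str
    n_genes: int
    beta: float
    se: float
    p: float
    q: float = math.nan
    significant: bool = False
    novel_vs_single_trait: bool | None = None


def default_covariates(gene_table: pd.DataFrame) -> np.ndarray:
    """Standard confounder matrix from a gene-result table.

    Uses ``n_snps`` and ``log(n_snps)`` always, plus ``mac`` and
    ``log(mac)`` when an aggregate minor-allele-count column is present.
    """
    cols = [gene_table["n_snps"].to_numpy(float)]
    cols.append(np.log(cols[0]))
    if "mac" in gene_table.columns:
        mac = gene_table["mac"].to_numpy(float)
        cols.append(mac)
        cols.append(np.log(np.maximum(mac, 1.0)))
    return np.column_stack(cols)


def _drop_collinear(X: np.ndarray, tol: float = 1e-10):
    """QR-based removal of linearly dependent columns (kept-column indices)."""
    keep: list[int] = []
    basis = np.empty((X.shape[0], 0))
    for j in range(X.shape[1]):
        cand = np.column_stack([basis, X[:, j]])
        if np.linalg.matrix_rank(cand, tol * max(1.0, np.abs(X).max())) > basis.shape[1]:
            basis = cand
            keep.append(j)
    return keep


def competitive_geneset_test(
    gene_z: np.ndarray,
    membership: np.ndarray,
    covariates: np.ndarray | None = None,
) -> tuple[float, float, float]:
    """One-sided competitive enrichment test for a single gene set.

    OLS of gene Z on [intercept, membership, covariates]; returns
    ``(beta, se, p)`` with p the one-sided upper-tail t probability for
    beta > 0.  Constant membership is a degenerate design; collinear
    covariates are dropped with a warning.
    """
    y = np.asarray(gene_z, dtype=float)
    s = np.asarray(membership, dtype=float)
    if y.shape != s.shape or y.ndim != 1:
        raise ValueError("gene_z and membership must be aligned vectors")
    if s.min() == s.max():
        raise ValueError("membership is constant: competitive test needs "
                         "both member and non-member genes")
    cols = [np.ones_like(y), s]
    if covariates is not None:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != len(y):
            C = C.T
        X0 = np.column_stack([*cols, C])
        keep = _drop_collinear(X0)
        if len(keep) < X0.shape[1]:
            warnings.warn(
                f"dropped {X0.shape[1] - len(keep)} collinear covariate "
                "column(s)", stacklevel=2,
            )
        if 1 not in keep:
            raise ValueError("membership collinear with covariates")
        X = X0[:, keep]
        beta_col = keep.index(1)
    else:
        X = np.column_stack(cols)
        beta_col = 1
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    dof = len(y) - X.shape[1]
    if dof <= 0:
        raise ValueError("not enough genes for the design")
    sigma2 = float(resid @ resid) / dof
    XtX_inv = np.linalg.inv(X.T @ X)
    se = math.sqrt(sigma2 * XtX_inv[beta_col, beta_col])
    beta = float(coef[beta_col])
    if se == 0.0:                      # perfectly flat outcome: no evidence
        return beta, se, 1.0 if beta <= 0 else 0.0
    t = beta / se
    p = float(stats.t.sf(t, dof))
    return beta, se, p


def run_geneset_collection(
    gene_table: pd.DataFrame,
    collection: GeneSetCollection,
    covariates: np.ndarray | None = None,
    min_set_size: int = 3,
    fdr_alpha: float = 0.05,
    compare_run: "pd.DataFrame | None" = None,
) -> pd.DataFrame:
    """Competitive test for every set in a collection, with BH FDR.

    ``gene_table`` needs columns ``gene_id, z, n_snps`` (plus ``mac`` if
    available); it defines the gene universe.  Sets are intersected with
    the universe; sets smaller than ``min_set_size`` after intersection are
    skipped (reported with NaN statistics).  When ``compare_run`` (a result
    frame from a single-trait analysis) is given, sets significant here but
    not there are flagged ``novel_vs_single_trait``.
    """
    if covariates is None:
        covariates = default_covariates(gene_table)
    universe = gene_table["gene_id"].to_numpy()
    index = {g: i for i, g in enumerate(universe)}
    z = gene_table["z"].to_numpy(float)

    rows = []
    tested_sets = []
    for sid, genes in collection.sets.items():
        members = [index[g] for g in genes if g in index]
        n_mem = len(members)
        if n_mem < min_set_size or n_mem == len(universe):
            rows.append({"set_id": sid, "n_genes": n_mem, "beta": math.nan,
                         "se": math.nan, "p": math.nan, "skipped": True})
            continue
        s = np.zeros(len(universe))
        s[members] = 1.0
        beta, se, p = competitive_geneset_test(z, s, covariates)
        rows.append({"set_id": sid, "n_genes": n_mem, "beta": beta,
                     "se": se, "p": p, "skipped": False})
        tested_sets.append(sid)
    df = pd.DataFrame(rows)
    if not tested_sets:
        raise ValueError(
            f"collection {collection.collection_name!r}: no set of size "
            f">= {min_set_size} intersects the gene universe"
        )
    tested = ~df["skipped"]
    _, q, _, _ = multipletests(df.loc[tested, "p"], method="fdr_bh")
    df.loc[tested, "q"] = q
    df["significant"] = tested & (df["q"] < fdr_alpha)
    if compare_run is not None:
        prev_sig = set(
            compare_run.loc[compare_run["significant"], "set_id"]
        )
        df["novel_vs_single_trait"] = df["significant"] & ~df["set_id"].isin(
            prev_sig
        )
    return df
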