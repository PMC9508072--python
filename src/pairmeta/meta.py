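"""Pairwise gene-level meta-analysis across two traits.

Two combination rules over per-gene statistics:

* Weighted Stouffer (inverse normal): gene p-values are probit-transformed
  to one-sided Z-scores and combined as
  ``z_meta = sum(sqrt(n_i) * z_i) / sqrt(sum(n_i))`` with the study sample
  sizes as weights — MAGMA's meta-analysis convention.  Exact under
  independent studies, anti-conservative under sample overlap.
* Cauchy combination (ACAT): ``T = sum(w_i * tan((0.5 - p_i) * pi))`` with
  ``w_i = n_i / sum(n)``; ``p_meta = 0.5 - arctan(T)/pi``.  The heavy Cauchy
  tail makes the combined p-value insensitive to unknown correlation among
  the inputs, e.g. from overlapping samples.

Both are one-sided on the gene-level scale (gene p-values are inherently
one-sided: small means associated).

The novel-signal filter isolates pleiotropic candidates: genes Bonferroni-
significant in the meta-analysis, at least nominally significant
(p < 0.05) in *both* single-trait runs, yet Bonferroni-significant in
neither — associations only visible when the traits are combined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genes import probit_z

__all__ = [
    "MetaResult",
    "stouffer_combine",
    "stouffer_combine_p",
    "cauchy_combine",
    "method_concordance",
    "novel_signal_filter",
    "count_recurrence",
]

#: Below this, tan((0.5 - p) * pi) is replaced by its asymptote 1/(p * pi).
_TAN_SMALL_P = 1e-15
#: Above this statistic, the Cauchy upper tail is taken as 1/(T * pi).
_CAUCHY_BIG_T = 1e15


@dataclass
class MetaResult:
    gene_id: str
    z_meta: float
    p_meta: float
    log_p_meta: float
    method: str                       # "stouffer" | "cauchy"
    n1: float
    n2: float


def stouffer_combine(z, n) -> tuple[float, float]:
    """Sample-size-weighted inverse-normal combination of Z-scores.

    ``z_meta = sum(sqrt(n_i) z_i) / sqrt(sum(n_i))``; the returned p is the
    one-sided upper tail, computed in log space so extreme Z-scores do not
    underflow.  Returns ``(z_meta, p_meta)``.
    """
    z = np.asarray(z, dtype=float)
    n = np.asarray(n, dtype=float)
    if z.shape != n.shape or z.ndim != 1 or len(z) < 2:
        raise ValueError("z and n must be equal-length vectors of length >= 2")
    if np.any(n <= 0):
        raise ValueError("all sample sizes must be positive")
    z_meta = float(np.sqrt(n) @ z / math.sqrt(n.sum()))
    # clamp into (0, 1]: the log-space tail is kept by combine_gene_tables
    return z_meta, max(math.exp(stats.norm.logsf(z_meta)), 5e-324)


def stouffer_combine_p(p, n) -> tuple[float, float]:
    """Stouffer combination taking one-sided p-values (probit applied here)."""
    p = np.asarray(p, dtype=float)
    z = np.array([probit_z(pi) for pi in p])
    return stouffer_combine(z, n)


def cauchy_combine(p, n) -> float:
    """Cauchy combination (ACAT) of p-values with sample-size weights.

    Robust to arbitrary dependence among the inputs.  Stable substitutions:
    ``tan((0.5 - p) pi) -> 1/(p pi)`` for p below 1e-15, and the Cauchy
    upper tail ``0.5 - arctan(T)/pi -> 1/(T pi)`` for very large T.
    """
    p = np.asarray(p, dtype=float)
    n = np.asarray(n, dtype=float)
    if p.shape != n.shape or p.ndim != 1 or len(p) < 2:
        raise ValueError("p and n must be equal-length vectors of length >= 2")
    if np.any((p <= 0.0) | (p >= 1.0)):
        raise ValueError("all p-values must lie strictly in (0, 1)")
    if np.any(n <= 0):
        raise ValueError("all sample sizes must be positive")
    w = n / n.sum()
    # the asymptote 1/(p*pi) saturates at p ~ 1e-300 so T stays finite even
    # when an input p-value has underflowed to the smallest positive float
    p_safe = np.maximum(p, 1e-300)
    t = np.where(p < _TAN_SMALL_P, 1.0 / (p_safe * math.pi),
                 np.tan((0.5 - p) * math.pi))
    T = float(w @ t)
    if T > _CAUCHY_BIG_T:
        return 1.0 / (T * math.pi)
    return 0.5 - math.atan(T) / math.pi


def combine_gene_tables(
    res1, res2, n1: float, n2: float, method: str = "stouffer"
) -> list[MetaResult]:
    """Combine two aligned gene-result sets (same gene universe).

    ``res1``/``res2`` are :class:`~pairmeta.genes.GeneAnalysis` objects or
    gene_id -> GeneResult mappings; only genes present in both are combined,
    in the order of ``res1``.
    """
    d1 = res1.by_gene() if hasattr(res1, "by_gene") else dict(res1)
    d2 = res2.by_gene() if hasattr(res2, "by_gene") else dict(res2)
    shared = [gid for gid in d1 if gid in d2]
    out = []
    for gid in shared:
        r1, r2 = d1[gid], d2[gid]
        if method == "stouffer":
            z_meta, p_meta = stouffer_combine(
                [r1.z, r2.z], [n1, n2]
            )
            log_p = stats.norm.logsf(z_meta)
        elif method == "cauchy":
            p_meta = cauchy_combine([r1.p, r2.p], [n1, n2])
            log_p = math.log(p_meta)
            z_meta = probit_z(None, log_p=min(log_p, -1e-17))
        else:
            raise ValueError(f"unknown combination method {method!r}")
        out.append(
            MetaResult(gene_id=gid, z_meta=z_meta, p_meta=p_meta,
                       log_p_meta=float(log_p), method=method, n1=n1, n2=n2)
        )
    return out


def method_concordance(p_a, p_b) -> tuple[float, float, float]:
    """Pearson correlation of ``-log10`` p-values with a Fisher-z 95% CI.

    Requires aligned vectors of length >= 4 (the Fisher CI needs n > 3).
    Returns ``(r, ci_low, ci_high)``.
    """
    p_a = np.asarray(p_a, dtype=float)
    p_b = np.asarray(p_b, dtype=float)
    if p_a.shape != p_b.shape or p_a.ndim != 1 or len(p_a) < 4:
        raise ValueError("need aligned p-value vectors of length >= 4")
    x = -np.log10(p_a)
    y = -np.log10(p_b)
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise ValueError("zero variance in a -log10 p vector: "
                         "correlation undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    if abs(r) >= 1.0:
        return r, r, r                      # degenerate: identical vectors
    n = len(p_a)
    fz = math.atanh(r)
    half = 1.959963984540054 / math.sqrt(n - 3)
    return r, math.tanh(fz - half), math.tanh(fz + half)


def novel_signal_filter(
    res1,
    res2,
    meta: list[MetaResult],
    alpha_gene: float = 2.7e-6,
    nominal: float = 0.05,
) -> pd.DataFrame:
    """Flag novel pleiotropic genes from a pairwise meta-analysis.

    A gene is retained iff its meta p-value beats the gene-level Bonferroni
    threshold, it is nominally significant in *both* single-trait runs, and
    Bonferroni-significant in *neither* — i.e. the association emerges only
    jointly.  Returns one row per meta-analysed gene with the three flags
    and the retained verdict; a gene present in ``meta`` but missing from
    either trait is a consistency error.
    """
    d1 = res1.by_gene() if hasattr(res1, "by_gene") else dict(res1)
    d2 = res2.by_gene() if hasattr(res2, "by_gene") else dict(res2)
    rows = []
    for m in meta:
        if m.gene_id not in d1 or m.gene_id not in d2:
            raise ValueError(
                f"gene {m.gene_id!r} in meta-analysis but missing from a "
                "single-trait run"
            )
        p1 = d1[m.gene_id].p
        p2 = d2[m.gene_id].p
        meta_bonf = m.p_meta < alpha_gene
        nominal_both = (p1 < nominal) and (p2 < nominal)
        sub_bonf_both = (p1 >= alpha_gene) and (p2 >= alpha_gene)
        rows.append(
            {
                "gene_id": m.gene_id,
                "p_trait1": p1,
                "p_trait2": p2,
                "p_meta": m.p_meta,
                "meta_bonf": meta_bonf,
                "nominal_both": nominal_both,
                "sub_bonf_both": sub_bonf_both,
                "retained": meta_bonf and nominal_both and sub_bonf_both,
            }
        )
    return pd.DataFrame(rows)


def count_recurrence(reports: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Count how often each retained gene recurs across trait-pair runs.

    ``reports`` maps a pair label to its novel-signal report.  Returns genes
    retained in at least one pair, with the recurrence count and the pairs.
    """
    hits: dict[str, list[str]] = {}
    for pair, rep in reports.items():
        for gid in rep.loc[rep["retained"], "gene_id"]:
            hits.setdefault(gid, []).append(pair)
    rows = [
        {"gene_id": gid, "n_pairs": len(pairs), "pairs": ",".join(pairs)}
        for gid, pairs in sorted(hits.items(), key=lambda kv: -len(kv[1]))
    ]
    return pd.DataFrame(rows, columns=["gene_id", "n_pairs", "pairs"])
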