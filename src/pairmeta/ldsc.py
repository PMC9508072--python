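"""LD score regression: SNP heritability and cross-trait genetic correlation.

The regression model for a single trait is

    E[chi2_j] = 1 + N * h2 * l_j / M  (+ confounding absorbed by a free
                                        intercept),

so the slope of chi-square on LD score, rescaled by M/N, estimates the SNP
heritability, and the intercept captures population structure or other
uniform inflation.  For two traits,

    E[z1_j z2_j] = sqrt(N1*N2) * rho_g * l_j / M + c,

where the cross-trait intercept c equals the phenotypic correlation in the
overlapping samples scaled by the overlap fraction — non-zero only under
sample overlap or shared confounding — and the slope yields the genetic
covariance rho_g; the genetic correlation is rg = rho_g / sqrt(h2_1*h2_2).

Estimation is a single weighted least-squares fit with a free intercept and
heteroskedasticity weights ``1 / (1 + N*h2*l/M)**2`` iterated twice from an
unweighted start (the two-step constrained-intercept refinement of the
original LDSC software is deliberately not implemented; see the methods
note).  Standard errors come from a delete-one block jackknife over
contiguous SNP blocks, with weights frozen at the full-data fit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import SummaryStats, align_snp_panels
from .genes import MHC_REGION

__all__ = [
    "H2Estimate",
    "RgEstimate",
    "qc_filter",
    "estimate_h2",
    "estimate_rg",
]


@dataclass
class H2Estimate:
    h2: float
    se: float
    intercept: float
    intercept_se: float
    m_snps: int
    n_blocks: int

    @property
    def z_h2(self) -> float:
        return self.h2 / self.se


@dataclass
class RgEstimate:
    rho_g: float
    rg: float
    se: float
    p: float
    cross_intercept: float
    cross_intercept_se: float
    cross_intercept_p: float
    h2_1: H2Estimate
    h2_2: H2Estimate
    m_snps: int
    n_blocks: int

    @property
    def z(self) -> float:
        return self.rg / self.se

    @property
    def overlap_flagged(self) -> bool:
        """Markedly non-zero cross-trait intercept (p < 0.01)."""
        return self.cross_intercept_p < 0.01


def qc_filter(
    ss: SummaryStats,
    whitelist=None,
    maf_min: float = 0.05,
    mhc: tuple[str, int, int] = MHC_REGION,
    min_snps: int = 200,
):
    """Standard pre-LDSC SNP filter.

    Keeps SNPs with MAF strictly above ``maf_min`` (a SNP at exactly the
    threshold is removed), id in the whitelist (HapMap3-style; ``None``
    disables), and outside the MHC interval.  Returns the filtered table
    and a dict of per-rule removal counts.
    """
    t = ss.table
    keep = np.ones(len(t), dtype=bool)
    counts = {}
    if maf_min is not None:
        maf_ok = t["maf"].to_numpy(float) > maf_min
        counts["maf"] = int((~maf_ok & keep).sum())
        keep &= maf_ok
    if whitelist is not None:
        wl = set(whitelist)
        in_wl = t["snp_id"].isin(wl).to_numpy()
        counts["whitelist"] = int((~in_wl & keep).sum())
        keep &= in_wl
    if mhc is not None:
        chrom, lo, hi = mhc
        in_mhc = (
            (t["chrom"].to_numpy() == chrom)
            & (t["pos"].to_numpy() >= lo)
            & (t["pos"].to_numpy() <= hi)
        )
        counts["mhc"] = int((in_mhc & keep).sum())
        keep &= ~in_mhc
    out = t.loc[keep].reset_index(drop=True)
    if len(out) < min_snps:
        raise ValueError(
            f"only {len(out)} SNPs survive QC (< {min_snps}); "
            "insufficient data for LD score regression"
        )
    return SummaryStats(table=out), counts


def _block_bounds(m: int, n_blocks: int) -> list[slice]:
    edges = np.linspace(0, m, n_blocks + 1).astype(int)
    return [slice(a, b) for a, b in zip(edges[:-1], edges[1:]) if b > a]


def _wls(x, y, w) -> tuple[float, float]:
    """Weighted LS of y on [1, x]; returns (intercept, slope)."""
    sw = w.sum()
    sx = (w * x).sum()
    sy = (w * y).sum()
    sxx = (w * x * x).sum()
    sxy = (w * x * y).sum()
    det = sw * sxx - sx * sx
    slope = (sw * sxy - sx * sy) / det
    inter = (sy * sxx - sx * sxy) / det
    return float(inter), float(slope)


def _jackknife(x, y, w, blocks) -> tuple[float, float, float, float]:
    """Delete-one-block jackknife of the WLS fit (weights fixed).

    Returns (intercept, slope, se_intercept, se_slope) where the point
    estimates are the full-data fit.
    """
    # Accumulate the 5 sufficient statistics per block, then subtract.
    stats_full = np.zeros(5)
    per_block = np.zeros((len(blocks), 5))
    for i, sl in enumerate(blocks):
        xb, yb, wb = x[sl], y[sl], w[sl]
        per_block[i] = [
            wb.sum(),
            (wb * xb).sum(),
            (wb * yb).sum(),
            (wb * xb * xb).sum(),
            (wb * xb * yb).sum(),
        ]
    stats_full = per_block.sum(axis=0)

    def solve(s):
        sw, sx, sy, sxx, sxy = s
        det = sw * sxx - sx * sx
        return (
            (sy * sxx - sx * sxy) / det,
            (sw * sxy - sx * sy) / det,
        )

    inter, slope = solve(stats_full)
    deleted = np.array([solve(stats_full - pb) for pb in per_block])
    B = len(blocks)
    se = np.sqrt((B - 1) / B * ((deleted - deleted.mean(axis=0)) ** 2).sum(axis=0))
    return inter, slope, float(se[0]), float(se[1])


def _iterated_weights(x, y, n_bar, m, n_iter: int = 2):
    """LDSC heteroskedasticity weights, iterated from an unweighted fit."""
    w = np.ones_like(x)
    h2 = 0.0
    for _ in range(n_iter):
        _, slope = _wls(x, y, w)
        h2 = max(0.0, min(1.0, slope * m / n_bar))
        w = 1.0 / (1.0 + n_bar * h2 * x / m) ** 2
    return w


def estimate_h2(
    ss: SummaryStats,
    ldscores: np.ndarray,
    n_blocks: int = 200,
    m_total: int | None = None,
) -> H2Estimate:
    """SNP heritability by LD score regression with jackknife SE.

    ``ldscores`` must be aligned with the table's SNP order.  ``m_total``
    defaults to the number of regression SNPs (appropriate when the panel is
    the full variant set, as in the simulator).
    """
    if n_blocks < 20:
        raise ValueError("need at least 20 jackknife blocks")
    z = ss.z
    if not np.isfinite(z).all():
        raise ValueError("h2 estimation requires a Z column for every SNP")
    l = np.asarray(ldscores, dtype=float)
    if len(l) != len(z):
        raise ValueError("LD scores not aligned with summary statistics")
    m = int(m_total if m_total is not None else len(z))
    n_bar = float(np.mean(ss.n))
    chi2 = z**2

    w = _iterated_weights(l, chi2, n_bar, m)
    blocks = _block_bounds(len(z), n_blocks)
    inter, slope, se_i, se_s = _jackknife(l, chi2, w, blocks)
    scale = m / n_bar
    return H2Estimate(
        h2=slope * scale,
        se=max(se_s * scale, 1e-12),
        intercept=inter,
        intercept_se=se_i,
        m_snps=len(z),
        n_blocks=len(blocks),
    )


def estimate_rg(
    ss1: SummaryStats,
    ss2: SummaryStats,
    ldscores: np.ndarray,
    n_blocks: int = 200,
    m_total: int | None = None,
) -> RgEstimate:
    """Cross-trait LD score regression: genetic covariance and correlation.

    The two tables must share an identical, identically oriented SNP panel
    (checked; a mismatch raises naming the first offender).  The jackknife
    re-estimates h2 of both traits and rho_g per deleted block, so the SE of
    rg propagates the uncertainty of all three regressions.
    """
    if n_blocks < 20:
        raise ValueError("need at least 20 jackknife blocks")
    align_snp_panels(ss1, ss2)
    z1, z2 = ss1.z, ss2.z
    l = np.asarray(ldscores, dtype=float)
    if len(l) != len(z1):
        raise ValueError("LD scores not aligned with summary statistics")
    m = int(m_total if m_total is not None else len(z1))
    n1 = float(np.mean(ss1.n))
    n2 = float(np.mean(ss2.n))

    h1 = estimate_h2(ss1, l, n_blocks=n_blocks, m_total=m)
    h2e = estimate_h2(ss2, l, n_blocks=n_blocks, m_total=m)

    # Cross regression: z1*z2 on l.  The cross weights are the geometric
    # mean of the per-trait weights — symmetric in the traits, and exactly
    # reproducing rg = 1 when a trait is paired with itself.
    y = z1 * z2
    blocks = _block_bounds(len(y), n_blocks)

    w1 = _iterated_weights(l, z1**2, n1, m)
    w2 = _iterated_weights(l, z2**2, n2, m)
    w = np.sqrt(w1 * w2)

    # Per-block sufficient statistics for the three regressions.
    def suff(x, yv, wv):
        per = np.zeros((len(blocks), 5))
        for i, sl in enumerate(blocks):
            xb, yb, wb = x[sl], yv[sl], wv[sl]
            per[i] = [
                wb.sum(), (wb * xb).sum(), (wb * yb).sum(),
                (wb * xb * xb).sum(), (wb * xb * yb).sum(),
            ]
        return per

    def solve(s):
        sw, sx, sy, sxx, sxy = s
        det = sw * sxx - sx * sx
        return (sy * sxx - sx * sxy) / det, (sw * sxy - sx * sy) / det

    per_c = suff(l, y, w)
    per_1 = suff(l, z1**2, w1)
    per_2 = suff(l, z2**2, w2)
    full_c, full_1, full_2 = per_c.sum(0), per_1.sum(0), per_2.sum(0)

    scale_c = m / math.sqrt(n1 * n2)

    def rg_from(sc, s1, s2):
        ic, slc = solve(sc)
        _, sl1 = solve(s1)
        _, sl2 = solve(s2)
        rho = slc * scale_c
        h2a = sl1 * m / n1
        h2b = sl2 * m / n2
        denom = math.sqrt(max(h2a, 1e-12) * max(h2b, 1e-12))
        return rho, rho / denom, ic

    rho_g, rg, cross_i = rg_from(full_c, full_1, full_2)
    dele = np.array([
        rg_from(full_c - per_c[i], full_1 - per_1[i], full_2 - per_2[i])
        for i in range(len(blocks))
    ])
    B = len(blocks)
    sds = np.sqrt((B - 1) / B * ((dele - dele.mean(0)) ** 2).sum(0))
    se_rg = max(float(sds[1]), 1e-12)
    se_ci = max(float(sds[2]), 1e-12)

    if abs(rg) > 1.25:
        import warnings

        warnings.warn(
            f"genetic correlation estimate {rg:.3f} outside [-1.25, 1.25] "
            "plausible numeric range", stacklevel=2,
        )
    p_rg = float(2.0 * stats.norm.sf(abs(rg) / se_rg))
    p_ci = float(2.0 * stats.norm.sf(abs(cross_i) / se_ci))
    return RgEstimate(
        rho_g=rho_g,
        rg=rg,
        se=se_rg,
        p=p_rg,
        cross_intercept=cross_i,
        cross_intercept_se=se_ci,
        cross_intercept_p=p_ci,
        h2_1=h1,
        h2_2=h2e,
        m_snps=len(z1),
        n_blocks=B,
    )
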