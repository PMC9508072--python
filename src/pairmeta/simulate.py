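"""Paired GWAS summary-statistic simulator with block LD and known truth.

The generator emulates what the real pipeline consumes — two traits' worth of
per-SNP Z-scores over a shared SNP panel — from a fully specified generative
model, so heritability, genetic correlation, sample overlap and latent causal
architecture are all known exactly and every downstream estimator can be
tested for recovery.

Model
-----
LD is a block-diagonal correlation structure; each block is AR(1),
``r_jk = rho**|j-k|``.  Per-SNP standardised true effects ``beta`` are drawn
jointly for the two traits, either

* ``bivariate_normal`` — ``(beta1_j, beta2_j)`` i.i.d. bivariate normal with
  variances ``h2_i / M`` and correlation ``rg``; or
* ``lcv_latent`` — a shared latent component with a kurtotic (point-normal)
  effect distribution: ``alpha_i = q_i * pi + gamma_i`` with ``Var(pi) = 1``,
  ``gamma_i ~ N(0, 1 - q_i**2)`` independent across traits, and
  ``beta_i = alpha_i * sqrt(h2_i / M)``.  Then ``corr(alpha1, alpha2) =
  q1*q2 = rg``, and the asymmetry of the mixed fourth moments
  ``E[alpha1**3 alpha2] / E[alpha1 alpha2**3] = (q1/q2)**2`` carries the
  causal signal.  Gaussian effects make the genetic causality proportion
  unidentifiable, hence the kurtotic latent is mandatory in this mode.

Marginal GWAS Z-scores follow the standard summary-statistic model

    z_i = sqrt(N_i) * R @ beta_i + eps_i,      eps_i ~ N(0, R),

with cross-trait noise correlation ``pheno_corr * n_overlap / sqrt(n1*n2)``
— the sample-overlap term that appears as the LD score regression
cross-trait intercept.  Overlap is modelled only in this noise term, not by
simulating individual genotypes.

Seeding: a single master seed; per-block child streams are spawned
deterministically so increasing the block count never changes earlier blocks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import SummaryStats

__all__ = [
    "LDBlock",
    "LDStructure",
    "SimTruth",
    "build_ld_structure",
    "compute_ld_scores",
    "simulate_pair",
]


@dataclass
class LDBlock:
    chrom: str
    positions: np.ndarray          # 1-based bp, sorted
    corr: np.ndarray               # unit-diagonal correlation matrix
    start_index: int = 0           # offset of this block in the global panel

    def __len__(self) -> int:
        return len(self.positions)


@dataclass
class LDStructure:
    """Block-diagonal LD: disjoint blocks, zero correlation across blocks."""

    blocks: list[LDBlock]
    _sqrt_cache: dict[int, np.ndarray] = field(default_factory=dict, repr=False)

    @property
    def M(self) -> int:
        return sum(len(b) for b in self.blocks)

    def block_slices(self) -> list[slice]:
        return [slice(b.start_index, b.start_index + len(b)) for b in self.blocks]

    def sqrt_factor(self, i: int) -> np.ndarray:
        """Symmetric PSD square root of block i's correlation matrix.

        Negative eigenvalues (numerical, or from a user-supplied matrix) are
        clipped at zero; clipping beyond 1e-8 raises rather than repairing
        silently, since that indicates a genuinely invalid matrix.
        """
        if i not in self._sqrt_cache:
            R = self.blocks[i].corr
            w, V = np.linalg.eigh(R)
            if w.min() < -1e-8:
                raise ValueError(
                    f"LD block {i}: correlation matrix not PSD "
                    f"(min eigenvalue {w.min():.3g})"
                )
            w = np.clip(w, 0.0, None)
            self._sqrt_cache[i] = (V * np.sqrt(w)) @ V.T
        return self._sqrt_cache[i]

    def correlation_submatrix(self, indices: np.ndarray) -> np.ndarray:
        """Correlation matrix for arbitrary global SNP indices.

        Cross-block entries are exactly zero by construction.
        """
        indices = np.asarray(indices)
        k = len(indices)
        out = np.zeros((k, k))
        np.fill_diagonal(out, 1.0)
        for b in self.blocks:
            lo, hi = b.start_index, b.start_index + len(b)
            inblock = (indices >= lo) & (indices < hi)
            if inblock.sum() < 2:
                continue
            local = indices[inblock] - lo
            sub = b.corr[np.ix_(local, local)]
            out[np.ix_(inblock, inblock)] = sub
        return out


@dataclass
class SimTruth:
    """Generative parameters a simulation was drawn from.

    ``q1, q2`` are latent loadings used only in ``lcv_latent`` mode and must
    satisfy ``q1*q2 == rg``; :meth:`from_gcp` builds them from a target
    genetic causality proportion via ``q1 = |rg|**((1-gcp)/2)``,
    ``q2 = |rg|**((1+gcp)/2)`` (so ``gcp = log(q2/q1)/log|rg|``).
    ``p_causal`` is the point-normal causal fraction; excess kurtosis of the
    latent effect is ``3*(1-p_causal)/p_causal``.
    """

    h2_1: float
    h2_2: float
    rg: float
    n1: int
    n2: int
    n_overlap: int = 0
    pheno_corr: float = 0.0
    q1: float | None = None
    q2: float | None = None
    p_causal: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for h2 in (self.h2_1, self.h2_2):
            if not 0.0 <= h2 <= 1.0:
                raise ValueError(f"heritability {h2} outside [0, 1]")
        if abs(self.rg) > 1.0:
            raise ValueError(f"|rg| = {abs(self.rg)} > 1")
        if self.n_overlap > min(self.n1, self.n2):
            raise ValueError("n_overlap exceeds min(n1, n2)")
        if not 0.0 < self.p_causal <= 1.0:
            raise ValueError("p_causal must lie in (0, 1]")
        if (self.q1 is None) != (self.q2 is None):
            raise ValueError("q1 and q2 must be given together")
        if self.q1 is not None and abs(self.q1 * self.q2 - self.rg) > 1e-9:
            raise ValueError(
                f"latent loadings inconsistent: q1*q2 = {self.q1 * self.q2} "
                f"but rg = {self.rg}"
            )

    @classmethod
    def from_gcp(
        cls, gcp: float, rg: float, **kwargs
    ) -> "SimTruth":
        """Build latent loadings realising a genetic causality proportion."""
        if not -1.0 <= gcp <= 1.0:
            raise ValueError("gcp must lie in [-1, 1]")
        if rg == 0.0:
            raise ValueError("gcp is undefined at rg = 0")
        a = abs(rg)
        q1 = a ** ((1.0 - gcp) / 2.0)
        q2 = a ** ((1.0 + gcp) / 2.0)
        if rg < 0:
            q2 = -q2
        return cls(rg=rg, q1=q1, q2=q2, **kwargs)

    @property
    def overlap_corr(self) -> float:
        """Cross-trait noise correlation (the LDSC cross-intercept term)."""
        if self.n_overlap == 0:
            return 0.0
        return self.pheno_corr * self.n_overlap / math.sqrt(self.n1 * self.n2)


def build_ld_structure(
    n_blocks: int,
    block_size: int,
    rho,
    seed: int = 0,
    chrom: str = "1",
    spacing_bp: int = 1000,
) -> LDStructure:
    """Block-diagonal AR(1) LD: ``r_jk = rho**|j-k|`` within each block.

    ``rho`` is either a scalar (every block identical) or a ``(lo, hi)``
    range from which each block's parameter is drawn uniformly using
    ``seed``.  Heterogeneous blocks matter: with a single rho the LD scores
    are nearly constant across SNPs and the LD score *regression* loses its
    lever arm, so recovery studies should use a range.  Positions are laid
    contiguously along ``chrom`` at ``spacing_bp`` intervals; deterministic
    given arguments and seed.
    """
    if n_blocks < 1 or block_size < 1:
        raise ValueError("n_blocks and block_size must be positive")
    if np.isscalar(rho):
        rhos = np.full(n_blocks, float(rho))
    else:
        lo, hi = float(rho[0]), float(rho[1])
        if not 0.0 <= lo <= hi < 1.0:
            raise ValueError(f"AR(1) range ({lo}, {hi}) outside [0, 1)")
        rhos = np.random.default_rng(seed).uniform(lo, hi, size=n_blocks)
    if np.any((rhos < 0.0) | (rhos >= 1.0)):
        raise ValueError(f"AR(1) parameter rho = {rho} outside [0, 1)")
    idx = np.arange(block_size)
    dist = np.abs(idx[:, None] - idx[None, :])
    blocks = []
    offset = 0
    for b in range(n_blocks):
        pos = 1 + spacing_bp * (offset + np.arange(block_size))
        blocks.append(
            LDBlock(chrom=chrom, positions=pos, corr=rhos[b] ** dist,
                    start_index=offset)
        )
        offset += block_size
    return LDStructure(blocks=blocks)


def compute_ld_scores(ld: LDStructure) -> np.ndarray:
    """LD score of each SNP: sum of squared correlations over its block.

    Always >= 1 because the self-correlation contributes 1.
    """
    out = np.empty(ld.M)
    for b in ld.blocks:
        out[b.start_index : b.start_index + len(b)] = (b.corr ** 2).sum(axis=1)
    return out


def _draw_block_effects(
    truth: SimTruth, mode: str, M: int, k: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Standardised true effects for one block of k SNPs, Var = h2_i/M each."""
    s1 = math.sqrt(truth.h2_1 / M)
    s2 = math.sqrt(truth.h2_2 / M)
    if mode == "bivariate_normal":
        rg = truth.rg
        u = rng.standard_normal(k)
        v = rng.standard_normal(k)
        a1 = u
        a2 = rg * u + math.sqrt(max(0.0, 1.0 - rg**2)) * v
    elif mode == "lcv_latent":
        if truth.q1 is None:
            raise ValueError("lcv_latent mode requires latent loadings q1, q2 "
                             "(use SimTruth.from_gcp)")
        if truth.p_causal >= 1.0:
            raise ValueError("lcv_latent requires p_causal < 1: Gaussian "
                             "latent effects make the causality proportion "
                             "unidentifiable")
        p = truth.p_causal
        causal = rng.random(k) < p
        pi = np.where(causal, rng.standard_normal(k) / math.sqrt(p), 0.0)
        g1 = math.sqrt(max(0.0, 1.0 - truth.q1**2)) * rng.standard_normal(k)
        g2 = math.sqrt(max(0.0, 1.0 - truth.q2**2)) * rng.standard_normal(k)
        a1 = truth.q1 * pi + g1
        a2 = truth.q2 * pi + g2
    else:
        raise ValueError(f"unknown simulation mode {mode!r}")
    return s1 * a1, s2 * a2


def simulate_pair(
    ld: LDStructure,
    truth: SimTruth,
    mode: str = "bivariate_normal",
    seed: int | None = None,
    return_effects: bool = False,
):
    """Simulate a pair of GWAS summary-statistic tables over a shared panel.

    Returns two :class:`~pairmeta.io.SummaryStats` with identical SNP panels
    and allele orientation (plus the standardised true effect vectors when
    ``return_effects``).  Z and P columns are mutually consistent
    (two-sided).  Reproducible given ``seed`` (defaults to ``truth.seed``);
    every random quantity is drawn from a per-block child stream, so
    appending blocks never changes earlier blocks.
    """
    master = truth.seed if seed is None else seed
    M = ld.M
    children = np.random.SeedSequence(master).spawn(len(ld.blocks))

    beta1 = np.empty(M)
    beta2 = np.empty(M)
    maf = np.empty(M)
    c = truth.overlap_corr
    z1 = np.empty(M)
    z2 = np.empty(M)
    rn1 = math.sqrt(truth.n1)
    rn2 = math.sqrt(truth.n2)
    for i, b in enumerate(ld.blocks):
        k = len(b)
        sl = slice(b.start_index, b.start_index + k)
        rng = np.random.default_rng(children[i])
        beta1[sl], beta2[sl] = _draw_block_effects(truth, mode, M, k, rng)
        maf[sl] = rng.uniform(0.05, 0.5, size=k)
        L = ld.sqrt_factor(i)
        u = L @ rng.standard_normal(k)
        v = L @ rng.standard_normal(k)
        eps1 = u
        eps2 = c * u + math.sqrt(max(0.0, 1.0 - c**2)) * v
        z1[sl] = rn1 * (b.corr @ beta1[sl]) + eps1
        z2[sl] = rn2 * (b.corr @ beta2[sl]) + eps2

    chroms = np.concatenate([np.repeat(b.chrom, len(b)) for b in ld.blocks])
    pos = np.concatenate([b.positions for b in ld.blocks])
    snp_id = np.array([f"rs{j + 1}" for j in range(M)])

    def _table(z: np.ndarray, n: int) -> SummaryStats:
        from scipy import stats as st

        return SummaryStats(
            table=pd.DataFrame(
                {
                    "snp_id": snp_id,
                    "chrom": chroms,
                    "pos": pos,
                    "a1": "A",
                    "a2": "G",
                    "z": z,
                    "p": 2.0 * st.norm.sf(np.abs(z)),
                    "n": float(n),
                    "maf": maf,
                }
            )
        )

    t1, t2 = _table(z1, truth.n1), _table(z2, truth.n2)
    if return_effects:
        return t1, t2, beta1, beta2
    return t1, t2
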