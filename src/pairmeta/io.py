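"""Readers, writers and validation for the text formats the pipeline touches.

Summary statistics, gene locations, gene-set collections (GMT) and LD scores
are all plain delimited text.  Coordinates are 1-based, closed intervals
throughout, matching hg19 gene location tables.  Strand is ignored: gene
intervals are strand-collapsed, which is safe because every downstream test
is strand-agnostic.

Allele columns are carried but not harmonised across traits: the gene-level
meta-analysis operates on allele-free statistics, while SNP-level cross-trait
operations (LD score regression, the latent causal variable model) demand
identical panels and identical a1/a2 orientation and raise on any mismatch
rather than silently flipping.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SummaryStats",
    "GeneModel",
    "GeneAnnotation",
    "GeneSetCollection",
    "FormatError",
    "DEFAULT_DIALECT",
    "read_sumstats",
    "write_sumstats",
    "read_gene_loc",
    "write_gene_loc",
    "map_snps_to_genes",
    "read_gmt",
    "write_gmt",
    "read_ld_scores",
    "write_ld_scores",
    "AUTOSOMES",
]

AUTOSOMES = frozenset(str(c) for c in range(1, 23))

#: Column-name mapping used when a caller does not supply one.  Keys are the
#: internal field names, values the header names expected in the file.
DEFAULT_DIALECT = {
    "snp_id": "SNP",
    "chrom": "CHR",
    "pos": "BP",
    "a1": "A1",
    "a2": "A2",
    "z": "Z",
    "p": "P",
    "n": "N",
    "maf": "MAF",
}

#: Relative tolerance for agreement between a signed Z column and a two-sided
#: P column when both are present.
_ZP_RTOL = 1e-6


class FormatError(ValueError):
    """A file violated the expected dialect or an internal consistency rule."""


@dataclass
class SummaryStats:
    """Per-SNP association records for one trait.

    ``table`` holds columns ``snp_id, chrom, pos, a1, a2, z, p, n, maf``
    (``z``/``p``/``maf`` may be NaN when absent from the source file).
    ``n_dropped`` counts rows removed by row-level validation on read.
    """

    table: pd.DataFrame
    n_dropped: int = 0

    def __len__(self) -> int:
        return len(self.table)

    @property
    def z(self) -> np.ndarray:
        return self.table["z"].to_numpy(float)

    @property
    def p(self) -> np.ndarray:
        return self.table["p"].to_numpy(float)

    @property
    def n(self) -> np.ndarray:
        return self.table["n"].to_numpy(float)


@dataclass(frozen=True)
class GeneModel:
    """One gene interval: 1-based, closed ``[start, end]`` on ``chrom``."""

    gene_id: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise FormatError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.start < 1:
            raise FormatError(f"gene {self.gene_id}: start {self.start} < 1")


@dataclass
class GeneAnnotation:
    """Mapping gene_id -> ordered SNP row indices into a SummaryStats table."""

    mapping: dict[str, np.ndarray]
    window_kb: float
    n_genes_unmapped: int = 0

    def __len__(self) -> int:
        return len(self.mapping)


@dataclass
class GeneSetCollection:
    """Named gene sets read from a GMT file, preserved in file order."""

    collection_name: str
    sets: dict[str, list[str]]
    source: str = ""
    descriptions: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def sizes(self) -> dict[str, int]:
        return {sid: len(genes) for sid, genes in self.sets.items()}


def _two_sided_p_from_z(z: np.ndarray) -> np.ndarray:
    return 2.0 * stats.norm.sf(np.abs(z))


def read_sumstats(
    path,
    dialect: dict[str, str] | None = None,
    n: float | None = None,
    sep: str = "\t",
) -> SummaryStats:
    """Read a summary-statistics table, validating rows as it goes.

    Parameters
    ----------
    path
        Delimited text file with a header row.
    dialect
        Mapping from internal field names (``snp_id``, ``chrom``, ``pos``,
        ``a1``, ``a2``, ``z``, ``p``, ``n``, ``maf``) to the column names
        used in the file.  Defaults to :data:`DEFAULT_DIALECT`.
    n
        Study-wide sample size, used when the file has no N column.

    Rows failing validation (p outside (0,1], non-positive N, position < 1)
    are dropped and counted in ``n_dropped``.  A table carrying both Z and P
    must have them mutually consistent (two-sided p = 2*Phi(-|z|) within
    1e-6 relative); the first offending SNP is named in the error.  P-only
    tables are admitted with z marked absent — a sign cannot be inferred
    from a two-sided p-value.
    """
    dialect = {**DEFAULT_DIALECT, **(dialect or {})}
    df = pd.read_csv(path, sep=sep, dtype={dialect["chrom"]: str})

    mandatory = ["snp_id", "chrom", "pos", "a1", "a2"]
    for fieldname in mandatory:
        if dialect[fieldname] not in df.columns:
            raise FormatError(
                f"{path}: missing mandatory column {dialect[fieldname]!r} "
                f"(field {fieldname})"
            )
    has_z = dialect["z"] in df.columns
    has_p = dialect["p"] in df.columns
    if not has_z and not has_p:
        raise FormatError(f"{path}: need at least one of columns "
                          f"{dialect['z']!r} (Z) or {dialect['p']!r} (P)")
    has_n = dialect["n"] in df.columns
    if not has_n and n is None:
        raise FormatError(f"{path}: no column {dialect['n']!r} and no "
                          "study-wide n= provided")

    out = pd.DataFrame(
        {
            "snp_id": df[dialect["snp_id"]].astype(str),
            "chrom": df[dialect["chrom"]].astype(str),
            "pos": pd.to_numeric(df[dialect["pos"]]).astype(np.int64),
            "a1": df[dialect["a1"]].astype(str),
            "a2": df[dialect["a2"]].astype(str),
        }
    )
    out["z"] = pd.to_numeric(df[dialect["z"]]) if has_z else np.nan
    out["p"] = pd.to_numeric(df[dialect["p"]]) if has_p else np.nan
    out["n"] = pd.to_numeric(df[dialect["n"]]) if has_n else float(n)
    out["maf"] = (
        pd.to_numeric(df[dialect["maf"]])
        if dialect["maf"] in df.columns
        else np.nan
    )

    dupes = out["snp_id"][out["snp_id"].duplicated()]
    if len(dupes):
        raise FormatError(f"{path}: duplicate snp_id {dupes.iloc[0]!r}")

    # Z/P cross-check happens before row dropping so an inconsistent source
    # table is an error, not a silent shrinkage.
    if has_z and has_p:
        both = out["z"].notna() & out["p"].notna() & (out["p"] > 0)
        if both.any():
            expect = _two_sided_p_from_z(out.loc[both, "z"].to_numpy())
            got = out.loc[both, "p"].to_numpy()
            rel = np.abs(got - expect) / np.maximum(expect, 1e-300)
            bad = rel > _ZP_RTOL
            if bad.any():
                first = out.loc[both, "snp_id"].to_numpy()[bad][0]
                raise FormatError(
                    f"{path}: Z and P disagree beyond {_ZP_RTOL:g} relative; "
                    f"first offending snp_id {first!r}"
                )

    keep = (out["pos"] >= 1) & (out["n"] > 0)
    if has_p:
        keep &= out["p"].isna() | ((out["p"] > 0) & (out["p"] <= 1))
    if out["maf"].notna().any():
        keep &= out["maf"].isna() | ((out["maf"] >= 0) & (out["maf"] <= 0.5))
    n_dropped = int((~keep).sum())
    out = out.loc[keep].reset_index(drop=True)
    if len(out) == 0:
        raise FormatError(f"{path}: no rows survived validation")
    return SummaryStats(table=out, n_dropped=n_dropped)


def write_sumstats(ss: SummaryStats, path, sep: str = "\t") -> None:
    """Write in the default dialect; full float precision for round-trips."""
    df = ss.table.rename(
        columns={k: v for k, v in DEFAULT_DIALECT.items()}
    )
    df.to_csv(path, sep=sep, index=False, float_format="%.17g")


def read_gene_loc(path, autosomes_only: bool = True):
    """Read a 4+ column gene location table (id, chrom, start, end).

    Returns ``(genes, n_excluded)`` where ``n_excluded`` counts
    non-autosomal genes removed when ``autosomes_only``.
    """
    df = pd.read_csv(
        path,
        sep=r"\s+",
        header=None,
        comment="#",
        dtype={1: str},
        usecols=[0, 1, 2, 3],
        names=["gene_id", "chrom", "start", "end"],
    )
    dupes = df["gene_id"][df["gene_id"].duplicated()]
    if len(dupes):
        raise FormatError(f"{path}: duplicate gene_id {dupes.iloc[0]!r}")
    n_excluded = 0
    if autosomes_only:
        chrom = df["chrom"].str.removeprefix("chr")
        keep = chrom.isin(AUTOSOMES)
        n_excluded = int((~keep).sum())
        df = df.loc[keep]
    genes = [
        GeneModel(r.gene_id, str(r.chrom).removeprefix("chr"),
                  int(r.start), int(r.end))
        for r in df.itertuples(index=False)
    ]
    return genes, n_excluded


def write_gene_loc(genes, path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.start}\t{g.end}\n")


def map_snps_to_genes(
    ss: SummaryStats, genes, window_kb: float = 0.0
) -> GeneAnnotation:
    """Assign SNPs to genes by position with a symmetric flanking window.

    SNP *j* belongs to gene *g* iff the chromosomes match and
    ``start - w <= pos_j <= end + w`` with ``w = window_kb * 1000`` (closed
    interval on both sides).  A SNP may land in several genes.  Genes with no
    SNP are left out of the mapping and counted in ``n_genes_unmapped``.
    The default window is 0 kb and is recorded on the annotation.
    """
    if window_kb < 0:
        raise ValueError("window_kb must be non-negative")
    w = int(round(window_kb * 1000))
    pos = ss.table["pos"].to_numpy()
    chrom = ss.table["chrom"].to_numpy()

    # Group SNPs per chromosome once; per gene a sorted-position bisect.
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for c in np.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        order = np.argsort(pos[idx], kind="stable")
        by_chrom[str(c)] = (pos[idx][order], idx[order])

    mapping: dict[str, np.ndarray] = {}
    unmapped = 0
    for g in genes:
        entry = by_chrom.get(g.chrom)
        if entry is None:
            unmapped += 1
            continue
        cpos, cidx = entry
        lo = np.searchsorted(cpos, g.start - w, side="left")
        hi = np.searchsorted(cpos, g.end + w, side="right")
        if hi > lo:
            hit = np.sort(cidx[lo:hi])
            mapping[g.gene_id] = hit
        else:
            unmapped += 1
    return GeneAnnotation(mapping=mapping, window_kb=window_kb,
                          n_genes_unmapped=unmapped)


def read_gmt(path, collection_name: str | None = None) -> GeneSetCollection:
    """Read a standard GMT file: set_id <tab> description <tab> genes...

    Sets are preserved in file order; duplicate genes within a set are
    deduplicated (first occurrence kept).
    """
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, "
                    "need at least 3 (set_id, description, >=1 gene)"
                )
            set_id, desc, *genes = fields
            seen: dict[str, None] = {}
            for g in genes:
                if g:
                    seen.setdefault(g)
            sets[set_id] = list(seen)
            descriptions[set_id] = desc
    if not sets:
        raise FormatError(f"{path}: empty GMT collection")
    name = collection_name or str(path)
    return GeneSetCollection(collection_name=name, sets=sets,
                             source=str(path), descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for sid, genes in collection.sets.items():
            desc = collection.descriptions.get(sid, "na")
            fh.write("\t".join([sid, desc, *genes]) + "\n")


def read_ld_scores(path) -> pd.DataFrame:
    """Read a two-column LD score table (snp_id, ldscore)."""
    df = pd.read_csv(path, sep="\t")
    if not {"snp_id", "ldscore"}.issubset(df.columns):
        raise FormatError(f"{path}: need columns snp_id, ldscore")
    return df


def write_ld_scores(snp_ids, ldscores, path) -> None:
    pd.DataFrame({"snp_id": snp_ids, "ldscore": ldscores}).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def align_snp_panels(ss1: SummaryStats, ss2: SummaryStats):
    """Check two tables share an identical SNP panel and allele orientation.

    Returns the shared (validated) snp_id array.  Any difference in id set,
    order, or a1/a2 assignment is an error naming the first mismatch — a
    silent allele flip would corrupt every signed cross-trait statistic.
    """
    t1, t2 = ss1.table, ss2.table
    if len(t1) != len(t2):
        raise FormatError(
            f"SNP panels differ in size: {len(t1)} vs {len(t2)}"
        )
    ids1 = t1["snp_id"].to_numpy()
    ids2 = t2["snp_id"].to_numpy()
    neq = ids1 != ids2
    if neq.any():
        i = int(np.flatnonzero(neq)[0])
        raise FormatError(
            f"SNP panel mismatch at row {i}: {ids1[i]!r} vs {ids2[i]!r}"
        )
    for col in ("a1", "a2"):
        neq = t1[col].to_numpy() != t2[col].to_numpy()
        if neq.any():
            i = int(np.flatnonzero(neq)[0])
            raise FormatError(
                f"allele orientation mismatch ({col}) at snp "
                f"{ids1[i]!r}: {t1[col].iloc[i]!r} vs {t2[col].iloc[i]!r}"
            )
    return ids1
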