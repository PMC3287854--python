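"""Synthetic founder genotypes emulating a rare-variant exome panel.

The simulated exome consists of ~24.5k autosomal biallelic SNPs assigned to
~3.2k genes, with an allele-frequency spectrum dominated by rare variation:
38.4% of sites are private (one minor-allele copy in the sample), 74% have
MAF <= 0.01, only 12.8% have MAF >= 0.05, and the median MAF is ~0.002
(three copies in 697 diploids).  This module draws target MAFs from that
spectrum, generates fully phased founder haplotypes (no missing data),
derives 0/1/2 dosage matrices, computes folded observed MAFs and binned
spectrum summaries, assigns markers to genes by the first intersecting
interval, and reads/writes VCF and marker-map TSV.

Markers are labelled ``C<chrom>S<index>``; for maps the generator names
itself the S-index is the marker's rank on its chromosome.  Functional
variants from an effect table are injected under their verbatim labels at
their reference MAFs (private ones with exactly the implied single copy);
to keep labels unique the generator's own ranks are offset above the
injected indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .effect_model import EffectTable, FunctionalVariant

__all__ = [
    "MarkerMap",
    "HaplotypePanel",
    "GenotypeMatrix",
    "MafSpectrum",
    "DEFAULT_SPECTRUM",
    "sample_maf_spectrum",
    "generate_founder_haplotypes",
    "compute_maf",
    "spectrum_summary",
    "figure_bin_edges",
    "assign_snps_to_genes",
    "synthesize_marker_map",
    "synthesize_panel",
    "write_vcf",
    "read_vcf",
]

N_MARKERS_DEFAULT = 24_487
N_GENES_DEFAULT = 3_205
N_AUTOSOMES = 22
# per-gene SNP-count target moments (mean 7.64, SD 14.00, max 231)
GENE_SIZE_MEAN = 7.64
GENE_SIZE_SD = 14.00
GENE_SIZE_MAX = 231
# synthetic S-indices start above any injected functional label index
_SYNTH_RANK_OFFSET = 20_000


# --------------------------------------------------------------------------
# Marker map
# --------------------------------------------------------------------------

@dataclass
class MarkerMap:
    """Per-marker metadata: label, chromosome, bp position, gene (or None).

    Positions are 1-based and strictly increasing within a chromosome; rows
    are sorted by (chrom, pos).
    """

    df: pd.DataFrame  # columns snp_id, chrom, pos, gene

    def __post_init__(self) -> None:
        required = ["snp_id", "chrom", "pos", "gene"]
        missing = [c for c in required if c not in self.df.columns]
        if missing:
            raise ValueError(f"MarkerMap missing columns {missing}")
        self.df = self.df.reset_index(drop=True)
        if self.df["snp_id"].duplicated().any():
            dupes = self.df.loc[self.df["snp_id"].duplicated(), "snp_id"].tolist()
            raise ValueError(f"duplicate snp_ids in map: {dupes[:5]}")
        for chrom, grp in self.df.groupby("chrom"):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on chrom {chrom}")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def snp_ids(self) -> np.ndarray:
        return self.df["snp_id"].to_numpy()

    @property
    def chroms(self) -> np.ndarray:
        return self.df["chrom"].to_numpy()

    @property
    def positions(self) -> np.ndarray:
        return self.df["pos"].to_numpy()

    def index_of(self, snp_ids: Sequence[str]) -> np.ndarray:
        """Row indices of the given labels; raises listing absent ones."""
        lookup = {s: i for i, s in enumerate(self.df["snp_id"])}
        missing = [s for s in snp_ids if s not in lookup]
        if missing:
            raise KeyError(f"markers absent from map: {missing}")
        return np.array([lookup[s] for s in snp_ids], dtype=int)

    def chrom_extent(self, chrom: int) -> tuple[int, int]:
        grp = self.df[self.df["chrom"] == chrom]
        if grp.empty:
            raise ValueError(f"no markers on chrom {chrom}")
        return int(grp["pos"].min()), int(grp["pos"].max())

    def to_tsv(self, path: str | Path) -> None:
        out = self.df[["chrom", "pos", "snp_id", "gene"]].copy()
        out["gene"] = out["gene"].fillna(".")
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MarkerMap":
        df = pd.read_csv(path, sep="\t")
        df["gene"] = df["gene"].replace(".", np.nan)
        return cls(df[["snp_id", "chrom", "pos", "gene"]])


# --------------------------------------------------------------------------
# Panels and dosage matrices
# --------------------------------------------------------------------------

@dataclass
class HaplotypePanel:
    """Phased haplotypes: array (2*n_individuals, n_markers) of 0/1 alleles.

    Row 2i / 2i+1 are the two haplotypes of individual i; allele 1 is the
    minor allele.  No missing data.
    """

    haplotypes: np.ndarray
    map: MarkerMap
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        if self.haplotypes.ndim != 2 or self.haplotypes.shape[0] % 2:
            raise ValueError("haplotypes must be (2*n_individuals, n_markers)")
        if self.haplotypes.shape[1] != len(self.map):
            raise ValueError("haplotype column count != marker count")
        if not np.isin(self.haplotypes, [0, 1]).all():
            raise ValueError("alleles must be 0 (major) or 1 (minor)")
        if not self.sample_ids:
            self.sample_ids = [f"U{i+1:04d}" for i in range(self.n_individuals)]

    @property
    def n_individuals(self) -> int:
        return self.haplotypes.shape[0] // 2

    def to_dosage(self) -> "GenotypeMatrix":
        d = self.haplotypes[0::2] + self.haplotypes[1::2]
        return GenotypeMatrix(d, self.map, list(self.sample_ids))

    def subset_individuals(self, idx: Sequence[int],
                           sample_ids: Sequence[str] | None = None) -> "HaplotypePanel":
        idx = np.asarray(idx, dtype=int)
        rows = np.ravel(np.column_stack([2 * idx, 2 * idx + 1]))
        sids = list(sample_ids) if sample_ids is not None else [
            self.sample_ids[i] for i in idx
        ]
        return HaplotypePanel(self.haplotypes[rows], self.map, sids)


@dataclass
class GenotypeMatrix:
    """Minor-allele dosage matrix (individuals x markers), entries 0/1/2."""

    dosage: np.ndarray
    map: MarkerMap
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.ndim != 2:
            raise ValueError("dosage must be 2-D (individuals x markers)")
        if self.dosage.shape[1] != len(self.map):
            raise ValueError("dosage column count != marker count")
        if not np.isin(self.dosage, [0, 1, 2]).all():
            raise ValueError("dosages must be 0, 1 or 2")
        if not self.sample_ids:
            self.sample_ids = [f"U{i+1:04d}" for i in range(self.n_individuals)]

    @property
    def n_individuals(self) -> int:
        return self.dosage.shape[0]

    def dosages_for(self, snp_ids: Sequence[str]) -> np.ndarray:
        return self.dosage[:, self.map.index_of(snp_ids)]


# --------------------------------------------------------------------------
# MAF spectrum
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class MafSpectrum:
    """Target allele-frequency spectrum.

    ``private_fraction`` of markers are private (MAF = 1/(2n)); the rest
    fall into ``bins`` = (low, high, probability) with probabilities summing
    to 1 over the non-private mass.  Within a bin whose upper edge is
    <= ``copy_sampling_below``, MAFs are drawn as discrete allele counts
    k/(2n) with weights proportional to 1/k (a heavy rare tail that puts the
    sample median near three copies); other bins are log-uniform.
    """

    private_fraction: float = 0.384
    bins: tuple[tuple[float, float, float], ...] = (
        (0.0, 0.01, 0.578),
        (0.01, 0.05, 0.214),
        (0.05, 0.5, 0.208),
    )
    copy_sampling_below: float = 0.01

    def validate(self) -> None:
        probs = np.array([b[2] for b in self.bins], dtype=float)
        if np.any(probs < 0):
            raise ValueError("negative bin probability in MAF spectrum")
        if not np.isclose(probs.sum(), 1.0):
            raise ValueError(f"bin probabilities sum to {probs.sum()}, expected 1")
        if not (0.0 <= self.private_fraction <= 1.0):
            raise ValueError("private_fraction outside [0, 1]")


#: spectrum matching the reported site-frequency summary (38.4% private,
#: 74% <= 0.01 overall, 12.8% >= 0.05 overall).
DEFAULT_SPECTRUM = MafSpectrum()


def sample_maf_spectrum(
    n_snps: int,
    n_individuals: int,
    spectrum: MafSpectrum = DEFAULT_SPECTRUM,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Draw target MAFs for ``n_snps`` markers in a sample of diploids.

    Private markers receive MAF exactly ``1/(2*n_individuals)``.
    """
    spectrum.validate()
    if n_individuals <= 0:
        raise ValueError("n_individuals must be > 0")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if n_snps == 0:
        return np.empty(0, dtype=float)
    two_n = 2 * n_individuals
    private_maf = 1.0 / two_n

    is_private = rng.random(n_snps) < spectrum.private_fraction
    mafs = np.full(n_snps, private_maf, dtype=float)

    n_rest = int((~is_private).sum())
    if n_rest:
        probs = np.array([b[2] for b in spectrum.bins])
        which = rng.choice(len(spectrum.bins), size=n_rest, p=probs)
        vals = np.empty(n_rest, dtype=float)
        for b, (lo, hi, _p) in enumerate(spectrum.bins):
            m = which == b
            k = int(m.sum())
            if not k:
                continue
            if hi <= spectrum.copy_sampling_below:
                k_lo = max(2, int(np.ceil(lo * two_n + 1e-9)))
                k_hi = max(k_lo, int(np.floor(hi * two_n)))
                counts = np.arange(k_lo, k_hi + 1)
                w = 1.0 / counts
                vals[m] = rng.choice(counts, size=k, p=w / w.sum()) / two_n
            else:
                lo_eff = max(lo, private_maf * 2)
                vals[m] = np.exp(rng.uniform(np.log(lo_eff), np.log(hi), size=k))
        mafs[~is_private] = vals
    return mafs


# --------------------------------------------------------------------------
# Founder haplotypes
# --------------------------------------------------------------------------

def generate_founder_haplotypes(
    mafs: Sequence[float],
    n_individuals: int,
    marker_map: MarkerMap,
    seed: int | np.random.Generator = 0,
) -> HaplotypePanel:
    """Draw a phased panel hitting the target MAFs.

    Markers whose target MAF equals 1/(2n) (private) carry exactly one
    minor-allele copy, placed on a uniformly chosen haplotype.  All other
    markers get independent per-haplotype Bernoulli(maf) draws.
    """
    mafs = np.asarray(mafs, dtype=float)
    if len(mafs) != len(marker_map):
        raise ValueError(
            f"{len(mafs)} MAFs for {len(marker_map)} markers in map"
        )
    if np.any((mafs <= 0) | (mafs > 0.5)):
        bad = np.flatnonzero((mafs <= 0) | (mafs > 0.5))[:5]
        raise ValueError(f"MAF outside (0, 0.5] at marker indices {bad.tolist()}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n_hap = 2 * n_individuals
    private_maf = 1.0 / n_hap
    # printed MAFs are rounded; anything within half a copy of 1/(2n) is
    # treated as private
    is_private = np.abs(mafs - private_maf) < 0.5 / n_hap

    hap = (rng.random((n_hap, len(mafs))) < mafs[None, :]).astype(np.int8)
    priv_cols = np.flatnonzero(is_private)
    if priv_cols.size:
        hap[:, priv_cols] = 0
        carriers = rng.integers(0, n_hap, size=priv_cols.size)
        hap[carriers, priv_cols] = 1
    return HaplotypePanel(hap, marker_map)


# --------------------------------------------------------------------------
# Observed MAF and spectrum summary
# --------------------------------------------------------------------------

def compute_maf(g: GenotypeMatrix) -> np.ndarray:
    """Observed per-marker MAF, folded so the result never exceeds 0.5."""
    if g.n_individuals == 0:
        raise ValueError("empty genotype matrix")
    freq = g.dosage.mean(axis=0) / 2.0
    return np.minimum(freq, 1.0 - freq)


def figure_bin_edges() -> np.ndarray:
    """Uneven MAF histogram edges: 0.5% steps below 0.01, 1% steps to 0.05,
    5% steps to 0.5.  Bins are half-open, closed on the left."""
    return np.concatenate(
        [np.arange(0.0, 0.01, 0.005),
         np.arange(0.01, 0.05, 0.01),
         np.arange(0.05, 0.5001, 0.05)]
    )


def spectrum_summary(mafs: Sequence[float]) -> dict:
    """Binned counts on the uneven grid plus the median over segregating sites.

    Monomorphic markers (MAF 0) are excluded from the median, mirroring a
    summary computed over sites present in at least one copy.
    """
    mafs = np.asarray(mafs, dtype=float)
    edges = figure_bin_edges()
    if mafs.size:
        idx = np.searchsorted(edges, mafs, side="right") - 1
        idx = np.clip(idx, 0, len(edges) - 1)
        counts = np.bincount(idx, minlength=len(edges))
    else:
        counts = np.zeros(len(edges), dtype=int)
    nonzero = mafs[mafs > 0]
    return {
        "bin_edges": edges,
        "counts": counts,
        "median_maf": float(np.median(nonzero)) if nonzero.size else float("nan"),
        "n_markers": int(mafs.size),
    }


# --------------------------------------------------------------------------
# Gene assignment
# --------------------------------------------------------------------------

def assign_snps_to_genes(marker_map: MarkerMap, genes: pd.DataFrame) -> MarkerMap:
    """Assign each marker to the FIRST listed gene interval containing it.

    ``genes`` has columns (gene, chrom, start, end), intervals 1-based and
    inclusive on both ends.  Markers contained in no interval keep gene=None;
    markers overlapping several genes get only the first by table order.
    """
    df = marker_map.df.copy()
    assigned = df["gene"].notna().to_numpy()
    assigned[:] = False
    gene_col = np.full(len(df), None, dtype=object)
    chrom = df["chrom"].to_numpy()
    pos = df["pos"].to_numpy()
    for row in genes.itertuples(index=False):
        m = (~assigned) & (chrom == row.chrom) & (pos >= row.start) & (pos <= row.end)
        if m.any():
            gene_col[m] = row.gene
            assigned |= m
    df["gene"] = gene_col
    return MarkerMap(df)


# --------------------------------------------------------------------------
# Full synthetic map + panel
# --------------------------------------------------------------------------

def _gene_sizes(n_genes: int, n_snps: int, rng: np.random.Generator) -> np.ndarray:
    """Per-gene SNP counts: truncated negative binomial targeting mean 7.64,
    SD 14.0, support [1, 231], adjusted to sum exactly to n_snps."""
    mu, var = GENE_SIZE_MEAN, GENE_SIZE_SD ** 2
    r = mu * mu / (var - mu)          # overdispersion
    p = r / (r + mu)
    sizes = np.empty(n_genes, dtype=int)
    filled = 0
    while filled < n_genes:
        draw = rng.negative_binomial(r, p, size=2 * (n_genes - filled))
        draw = draw[(draw >= 1) & (draw <= GENE_SIZE_MAX)]
        take = min(draw.size, n_genes - filled)
        sizes[filled:filled + take] = draw[:take]
        filled += take
    # nudge random genes +-1 until the total matches exactly
    diff = n_snps - int(sizes.sum())
    step = 1 if diff > 0 else -1
    while diff != 0:
        i = rng.integers(0, n_genes)
        new = sizes[i] + step
        if 1 <= new <= GENE_SIZE_MAX:
            sizes[i] = new
            diff -= step
    return sizes


def _functional_by_chrom(tables: Iterable[EffectTable]) -> dict[int, list[FunctionalVariant]]:
    by_gene: dict[str, dict[str, FunctionalVariant]] = {}
    for t in tables:
        for v in t.variants:
            by_gene.setdefault(v.gene, {})[v.snp_id] = v
    out: dict[int, list[FunctionalVariant]] = {}
    for gene, vs in by_gene.items():
        chroms = {v.chrom for v in vs.values()}
        assert len(chroms) == 1, f"gene {gene} spans chromosomes {chroms}"
        out.setdefault(chroms.pop(), []).extend(
            sorted(vs.values(), key=lambda v: v.s_index)
        )
    return out


def synthesize_marker_map(
    n_snps: int = N_MARKERS_DEFAULT,
    n_genes: int = N_GENES_DEFAULT,
    effect_tables: Sequence[EffectTable] = (),
    seed: int | np.random.Generator = 0,
    marker_spacing: tuple[int, int] = (100, 5_000),
    gene_gap: tuple[int, int] = (10_000, 200_000),
) -> tuple[MarkerMap, pd.DataFrame, np.ndarray]:
    """Build a synthetic exome map: genes laid along 22 autosomes, markers
    at increasing positions inside gene spans.

    Functional variants from ``effect_tables`` are injected under their
    verbatim labels, grouped into their genes on their own chromosomes and
    ordered by label index.  Purely synthetic markers are labelled by
    within-chromosome rank (offset above the injected indices when tables
    are present, so labels stay unique).

    Returns (map, gene interval table, target MAF slots for functional
    markers as a boolean mask aligned with the map).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    func_by_chrom = _functional_by_chrom(effect_tables)
    func_genes: dict[str, list[FunctionalVariant]] = {}
    for vs in func_by_chrom.values():
        for v in vs:
            func_genes.setdefault(v.gene, []).append(v)
    n_func_genes = len(func_genes)
    if n_genes < n_func_genes:
        raise ValueError(f"n_genes={n_genes} < {n_func_genes} functional genes")

    sizes = np.sort(_gene_sizes(n_genes, n_snps, rng))
    used = np.zeros(n_genes, dtype=bool)

    # functional genes first claim the smallest size covering their variant
    # count (best fit keeps the total marker count exact); synthetic genes
    # then take the remaining sizes in random order.
    final: list[tuple[str, int, int]] = []  # (name, chrom, n snps)
    for gene, vs in sorted(func_genes.items()):
        j = int(np.searchsorted(sizes, len(vs)))
        while j < n_genes and used[j]:
            j += 1
        if j == n_genes:  # no size big enough: grow the largest unused one
            j = int(np.flatnonzero(~used)[-1])
            sizes[j] = len(vs)
        used[j] = True
        final.append((gene, vs[0].chrom, int(sizes[j])))
    remaining = sizes[~used]
    rng.shuffle(remaining)
    synth_chroms = rng.integers(1, N_AUTOSOMES + 1, size=remaining.size)
    for i, (s, chrom) in enumerate(zip(remaining, synth_chroms)):
        final.append((f"G{i+1:04d}", int(chrom), int(s)))

    # lay out genes chromosome by chromosome, in order of appearance
    rows = []
    gene_rows = []
    for chrom in range(1, N_AUTOSOMES + 1):
        pos = int(rng.integers(50_000, 150_000))
        rank = 0
        chrom_genes = [g for g in final if g[1] == chrom]
        # keep functional genes ordered by their smallest label index
        def sort_key(rec):
            name = rec[0]
            if name in func_genes:
                return (0, func_genes[name][0].s_index)
            return (1, rng.integers(0, 1 << 30))
        chrom_genes.sort(key=sort_key)
        for name, _, size in chrom_genes:
            start = pos
            fvs = func_genes.get(name, [])
            labels: list[str | None] = [None] * size
            # spread the functional variants across the gene's marker slots
            if fvs:
                slots = np.linspace(0, size - 1, num=len(fvs)).round().astype(int)
                slots = np.unique(slots)
                while len(slots) < len(fvs):  # collisions at tiny sizes
                    extra = [s for s in range(size) if s not in slots]
                    slots = np.sort(np.append(slots, extra[: len(fvs) - len(slots)]))
                for s, v in zip(slots, fvs):
                    labels[int(s)] = v.snp_id
            for k in range(size):
                pos += int(rng.integers(*marker_spacing))
                rank += 1
                if labels[k] is not None:
                    snp_id = labels[k]
                else:
                    off = _SYNTH_RANK_OFFSET if func_genes else 0
                    snp_id = f"C{chrom}S{off + rank}"
                rows.append((snp_id, chrom, pos, name))
            gene_rows.append((name, chrom, start + 1, pos))
            pos += int(rng.integers(*gene_gap))

    map_df = pd.DataFrame(rows, columns=["snp_id", "chrom", "pos", "gene"])
    genes_df = pd.DataFrame(gene_rows, columns=["gene", "chrom", "start", "end"])
    marker_map = MarkerMap(map_df)
    func_ids = {v.snp_id for vs in func_genes.values() for v in vs}
    is_functional = map_df["snp_id"].isin(func_ids).to_numpy()
    return marker_map, genes_df, is_functional


def synthesize_panel(
    n_individuals: int = 697,
    n_snps: int = N_MARKERS_DEFAULT,
    n_genes: int = N_GENES_DEFAULT,
    effect_tables: Sequence[EffectTable] = (),
    spectrum: MafSpectrum = DEFAULT_SPECTRUM,
    seed: int | np.random.Generator = 0,
) -> tuple[HaplotypePanel, pd.DataFrame]:
    """One-call founder panel: map + spectrum + haplotypes.

    Functional markers take their reference MAFs from the effect tables
    (private ones get exactly one copy via the private rule); all other
    markers draw from ``spectrum``.  Returns (panel, gene interval table).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    marker_map, genes_df, _ = synthesize_marker_map(
        n_snps=n_snps, n_genes=n_genes, effect_tables=effect_tables, seed=rng
    )
    mafs = sample_maf_spectrum(len(marker_map), n_individuals, spectrum, seed=rng)
    maf_by_id = {
        v.snp_id: v.maf_ref for t in effect_tables for v in t.variants
    }
    if maf_by_id:
        ids = marker_map.snp_ids
        for i, s in enumerate(ids):
            if s in maf_by_id:
                mafs[i] = maf_by_id[s]
    panel = generate_founder_haplotypes(mafs, n_individuals, marker_map, seed=rng)
    return panel, genes_df


def functional_only_map(
    effect_tables: Sequence[EffectTable],
) -> tuple[MarkerMap, pd.DataFrame]:
    """Minimal map holding exactly the functional variants (deduplicated
    across tables), positioned by label index; used when only the
    trait-driving markers are needed (validation, estimator checks).

    Returns (map, gene interval table with 1-based inclusive bounds).
    """
    func_by_chrom = _functional_by_chrom(effect_tables)
    rows = []
    for chrom in sorted(func_by_chrom):
        for v in sorted(func_by_chrom[chrom], key=lambda v: v.s_index):
            rows.append((v.snp_id, chrom, v.s_index * 1_000, v.gene))
    df = pd.DataFrame(rows, columns=["snp_id", "chrom", "pos", "gene"])
    gene_rows = [
        (gene, grp["chrom"].iloc[0], int(grp["pos"].min()) - 500,
         int(grp["pos"].max()) + 500)
        for gene, grp in df.groupby("gene", sort=False)
    ]
    genes_df = pd.DataFrame(gene_rows, columns=["gene", "chrom", "start", "end"])
    return MarkerMap(df), genes_df


def functional_mafs(marker_map: MarkerMap,
                    effect_tables: Sequence[EffectTable]) -> np.ndarray:
    """Target MAF vector for a map, taking reference MAFs from the tables
    for functional markers (others must already be absent)."""
    maf_by_id = {v.snp_id: v.maf_ref for t in effect_tables for v in t.variants}
    return np.array([maf_by_id[s] for s in marker_map.snp_ids])


# --------------------------------------------------------------------------
# VCF I/O
# --------------------------------------------------------------------------

_VCF_HEADER = """##fileformat=VCFv4.2
##source=miniexome
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""


def write_vcf(
    data: HaplotypePanel | GenotypeMatrix,
    path: str | Path,
) -> None:
    """Write a panel (phased, ``|``) or dosage matrix (unphased, ``/``) as
    uncompressed VCF v4.2 with a GT-only FORMAT."""
    phased = isinstance(data, HaplotypePanel)
    m = data.map
    sample_ids = data.sample_ids
    if phased:
        a0 = data.haplotypes[0::2]
        a1 = data.haplotypes[1::2]
    else:
        d = data.dosage
    sep = "|" if phased else "/"
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_VCF_HEADER)
        for chrom in sorted(m.df["chrom"].unique()):
            hi = m.chrom_extent(int(chrom))[1]
            fh.write(f"##contig=<ID={chrom},length={hi + 1}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(sample_ids) + "\n")
        chroms = m.chroms
        poss = m.positions
        ids = m.snp_ids
        for j in range(len(m)):
            if phased:
                gts = [f"{a0[i, j]}{sep}{a1[i, j]}" for i in range(len(sample_ids))]
            else:
                gts = [("0/0", "0/1", "1/1")[d[i, j]] for i in range(len(sample_ids))]
            fh.write(
                f"{chroms[j]}\t{poss[j]}\t{ids[j]}\tA\tG\t.\t.\t.\tGT\t"
                + "\t".join(gts) + "\n"
            )


def read_vcf(path: str | Path, gene_map: MarkerMap | None = None):
    """Read a VCF; returns a HaplotypePanel if all genotypes are phased,
    else a GenotypeMatrix.  Gene labels are taken from ``gene_map`` when
    given (matched on snp_id), otherwise left unset."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    rows, a0s, a1s, phased_all = [], [], [], True
    for var in vcf:
        gts = np.array([g[:3] for g in var.genotypes])  # (n, 3): a0, a1, phased
        a0s.append(gts[:, 0])
        a1s.append(gts[:, 1])
        phased_all = phased_all and bool(gts[:, 2].all())
        rows.append((var.ID, int(var.CHROM), var.POS, None))
    df = pd.DataFrame(rows, columns=["snp_id", "chrom", "pos", "gene"])
    if gene_map is not None:
        gene_lookup = dict(zip(gene_map.df["snp_id"], gene_map.df["gene"]))
        df["gene"] = df["snp_id"].map(gene_lookup)
    m = MarkerMap(df)
    a0 = np.array(a0s, dtype=np.int8).T
    a1 = np.array(a1s, dtype=np.int8).T
    if phased_all:
        hap = np.empty((2 * a0.shape[0], a0.shape[1]), dtype=np.int8)
        hap[0::2] = a0
        hap[1::2] = a1
        return HaplotypePanel(hap, m, sample_ids)
    return GenotypeMatrix(a0 + a1, m, sample_ids)
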