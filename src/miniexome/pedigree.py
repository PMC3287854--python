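"""Extended-pedigree sampling design: family generation, kinship,
gene-dropping with recombination, and per-gene IBD matrices.

The family design places the same number of individuals as the unrelated
design (default 697) into a small number of large four-generation pedigrees
(default 8) whose founders (default 202) receive phased haplotypes drawn
from the unrelated panel.  Haplotypes descend through the pedigree meiosis
by meiosis; each meiosis recombines with a single obligate crossover per
chromosome at a uniformly drawn base-pair position.  Because every founder
haplotype carries a unique label, allele sharing identical by descent is
known exactly at any locus ("fully informative markers"); per-gene IBD
matrices read each individual's two founder labels at the gene midpoint, so
a gene is inherited atomically even if a crossover falls inside its span.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genotype_synth import GenotypeMatrix, HaplotypePanel, MarkerMap

__all__ = [
    "Member",
    "Pedigree",
    "KinshipMatrix",
    "InheritanceVectors",
    "IBDMatrix",
    "PedigreeError",
    "generate_pedigree_set",
    "kinship",
    "gene_drop",
    "ibd_matrices",
    "write_ped",
    "read_ped",
]


class PedigreeError(ValueError):
    """Invalid or infeasible pedigree specification."""


@dataclass(frozen=True)
class Member:
    person_id: str
    family_id: str
    father_id: str | None
    mother_id: str | None
    sex: str  # 'M' or 'F'

    @property
    def is_founder(self) -> bool:
        return self.father_id is None and self.mother_id is None


@dataclass
class Pedigree:
    """Members listed with parents before children (topological order).

    Every non-founder has both parents present; fathers are male, mothers
    female; no cycles (guaranteed by the ordering check).
    """

    members: list[Member]

    def __post_init__(self) -> None:
        seen: dict[str, Member] = {}
        for m in self.members:
            if m.person_id in seen:
                raise PedigreeError(f"duplicate person_id {m.person_id}")
            if (m.father_id is None) != (m.mother_id is None):
                raise PedigreeError(
                    f"{m.person_id}: must have both parents or neither"
                )
            if m.father_id is not None:
                for pid, want in ((m.father_id, "M"), (m.mother_id, "F")):
                    if pid not in seen:
                        raise PedigreeError(
                            f"{m.person_id}: parent {pid} not listed earlier "
                            "(missing, out of order, or a cycle)"
                        )
                    if seen[pid].sex != want:
                        raise PedigreeError(
                            f"{m.person_id}: parent {pid} has sex "
                            f"{seen[pid].sex}, expected {want}"
                        )
            if m.sex not in ("M", "F"):
                raise PedigreeError(f"{m.person_id}: sex must be M or F")
            seen[m.person_id] = m
        self._index = {m.person_id: i for i, m in enumerate(self.members)}

    def __len__(self) -> int:
        return len(self.members)

    def index_of(self, person_id: str) -> int:
        return self._index[person_id]

    @property
    def ids(self) -> list[str]:
        return [m.person_id for m in self.members]

    @property
    def founder_indices(self) -> np.ndarray:
        return np.array([i for i, m in enumerate(self.members) if m.is_founder])

    @property
    def n_founders(self) -> int:
        return int(sum(m.is_founder for m in self.members))

    @property
    def family_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for m in self.members:
            seen.setdefault(m.family_id, None)
        return list(seen)

    @property
    def sexes(self) -> np.ndarray:
        return np.array([m.sex for m in self.members])


# --------------------------------------------------------------------------
# Family generation
# --------------------------------------------------------------------------

def _partition(total: int, parts: int, minimum: int, rng: np.random.Generator) -> list[int]:
    """Random composition of ``total`` into ``parts`` parts, each >= minimum."""
    if total < parts * minimum:
        raise PedigreeError(f"cannot split {total} into {parts} parts >= {minimum}")
    extra = rng.multinomial(total - parts * minimum, np.full(parts, 1.0 / parts))
    return [minimum + int(e) for e in extra]


def _build_family(
    family_id: str,
    n_members: int,
    n_founders: int,
    n_generations: int,
    rng: np.random.Generator,
    next_id: Iterable[int],
) -> list[Member]:
    members: list[Member] = []

    def add(father=None, mother=None, sex=None) -> Member:
        sex = sex or ("M" if rng.random() < 0.5 else "F")
        m = Member(str(next(next_id)), family_id, father, mother, sex)
        members.append(m)
        return m

    def couple() -> tuple[Member, Member]:
        return add(sex="M"), add(sex="F")

    def marry(person: Member) -> tuple[Member, Member]:
        spouse = add(sex="F" if person.sex == "M" else "M")
        f, m = (person, spouse) if person.sex == "M" else (spouse, person)
        return f, m

    if n_generations == 2:
        if n_founders != 2:
            raise PedigreeError(
                "a 2-generation family needs exactly 2 founders (one couple)"
            )
        if n_members < 3:
            raise PedigreeError("a 2-generation family needs >= 3 members")
        f, m = couple()
        for _ in range(n_members - 2):
            add(father=f.person_id, mother=m.person_id)
        return members

    if n_generations == 3:
        s2 = n_founders - 2
        n3 = n_members - n_founders - s2
        if s2 < 1 or n3 < s2:
            raise PedigreeError(
                f"infeasible 3-generation family: members={n_members}, "
                f"founders={n_founders}"
            )
        g1f, g1m = couple()
        sib3 = _partition(n3, s2, 1, rng)
        for k in range(s2):
            child = add(father=g1f.person_id, mother=g1m.person_id)
            f, m = marry(child)
            for _ in range(sib3[k]):
                add(father=f.person_id, mother=m.person_id)
        return members

    if n_generations != 4:
        raise PedigreeError(f"unsupported n_generations={n_generations}")

    # four generations: founder couple, married G2 children, married G3
    # grandchildren, G4 great-grandchildren (second cousins arise when the
    # reproducing G3 come from different G2 sibships).
    avail = n_founders - 2  # married-in spouses across G2 and G3
    s2 = min(4, avail - 2)
    if s2 < 2:
        raise PedigreeError(
            f"family {family_id}: needs >= 6 founders for 4 generations"
        )
    s3 = avail - s2
    rest = n_members - n_founders - s2  # G3 + G4 children
    if s3 < 2 or rest < 2 * s3:
        raise PedigreeError(
            f"infeasible 4-generation family: members={n_members}, "
            f"founders={n_founders}"
        )
    n3 = s3 + (rest - 2 * s3) // 2
    n3 = max(n3, s2)  # every G2 couple has at least one child
    n4 = rest - n3
    if n3 < max(s2, s3) or n4 < s3:
        raise PedigreeError(
            f"infeasible 4-generation family: members={n_members}, "
            f"founders={n_founders}"
        )

    g1f, g1m = couple()
    sib3 = _partition(n3, s2, 1, rng)
    g3_by_sibship: list[list[Member]] = []
    for k in range(s2):
        child = add(father=g1f.person_id, mother=g1m.person_id)
        f, m = marry(child)
        kids = [add(father=f.person_id, mother=m.person_id) for _ in range(sib3[k])]
        g3_by_sibship.append(kids)

    # choose the s3 reproducing G3 round-robin across sibships so that the
    # fourth generation contains second cousins
    order: list[Member] = []
    depth = 0
    while len(order) < s3:
        for kids in g3_by_sibship:
            if depth < len(kids) and len(order) < s3:
                order.append(kids[depth])
        depth += 1
    sib4 = _partition(n4, s3, 1, rng)
    for k, g3 in enumerate(order):
        f, m = marry(g3)
        for _ in range(sib4[k]):
            add(father=f.person_id, mother=m.person_id)
    return members


def generate_pedigree_set(
    n_families: int = 8,
    n_total: int = 697,
    n_founders: int = 202,
    n_generations: int = 4,
    seed: int | np.random.Generator = 0,
) -> Pedigree:
    """Build the family sampling design: ``n_families`` pedigrees totalling
    exactly ``n_total`` members and ``n_founders`` founders.

    With four generations the deepest relationships are second cousins.
    Raises :class:`PedigreeError` when the counts are infeasible.
    """
    if n_founders > n_total:
        raise PedigreeError(
            f"n_founders={n_founders} exceeds n_total={n_total}"
        )
    if n_families < 1 or n_generations < 2:
        raise PedigreeError("need n_families >= 1 and n_generations >= 2")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    base_m, rem_m = divmod(n_total, n_families)
    base_f, rem_f = divmod(n_founders, n_families)
    members_per = [base_m + (1 if i < rem_m else 0) for i in range(n_families)]
    founders_per = [base_f + (1 if i < rem_f else 0) for i in range(n_families)]

    counter = iter(range(1, n_total + 1))
    members: list[Member] = []
    for i in range(n_families):
        members.extend(
            _build_family(
                f"FAM{i+1}", members_per[i], founders_per[i],
                n_generations, rng, counter,
            )
        )
    ped = Pedigree(members)
    assert len(ped) == n_total and ped.n_founders == n_founders
    return ped


# --------------------------------------------------------------------------
# Kinship
# --------------------------------------------------------------------------

@dataclass
class KinshipMatrix:
    ids: list[str]
    phi: np.ndarray

    def value(self, id_i: str, id_j: str) -> float:
        i, j = self.ids.index(id_i), self.ids.index(id_j)
        return float(self.phi[i, j])

    @property
    def expected_sharing(self) -> np.ndarray:
        """2*Phi, the expected proportion of alleles shared IBD."""
        return 2.0 * self.phi


def kinship(ped: Pedigree) -> KinshipMatrix:
    """Recursive kinship coefficients, founders to leaves.

    Phi(i,i) = 1/2 + Phi(father, mother)/2; for j listed before i,
    Phi(i,j) = (Phi(father,j) + Phi(mother,j)) / 2; founders are mutually
    unrelated and non-inbred.
    """
    n = len(ped)
    phi = np.zeros((n, n))
    for i, m in enumerate(ped.members):
        if m.is_founder:
            phi[i, i] = 0.5
        else:
            f = ped.index_of(m.father_id)
            mo = ped.index_of(m.mother_id)
            phi[i, i] = 0.5 + 0.5 * phi[f, mo]
            phi[i, :i] = 0.5 * (phi[f, :i] + phi[mo, :i])
            phi[:i, i] = phi[i, :i]
    return KinshipMatrix(ped.ids, phi)


# --------------------------------------------------------------------------
# Gene dropping
# --------------------------------------------------------------------------

@dataclass
class InheritanceVectors:
    """Per-meiosis recombination records sufficient to replay inheritance.

    For non-founder ``i`` and parent slot ``s`` (0 = paternal, 1 = maternal)
    and chromosome index ``c``: ``phase[i, s, c]`` is the grandparental
    haplotype transmitted at the chromosome start and ``crossover[i, s, c]``
    the bp position of the single obligate crossover.  Founder haplotype
    labels are ``2k`` and ``2k+1`` for the k-th founder.
    """

    ped: Pedigree
    chrom_order: list[int]
    chrom_extents: dict[int, tuple[int, int]]
    phase: np.ndarray      # (n, 2, n_chrom) int8; founder rows unused
    crossover: np.ndarray  # (n, 2, n_chrom) float

    def transmitted_hap(self, member_index: int, slot: int,
                        chrom: int, pos: np.ndarray) -> np.ndarray:
        """Which parental haplotype (0/1) slot ``slot`` of ``member_index``
        carries at position(s) ``pos`` on ``chrom``."""
        c = self.chrom_order.index(chrom)
        ph = self.phase[member_index, slot, c]
        xo = self.crossover[member_index, slot, c]
        return np.where(np.asarray(pos) < xo, ph, 1 - ph).astype(np.int8)

    def founder_labels_at(self, loci: Sequence[tuple[int, float]]) -> np.ndarray:
        """Founder-haplotype labels, shape (n_members, 2, n_loci), for the
        given (chrom, pos) loci."""
        ped = self.ped
        n, L = len(ped), len(loci)
        chrom_idx = np.array([self.chrom_order.index(c) for c, _ in loci])
        pos = np.array([p for _, p in loci], dtype=float)
        lab = np.empty((n, 2, L), dtype=np.int32)
        founder_rank = {int(i): k for k, i in enumerate(ped.founder_indices)}
        for i, m in enumerate(ped.members):
            if m.is_founder:
                k = founder_rank[i]
                lab[i, 0] = 2 * k
                lab[i, 1] = 2 * k + 1
                continue
            for slot, pid in ((0, m.father_id), (1, m.mother_id)):
                p = ped.index_of(pid)
                ph = self.phase[i, slot, chrom_idx]
                xo = self.crossover[i, slot, chrom_idx]
                h = np.where(pos < xo, ph, 1 - ph)
                lab[i, slot] = lab[p, h, np.arange(L)]
        return lab


def gene_drop(
    ped: Pedigree,
    founders: HaplotypePanel,
    seed: int | np.random.Generator = 0,
) -> tuple[GenotypeMatrix, InheritanceVectors]:
    """Drop phased founder haplotypes through the pedigree.

    Each meiosis transmits a recombinant haplotype with exactly one
    crossover per chromosome at a uniform bp position over the chromosome's
    marker extent; founder genotypes are reproduced unchanged and no
    mutation is introduced.  Panel individual ``k`` supplies the k-th
    founder in pedigree order.
    """
    if founders.n_individuals != ped.n_founders:
        raise PedigreeError(
            f"panel has {founders.n_individuals} individuals but pedigree "
            f"has {ped.n_founders} founders"
        )
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    m = founders.map
    chrom_order = sorted(int(c) for c in np.unique(m.chroms))
    extents = {c: m.chrom_extent(c) for c in chrom_order}
    chrom_of = m.chroms
    pos = m.positions
    slices = {c: np.flatnonzero(chrom_of == c) for c in chrom_order}

    n = len(ped)
    n_markers = len(m)
    n_chrom = len(chrom_order)
    alleles = np.zeros((n, 2, n_markers), dtype=np.int8)
    phase = np.zeros((n, 2, n_chrom), dtype=np.int8)
    xo = np.zeros((n, 2, n_chrom), dtype=float)

    founder_rank = {int(i): k for k, i in enumerate(ped.founder_indices)}
    for i, mem in enumerate(ped.members):
        if mem.is_founder:
            k = founder_rank[i]
            alleles[i, 0] = founders.haplotypes[2 * k]
            alleles[i, 1] = founders.haplotypes[2 * k + 1]
            continue
        for slot, pid in ((0, mem.father_id), (1, mem.mother_id)):
            p = ped.index_of(pid)
            for c_idx, c in enumerate(chrom_order):
                lo, hi = extents[c]
                ph = int(rng.integers(0, 2))
                u = float(rng.uniform(lo, hi))
                phase[i, slot, c_idx] = ph
                xo[i, slot, c_idx] = u
                sl = slices[c]
                before = pos[sl] < u
                alleles[i, slot, sl] = np.where(
                    before, alleles[p, ph, sl], alleles[p, 1 - ph, sl]
                )

    dosage = alleles[:, 0, :] + alleles[:, 1, :]
    geno = GenotypeMatrix(dosage, m, ped.ids)
    vectors = InheritanceVectors(ped, chrom_order, extents, phase, xo)
    return geno, vectors


# --------------------------------------------------------------------------
# IBD matrices
# --------------------------------------------------------------------------

@dataclass
class IBDMatrix:
    gene: str
    ids: list[str]
    pi_hat: np.ndarray  # entries in [0, 1]; exact multiples of 0.5 here


def ibd_matrices(
    vectors: InheritanceVectors,
    ped: Pedigree,
    gene_loci: Sequence[tuple[str, int, float]],
) -> list[IBDMatrix]:
    """Exact IBD-sharing proportions per gene from fully informative labels.

    Each individual's two founder-haplotype labels are read at the gene's
    midpoint (genes are inherited atomically: recombination is ignored
    within the gene for IBD purposes).  pi_hat(i,j) = matching label pairs
    between i's and j's two labels, divided by 2.
    """
    for _, chrom, _ in gene_loci:
        if chrom not in vectors.chrom_order:
            raise PedigreeError(f"locus chromosome {chrom} not in panel")
    loci = [(chrom, mid) for _, chrom, mid in gene_loci]
    lab = vectors.founder_labels_at(loci)
    out = []
    for g, (gene, chrom, mid) in enumerate(gene_loci):
        a = lab[:, 0, g]
        b = lab[:, 1, g]
        match = (
            (a[:, None] == a[None, :]).astype(np.int8)
            + (a[:, None] == b[None, :])
            + (b[:, None] == a[None, :])
            + (b[:, None] == b[None, :])
        )
        out.append(IBDMatrix(gene, ped.ids, match / 2.0))
    return out


def write_ibd(matrices: Sequence[IBDMatrix], out_dir: str | Path) -> Path:
    """One whitespace-delimited square matrix file per gene, an index file
    mapping gene to filename, and a long-format TSV (id1, id2, gene, pi_hat
    for related pairs)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    index_rows = []
    long_rows = []
    for mat in matrices:
        fname = f"{mat.gene}.txt"
        np.savetxt(out_dir / fname, mat.pi_hat, fmt="%.1f")
        index_rows.append((mat.gene, fname))
        nz = np.argwhere(np.triu(mat.pi_hat, k=1) > 0)
        for i, j in nz:
            long_rows.append((mat.ids[i], mat.ids[j], mat.gene, mat.pi_hat[i, j]))
    pd.DataFrame(index_rows, columns=["gene", "filename"]).to_csv(
        out_dir / "index.tsv", sep="\t", index=False
    )
    pd.DataFrame(long_rows, columns=["id1", "id2", "gene", "pi_hat"]).to_csv(
        out_dir / "ibd_long.tsv", sep="\t", index=False
    )
    return out_dir


# --------------------------------------------------------------------------
# PED/FAM I/O
# --------------------------------------------------------------------------

def write_ped(ped: Pedigree, path: str | Path) -> None:
    """FAM-style: family, individual, father, mother, sex (1=M, 2=F),
    phenotype placeholder (-9); 0 marks a missing parent."""
    with open(path, "w", encoding="utf-8") as fh:
        for m in ped.members:
            fh.write(
                f"{m.family_id}\t{m.person_id}\t{m.father_id or 0}\t"
                f"{m.mother_id or 0}\t{1 if m.sex == 'M' else 2}\t-9\n"
            )


def read_ped(path: str | Path) -> Pedigree:
    rows = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip():
            continue
        fam, pid, fid, mid, sex, *_ = line.split()
        rows.append(
            Member(
                pid, fam,
                None if fid == "0" else fid,
                None if mid == "0" else mid,
                "M" if sex == "1" else "F",
            )
        )
    return Pedigree(rows)
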