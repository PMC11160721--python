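"""Germline V/D/J gene references: generation, FASTA I/O, and perturbation.

A germline reference is the set of named V, D and J gene segments that VDJ
recombination draws from.  For benchmarking we either generate a synthetic
reference (random sequences of realistic segment lengths — the human heavy
chain locus carries 44 functional V, 27 D and 6 J genes) or read one from a
FASTA file.  The :func:`perturb_v_genes` operation degrades the V genes with
indels and point mutations, emulating the situation of a non-model organism
whose reference assembly does not match the true germline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

NUCLEOTIDES = "ACGT"
_NT_SET = frozenset(NUCLEOTIDES)
SEGMENTS = ("V", "D", "J")


class GermlineError(ValueError):
    """Raised for malformed germline references or FASTA files."""


@dataclass(frozen=True)
class GermlineGene:
    """A single named germline gene segment."""

    name: str
    segment: str  # "V", "D" or "J"
    sequence: str

    def __post_init__(self) -> None:
        if self.segment not in SEGMENTS:
            raise GermlineError(f"unknown segment {self.segment!r} for gene {self.name!r}")
        if not self.sequence or set(self.sequence) - _NT_SET:
            raise GermlineError(f"gene {self.name!r}: sequence must be nonempty over A/C/G/T")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GermlineReference:
    """Ordered collections of V, D and J genes with unique names."""

    v_genes: tuple[GermlineGene, ...]
    d_genes: tuple[GermlineGene, ...]
    j_genes: tuple[GermlineGene, ...]

    def __post_init__(self) -> None:
        for seg, genes in (("V", self.v_genes), ("D", self.d_genes), ("J", self.j_genes)):
            if not genes:
                raise GermlineError(f"reference has no {seg} genes")
        names = [g.name for g in self.all_genes()]
        if len(names) != len(set(names)):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise GermlineError(f"duplicate gene names in reference: {dup}")

    def all_genes(self) -> tuple[GermlineGene, ...]:
        return self.v_genes + self.d_genes + self.j_genes

    def genes(self, segment: str) -> tuple[GermlineGene, ...]:
        return {"V": self.v_genes, "D": self.d_genes, "J": self.j_genes}[segment]


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(NUCLEOTIDES[i] for i in rng.integers(0, 4, size=length))


def generate_synthetic_germline(
    n_v: int = 44,
    n_d: int = 27,
    n_j: int = 6,
    v_len: int = 300,
    d_len: int = 20,
    j_len: int = 50,
    seed: int | None = None,
) -> GermlineReference:
    """Generate a synthetic germline reference of i.i.d. uniform sequences.

    Defaults mirror the functional human heavy-chain gene counts (44 V, 27 D,
    6 J) and typical segment lengths (V ~300 nt, D ~20 nt, J ~50 nt).
    Deterministic for a fixed ``seed``.
    """
    for label, value in (("n_v", n_v), ("n_d", n_d), ("n_j", n_j),
                         ("v_len", v_len), ("d_len", d_len), ("j_len", j_len)):
        if value < 1:
            raise GermlineError(f"{label} must be >= 1, got {value}")
    rng = np.random.default_rng(seed)
    make = lambda seg, n, ln: tuple(
        GermlineGene(f"{seg}{i + 1}", seg, _random_sequence(rng, ln)) for i in range(n)
    )
    return GermlineReference(make("V", n_v, v_len), make("D", n_d, d_len), make("J", n_j, j_len))


# FASTA dialect: headers are ">NAME|SEGMENT" with SEGMENT in {V, D, J}.

def write_germline_fasta(ref: GermlineReference, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(g.sequence), id=f"{g.name}|{g.segment}", description="")
        for g in ref.all_genes()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_germline_fasta(path: str | Path) -> GermlineReference:
    genes: dict[str, list[GermlineGene]] = {"V": [], "D": [], "J": []}
    seen: set[str] = set()
    n = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        n += 1
        if "|" not in rec.id:
            raise GermlineError(f"record {rec.id!r}: header must be 'NAME|SEGMENT'")
        name, _, segment = rec.id.rpartition("|")
        if segment not in SEGMENTS:
            raise GermlineError(f"record {rec.id!r}: unknown segment tag {segment!r}")
        if name in seen:
            raise GermlineError(f"record {rec.id!r}: duplicate gene name {name!r}")
        seen.add(name)
        genes[segment].append(GermlineGene(name, segment, str(rec.seq).upper()))
    if n == 0:
        raise GermlineError(f"no germline records in {path}")
    return GermlineReference(tuple(genes["V"]), tuple(genes["D"]), tuple(genes["J"]))


def _perturb_one(
    sequence: str,
    n_deletions: int,
    n_insertions: int,
    indel_size_range: tuple[int, int],
    point_mut_range: tuple[int, int],
    rng: np.random.Generator,
) -> str:
    """Apply deletions, then insertions, then point mutations to one gene."""
    lo, hi = indel_size_range
    seq = list(sequence)
    for _ in range(n_deletions):
        size = int(rng.integers(lo, hi + 1))
        if size > len(seq):
            raise GermlineError(
                f"deletion of size {size} exceeds remaining gene length {len(seq)}"
            )
        start = int(rng.integers(0, len(seq) - size + 1))
        del seq[start:start + size]
    for _ in range(n_insertions):
        size = int(rng.integers(lo, hi + 1))
        start = int(rng.integers(0, len(seq) + 1))
        seq[start:start] = _random_sequence(rng, size)
    n_mut = int(rng.integers(point_mut_range[0], point_mut_range[1] + 1))
    for _ in range(n_mut):
        pos = int(rng.integers(0, len(seq)))
        alternatives = [b for b in NUCLEOTIDES if b != seq[pos]]
        seq[pos] = alternatives[int(rng.integers(0, 3))]
    return "".join(seq)


def perturb_v_genes(
    ref: GermlineReference,
    n_deletions: int = 3,
    n_insertions: int = 3,
    indel_size_range: tuple[int, int] = (1, 4),
    point_mut_range: tuple[int, int] = (20, 40),
    seed: int | None = None,
) -> GermlineReference:
    """Return a degraded ("fake") reference: each V gene independently receives
    ``n_deletions`` deletions and ``n_insertions`` insertions with sizes uniform
    in ``indel_size_range``, followed by a uniform number of point mutations in
    ``point_mut_range``.  D and J genes are returned unchanged — they are too
    short to perturb without destroying them.

    Point mutations are applied last and may therefore hit inserted bases.
    """
    for label, r in (("indel_size_range", indel_size_range), ("point_mut_range", point_mut_range)):
        if r[0] > r[1] or r[0] < 0:
            raise GermlineError(f"{label} must be a well-ordered non-negative range, got {r}")
    if n_deletions < 0 or n_insertions < 0:
        raise GermlineError("indel counts must be non-negative")
    rng = np.random.default_rng(seed)
    new_v = tuple(
        replace(g, sequence=_perturb_one(
            g.sequence, n_deletions, n_insertions, indel_size_range, point_mut_range, rng))
        for g in ref.v_genes
    )
    return GermlineReference(new_v, ref.d_genes, ref.j_genes)
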