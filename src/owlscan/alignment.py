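"""In-frame codon alignments and candidate-gene lists.

A :class:`CodonAlignment` is the unit of data for every downstream stage:
QC, the codon-model likelihood fits and the simulation round trips. It is a
thin, validated container over per-taxon nucleotide strings whose common
length is a multiple of three.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

from Bio.SeqIO.FastaIO import SimpleFastaParser

__all__ = [
    "CodonAlignment",
    "CandidateList",
    "AlignmentError",
    "FrameError",
    "AlphabetError",
    "read_codon_fasta",
    "write_codon_fasta",
    "read_candidate_list",
    "CANDIDATE_CATEGORIES",
]

#: Functional categories allowed for a priori candidate genes.
CANDIDATE_CATEGORIES = ("vision", "hearing", "circadian", "feather")

_VALID_CHARS = frozenset("ACGTN-")


class AlignmentError(ValueError):
    """Sequences do not form a valid alignment (unequal lengths, bad taxa)."""


class FrameError(AlignmentError):
    """Alignment length is not a multiple of three."""


class AlphabetError(AlignmentError):
    """A sequence contains characters outside {A,C,G,T,N,-} after normalization."""


@dataclass(frozen=True)
class CodonAlignment:
    """An in-frame multispecies codon alignment for one gene.

    Parameters
    ----------
    gene_id : str
        Gene identifier (by convention the FASTA file stem).
    taxa : tuple of str
        Taxon names, unique and non-empty, in alignment order.
    seqs : tuple of str
        Aligned nucleotide strings over ``{A,C,G,T,N,-}``, all of identical
        length which must be a multiple of 3.
    """

    gene_id: str
    taxa: tuple[str, ...]
    seqs: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.seqs):
            raise AlignmentError("taxa and seqs must have matching lengths")
        if len(set(self.taxa)) != len(self.taxa):
            raise AlignmentError(f"duplicate taxon names in {self.gene_id!r}")
        if any(not t for t in self.taxa):
            raise AlignmentError("empty taxon name")
        if not self.seqs:
            raise AlignmentError("alignment needs at least one sequence")
        lengths = {len(s) for s in self.seqs}
        if len(lengths) != 1:
            raise AlignmentError(
                f"unequal sequence lengths in {self.gene_id!r}: {sorted(lengths)}"
            )
        (length,) = lengths
        if length % 3 != 0:
            raise FrameError(
                f"alignment length {length} of {self.gene_id!r} is not a multiple of 3"
            )
        for taxon, seq in zip(self.taxa, self.seqs):
            bad = set(seq) - _VALID_CHARS
            if bad:
                raise AlphabetError(
                    f"invalid characters {sorted(bad)} in {taxon!r} of {self.gene_id!r}"
                )

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_codons(self) -> int:
        return len(self.seqs[0]) // 3

    def codon(self, taxon_index: int, site: int) -> str:
        """Return the codon of one taxon at codon column ``site`` (0-based)."""
        return self.seqs[taxon_index][3 * site : 3 * site + 3]

    def column(self, site: int) -> tuple[str, ...]:
        """All codons at one codon column, in taxon order."""
        return tuple(self.codon(i, site) for i in range(self.n_taxa))

    def taxon_index(self, name: str) -> int:
        try:
            return self.taxa.index(name)
        except ValueError:
            raise KeyError(f"taxon {name!r} not in alignment {self.gene_id!r}") from None

    def select_codons(self, sites: list[int] | tuple[int, ...]) -> "CodonAlignment":
        """New alignment restricted to the given codon columns (order preserved)."""
        seqs = tuple(
            "".join(seq[3 * s : 3 * s + 3] for s in sites) for seq in self.seqs
        )
        return CodonAlignment(self.gene_id, self.taxa, seqs)

    def with_gene_id(self, gene_id: str) -> "CodonAlignment":
        return CodonAlignment(gene_id, self.taxa, self.seqs)


def _normalize(seq: str, header: str) -> str:
    s = seq.upper().replace("U", "T")
    bad = set(s) - _VALID_CHARS
    if bad:
        raise AlphabetError(f"invalid characters {sorted(bad)} in record {header!r}")
    return s


def read_codon_fasta(path: str | os.PathLike, gene_id: str | None = None) -> CodonAlignment:
    """Read one in-frame codon alignment from an aligned FASTA file.

    Sequences are uppercased and ``U`` is folded to ``T``. The gene id is the
    file stem unless overridden.
    """
    path = Path(path)
    taxa: list[str] = []
    seqs: list[str] = []
    with open(path) as handle:
        for header, seq in SimpleFastaParser(handle):
            name = header.split()[0] if header.split() else header
            taxa.append(name)
            seqs.append(_normalize(seq, name))
    if not taxa:
        raise AlignmentError(f"no FASTA records in {path}")
    return CodonAlignment(gene_id or path.stem, tuple(taxa), tuple(seqs))


def write_codon_fasta(aln: CodonAlignment, path: str | os.PathLike, width: int = 70) -> None:
    """Write the alignment back as wrapped FASTA (inverse of :func:`read_codon_fasta`)."""
    with open(path, "w") as out:
        for taxon, seq in zip(aln.taxa, aln.seqs):
            out.write(f">{taxon}\n")
            for i in range(0, len(seq), width):
                out.write(seq[i : i + width] + "\n")


@dataclass(frozen=True)
class CandidateList:
    """A priori candidate genes, each assigned to exactly one functional category."""

    entries: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for gene, cat in self.entries.items():
            if cat not in CANDIDATE_CATEGORIES:
                raise ValueError(
                    f"unknown category {cat!r} for gene {gene!r}; "
                    f"allowed: {CANDIDATE_CATEGORIES}"
                )

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, gene: str) -> bool:
        return gene in self.entries

    def category_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in CANDIDATE_CATEGORIES}
        for cat in self.entries.values():
            counts[cat] += 1
        return counts

    def genes(self, category: str | None = None) -> list[str]:
        if category is None:
            return list(self.entries)
        return [g for g, c in self.entries.items() if c == category]


def read_candidate_list(path: str | os.PathLike) -> CandidateList:
    """Read a tab-separated candidate list with columns ``gene_id`` and ``category``."""
    entries: dict[str, str] = {}
    with open(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
        try:
            gi = header.index("gene_id")
            ci = header.index("category")
        except ValueError:
            raise ValueError(
                f"candidate list {path} must have columns gene_id and category"
            ) from None
        for lineno, line in enumerate(handle, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            gene, cat = fields[gi].strip(), fields[ci].strip()
            if gene in entries:
                raise ValueError(f"duplicate gene {gene!r} at line {lineno} of {path}")
            if cat not in CANDIDATE_CATEGORIES:
                raise ValueError(
                    f"unknown category {cat!r} for gene {gene!r} "
                    f"(line {lineno} of {path})"
                )
            entries[gene] = cat
    return CandidateList(entries)
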