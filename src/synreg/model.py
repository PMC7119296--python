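"""Domain types for the synonymous-mutation regulatory annotation pipeline.

Conventions adopted throughout the package:

* genomic positions in mutation records are **1-based** (COSMIC/VCF style);
* interval tracks and exon models are **0-based half-open** (BED style);
* conversion between the two happens exactly once, at the I/O boundary;
* sequence context, CDS sequences and alleles are stored in **coding-strand**
  orientation (motif scanning is defined on the mRNA sense sequence);
  minus-strand inputs are reverse-complemented at load.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from Bio.Data.CodonTable import standard_dna_table
from intervaltree import IntervalTree

DNA_BASES = frozenset("ACGT")
COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: 61 sense codons of the standard genetic code -> one-letter amino acid.
GENETIC_CODE: Mapping[str, str] = dict(standard_dna_table.forward_table)

#: Default half-width of the stored sequence context (21-nt window), wide
#: enough for both the 6-bp splicing-regulator windows and the 7-bp
#: miRNA-target windows.
DEFAULT_CONTEXT_W = 10


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N allowed)."""
    return seq.translate(COMPLEMENT)[::-1]


def translate_codon(codon: str) -> Optional[str]:
    """Amino acid for a codon, or None for a stop codon."""
    return GENETIC_CODE.get(codon)


class InvariantError(ValueError):
    """A domain object violated one of its stated invariants."""


@dataclass(frozen=True)
class Mutation:
    """One somatic synonymous single-nucleotide substitution.

    ``ref_allele``/``alt_allele`` and ``context`` are coding-strand;
    ``pos`` is the 1-based genomic coordinate; ``cds_pos`` the 1-based
    offset within the CDS. ``score`` is a FATHMM-style pathogenicity score
    in [0, 1] (None when the source record carried no score);
    ``sample_count`` the number of distinct tumour samples carrying the
    variant.
    """

    gene_symbol: str
    transcript_id: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    strand: str
    sample_count: int
    score: Optional[float]
    cds_pos: int
    context: str

    def __post_init__(self) -> None:
        if self.ref_allele == self.alt_allele:
            raise InvariantError("not a substitution")
        for allele, name in ((self.ref_allele, "ref"), (self.alt_allele, "alt")):
            if allele not in DNA_BASES:
                raise InvariantError(f"{name} allele {allele!r} is not a single DNA base")
        if self.strand not in {"+", "-"}:
            raise InvariantError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.sample_count < 1:
            raise InvariantError("sample_count must be >= 1")
        if self.score is not None and not 0.0 <= self.score <= 1.0:
            raise InvariantError(f"score {self.score} outside [0, 1]")
        if self.cds_pos < 1:
            raise InvariantError("cds_pos must be >= 1")
        w = len(self.context) // 2
        if len(self.context) < 3 or len(self.context) % 2 == 0:
            raise InvariantError("context must have odd length >= 3")
        if self.context[w] != self.ref_allele:
            raise InvariantError("context centre does not match ref allele")

    @property
    def context_w(self) -> int:
        return len(self.context) // 2

    @property
    def scan_eligible(self) -> bool:
        """False when the context carries non-ACGT characters (padding)."""
        return set(self.context) <= DNA_BASES


@dataclass(frozen=True)
class TranscriptModel:
    """Exon structure and CDS of one coding transcript.

    ``exons`` are 0-based half-open genomic intervals sorted by start;
    ``cds_sequence`` is the spliced CDS in coding-strand orientation.
    """

    gene_symbol: str
    transcript_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_interval: tuple[int, int]
    cds_sequence: str

    def __post_init__(self) -> None:
        prev_end = None
        for start, end in self.exons:
            if start >= end:
                raise InvariantError(f"empty exon [{start}, {end})")
            if prev_end is not None and start < prev_end:
                raise InvariantError("exons overlap or are unsorted")
            prev_end = end
        if len(self.cds_sequence) % 3 != 0:
            raise InvariantError("CDS length not divisible by 3")
        if len(self.cds_sequence) != self.cds_exon_length():
            raise InvariantError(
                "cds_sequence length differs from summed CDS-overlapping exon length"
            )

    def cds_exon_length(self) -> int:
        cs, ce = self.cds_interval
        return sum(max(0, min(end, ce) - max(start, cs)) for start, end in self.exons)

    @property
    def cds_len(self) -> int:
        return len(self.cds_sequence)

    def internal_boundaries(self) -> tuple[int, ...]:
        """0-based genomic coordinates of internal exon/intron boundaries.

        For exon [s, e) the donor boundary sits after base e-1 and the
        acceptor before base s; transcript 5'/3' termini are not splice
        sites. Returned as the positions used by the distance rule:
        a boundary contributes |pos - s| + 1 or e - pos.
        """
        bounds: list[int] = []
        n = len(self.exons)
        for i, (s, e) in enumerate(self.exons):
            if i > 0:
                bounds.append(s)  # acceptor side
            if i < n - 1:
                bounds.append(e)  # donor side (half-open end)
        return tuple(bounds)

    def genomic_to_cds(self, pos0: int) -> Optional[int]:
        """Map a 0-based genomic position to a 1-based CDS offset (or None)."""
        cs, ce = self.cds_interval
        if not cs <= pos0 < ce:
            return None
        offset = 0
        for start, end in self.exons:
            lo, hi = max(start, cs), min(end, ce)
            if lo >= hi:
                continue
            if lo <= pos0 < hi:
                off = offset + (pos0 - lo)
                if self.strand == "-":
                    off = self.cds_len - 1 - off
                return off + 1
            offset += hi - lo
        return None

    def cds_to_genomic(self, cds_pos: int) -> int:
        """Map a 1-based CDS offset to the 0-based genomic position."""
        if not 1 <= cds_pos <= self.cds_len:
            raise ValueError(f"cds_pos {cds_pos} outside CDS of length {self.cds_len}")
        off = cds_pos - 1
        if self.strand == "-":
            off = self.cds_len - 1 - off
        cs, ce = self.cds_interval
        offset = 0
        for start, end in self.exons:
            lo, hi = max(start, cs), min(end, ce)
            if lo >= hi:
                continue
            if off < offset + (hi - lo):
                return lo + (off - offset)
            offset += hi - lo
        raise AssertionError("unreachable: cds_pos inside CDS but not mapped")


@dataclass(frozen=True)
class MotifSet:
    """A labelled set of exonic-splicing-regulator hexamers (DNA, uppercase)."""

    label: str
    motifs: frozenset[str]
    source_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.label not in {"ESE", "ESS"}:
            raise InvariantError(f"MotifSet label must be ESE or ESS, got {self.label!r}")
        for m in self.motifs:
            if len(m) != 6 or set(m) - DNA_BASES:
                raise InvariantError(f"motif {m!r} is not an uppercase DNA 6-mer")

    def __len__(self) -> int:
        return len(self.motifs)

    def __contains__(self, kmer: str) -> bool:
        return kmer in self.motifs


def union_motif_sets(sets: Sequence[MotifSet]) -> MotifSet:
    """Union of same-label motif sets (e.g. RESCUE-ESE ∪ ESEseq top-200)."""
    if not sets:
        raise ValueError("no motif sets given")
    labels = {s.label for s in sets}
    if len(labels) > 1:
        raise ValueError(f"cannot union motif sets with mixed labels {sorted(labels)}")
    motifs: frozenset[str] = frozenset().union(*(s.motifs for s in sets))
    names = tuple(n for s in sets for n in s.source_names)
    return MotifSet(label=sets[0].label, motifs=motifs, source_names=names)


@dataclass(frozen=True)
class MiRNA:
    """A mature miRNA (5'→3' RNA sequence)."""

    mirna_id: str
    mature_seq: str

    def __post_init__(self) -> None:
        if len(self.mature_seq) < 8:
            raise InvariantError(f"{self.mirna_id}: mature sequence shorter than 8 nt")
        if set(self.mature_seq) - set("ACGU"):
            raise InvariantError(f"{self.mirna_id}: sequence not RNA (ACGU)")


@dataclass(frozen=True)
class SeedMotif:
    """A miRNA seed and the DNA 7-mer its target site spells on the mRNA.

    ``anchored`` marks the A-anchor rule: a 6-nt seed (positions 2-7)
    whose complementary site is followed by a target-side adenine.
    """

    mirna_id: str
    seed: str
    anchored: bool
    target_motif: str

    def __post_init__(self) -> None:
        if self.anchored:
            if len(self.seed) != 6:
                raise InvariantError("anchored seed must be 6 nt")
            if not self.target_motif.endswith("A"):
                raise InvariantError("anchored target motif must end in 'A'")
        elif len(self.seed) != 7:
            raise InvariantError("non-anchored seed must be 7 nt")
        if len(self.target_motif) != 7:
            raise InvariantError("target motif must be a 7-mer")


@dataclass(frozen=True)
class CodonTable:
    """Sense-codon → amino-acid map plus the designated optimal codons."""

    codon_to_aa: Mapping[str, str] = field(default_factory=lambda: dict(GENETIC_CODE))
    optimal_codons: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        extra = set(self.optimal_codons) - set(self.codon_to_aa)
        if extra:
            raise InvariantError(f"optimal codons not in the sense-codon table: {sorted(extra)}")

    def is_optimal(self, codon: str) -> bool:
        return codon in self.optimal_codons

    def synonymous(self, codon_a: str, codon_b: str) -> bool:
        return (
            codon_a in self.codon_to_aa
            and codon_b in self.codon_to_aa
            and self.codon_to_aa[codon_a] == self.codon_to_aa[codon_b]
        )


class IntervalTrack:
    """Per-chromosome 0-based half-open intervals (DHS peaks, TF sites, ...)."""

    def __init__(self, label: str, intervals: Mapping[str, Iterable[tuple[int, int]]]):
        self.label = label
        self._trees: dict[str, IntervalTree] = {}
        for chrom, ivs in intervals.items():
            tree = IntervalTree()
            for start, end in ivs:
                if start >= end:
                    raise InvariantError(f"empty interval [{start}, {end}) on {chrom}")
                tree.addi(start, end)
            if tree:
                self._trees[chrom] = tree

    def contains(self, chrom: str, pos0: int) -> bool:
        """Strict containment of the 0-based position (no proximity window)."""
        tree = self._trees.get(chrom)
        return bool(tree is not None and tree.overlaps_point(pos0))

    def covered_bases(self) -> int:
        total = 0
        for tree in self._trees.values():
            merged = tree.copy()
            merged.merge_overlaps()
            total += sum(iv.end - iv.begin for iv in merged)
        return total

    def intervals(self) -> dict[str, list[tuple[int, int]]]:
        return {
            chrom: sorted((iv.begin, iv.end) for iv in tree)
            for chrom, tree in sorted(self._trees.items())
        }

    def __len__(self) -> int:
        return sum(len(t) for t in self._trees.values())


@dataclass(frozen=True)
class GeneRateTable:
    """Per-gene background synonymous mutation rate R and CDS length (nt).

    R is the expected number of synonymous mutations per sample per allele
    copy, so the cohort-level expectation is λ = 2·R·S for S samples.
    """

    rates: Mapping[str, tuple[float, int]]

    def __post_init__(self) -> None:
        for gene, (rate, _length) in self.rates.items():
            if rate <= 0:
                raise InvariantError(f"rate for {gene} must be > 0")

    def rate(self, gene: str) -> Optional[float]:
        entry = self.rates.get(gene)
        return entry[0] if entry else None

    def length(self, gene: str) -> Optional[int]:
        entry = self.rates.get(gene)
        return entry[1] if entry else None

    def __contains__(self, gene: str) -> bool:
        return gene in self.rates


@dataclass(frozen=True)
class GeneScoreTable:
    """Per-gene scalar scores (e.g. RVIS percentile) and per-site scores
    (e.g. phyloP conservation), both optional."""

    gene_scores: Mapping[str, float] = field(default_factory=dict)
    site_scores: Mapping[tuple[str, int], float] = field(default_factory=dict)
    kind: str = "generic"

    def __post_init__(self) -> None:
        if self.kind == "rvis":
            for gene, pct in self.gene_scores.items():
                if not 0.0 <= pct <= 100.0:
                    raise InvariantError(f"RVIS percentile for {gene} outside [0, 100]")

    def gene(self, gene_symbol: str) -> Optional[float]:
        return self.gene_scores.get(gene_symbol)

    def site(self, chrom: str, pos: int) -> Optional[float]:
        """Score at a 1-based genomic position."""
        return self.site_scores.get((chrom, pos))


def select_longest_transcript(
    transcripts: Sequence[TranscriptModel],
) -> dict[str, TranscriptModel]:
    """Keep one transcript per gene: maximal CDS length, ties broken by the
    lexicographically smallest transcript_id."""
    if not transcripts:
        raise ValueError("no transcripts given")
    best: dict[str, TranscriptModel] = {}
    for t in transcripts:
        cur = best.get(t.gene_symbol)
        if (
            cur is None
            or t.cds_len > cur.cds_len
            or (t.cds_len == cur.cds_len and t.transcript_id < cur.transcript_id)
        ):
            best[t.gene_symbol] = t
    return best
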