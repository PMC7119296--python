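"""Readers and writers for every file format the pipeline touches.

Mutation tables come in two dialects: a COSMIC-like TSV (header required)
and VCF 4.x with the INFO keys GENE, TRANSCRIPT, STRAND, FATHMM, NSAMP,
CDSPOS, CONTEXT. VCF REF/ALT are genomic plus-strand and are converted to
coding-strand orientation at load; the TSV dialect stores coding-strand
alleles directly. Rows violating the Mutation invariants are collected
into a rejects report, never silently dropped.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd
import pysam
from Bio import SeqIO

from .model import (
    DNA_BASES,
    CodonTable,
    GENETIC_CODE,
    GeneRateTable,
    GeneScoreTable,
    IntervalTrack,
    InvariantError,
    MiRNA,
    MotifSet,
    Mutation,
    TranscriptModel,
    revcomp,
)

MUTATION_COLUMNS = (
    "gene",
    "transcript",
    "chrom",
    "pos",
    "ref",
    "alt",
    "strand",
    "score",
    "sample_count",
    "cds_pos",
    "context",
)

VCF_INFO_KEYS = ("GENE", "TRANSCRIPT", "STRAND", "FATHMM", "NSAMP", "CDSPOS", "CONTEXT")


class FormatError(ValueError):
    """An input file does not conform to its declared format."""


@dataclass(frozen=True)
class Reject:
    """A row that failed validation, with the source row index and reason."""

    row: int
    reason: str


def _parse_score(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    text = str(value).strip()
    if text in {"", "NA", "NaN", "nan", "."}:
        return None
    return float(text)


def read_mutation_table(
    path: str | os.PathLike, dialect: str = "cosmic_tsv"
) -> tuple[list[Mutation], list[Reject]]:
    """Load a mutation table; returns (mutations, rejects).

    ``dialect`` is ``cosmic_tsv`` (tab-separated, header required) or
    ``vcf``. Missing required columns / INFO definitions raise
    :class:`FormatError` naming the field; individual bad rows become
    :class:`Reject` entries.
    """
    if dialect == "cosmic_tsv":
        return _read_mutation_tsv(path)
    if dialect == "vcf":
        return _read_mutation_vcf(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_mutation_tsv(path) -> tuple[list[Mutation], list[Reject]]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in MUTATION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"mutation table missing required column(s): {', '.join(missing)}")
    muts: list[Mutation] = []
    rejects: list[Reject] = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            ref, alt = row.ref.strip().upper(), row.alt.strip().upper()
            if len(ref) != 1 or len(alt) != 1:
                raise InvariantError("not a single-nucleotide variant")
            muts.append(
                Mutation(
                    gene_symbol=row.gene,
                    transcript_id=row.transcript,
                    chrom=row.chrom,
                    pos=int(row.pos),
                    ref_allele=ref,
                    alt_allele=alt,
                    strand=row.strand,
                    sample_count=int(row.sample_count),
                    score=_parse_score(row.score),
                    cds_pos=int(row.cds_pos),
                    context=row.context.strip().upper(),
                )
            )
        except (InvariantError, ValueError) as exc:
            rejects.append(Reject(row=i, reason=str(exc)))
    return muts, rejects


def _read_mutation_vcf(path) -> tuple[list[Mutation], list[Reject]]:
    vcf = pysam.VariantFile(os.fspath(path))
    declared = set(vcf.header.info.keys())
    missing = [k for k in VCF_INFO_KEYS if k not in declared]
    if missing:
        raise FormatError(f"VCF header missing required INFO key(s): {', '.join(missing)}")
    muts: list[Mutation] = []
    rejects: list[Reject] = []
    for i, rec in enumerate(vcf):
        try:
            if rec.alts is None or len(rec.alts) != 1:
                raise InvariantError("not a biallelic record")
            ref, alt = rec.ref.upper(), rec.alts[0].upper()
            if len(ref) != 1 or len(alt) != 1:
                raise InvariantError("not a single-nucleotide variant")
            info = rec.info
            absent = [k for k in VCF_INFO_KEYS if k not in info and k != "FATHMM"]
            if absent:
                raise InvariantError(f"missing INFO value(s): {', '.join(absent)}")
            strand = str(info["STRAND"])
            if strand == "-":  # REF/ALT are plus-strand; store coding-strand
                ref, alt = revcomp(ref), revcomp(alt)
            muts.append(
                Mutation(
                    gene_symbol=str(info["GENE"]),
                    transcript_id=str(info["TRANSCRIPT"]),
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref_allele=ref,
                    alt_allele=alt,
                    strand=strand,
                    sample_count=int(info["NSAMP"]),
                    # VCF floats are 32-bit; round away the representation noise
                    score=round(float(info["FATHMM"]), 6) if "FATHMM" in info else None,
                    cds_pos=int(info["CDSPOS"]),
                    context=str(info["CONTEXT"]).upper(),
                )
            )
        except (InvariantError, ValueError) as exc:
            rejects.append(Reject(row=i, reason=str(exc)))
    return muts, rejects


def mutations_to_frame(muts: Sequence[Mutation]) -> pd.DataFrame:
    """Tabular view of a mutation list (column names as in the TSV dialect)."""
    return pd.DataFrame(
        {
            "gene": [m.gene_symbol for m in muts],
            "transcript": [m.transcript_id for m in muts],
            "chrom": [m.chrom for m in muts],
            "pos": [m.pos for m in muts],
            "ref": [m.ref_allele for m in muts],
            "alt": [m.alt_allele for m in muts],
            "strand": [m.strand for m in muts],
            "score": [m.score for m in muts],
            "sample_count": [m.sample_count for m in muts],
            "cds_pos": [m.cds_pos for m in muts],
            "context": [m.context for m in muts],
        }
    )


def write_mutation_table(muts: Sequence[Mutation], path: str | os.PathLike) -> None:
    df = mutations_to_frame(muts)
    df["score"] = df["score"].map(lambda s: "" if s is None else repr(float(s)))
    df.to_csv(path, sep="\t", index=False)


def write_mutation_vcf(
    muts: Sequence[Mutation], path: str | os.PathLike, contig_length: int = 500_000_000
) -> None:
    """Write mutations as VCF 4.2 with the package's INFO keys.

    REF/ALT are emitted on the genomic plus strand (complemented back for
    minus-strand records); CONTEXT stays coding-strand.
    """
    header = pysam.VariantHeader()
    header.add_line('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">')
    header.add_line('##INFO=<ID=TRANSCRIPT,Number=1,Type=String,Description="Transcript id">')
    header.add_line('##INFO=<ID=STRAND,Number=1,Type=String,Description="Coding strand">')
    header.add_line('##INFO=<ID=FATHMM,Number=1,Type=Float,Description="Pathogenicity score">')
    header.add_line('##INFO=<ID=NSAMP,Number=1,Type=Integer,Description="Sample count">')
    header.add_line('##INFO=<ID=CDSPOS,Number=1,Type=Integer,Description="1-based CDS position">')
    header.add_line(
        '##INFO=<ID=CONTEXT,Number=1,Type=String,Description="Coding-strand context">'
    )
    for chrom in sorted({m.chrom for m in muts}):
        header.contigs.add(chrom, length=contig_length)
    vcf = pysam.VariantFile(os.fspath(path), "w", header=header)
    for m in sorted(muts, key=lambda m: (m.chrom, m.pos)):
        ref, alt = m.ref_allele, m.alt_allele
        if m.strand == "-":
            ref, alt = revcomp(ref), revcomp(alt)
        rec = vcf.new_record(
            contig=m.chrom, start=m.pos - 1, stop=m.pos, alleles=(ref, alt)
        )
        rec.info["GENE"] = m.gene_symbol
        rec.info["TRANSCRIPT"] = m.transcript_id
        rec.info["STRAND"] = m.strand
        if m.score is not None:
            rec.info["FATHMM"] = m.score
        rec.info["NSAMP"] = m.sample_count
        rec.info["CDSPOS"] = m.cds_pos
        rec.info["CONTEXT"] = m.context
        vcf.write(rec)
    vcf.close()


def read_motif_list(
    path: str | os.PathLike, label: str, source_name: Optional[str] = None
) -> MotifSet:
    """One hexamer per line; '#' comments and blank lines ignored; U→T and
    case normalised at load. Malformed lines raise with the line number."""
    motifs: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.strip()
            if not text or text.startswith("#"):
                continue
            motif = text.upper().replace("U", "T")
            if len(motif) != 6 or set(motif) - DNA_BASES:
                raise FormatError(f"{path}:{lineno}: {text!r} is not a 6-mer motif")
            motifs.add(motif)
    return MotifSet(
        label=label,
        motifs=frozenset(motifs),
        source_names=(source_name or os.path.basename(os.fspath(path)),),
    )


def write_motif_list(motifs: MotifSet, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for m in sorted(motifs.motifs):
            fh.write(m + "\n")


def read_bed_track(path: str | os.PathLike, label: str = "other") -> IntervalTrack:
    """BED3+ (0-based half-open); malformed lines raise with the line number."""
    intervals: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.strip()
            if not text or text.startswith(("#", "track", "browser")):
                continue
            parts = text.split()
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: expected at least 3 BED columns")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start < 0 or start >= end:
                raise FormatError(f"{path}:{lineno}: invalid interval [{start}, {end})")
            intervals.setdefault(chrom, []).append((start, end))
    return IntervalTrack(label=label, intervals=intervals)


def write_bed_track(track: IntervalTrack, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for chrom, ivs in track.intervals().items():
            for start, end in ivs:
                fh.write(f"{chrom}\t{start}\t{end}\n")


def read_mirna_fasta(path: str | os.PathLike) -> list[MiRNA]:
    """Mature miRNA sequences (FASTA); T→U normalised to RNA at load."""
    mirnas = []
    for rec in SeqIO.parse(os.fspath(path), "fasta"):
        seq = str(rec.seq).upper().replace("T", "U")
        mirnas.append(MiRNA(mirna_id=rec.id, mature_seq=seq))
    return mirnas


def write_fasta(records: Iterable[tuple[str, str]], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def read_codon_table(path: str | os.PathLike) -> CodonTable:
    """TSV with columns ``codon`` and ``optimal`` (0/1) over sense codons."""
    df = pd.read_csv(path, sep="\t", dtype={"codon": str, "optimal": int}, comment="#")
    for col in ("codon", "optimal"):
        if col not in df.columns:
            raise FormatError(f"codon table missing required column: {col}")
    optimal = set()
    for _, row in df.iterrows():
        codon = row["codon"].strip().upper().replace("U", "T")
        if codon not in GENETIC_CODE:
            raise FormatError(f"{codon!r} is not a sense codon of the standard code")
        if int(row["optimal"]):
            optimal.add(codon)
    return CodonTable(optimal_codons=frozenset(optimal))


def default_codon_table() -> CodonTable:
    """The packaged default optimal-codon table.

    This is a synthetic illustrative table (one commonly preferred codon
    per degenerate amino-acid family), shipped so the pipeline runs out of
    the box; analyses of real cohorts should supply their own table.
    """
    here = os.path.dirname(__file__)
    return read_codon_table(os.path.join(here, "data", "optimal_codons_synthetic.tsv"))


def write_codon_table(table: CodonTable, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("codon\toptimal\n")
        for codon in sorted(table.codon_to_aa):
            fh.write(f"{codon}\t{int(codon in table.optimal_codons)}\n")


def read_gene_rates(path: str | os.PathLike) -> GeneRateTable:
    """TSV with columns ``gene``, ``rate``, ``cds_length``."""
    df = pd.read_csv(path, sep="\t")
    for col in ("gene", "rate", "cds_length"):
        if col not in df.columns:
            raise FormatError(f"gene rate table missing required column: {col}")
    rates = {
        str(row.gene): (float(row.rate), int(row.cds_length))
        for row in df.itertuples(index=False)
    }
    return GeneRateTable(rates=rates)


def write_gene_rates(rates: GeneRateTable, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("gene\trate\tcds_length\n")
        for gene in sorted(rates.rates):
            r, length = rates.rates[gene]
            fh.write(f"{gene}\t{r!r}\t{length}\n")


def read_rvis_table(path: str | os.PathLike) -> GeneScoreTable:
    """TSV with columns ``gene``, ``percentile`` (0 = most intolerant)."""
    df = pd.read_csv(path, sep="\t")
    for col in ("gene", "percentile"):
        if col not in df.columns:
            raise FormatError(f"RVIS table missing required column: {col}")
    return GeneScoreTable(
        gene_scores={str(r.gene): float(r.percentile) for r in df.itertuples(index=False)},
        kind="rvis",
    )


def read_phylop_table(path: str | os.PathLike) -> GeneScoreTable:
    """TSV with columns ``chrom``, ``pos`` (1-based), ``score``."""
    df = pd.read_csv(path, sep="\t")
    for col in ("chrom", "pos", "score"):
        if col not in df.columns:
            raise FormatError(f"phyloP table missing required column: {col}")
    return GeneScoreTable(
        site_scores={
            (str(r.chrom), int(r.pos)): float(r.score) for r in df.itertuples(index=False)
        },
        kind="phylop",
    )


def write_site_scores(table: GeneScoreTable, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tscore\n")
        for (chrom, pos), score in sorted(table.site_scores.items()):
            fh.write(f"{chrom}\t{pos}\t{score!r}\n")


def write_gene_scores(table: GeneScoreTable, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tpercentile\n")
        for gene, score in sorted(table.gene_scores.items()):
            fh.write(f"{gene}\t{score!r}\n")


# --- transcript models -------------------------------------------------------

def read_transcripts_bed12(
    bed_path: str | os.PathLike, cds_fasta_path: str | os.PathLike
) -> list[TranscriptModel]:
    """BED12 transcript models plus a CDS FASTA keyed by transcript id.

    The BED name field is ``transcript_id|gene_symbol``; thickStart/thickEnd
    delimit the CDS. Block coordinates follow the BED12 convention
    (blockStarts relative to chromStart).
    """
    cds_seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(os.fspath(cds_fasta_path), "fasta")}
    transcripts: list[TranscriptModel] = []
    with open(bed_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.strip()
            if not text or text.startswith(("#", "track", "browser")):
                continue
            parts = text.split("\t")
            if len(parts) < 12:
                raise FormatError(f"{bed_path}:{lineno}: expected 12 BED columns")
            chrom, start, _end, name, _score, strand = parts[0], int(parts[1]), int(parts[2]), parts[3], parts[4], parts[5]
            thick_start, thick_end = int(parts[6]), int(parts[7])
            n_blocks = int(parts[9])
            sizes = [int(x) for x in parts[10].rstrip(",").split(",")]
            starts = [int(x) for x in parts[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise FormatError(f"{bed_path}:{lineno}: block count mismatch")
            exons = tuple((start + s, start + s + size) for s, size in zip(starts, sizes))
            tid, _, gene = name.partition("|")
            if tid not in cds_seqs:
                raise FormatError(f"{bed_path}:{lineno}: no CDS sequence for {tid!r}")
            transcripts.append(
                TranscriptModel(
                    gene_symbol=gene or tid,
                    transcript_id=tid,
                    chrom=chrom,
                    strand=strand,
                    exons=exons,
                    cds_interval=(thick_start, thick_end),
                    cds_sequence=cds_seqs[tid],
                )
            )
    return transcripts


def write_transcripts_bed12(
    transcripts: Sequence[TranscriptModel], bed_path: str | os.PathLike,
    cds_fasta_path: Optional[str | os.PathLike] = None,
) -> None:
    with open(bed_path, "w") as fh:
        for t in sorted(transcripts, key=lambda t: (t.chrom, t.exons[0][0], t.transcript_id)):
            start = t.exons[0][0]
            end = t.exons[-1][1]
            sizes = ",".join(str(e - s) for s, e in t.exons)
            starts = ",".join(str(s - start) for s, e in t.exons)
            name = f"{t.transcript_id}|{t.gene_symbol}"
            fh.write(
                f"{t.chrom}\t{start}\t{end}\t{name}\t0\t{t.strand}\t"
                f"{t.cds_interval[0]}\t{t.cds_interval[1]}\t0\t{len(t.exons)}\t{sizes}\t{starts}\n"
            )
    if cds_fasta_path is not None:
        write_fasta(
            sorted((t.transcript_id, t.cds_sequence) for t in transcripts), cds_fasta_path
        )


def read_transcripts_gff3(
    gff_path: str | os.PathLike, cds_fasta_path: str | os.PathLike
) -> list[TranscriptModel]:
    """GFF3 transcript models (gene/mRNA/exon/CDS features) plus a CDS FASTA."""
    import gffutils

    db = gffutils.create_db(
        os.fspath(gff_path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    cds_seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(os.fspath(cds_fasta_path), "fasta")}
    transcripts: list[TranscriptModel] = []
    for mrna in db.features_of_type("mRNA"):
        tid = mrna.id
        gene = mrna.attributes.get("gene", [None])[0]
        if gene is None:
            parents = list(db.parents(mrna, featuretype="gene"))
            gene = parents[0].attributes.get("Name", [parents[0].id])[0] if parents else tid
        exons = tuple(
            sorted((f.start - 1, f.end) for f in db.children(mrna, featuretype="exon"))
        )
        cds_parts = sorted((f.start - 1, f.end) for f in db.children(mrna, featuretype="CDS"))
        if not cds_parts:
            continue
        cds_interval = (cds_parts[0][0], cds_parts[-1][1])
        if tid not in cds_seqs:
            raise FormatError(f"{gff_path}: no CDS sequence for {tid!r}")
        transcripts.append(
            TranscriptModel(
                gene_symbol=gene,
                transcript_id=tid,
                chrom=mrna.seqid,
                strand=mrna.strand,
                exons=exons,
                cds_interval=cds_interval,
                cds_sequence=cds_seqs[tid],
            )
        )
    return transcripts
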