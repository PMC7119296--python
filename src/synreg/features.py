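"""Codon-optimality change, open-chromatin overlap, gene intolerance and
conservation annotations.

Codon optimality: replacing a designated optimal codon with a non-optimal
synonym (OPTIMAL_LOSS) can slow translation; the reverse is OPTIMAL_GAIN.
Chromatin: a mutation overlaps a DNase-I-hypersensitive-site (DHS) or
transcription-factor (TF) track only when the mutated base lies strictly
inside an interval — proximity does not count. RVIS: genes in the top 25%
most intolerant percentiles are flagged; mutations in genes without an
RVIS entry carry an absent flag and are excluded from that comparison
downstream. phyloP conservation scores attach per site when available.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional

from .model import (
    CodonTable,
    GeneScoreTable,
    IntervalTrack,
    Mutation,
    TranscriptModel,
)


class CodonChange(str, Enum):
    OPTIMAL_LOSS = "OPTIMAL_LOSS"
    OPTIMAL_GAIN = "OPTIMAL_GAIN"
    NO_CHANGE = "NO_CHANGE"


@dataclass(frozen=True)
class ChromatinAnnotation:
    in_dhs: bool
    in_tf: bool
    rvis_intolerant: Optional[bool]
    phylop: Optional[float]


def ref_alt_codons(m: Mutation, t: TranscriptModel) -> tuple[str, str]:
    """Reference and alternate codons read from the CDS at the mutated
    position (frame = (cds_pos − 1) mod 3)."""
    if not 1 <= m.cds_pos <= t.cds_len:
        raise ValueError(f"cds_pos {m.cds_pos} outside CDS of {t.transcript_id}")
    idx = (m.cds_pos - 1) // 3
    frame = (m.cds_pos - 1) % 3
    ref_codon = t.cds_sequence[3 * idx : 3 * idx + 3]
    if ref_codon[frame] != m.ref_allele:
        raise ValueError(
            f"CDS base {ref_codon[frame]!r} at cds_pos {m.cds_pos} of "
            f"{t.transcript_id} does not match ref allele {m.ref_allele!r}"
        )
    alt_codon = ref_codon[:frame] + m.alt_allele + ref_codon[frame + 1 :]
    return ref_codon, alt_codon


def classify_codon_change(
    ref_codon: str, alt_codon: str, table: CodonTable
) -> CodonChange:
    """OPTIMAL_LOSS / OPTIMAL_GAIN / NO_CHANGE for a synonymous codon pair."""
    if ref_codon == alt_codon:
        raise ValueError("codons are identical")
    if not table.synonymous(ref_codon, alt_codon):
        raise ValueError(f"{ref_codon}->{alt_codon} is not a synonymous change")
    ref_opt, alt_opt = table.is_optimal(ref_codon), table.is_optimal(alt_codon)
    if ref_opt and not alt_opt:
        return CodonChange.OPTIMAL_LOSS
    if alt_opt and not ref_opt:
        return CodonChange.OPTIMAL_GAIN
    return CodonChange.NO_CHANGE


def overlaps_track(m: Mutation, track: IntervalTrack) -> bool:
    """Strict containment of the mutated base (1-based → 0-based) in the
    track; no proximity window."""
    return track.contains(m.chrom, m.pos - 1)


def attach_scores(
    m: Mutation,
    rvis: Optional[GeneScoreTable] = None,
    phylop: Optional[GeneScoreTable] = None,
    intolerant_top_fraction: float = 0.25,
) -> tuple[Optional[bool], Optional[float]]:
    """(rvis_intolerant, phylop) for one mutation.

    RVIS percentiles run from 0 (most intolerant); a gene is intolerant
    when its percentile < 100 × intolerant_top_fraction. Genes missing
    from the table yield None (excluded from the comparison downstream).
    """
    intolerant: Optional[bool] = None
    if rvis is not None:
        pct = rvis.gene(m.gene_symbol)
        if pct is not None:
            intolerant = pct < 100.0 * intolerant_top_fraction
    score: Optional[float] = None
    if phylop is not None:
        score = phylop.site(m.chrom, m.pos)
    return intolerant, score
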