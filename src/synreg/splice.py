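"""Splice-proximity annotation and exonic-splicing-regulator (ESR) scanning.

A synonymous substitution can create or destroy exonic splicing enhancer
(ESE) or silencer (ESS) hexamers. Every k-mer window covering the mutated
base (k of them for a k-mer motif, offsets −(k−1)..0 through 0..k−1) is
compared between the reference and alternate alleles against the motif
sets; a membership change in any window is a gain or loss event. The
mutation's distance to the nearest internal exon/intron boundary defines
the near-splice flag (default: within 30 bp, with the intron-adjacent
exonic base at distance 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .model import DNA_BASES, MotifSet, Mutation, TranscriptModel

ESR_EVENT_TYPES = ("ESE_GAIN", "ESE_LOSS", "ESS_GAIN", "ESS_LOSS")

DEFAULT_NEAR_SPLICE_BP = 30


@dataclass(frozen=True)
class EsrEvents:
    """ESR gain/loss calls with the window offsets that triggered each."""

    events: frozenset[str] = frozenset()
    offsets: tuple[tuple[str, int], ...] = ()  # (event type, window start offset)

    def __bool__(self) -> bool:
        return bool(self.events)

    def as_text(self) -> str:
        return ";".join(sorted(self.events))


@dataclass(frozen=True)
class SpliceAnnotation:
    distance_bp: Optional[int]
    near_splice: bool
    esr_events: EsrEvents
    scan_eligible: bool = True

    @property
    def esr_near_splice(self) -> bool:
        """The enrichment-relevant composite: an ESR change at a near-splice
        mutation."""
        return bool(self.esr_events) and self.near_splice


def distance_to_nearest_splice_site(
    m: Mutation, t: TranscriptModel
) -> Optional[int]:
    """Distance in bases from the mutated base to the nearest internal
    exon/intron boundary (intron-adjacent exonic base = 1); None for
    single-exon transcripts. Transcript termini are not splice sites."""
    pos0 = m.pos - 1
    exon_idx = None
    for i, (s, e) in enumerate(t.exons):
        if s <= pos0 < e:
            exon_idx = i
            break
    if exon_idx is None:
        raise ValueError(f"mutation at {m.chrom}:{m.pos} is not exonic in {t.transcript_id}")
    n = len(t.exons)
    if n == 1:
        return None
    s, e = t.exons[exon_idx]
    candidates = []
    if exon_idx > 0:
        candidates.append(pos0 - s + 1)  # acceptor side of this exon
    if exon_idx < n - 1:
        candidates.append(e - pos0)  # donor side (half-open end)
    return min(candidates)


def scan_windows(
    context: str, centre_index: int, ref: str, alt: str, k: int
) -> tuple[list[str], list[str], list[int]]:
    """All k-mers of the context covering the centre position, for both
    alleles.

    Returns (ref_windows, alt_windows, start_offsets) where offsets are
    relative to the mutated base (offset −(k−1) is the window ending at
    the mutation, offset 0 the window starting at it). Windows extending
    past the context, or containing non-ACGT characters, are omitted
    rather than padded.
    """
    if not 0 <= centre_index < len(context):
        raise ValueError("centre_index outside context")
    if context[centre_index] != ref:
        raise ValueError("context centre does not match ref allele")
    alt_context = context[:centre_index] + alt + context[centre_index + 1 :]
    ref_windows: list[str] = []
    alt_windows: list[str] = []
    offsets: list[int] = []
    for off in range(-(k - 1), 1):
        start = centre_index + off
        if start < 0 or start + k > len(context):
            continue
        w_ref = context[start : start + k]
        if set(w_ref) - DNA_BASES:
            continue
        ref_windows.append(w_ref)
        alt_windows.append(alt_context[start : start + k])
        offsets.append(off)
    return ref_windows, alt_windows, offsets


def classify_esr_change(
    ref_windows: Sequence[str],
    alt_windows: Sequence[str],
    ese: MotifSet,
    ess: MotifSet,
    offsets: Optional[Sequence[int]] = None,
) -> EsrEvents:
    """Gain/loss calls: an event fires when a window's set membership differs
    between alleles. A mutation can carry several event types at once."""
    if offsets is None:
        offsets = range(-(len(ref_windows) - 1), 1)
    events: set[str] = set()
    detail: list[tuple[str, int]] = []

    def _check(motifs: MotifSet, gain: str, loss: str) -> None:
        for w_ref, w_alt, off in zip(ref_windows, alt_windows, offsets):
            in_ref, in_alt = w_ref in motifs, w_alt in motifs
            if in_alt and not in_ref:
                events.add(gain)
                detail.append((gain, off))
            elif in_ref and not in_alt:
                events.add(loss)
                detail.append((loss, off))

    _check(ese, "ESE_GAIN", "ESE_LOSS")
    _check(ess, "ESS_GAIN", "ESS_LOSS")
    return EsrEvents(events=frozenset(events), offsets=tuple(detail))


def annotate_splice(
    m: Mutation,
    t: TranscriptModel,
    ese: MotifSet,
    ess: MotifSet,
    near_threshold: int = DEFAULT_NEAR_SPLICE_BP,
) -> SpliceAnnotation:
    """Distance, near-splice flag and ESR events for one mutation."""
    distance = distance_to_nearest_splice_site(m, t)
    near = distance is not None and distance <= near_threshold
    ref_w, alt_w, offs = scan_windows(m.context, m.context_w, m.ref_allele, m.alt_allele, k=6)
    events = classify_esr_change(ref_w, alt_w, ese, ess, offs) if ref_w else EsrEvents()
    return SpliceAnnotation(
        distance_bp=distance,
        near_splice=near,
        esr_events=events,
        scan_eligible=bool(ref_w),
    )
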