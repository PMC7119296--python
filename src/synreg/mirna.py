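"""miRNA seed extraction and target-site gain/loss scanning.

Seeds follow the A-anchor rule: when the first base of the mature miRNA
is adenine, positions 2-7 form a 6-nt seed whose complementary site is
followed by a target-side adenine (the "A anchor"); otherwise positions
2-8 form a 7-nt seed. The mRNA target motif is the reverse complement of
the seed in DNA alphabet — always a 7-mer (the anchored case appends the
'A'). Each of the seven 7-bp windows covering a mutated base is compared
between alleles against the target-motif set; matching is exact (no
G:U wobble).

A ``direct`` matching mode compares the sense-mRNA windows to the seed
sequence itself rather than to its reverse complement (the literal
wording of some descriptions of this analysis); the default is the
canonical target-site definition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .model import MiRNA, SeedMotif, revcomp
from .splice import scan_windows

RNA_TO_DNA = str.maketrans("ACGU", "ACGT")


@dataclass(frozen=True)
class MirnaEvents:
    """Target-site gain/loss calls with the contributing miRNA ids."""

    events: frozenset[str] = frozenset()  # subset of {SITE_GAIN, SITE_LOSS}
    gained_ids: tuple[str, ...] = ()
    lost_ids: tuple[str, ...] = ()

    def __bool__(self) -> bool:
        return bool(self.events)

    def as_text(self) -> str:
        return ";".join(sorted(self.events))

    @property
    def mirna_ids(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.gained_ids) | set(self.lost_ids)))


def extract_seed(m: MiRNA) -> SeedMotif:
    """Seed of a mature miRNA under the A-anchor rule (1-based positions
    on the 5'→3' mature sequence)."""
    if len(m.mature_seq) < 8:
        raise ValueError(f"{m.mirna_id}: mature sequence must be >= 8 nt")
    anchored = m.mature_seq[0] == "A"
    seed = m.mature_seq[1:7] if anchored else m.mature_seq[1:8]
    return SeedMotif(
        mirna_id=m.mirna_id,
        seed=seed,
        anchored=anchored,
        target_motif=seed_to_target_motif_seq(seed, anchored),
    )


def seed_to_target_motif_seq(seed: str, anchored: bool) -> str:
    """DNA 7-mer the target site spells on the mRNA (5'→3'): the reverse
    complement of the seed, with the anchored case appending the target
    adenine after the 6-nt match."""
    dna = seed.translate(RNA_TO_DNA)
    motif = revcomp(dna)
    if anchored:
        motif += "A"
    return motif


def seed_to_target_motif(s: SeedMotif) -> str:
    return seed_to_target_motif_seq(s.seed, s.anchored)


def build_target_index(
    motifs: Sequence[SeedMotif], match: str = "target"
) -> dict[str, tuple[str, ...]]:
    """Motif k-mer → contributing miRNA ids.

    ``match='target'`` indexes the reverse-complement target 7-mer
    (canonical target-site definition); ``match='direct'`` indexes the
    seed itself in DNA alphabet on the sense strand (6-mers for anchored
    seeds, 7-mers otherwise).
    """
    index: dict[str, list[str]] = {}
    for s in motifs:
        if match == "target":
            key = s.target_motif
        elif match == "direct":
            key = s.seed.translate(RNA_TO_DNA)
        else:
            raise ValueError(f"unknown match mode {match!r}")
        index.setdefault(key, []).append(s.mirna_id)
    return {k: tuple(v) for k, v in index.items()}


def scan_mirna_change(
    context: str,
    centre_index: int,
    ref: str,
    alt: str,
    motifs: Sequence[SeedMotif],
    match: str = "target",
) -> MirnaEvents:
    """Gain/loss of miRNA target sites in the k-bp windows covering the
    mutated base (k = 7 for target motifs; direct anchored seeds scan
    their native 6-mers).

    A gain fires when an alternate-allele window equals a motif whose
    reference counterpart (same offset) does not, and conversely for a
    loss — equivalent to diffing positioned motif occurrences that
    overlap the mutated base.
    """
    index = build_target_index(motifs, match=match)
    return scan_with_index(context, centre_index, ref, alt, index)


def scan_with_index(
    context: str,
    centre_index: int,
    ref: str,
    alt: str,
    index: dict[str, tuple[str, ...]],
) -> MirnaEvents:
    """As :func:`scan_mirna_change` but with a prebuilt motif index
    (cohort loops build the index once)."""
    gained: set[str] = set()
    lost: set[str] = set()
    for k in sorted({len(key) for key in index}):
        ref_w, alt_w, _ = scan_windows(context, centre_index, ref, alt, k=k)
        for w_ref, w_alt in zip(ref_w, alt_w):
            ids_ref = index.get(w_ref)
            ids_alt = index.get(w_alt)
            if ids_alt and (not ids_ref or ids_ref != ids_alt):
                gained.update(set(ids_alt) - set(ids_ref or ()))
            if ids_ref and (not ids_alt or ids_ref != ids_alt):
                lost.update(set(ids_ref) - set(ids_alt or ()))
    events: set[str] = set()
    if gained:
        events.add("SITE_GAIN")
    if lost:
        events.add("SITE_LOSS")
    return MirnaEvents(
        events=frozenset(events),
        gained_ids=tuple(sorted(gained)),
        lost_ids=tuple(sorted(lost)),
    )
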