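"""Cohort-level annotation: applies every mechanism annotator to a
mutation table and returns the table with the annotation columns the
enrichment and recurrence stages consume.

The per-mutation operations live in :mod:`synreg.splice`,
:mod:`synreg.mirna` and :mod:`synreg.features`; this module only loops
them efficiently over a cohort DataFrame (columns as produced by
``io.mutations_to_frame`` plus the ``class`` column from stratify).
"""

from __future__ import annotations

from bisect import bisect_right
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .features import classify_codon_change
from .mirna import SeedMotif, build_target_index, scan_with_index
from .model import (
    CodonTable,
    GeneScoreTable,
    IntervalTrack,
    MotifSet,
    TranscriptModel,
)
from .splice import classify_esr_change, scan_windows

ANNOTATION_COLUMNS = (
    "distance_bp",
    "near_splice",
    "esr_events",
    "esr_near_splice",
    "scan_eligible",
    "mirna_events",
    "mirna_ids",
    "ref_codon",
    "alt_codon",
    "codon_change",
    "in_dhs",
    "in_tf",
    "rvis_intolerant",
    "phylop",
)


def _distance(t: TranscriptModel, pos0: int, starts: list[int]) -> Optional[float]:
    i = bisect_right(starts, pos0) - 1
    if i < 0 or pos0 >= t.exons[i][1]:
        raise ValueError(
            f"mutation at {t.chrom}:{pos0 + 1} is not exonic in {t.transcript_id}"
        )
    n = len(t.exons)
    if n == 1:
        return None
    s, e = t.exons[i]
    best = None
    if i > 0:
        best = pos0 - s + 1
    if i < n - 1:
        d = e - pos0
        best = d if best is None else min(best, d)
    return float(best)


def annotate_cohort(
    df: pd.DataFrame,
    transcripts: Mapping[str, TranscriptModel],
    ese: MotifSet,
    ess: MotifSet,
    seed_motifs: Sequence[SeedMotif] = (),
    codon_table: Optional[CodonTable] = None,
    dhs: Optional[IntervalTrack] = None,
    tf: Optional[IntervalTrack] = None,
    rvis: Optional[GeneScoreTable] = None,
    phylop: Optional[GeneScoreTable] = None,
    near_threshold: int = 30,
    mirna_match: str = "target",
    intolerant_top_fraction: float = 0.25,
) -> pd.DataFrame:
    """Annotate every mutation with splice, miRNA, codon and chromatin
    features. ``transcripts`` is keyed by transcript_id (e.g. the output
    of ``select_longest_transcript`` re-keyed, or any id → model map)."""
    codon_table = codon_table or CodonTable()
    mirna_index = build_target_index(seed_motifs, match=mirna_match) if seed_motifs else {}
    exon_starts = {tid: [s for s, _ in t.exons] for tid, t in transcripts.items()}

    n = len(df)
    distance = np.full(n, np.nan)
    near = np.zeros(n, dtype=bool)
    esr_events = [""] * n
    esr_near = np.zeros(n, dtype=bool)
    eligible = np.ones(n, dtype=bool)
    mir_events = [""] * n
    mir_ids = [""] * n
    ref_codons = [""] * n
    alt_codons = [""] * n
    codon_changes = [""] * n
    in_dhs = np.zeros(n, dtype=bool)
    in_tf = np.zeros(n, dtype=bool)
    rvis_flags: list[Optional[bool]] = [None] * n
    phylop_scores = np.full(n, np.nan)

    cols = {c: df.columns.get_loc(c) for c in
            ("gene", "transcript", "chrom", "pos", "ref", "alt", "cds_pos", "context")}
    intolerant_cut = 100.0 * intolerant_top_fraction

    for i, row in enumerate(df.itertuples(index=False)):
        tid = row[cols["transcript"]]
        t = transcripts.get(tid)
        if t is None:
            raise KeyError(f"no transcript model for {tid!r}")
        chrom = row[cols["chrom"]]
        pos = int(row[cols["pos"]])
        ref = row[cols["ref"]]
        alt = row[cols["alt"]]
        context = row[cols["context"]]
        centre = len(context) // 2

        d = _distance(t, pos - 1, exon_starts[tid])
        if d is not None:
            distance[i] = d
            near[i] = d <= near_threshold

        ref_w, alt_w, offs = scan_windows(context, centre, ref, alt, k=6)
        if ref_w:
            ev = classify_esr_change(ref_w, alt_w, ese, ess, offs)
            esr_events[i] = ev.as_text()
            esr_near[i] = bool(ev) and near[i]
        else:
            eligible[i] = False

        if mirna_index:
            mev = scan_with_index(context, centre, ref, alt, mirna_index)
            mir_events[i] = mev.as_text()
            mir_ids[i] = ";".join(mev.mirna_ids)

        cds_pos = int(row[cols["cds_pos"]])
        idx3 = (cds_pos - 1) // 3
        frame = (cds_pos - 1) % 3
        ref_codon = t.cds_sequence[3 * idx3 : 3 * idx3 + 3]
        if ref_codon[frame] != ref:
            raise ValueError(
                f"CDS base at cds_pos {cds_pos} of {tid} does not match ref allele"
            )
        alt_codon = ref_codon[:frame] + alt + ref_codon[frame + 1 :]
        ref_codons[i] = ref_codon
        alt_codons[i] = alt_codon
        codon_changes[i] = classify_codon_change(ref_codon, alt_codon, codon_table).value

        if dhs is not None:
            in_dhs[i] = dhs.contains(chrom, pos - 1)
        if tf is not None:
            in_tf[i] = tf.contains(chrom, pos - 1)
        if rvis is not None:
            pct = rvis.gene(row[cols["gene"]])
            if pct is not None:
                rvis_flags[i] = pct < intolerant_cut
        if phylop is not None:
            score = phylop.site(chrom, pos)
            if score is not None:
                phylop_scores[i] = score

    out = df.copy()
    out["distance_bp"] = distance
    out["near_splice"] = near
    out["esr_events"] = esr_events
    out["esr_near_splice"] = esr_near
    out["scan_eligible"] = eligible
    out["mirna_events"] = mir_events
    out["mirna_ids"] = mir_ids
    out["ref_codon"] = ref_codons
    out["alt_codon"] = alt_codons
    out["codon_change"] = codon_changes
    out["in_dhs"] = in_dhs
    out["in_tf"] = in_tf
    out["rvis_intolerant"] = pd.array(rvis_flags, dtype="boolean")
    out["phylop"] = phylop_scores
    return out
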