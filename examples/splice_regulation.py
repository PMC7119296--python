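"""Annotate one mutation for splice proximity and ESE/ESS change.

A substitution 11 bp inside an exon converts TAAGAA-containing windows
into the ESE hexamer GAAGAA: an ESE gain at a near-splice position —
the composite feature the enrichment stage tests.
"""

from synreg.model import MotifSet, Mutation, TranscriptModel
from synreg.splice import annotate_splice, scan_windows

transcript = TranscriptModel(
    gene_symbol="DEMO", transcript_id="DEMO-1", chrom="chr1", strand="+",
    exons=((100, 200), (300, 400)),
    cds_interval=(100, 398),
    cds_sequence="A" * 198,
)
mutation = Mutation(
    gene_symbol="DEMO", transcript_id="DEMO-1", chrom="chr1", pos=190,
    ref_allele="T", alt_allele="A", strand="+", sample_count=3, score=0.85,
    cds_pos=90, context="GAAGATAAGAA",
)

ref_w, alt_w, offsets = scan_windows(mutation.context, 5, "T", "A", k=6)
print("6-bp windows covering the mutated base (offset: ref -> alt):")
for off, r, a in zip(offsets, ref_w, alt_w):
    print(f"  {off:+d}: {r} -> {a}")

ese = MotifSet("ESE", frozenset({"GAAGAA"}))
ess = MotifSet("ESS", frozenset())
ann = annotate_splice(mutation, transcript, ese, ess)
print(f"\ndistance to nearest splice site: {ann.distance_bp} bp "
      f"(near-splice: {ann.near_splice})")
print("ESR events:", ann.esr_events.as_text() or "none")
print("composite near-splice ESR flag:", ann.esr_near_splice)
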