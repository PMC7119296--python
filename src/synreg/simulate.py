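"""Synthetic reference and cohort generator with planted effect sizes.

The generator emulates the statistical structure of a melanoma
synonymous-mutation cohort: multi-exon coding transcripts, a
UV-signature-like 12-type substitution spectrum (C→T / G→A excess),
a two-population pathogenicity-score mixture (pathogenic mass above 0.7,
neutral below 0.5), per-mutation sample-recurrence counts, ESE/ESS
hexamer sets of configurable size, miRNA seed motifs, DHS/TF interval
tracks covering a configurable fraction of exonic bases, and per-gene
background rates R consistent with λ = 2·R·S.

Synonymy is guaranteed by construction: candidate sites are enumerated
from the degenerate codon positions of the generated CDS, so every
emitted mutation re-translates to the same amino acid. Mechanism
features are *planted* by odds multiplication: the pathogenic class
samples candidate events with their baseline weight multiplied by
``or_feature`` for every feature the event carries, while the neutral
class samples from the baseline — so the population odds ratio of each
feature is exactly the configured multiplier, and enrichment-parameter
recovery is a closed loop.

Randomness comes from one seed, split into named substreams
(genome / motifs / mirna / tracks / rates / codon for the reference;
classes / sites / scores for each cohort); identical (config, seed)
pairs produce byte-identical emitted files.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from . import io as sio
from .mirna import build_target_index, extract_seed, scan_with_index
from .model import (
    CodonTable,
    GENETIC_CODE,
    GeneRateTable,
    GeneScoreTable,
    IntervalTrack,
    MiRNA,
    MotifSet,
    TranscriptModel,
    revcomp,
)
from .splice import classify_esr_change, scan_windows
from .stratify import SUBSTITUTION_TYPES

_BASES = "ACGT"
_SENSE_CODONS = tuple(sorted(GENETIC_CODE))

#: Melanoma-like default substitution-type probabilities: the UV signature
#: puts most mass on C→T and its complement G→A.
DEFAULT_SUBSTITUTION_PROBS: Mapping[str, float] = {
    t: (0.38 if t in ("C>T", "G>A") else 0.024) for t in SUBSTITUTION_TYPES
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the real study's scale where it states one: S = 341
    samples, 6,033 mutations of which 1,080 are pathogenic, 402 ESE and
    316 ESS hexamers. Remaining values are chosen as realistic for human
    coding genes (exon ~60-300 nt, CDS 0.9-6 kb, introns 0.2-2 kb) and
    ENCODE-like track coverage.
    """

    n_genes: int = 60
    exons_per_gene: tuple[int, int] = (2, 8)
    cds_length: tuple[int, int] = (900, 6000)
    intron_length: tuple[int, int] = (200, 2000)
    n_samples: int = 341
    n_mutations: int = 6033
    pathogenic_fraction: float = 1080 / 6033
    score_pathogenic_shape: tuple[float, float] = (2.0, 1.5)
    score_neutral_shape: tuple[float, float] = (1.5, 2.0)
    substitution_probs: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SUBSTITUTION_PROBS)
    )
    or_near_splice_esr: float = 1.0
    or_dhs: float = 1.0
    or_optimal_loss: float = 1.0
    dhs_coverage_fraction: float = 0.15
    tf_coverage_fraction: float = 0.10
    n_ese: int = 402
    n_ess: int = 316
    n_mirna: int = 50
    base_rate_per_nt: float = 5e-9
    recurrent_gene_boost: Mapping[str, float] = field(default_factory=dict)
    mirna_conservation_shift: float = 0.5
    context_w: int = 10

    def __post_init__(self) -> None:
        probs = self.substitution_probs
        if set(probs) != set(SUBSTITUTION_TYPES):
            raise ValueError("substitution_probs must cover exactly the 12 types")
        if abs(sum(probs.values()) - 1.0) > 1e-9:
            raise ValueError("substitution_probs must sum to 1")
        if not 0.0 <= self.pathogenic_fraction <= 1.0:
            raise ValueError("pathogenic_fraction must be in [0, 1]")
        for name in ("or_near_splice_esr", "or_dhs", "or_optimal_loss"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_ese + self.n_ess > 4096:
            raise ValueError("n_ese + n_ess exceeds the 4096 possible hexamers")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["substitution_probs"] = dict(self.substitution_probs)
        d["recurrent_gene_boost"] = dict(self.recurrent_gene_boost)
        return d


@dataclass
class SyntheticReference:
    """Reference bundle: transcripts, motif sets, miRNAs, tracks, tables,
    plus the enumerated candidate-event pool cohorts are drawn from."""

    transcripts: dict[str, TranscriptModel]
    ese: MotifSet
    ess: MotifSet
    mirnas: list[MiRNA]
    codon_table: CodonTable
    dhs: IntervalTrack
    tf: IntervalTrack
    gene_rates: GeneRateTable
    rvis: GeneScoreTable
    events: pd.DataFrame
    config: SyntheticConfig
    seed: int

    @property
    def seed_motifs(self):
        return [extract_seed(m) for m in self.mirnas]


@dataclass
class TruthRecord:
    """Planted truth for one generated cohort."""

    config: dict
    reference_seed: int
    cohort_seed: int
    per_mutation: pd.DataFrame  # class + planted feature booleans
    gene_rates: dict[str, float]

    def to_json_dict(self) -> dict:
        return {
            "config": self.config,
            "reference_seed": self.reference_seed,
            "cohort_seed": self.cohort_seed,
            "gene_rates": self.gene_rates,
            "per_mutation": self.per_mutation.to_dict(orient="list"),
        }


def _substream(seed: int, name: str) -> np.random.Generator:
    """Named substream of one root seed (stable across runs)."""
    digest = int.from_bytes(name.encode(), "big") % (2**31)
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(digest,)))


def _hexamer(index: int) -> str:
    out = []
    for _ in range(6):
        out.append(_BASES[index % 4])
        index //= 4
    return "".join(reversed(out))


def _make_gene(
    rng: np.random.Generator, cfg: SyntheticConfig, gene_idx: int
) -> TranscriptModel:
    lo_c, hi_c = cfg.cds_length[0] // 3, cfg.cds_length[1] // 3
    total_codons = int(rng.integers(lo_c, hi_c + 1))
    n_exons = int(rng.integers(cfg.exons_per_gene[0], cfg.exons_per_gene[1] + 1))
    min_codons = 20  # >= 60 nt per exon
    n_exons = max(1, min(n_exons, total_codons // min_codons))
    free = total_codons - n_exons * min_codons
    alloc = rng.multinomial(free, np.full(n_exons, 1.0 / n_exons))
    exon_lengths = (min_codons + alloc) * 3
    introns = rng.integers(cfg.intron_length[0], cfg.intron_length[1] + 1, size=n_exons - 1)
    exons = []
    pos = 1000
    for i, length in enumerate(exon_lengths):
        exons.append((pos, pos + int(length)))
        pos += int(length)
        if i < n_exons - 1:
            pos += int(introns[i])
    strand = "+" if rng.random() < 0.5 else "-"
    codons = rng.choice(len(_SENSE_CODONS), size=total_codons)
    cds = "ATG" + "".join(_SENSE_CODONS[c] for c in codons[1:])
    return TranscriptModel(
        gene_symbol=f"GENE{gene_idx:03d}",
        transcript_id=f"TR{gene_idx:03d}",
        chrom=f"chr{gene_idx + 1}",
        strand=strand,
        exons=tuple(exons),
        cds_interval=(exons[0][0], exons[-1][1]),
        cds_sequence=cds,
    )


def _cds_to_genomic_array(t: TranscriptModel) -> np.ndarray:
    """0-based genomic position of every CDS offset (coding order)."""
    positions = []
    for s, e in t.exons:
        positions.extend(range(s, e))
    arr = np.asarray(positions)
    if t.strand == "-":
        arr = arr[::-1]
    return arr


def _boundary_distance(t: TranscriptModel, pos0_arr: np.ndarray) -> np.ndarray:
    """Distance to nearest internal splice boundary per position (nan for
    single-exon transcripts)."""
    n = len(t.exons)
    out = np.full(pos0_arr.shape, np.nan)
    if n == 1:
        return out
    for i, (s, e) in enumerate(t.exons):
        mask = (pos0_arr >= s) & (pos0_arr < e)
        if not mask.any():
            continue
        cands = []
        if i > 0:
            cands.append(pos0_arr[mask] - s + 1)
        if i < n - 1:
            cands.append(e - pos0_arr[mask])
        out[mask] = np.minimum.reduce(cands)
    return out


def generate_reference(cfg: SyntheticConfig, seed: int) -> SyntheticReference:
    """Build the full synthetic reference, deterministic under (cfg, seed)."""
    rng_genome = _substream(seed, "genome")
    transcripts = {
        f"TR{g:03d}": _make_gene(rng_genome, cfg, g) for g in range(cfg.n_genes)
    }

    rng_motif = _substream(seed, "motifs")
    picks = rng_motif.choice(4096, size=cfg.n_ese + cfg.n_ess, replace=False)
    ese = MotifSet(
        "ESE", frozenset(_hexamer(int(i)) for i in picks[: cfg.n_ese]), ("synthetic-ese",)
    )
    ess = MotifSet(
        "ESS", frozenset(_hexamer(int(i)) for i in picks[cfg.n_ese :]), ("synthetic-ess",)
    )

    rng_mirna = _substream(seed, "mirna")
    mirnas = [
        MiRNA(
            mirna_id=f"syn-miR-{i + 1}",
            mature_seq="".join(rng_mirna.choice(list("ACGU"), size=22)),
        )
        for i in range(cfg.n_mirna)
    ]

    rng_codon = _substream(seed, "codon")
    by_aa: dict[str, list[str]] = {}
    for codon, aa in GENETIC_CODE.items():
        by_aa.setdefault(aa, []).append(codon)
    optimal = set()
    for aa, codons in sorted(by_aa.items()):
        if len(codons) > 1 and rng_codon.random() < 0.9:
            optimal.add(sorted(codons)[int(rng_codon.integers(len(codons)))])
    codon_table = CodonTable(optimal_codons=frozenset(optimal))

    rng_tracks = _substream(seed, "tracks")
    all_exons = [
        (t.chrom, s, e) for t in transcripts.values() for s, e in t.exons
    ]
    dhs = _coverage_track("DHS", all_exons, cfg.dhs_coverage_fraction, rng_tracks)
    tf = _coverage_track("TF", all_exons, cfg.tf_coverage_fraction, rng_tracks)

    rng_rates = _substream(seed, "rates")
    rates = {
        t.gene_symbol: (cfg.base_rate_per_nt * t.cds_len, t.cds_len)
        for t in transcripts.values()
    }
    gene_rates = GeneRateTable(rates=rates)
    rvis = GeneScoreTable(
        gene_scores={
            t.gene_symbol: float(rng_rates.uniform(0.0, 100.0))
            for t in sorted(transcripts.values(), key=lambda t: t.gene_symbol)
        },
        kind="rvis",
    )

    events = _enumerate_events(cfg, transcripts, ese, ess, mirnas, codon_table, dhs)
    return SyntheticReference(
        transcripts=transcripts,
        ese=ese,
        ess=ess,
        mirnas=mirnas,
        codon_table=codon_table,
        dhs=dhs,
        tf=tf,
        gene_rates=gene_rates,
        rvis=rvis,
        events=events,
        config=cfg,
        seed=seed,
    )


def _coverage_track(
    label: str,
    exons: list[tuple[str, int, int]],
    fraction: float,
    rng: np.random.Generator,
) -> IntervalTrack:
    """Intervals covering ``fraction`` of the exonic bases (to the base):
    whole exons in random order, the last one truncated to hit the target."""
    if fraction <= 0:
        return IntervalTrack(label, {})
    total = sum(e - s for _, s, e in exons)
    target = int(round(fraction * total))
    order = rng.permutation(len(exons))
    intervals: dict[str, list[tuple[int, int]]] = {}
    got = 0
    for idx in order:
        if got >= target:
            break
        chrom, s, e = exons[int(idx)]
        take = min(e - s, target - got)
        off = int(rng.integers(0, e - s - take + 1)) if take < e - s else 0
        intervals.setdefault(chrom, []).append((s + off, s + off + take))
        got += take
    return IntervalTrack(label, intervals)


def _enumerate_events(
    cfg: SyntheticConfig,
    transcripts: dict[str, TranscriptModel],
    ese: MotifSet,
    ess: MotifSet,
    mirnas: list[MiRNA],
    codon_table: CodonTable,
    dhs: IntervalTrack,
) -> pd.DataFrame:
    """All synonymous single-base events of the reference, annotated with
    the mechanism features used for planting."""
    mirna_index = build_target_index([extract_seed(m) for m in mirnas]) if mirnas else {}
    w = cfg.context_w
    records: dict[str, list] = {
        k: []
        for k in (
            "gene", "transcript", "chrom", "pos", "ref", "alt", "strand",
            "cds_pos", "context", "type", "distance",
            "near", "esr", "dhs", "loss", "mirna",
        )
    }
    for tid in sorted(transcripts):
        t = transcripts[tid]
        cds = t.cds_sequence
        gpos = _cds_to_genomic_array(t)
        dist = _boundary_distance(t, gpos)
        padded = "N" * w + cds + "N" * w
        for off in range(len(cds)):
            ref = cds[off]
            codon_idx, frame = divmod(off, 3)
            ref_codon = cds[3 * codon_idx : 3 * codon_idx + 3]
            aa = GENETIC_CODE[ref_codon]
            for alt in _BASES:
                if alt == ref:
                    continue
                alt_codon = ref_codon[:frame] + alt + ref_codon[frame + 1 :]
                if GENETIC_CODE.get(alt_codon) != aa:
                    continue
                context = padded[off : off + 2 * w + 1]
                ref_w, alt_w, offs = scan_windows(context, w, ref, alt, k=6)
                esr = bool(classify_esr_change(ref_w, alt_w, ese, ess, offs)) if ref_w else False
                mirna_ev = (
                    bool(scan_with_index(context, w, ref, alt, mirna_index))
                    if mirna_index
                    else False
                )
                d = dist[off]
                near = bool(d <= 30) if not np.isnan(d) else False
                g_ref, g_alt = (ref, alt) if t.strand == "+" else (revcomp(ref), revcomp(alt))
                records["gene"].append(t.gene_symbol)
                records["transcript"].append(tid)
                records["chrom"].append(t.chrom)
                records["pos"].append(int(gpos[off]) + 1)
                records["ref"].append(ref)
                records["alt"].append(alt)
                records["strand"].append(t.strand)
                records["cds_pos"].append(off + 1)
                records["context"].append(context)
                records["type"].append(f"{g_ref}>{g_alt}")
                records["distance"].append(d)
                records["near"].append(near)
                records["esr"].append(esr)
                records["dhs"].append(dhs.contains(t.chrom, int(gpos[off])))
                records["loss"].append(
                    codon_table.is_optimal(ref_codon) and not codon_table.is_optimal(alt_codon)
                )
                records["mirna"].append(mirna_ev)
    df = pd.DataFrame(records)
    df["f_esr_near"] = df["esr"] & df["near"]
    return df


def _draw_type_counts(
    rng: np.random.Generator, n: int, probs: np.ndarray, capacity: np.ndarray
) -> np.ndarray:
    """Multinomial type counts clipped to per-type availability; any
    overflow is redistributed over types with spare capacity."""
    if n > int(capacity.sum()):
        raise ValueError("not enough candidate events for the requested cohort")
    avail = capacity > 0
    p = np.where(avail, probs, 0.0)
    if p.sum() == 0:
        raise ValueError("no candidate events for any configured substitution type")
    counts = rng.multinomial(n, p / p.sum())
    while True:
        over = counts - capacity
        excess = int(over[over > 0].sum())
        if excess == 0:
            return counts
        counts = np.minimum(counts, capacity)
        spare = capacity - counts
        p2 = np.where(spare > 0, probs, 0.0)
        if p2.sum() == 0:
            p2 = (spare > 0).astype(float)
        counts = counts + rng.multinomial(excess, p2 / p2.sum())


def generate_cohort(
    cfg: SyntheticConfig, reference: SyntheticReference, seed: int
) -> tuple[pd.DataFrame, TruthRecord]:
    """Draw one cohort from the reference's candidate-event pool.

    Sampling is two-stage. First the per-class substitution-type counts
    are drawn from a multinomial over the configured 12-vector (restricted
    to types with available events), so the realized spectrum follows the
    configuration exactly up to multinomial noise. Then sites are drawn
    within each type without replacement (Gumbel top-k): neutral
    mutations with baseline weights (any per-gene boost), pathogenic
    mutations with the weight multiplied by the configured odds
    multiplier for every mechanism feature the event carries. Mutations
    are unique (chrom, pos, ref, alt) records.
    """
    events = reference.events
    n = cfg.n_mutations
    if n > len(events):
        raise ValueError(
            f"requested {n} mutations but only {len(events)} candidate events"
        )
    n_path = int(round(n * cfg.pathogenic_fraction))
    n_neut = n - n_path

    boost = np.ones(len(events))
    if cfg.recurrent_gene_boost:
        for gene, mult in cfg.recurrent_gene_boost.items():
            boost[(events["gene"] == gene).to_numpy()] = mult
    w_path = (
        boost
        * np.power(cfg.or_near_splice_esr, events["f_esr_near"].to_numpy(dtype=float))
        * np.power(cfg.or_dhs, events["dhs"].to_numpy(dtype=float))
        * np.power(cfg.or_optimal_loss, events["loss"].to_numpy(dtype=float))
    )

    rng_sites = _substream(seed, "sites")
    types = list(SUBSTITUTION_TYPES)
    type_arr = events["type"].to_numpy()
    by_type = {t: np.flatnonzero(type_arr == t) for t in types}
    capacity = np.array([len(by_type[t]) for t in types])
    probs = np.array([cfg.substitution_probs[t] for t in types])

    counts_p = _draw_type_counts(rng_sites, n_path, probs, capacity)
    counts_n = _draw_type_counts(rng_sites, n_neut, probs, capacity - counts_p)

    path_parts: list[np.ndarray] = []
    neut_parts: list[np.ndarray] = []
    with np.errstate(divide="ignore"):
        log_w_path = np.log(w_path)
        log_w_base = np.log(boost)
    for i, t in enumerate(types):
        pool = by_type[t]
        if len(pool) == 0:
            continue
        key = log_w_path[pool] + rng_sites.gumbel(size=len(pool))
        order = np.argsort(-key, kind="stable")
        take_p = order[: counts_p[i]]
        path_parts.append(pool[take_p])
        rest = order[counts_p[i] :]
        key_n = log_w_base[pool[rest]] + rng_sites.gumbel(size=len(rest))
        take_n = rest[np.argsort(-key_n, kind="stable")[: counts_n[i]]]
        neut_parts.append(pool[take_n])
    path_idx = np.concatenate(path_parts) if path_parts else np.array([], dtype=int)
    neut_idx = np.concatenate(neut_parts) if neut_parts else np.array([], dtype=int)
    assert len(path_idx) == n_path and len(neut_idx) == n_neut

    rng_scores = _substream(seed, "scores")
    a_p, b_p = cfg.score_pathogenic_shape
    a_n, b_n = cfg.score_neutral_shape
    eps = 1e-9
    path_scores = 0.7 + 0.3 * np.clip(rng_scores.beta(a_p, b_p, size=n_path), eps, 1 - eps)
    neut_scores = 0.5 * np.clip(rng_scores.beta(a_n, b_n, size=n_neut), eps, 1 - eps)
    path_samples = 2 + rng_scores.poisson(0.7, size=n_path)

    chosen = pd.concat(
        [events.iloc[path_idx], events.iloc[neut_idx]], ignore_index=True
    )
    chosen["class_true"] = ["PATHOGENIC"] * n_path + ["NEUTRAL"] * n_neut
    chosen["score"] = np.concatenate([path_scores, neut_scores])
    chosen["sample_count"] = np.concatenate(
        [path_samples, np.ones(n_neut, dtype=int)]
    )
    chosen["phylop"] = rng_scores.normal(0.0, 1.0, size=len(chosen)) + (
        cfg.mirna_conservation_shift * chosen["mirna"].to_numpy(dtype=float)
    )
    chosen = chosen.sort_values(
        ["transcript", "cds_pos", "alt"], kind="mergesort"
    ).reset_index(drop=True)

    cohort = pd.DataFrame(
        {
            "gene": chosen["gene"],
            "transcript": chosen["transcript"],
            "chrom": chosen["chrom"],
            "pos": chosen["pos"],
            "ref": chosen["ref"],
            "alt": chosen["alt"],
            "strand": chosen["strand"],
            "score": chosen["score"].round(6),
            "sample_count": chosen["sample_count"],
            "cds_pos": chosen["cds_pos"],
            "context": chosen["context"],
        }
    )
    truth = TruthRecord(
        config=cfg.to_dict(),
        reference_seed=reference.seed,
        cohort_seed=seed,
        per_mutation=chosen[
            ["gene", "chrom", "pos", "ref", "alt", "class_true",
             "f_esr_near", "dhs", "loss", "mirna", "phylop"]
        ].rename(columns={"dhs": "f_dhs", "loss": "f_optimal_loss", "mirna": "f_mirna"}),
        gene_rates={g: r for g, (r, _) in reference.gene_rates.rates.items()},
    )
    return cohort, truth


def emulate_paper_scale(seed: int) -> tuple[SyntheticReference, pd.DataFrame, TruthRecord]:
    """Convenience preset at the real study's scale: S = 341, exactly
    1,080 pathogenic + 4,953 neutral mutations, planted multipliers
    (1.76, 1.5, 1.3) for near-splice-ESR / DHS / optimal-loss, one gene
    boosted 10-fold."""
    cfg = SyntheticConfig(
        n_mutations=6033,
        pathogenic_fraction=1080 / 6033,
        or_near_splice_esr=1.76,
        or_dhs=1.5,
        or_optimal_loss=1.3,
        recurrent_gene_boost={"GENE000": 10.0},
    )
    reference = generate_reference(cfg, seed)
    cohort, truth = generate_cohort(cfg, reference, seed)
    return reference, cohort, truth


def write_bundle(
    reference: SyntheticReference,
    cohort: pd.DataFrame,
    truth: TruthRecord,
    outdir: str | os.PathLike,
) -> dict[str, str]:
    """Write the full input bundle (plain-text formats only) plus
    truth.json; returns the path map."""
    outdir = os.fspath(outdir)
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "mutations": os.path.join(outdir, "mutations.tsv"),
        "transcripts_bed": os.path.join(outdir, "transcripts.bed"),
        "cds_fasta": os.path.join(outdir, "cds.fa"),
        "ese": os.path.join(outdir, "ese.txt"),
        "ess": os.path.join(outdir, "ess.txt"),
        "mirna_fasta": os.path.join(outdir, "mirna.fa"),
        "dhs_bed": os.path.join(outdir, "dhs.bed"),
        "tf_bed": os.path.join(outdir, "tf.bed"),
        "codon_table": os.path.join(outdir, "codon_table.tsv"),
        "gene_rates": os.path.join(outdir, "gene_rates.tsv"),
        "rvis": os.path.join(outdir, "rvis.tsv"),
        "phylop": os.path.join(outdir, "phylop.tsv"),
        "truth": os.path.join(outdir, "truth.json"),
        "config": os.path.join(outdir, "config.json"),
    }
    cohort.to_csv(paths["mutations"], sep="\t", index=False)
    sio.write_transcripts_bed12(
        list(reference.transcripts.values()), paths["transcripts_bed"], paths["cds_fasta"]
    )
    sio.write_motif_list(reference.ese, paths["ese"])
    sio.write_motif_list(reference.ess, paths["ess"])
    sio.write_fasta(
        [(m.mirna_id, m.mature_seq) for m in reference.mirnas], paths["mirna_fasta"]
    )
    sio.write_bed_track(reference.dhs, paths["dhs_bed"])
    sio.write_bed_track(reference.tf, paths["tf_bed"])
    sio.write_codon_table(reference.codon_table, paths["codon_table"])
    sio.write_gene_rates(reference.gene_rates, paths["gene_rates"])
    sio.write_gene_scores(reference.rvis, paths["rvis"])
    phylop = GeneScoreTable(
        site_scores={
            (str(c), int(p)): float(s)
            for c, p, s in zip(
                truth.per_mutation["chrom"],
                truth.per_mutation["pos"],
                truth.per_mutation["phylop"],
            )
        },
        kind="phylop",
    )
    sio.write_site_scores(phylop, paths["phylop"])
    with open(paths["truth"], "w") as fh:
        json.dump(truth.to_json_dict(), fh, indent=1, sort_keys=True, default=str)
        fh.write("\n")
    with open(paths["config"], "w") as fh:
        json.dump(reference.config.to_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")
    return paths
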