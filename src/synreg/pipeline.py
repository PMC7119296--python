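"""End-to-end orchestration: stratify → annotate → enrich → flag
functional → gene recurrence, with a structured run report.

All tabular outputs are TSV with headers; the recurrence table mirrors
the per-gene summary columns (gene, gene_length, mechanisms, k, lambda,
p). Optional precomputed boolean columns in the input table (for
example RNA-structure or splicing-predictor significance flags) pass
through to the enrichment stage untouched via ``extra_features``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from . import io as sio
from .annotate import annotate_cohort
from .mirna import extract_seed
from .model import select_longest_transcript
from .recurrence import (
    DEFAULT_RECURRENCE_THRESHOLD,
    flag_functional,
    recurrent_genes,
)
from .stats import (
    DEFAULT_DISTANCE_BINS,
    binned_distance_enrichment,
    cumulative_distance_curves,
    enrichment_table,
)
from .stratify import (
    MutationClass,
    StratifyConfig,
    base_change_spectrum,
    classify_cohort,
    spectrum_frame,
)

logger = logging.getLogger("synreg")

DEFAULT_FEATURES = (
    "near_splice",
    "esr_change",
    "esr_near_splice",
    "mirna_change",
    "optimal_loss",
    "optimal_gain",
    "in_dhs",
    "in_tf",
    "rvis_intolerant",
)


class ConfigError(ValueError):
    """The run configuration references missing inputs."""


@dataclass
class RunConfig:
    """Paths for every input plus analysis thresholds."""

    mutations: str
    transcripts_bed: str
    cds_fasta: str
    ese: str
    ess: str
    outdir: str
    mirna_fasta: Optional[str] = None
    dhs_bed: Optional[str] = None
    tf_bed: Optional[str] = None
    codon_table: Optional[str] = None
    gene_rates: Optional[str] = None
    rvis: Optional[str] = None
    phylop: Optional[str] = None
    dialect: str = "cosmic_tsv"
    stratify: StratifyConfig = field(default_factory=StratifyConfig)
    near_threshold: int = 30
    recurrence_threshold: float = DEFAULT_RECURRENCE_THRESHOLD
    recurrence_tail: bool = False
    n_samples: int = 341
    spectrum_strand: str = "genomic"
    extra_features: tuple[str, ...] = ()
    distance_bins: tuple = DEFAULT_DISTANCE_BINS

    def validate(self) -> None:
        required = {
            "mutations": self.mutations,
            "transcripts_bed": self.transcripts_bed,
            "cds_fasta": self.cds_fasta,
            "ese": self.ese,
            "ess": self.ess,
        }
        optional = {
            "mirna_fasta": self.mirna_fasta,
            "dhs_bed": self.dhs_bed,
            "tf_bed": self.tf_bed,
            "codon_table": self.codon_table,
            "gene_rates": self.gene_rates,
            "rvis": self.rvis,
            "phylop": self.phylop,
        }
        for name, path in required.items():
            if not path or not os.path.exists(path):
                raise ConfigError(f"required input {name!r} missing: {path!r}")
        for name, path in optional.items():
            if path is not None and not os.path.exists(path):
                raise ConfigError(f"input {name!r} does not exist: {path!r}")


@dataclass
class RunReport:
    """Filtering-cascade counts and the result tables of one run."""

    n_loaded: int
    n_rejected: int
    n_pathogenic: int
    n_neutral: int
    n_excluded: int
    n_functional: int
    spectrum: pd.DataFrame
    enrichment: pd.DataFrame
    bins: pd.DataFrame
    curves: pd.DataFrame
    recurrence: pd.DataFrame
    recurrence_missing: pd.DataFrame
    config: dict

    @property
    def functional_fraction_pct(self) -> float:
        return functional_fraction(self.n_functional, self.n_pathogenic + self.n_neutral)

    def cascade(self) -> dict[str, int]:
        return {
            "loaded": self.n_loaded,
            "rejected": self.n_rejected,
            "pathogenic": self.n_pathogenic,
            "neutral": self.n_neutral,
            "excluded": self.n_excluded,
            "functional": self.n_functional,
        }


def functional_fraction(functional: int, total: int) -> float:
    """100 × functional / total, rounded to one decimal (the headline
    'x% of studied mutations are potentially functional' number)."""
    if total == 0:
        raise ZeroDivisionError("total mutation count is zero")
    return round(100.0 * functional / total, 1)


def run_pipeline(cfg: RunConfig) -> RunReport:
    """Execute all stages and write the TSV/JSON artifacts to cfg.outdir."""
    cfg.validate()
    os.makedirs(cfg.outdir, exist_ok=True)

    logger.info("loading mutations from %s (%s)", cfg.mutations, cfg.dialect)
    muts, rejects = sio.read_mutation_table(cfg.mutations, dialect=cfg.dialect)
    df = sio.mutations_to_frame(muts)
    logger.info("loaded %d mutations, %d rejects", len(df), len(rejects))
    if rejects:
        pd.DataFrame([dataclasses.asdict(r) for r in rejects]).to_csv(
            os.path.join(cfg.outdir, "rejects.tsv"), sep="\t", index=False
        )

    transcripts_all = sio.read_transcripts_bed12(cfg.transcripts_bed, cfg.cds_fasta)
    longest = select_longest_transcript(transcripts_all)
    transcripts = {t.transcript_id: t for t in longest.values()}

    df = classify_cohort(df, cfg.stratify)
    n_path = int((df["class"] == MutationClass.PATHOGENIC.value).sum())
    n_neut = int((df["class"] == MutationClass.NEUTRAL.value).sum())
    n_excl = len(df) - n_path - n_neut
    logger.info("stratified: %d pathogenic, %d neutral, %d excluded", n_path, n_neut, n_excl)

    spectrum = spectrum_frame(base_change_spectrum(df, strand=cfg.spectrum_strand))

    ese = sio.read_motif_list(cfg.ese, "ESE")
    ess = sio.read_motif_list(cfg.ess, "ESS")
    seed_motifs = (
        [extract_seed(m) for m in sio.read_mirna_fasta(cfg.mirna_fasta)]
        if cfg.mirna_fasta
        else []
    )
    codon_table = (
        sio.read_codon_table(cfg.codon_table) if cfg.codon_table else sio.default_codon_table()
    )
    dhs = sio.read_bed_track(cfg.dhs_bed, "DHS") if cfg.dhs_bed else None
    tf = sio.read_bed_track(cfg.tf_bed, "TF") if cfg.tf_bed else None
    rvis = sio.read_rvis_table(cfg.rvis) if cfg.rvis else None
    phylop = sio.read_phylop_table(cfg.phylop) if cfg.phylop else None

    # keep only mutations whose transcript survived longest-transcript selection
    known = df["transcript"].isin(transcripts)
    if not known.all():
        logger.info("dropping %d mutations on non-selected transcripts", int((~known).sum()))
        df = df[known].reset_index(drop=True)

    annotated = annotate_cohort(
        df,
        transcripts,
        ese,
        ess,
        seed_motifs=seed_motifs,
        codon_table=codon_table,
        dhs=dhs,
        tf=tf,
        rvis=rvis,
        phylop=phylop,
        near_threshold=cfg.near_threshold,
    )
    annotated = flag_functional(annotated)
    n_functional = int(annotated["functional"].sum())
    logger.info("functional: %d of %d pathogenic", n_functional, n_path)

    features = [f for f in DEFAULT_FEATURES if _feature_available(annotated, f)]
    features += [f for f in cfg.extra_features if f in annotated.columns]
    enrich = enrichment_table(annotated, features)
    bins = binned_distance_enrichment(annotated, cfg.distance_bins).to_frame()
    curves = _curves_frame(annotated)

    rec, rec_missing = (
        recurrent_genes(
            annotated,
            sio.read_gene_rates(cfg.gene_rates),
            samples=cfg.n_samples,
            threshold=cfg.recurrence_threshold,
            tail=cfg.recurrence_tail,
        )
        if cfg.gene_rates
        else (pd.DataFrame(), pd.DataFrame())
    )

    annotated.to_csv(os.path.join(cfg.outdir, "annotated.tsv"), sep="\t", index=False)
    spectrum.to_csv(os.path.join(cfg.outdir, "spectrum.tsv"), sep="\t", index=False)
    enrich.to_csv(os.path.join(cfg.outdir, "enrichment.tsv"), sep="\t", index=False)
    bins.to_csv(os.path.join(cfg.outdir, "bins.tsv"), sep="\t", index=False)
    curves.to_csv(os.path.join(cfg.outdir, "curves.tsv"), sep="\t", index=False)
    rec.to_csv(os.path.join(cfg.outdir, "recurrence.tsv"), sep="\t", index=False)
    if len(rec_missing):
        rec_missing.to_csv(
            os.path.join(cfg.outdir, "recurrence_missing_rates.tsv"), sep="\t", index=False
        )

    report = RunReport(
        n_loaded=len(muts),
        n_rejected=len(rejects),
        n_pathogenic=n_path,
        n_neutral=n_neut,
        n_excluded=n_excl,
        n_functional=n_functional,
        spectrum=spectrum,
        enrichment=enrich,
        bins=bins,
        curves=curves,
        recurrence=rec,
        recurrence_missing=rec_missing,
        config=_config_echo(cfg),
    )
    with open(os.path.join(cfg.outdir, "report.json"), "w") as fh:
        json.dump(
            {
                "cascade": report.cascade(),
                "functional_fraction_pct": (
                    report.functional_fraction_pct if (n_path + n_neut) else None
                ),
                "config": report.config,
            },
            fh,
            indent=1,
            sort_keys=True,
        )
        fh.write("\n")
    return report


def _feature_available(annotated: pd.DataFrame, feature: str) -> bool:
    from .stats import feature_column

    try:
        col = feature_column(annotated, feature)
    except KeyError:
        return False
    col = col.dropna()
    if len(col) == 0:
        return False
    # Fisher needs both margins non-degenerate; skip all-false/all-true features
    return 0 < int(col.astype(bool).sum()) < len(col)


def _curves_frame(annotated: pd.DataFrame) -> pd.DataFrame:
    curves = cumulative_distance_curves(annotated)
    rows = []
    for cls, (x, y) in curves.items():
        for xi, yi in zip(x, y):
            rows.append({"class": cls, "distance_bp": xi, "cum_prop": yi})
    return pd.DataFrame(rows, columns=["class", "distance_bp", "cum_prop"])


def _config_echo(cfg: RunConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["stratify"] = dataclasses.asdict(cfg.stratify)
    try:
        from importlib.metadata import version

        d["synreg_version"] = version("synreg")
    except Exception:  # pragma: no cover - only outside an installed env
        d["synreg_version"] = "unknown"
    return d
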