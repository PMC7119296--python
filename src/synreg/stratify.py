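"""Stratification of synonymous mutations into pathogenic / neutral classes
and the 12-type base-substitution spectrum.

The class rules follow the COSMIC/FATHMM convention: score > 0.7 is
pathogenic, score < 0.5 neutral, with recurrence filters (pathogenic
mutations must be seen in at least two samples, neutral in exactly one)
applied to increase reliability and reduce false positives. Scores equal
to a threshold, scores in between, and unscored records are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from itertools import permutations
from typing import Optional, Sequence

import pandas as pd

from .model import Mutation, revcomp


class MutationClass(str, Enum):
    PATHOGENIC = "PATHOGENIC"
    NEUTRAL = "NEUTRAL"
    EXCLUDED = "EXCLUDED"


@dataclass(frozen=True)
class StratifyConfig:
    """Score thresholds (strict inequalities) and sample-recurrence filters."""

    pathogenic_score_min: float = 0.7
    neutral_score_max: float = 0.5
    pathogenic_min_samples: int = 2
    neutral_exact_samples: int = 1

    def __post_init__(self) -> None:
        if self.neutral_score_max > self.pathogenic_score_min:
            raise ValueError("neutral_score_max must be <= pathogenic_score_min")


#: The 12 ordered substitution types ref→alt, ref ≠ alt.
SUBSTITUTION_TYPES: tuple[str, ...] = tuple(
    f"{r}>{a}" for r, a in permutations("ACGT", 2)
)


def classify_mutation(
    m: Mutation, cfg: StratifyConfig = StratifyConfig()
) -> MutationClass:
    """Assign exactly one of PATHOGENIC / NEUTRAL / EXCLUDED."""
    if m.score is None:
        return MutationClass.EXCLUDED
    if not 0.0 <= m.score <= 1.0:
        raise ValueError(f"score {m.score} outside [0, 1]")
    if m.score > cfg.pathogenic_score_min and m.sample_count >= cfg.pathogenic_min_samples:
        return MutationClass.PATHOGENIC
    if m.score < cfg.neutral_score_max and m.sample_count == cfg.neutral_exact_samples:
        return MutationClass.NEUTRAL
    return MutationClass.EXCLUDED


def classify_cohort(df: pd.DataFrame, cfg: StratifyConfig = StratifyConfig()) -> pd.DataFrame:
    """Append a ``class`` column to a cohort table (see io.mutations_to_frame)."""
    def _cls(row) -> str:
        score = row.score
        if score is None or pd.isna(score):
            return MutationClass.EXCLUDED.value
        score = float(score)
        if not 0.0 <= score <= 1.0:
            raise ValueError(f"score {score} outside [0, 1]")
        n = int(row.sample_count)
        if score > cfg.pathogenic_score_min and n >= cfg.pathogenic_min_samples:
            return MutationClass.PATHOGENIC.value
        if score < cfg.neutral_score_max and n == cfg.neutral_exact_samples:
            return MutationClass.NEUTRAL.value
        return MutationClass.EXCLUDED.value

    out = df.copy()
    out["class"] = [_cls(row) for row in df.itertuples(index=False)]
    return out


def base_change_spectrum(
    muts: Sequence[Mutation] | pd.DataFrame, strand: str = "genomic"
) -> dict[str, int]:
    """Counts over the 12 ordered substitution types.

    ``strand='genomic'`` (default) reports substitutions on the genomic
    plus strand, complementing minus-strand records — the convention under
    which UV-driven melanoma cohorts show the characteristic C→T / G→A
    excess. ``strand='coding'`` counts the stored coding-strand alleles.
    """
    if strand not in {"genomic", "coding"}:
        raise ValueError(f"strand must be 'genomic' or 'coding', got {strand!r}")
    counts = {t: 0 for t in SUBSTITUTION_TYPES}
    if isinstance(muts, pd.DataFrame):
        triples = zip(muts["ref"], muts["alt"], muts["strand"])
    else:
        triples = ((m.ref_allele, m.alt_allele, m.strand) for m in muts)
    for ref, alt, strnd in triples:
        if strand == "genomic" and strnd == "-":
            ref, alt = revcomp(ref), revcomp(alt)
        counts[f"{ref}>{alt}"] += 1
    return counts


def spectrum_frame(counts: dict[str, int]) -> pd.DataFrame:
    total = sum(counts.values())
    return pd.DataFrame(
        {
            "substitution": list(SUBSTITUTION_TYPES),
            "count": [counts[t] for t in SUBSTITUTION_TYPES],
            "fraction": [
                counts[t] / total if total else 0.0 for t in SUBSTITUTION_TYPES
            ],
        }
    )
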