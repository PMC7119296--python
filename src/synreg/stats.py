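"""Hypothesis-level statistics for the annotated cohort.

Everything here compares the PATHOGENIC and NEUTRAL mutation classes:
2×2 Fisher exact tests with odds ratios for each mechanism feature,
distance-binned enrichment near splice sites, cumulative distance
curves, a one-sided rank-sum comparison of conservation scores, and a
hypergeometric over-representation test with Benjamini–Hochberg
adjustment for gene-set analysis.

The two-sided Fisher p sums hypergeometric point probabilities no larger
than that of the observed table (the common exact-test convention). The
odds ratio is the sample OR (a·d)/(b·c), reported as infinity when
b·c = 0 with a·d > 0, alongside a Haldane–Anscombe companion (+0.5 to
every cell).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .stratify import MutationClass

DEFAULT_DISTANCE_BINS: tuple[tuple[int, Optional[int]], ...] = (
    (1, 30),
    (31, 70),
    (71, None),
)


@dataclass(frozen=True)
class ContingencyResult:
    """A 2×2 feature-by-class table: a/b feature+/− in pathogenic,
    c/d feature+/− in neutral."""

    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    odds_ratio_corrected: float
    p_two_sided: float

    @property
    def pathogenic_total(self) -> int:
        return self.a + self.b

    @property
    def neutral_total(self) -> int:
        return self.c + self.d

    def ci_95(self) -> tuple[float, float]:
        """Exact (conditional) 95% confidence interval for the odds ratio."""
        res = sps.contingency.odds_ratio(
            [[self.a, self.b], [self.c, self.d]], kind="conditional"
        )
        ci = res.confidence_interval(confidence_level=0.95)
        return float(ci.low), float(ci.high)


def fisher_2x2(a: int, b: int, c: int, d: int) -> ContingencyResult:
    """Two-sided Fisher exact test and odds ratio for a 2×2 table."""
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise ValueError("cell counts must be non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        raise ValueError("2x2 table has an all-zero margin")
    _, p = sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if b * c > 0:
        oddsr = (a * d) / (b * c)
    elif a * d > 0:
        oddsr = math.inf
    else:
        oddsr = math.nan
    corrected = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    return ContingencyResult(
        a=a, b=b, c=c, d=d,
        odds_ratio=oddsr,
        odds_ratio_corrected=corrected,
        p_two_sided=float(p),
    )


#: Named boolean features the enrichment test understands, mapped to the
#: annotated-cohort column or derivation.
_FEATURE_DERIVATIONS = {
    "near_splice": lambda df: df["near_splice"].astype(bool),
    "esr_change": lambda df: df["esr_events"].astype(str).str.len() > 0,
    "esr_near_splice": lambda df: df["esr_near_splice"].astype(bool),
    "mirna_change": lambda df: df["mirna_events"].astype(str).str.len() > 0,
    "optimal_loss": lambda df: df["codon_change"] == "OPTIMAL_LOSS",
    "optimal_gain": lambda df: df["codon_change"] == "OPTIMAL_GAIN",
    "in_dhs": lambda df: df["in_dhs"].astype(bool),
    "in_tf": lambda df: df["in_tf"].astype(bool),
    "rvis_intolerant": lambda df: df["rvis_intolerant"],
}


def feature_column(annotated: pd.DataFrame, feature: str) -> pd.Series:
    """Resolve a feature name to a boolean Series (NA allowed; NA rows are
    dropped from the contingency table)."""
    if feature in _FEATURE_DERIVATIONS:
        try:
            return _FEATURE_DERIVATIONS[feature](annotated)
        except KeyError as exc:
            raise KeyError(
                f"feature {feature!r} needs annotation column {exc.args[0]!r}; "
                "run the corresponding annotation stage first"
            ) from None
    if feature in annotated.columns:  # pass-through precomputed boolean column
        return annotated[feature]
    raise KeyError(f"unknown feature {feature!r}")


def feature_enrichment(annotated: pd.DataFrame, feature: str) -> ContingencyResult:
    """Fisher test of a boolean feature, pathogenic vs neutral."""
    flags = feature_column(annotated, feature)
    mask = flags.notna() & annotated["class"].isin(
        [MutationClass.PATHOGENIC.value, MutationClass.NEUTRAL.value]
    )
    flags = flags[mask].astype(bool)
    classes = annotated.loc[mask, "class"]
    path = classes == MutationClass.PATHOGENIC.value
    a = int((path & flags).sum())
    b = int((path & ~flags).sum())
    c = int((~path & flags).sum())
    d = int((~path & ~flags).sum())
    return fisher_2x2(a, b, c, d)


@dataclass(frozen=True)
class BinnedEnrichment:
    bins: tuple[tuple[int, Optional[int]], ...]
    results: tuple[Optional[ContingencyResult], ...]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (lo, hi), res in zip(self.bins, self.results):
            label = f"{lo}-{hi}" if hi is not None else f">={lo}"
            if res is None:
                rows.append({"bin": label, "a": 0, "b": 0, "c": 0, "d": 0,
                             "odds_ratio": np.nan, "p": np.nan})
            else:
                rows.append({"bin": label, "a": res.a, "b": res.b, "c": res.c,
                             "d": res.d, "odds_ratio": res.odds_ratio,
                             "p": res.p_two_sided})
        return pd.DataFrame(rows)


def binned_distance_enrichment(
    annotated: pd.DataFrame,
    bins: Sequence[tuple[int, Optional[int]]] = DEFAULT_DISTANCE_BINS,
) -> BinnedEnrichment:
    """Per-distance-bin 2×2 (in-bin vs not) pathogenic-vs-neutral tests.

    Rows without a distance (single-exon transcripts) are excluded.
    Degenerate bins (a zero margin) report an absent result.
    """
    prev_hi: Optional[int] = None
    for lo, hi in bins:
        if hi is not None and hi < lo:
            raise ValueError(f"invalid bin [{lo}, {hi}]")
        if prev_hi is not None and lo <= prev_hi:
            raise ValueError("bins must be disjoint and ordered")
        prev_hi = hi if hi is not None else math.inf  # type: ignore[assignment]
    mask = annotated["distance_bp"].notna() & annotated["class"].isin(
        [MutationClass.PATHOGENIC.value, MutationClass.NEUTRAL.value]
    )
    dist = annotated.loc[mask, "distance_bp"].astype(float)
    path = annotated.loc[mask, "class"] == MutationClass.PATHOGENIC.value
    results = []
    for lo, hi in bins:
        in_bin = (dist >= lo) & (dist <= hi if hi is not None else True)
        a = int((path & in_bin).sum())
        b = int((path & ~in_bin).sum())
        c = int((~path & in_bin).sum())
        d = int((~path & ~in_bin).sum())
        try:
            results.append(fisher_2x2(a, b, c, d))
        except ValueError:
            results.append(None)
    return BinnedEnrichment(bins=tuple(bins), results=tuple(results))


def cumulative_distance_curves(
    annotated: pd.DataFrame,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Empirical cumulative distance distributions per class: class →
    (sorted distances, cumulative proportion). Right-continuous steps,
    terminal value 1."""
    curves = {}
    for cls in (MutationClass.PATHOGENIC.value, MutationClass.NEUTRAL.value):
        dist = annotated.loc[
            (annotated["class"] == cls) & annotated["distance_bp"].notna(),
            "distance_bp",
        ].astype(float).to_numpy()
        if dist.size == 0:
            curves[cls] = (np.array([]), np.array([]))
            continue
        x = np.unique(dist)
        y = np.searchsorted(np.sort(dist), x, side="right") / dist.size
        curves[cls] = (x, y)
    return curves


def compare_conservation(
    scores_a: Sequence[float], scores_b: Sequence[float]
) -> float:
    """One-sided rank-sum p for H1: scores in A are larger than in B
    (exact for small samples without ties, tie-corrected normal
    approximation otherwise)."""
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both score groups must be non-empty")
    res = sps.mannwhitneyu(a, b, alternative="greater", method="auto")
    return float(res.pvalue)


def overrepresentation(
    query_genes: set[str],
    gene_sets: Mapping[str, set[str]],
    universe: set[str],
    min_hits: int = 6,
) -> pd.DataFrame:
    """Hypergeometric over-representation of a gene list against named sets.

    Per term: upper-tail P(X ≥ hits) with population = universe, successes
    = term∩universe, draws = |query|. Terms with hits < ``min_hits``
    (default: ≤5 hits) are removed before Benjamini–Hochberg adjustment.
    """
    if not universe:
        raise ValueError("empty universe")
    extra = query_genes - universe
    if extra:
        raise ValueError(f"query genes outside the universe: {sorted(extra)[:5]}")
    n_universe = len(universe)
    n_query = len(query_genes)
    rows = []
    for term, genes in gene_sets.items():
        in_universe = genes & universe
        hits = len(query_genes & in_universe)
        if hits < min_hits:
            continue
        p = float(sps.hypergeom.sf(hits - 1, n_universe, len(in_universe), n_query))
        rows.append({"term": term, "term_size": len(in_universe), "hits": hits, "p": p})
    df = pd.DataFrame(rows, columns=["term", "term_size", "hits", "p"])
    if len(df):
        df["q"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
        df = df.sort_values(["p", "term"], kind="mergesort").reset_index(drop=True)
    else:
        df["q"] = pd.Series(dtype=float)
    return df


def enrichment_table(
    annotated: pd.DataFrame, features: Sequence[str]
) -> pd.DataFrame:
    """Tidy per-feature enrichment summary (one Fisher test per feature)."""
    rows = []
    for feature in features:
        res = feature_enrichment(annotated, feature)
        rows.append(
            {
                "feature": feature,
                "a": res.a, "b": res.b, "c": res.c, "d": res.d,
                "odds_ratio": res.odds_ratio,
                "odds_ratio_corrected": res.odds_ratio_corrected,
                "p": res.p_two_sided,
            }
        )
    return pd.DataFrame(rows)
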