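"""Potentially functional mutations and the per-gene Poisson recurrence test.

A pathogenic synonymous mutation is *potentially functional* when it shows
at least one of three mechanism aspects: an ESR change at a near-splice
position, containment in a DNase-I-hypersensitive site, or loss of an
optimal codon. Per gene, the observed count k of functional mutations is
compared with the expected count

    λ = 2 · R · S

(R: per-gene background synonymous mutation rate per sample per allele
copy; S: number of tumour samples; the factor 2 counts both allele
copies) through the Poisson point probability

    P(X = k) = λ^k e^{−λ} / k!

evaluated in log space (a log-gamma routine for ln k!, since a naive
factorial overflows at k ≈ 171). Genes with P below a threshold (default
1 × 10⁻⁶) are called recurrent; p-values are deliberately not adjusted
for multiple comparisons. A tail-probability option P(X ≥ k) is provided
but off by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .model import GeneRateTable
from .stratify import MutationClass

DEFAULT_RECURRENCE_THRESHOLD = 1e-6
#: Genome-wide significance threshold sometimes used instead of the default.
GENOME_WIDE_THRESHOLD = 2.74e-6

MECHANISM_LABELS = ("ESR_NEAR_SPLICE", "DHS", "OPTIMAL_LOSS")

_REQUIRED_COLUMNS = ("class", "esr_near_splice", "in_dhs", "codon_change")


@dataclass(frozen=True)
class GeneRecurrenceResult:
    gene_symbol: str
    gene_length: Optional[int]
    mechanisms_summary: str
    k: int
    lam: float
    p_point: float
    significant: bool


def mechanisms_of(row) -> frozenset[str]:
    """Mechanism aspects present in one annotated row (class-independent)."""
    out = set()
    if bool(row.esr_near_splice):
        out.add("ESR_NEAR_SPLICE")
    if bool(row.in_dhs):
        out.add("DHS")
    if str(row.codon_change) == "OPTIMAL_LOSS":
        out.add("OPTIMAL_LOSS")
    return frozenset(out)


def flag_functional(annotated: pd.DataFrame) -> pd.DataFrame:
    """Append ``functional`` (bool) and ``mechanisms`` (semicolon-joined)
    columns: functional ⇔ PATHOGENIC and at least one mechanism aspect."""
    missing = [c for c in _REQUIRED_COLUMNS if c not in annotated.columns]
    if missing:
        raise ValueError(
            f"annotation column(s) {', '.join(missing)} missing; run the "
            "stratify/annotate stages first"
        )
    out = annotated.copy()
    mech_texts = []
    functional = []
    for row in annotated.itertuples(index=False):
        mechs = mechanisms_of(row)
        mech_texts.append(";".join(sorted(mechs)))
        functional.append(
            bool(mechs) and row[annotated.columns.get_loc("class")] == MutationClass.PATHOGENIC.value
        )
    out["mechanisms"] = mech_texts
    out["functional"] = functional
    return out


def expected_count(rate: float, samples: int) -> float:
    """λ = 2·R·S."""
    if rate <= 0:
        raise ValueError("rate R must be > 0")
    if samples < 1:
        raise ValueError("sample count S must be >= 1")
    return 2.0 * rate * samples


def poisson_point_prob(k: int, lam: float) -> float:
    """P(X = k) = λ^k e^{−λ} / k!, in log space."""
    if k < 0 or int(k) != k:
        raise ValueError("k must be a non-negative integer")
    if lam <= 0:
        raise ValueError("lambda must be > 0")
    k = int(k)
    if k == 0:
        return math.exp(-lam)
    return math.exp(k * math.log(lam) - math.lgamma(k + 1) - lam)


def poisson_tail_prob(k: int, lam: float) -> float:
    """P(X ≥ k) — optional alternative statistic."""
    if k < 0 or int(k) != k:
        raise ValueError("k must be a non-negative integer")
    if lam <= 0:
        raise ValueError("lambda must be > 0")
    from scipy import stats as sps

    return float(sps.poisson.sf(int(k) - 1, lam))


_MECH_TEXT = {
    "ESR_NEAR_SPLICE": "disrupt ESR sequence in near SS",
    "DHS": "alter DHS",
    "OPTIMAL_LOSS": "decrease the use of optimal codons",
}


def recurrent_genes(
    annotated: pd.DataFrame,
    rates: GeneRateTable,
    samples: int,
    threshold: float = DEFAULT_RECURRENCE_THRESHOLD,
    tail: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene recurrence of functional mutations.

    Returns (results, missing): ``results`` has one row per gene with a
    rate entry and k ≥ 1, sorted ascending by p; ``missing`` lists genes
    with functional mutations but no rate entry (absent p). No
    multiple-testing adjustment is applied.
    """
    if "functional" not in annotated.columns:
        annotated = flag_functional(annotated)
    func = annotated[annotated["functional"].astype(bool)]
    stat = poisson_tail_prob if tail else poisson_point_prob
    rows = []
    missing_rows = []
    for gene, group in func.groupby("gene", sort=True):
        k = len(group)
        mechs: set[str] = set()
        for text in group["mechanisms"]:
            mechs.update(m for m in str(text).split(";") if m)
        summary = ", ".join(
            _MECH_TEXT[m] for m in MECHANISM_LABELS if m in mechs
        )
        rate = rates.rate(str(gene))
        if rate is None:
            missing_rows.append(
                {"gene": gene, "k": k, "mechanisms": summary}
            )
            continue
        lam = expected_count(rate, samples)
        p = stat(k, lam)
        rows.append(
            {
                "gene": gene,
                "gene_length": rates.length(str(gene)),
                "mechanisms": summary,
                "k": k,
                "lambda": lam,
                "p": p,
                "significant": p < threshold,
            }
        )
    results = pd.DataFrame(
        rows,
        columns=["gene", "gene_length", "mechanisms", "k", "lambda", "p", "significant"],
    )
    if len(results):
        results = results.sort_values(["p", "gene"], kind="mergesort").reset_index(drop=True)
    missing = pd.DataFrame(missing_rows, columns=["gene", "k", "mechanisms"])
    return results, missing
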