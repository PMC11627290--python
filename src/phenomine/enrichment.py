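"""Enrichment of terms in aging-keyword abstracts against a resampling null.

For each term the observed statistic is the *aging-count*: the number of
keyword-positive abstracts in which the term is present. The null is the
*expected-count*: the mean of the same statistic over R independent uniform
random subsets of the whole corpus, each of the same size as the
keyword-positive set. Their ratio is the enrichment (1 under
exchangeability); a per-term Pearson chi-squared test on the 2x2
presence x keyword table supplies a p-value.

All counts are presence-based (0/1 per abstract). A single integer seed
drives all resampling draws through a counter-based stream, so per-term
results do not depend on term order and doubling R only refines the null
mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .corpus import TermDocMatrix

__all__ = [
    "EnrichmentResult",
    "EnrichmentSummary",
    "aging_count",
    "resample_expected_count",
    "chi_squared_term",
    "enrichment_ratio",
    "run_enrichment",
    "summarize",
]


@dataclass
class EnrichmentResult:
    term: str
    aging_count: int
    expected_count: float
    ratio: float  # nan when expected_count == 0 (flagged by `defined`)
    chi2_stat: float
    p_value: float
    n_resamples: int

    @property
    def defined(self) -> bool:
        return not math.isnan(self.ratio)


@dataclass
class EnrichmentSummary:
    """Mean enrichment over terms with a defined ratio, with its SEM."""

    mean_ratio: float
    sem: float
    n_terms: int


def aging_count(term_matrix: TermDocMatrix, keyword_positive_ids: list[str]) -> np.ndarray:
    """Per-term number of keyword-positive abstracts containing the term."""
    cols = term_matrix.col_indices(keyword_positive_ids)
    presence = term_matrix.binarize().values
    if len(cols) == 0:
        return np.zeros(presence.shape[0], dtype=int)
    return np.asarray(presence[:, cols].sum(axis=1)).ravel().astype(int)


def resample_expected_count(
    term_matrix: TermDocMatrix,
    sample_size: int,
    n_resamples: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Per-term mean presence count over R random same-size abstract subsets.

    Each draw selects ``sample_size`` abstracts uniformly without
    replacement from the whole corpus; draws are independent across the R
    repetitions. Deterministic for a given seed.
    """
    n_total = term_matrix.shape[1]
    if sample_size > n_total:
        raise ValueError(f"sample_size {sample_size} exceeds corpus size {n_total}")
    presence = term_matrix.binarize().values.tocsc()
    totals = np.zeros(presence.shape[0], dtype=float)
    for r in range(n_resamples):
        rng = np.random.default_rng([seed, r])
        cols = rng.choice(n_total, size=sample_size, replace=False)
        totals += np.asarray(presence[:, cols].sum(axis=1)).ravel()
    return totals / n_resamples


def chi_squared_term(
    term_matrix: TermDocMatrix,
    keyword_positive_ids: list[str],
    term: str,
    continuity_correction: bool = False,
) -> tuple[float, float]:
    """Pearson chi-squared on the 2x2 {term present/absent} x {keyword
    present/absent} table (1 df, no continuity correction by default).

    Returns ``(nan, nan)`` for degenerate tables (a zero marginal).
    """
    i = term_matrix.row_index(term)
    presence = term_matrix.binarize().values
    row = np.asarray(presence[i].todense()).ravel()
    kw_mask = np.zeros(term_matrix.shape[1], dtype=bool)
    kw_mask[term_matrix.col_indices(keyword_positive_ids)] = True

    a = int(np.sum(row[kw_mask] > 0))          # term+, kw+
    b = int(np.sum(row[~kw_mask] > 0))         # term+, kw-
    c = int(kw_mask.sum()) - a                 # term-, kw+
    d = int((~kw_mask).sum()) - b              # term-, kw-
    table = np.array([[a, b], [c, d]])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return (float("nan"), float("nan"))
    res = stats.chi2_contingency(table, correction=continuity_correction)
    return (float(res.statistic), float(res.pvalue))


def enrichment_ratio(aging: float, expected: float) -> float:
    """Aging-count over expected-count; nan (flagged) when expected is 0."""
    if expected == 0:
        return float("nan")
    return aging / expected


def run_enrichment(
    term_matrix: TermDocMatrix,
    keyword_positive_ids: list[str],
    n_resamples: int = 100,
    seed: int = 0,
    compute_chi2: bool = True,
) -> list[EnrichmentResult]:
    """Full per-term enrichment: counts, null, ratio and chi-squared."""
    aging = aging_count(term_matrix, keyword_positive_ids)
    expected = resample_expected_count(
        term_matrix, len(keyword_positive_ids), n_resamples, seed
    )
    results = []
    for i, term in enumerate(term_matrix.row_labels):
        if compute_chi2:
            chi2, p = chi_squared_term(term_matrix, keyword_positive_ids, term)
        else:
            chi2, p = float("nan"), float("nan")
        results.append(
            EnrichmentResult(
                term=term,
                aging_count=int(aging[i]),
                expected_count=float(expected[i]),
                ratio=enrichment_ratio(float(aging[i]), float(expected[i])),
                chi2_stat=chi2,
                p_value=p,
                n_resamples=n_resamples,
            )
        )
    return results


def summarize(results: list[EnrichmentResult]) -> EnrichmentSummary:
    """Mean enrichment ratio +/- SEM over terms with a defined ratio."""
    ratios = np.array([r.ratio for r in results if r.defined])
    if ratios.size == 0:
        return EnrichmentSummary(float("nan"), float("nan"), 0)
    sem = float(ratios.std(ddof=1) / np.sqrt(ratios.size)) if ratios.size > 1 else 0.0
    return EnrichmentSummary(float(ratios.mean()), sem, int(ratios.size))


def to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    """Tabular view, one row per term."""
    return pd.DataFrame(
        {
            "term": [r.term for r in results],
            "aging_count": [r.aging_count for r in results],
            "expected_count": [r.expected_count for r in results],
            "ratio": [r.ratio for r in results],
            "chi2": [r.chi2_stat for r in results],
            "p": [r.p_value for r in results],
        }
    )
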