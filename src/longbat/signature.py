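"""Anti-/pro-longevity signature tests with a subsampling null.

The observed statistic is a paired, one-tailed Wilcoxon signed-rank
test on (per-gene mean expression in the long-lived species, in the
short-lived species) over a curated gene list — ``less`` tests lower
expression in the long-lived species (the anti-longevity expectation).
Its significance is benchmarked against a null built by repeatedly
subsampling equally-sized random gene sets from a background (by
default the variance-screened set) and collecting the resulting
p-values; the observed p is called significant only when it falls
strictly outside the 95% highest density interval of that null sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats import Interval, TestResult, hdi, wilcoxon_signed_rank

logger = logging.getLogger(__name__)


@dataclass
class NullDistribution:
    p_values: np.ndarray
    B: int
    list_size: int
    background: frozenset
    seed: int
    hdi: Interval

    def __post_init__(self) -> None:
        if len(self.p_values) != self.B:
            raise ValueError("p_values length must equal B")


@dataclass
class SignatureDecision:
    observed_p: float
    inside_hdi: bool
    call: str  # significant / not_significant


def _usable_genes(species_means: pd.DataFrame, gene_list) -> list[str]:
    present = [g for g in gene_list if g in species_means.index]
    missing = [g for g in gene_list if g not in species_means.index]
    if missing:
        logger.warning("%d list genes missing from expression table: %s%s",
                       len(missing), ",".join(missing[:5]), "..." if len(missing) > 5 else "")
    return present


def signature_test(
    species_means: pd.DataFrame, gene_list, alternative: str = "less"
) -> TestResult:
    """Paired signed-rank test over a gene list.

    ``species_means`` has per-gene columns ``mean_A`` (long-lived) and
    ``mean_B`` (short-lived); ``alternative="less"`` tests lower
    expression in the long-lived species.  Genes missing from the table
    are dropped with a log message; fewer than 2 usable genes is an
    error.
    """
    usable = _usable_genes(species_means, gene_list)
    if len(usable) < 2:
        raise ValueError("fewer than 2 list genes present in the expression table")
    diffs = (species_means.loc[usable, "mean_A"] - species_means.loc[usable, "mean_B"]).to_numpy()
    return wilcoxon_signed_rank(diffs, alternative)


def subsample_null(
    species_means: pd.DataFrame,
    background,
    list_size: int,
    B: int = 1000,
    seed: int = 0,
    alternative: str = "less",
    hdi_mass: float = 0.95,
) -> NullDistribution:
    """Null p-value distribution from B random subsamples of the background."""
    bg = sorted(set(background) & set(species_means.index))
    if len(bg) < list_size:
        raise ValueError("background smaller than the list size")
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    pvals = np.empty(B)
    for i in range(B):
        draw = rng.choice(bg, size=list_size, replace=False)
        pvals[i] = signature_test(species_means, draw, alternative).p_value
    return NullDistribution(pvals, B, list_size, frozenset(bg), int(seed), hdi(pvals, hdi_mass))


def signature_call(observed: TestResult, null: NullDistribution) -> SignatureDecision:
    """Significant iff the observed p falls strictly outside the null HDI."""
    inside = null.hdi.contains(observed.p_value)
    return SignatureDecision(observed.p_value, inside, "not_significant" if inside else "significant")
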