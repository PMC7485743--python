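"""Count-matrix processing and differential expression.

Raw counts are filtered for genes unexpressed in both species, normalized
with trimmed-mean-of-M-values (TMM) scaling factors, converted to log2
counts-per-million, and compared between species gene-by-gene with a
two-sided rank-sum test (BH-adjusted).  The module also computes the
sample correlation structure (Spearman) and the association tests
between selection (Ka/Ks) and differential expression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats import (
    TestResult,
    bh_adjust,
    chi2_2x2,
    ks_2samp,
    midrank,
    spearman_rho,
    wilcoxon_rank_sum,
)


@dataclass
class ExpressionStudy:
    """Counts, sample metadata and (after normalization) log2 expression.

    ``samples`` is indexed by sample id with ``species`` and ``sex``
    columns; ``species_a`` is the long-lived species.  Library sizes are
    the column sums of the (filtered) count matrix.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    species_a: str
    species_b: str
    tmm_factor: pd.Series = field(default=None)
    normalized: pd.DataFrame = field(default=None)

    def __post_init__(self) -> None:
        if list(self.counts.columns) != list(self.samples.index):
            if set(self.counts.columns) != set(self.samples.index):
                raise ValueError("count matrix columns and sample table ids disagree")
            self.samples = self.samples.loc[self.counts.columns]
        present = set(self.samples["species"])
        if present != {self.species_a, self.species_b}:
            raise ValueError(
                f"sample table species {sorted(present)} do not match "
                f"({self.species_a}, {self.species_b})"
            )

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0).astype(float)

    def species_columns(self, species: str) -> list[str]:
        return list(self.samples.index[self.samples["species"] == species])


def filter_unexpressed(study: ExpressionStudy) -> ExpressionStudy:
    """Drop genes with zero counts in both species (idempotent).

    A gene is removed only when its count sum is zero within species A
    *and* zero within species B.
    """
    if study.counts.shape[0] == 0:
        raise ValueError("empty count matrix")
    cols_a = study.species_columns(study.species_a)
    cols_b = study.species_columns(study.species_b)
    zero_a = study.counts[cols_a].sum(axis=1) == 0
    zero_b = study.counts[cols_b].sum(axis=1) == 0
    keep = ~(zero_a & zero_b)
    return ExpressionStudy(
        study.counts.loc[keep].copy(), study.samples, study.species_a, study.species_b
    )


# ---------------------------------------------------------------------------
# TMM normalization

#: trim fractions per tail for M-values and A-values
TMM_M_TRIM = 0.15
TMM_A_TRIM = 0.025


def tmm_factors(counts: pd.DataFrame, library_sizes: pd.Series | None = None) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factors, geometric-mean centred.

    The reference sample is the one whose 75th-percentile count fraction
    is closest to the across-sample mean.  For every sample, M (log2
    expression ratio vs reference) and A (average log2 abundance) are
    computed over genes nonzero in both, the top/bottom 15% of M and
    2.5% of A are trimmed, and the factor is 2**(precision-weighted mean
    M) with weights from the asymptotic binomial variance.
    """
    if counts.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    lib = counts.sum(axis=0).astype(float) if library_sizes is None else library_sizes.astype(float)
    if (lib <= 0).any():
        raise ValueError("each sample needs at least one nonzero gene")
    frac = counts.div(lib, axis=1)
    q75 = frac.quantile(0.75, axis=0)
    ref = (q75 - q75.mean()).abs().idxmin()

    c_ref = counts[ref].to_numpy(dtype=float)
    lib_ref = lib[ref]
    factors = {}
    for s in counts.columns:
        if s == ref:
            factors[s] = 1.0
            continue
        c_s = counts[s].to_numpy(dtype=float)
        ok = (c_s > 0) & (c_ref > 0)
        p_s = c_s[ok] / lib[s]
        p_r = c_ref[ok] / lib_ref
        m = np.log2(p_s / p_r)
        a = 0.5 * np.log2(p_s * p_r)
        n = m.size
        if n == 0:
            factors[s] = 1.0
            continue
        rank_m = midrank(m)
        rank_a = midrank(a)
        lo_m, hi_m = math.floor(n * TMM_M_TRIM), n - math.floor(n * TMM_M_TRIM)
        lo_a, hi_a = math.floor(n * TMM_A_TRIM), n - math.floor(n * TMM_A_TRIM)
        keep = (rank_m > lo_m) & (rank_m <= hi_m) & (rank_a > lo_a) & (rank_a <= hi_a)
        if not keep.any():
            factors[s] = 1.0
            continue
        # binomial asymptotic variance of log2 M, in proportion terms so the
        # factors are exactly invariant to rescaling any sample's counts;
        # floored to keep weights finite when a gene owns a whole library
        var = np.maximum((1.0 - p_s) / p_s + (1.0 - p_r) / p_r, 1e-12)
        w = 1.0 / var[keep]
        factors[s] = float(2.0 ** (np.sum(w * m[keep]) / np.sum(w)))
    f = pd.Series(factors).loc[counts.columns]
    return f / 2.0 ** np.log2(f).mean()


def normalize_log(study: ExpressionStudy, pseudocount: float = 1.0) -> ExpressionStudy:
    """TMM-scaled log2 counts-per-million: log2(count / (lib * factor) * 1e6 + pseudocount)."""
    factors = tmm_factors(study.counts)
    eff = study.library_sizes * factors
    cpm = study.counts.div(eff, axis=1) * 1e6
    study.tmm_factor = factors
    study.normalized = np.log2(cpm + pseudocount)
    return study


# ---------------------------------------------------------------------------
# correlation structure


def correlation_analysis(study: ExpressionStudy) -> dict:
    """Sample x sample Spearman matrix and the intra- vs inter-species comparison.

    Off-diagonal coefficients are split into intraspecific and
    interspecific sets; their medians are reported and compared with a
    one-sided rank-sum test (intra greater).
    """
    if study.normalized is None:
        raise ValueError("normalize the study first")
    x = study.normalized.to_numpy()
    ranks = np.column_stack([midrank(x[:, j]) for j in range(x.shape[1])])
    corr = np.corrcoef(ranks, rowvar=False)
    corr_df = pd.DataFrame(corr, index=study.normalized.columns, columns=study.normalized.columns)

    species = study.samples["species"].to_numpy()
    intra, inter = [], []
    cols = list(study.normalized.columns)
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            (intra if species[i] == species[j] else inter).append(corr[i, j])
    test = wilcoxon_rank_sum(intra, inter, alternative="greater")
    return {
        "matrix": corr_df,
        "intra": np.asarray(intra),
        "inter": np.asarray(inter),
        "median_intra": float(np.median(intra)),
        "median_inter": float(np.median(inter)),
        "test": test,
    }


# ---------------------------------------------------------------------------
# differential expression


def differential_expression(study: ExpressionStudy, fdr_threshold: float = 0.05) -> pd.DataFrame:
    """Per-gene two-sided rank-sum test between species on normalized values.

    Returns a table with log2 fold change (species A mean - species B
    mean), raw and BH-adjusted p-values, and the DEG call at
    ``fdr_threshold``.
    """
    if study.normalized is None:
        raise ValueError("normalize the study first")
    cols_a = study.species_columns(study.species_a)
    cols_b = study.species_columns(study.species_b)
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("need at least 2 samples per species")
    a = study.normalized[cols_a].to_numpy()
    b = study.normalized[cols_b].to_numpy()
    n_genes = a.shape[0]
    if n_genes == 0:
        return pd.DataFrame(columns=["gene_id", "log2_fc", "p_value", "fdr", "is_DEG"])
    pvals = np.empty(n_genes)
    for g in range(n_genes):
        pvals[g] = wilcoxon_rank_sum(a[g], b[g], alternative="two_sided").p_value
    fdr = bh_adjust(pvals)
    return pd.DataFrame(
        {
            "gene_id": study.normalized.index,
            "log2_fc": a.mean(axis=1) - b.mean(axis=1),
            "p_value": pvals,
            "fdr": fdr,
            "is_DEG": fdr < fdr_threshold,
        }
    ).reset_index(drop=True)


def selection_expression_association(de: pd.DataFrame, kaks: pd.DataFrame) -> dict:
    """Association between selection pressure and differential expression.

    KS test compares the omega distributions of DEGs vs non-DEGs;
    chi-square tests independence of the DEG x PSG 2x2 classification.
    Gene ids are matched across the two tables; genes without a defined
    omega are excluded from the KS test.
    """
    merged = de.merge(kaks[["gene_id", "omega", "classification"]], on="gene_id", how="inner")
    if merged.empty:
        raise ValueError("no shared gene ids between DE and Ka/Ks tables")
    with_omega = merged.dropna(subset=["omega"])
    omega_deg = with_omega.loc[with_omega["is_DEG"], "omega"].to_numpy()
    omega_non = with_omega.loc[~with_omega["is_DEG"], "omega"].to_numpy()
    if omega_deg.size == 0 or omega_non.size == 0:
        raise ValueError("empty stratum: KS test needs both DEG and non-DEG genes")
    ks = ks_2samp(omega_deg, omega_non)

    is_psg = merged["classification"] == "positive"
    table = [
        [int((merged["is_DEG"] & is_psg).sum()), int((merged["is_DEG"] & ~is_psg).sum())],
        [int((~merged["is_DEG"] & is_psg).sum()), int((~merged["is_DEG"] & ~is_psg).sum())],
    ]
    chi2 = chi2_2x2(table)
    return {"ks": ks, "chi2": chi2, "table": table, "n": len(merged)}
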