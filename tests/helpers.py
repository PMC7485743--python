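"""Independent brute-force oracles and small study builders for the tests.

Everything here is deliberately written by a different route than the
package code it checks: itertools enumeration instead of dynamic
programming, Biopython translation instead of precomputed codon tables,
explicit window scans instead of vectorized argmin, and balanced-ANOVA
method-of-moments instead of REML.
"""

from __future__ import annotations

import itertools
from math import comb

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from longbat.expression import ExpressionStudy, filter_unexpressed, normalize_log
from longbat.simulate import ExpressionTruth, SampleDesign, simulate_counts

# ---------------------------------------------------------------------------
# statistics oracles


def rankdata_simple(values):
    a = np.asarray(values, dtype=float)
    ranks = np.zeros(a.size)
    for i, v in enumerate(a):
        ranks[i] = 1 + np.sum(a < v) + (np.sum(a == v) - 1) / 2.0
    return ranks


def signed_rank_p_enumeration(diffs, alternative):
    """Exact signed-rank p by enumerating all 2^n sign assignments."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    ranks = rankdata_simple(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = d.size
    ws = [sum(r for r, s in zip(ranks, signs) if s) for signs in itertools.product([0, 1], repeat=n)]
    ws = np.asarray(ws)
    p_ge = np.mean(ws >= w_obs - 1e-12)
    p_le = np.mean(ws <= w_obs + 1e-12)
    if alternative == "greater":
        return p_ge
    if alternative == "less":
        return p_le
    return min(1.0, 2 * min(p_ge, p_le))


def rank_sum_p_enumeration(x, y, alternative):
    """Exact rank-sum p by enumerating all C(n, nx) rank splits (no ties)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    ranks = rankdata_simple(pooled)
    w_obs = ranks[: x.size].sum()
    sums = [sum(c) for c in itertools.combinations(ranks, x.size)]
    sums = np.asarray(sums)
    p_ge = np.mean(sums >= w_obs - 1e-12)
    p_le = np.mean(sums <= w_obs + 1e-12)
    if alternative == "greater":
        return p_ge
    if alternative == "less":
        return p_le
    return min(1.0, 2 * min(p_ge, p_le))


def hypergeom_pmf_exact(k, N, K, n):
    return comb(K, k) * comb(N - K, n - k) / comb(N, n)


def fisher_p_enumeration(table, alternative):
    """Fisher p by summing exact rational hypergeometric probabilities."""
    a, b = table[0]
    c, d = table[1]
    r1, r2, c1 = a + b, c + d, a + c
    N = r1 + r2
    lo, hi = max(0, c1 - r2), min(r1, c1)
    pmf = {k: hypergeom_pmf_exact(k, N, r1, c1) for k in range(lo, hi + 1)}
    if alternative == "greater":
        return sum(pmf[k] for k in range(a, hi + 1))
    if alternative == "less":
        return sum(pmf[k] for k in range(lo, a + 1))
    return min(1.0, sum(p for p in pmf.values() if p <= pmf[a] * (1 + 1e-9)))


def bh_stepup_oracle(pvals):
    """Textbook step-up: q_(i) = min_{j>=i} p_(j) m / j, mapped back."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    for pos, idx in enumerate(order):
        q[idx] = min(1.0, min(p[order[j]] * m / (j + 1) for j in range(pos, m)))
    return q


def hdi_window_scan(sample, mass):
    """Exhaustive scan of every contiguous window of the sorted sample.

    Ties in width resolve to the first (lowest-lower-bound) window.
    """
    s = np.sort(np.asarray(sample, dtype=float))
    n = s.size
    k = min(n, int(np.ceil(mass * n)))
    best = None
    for i in range(n - k + 1):
        width = s[i + k - 1] - s[i]
        if best is None or width < best[0]:
            best = (width, s[i], s[i + k - 1])
    return best[1], best[2]


# ---------------------------------------------------------------------------
# codon oracles (Biopython translation, path enumeration)


def translate(codon: str) -> str:
    return str(Seq(codon).translate())


def ng86_sites_oracle(codon: str):
    from longbat.codon import BASES

    s = 0.0
    for pos in range(3):
        for alt in BASES:
            if alt == codon[pos]:
                continue
            mutant = codon[:pos] + alt + codon[pos + 1 :]
            if translate(mutant) != "*" and translate(mutant) == translate(codon):
                s += 1 / 3
    return s, 3 - s


def ng86_subs_oracle(ca: str, cb: str):
    diff = [i for i in range(3) if ca[i] != cb[i]]
    if not diff:
        return 0.0, 0.0
    kept, all_paths = [], []
    for order in itertools.permutations(diff):
        cur, syn, nonsyn, blocked = ca, 0, 0, False
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
            if translate(nxt) == "*" and nxt != cb:
                blocked = True
            if translate(cur) == translate(nxt):
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        all_paths.append((syn, nonsyn))
        if not blocked:
            kept.append((syn, nonsyn))
    paths = kept or all_paths
    return (
        sum(s for s, _ in paths) / len(paths),
        sum(n for _, n in paths) / len(paths),
    )


# ---------------------------------------------------------------------------
# variance-component oracle


def anova_variance_fractions(y, species, sex):
    """Balanced crossed-design method-of-moments fractions (truncated at 0).

    For a 2x2 balanced layout with r replicates per cell and no
    interaction term in the model: E[MS_factor] = sigma_e^2 + 2r sigma^2,
    with MSE pooling everything beyond the two main effects.
    """
    y = np.asarray(y, dtype=float)
    species = np.asarray(species)
    sex = np.asarray(sex)
    n = y.size
    grand = y.mean()
    ss_sp = sum(
        np.sum(species == lv) * (y[species == lv].mean() - grand) ** 2 for lv in np.unique(species)
    )
    ss_sex = sum(
        np.sum(sex == lv) * (y[sex == lv].mean() - grand) ** 2 for lv in np.unique(sex)
    )
    ss_tot = np.sum((y - grand) ** 2)
    ss_err = ss_tot - ss_sp - ss_sex
    df_err = n - 3
    mse = max(ss_err / df_err, 0.0)
    per_level = n / 2  # balanced: E[MS_factor] = sigma_e^2 + (n/2) sigma_f^2
    var_sp = max((ss_sp / 1 - mse) / per_level, 0.0)
    var_sex = max((ss_sex / 1 - mse) / per_level, 0.0)
    total = var_sp + var_sex + mse
    if total == 0:
        return 0.0, 0.0, 1.0
    return var_sp / total, var_sex / total, mse / total


# ---------------------------------------------------------------------------
# study builders


def uniform_truth(n_genes, f_species=0.0, f_sex=0.0, direction="none", total_sd=1.0, baseline=5.0):
    """Truth table with identical fractions for every gene."""
    genes = pd.DataFrame(
        {
            "baseline_log2_mean": baseline,
            "var_fraction_species": f_species,
            "var_fraction_sex": f_sex,
            "var_fraction_residual": 1.0 - f_species - f_sex,
            "species_direction": direction,
            "expressed": True,
            "anti": False,
            "pro": False,
        },
        index=pd.Index([f"g{i + 1:04d}" for i in range(n_genes)], name="gene_id"),
    )
    return ExpressionTruth(genes, total_sd=total_sd)


def simulated_study(truth, seed, n_per_species=8, species=("A", "B")):
    """Counts -> filtered -> TMM-normalized ExpressionStudy."""
    design = SampleDesign.balanced(n_per_species=n_per_species, species=species)
    counts, samples = simulate_counts(truth, design, seed)
    study = ExpressionStudy(counts, samples, species[0], species[1])
    study = filter_unexpressed(study)
    return normalize_log(study)


def species_means(study):
    cols_a = study.species_columns(study.species_a)
    cols_b = study.species_columns(study.species_b)
    return pd.DataFrame(
        {
            "mean_A": study.normalized[cols_a].mean(axis=1),
            "mean_B": study.normalized[cols_b].mean(axis=1),
        }
    )
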