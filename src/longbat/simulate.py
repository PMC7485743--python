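"""Synthetic data with known ground truth.

Emulates the study design the pipeline targets: two species (one
long-lived, one short-lived), eight individuals each with alternating
sex, per-gene log2-scale expression decomposed into species / sex /
residual variance components, codon pairs evolved under a controllable
omega (dN/dS) and divergence, and gene-to-term annotations with planted
differentially expressed terms.

The codon simulator proposes single-nucleotide changes uniformly over
the sequence and accepts nonsynonymous proposals with probability
min(omega, 1) and synonymous ones with probability min(1/omega, 1), so
the realized nonsynonymous:synonymous rate ratio matches the requested
omega.  Proposals creating stop codons are rejected.  Counts are drawn
as Poisson around library-size-scaled latent expression; a gamma
mixture (negative binomial) is available through ``dispersion``.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io as lio
from .codon import AMINO_ACID, BASES, CODONS, SENSE_CODONS, STOP_CODONS
from .rng import stage_rng
from .selection import CodonAlignment

# ---------------------------------------------------------------------------
# codon evolution

_SYN, _NONSYN, _STOP = 0, 1, 2


def _build_mutation_tables():
    """For each (codon index, position, alt rank): new codon index and class."""
    new_codon = np.zeros((64, 3, 3), dtype=np.int16)
    mclass = np.zeros((64, 3, 3), dtype=np.int8)
    for ci, codon in enumerate(CODONS):
        for pos in range(3):
            alts = [b for b in BASES if b != codon[pos]]
            for ar, alt in enumerate(alts):
                mutant = codon[:pos] + alt + codon[pos + 1 :]
                mi = CODONS.index(mutant)
                new_codon[ci, pos, ar] = mi
                if mutant in STOP_CODONS:
                    mclass[ci, pos, ar] = _STOP
                elif AMINO_ACID[mutant] == AMINO_ACID[codon]:
                    mclass[ci, pos, ar] = _SYN
                else:
                    mclass[ci, pos, ar] = _NONSYN
    return new_codon, mclass


_NEW_CODON, _MUT_CLASS = _build_mutation_tables()
_SENSE_IDX = np.array([CODONS.index(c) for c in SENSE_CODONS])


def _evolve(seq: np.ndarray, n_subs: int, omega: float, rng: np.random.Generator) -> np.ndarray:
    """Apply ``n_subs`` accepted substitutions to a codon-index sequence."""
    if omega < 0:
        raise ValueError("omega must be >= 0")
    p_nonsyn = min(omega, 1.0)
    p_syn = 1.0 if omega <= 1.0 else min(1.0 / omega, 1.0)
    seq = seq.copy()
    L = seq.size
    accepted = 0
    proposals = 0
    cap = 200 * max(n_subs, 1) + 1000
    chunk = 4 * max(n_subs, 16)
    while accepted < n_subs and proposals < cap:
        codon_pos = rng.integers(0, L, size=chunk)
        nt_pos = rng.integers(0, 3, size=chunk)
        alt = rng.integers(0, 3, size=chunk)
        u = rng.random(size=chunk)
        for i in range(chunk):
            proposals += 1
            ci = seq[codon_pos[i]]
            cls = _MUT_CLASS[ci, nt_pos[i], alt[i]]
            if cls == _STOP:
                continue
            p = p_syn if cls == _SYN else p_nonsyn
            if u[i] < p:
                seq[codon_pos[i]] = _NEW_CODON[ci, nt_pos[i], alt[i]]
                accepted += 1
                if accepted >= n_subs:
                    break
            if proposals >= cap:
                break
    return seq


def _codon_string(seq: np.ndarray) -> str:
    return "".join(CODONS[i] for i in seq)


def simulate_codon_pair(
    gene_id: str,
    length_codons: int,
    omega: float,
    target_divergence: float,
    seed,
    species_a: str = "A",
    species_b: str = "B",
) -> CodonAlignment:
    """Evolve an ancestral stop-free codon sequence into two descendants.

    ``target_divergence`` is the expected number of accepted substitutions
    per nucleotide site between the two descendants (split evenly over
    the two lineages).
    """
    if length_codons < 1:
        raise ValueError("length_codons must be >= 1")
    if target_divergence < 0:
        raise ValueError("target_divergence must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ancestor = rng.choice(_SENSE_IDX, size=length_codons)
    n_total = int(round(target_divergence * 3 * length_codons))
    n_a = int(rng.binomial(n_total, 0.5))
    n_b = n_total - n_a
    seq_a = _evolve(ancestor, n_a, omega, rng)
    seq_b = _evolve(ancestor, n_b, omega, rng)
    return CodonAlignment(gene_id, _codon_string(seq_a), _codon_string(seq_b), species_a, species_b)


# ---------------------------------------------------------------------------
# expression truth and design

DIRECTIONS = ("up_in_A", "up_in_B", "none")

TRUTH_COLUMNS = [
    "baseline_log2_mean",
    "var_fraction_species",
    "var_fraction_sex",
    "var_fraction_residual",
    "species_direction",
    "expressed",
    "anti",
    "pro",
]


@dataclass
class ExpressionTruth:
    """Ground truth of the simulated expression study.

    ``genes`` is indexed by gene id with columns
    ``baseline_log2_mean``, ``var_fraction_species``, ``var_fraction_sex``,
    ``var_fraction_residual``, ``species_direction`` (up_in_A / up_in_B /
    none, species A being the long-lived one), ``expressed``, ``anti``
    and ``pro`` (longevity-list membership).  ``total_sd`` is the latent
    log2 standard deviation that the fractions partition.
    """

    genes: pd.DataFrame
    total_sd: float = 1.0

    def __post_init__(self) -> None:
        missing = set(TRUTH_COLUMNS) - set(self.genes.columns)
        if missing:
            raise ValueError(f"truth table missing columns {sorted(missing)}")
        expressed = self.genes[self.genes["expressed"]]
        fr = expressed[
            ["var_fraction_species", "var_fraction_sex", "var_fraction_residual"]
        ].to_numpy(dtype=float)
        if fr.size and (np.any(fr < -1e-12) or np.any(np.abs(fr.sum(axis=1) - 1.0) > 1e-8)):
            raise ValueError("variance fractions must be nonnegative and sum to 1 per gene")
        bad = set(self.genes["species_direction"]) - set(DIRECTIONS)
        if bad:
            raise ValueError(f"unknown species_direction values: {sorted(bad)}")


@dataclass
class SampleDesign:
    """Two-species sample layout with per-sample sex and library size."""

    samples: pd.DataFrame  # index sample_id; columns species, sex
    species_a: str
    species_b: str
    library_sizes: pd.Series = field(default=None)

    def __post_init__(self) -> None:
        counts = self.samples["species"].value_counts()
        if set(counts.index) != {self.species_a, self.species_b}:
            raise ValueError("samples must cover exactly the two declared species")
        if counts.min() < 2:
            raise ValueError("need at least 2 samples per species")
        if self.library_sizes is None:
            self.library_sizes = pd.Series(2e6, index=self.samples.index)
        if (self.library_sizes <= 0).any():
            raise ValueError("library sizes must be positive")

    @classmethod
    def balanced(
        cls,
        n_per_species: int = 8,
        species: tuple[str, str] = ("M_myotis", "M_molossus"),
        library_size: float = 2e6,
    ) -> "SampleDesign":
        """Balanced design with sex alternating F/M within each species."""
        rows = []
        for sp in species:
            for i in range(n_per_species):
                rows.append({"sample_id": f"{sp}_{i + 1}", "species": sp, "sex": "FM"[i % 2]})
        samples = pd.DataFrame(rows).set_index("sample_id")
        return cls(samples, species[0], species[1],
                   pd.Series(library_size, index=samples.index))


def simulate_latent(truth: ExpressionTruth, design: SampleDesign, rng) -> pd.DataFrame:
    """Latent log2 expression for expressed genes: baseline + species + sex + residual.

    Species and sex effects are fixed offsets of magnitude
    sqrt(fraction/2) * total_sd with signs +/-1 across the two levels.
    The sqrt(1/2) matches the offsets to the random-effects scale a
    2-level variance component estimates (a component sigma^2 implies a
    between-level sample variance of sigma^2/2), so REML fractions
    recover the requested fractions without bias.  At zero residual the
    balanced-design ANOVA decomposition of the latent values equals the
    requested fractions exactly (the 1/2 cancels in the ratio).
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    genes = truth.genes[truth.genes["expressed"]]
    n_g = len(genes)
    samples = design.samples
    sp_sign = np.where(samples["species"].to_numpy() == design.species_a, 1.0, -1.0)
    sex_sign = np.where(samples["sex"].to_numpy() == "F", 1.0, -1.0)

    f_sp = genes["var_fraction_species"].to_numpy(dtype=float)
    f_sex = genes["var_fraction_sex"].to_numpy(dtype=float)
    f_res = genes["var_fraction_residual"].to_numpy(dtype=float)
    h_sp = np.sqrt(f_sp / 2.0) * truth.total_sd
    h_sex = np.sqrt(f_sex / 2.0) * truth.total_sd

    direction = genes["species_direction"].to_numpy()
    dir_sign = np.where(direction == "up_in_A", 1.0, np.where(direction == "up_in_B", -1.0, 0.0))
    random_sign = rng.choice([-1.0, 1.0], size=n_g)
    dir_sign = np.where(direction == "none", random_sign, dir_sign)
    sex_orient = rng.choice([-1.0, 1.0], size=n_g)

    y = (
        genes["baseline_log2_mean"].to_numpy(dtype=float)[:, None]
        + (dir_sign * h_sp)[:, None] * sp_sign[None, :]
        + (sex_orient * h_sex)[:, None] * sex_sign[None, :]
        + rng.standard_normal((n_g, len(samples))) * (np.sqrt(f_res) * truth.total_sd)[:, None]
    )
    return pd.DataFrame(y, index=genes.index, columns=samples.index)


def simulate_counts(
    truth: ExpressionTruth,
    design: SampleDesign,
    seed,
    dispersion: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw the gene x sample count matrix and its sample table.

    Per sample, counts are Poisson(library_size * 2^y / sum_g 2^y) over
    expressed genes (unexpressed genes get all-zero rows).  With
    ``dispersion`` d > 0 the Poisson rate is scattered by a
    Gamma(1/d, d) factor, giving negative-binomial counts.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    latent = simulate_latent(truth, design, rng)
    weights = np.exp2(latent.to_numpy())
    props = weights / weights.sum(axis=0, keepdims=True)
    lam = props * design.library_sizes.loc[latent.columns].to_numpy()[None, :]
    if dispersion is not None and dispersion > 0:
        lam = lam * rng.gamma(1.0 / dispersion, dispersion, size=lam.shape)
    drawn = rng.poisson(lam)
    counts = pd.DataFrame(0, index=truth.genes.index, columns=latent.columns, dtype=np.int64)
    counts.loc[latent.index] = drawn
    samples = design.samples.copy()
    return counts, samples


def simulate_annotation(
    genes,
    n_terms: int,
    term_size_range: tuple[int, int] = (10, 60),
    planted_terms=None,
    seed=0,
) -> pd.DataFrame:
    """Random gene-to-term annotation with optional planted terms.

    Each of ``n_terms`` background terms receives a uniform random gene
    subset with size drawn from ``term_size_range``; planted terms keep
    exactly the member lists given as ``(term_id, members)`` pairs.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    genes = list(genes)
    lo, hi = term_size_range
    if hi > len(genes):
        raise ValueError("term size range exceeds number of genes")
    rows = []
    for t in range(n_terms):
        term_id = f"T{t + 1:04d}"
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(genes, size=size, replace=False)
        for g in sorted(members):
            rows.append({"gene_id": g, "term_id": term_id, "term_name": f"simulated term {t + 1}"})
    for term_id, members in planted_terms or []:
        unknown = set(members) - set(genes)
        if unknown:
            raise ValueError(f"planted members not in gene universe: {sorted(unknown)[:5]}")
        for g in members:
            rows.append({"gene_id": g, "term_id": term_id, "term_name": f"planted {term_id}"})
    return pd.DataFrame(rows, columns=["gene_id", "term_id", "term_name"])


# ---------------------------------------------------------------------------
# complete fixture


def default_truth(
    seed: int,
    n_genes: int = 1200,
    frac_unexpressed: float = 0.15,
    n_high_fraction: int = 100,
    n_anti: int = 19,
    n_pro: int = 28,
    high_fraction: float = 0.95,
    total_sd: float = 1.0,
) -> tuple[ExpressionTruth, dict]:
    """Expression ground truth mirroring the two-species blood study.

    15% of genes are unexpressed in both species; ``n_high_fraction``
    genes carry >= ``high_fraction`` of their latent variance in the
    species component, split evenly up-in-A / up-in-B; the anti-longevity
    list is planted inside the up-in-B (lower in the long-lived species)
    half; the pro-longevity list has no species effect.
    """
    rng = stage_rng(seed, "truth")
    gene_ids = [f"g{i + 1:04d}" for i in range(n_genes)]
    expressed = rng.random(n_genes) >= frac_unexpressed
    # planted expression genes must be expressed
    expressed_idx = np.flatnonzero(expressed)
    need = n_high_fraction + n_pro
    if expressed_idx.size < need + 50:
        raise ValueError("too few expressed genes for the planted structure")
    chosen = rng.choice(expressed_idx, size=need, replace=False)
    high_idx = chosen[:n_high_fraction]
    pro_idx = chosen[n_high_fraction:]
    up_a_idx = high_idx[: n_high_fraction // 2]
    up_b_idx = high_idx[n_high_fraction // 2 :]
    anti_idx = up_b_idx[:n_anti]

    f_sp = np.minimum(rng.beta(2.0, 6.0, size=n_genes), 0.75)
    f_sex = np.minimum(rng.beta(1.0, 30.0, size=n_genes), 0.2)
    direction = np.full(n_genes, "none", dtype=object)
    f_sp[high_idx] = high_fraction
    f_sex[high_idx] = 0.01
    direction[up_a_idx] = "up_in_A"
    direction[up_b_idx] = "up_in_B"
    f_sp[pro_idx] = 0.0
    f_res = 1.0 - f_sp - f_sex

    genes = pd.DataFrame(
        {
            "baseline_log2_mean": rng.normal(4.0, 1.5, size=n_genes),
            "var_fraction_species": f_sp,
            "var_fraction_sex": f_sex,
            "var_fraction_residual": f_res,
            "species_direction": direction,
            "expressed": expressed,
            "anti": np.isin(np.arange(n_genes), anti_idx),
            "pro": np.isin(np.arange(n_genes), pro_idx),
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    planted = {
        "high_fraction_genes": [gene_ids[i] for i in sorted(high_idx)],
        "up_in_A_genes": [gene_ids[i] for i in sorted(up_a_idx)],
        "up_in_B_genes": [gene_ids[i] for i in sorted(up_b_idx)],
        "anti_genes": [gene_ids[i] for i in sorted(anti_idx)],
        "pro_genes": [gene_ids[i] for i in sorted(pro_idx)],
    }
    return ExpressionTruth(genes, total_sd=total_sd), planted


def make_fixture(
    outdir: str,
    seed: int,
    n_genes: int = 1200,
    n_per_species: int = 8,
    species: tuple[str, str] = ("M_myotis", "M_molossus"),
    n_planted_psg: int = 5,
    planted_omega: float = 3.0,
    background_omega_median: float = 0.103,
    background_omega_sigma: float = 0.85,
    n_terms: int = 40,
    planted_term_size: int = 30,
) -> dict:
    """Write a complete self-consistent synthetic dataset to ``outdir``.

    Emits codon alignments (FASTA), counts and sample metadata (TSV),
    annotation (TSV), anti-/pro-longevity gene lists (text), the ground
    truth (JSON) and a ready-to-run pipeline config (YAML).  Species A
    (first in ``species``) is the long-lived one.
    """
    os.makedirs(outdir, exist_ok=True)
    truth, planted = default_truth(seed, n_genes=n_genes)
    gene_ids = list(truth.genes.index)

    # --- codon alignments -------------------------------------------------
    rng_sel = stage_rng(seed, "selection")
    omegas = np.exp(rng_sel.normal(np.log(background_omega_median), background_omega_sigma, n_genes))
    divergences = rng_sel.uniform(0.05, 0.30, size=n_genes)
    lengths = rng_sel.integers(30, 501, size=n_genes)
    psg_pool = [g for g in gene_ids if g not in set(planted["high_fraction_genes"])]
    psg_genes = sorted(str(g) for g in rng_sel.choice(psg_pool, size=n_planted_psg, replace=False))
    # planted positives get long CDSs so the Fisher test has decisive power
    for g in psg_genes:
        i = gene_ids.index(g)
        omegas[i] = planted_omega
        divergences[i] = 0.25
        lengths[i] = int(rng_sel.integers(600, 901))
    alignments = [
        simulate_codon_pair(
            g, int(lengths[i]), float(omegas[i]), float(divergences[i]), rng_sel,
            species_a=species[0], species_b=species[1],
        )
        for i, g in enumerate(gene_ids)
    ]

    # --- expression -------------------------------------------------------
    rng_expr = stage_rng(seed, "expression")
    design = SampleDesign.balanced(n_per_species=n_per_species, species=species)
    design.library_sizes = pd.Series(
        rng_expr.uniform(1.5e6, 2.5e6, size=len(design.samples)), index=design.samples.index
    )
    counts, samples = simulate_counts(truth, design, rng_expr)

    # --- annotation -------------------------------------------------------
    expressed_genes = list(truth.genes.index[truth.genes["expressed"]])
    planted_term_id = "T_PLANT"
    term_members = planted["up_in_A_genes"][:planted_term_size]
    annotation = simulate_annotation(
        expressed_genes,
        n_terms=n_terms,
        term_size_range=(10, 60),
        planted_terms=[(planted_term_id, term_members)],
        seed=stage_rng(seed, "annotation"),
    )

    # --- write ------------------------------------------------------------
    paths = {
        "alignments": os.path.join(outdir, "alignments.fasta"),
        "counts": os.path.join(outdir, "counts.tsv"),
        "samples": os.path.join(outdir, "samples.tsv"),
        "annotation": os.path.join(outdir, "annotation.tsv"),
        "anti_list": os.path.join(outdir, "anti_longevity.txt"),
        "pro_list": os.path.join(outdir, "pro_longevity.txt"),
        "truth": os.path.join(outdir, "truth.json"),
        "config": os.path.join(outdir, "config.yaml"),
    }
    lio.write_codon_alignments(alignments, paths["alignments"])
    counts.index.name = "gene_id"
    lio.write_tsv(counts, paths["counts"], index=True)
    lio.write_tsv(samples.reset_index(), paths["samples"])
    lio.write_tsv(annotation, paths["annotation"])
    lio.write_gene_list(planted["anti_genes"], paths["anti_list"])
    lio.write_gene_list(planted["pro_genes"], paths["pro_list"])

    truth_record = {
        "seed": int(seed),
        "n_genes": int(n_genes),
        "planted_psg": list(psg_genes),
        "planted_term": planted_term_id,
        "planted_term_members": list(term_members),
        **planted,
    }
    with open(paths["truth"], "w") as fh:
        json.dump(truth_record, fh, indent=2, sort_keys=True)

    import yaml

    config = {
        "alignments": paths["alignments"],
        "counts": paths["counts"],
        "samples": paths["samples"],
        "annotation": paths["annotation"],
        "anti_list": paths["anti_list"],
        "pro_list": paths["pro_list"],
        "outdir": os.path.join(outdir, "results"),
        "long_lived_species": species[0],
        "seed": int(seed),
    }
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)

    return {"paths": paths, "truth": truth_record, "truth_table": truth, "design": design}
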