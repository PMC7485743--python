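"""Pairwise Ka/Ks estimation and positive-selection scanning.

For each ortholog pair the NG86 counting estimator is used: synonymous
and nonsynonymous sites are counted per codon (averaged between the two
sequences), substitutions are pathway-averaged per codon pair, observed
proportions are corrected for multiple hits with the Jukes–Cantor
formula d = -(3/4) ln(1 - (4/3) p), and omega = Ka/Ks.  Significance of
positive selection comes from a one-sided Fisher exact test on the
rounded substitution/site table, with Benjamini–Hochberg adjustment
across genes.  Genes are filtered for short alignments, low coverage and
saturated distances before classification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .codon import SiteCounts, is_valid_codon, ng86_sites, ng86_substitutions, STOP_CODONS
from .stats import bh_adjust, fisher_exact_2x2

#: Jukes–Cantor saturation threshold: distances undefined at p >= 3/4
JC_SATURATION = 0.75


@dataclass
class CodonAlignment:
    """A pairwise codon alignment for one gene (gap character ``-``)."""

    gene_id: str
    seq_a: str
    seq_b: str
    species_a: str = "A"
    species_b: str = "B"

    def __post_init__(self) -> None:
        self.seq_a = self.seq_a.upper()
        self.seq_b = self.seq_b.upper()
        if len(self.seq_a) != len(self.seq_b):
            raise ValueError(f"{self.gene_id}: sequences differ in length")
        if len(self.seq_a) % 3 != 0:
            raise ValueError(f"{self.gene_id}: alignment length not divisible by 3")

    @property
    def n_columns(self) -> int:
        return len(self.seq_a)


@dataclass
class KaKsResult:
    gene_id: str
    Sd: float = math.nan
    Nd: float = math.nan
    S: float = math.nan
    N: float = math.nan
    Ka: float = math.nan
    Ks: float = math.nan
    omega: float = math.nan
    p_value: float = math.nan  # one-sided Fisher (excess nonsynonymous)
    p_purifying: float = math.nan  # opposite tail (deficit of nonsynonymous)
    fdr: float = math.nan
    fdr_purifying: float = math.nan
    classification: str = "none"
    filter_flags: set[str] = field(default_factory=set)
    compared_bp: int = 0
    total_columns: int = 0


def jukes_cantor(p: float) -> float:
    """JC69 distance; raises at saturation (p >= 3/4)."""
    if p < 0:
        raise ValueError("negative proportion")
    if p >= JC_SATURATION:
        raise ValueError("saturated: p >= 3/4")
    d = -0.75 * math.log(1.0 - (4.0 / 3.0) * p)
    return 0.0 if d == 0.0 else d


def _comparable_codons(aln: CodonAlignment):
    """Yield codon pairs with no gaps, ambiguity or stop codons in either sequence."""
    for i in range(0, aln.n_columns, 3):
        ca = aln.seq_a[i : i + 3]
        cb = aln.seq_b[i : i + 3]
        if not (is_valid_codon(ca) and is_valid_codon(cb)):
            continue
        if ca in STOP_CODONS or cb in STOP_CODONS:
            continue
        yield ca, cb


def kaks_pair(aln: CodonAlignment) -> KaKsResult:
    """NG86 Ka/Ks estimate with Fisher exact significance for one gene.

    Sites are summed per sequence then averaged between the two; the
    Fisher table is [[round(Nd), round(N - Nd)], [round(Sd), round(S - Sd)]]
    with the `greater` tail testing an excess of nonsynonymous change.
    """
    res = KaKsResult(aln.gene_id, total_columns=aln.n_columns)
    sites_a = SiteCounts(0.0, 0.0)
    sites_b = SiteCounts(0.0, 0.0)
    sd = nd = 0.0
    n_codons = 0
    for ca, cb in _comparable_codons(aln):
        sites_a = sites_a + ng86_sites(ca)
        sites_b = sites_b + ng86_sites(cb)
        s, n = ng86_substitutions(ca, cb)
        sd += s
        nd += n
        n_codons += 1
    if n_codons == 0:
        raise ValueError(f"{aln.gene_id}: no comparable codons")
    res.compared_bp = 3 * n_codons
    res.S = (sites_a.S + sites_b.S) / 2.0
    res.N = (sites_a.N + sites_b.N) / 2.0
    res.Sd, res.Nd = sd, nd

    ps = sd / res.S if res.S > 0 else math.nan
    pn = nd / res.N if res.N > 0 else math.nan
    try:
        res.Ks = jukes_cantor(ps) if not math.isnan(ps) else math.nan
        res.Ka = jukes_cantor(pn) if not math.isnan(pn) else math.nan
    except ValueError:
        res.filter_flags.add("saturated")
        res.Ka = res.Ks = res.omega = math.nan
    if "saturated" not in res.filter_flags:
        if math.isnan(res.Ks) or res.Ks <= 0.0:
            res.filter_flags.add("undefined_ratio")
            res.omega = math.nan
        else:
            res.omega = res.Ka / res.Ks

    table = [
        [int(round(nd)), int(round(res.N - nd))],
        [int(round(sd)), int(round(res.S - sd))],
    ]
    res.p_value = fisher_exact_2x2(table, "greater").p_value
    res.p_purifying = fisher_exact_2x2(table, "less").p_value
    return res


def selection_scan(
    alignments,
    kaks_fdr: float = 0.05,
    min_len_bp: int = 100,
    min_coverage: float = 0.8,
) -> pd.DataFrame:
    """Ka/Ks scan over a set of ortholog alignments.

    Applies the short-alignment (< ``min_len_bp`` compared bp) and
    low-coverage (compared bp / alignment columns < ``min_coverage``)
    filters, BH-adjusts the Fisher p-values across genes (saturated
    genes excluded), and classifies each gene:

    * ``positive``  — omega > 1, FDR < ``kaks_fdr``, no filter flags
    * ``purifying`` — omega < 1, opposite-tail FDR < ``kaks_fdr``, no flags
    * ``none``      — otherwise
    """
    results: list[KaKsResult] = []
    for aln in alignments:
        try:
            res = kaks_pair(aln)
        except ValueError:
            res = KaKsResult(aln.gene_id, total_columns=aln.n_columns)
            res.filter_flags.add("undefined_ratio")
        if res.compared_bp < min_len_bp:
            res.filter_flags.add("short_alignment")
        if res.total_columns > 0 and res.compared_bp / res.total_columns < min_coverage:
            res.filter_flags.add("low_coverage")
        results.append(res)

    testable = [
        i
        for i, r in enumerate(results)
        if not math.isnan(r.p_value) and "saturated" not in r.filter_flags
    ]
    if testable:
        fdr_pos = bh_adjust([results[i].p_value for i in testable])
        fdr_pur = bh_adjust([results[i].p_purifying for i in testable])
        for j, i in enumerate(testable):
            results[i].fdr = float(fdr_pos[j])
            results[i].fdr_purifying = float(fdr_pur[j])

    for r in results:
        if r.filter_flags or math.isnan(r.omega):
            r.classification = "none"
        elif r.omega > 1.0 and r.fdr < kaks_fdr:
            r.classification = "positive"
        elif r.omega < 1.0 and r.fdr_purifying < kaks_fdr:
            r.classification = "purifying"
        else:
            r.classification = "none"

    rows = [
        {
            "gene_id": r.gene_id,
            "Sd": r.Sd,
            "Nd": r.Nd,
            "S": r.S,
            "N": r.N,
            "Ka": r.Ka,
            "Ks": r.Ks,
            "omega": r.omega,
            "p_value": r.p_value,
            "fdr": r.fdr,
            "p_purifying": r.p_purifying,
            "fdr_purifying": r.fdr_purifying,
            "classification": r.classification,
            "filter_flags": ",".join(sorted(r.filter_flags)),
            "compared_bp": r.compared_bp,
            "total_columns": r.total_columns,
        }
        for r in results
    ]
    return pd.DataFrame(rows).sort_values("gene_id").reset_index(drop=True)


def pairwise_species_scan(pair_alignments: dict, **scan_kwargs) -> dict:
    """All-pairs Ka/Ks scans across k species.

    ``pair_alignments`` maps an ordered species pair ``(sp1, sp2)`` to the
    list of :class:`CodonAlignment` for their shared orthologs.  Returns
    per-pair scan tables, the per-pair positively-selected gene sets, and
    gene x pair matrices of omega and FDR (genes missing from a pair are
    NaN in the matrices).
    """
    if not pair_alignments:
        raise ValueError("need at least one species pair")
    scans: dict[tuple[str, str], pd.DataFrame] = {}
    psg_sets: dict[tuple[str, str], set[str]] = {}
    for pair, alns in pair_alignments.items():
        scan = selection_scan(alns, **scan_kwargs)
        scans[pair] = scan
        psg_sets[pair] = set(scan.loc[scan["classification"] == "positive", "gene_id"])
    genes = sorted(set().union(*(set(s["gene_id"]) for s in scans.values())))
    pair_labels = [f"{a}~{b}" for a, b in scans]
    omega = pd.DataFrame(np.nan, index=genes, columns=pair_labels)
    fdr = pd.DataFrame(np.nan, index=genes, columns=pair_labels)
    for (pair, scan), label in zip(scans.items(), pair_labels):
        omega.loc[scan["gene_id"].to_numpy(), label] = scan["omega"].to_numpy()
        fdr.loc[scan["gene_id"].to_numpy(), label] = scan["fdr"].to_numpy()
    return {"scans": scans, "psg_sets": psg_sets, "omega": omega, "fdr": fdr}
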