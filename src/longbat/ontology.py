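"""Term-level analyses: over-representation and paired expression tests.

Over-representation of a foreground gene set within each annotated term
is scored with an upper-tail hypergeometric test against a supplied
background (no term-graph propagation — the annotation table is taken
as given), BH-adjusted across tested terms.  Enriched terms from the
two direction-specific runs are pooled, ranked by best FDR and cut to
the top k.  Each term is then tested for coordinate differential
expression: a paired, one-tailed Wilcoxon signed-rank test on
(per-gene species A mean, species B mean) over the term's member
genes, run in both directions and BH-adjusted per direction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .stats import bh_adjust, hypergeom_sf_at_least, wilcoxon_signed_rank

logger = logging.getLogger(__name__)


def annotation_terms(annotation: pd.DataFrame) -> dict[str, set]:
    """term_id -> set of member genes."""
    return {t: set(g["gene_id"]) for t, g in annotation.groupby("term_id")}


def term_names(annotation: pd.DataFrame) -> dict[str, str]:
    return annotation.drop_duplicates("term_id").set_index("term_id")["term_name"].to_dict()


def hypergeom_enrich(
    foreground,
    background,
    annotation: pd.DataFrame,
    fdr_threshold: float = 0.05,
    min_overlap: int = 3,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``foreground`` per term.

    Terms overlapping the foreground by fewer than ``min_overlap`` genes
    are not tested.  Returns one row per tested term with counts, p,
    BH FDR, and the enrichment call.
    """
    fg = set(foreground)
    bg = set(background)
    if not fg <= bg:
        raise ValueError("foreground must be a subset of background")
    names = term_names(annotation)
    rows = []
    for term, members in sorted(annotation_terms(annotation).items()):
        in_bg = members & bg
        in_fg = members & fg
        if len(in_fg) < min_overlap:
            continue
        p = hypergeom_sf_at_least(len(in_fg), len(bg), len(in_bg), len(fg))
        rows.append(
            {
                "term_id": term,
                "term_name": names.get(term, term),
                "n_term_background": len(in_bg),
                "n_term_foreground": len(in_fg),
                "p_value": p,
            }
        )
    result = pd.DataFrame(
        rows, columns=["term_id", "term_name", "n_term_background", "n_term_foreground", "p_value"]
    )
    if len(result):
        result["fdr"] = bh_adjust(result["p_value"].to_numpy())
        result["enriched"] = result["fdr"] < fdr_threshold
    else:
        result["fdr"] = []
        result["enriched"] = []
    return result.sort_values(["fdr", "p_value", "term_id"]).reset_index(drop=True)


def select_top_terms(enrich_up_a: pd.DataFrame, enrich_up_b: pd.DataFrame, k: int = 20) -> list[str]:
    """Union of enriched terms from both runs, ranked by best FDR, top k."""
    best: dict[str, float] = {}
    for table in (enrich_up_a, enrich_up_b):
        for _, row in table.loc[table["enriched"]].iterrows():
            fdr = float(row["fdr"])
            t = row["term_id"]
            if t not in best or fdr < best[t]:
                best[t] = fdr
    ranked = sorted(best, key=lambda t: (best[t], t))
    return ranked[:k]


@dataclass
class TermTest:
    term_id: str
    n_genes: int
    p_up_in_A: float
    p_up_in_B: float
    fdr_up_in_A: float = float("nan")
    fdr_up_in_B: float = float("nan")
    call: str = "none"


def term_expression_test(
    species_means: pd.DataFrame,
    terms: dict[str, set],
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Paired one-tailed signed-rank tests per term, BH per direction.

    ``species_means`` has one row per gene with columns ``mean_A`` and
    ``mean_B`` (mean normalized expression per species).  Terms with
    fewer than 2 usable member genes, or whose paired differences are
    all zero, are skipped with a warning.  A term is called in the
    direction whose FDR clears the threshold; if (degenerately) both
    do, the call is ``none``.
    """
    tests: list[TermTest] = []
    for term in sorted(terms):
        genes = sorted(terms[term] & set(species_means.index))
        if len(genes) < 2:
            logger.warning("term %s: fewer than 2 genes with expression; skipped", term)
            continue
        diffs = (species_means.loc[genes, "mean_A"] - species_means.loc[genes, "mean_B"]).to_numpy()
        try:
            p_a = wilcoxon_signed_rank(diffs, "greater").p_value
            p_b = wilcoxon_signed_rank(diffs, "less").p_value
        except ValueError:
            logger.warning("term %s: degenerate paired sample; call none", term)
            continue
        tests.append(TermTest(term, len(genes), p_a, p_b))
    if tests:
        fdr_a = bh_adjust([t.p_up_in_A for t in tests])
        fdr_b = bh_adjust([t.p_up_in_B for t in tests])
        for t, fa, fb in zip(tests, fdr_a, fdr_b):
            t.fdr_up_in_A = float(fa)
            t.fdr_up_in_B = float(fb)
            sig_a = fa < fdr_threshold
            sig_b = fb < fdr_threshold
            if sig_a and sig_b:
                logger.warning("term %s: both directions significant; call none", t.term_id)
                t.call = "none"
            elif sig_a:
                t.call = "higher_in_A"
            elif sig_b:
                t.call = "higher_in_B"
    return pd.DataFrame(
        [
            {
                "term_id": t.term_id,
                "n_genes": t.n_genes,
                "p_up_in_A": t.p_up_in_A,
                "p_up_in_B": t.p_up_in_B,
                "fdr_up_in_A": t.fdr_up_in_A,
                "fdr_up_in_B": t.fdr_up_in_B,
                "call": t.call,
            }
            for t in tests
        ],
        columns=["term_id", "n_genes", "p_up_in_A", "p_up_in_B", "fdr_up_in_A", "fdr_up_in_B", "call"],
    )
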