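"""End-to-end orchestration of the comparative longevity analysis.

Stage order: Ka/Ks selection scan -> expression (filter, TMM, log2,
correlations, differential expression) -> selection/expression
association -> per-gene variance partitioning and the >=80% species-
variance screen -> per-direction term enrichment -> top-k terms ->
term-level paired tests -> anti-/pro-longevity signature tests with the
subsampling HDI null.  All stage tables are written as TSV (ids sorted
lexicographically) plus a JSON summary; identical config + seed gives
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import time
import zlib
from dataclasses import dataclass

import pandas as pd
import yaml

from . import io as lio
from .expression import (
    ExpressionStudy,
    correlation_analysis,
    differential_expression,
    filter_unexpressed,
    normalize_log,
    selection_expression_association,
)
from .ontology import annotation_terms, hypergeom_enrich, select_top_terms, term_expression_test
from .selection import selection_scan
from .signature import signature_call, signature_test, subsample_null
from .varpart import fit_all_genes, screen_table, variance_screen

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "1.0"

#: summary schema: key -> JSON type name
SUMMARY_SCHEMA = {
    "schema_version": "string",
    "seed": "integer",
    "long_lived_species": "string",
    "short_lived_species": "string",
    "thresholds": "object",
    "n_genes_input": "integer",
    "n_genes_expressed": "integer",
    "selection": "object",
    "expression": "object",
    "association": "object",
    "variance_screen": "object",
    "ontology": "object",
    "signature": "object",
}


@dataclass
class PipelineConfig:
    """Input paths, thresholds and the global seed for one pipeline run."""

    alignments: str
    counts: str
    samples: str
    annotation: str
    anti_list: str
    pro_list: str
    outdir: str
    long_lived_species: str
    seed: int = 0
    kaks_fdr: float = 0.05
    min_len_bp: int = 100
    min_coverage: float = 0.8
    de_fdr: float = 0.05
    varfrac_threshold: float = 0.8
    enrich_fdr: float = 0.05
    min_overlap: int = 3
    n_top_terms: int = 20
    B: int = 1000
    hdi_mass: float = 0.95
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        for name, lo, hi in [
            ("kaks_fdr", 0, 1), ("de_fdr", 0, 1), ("enrich_fdr", 0, 1),
            ("varfrac_threshold", 0, 1), ("min_coverage", 0, 1), ("hdi_mass", 0, 1),
        ]:
            v = getattr(self, name)
            if not (lo < v <= hi):
                raise ValueError(f"{name} must be in ({lo}, {hi}]: {v}")
        if self.B < 1 or self.min_len_bp < 0 or self.min_overlap < 0:
            raise ValueError("invalid threshold configuration")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _derive_seed(seed: int, stage: str) -> int:
    return (int(seed) * 0x9E3779B1 + zlib.crc32(stage.encode())) & 0x7FFFFFFF


def _round(obj, ndigits: int = 6):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round(v, ndigits) for v in obj]
    return obj


def validate_summary(summary: dict) -> None:
    """Check the JSON summary against the versioned schema."""
    type_map = {"string": str, "integer": int, "object": dict}
    for key, tname in SUMMARY_SCHEMA.items():
        if key not in summary:
            raise ValueError(f"summary missing key {key!r}")
        if not isinstance(summary[key], type_map[tname]):
            raise ValueError(f"summary key {key!r} must be {tname}")


class _Stage:
    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        self.t0 = time.perf_counter()
        logger.info("stage %s: start", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        dt = time.perf_counter() - self.t0
        if exc is not None:
            logger.error("stage %s: failed after %.1fs: %s", self.name, dt, exc)
            return False
        logger.info("stage %s: done in %.1fs", self.name, dt)
        return False


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline; returns the JSON-ready summary dict."""
    os.makedirs(config.outdir, exist_ok=True)

    with _Stage("load"):
        alignments = lio.read_codon_alignments(config.alignments)
        counts = lio.read_counts(config.counts)
        samples = lio.read_samples(config.samples)
        annotation = lio.read_annotation(config.annotation)
        anti = lio.read_gene_list(config.anti_list)
        pro = lio.read_gene_list(config.pro_list)

        if set(counts.columns) != set(samples.index):
            raise ValueError(
                f"sample ids in {config.counts} and {config.samples} disagree"
            )
        species = sorted(set(samples["species"]))
        if len(species) != 2:
            raise ValueError(f"{config.samples}: expected exactly 2 species, found {species}")
        if config.long_lived_species not in species:
            raise ValueError(
                f"long_lived_species {config.long_lived_species!r} not in {config.samples}"
            )
        short_lived = next(s for s in species if s != config.long_lived_species)
        aln_genes = {a.gene_id for a in alignments}
        if not aln_genes & set(counts.index):
            raise ValueError(
                f"no shared gene ids between {config.alignments} and {config.counts}"
            )

    with _Stage("selection_scan"):
        kaks = selection_scan(
            alignments,
            kaks_fdr=config.kaks_fdr,
            min_len_bp=config.min_len_bp,
            min_coverage=config.min_coverage,
        )
        lio.write_tsv(kaks, os.path.join(config.outdir, "kaks.tsv"))
        psg = sorted(kaks.loc[kaks["classification"] == "positive", "gene_id"])
        omega = kaks["omega"].dropna()

    with _Stage("expression"):
        study = ExpressionStudy(counts, samples, config.long_lived_species, short_lived)
        study = filter_unexpressed(study)
        study = normalize_log(study, pseudocount=config.pseudocount)
        norm_out = study.normalized.sort_index()
        norm_out.index.name = "gene_id"
        lio.write_tsv(norm_out, os.path.join(config.outdir, "normalized.tsv"), index=True)
        corr = correlation_analysis(study)
        lio.write_tsv(corr["matrix"], os.path.join(config.outdir, "correlation.tsv"), index=True)
        de = differential_expression(study, fdr_threshold=config.de_fdr)
        lio.write_tsv(de.sort_values("gene_id"), os.path.join(config.outdir, "de.tsv"))

    with _Stage("association"):
        try:
            assoc = selection_expression_association(de, kaks)
            association = {
                "ks_statistic": float(assoc["ks"].statistic),
                "ks_p": float(assoc["ks"].p_value),
                "chi2_statistic": float(assoc["chi2"].statistic),
                "chi2_p": float(assoc["chi2"].p_value),
                "n_genes": int(assoc["n"]),
            }
        except ValueError as err:
            logger.warning("association tests undefined: %s", err)
            association = {"error": str(err)}

    with _Stage("variance_partition"):
        fractions = fit_all_genes(study)
        screen = variance_screen(fractions, study, threshold=config.varfrac_threshold)
        lio.write_tsv(screen_table(fractions, screen), os.path.join(config.outdir, "variance.tsv"))
        up_a = sorted(g for g, d in screen.direction.items() if d == "up_in_A")
        up_b = sorted(g for g, d in screen.direction.items() if d == "up_in_B")

    with _Stage("ontology"):
        background = set(study.normalized.index)
        enrich_a = hypergeom_enrich(
            up_a, background, annotation, config.enrich_fdr, config.min_overlap
        )
        enrich_b = hypergeom_enrich(
            up_b, background, annotation, config.enrich_fdr, config.min_overlap
        )
        lio.write_tsv(enrich_a, os.path.join(config.outdir, "enrichment_up_A.tsv"))
        lio.write_tsv(enrich_b, os.path.join(config.outdir, "enrichment_up_B.tsv"))
        top_terms = select_top_terms(enrich_a, enrich_b, k=config.n_top_terms)

        cols_a = study.species_columns(study.species_a)
        cols_b = study.species_columns(study.species_b)
        species_means = pd.DataFrame(
            {
                "mean_A": study.normalized[cols_a].mean(axis=1),
                "mean_B": study.normalized[cols_b].mean(axis=1),
            }
        )
        screened_means = species_means.loc[sorted(screen.selected)]
        terms = {
            t: members & screen.selected
            for t, members in annotation_terms(annotation).items()
            if t in top_terms
        }
        term_tests = term_expression_test(screened_means, terms, config.enrich_fdr)
        lio.write_tsv(term_tests.sort_values("term_id"), os.path.join(config.outdir, "term_tests.tsv"))

    with _Stage("signature"):
        signature = {}
        bg = screen.selected if screen.selected else set(study.normalized.index)
        for list_name, gene_list, alternative in (
            ("anti", anti, "less"),
            ("pro", pro, "greater"),
        ):
            observed = signature_test(species_means, gene_list, alternative)
            usable = len([g for g in gene_list if g in species_means.index])
            null = subsample_null(
                species_means,
                bg,
                list_size=usable,
                B=config.B,
                seed=_derive_seed(config.seed, f"null_{list_name}"),
                alternative=alternative,
                hdi_mass=config.hdi_mass,
            )
            decision = signature_call(observed, null)
            signature[list_name] = {
                "n_list": len(gene_list),
                "n_usable": usable,
                "alternative": alternative,
                "observed_p": float(observed.p_value),
                "B": null.B,
                "null_seed": null.seed,
                "hdi_lower": null.hdi.lower,
                "hdi_upper": null.hdi.upper,
                "hdi_mass": null.hdi.mass,
                "call": decision.call,
            }
        with open(os.path.join(config.outdir, "signature.json"), "w") as fh:
            json.dump(_round(signature), fh, indent=2, sort_keys=True)

    summary = {
        "schema_version": SCHEMA_VERSION,
        "seed": int(config.seed),
        "long_lived_species": config.long_lived_species,
        "short_lived_species": short_lived,
        "thresholds": {
            "kaks_fdr": config.kaks_fdr,
            "min_len_bp": config.min_len_bp,
            "min_coverage": config.min_coverage,
            "de_fdr": config.de_fdr,
            "varfrac_threshold": config.varfrac_threshold,
            "enrich_fdr": config.enrich_fdr,
            "min_overlap": config.min_overlap,
            "n_top_terms": config.n_top_terms,
            "B": config.B,
            "hdi_mass": config.hdi_mass,
            "pseudocount": config.pseudocount,
        },
        "n_genes_input": int(counts.shape[0]),
        "n_genes_expressed": int(study.counts.shape[0]),
        "selection": {
            "n_genes_scanned": int(len(kaks)),
            "median_omega": float(omega.median()) if len(omega) else None,
            "n_omega_gt1": int((omega > 1).sum()),
            "n_positive": len(psg),
            "positive_genes": psg,
            "pct_purifying": float(100.0 * (kaks["classification"] == "purifying").mean()),
        },
        "expression": {
            "median_rho_intra": corr["median_intra"],
            "median_rho_inter": corr["median_inter"],
            "correlation_p": float(corr["test"].p_value),
            "n_deg": int(de["is_DEG"].sum()),
            "pct_deg": float(100.0 * de["is_DEG"].mean()),
        },
        "association": association,
        "variance_screen": {
            "threshold": config.varfrac_threshold,
            "n_selected": len(screen.selected),
            "n_up_in_long_lived": len(up_a),
            "n_up_in_short_lived": len(up_b),
        },
        "ontology": {
            "n_enriched_up_A": int(enrich_a["enriched"].sum()) if len(enrich_a) else 0,
            "n_enriched_up_B": int(enrich_b["enriched"].sum()) if len(enrich_b) else 0,
            "top_terms": top_terms,
            "n_terms_tested": int(len(term_tests)),
            "n_higher_in_long_lived": int((term_tests["call"] == "higher_in_A").sum()),
            "n_higher_in_short_lived": int((term_tests["call"] == "higher_in_B").sum()),
        },
        "signature": signature,
    }
    summary = _round(summary)
    validate_summary(summary)
    with open(os.path.join(config.outdir, "summary_schema.json"), "w") as fh:
        json.dump({"schema_version": SCHEMA_VERSION, "keys": SUMMARY_SCHEMA}, fh, indent=2, sort_keys=True)
    with open(os.path.join(config.outdir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
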