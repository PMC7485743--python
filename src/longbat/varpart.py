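"""Per-gene crossed random-effects variance decomposition.

Each gene's normalized log2 expression is modelled as
``y = mu + u_species + v_sex + eps`` with independent zero-mean random
effects for species and sex (both 2-level factors, deliberately treated
as random so their contributions are reported as variance fractions)
and residual noise.  Components are estimated by REML — bounded
quasi-Newton maximization of the restricted log-likelihood with
nonnegativity constraints — and reported as fractions of the total.
Genes whose species fraction reaches the screen threshold (default
0.80, inclusive) are selected and split by the direction of the species
mean difference.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .expression import ExpressionStudy

logger = logging.getLogger(__name__)

REML_TOL = 1e-8
REML_MAX_ITER = 500
_SIGMA_E_FLOOR = 1e-10


@dataclass(frozen=True)
class VarianceFractions:
    gene_id: str
    frac_species: float
    frac_sex: float
    frac_residual: float
    converged: bool
    n_iter: int

    def __post_init__(self) -> None:
        total = self.frac_species + self.frac_sex + self.frac_residual
        if abs(total - 1.0) > 1e-6:
            raise ValueError("variance fractions must sum to 1")


def _indicator(labels) -> np.ndarray:
    labels = np.asarray(labels)
    levels = np.unique(labels)
    return (labels[:, None] == levels[None, :]).astype(float)


def _is_balanced(species: np.ndarray, sex: np.ndarray) -> bool:
    """Balanced orthogonal crossed layout: all species x sex cells equal."""
    if np.unique(species).size != 2 or np.unique(sex).size != 2:
        return False
    cells = [
        np.sum((species == sp) & (sex == sx))
        for sp in np.unique(species)
        for sx in np.unique(sex)
    ]
    return len(set(cells)) == 1 and cells[0] > 0


def _reml_balanced(z: np.ndarray, species: np.ndarray, sex: np.ndarray):
    """Exact REML for the balanced orthogonal design.

    With orthogonal 1-df contrasts the restricted likelihood separates:
    -2l = ln(lam_s) + SS_s/lam_s + ln(lam_x) + SS_x/lam_x
          + (n-3) ln(se) + SS_e/se,   lam_f = se + (n/2) sf.
    The unconstrained optimum is the ANOVA method-of-moments solution;
    the nonnegativity-constrained optimum is found by evaluating the
    four boundary patterns (each variance free or pinned at zero).
    """
    n = z.size
    c_s = np.where(species == np.unique(species)[0], 1.0, -1.0) / math.sqrt(n)
    c_x = np.where(sex == np.unique(sex)[0], 1.0, -1.0) / math.sqrt(n)
    ss_s = float(z @ c_s) ** 2
    ss_x = float(z @ c_x) ** 2
    ss_e = max(float(z @ z) - n * z.mean() ** 2 - ss_s - ss_x, 0.0)
    half = n / 2.0
    df_e = n - 3

    def neg2(lam_s, lam_x, se):
        lam_s, lam_x, se = (max(v, _SIGMA_E_FLOOR) for v in (lam_s, lam_x, se))
        return (
            math.log(lam_s) + ss_s / lam_s
            + math.log(lam_x) + ss_x / lam_x
            + df_e * math.log(se) + ss_e / se
        )

    candidates = []
    # both factors free
    se = ss_e / df_e
    candidates.append((max(ss_s, se), max(ss_x, se), se))
    # species variance pinned at zero
    se = (ss_s + ss_e) / (df_e + 1)
    candidates.append((se, max(ss_x, se), se))
    # sex variance pinned at zero
    se = (ss_x + ss_e) / (df_e + 1)
    candidates.append((max(ss_s, se), se, se))
    # both pinned
    se = (ss_s + ss_x + ss_e) / (df_e + 2)
    candidates.append((se, se, se))

    best = min(candidates, key=lambda c: neg2(*c))
    lam_s, lam_x, se = best
    sig = np.array([max(lam_s - se, 0.0) / half, max(lam_x - se, 0.0) / half, max(se, 0.0)])
    return sig, True, len(candidates)


def _neg2_reml_and_grad(sig: np.ndarray, y: np.ndarray, A: np.ndarray, B: np.ndarray):
    n = y.size
    V = sig[2] * np.eye(n) + sig[0] * A + sig[1] * B
    try:
        Vi = np.linalg.inv(V)
    except np.linalg.LinAlgError:
        return 1e12, np.zeros(3)
    sign, logdet = np.linalg.slogdet(V)
    if sign <= 0:
        return 1e12, np.zeros(3)
    ones = np.ones(n)
    vi_1 = Vi @ ones
    xvx = float(ones @ vi_1)
    P = Vi - np.outer(vi_1, vi_1) / xvx
    py = P @ y
    value = logdet + math.log(xvx) + float(y @ py)
    grad = np.array(
        [
            float(np.sum(P * G)) - float(py @ (G @ py))
            for G in (A, B, np.eye(n))
        ]
    )
    return value, grad


def _reml_general(z: np.ndarray, species: np.ndarray, sex: np.ndarray):
    """Iterative REML (bounded quasi-Newton with analytic gradient)."""
    Zs = _indicator(species)
    Zx = _indicator(sex)
    A = Zs @ Zs.T
    B = Zx @ Zx.T
    best = None
    for x0 in ((0.3, 0.1, 0.6), (0.8, 0.05, 0.15), (0.02, 0.02, 0.96)):
        res = minimize(
            _neg2_reml_and_grad,
            np.asarray(x0),
            args=(z, A, B),
            jac=True,
            method="L-BFGS-B",
            bounds=[(0.0, None), (0.0, None), (_SIGMA_E_FLOOR, None)],
            options={"maxiter": REML_MAX_ITER, "ftol": REML_TOL, "gtol": 1e-10},
        )
        if best is None or res.fun < best.fun - 1e-12:
            best = res
    return np.maximum(best.x, 0.0), bool(best.success), int(best.nit)


def fit_gene_lmm(y, species, sex, gene_id: str = "") -> VarianceFractions:
    """REML variance fractions for one gene.

    ``y`` is standardized internally (fractions are scale-free).  A
    constant response returns the degenerate (0, 0, 1) split.  Balanced
    orthogonal designs are solved exactly through the sufficient
    statistics; unbalanced ones fall back to iterative bounded
    optimization of the restricted likelihood.
    """
    y = np.asarray(y, dtype=float)
    species = np.asarray(species)
    sex = np.asarray(sex)
    if y.size < 4:
        raise ValueError("need at least 4 observations")
    if np.unique(species).size < 2:
        raise ValueError("need 2 species levels")
    sd = y.std()
    if sd == 0.0:
        return VarianceFractions(gene_id, 0.0, 0.0, 1.0, True, 0)
    z = (y - y.mean()) / sd
    if _is_balanced(species, sex):
        sig, converged, n_iter = _reml_balanced(z, species, sex)
    else:
        sig, converged, n_iter = _reml_general(z, species, sex)
    total = sig.sum()
    if total <= 0:
        return VarianceFractions(gene_id, 0.0, 0.0, 1.0, True, n_iter)
    frac = sig / total
    return VarianceFractions(
        gene_id, float(frac[0]), float(frac[1]), float(frac[2]), converged, n_iter
    )


def fit_all_genes(study: ExpressionStudy) -> pd.DataFrame:
    """Variance fractions for every gene of a normalized study."""
    if study.normalized is None:
        raise ValueError("normalize the study first")
    species = study.samples["species"].to_numpy()
    sex = study.samples["sex"].to_numpy()
    rows = []
    for gene_id, y in study.normalized.iterrows():
        vf = fit_gene_lmm(y.to_numpy(), species, sex, gene_id=gene_id)
        rows.append(
            {
                "gene_id": gene_id,
                "frac_species": vf.frac_species,
                "frac_sex": vf.frac_sex,
                "frac_residual": vf.frac_residual,
                "converged": vf.converged,
                "n_iter": vf.n_iter,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class ScreenResult:
    threshold: float
    selected: set
    direction: dict  # gene -> up_in_A / up_in_B


def variance_screen(
    fractions: pd.DataFrame, study: ExpressionStudy, threshold: float = 0.80
) -> ScreenResult:
    """Select genes with frac_species >= threshold and assign direction.

    Direction is the sign of (species A mean - species B mean) on the
    normalized scale; exact ties are excluded with a warning.
    """
    if study.normalized is None:
        raise ValueError("normalize the study first")
    chosen = fractions.loc[fractions["frac_species"] >= threshold, "gene_id"]
    cols_a = study.species_columns(study.species_a)
    cols_b = study.species_columns(study.species_b)
    mean_a = study.normalized[cols_a].mean(axis=1)
    mean_b = study.normalized[cols_b].mean(axis=1)
    selected: set[str] = set()
    direction: dict[str, str] = {}
    for g in chosen:
        diff = mean_a.loc[g] - mean_b.loc[g]
        if diff == 0.0:
            logger.warning("gene %s: species means exactly tied; excluded from screen", g)
            continue
        selected.add(g)
        direction[g] = "up_in_A" if diff > 0 else "up_in_B"
    return ScreenResult(threshold, selected, direction)


def screen_table(fractions: pd.DataFrame, screen: ScreenResult) -> pd.DataFrame:
    out = fractions.copy()
    out["selected"] = out["gene_id"].isin(screen.selected)
    out["direction"] = out["gene_id"].map(screen.direction).fillna("")
    return out.sort_values("gene_id").reset_index(drop=True)
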