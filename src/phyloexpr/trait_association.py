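"""Life-history traits and per-gene expression association.

Traits (gestation period, weaning time, time to maturity, maximum
lifespan, growth rate, adult body weight, metabolic rate) enter the
models as log2 ratios to the minimum observed value.  Per gene the
species-level mean relative expression is regressed on the trait by
ordinary least squares (nonphylogenetic, by design: life-history
variation departs from pure Brownian motion, and misapplied
phylogenetic regression can perform poorly).  The machinery:

* overall / partial F-tests with Benjamini-Hochberg FDR correction per
  organ x trait family,
* a Kruskal-Wallis post-hoc test per gene on replicate-level values
  grouped by species, ensuring interspecies variation exceeds
  within-species variation,
* an add-one permutation test shuffling species-level trait values,
* an interaction (residual) scan comparing the full model
  ``Y ~ trait + weight + trait:weight`` against ``Y ~ weight`` by
  partial F, which flags genes tracking a trait beyond allometry,
* trait-trait regression and allometric residuals (log2 trait on log2
  body weight).

A gene is called "associated" when its BH q-value and its KW p-value
are both below alpha.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .expression_norm import RelativeExpression

__all__ = [
    "OLSModel",
    "AssociationError",
    "read_traits",
    "relative_log_trait",
    "ols_fit",
    "trait_pair_regression",
    "allometric_residuals",
    "bh_fdr",
    "kw_test",
    "permutation_pvalue",
    "associate",
    "residual_interaction_scan",
    "summarize_counts",
]

TRAIT_COLUMNS = (
    "gestation_days",
    "weaning_days",
    "maturity_days",
    "max_lifespan_years",
    "growth_rate",
    "adult_weight_g",
    "metabolic_rate",
)


class AssociationError(ValueError):
    """Raised for invalid association inputs (rank deficiency etc.)."""


@dataclass
class OLSModel:
    """Closed-form OLS fit with the overall F-test.

    ``coef[0]`` is the intercept; ``p`` is the F-test p-value of the
    regression (all non-intercept coefficients zero under H0).
    """

    coef: np.ndarray
    names: list[str]
    r2: float
    fstat: float
    p: float
    df_model: int
    df_resid: int
    residuals: np.ndarray
    fitted: np.ndarray
    sigma2: float


def read_traits(path) -> pd.DataFrame:
    """Load a species x traits TSV (column 1 = species, raw scales)."""
    t = pd.read_csv(path, sep="\t", index_col=0)
    t.index = t.index.astype(str)
    if t.index.duplicated().any():
        raise AssociationError("duplicate species in trait table")
    if (t.to_numpy(float) <= 0).any():
        raise AssociationError("trait values must be positive on raw scale")
    return t


def relative_log_trait(values) -> np.ndarray:
    """log2 ratio of each value to the minimum observed value."""
    v = np.asarray(values, dtype=float)
    if np.any(v <= 0):
        raise AssociationError("relative_log_trait requires positive values")
    return np.log2(v / v.min())


# ---------------------------------------------------------------------------
# OLS core
# ---------------------------------------------------------------------------

def _design(X, names=None) -> tuple[np.ndarray, list[str]]:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if names is None:
        names = [f"x{j + 1}" for j in range(X.shape[1])]
    Xd = np.column_stack([np.ones(X.shape[0]), X])
    return Xd, ["intercept"] + list(names)


def ols_fit(y, X, names=None) -> OLSModel:
    """Ordinary least squares with intercept and overall F-test.

    Raises :class:`AssociationError` naming near-collinear columns on
    rank deficiency.
    """
    y = np.asarray(y, dtype=float)
    Xd, all_names = _design(X, names)
    n, p = Xd.shape
    if n <= p:
        raise AssociationError(f"n={n} observations for {p} parameters")
    q_r = np.linalg.qr(Xd, mode="r")
    diag = np.abs(np.diag(q_r))
    tol = max(Xd.shape) * np.finfo(float).eps * diag.max()
    if (diag < tol).any():
        bad = [all_names[j] for j in np.nonzero(diag < tol)[0]]
        raise AssociationError(f"design is rank deficient; collinear columns: {bad}")
    coef, _, _, _ = np.linalg.lstsq(Xd, y, rcond=None)
    fitted = Xd @ coef
    resid = y - fitted
    rss = float(resid @ resid)
    tss = float(np.sum((y - y.mean()) ** 2))
    df_model = p - 1
    df_resid = n - p
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    if rss <= np.finfo(float).eps * max(tss, 1.0):
        fstat, pval = np.inf, 0.0
    else:
        fstat = (tss - rss) / df_model / (rss / df_resid)
        pval = float(stats.f.sf(fstat, df_model, df_resid))
    return OLSModel(coef=coef, names=all_names, r2=float(r2),
                    fstat=float(fstat), p=pval, df_model=df_model,
                    df_resid=df_resid, residuals=resid, fitted=fitted,
                    sigma2=rss / df_resid if df_resid > 0 else np.nan)


def trait_pair_regression(x_trait, y_trait) -> tuple[float, float, tuple[float, float]]:
    """OLS of one log-scale trait on another.

    Returns ``(r2, F-test p, (intercept, slope))``.
    """
    fit = ols_fit(y_trait, x_trait, names=["x"])
    return fit.r2, fit.p, (float(fit.coef[0]), float(fit.coef[1]))


def allometric_residuals(trait, weight) -> tuple[np.ndarray, tuple[float, float]]:
    """Residuals of log2 trait regressed on log2 body weight.

    Both inputs are raw-scale positive values; log2 is applied
    internally.  Residuals sum to zero (intercept included).  Returns
    ``(residuals, (intercept, slope))`` of the allometric line.
    """
    t = np.asarray(trait, dtype=float)
    w = np.asarray(weight, dtype=float)
    if np.any(t <= 0) or np.any(w <= 0):
        raise AssociationError("allometric_residuals requires positive values")
    fit = ols_fit(np.log2(t), np.log2(w), names=["log2_weight"])
    return fit.residuals, (float(fit.coef[0]), float(fit.coef[1]))


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise AssociationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Kruskal-Wallis post-hoc
# ---------------------------------------------------------------------------

def kw_test(groups) -> tuple[float, float]:
    """Kruskal-Wallis H with tie correction and chi-square p (df = k-1)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise AssociationError("Kruskal-Wallis requires at least 2 groups")
    allv = np.concatenate(groups)
    if allv.size < 2:
        raise AssociationError("Kruskal-Wallis requires at least 2 observations")
    if np.ptp(allv) == 0.0:
        return 0.0, 1.0
    res = stats.kruskal(*groups)
    return float(res.statistic), float(res.pvalue)


def _kw_many(values: np.ndarray, group_codes: np.ndarray,
             n_groups: int) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized KW across many genes sharing one grouping.

    ``values`` is genes x observations (no NaN), ``group_codes`` maps
    each observation column to its species.  Tie correction falls back
    to a per-row pass only for rows that actually contain ties.
    """
    G, N = values.shape
    ranks = stats.rankdata(values, axis=1)
    ind = np.zeros((N, n_groups))
    ind[np.arange(N), group_codes] = 1.0
    n_j = ind.sum(axis=0)
    R_j = ranks @ ind
    H = 12.0 / (N * (N + 1)) * np.sum(R_j ** 2 / n_j, axis=1) - 3.0 * (N + 1)

    srt = np.sort(values, axis=1)
    has_ties = (srt[:, 1:] == srt[:, :-1]).any(axis=1)
    if has_ties.any():
        for i in np.nonzero(has_ties)[0]:
            _, counts = np.unique(values[i], return_counts=True)
            corr = 1.0 - np.sum(counts ** 3 - counts) / (N ** 3 - N)
            H[i] = H[i] / corr if corr > 0 else 0.0
    p = stats.chi2.sf(H, df=n_groups - 1)
    constant = np.ptp(values, axis=1) == 0.0
    H[constant] = 0.0
    p[constant] = 1.0
    return H, p


# ---------------------------------------------------------------------------
# Permutation null
# ---------------------------------------------------------------------------

def permutation_pvalue(y, x, n_reps: int, seed=None) -> float:
    """Add-one permutation p-value for the simple-regression F statistic.

    Species-level trait values are shuffled; the estimator is
    ``(1 + #[F_perm >= F_obs]) / (1 + n_reps)``, so the minimum
    attainable p is ``1 / (n_reps + 1)``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    n = y.size
    if np.ptp(y) == 0.0 or np.ptp(x) == 0.0:
        return 1.0
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    yc = y - y.mean()
    sy = float(np.sqrt(yc @ yc))

    def f_of_r2(r2):
        return (n - 2) * r2 / np.maximum(1.0 - r2, 1e-300)

    xc = x - x.mean()
    sx = float(np.sqrt(xc @ xc))
    r_obs = float(xc @ yc) / (sx * sy)
    f_obs = f_of_r2(r_obs ** 2)

    count = 0
    chunk = 20000
    done = 0
    while done < n_reps:
        b = min(chunk, n_reps - done)
        P = rng.permuted(np.broadcast_to(x, (b, n)), axis=1)
        Pc = P - P.mean(axis=1, keepdims=True)
        num = Pc @ yc
        den = np.sqrt(np.sum(Pc ** 2, axis=1)) * sy
        r2 = (num / den) ** 2
        count += int(np.sum(f_of_r2(r2) >= f_obs * (1.0 - 1e-12)))
        done += b
    return (1 + count) / (1 + n_reps)


# ---------------------------------------------------------------------------
# Per-gene association scans
# ---------------------------------------------------------------------------

def _align(expr: RelativeExpression, traits: pd.DataFrame):
    common = [sp for sp in expr.species if sp in traits.index]
    if len(common) < 4:
        raise AssociationError(
            f"only {len(common)} species shared between expression and traits"
        )
    return common


def _partial_f(Y: np.ndarray, X_full: np.ndarray, X_red: np.ndarray
               ) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized partial F of the full vs reduced design for many genes.

    ``Y`` is genes x n.  Residual sums of squares come from the
    annihilator matrices of the two fixed designs.
    """
    n = X_full.shape[0]
    p_full, p_red = X_full.shape[1], X_red.shape[1]
    if np.linalg.matrix_rank(X_full) < p_full:
        raise AssociationError("design is rank deficient; collinear columns "
                               "in the full model")
    M_full = np.eye(n) - X_full @ np.linalg.pinv(X_full)
    M_red = np.eye(n) - X_red @ np.linalg.pinv(X_red)
    rss_full = np.einsum("gi,ij,gj->g", Y, M_full, Y)
    rss_red = np.einsum("gi,ij,gj->g", Y, M_red, Y)
    df1 = p_full - p_red
    df2 = n - p_full
    rss_full = np.maximum(rss_full, 0.0)
    rss_red = np.maximum(rss_red, rss_full)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (rss_red - rss_full) / df1 / (rss_full / df2)
    F = np.where(rss_full <= 1e-300, np.inf, F)
    p = stats.f.sf(F, df1, df2)
    return F, p


def associate(expr: RelativeExpression, traits: pd.DataFrame, trait: str,
              covariate: str | None = None, n_perm: int = 0,
              alpha: float = 0.05, seed=None, organ: str = "",
              ) -> pd.DataFrame:
    """Per-gene OLS association of expression with one life-history trait.

    For each gene, species-level mean relative expression is regressed
    on the log2-relative trait (plus a log2-relative covariate when
    given; the reported p is then the partial F for the trait beyond
    the covariate).  p-values are BH-corrected across all genes of the
    organ x trait family; the Kruskal-Wallis post-hoc p uses
    replicate-level values grouped by species; an optional permutation
    p shuffles species-level trait values (covariate-free models only).

    Returns one row per gene with columns ``gene, organ, trait, slope,
    direction, r2, f_p, q, kw_p, perm_p, associated``.
    """
    if trait not in traits.columns:
        raise AssociationError(f"trait column not found: {trait!r}")
    common = _align(expr, traits)
    x = relative_log_trait(traits.loc[common, trait].to_numpy(float))
    Y = expr.species_means[common].to_numpy(float)
    genes = expr.genes
    n = len(common)

    if covariate is not None:
        if covariate == trait:
            raise AssociationError("covariate must differ from the trait")
        z = relative_log_trait(traits.loc[common, covariate].to_numpy(float))
        X_full = np.column_stack([np.ones(n), x, z])
        X_red = np.column_stack([np.ones(n), z])
    else:
        X_full = np.column_stack([np.ones(n), x])
        X_red = np.ones((n, 1))
    _, f_p = _partial_f(Y, X_full, X_red)

    beta = Y @ np.linalg.pinv(X_full).T   # genes x p
    slope = beta[:, 1]
    fitted = beta @ X_full.T
    rss = np.sum((Y - fitted) ** 2, axis=1)
    tss = np.sum((Y - Y.mean(axis=1, keepdims=True)) ** 2, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(tss > 0, 1.0 - rss / tss, 0.0)

    q = bh_fdr(np.nan_to_num(f_p, nan=1.0))
    kw_p = _kw_genes(expr, common)

    perm_p = np.full(len(genes), np.nan)
    if n_perm > 0:
        if covariate is not None:
            raise AssociationError(
                "permutation test is only supported without a covariate")
        rng = (seed if isinstance(seed, np.random.Generator)
               else np.random.default_rng(seed))
        for i in range(len(genes)):
            perm_p[i] = permutation_pvalue(Y[i], x, n_perm, rng)

    associated = (q < alpha) & (kw_p < alpha)
    return pd.DataFrame({
        "gene": genes,
        "organ": organ,
        "trait": trait,
        "slope": slope,
        "direction": np.where(slope >= 0, "up", "down"),
        "r2": r2,
        "f_p": f_p,
        "q": q,
        "kw_p": kw_p,
        "perm_p": perm_p,
        "associated": associated,
    })


def _kw_genes(expr: RelativeExpression, species: list[str]) -> np.ndarray:
    """Per-gene Kruskal-Wallis p across species replicate groups."""
    sheet = expr.sheet
    by_sp = sheet.samples_by_species()
    cols: list[str] = []
    codes: list[int] = []
    for k, sp in enumerate(species):
        for sid in by_sp.get(sp, []):
            if sid in expr.replicate_values.columns:
                cols.append(sid)
                codes.append(k)
    vals = expr.replicate_values[cols].to_numpy(float)
    codes_arr = np.asarray(codes)
    complete = ~np.isnan(vals).any(axis=1)
    p = np.ones(vals.shape[0])
    if complete.any():
        _, p_c = _kw_many(vals[complete], codes_arr, len(species))
        p[complete] = p_c
    incomplete = np.nonzero(~complete)[0]
    for i in incomplete:
        row = vals[i]
        groups = [row[(codes_arr == k) & ~np.isnan(row)]
                  for k in range(len(species))]
        groups = [g for g in groups if g.size > 0]
        if len(groups) < 2 or sum(g.size for g in groups) < 3:
            p[i] = 1.0
        else:
            p[i] = kw_test(groups)[1]
    return p


def residual_interaction_scan(expr: RelativeExpression, traits: pd.DataFrame,
                              trait: str, alpha: float = 0.05,
                              weight_col: str = "adult_weight_g",
                              organ: str = "") -> pd.DataFrame:
    """Scan for genes tracking a trait beyond its allometric component.

    Per gene the full model ``Y ~ 1 + t + w + t*w`` is compared to the
    reduced model ``Y ~ 1 + w`` by partial F (t = log2-relative trait,
    w = log2-relative body weight); BH-FDR is applied across genes.
    Genes whose expression is a pure function of body weight carry no
    signal in the extra terms and are not detected.
    """
    if weight_col not in traits.columns:
        raise AssociationError(f"weight column not found: {weight_col!r}")
    common = _align(expr, traits)
    t = relative_log_trait(traits.loc[common, trait].to_numpy(float))
    w = relative_log_trait(traits.loc[common, weight_col].to_numpy(float))
    n = len(common)
    X_full = np.column_stack([np.ones(n), t, w, t * w])
    X_red = np.column_stack([np.ones(n), w])
    Y = expr.species_means[common].to_numpy(float)
    F, p = _partial_f(Y, X_full, X_red)
    q = bh_fdr(np.nan_to_num(p, nan=1.0))
    beta = Y @ np.linalg.pinv(X_full).T
    return pd.DataFrame({
        "gene": expr.genes,
        "organ": organ,
        "trait": trait,
        "partial_F": F,
        "p": p,
        "q": q,
        "beta_intercept": beta[:, 0],
        "beta_trait": beta[:, 1],
        "beta_weight": beta[:, 2],
        "beta_interaction": beta[:, 3],
        "significant": q < alpha,
    })


# ---------------------------------------------------------------------------
# Count summaries (Table-style set algebra)
# ---------------------------------------------------------------------------

def summarize_counts(gene_sets: dict[tuple[str, str], set],
                     universe_sizes: dict[str, int]) -> pd.DataFrame:
    """Summarize associated-gene sets per organ x trait.

    ``gene_sets`` maps ``(organ, trait)`` to the set of associated
    genes; ``universe_sizes`` gives the number of genes tested per
    organ.  Per organ x trait the summary reports the gene count, the
    trait-specific count (genes not associated with any other trait in
    that organ), and percentages of the organ universe; per trait the
    cross-organ union and the intersection across all organs; plus a
    combined row with per-organ unions over traits.
    """
    organs = sorted({o for o, _ in gene_sets})
    traits = sorted({t for _, t in gene_sets})
    rows = []
    for tr in traits:
        row: dict[str, object] = {"trait": tr}
        union_across_organs: set = set()
        inter_across_organs: set | None = None
        for org in organs:
            s = gene_sets.get((org, tr), set())
            others = set().union(*(gene_sets.get((org, t2), set())
                                   for t2 in traits if t2 != tr)) if len(traits) > 1 else set()
            row[f"{org}_n"] = len(s)
            row[f"{org}_specific"] = len(s - others)
            total = universe_sizes.get(org, 0)
            row[f"{org}_pct"] = round(100.0 * len(s) / total, 1) if total else np.nan
            union_across_organs |= s
            inter_across_organs = s if inter_across_organs is None else (inter_across_organs & s)
        row["combined_n"] = len(union_across_organs)
        row["combined_overlap"] = len(inter_across_organs or set())
        rows.append(row)

    combo: dict[str, object] = {"trait": "combined"}
    union_all: set = set()
    for org in organs:
        sets_org = [gene_sets.get((org, tr), set()) for tr in traits]
        u = set().union(*sets_org) if sets_org else set()
        inter = set.intersection(*sets_org) if sets_org else set()
        combo[f"{org}_n"] = len(u)
        combo[f"{org}_specific"] = len(inter)
        total = universe_sizes.get(org, 0)
        combo[f"{org}_pct"] = round(100.0 * len(u) / total, 1) if total else np.nan
        union_all |= u
    per_organ_unions = [set().union(*(gene_sets.get((org, tr), set()) for tr in traits))
                        for org in organs]
    combo["combined_n"] = len(union_all)
    combo["combined_overlap"] = len(set.intersection(*per_organ_unions)) if per_organ_unions else 0
    rows.append(combo)
    return pd.DataFrame(rows)
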