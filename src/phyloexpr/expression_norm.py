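"""Cross-species FPKM normalization and quality control.

Expression input is a genes x samples FPKM matrix per organ plus a
sample sheet mapping samples to species/organ/replicate.  Processing
steps:

* abundance filter: within an organ a gene is kept only when its
  species-mean FPKM reaches a threshold (default 3.0) in every species,
  so downstream per-gene regressions have complete rows across species;
* pairwise upper-quartile normalization with a cyclic log2-ratio
  procedure over every ordered sample pair, each pair's ratio
  distribution centered on zero (median subtraction by default) — the
  all-pairs design makes the final per-species summaries independent of
  any single reference sample;
* species-relative expression: per gene, log2 of each species' mean
  FPKM over the minimum species mean (the minimum species maps to 0);
* QC: per-gene per-species coefficient of variation across replicates
  (sample sd / mean), plus pairwise two-sample Kolmogorov-Smirnov and
  Welch tests between species-level log-expression distributions.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SampleSheet",
    "RelativeExpression",
    "QCReport",
    "ExpressionError",
    "read_expression",
    "read_sample_sheet",
    "filter_fpkm",
    "upper_quartile_factor",
    "pair_log_ratios",
    "cyclic_log_ratios",
    "species_relative_expression",
    "qc_report",
]

logger = logging.getLogger(__name__)

SHEET_COLUMNS = ("sample_id", "species", "organ", "replicate")


class ExpressionError(ValueError):
    """Raised for malformed expression matrices or sample sheets."""


@dataclass
class SampleSheet:
    """Sample metadata: one row per sample (species, organ, replicate)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in SHEET_COLUMNS if c not in self.table.columns]
        if missing:
            raise ExpressionError(f"sample sheet missing columns: {missing}")
        ids = self.table["sample_id"]
        if ids.duplicated().any():
            dup = sorted(ids[ids.duplicated()].unique())
            raise ExpressionError(f"duplicate sample ids: {dup}")
        self.table = self.table.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def species_of(self, sample_id: str) -> str:
        row = self.table.loc[self.table["sample_id"] == sample_id]
        if row.empty:
            raise ExpressionError(f"unknown sample id: {sample_id}")
        return str(row["species"].iloc[0])

    def samples_by_species(self) -> dict[str, list[str]]:
        return {
            str(sp): list(grp["sample_id"])
            for sp, grp in self.table.groupby("species", sort=True)
        }

    def subset(self, sample_ids: list[str]) -> "SampleSheet":
        t = self.table[self.table["sample_id"].isin(sample_ids)]
        return SampleSheet(t.copy())


@dataclass
class RelativeExpression:
    """Per-species relative log2 expression with replicate-level detail.

    ``species_means`` is genes x species (mean log2-relative value per
    species); ``replicate_values`` is genes x samples and is retained
    for the Kruskal-Wallis post-hoc test downstream.
    """

    species_means: pd.DataFrame
    replicate_values: pd.DataFrame
    sheet: SampleSheet
    method: str = "cyclic"

    @property
    def genes(self) -> list[str]:
        return list(self.species_means.index)

    @property
    def species(self) -> list[str]:
        return list(self.species_means.columns)


@dataclass
class QCReport:
    """Replicate CV and pairwise distribution-test results.

    ``cv`` is genes x species (NaN where a species has one replicate);
    ``pair_tests`` has one row per species pair with K-S and Welch
    statistics on species-level log2 expression; ``flags`` lists
    species whose median CV exceeds the flag threshold or that reject
    a distribution test at ``alpha``.
    """

    cv: pd.DataFrame
    median_cv: pd.Series
    pair_tests: pd.DataFrame
    flags: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_sample_sheet(path) -> SampleSheet:
    return SampleSheet(pd.read_csv(path, sep="\t", dtype={"sample_id": str,
                                                          "species": str,
                                                          "organ": str}))


def read_expression(matrix_path, samples_path) -> tuple[pd.DataFrame, SampleSheet]:
    """Read an FPKM TSV (genes x samples) and its sample sheet.

    Validates that matrix columns and sheet sample ids agree exactly,
    that gene ids are unique, and that no value is negative.
    """
    sheet = read_sample_sheet(samples_path)
    m = pd.read_csv(matrix_path, sep="\t", index_col=0)
    m.index = m.index.astype(str)
    m.columns = m.columns.astype(str)
    if m.index.duplicated().any():
        dup = sorted(m.index[m.index.duplicated()].unique())
        raise ExpressionError(f"duplicate gene ids: {dup}")
    orphans = set(m.columns) - set(sheet.sample_ids)
    if orphans:
        raise ExpressionError(
            f"matrix samples absent from sample sheet: {sorted(orphans)}")
    if (m.values < 0).any():
        bad = m.stack()
        offenders = bad[bad < 0]
        raise ExpressionError(
            "negative FPKM values at "
            + ", ".join(f"{g}/{s}" for (g, s) in offenders.index[:10])
        )
    return m, sheet


# ---------------------------------------------------------------------------
# Filtering and normalization
# ---------------------------------------------------------------------------

def _species_means(m: pd.DataFrame, sheet: SampleSheet) -> pd.DataFrame:
    """Genes x species matrix of replicate-mean FPKM."""
    by_sp = sheet.subset(list(m.columns)).samples_by_species()
    return pd.DataFrame(
        {sp: m[cols].mean(axis=1) for sp, cols in by_sp.items()}
    )


def filter_fpkm(m: pd.DataFrame, sheet: SampleSheet,
                threshold: float = 3.0) -> pd.DataFrame:
    """Keep genes whose species-mean FPKM >= threshold in every species."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    means = _species_means(m, sheet)
    keep = (means >= threshold).all(axis=1)
    return m.loc[keep]


def upper_quartile_factor(sample: np.ndarray, reference: np.ndarray) -> float:
    """Scale factor Q75(reference) / Q75(sample).

    Percentiles use linear interpolation between order statistics.
    Multiplying the sample by the factor equalizes upper quartiles.
    """
    sample = np.asarray(sample, float)
    reference = np.asarray(reference, float)
    if sample.shape != reference.shape:
        raise ValueError("sample and reference must cover the same genes")
    q_s = float(np.percentile(sample, 75))
    q_r = float(np.percentile(reference, 75))
    if q_s <= 0 or q_r <= 0:
        raise ExpressionError("zero upper quartile; cannot normalize")
    return q_r / q_s


def pair_log_ratios(m: pd.DataFrame, sample: str, reference: str,
                    center: str = "median") -> pd.Series:
    """Centered per-gene log2 ratios of one sample against one reference.

    The sample is upper-quartile normalized against the reference over
    genes positive in both; the pair's log2-ratio distribution is then
    centered on 0 (median by default, mean behind the flag).  Genes with
    a zero value in either member are NaN.
    """
    s = m[sample].to_numpy(float)
    r = m[reference].to_numpy(float)
    valid = (s > 0) & (r > 0)
    out = np.full(s.shape, np.nan)
    if valid.sum() == 0:
        return pd.Series(out, index=m.index)
    factor = upper_quartile_factor(s[valid], r[valid])
    ratios = np.log2(s[valid] * factor) - np.log2(r[valid])
    if center == "median":
        ratios = ratios - np.median(ratios)
    elif center == "mean":
        ratios = ratios - np.mean(ratios)
    else:
        raise ValueError(f"unknown centering mode: {center}")
    out[valid] = ratios
    return pd.Series(out, index=m.index)


def cyclic_log_ratios(m: pd.DataFrame, sheet: SampleSheet,
                      center: str = "median") -> RelativeExpression:
    """All-pairs upper-quartile log2-ratio normalization.

    For every ordered sample pair (s, r) the sample is upper-quartile
    normalized against the reference, per-gene log2 ratios are computed
    and the pair's distribution centered on 0.  Per-gene per-sample
    values are means over all references; per-species values are means
    over the species' samples.  Genes lacking a positive value in some
    pair are excluded from that pair (count logged).
    """
    samples = list(m.columns)
    if len(samples) < 2:
        raise ExpressionError("cyclic normalization needs at least 2 samples")
    M = m.to_numpy(float)
    G, S = M.shape
    pos = M > 0
    logM = np.where(pos, np.log2(np.where(pos, M, 1.0)), np.nan)

    if center == "median":
        center_fn = np.nanmedian
    elif center == "mean":
        center_fn = np.nanmean
    else:
        raise ValueError(f"unknown centering mode: {center}")

    sample_means = np.full((G, S), np.nan)
    n_excluded = 0
    for si in range(S):
        # pairwise-valid gene mask for sample si against every reference
        # (the self-pair column is computed trivially and dropped below)
        valid = pos[:, [si]] & pos  # G x S
        Mv = np.where(valid, M, np.nan)
        sv = np.where(valid, M[:, [si]], np.nan)
        with np.errstate(invalid="ignore"):
            q_ref = np.nanpercentile(Mv, 75, axis=0)
            q_smp = np.nanpercentile(sv, 75, axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            shift = np.log2(q_ref / q_smp)  # log2 of UQ factor, per reference
            ratios = (logM[:, [si]] - logM) + shift[None, :]
        ratios[~valid] = np.nan
        ratios = ratios - center_fn(ratios, axis=0, keepdims=True)
        ratios[:, si] = np.nan
        n_excluded += int((pos[:, si][:, None] & ~valid).sum())
        with np.errstate(invalid="ignore"):
            sample_means[:, si] = np.nanmean(ratios, axis=1)
    if n_excluded:
        logger.info("cyclic_log_ratios: %d gene/pair values excluded "
                    "for zero FPKM", n_excluded)

    rep = pd.DataFrame(sample_means, index=m.index, columns=samples)
    by_sp = sheet.subset(samples).samples_by_species()
    species_means = pd.DataFrame(
        {sp: rep[cols].mean(axis=1) for sp, cols in by_sp.items()}
    )
    return RelativeExpression(species_means, rep, sheet.subset(samples),
                              method=f"cyclic/{center}")


def species_relative_expression(m: pd.DataFrame, sheet: SampleSheet
                                ) -> RelativeExpression:
    """Per-species log2 ratio of mean FPKM to the minimum species mean.

    The species with the smallest mean maps to 0 for each gene, so all
    values are nonnegative with at least one zero per gene.  Genes with
    a zero species mean are excluded (count logged).  Replicate-level
    values are log2 of replicate FPKM over the same per-gene minimum
    mean (NaN where the replicate value is 0).
    """
    means = _species_means(m, sheet)
    minval = means.min(axis=1)
    ok = minval > 0
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("species_relative_expression: %d genes dropped for "
                    "zero species-mean FPKM", n_dropped)
    means = means.loc[ok]
    minval = minval.loc[ok]
    rel = np.log2(means.div(minval, axis=0))

    sub = m.loc[ok]
    with np.errstate(divide="ignore"):
        repvals = np.log2(sub.div(minval, axis=0))
    repvals = repvals.replace(-np.inf, np.nan)
    return RelativeExpression(rel, repvals, sheet.subset(list(m.columns)),
                              method="min-referenced")


# ---------------------------------------------------------------------------
# Quality control
# ---------------------------------------------------------------------------

def qc_report(m: pd.DataFrame, sheet: SampleSheet, cv_flag: float = 0.6,
              alpha: float = 0.001) -> QCReport:
    """Replicate CV and pairwise species distribution tests.

    CV is the sample standard deviation (ddof=1) over replicate FPKM
    divided by the replicate mean, per gene per species; species with a
    single replicate are reported as missing.  Species-level log2 mean
    expression distributions are compared pairwise with the two-sample
    K-S test and two-tailed Welch's t-test.  A species is flagged when
    its median CV exceeds ``cv_flag`` or when it rejects a distribution
    test against another species at ``alpha``.
    """
    by_sp = sheet.subset(list(m.columns)).samples_by_species()
    cv_cols = {}
    for sp, cols in by_sp.items():
        if len(cols) < 2:
            cv_cols[sp] = pd.Series(np.nan, index=m.index)
            continue
        vals = m[cols]
        mean = vals.mean(axis=1)
        sd = vals.std(axis=1, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            cv = sd / mean
        cv[mean == 0] = np.nan
        cv_cols[sp] = cv
    cv_df = pd.DataFrame(cv_cols)
    median_cv = cv_df.median(axis=0, skipna=True)

    means = _species_means(m, sheet)
    log_means = {}
    for sp in means.columns:
        v = means[sp].to_numpy(float)
        log_means[sp] = np.log2(v[v > 0])
    rows = []
    for a, b in itertools.combinations(sorted(means.columns), 2):
        xa, xb = log_means[a], log_means[b]
        ks = stats.ks_2samp(xa, xb)
        wt = stats.ttest_ind(xa, xb, equal_var=False)
        rows.append({"species_a": a, "species_b": b,
                     "ks_stat": float(ks.statistic), "ks_p": float(ks.pvalue),
                     "welch_t": float(wt.statistic), "welch_p": float(wt.pvalue)})
    pair_tests = pd.DataFrame(rows)

    flags = sorted(median_cv.index[median_cv > cv_flag].tolist())
    if not pair_tests.empty:
        reject = pair_tests[(pair_tests["ks_p"] < alpha)
                            | (pair_tests["welch_p"] < alpha)]
        for _, row in reject.iterrows():
            for sp in (row["species_a"], row["species_b"]):
                if sp not in flags:
                    flags.append(sp)
    return QCReport(cv=cv_df, median_cv=median_cv, pair_tests=pair_tests,
                    flags=sorted(flags))
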