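"""Alignment-based conservation scoring of ortholog groups.

Each ortholog group is a protein multiple alignment (20 amino acids
plus gap).  Per column the module computes

* Shannon information entropy in bits, ``H = -sum p_a log2 p_a`` over
  non-gap residue frequencies (0 for a fully conserved column,
  log2(20) at saturation), and
* a similarity score in [0, 1]: the mean normalized pairwise
  similarity over all unordered non-gap residue pairs.  The default
  residue-pair table is identity (1 for a match, 0 otherwise), i.e.
  the fraction of identical pairs; a substitution-matrix table can be
  loaded and min-max normalized instead.

Per-protein profiles average the column scores over columns with at
most 50% gaps.  Groups of proteins (e.g. up- vs down-regulated
orthologs) are compared with two-tailed Welch's t-tests on the
per-protein means.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import AlignIO
from scipy import stats

__all__ = [
    "AMINO_ACIDS",
    "GAP",
    "MultipleAlignment",
    "ConservationProfile",
    "GroupComparison",
    "AlignmentError",
    "read_alignment",
    "load_similarity_matrix",
    "column_entropy",
    "column_similarity",
    "protein_profile",
    "welch_t",
    "compare_direction_groups",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
_AA_SET = set(AMINO_ACIDS)


class AlignmentError(ValueError):
    """Raised for ragged or otherwise invalid alignments."""


@dataclass
class MultipleAlignment:
    """Validated protein alignment: ids plus an (n_rows, length) residue array."""

    ids: list[str]
    rows: np.ndarray  # dtype '<U1'

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype="<U1")
        if self.rows.ndim != 2:
            raise AlignmentError("alignment rows must form a 2-d array")
        if len(self.ids) != self.rows.shape[0]:
            raise AlignmentError("id count does not match row count")

    @property
    def length(self) -> int:
        return self.rows.shape[1]

    @property
    def n_rows(self) -> int:
        return self.rows.shape[0]


@dataclass
class ConservationProfile:
    """Per-column and per-protein conservation summaries for one group."""

    similarity: np.ndarray       # per eligible column, in [0, 1]
    entropy: np.ndarray          # per eligible column, bits
    eligible_columns: np.ndarray  # indices of columns with <= max gap fraction
    mean_similarity: float
    mean_entropy: float


@dataclass
class GroupComparison:
    """Welch comparison of two groups of per-protein profiles."""

    similarity_t: float
    similarity_p: float
    entropy_t: float
    entropy_p: float
    more_conserved: str  # "up", "down" or "tie"


def read_alignment(source) -> MultipleAlignment:
    """Read an aligned FASTA (path, file object, or string content).

    Rows must have equal length; residues are upper-cased and any
    character outside the 20 amino acids is mapped to the gap symbol.
    """
    if isinstance(source, str) and "\n" in source:
        source = io.StringIO(source)
    try:
        aln = AlignIO.read(source, "fasta")
    except ValueError as exc:
        raise AlignmentError(f"invalid alignment: {exc}") from exc
    ids = [rec.id for rec in aln]
    rows = np.array([list(str(rec.seq).upper()) for rec in aln], dtype="<U1")
    known = np.isin(rows, list(_AA_SET))
    rows[~known] = GAP
    return MultipleAlignment(ids, rows)


def load_similarity_matrix(path) -> pd.DataFrame:
    """Load a whitespace-delimited 20x20 residue similarity table.

    The table is min-max normalized to [0, 1] and the diagonal set to
    1 (unit self-similarity convention); it must be symmetric.
    """
    tab = pd.read_csv(path, sep=r"\s+", index_col=0)
    tab.index = tab.index.astype(str)
    tab.columns = tab.columns.astype(str)
    missing = sorted(_AA_SET - set(tab.index)) + sorted(_AA_SET - set(tab.columns))
    if missing:
        raise AlignmentError(f"similarity table missing residues: {missing}")
    tab = tab.loc[list(AMINO_ACIDS), list(AMINO_ACIDS)].astype(float)
    if not np.allclose(tab.values, tab.values.T):
        raise AlignmentError("similarity table is not symmetric")
    lo, hi = tab.values.min(), tab.values.max()
    if hi <= lo:
        raise AlignmentError("similarity table is constant")
    norm = (tab - lo) / (hi - lo)
    np.fill_diagonal(norm.values, 1.0)
    return norm


def column_entropy(column) -> float:
    """Shannon entropy (bits) of non-gap residue frequencies.

    Returns NaN for an all-gap column (marked missing).
    """
    col = np.asarray(list(column), dtype="<U1")
    residues = col[col != GAP]
    if residues.size == 0:
        return float("nan")
    _, counts = np.unique(residues, return_counts=True)
    p = counts / counts.sum()
    return float(-np.sum(p * np.log2(p)))


def column_similarity(column, matrix: pd.DataFrame | None = None) -> float:
    """Mean pairwise residue similarity of a column, in [0, 1].

    With the default identity table this is the fraction of identical
    unordered non-gap pairs.  A column with a single non-gap residue
    scores 1 by convention; an all-gap column is NaN.
    """
    col = np.asarray(list(column), dtype="<U1")
    residues = col[col != GAP]
    m = residues.size
    if m == 0:
        return float("nan")
    if m == 1:
        return 1.0
    if matrix is None:
        _, counts = np.unique(residues, return_counts=True)
        same = np.sum(counts * (counts - 1) / 2)
        return float(same / (m * (m - 1) / 2))
    vals = matrix.loc[residues, residues].to_numpy(float)
    iu = np.triu_indices(m, k=1)
    return float(np.mean(vals[iu]))


def protein_profile(aln: MultipleAlignment, max_gap_frac: float = 0.5,
                    matrix: pd.DataFrame | None = None) -> ConservationProfile:
    """Column-wise conservation profile of one ortholog alignment.

    Columns with more than ``max_gap_frac`` gaps are excluded from the
    per-protein means.  Raises :class:`AlignmentError` when no column
    is eligible.
    """
    gaps = np.mean(aln.rows == GAP, axis=0)
    eligible = np.nonzero(gaps <= max_gap_frac)[0]
    if eligible.size == 0:
        raise AlignmentError("no columns pass the gap-fraction filter")
    sims = np.array([column_similarity(aln.rows[:, j], matrix) for j in eligible])
    ents = np.array([column_entropy(aln.rows[:, j]) for j in eligible])
    return ConservationProfile(
        similarity=sims,
        entropy=ents,
        eligible_columns=eligible,
        mean_similarity=float(np.nanmean(sims)),
        mean_entropy=float(np.nanmean(ents)),
    )


def welch_t(a, b) -> tuple[float, float]:
    """Two-tailed Welch's t-test (unequal variances, W-S df)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        return (0.0, 1.0) if a.mean() == b.mean() else (float("inf"), 0.0)
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def compare_direction_groups(up_profiles, down_profiles) -> GroupComparison:
    """Welch tests of up- vs down-regulated ortholog conservation.

    Compares the distributions of per-protein mean similarity and mean
    entropy between the two groups; ``more_conserved`` names the group
    with the higher mean similarity.
    """
    up_sim = [p.mean_similarity for p in up_profiles]
    dn_sim = [p.mean_similarity for p in down_profiles]
    up_ent = [p.mean_entropy for p in up_profiles]
    dn_ent = [p.mean_entropy for p in down_profiles]
    if not up_sim or not dn_sim:
        raise ValueError("both groups must be nonempty")
    st, sp = welch_t(up_sim, dn_sim)
    et, ep = welch_t(up_ent, dn_ent)
    if np.mean(dn_sim) > np.mean(up_sim):
        winner = "down"
    elif np.mean(dn_sim) < np.mean(up_sim):
        winner = "up"
    else:
        winner = "tie"
    return GroupComparison(similarity_t=st, similarity_p=sp,
                           entropy_t=et, entropy_p=ep,
                           more_conserved=winner)
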