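"""Phylogenetic signal estimation with Pagel's lambda.

Pagel's lambda rescales the off-diagonal entries of the Brownian-motion
(BM) phylogenetic covariance matrix by a factor ``lambda`` in [0, 1].
``lambda = 1`` corresponds to pure BM trait evolution (trait covariance
proportional to shared branch length), ``lambda = 0`` to phylogenetic
independence.  The maximum-likelihood estimate of lambda therefore
quantifies how much of the interspecies trait variance is attributable
to shared ancestry under neutral drift.

The module provides Newick I/O, construction of the species covariance
matrix from a tree, the lambda transform, a GLS profile likelihood,
maximum-likelihood fitting with likelihood-ratio tests against the two
boundary hypotheses (lambda = 0: no phylogenetic effect; lambda = 1:
pure BM), and simulation of traits under the lambda-BM model.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy import optimize, stats

__all__ = [
    "Phylogeny",
    "PhyloCovariance",
    "LambdaFit",
    "PhylogenyError",
    "read_newick",
    "write_newick",
    "vcv",
    "pagel_transform",
    "gls_loglik",
    "fit_lambda",
    "simulate_bm_lambda",
]

#: relative ridge added to the covariance diagonal before factorization
RIDGE = 1e-10

#: number of grid points for the coarse lambda profile scan
LAMBDA_GRID_SIZE = 201

#: absolute tolerance of the golden-section refinement of lambda
LAMBDA_TOL = 1e-6


class PhylogenyError(ValueError):
    """Raised for malformed trees or invalid phylogenetic input."""


@dataclass
class Phylogeny:
    """A rooted tree with branch lengths, wrapping a dendropy tree.

    Tip labels are unique species identifiers; branch lengths are
    nonnegative and share one time unit.  Multifurcations and
    zero-length branches are allowed.
    """

    tree: dendropy.Tree

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self.tree.leaf_node_iter())

    def __len__(self) -> int:  # pragma: no cover - convenience
        return self.n_tips


@dataclass
class PhyloCovariance:
    """Species-by-species shared-path covariance matrix.

    ``matrix[i, j]`` is the branch length shared between the root and
    the MRCA of species i and j; the diagonal holds root-to-tip
    distances.  Symmetric and positive semidefinite by construction.
    """

    species: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.species)
        if self.matrix.shape != (n, n):
            raise PhylogenyError(
                f"covariance shape {self.matrix.shape} does not match "
                f"{n} species"
            )

    @property
    def n(self) -> int:
        return len(self.species)

    def reorder(self, species: list[str]) -> "PhyloCovariance":
        """Return a copy with rows/columns ordered as ``species``."""
        missing = [s for s in species if s not in self.species]
        if missing:
            raise PhylogenyError(f"species not in covariance: {missing}")
        idx = [self.species.index(s) for s in species]
        return PhyloCovariance(list(species), self.matrix[np.ix_(idx, idx)])


@dataclass
class LambdaFit:
    """Result of a maximum-likelihood Pagel's lambda fit.

    ``p_vs_random`` is the likelihood-ratio p-value against lambda = 0
    (no phylogenetic effect), ``p_vs_bm`` against lambda = 1 (pure BM).
    Both use the chi-square distribution with 1 df; because the nulls
    sit on the boundary of the lambda parameter space the reference
    distribution is approximate (conservative).
    """

    lambda_hat: float
    sigma2_hat: float
    root_hat: float
    logL: float
    logL_at_0: float
    logL_at_1: float
    p_vs_random: float
    p_vs_bm: float
    species: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------

def read_newick(text: str) -> Phylogeny:
    """Parse a Newick string into a validated :class:`Phylogeny`.

    Raises :class:`PhylogenyError` for malformed strings, duplicate tip
    labels, missing or negative branch lengths.
    """
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:  # dendropy raises several error types
        raise PhylogenyError(f"malformed Newick string: {exc}") from exc

    labels = [leaf.taxon.label if leaf.taxon else None
              for leaf in tree.leaf_node_iter()]
    if any(lab is None for lab in labels):
        raise PhylogenyError("tree contains unlabeled tips")
    seen: set[str] = set()
    for lab in labels:
        if lab in seen:
            raise PhylogenyError(f"duplicate tip label: {lab!r}")
        seen.add(lab)

    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue  # root edge length is optional
        if edge.length is None:
            node = edge.head_node
            name = (node.taxon.label if node.taxon else "<internal node>")
            raise PhylogenyError(f"missing branch length above {name}")
        if edge.length < 0:
            raise PhylogenyError(f"negative branch length: {edge.length}")
    return Phylogeny(tree)


def write_newick(phy: Phylogeny) -> str:
    """Serialize a :class:`Phylogeny` back to Newick."""
    out = io.StringIO()
    phy.tree.write(file=out, schema="newick", suppress_rooting=True)
    return out.getvalue().strip()


# ---------------------------------------------------------------------------
# Covariance construction and the lambda transform
# ---------------------------------------------------------------------------

def vcv(phy: Phylogeny) -> PhyloCovariance:
    """Shared-path covariance matrix of a tree.

    ``C[i, j]`` = summed branch length from the root to the MRCA of
    tips i and j; ``C[i, i]`` = root-to-tip distance.  Computed in a
    single postorder pass, so multifurcations and zero branches need no
    special handling.
    """
    leaves = list(phy.tree.leaf_node_iter())
    labels = [leaf.taxon.label for leaf in leaves]
    index = {id(leaf): k for k, leaf in enumerate(leaves)}
    n = len(leaves)
    C = np.zeros((n, n))

    # depth of every node from the root
    depth: dict[int, float] = {id(phy.tree.seed_node): 0.0}
    for node in phy.tree.preorder_node_iter():
        if node is phy.tree.seed_node:
            continue
        depth[id(node)] = depth[id(node.parent_node)] + (node.edge.length or 0.0)

    # postorder: leaf sets per subtree; cross-subtree pairs share the node
    below: dict[int, list[int]] = {}
    for node in phy.tree.postorder_node_iter():
        if node.is_leaf():
            k = index[id(node)]
            below[id(node)] = [k]
            C[k, k] = depth[id(node)]
            continue
        child_sets = [below.pop(id(ch)) for ch in node.child_nodes()]
        d = depth[id(node)]
        for a in range(len(child_sets)):
            for b in range(a + 1, len(child_sets)):
                ia, ib = child_sets[a], child_sets[b]
                C[np.ix_(ia, ib)] = d
                C[np.ix_(ib, ia)] = d
        below[id(node)] = [k for s in child_sets for k in s]
    return PhyloCovariance(labels, C)


def pagel_transform(cov: PhyloCovariance, lam: float) -> PhyloCovariance:
    """Multiply off-diagonal covariance entries by ``lam`` in [0, 1]."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    C = cov.matrix
    out = lam * C + (1.0 - lam) * np.diag(np.diag(C))
    return PhyloCovariance(list(cov.species), out)


# ---------------------------------------------------------------------------
# GLS likelihood machinery
# ---------------------------------------------------------------------------

def _cho_factor(V: np.ndarray) -> np.ndarray:
    """Cholesky factor of V with a tiny relative ridge for stability."""
    n = V.shape[0]
    ridge = RIDGE * float(np.mean(np.diag(V)))
    try:
        return np.linalg.cholesky(V + ridge * np.eye(n))
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "phylogenetic covariance is singular after regularization"
        ) from exc


def gls_loglik(y: np.ndarray, cov: PhyloCovariance | np.ndarray
               ) -> tuple[float, float, float]:
    """ML log-likelihood of a single-mean GLS model y ~ N(mu*1, sigma2*V).

    Returns ``(logL, sigma2_hat, root_hat)`` where ``root_hat`` is the
    GLS estimate of the ancestral (root) state and ``sigma2_hat`` the
    divide-by-n ML rate estimate.  A zero-variance fit is degenerate;
    its log-likelihood is reported as ``+inf``.
    """
    V = cov.matrix if isinstance(cov, PhyloCovariance) else np.asarray(cov, float)
    y = np.asarray(y, dtype=float)
    n = y.size
    if V.shape != (n, n):
        raise ValueError("dimension mismatch between y and covariance")
    L = _cho_factor(V)
    # whiten: solve L z = x
    zy = np.linalg.solve(L, y)
    z1 = np.linalg.solve(L, np.ones(n))
    root_hat = float(z1 @ zy / (z1 @ z1))
    r = zy - root_hat * z1
    q = float(r @ r)
    sigma2_hat = q / n
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    if sigma2_hat <= 0.0:
        return math.inf, 0.0, root_hat
    logL = -0.5 * (n * math.log(2.0 * math.pi * sigma2_hat) + logdet + n)
    return logL, sigma2_hat, root_hat


def _profile_loglik(y: np.ndarray, C: np.ndarray, lam: float) -> float:
    V = lam * C + (1.0 - lam) * np.diag(np.diag(C))
    return gls_loglik(y, V)[0]


def _golden_section(f, lo: float, hi: float, tol: float) -> float:
    """Maximize a unimodal f on [lo, hi] by golden-section search."""
    invphi = (math.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = f(c), f(d)
    while b - a > tol:
        if fc >= fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = f(d)
    return (a + b) / 2.0


def fit_lambda(y, tree_or_cov, species: list[str] | None = None) -> LambdaFit:
    """Maximum-likelihood Pagel's lambda fit with boundary LRTs.

    Parameters
    ----------
    y
        Trait values: a pandas Series indexed by species, or an array
        (then ``species`` orders it against the tree).
    tree_or_cov
        A :class:`Phylogeny` or precomputed :class:`PhyloCovariance`
        (pass the latter when fitting many traits on one tree).
    species
        Species labels for array input; defaults to the tree's order.

    The profile likelihood over lambda in [0, 1] is scanned on a
    201-point grid and refined by golden-section search (tol 1e-6).
    p-values are chi-square (df=1) likelihood-ratio tests against the
    lambda = 0 and lambda = 1 boundaries.
    """
    cov = tree_or_cov if isinstance(tree_or_cov, PhyloCovariance) else vcv(tree_or_cov)

    if hasattr(y, "index") and hasattr(y, "values"):  # pandas Series
        species = [str(s) for s in y.index]
        yv = np.asarray(y.values, dtype=float)
    else:
        yv = np.asarray(y, dtype=float)
    if species is not None:
        cov = cov.reorder(list(species))
    n = cov.n
    if yv.size != n:
        raise ValueError("trait vector length does not match tree tips")
    if n < 4:
        raise PhylogenyError("lambda estimation requires at least 4 species")
    if not np.all(np.isfinite(yv)):
        raise ValueError("trait vector contains non-finite values")
    if np.ptp(yv) == 0.0:
        raise ValueError("trait is constant; lambda is undefined")

    C = cov.matrix
    offdiag = C[~np.eye(n, dtype=bool)]
    scale = float(np.mean(np.diag(C)))
    if np.all(np.abs(offdiag) <= RIDGE * scale):
        raise PhylogenyError(
            "lambda unidentifiable: star tree (all off-diagonal covariances zero)"
        )

    grid = np.linspace(0.0, 1.0, LAMBDA_GRID_SIZE)
    ll_grid = np.array([_profile_loglik(yv, C, lam) for lam in grid])
    k = int(np.argmax(ll_grid))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, grid.size - 1)]
    lam_ref = _golden_section(lambda lam: _profile_loglik(yv, C, lam),
                              lo, hi, LAMBDA_TOL)
    candidates = [grid[k], lam_ref]
    lls = [ll_grid[k], _profile_loglik(yv, C, lam_ref)]
    j = int(np.argmax(lls))
    lambda_hat = float(np.clip(candidates[j], 0.0, 1.0))
    logL = float(lls[j])

    logL0 = float(ll_grid[0])
    logL1 = float(ll_grid[-1])
    _, sigma2_hat, root_hat = gls_loglik(
        yv, pagel_transform(cov, lambda_hat).matrix)

    def _lrt(l_null: float) -> float:
        D = max(0.0, 2.0 * (logL - l_null))
        return float(stats.chi2.sf(D, df=1))

    return LambdaFit(
        lambda_hat=lambda_hat,
        sigma2_hat=float(sigma2_hat),
        root_hat=float(root_hat),
        logL=logL,
        logL_at_0=logL0,
        logL_at_1=logL1,
        p_vs_random=_lrt(logL0),
        p_vs_bm=_lrt(logL1),
        species=list(cov.species),
    )


# ---------------------------------------------------------------------------
# Simulation under lambda-transformed Brownian motion
# ---------------------------------------------------------------------------

def simulate_bm_lambda(tree_or_cov, lam: float, sigma2: float, root: float,
                       n_reps: int, seed=None) -> tuple[np.ndarray, list[str]]:
    """Draw trait vectors under the lambda-BM model.

    Rows of the returned ``(n_reps, n_species)`` matrix are multivariate
    normal with mean ``root`` and covariance
    ``sigma2 * pagel_transform(vcv(tree), lam)``.  ``seed`` may be an
    int or a ``numpy.random.Generator``.  Returns the matrix and the
    species order of its columns.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    if sigma2 < 0.0:
        raise ValueError(f"sigma2 must be >= 0, got {sigma2}")
    cov = tree_or_cov if isinstance(tree_or_cov, PhyloCovariance) else vcv(tree_or_cov)
    V = sigma2 * pagel_transform(cov, lam).matrix
    n = cov.n
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if sigma2 == 0.0:
        return np.full((n_reps, n), float(root)), list(cov.species)
    ridge = RIDGE * max(float(np.mean(np.diag(V))), 1e-300)
    L = np.linalg.cholesky(V + ridge * np.eye(n))
    Z = rng.standard_normal((n_reps, n))
    return root + Z @ L.T, list(cov.species)
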