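"""Statistical coupling analysis: conservation, coupling matrix, spectrum, sectors.

Normative formulas (per position i, amino acid a, background q):

* regularized frequencies     f_i^a   = (1-lam) f_raw + lam q^a
                              f_ij^ab = (1-lam) f_raw + lam q^a q^b   (i != j)
                              f_ii^ab = f_i^a * delta(a=b)
* binary relative entropy     D_i^a = f ln(f/q) + (1-f) ln((1-f)/(1-q))
* conservation weight         phi_i^a = | ln[ f_i^a (1-q^a) / (q^a (1-f_i^a)) ] |
* weighted coupling tensor    Ct_ij^ab = phi_i^a phi_j^b (f_ij^ab - f_i^a f_j^b)
* Frobenius reduction         Ct_ij = sqrt( sum_ab (Ct_ij^ab)^2 )

Eigenvalue significance is assessed against a null in which residues are
independently permuted within every column (inter-column correlation is
destroyed while per-column composition is preserved); ``k_star`` counts true
eigenvalues exceeding a quantile of the null top-eigenvalue distribution.
The significant eigenvectors are rotated by fixed-point ICA and thresholded
into sectors.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.stats
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .alignment import Alignment
from .background import AA_INDEX, BACKGROUND_FREQS, N_AA, SECTOR_PALETTE, validate_background

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# encoding
# ---------------------------------------------------------------------------

def encode_alignment(aln: Alignment) -> np.ndarray:
    """Integer-encode an alignment: M x L, values in 0..19, -1 for gap.

    Non-standard residues ('X', 'B', 'Z', ...) count as gaps for frequency
    estimation; they are preserved in the alignment object itself.
    """
    X = np.full((aln.M, aln.L), -1, dtype=np.int8)
    for m, rec in enumerate(aln.records):
        for i, c in enumerate(rec.residues):
            X[m, i] = AA_INDEX.get(c, -1)
    return X


def _one_hot_sparse(X: np.ndarray) -> sp.csr_matrix:
    """Binary one-hot of the encoded alignment, shape M x (L*20)."""
    M, L = X.shape
    rows, cols = np.nonzero(X >= 0)
    flat = cols * N_AA + X[rows, cols]
    data = np.ones(len(rows), dtype=np.float64)
    return sp.csr_matrix((data, (rows, flat)), shape=(M, L * N_AA))


# ---------------------------------------------------------------------------
# frequencies
# ---------------------------------------------------------------------------

@dataclass
class FrequencyModel:
    """Regularized single and pairwise amino-acid frequencies.

    ``f1`` is L x 20; ``f2`` is an (L, 20, L, 20) view of the flat
    (L*20, L*20) pairwise matrix, so ``f2[i, a, j, b]`` is f_ij^ab.
    """

    f1: np.ndarray
    f2_flat: np.ndarray
    q: np.ndarray
    lam: float
    M: int

    @property
    def L(self) -> int:
        return self.f1.shape[0]

    @property
    def f2(self) -> np.ndarray:
        L = self.L
        return self.f2_flat.reshape(L, N_AA, L, N_AA)


def compute_frequencies(
    aln: Alignment | np.ndarray,
    q: np.ndarray | None = None,
    lam: float = 0.03,
) -> FrequencyModel:
    """Estimate regularized single and pairwise frequencies.

    ``aln`` may be an :class:`Alignment` or an already-encoded integer
    matrix. Raw frequencies are counts divided by M with gaps excluded from
    the numerator only (gap mass is lost and compensated by the ``lam``
    mixture toward the background ``q``). Diagonal blocks are reset to
    ``f_i^a * delta(a=b)`` after regularization.
    """
    X = aln if isinstance(aln, np.ndarray) else encode_alignment(aln)
    M, L = X.shape
    if not 0 <= lam < 1:
        raise ValueError(f"lambda must be in [0, 1), got {lam}")
    q = BACKGROUND_FREQS if q is None else validate_background(q)
    if np.any((X < 0).all(axis=0)):
        bad = int(np.flatnonzero((X < 0).all(axis=0))[0]) + 1
        raise ValueError(
            f"column {bad} is entirely gaps/non-standard; drop gapped columns first"
        )
    Xs = _one_hot_sparse(X)
    f1_raw = np.asarray(Xs.sum(axis=0)).ravel().reshape(L, N_AA) / M
    f1 = (1.0 - lam) * f1_raw + lam * q

    f2_raw = np.asarray((Xs.T @ Xs).todense()) / M
    q_flat = np.tile(q, L)
    f2 = (1.0 - lam) * f2_raw + lam * np.outer(q_flat, q_flat)
    # diagonal blocks carry no pair information: f_ii^ab = f_i^a delta(a=b)
    for i in range(L):
        block = slice(i * N_AA, (i + 1) * N_AA)
        f2[block, block] = np.diag(f1[i])
    return FrequencyModel(f1=f1, f2_flat=f2, q=q, lam=lam, M=M)


# ---------------------------------------------------------------------------
# conservation and weights
# ---------------------------------------------------------------------------

def binary_relative_entropy(f: np.ndarray | float, q: np.ndarray | float) -> np.ndarray | float:
    """D(f || q) for a binary split {a, not-a}, in nats."""
    f = np.asarray(f, dtype=float)
    q = np.asarray(q, dtype=float)
    if np.any(f <= 0) or np.any(f >= 1) or np.any(q <= 0) or np.any(q >= 1):
        raise ValueError(
            "frequencies must lie strictly in (0, 1); use a positive "
            "regularization lambda and a strictly positive background"
        )
    out = f * np.log(f / q) + (1.0 - f) * np.log((1.0 - f) / (1.0 - q))
    return out if out.ndim else float(out)


def weight_gradient(f: np.ndarray | float, q: np.ndarray | float) -> np.ndarray | float:
    """Conservation gradient weight |ln[f(1-q) / (q(1-f))]|."""
    f = np.asarray(f, dtype=float)
    q = np.asarray(q, dtype=float)
    if np.any(f <= 0) or np.any(f >= 1) or np.any(q <= 0) or np.any(q >= 1):
        raise ValueError(
            "frequencies must lie strictly in (0, 1); use a positive "
            "regularization lambda and a strictly positive background"
        )
    out = np.abs(np.log(f * (1.0 - q) / (q * (1.0 - f))))
    return out if out.ndim else float(out)


@dataclass
class ConservationProfile:
    """Per-position conservation: D_ia (L x 20) and the KL summary D_i (L,)."""

    D_ia: np.ndarray
    D_i: np.ndarray


def positional_conservation(fm: FrequencyModel) -> ConservationProfile:
    """Binary relative entropy per (position, amino acid), plus a full
    Kullback-Leibler per-position summary D_i = sum_a f ln(f/q)."""
    D_ia = binary_relative_entropy(fm.f1, fm.q[None, :])
    D_i = np.sum(fm.f1 * np.log(fm.f1 / fm.q[None, :]), axis=1)
    return ConservationProfile(D_ia=np.asarray(D_ia), D_i=D_i)


def weighting_phi(fm: FrequencyModel) -> np.ndarray:
    """L x 20 matrix of conservation gradient weights."""
    return np.asarray(weight_gradient(fm.f1, fm.q[None, :]))


# ---------------------------------------------------------------------------
# coupling matrix
# ---------------------------------------------------------------------------

@dataclass
class CouplingMatrix:
    """The positional coupling matrix and its (optional) decompositions."""

    Ctilde: np.ndarray
    eigenvalues: np.ndarray | None = None
    eigenvectors: np.ndarray | None = None
    random_spectra: np.ndarray | None = None
    null_quantile: float | None = None
    k_star: int | None = None
    ica_start: int = 0
    ic_loadings: np.ndarray | None = None
    ic_eigenvalues: np.ndarray | None = None

    @property
    def L(self) -> int:
        return self.Ctilde.shape[0]


def _phi_clamped(fm: FrequencyModel, eps: float = 1e-12) -> np.ndarray:
    """phi with frequencies clamped away from {0, 1}.

    Lets the coupling tensor stay defined at lam=0, where unobserved residues
    have f=0 but also exactly zero covariance (0 * large-weight = 0).
    """
    f = np.clip(fm.f1, eps, 1.0 - eps)
    return np.abs(np.log(f * (1.0 - fm.q[None, :]) / (fm.q[None, :] * (1.0 - f))))


def coupling_tensor(fm: FrequencyModel) -> np.ndarray:
    """Full weighted coupling tensor, shape (L, 20, L, 20). O(L^2*400) memory."""
    phi_flat = _phi_clamped(fm).ravel()
    cov = fm.f2_flat - np.outer(fm.f1.ravel(), fm.f1.ravel())
    L = fm.L
    return (np.outer(phi_flat, phi_flat) * cov).reshape(L, N_AA, L, N_AA)


def coupling_matrix(fm: FrequencyModel) -> CouplingMatrix:
    """Frobenius reduction of the weighted coupling tensor to an L x L matrix."""
    phi_flat = _phi_clamped(fm).ravel()
    C = np.outer(phi_flat, phi_flat) * (
        fm.f2_flat - np.outer(fm.f1.ravel(), fm.f1.ravel())
    )
    np.square(C, out=C)
    L = fm.L
    Ct = np.sqrt(C.reshape(L, N_AA, L, N_AA).sum(axis=(1, 3)))
    Ct = 0.5 * (Ct + Ct.T)  # enforce exact symmetry against round-off
    return CouplingMatrix(Ctilde=Ct)


def sequence_correlation(aln: Alignment | np.ndarray) -> np.ndarray:
    """M x M fraction-identical similarity matrix (diagnostic only).

    Sector definition uses the positional matrix; this sequence-space view is
    exported for inspection of family structure.
    """
    X = aln if isinstance(aln, np.ndarray) else encode_alignment(aln)
    Xs = _one_hot_sparse(X)
    L = X.shape[1]
    return np.asarray((Xs @ Xs.T).todense()) / L


def _ctilde_from_encoded(X: np.ndarray, q: np.ndarray, lam: float) -> np.ndarray:
    fm = compute_frequencies(X, q=q, lam=lam)
    return coupling_matrix(fm).Ctilde


def shuffle_within_columns(X: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Independently permute the entries of every column (composition-preserving)."""
    Xp = np.empty_like(X)
    M = X.shape[0]
    for i in range(X.shape[1]):
        Xp[:, i] = X[rng.permutation(M), i]
    return Xp


def spectral_significance(
    cm: CouplingMatrix,
    aln: Alignment | np.ndarray,
    n_rand: int = 100,
    percentile: float = 0.95,
    seed: int | None = None,
    lam: float = 0.03,
    q: np.ndarray | None = None,
    exclude_top: bool = False,
) -> CouplingMatrix:
    """Eigendecompose ``Ctilde`` and count significant eigenvalues.

    For each of ``n_rand`` trials the alignment's residues are permuted
    within every column and the full coupling pipeline is re-run; ``k_star``
    is the number of true eigenvalues significantly exceeding the null
    top-eigenvalue distribution, judged by the standard permutation-test
    p-value ``(1 + #{null >= observed}) / (1 + n_rand) <= 1 - percentile``.
    The ``percentile`` quantile of the null tops is stored as
    ``null_quantile`` for reporting.

    ``exclude_top=True`` additionally discards the largest true eigenvalue
    (and its eigenvector) before counting, for families in which the top
    mode reflects overall conservation/phylogeny rather than a coupled group.
    The default keeps it: on data without a global correlated mode the top
    eigenvector is itself a coupled group and discarding it loses a sector.
    """
    if n_rand > 0 and seed is None:
        raise ValueError("a seed is required when n_rand > 0 (reproducibility contract)")
    if 0 < n_rand < 10:
        raise ValueError(f"n_rand must be 0 or >= 10, got {n_rand}")
    if n_rand > 0 and 1.0 / (1 + n_rand) > 1.0 - percentile:
        warnings.warn(
            f"n_rand={n_rand} cannot reach significance at percentile={percentile} "
            f"(minimum permutation p-value is 1/{1 + n_rand}); k_star will be 0"
        )
    X = aln if isinstance(aln, np.ndarray) else encode_alignment(aln)
    q = BACKGROUND_FREQS if q is None else validate_background(q)

    evals, evecs = np.linalg.eigh(cm.Ctilde)
    order = np.argsort(evals)[::-1]
    cm.eigenvalues = evals[order]
    cm.eigenvectors = evecs[:, order]

    rng = np.random.default_rng(seed)
    L = cm.L
    spectra = np.empty((n_rand, L))
    for t in range(n_rand):
        Xp = shuffle_within_columns(X, rng)
        null_evals = np.linalg.eigvalsh(_ctilde_from_encoded(Xp, q, lam))
        spectra[t] = null_evals[::-1]
    cm.random_spectra = spectra
    cm.ica_start = 1 if exclude_top else 0
    if n_rand > 0:
        tops = spectra[:, 0]
        cm.null_quantile = float(np.quantile(tops, percentile))
        considered = cm.eigenvalues[cm.ica_start:]
        # standard permutation-test convention: p = (1 + #{null >= obs}) / (1 + n)
        pvals = (1 + np.sum(tops[None, :] >= considered[:, None], axis=1)) / (1 + n_rand)
        cm.k_star = int(np.sum(pvals <= 1.0 - percentile))
    else:
        cm.null_quantile = None
        cm.k_star = 0
    return cm


# ---------------------------------------------------------------------------
# independent components and sectors
# ---------------------------------------------------------------------------

def independent_components(
    cm: CouplingMatrix,
    seed: int | None = None,
    max_iter: int = 1000,
    tol: float = 1e-8,
) -> CouplingMatrix:
    """Rotate the significant eigenvectors toward independent axes.

    Fixed-point ICA with a tanh (log-cosh) contrast, deterministic given
    ``seed``. Components are oriented so the largest-magnitude loading is
    positive and ordered by their associated eigenvalue. On non-convergence
    the unrotated eigenvectors are returned with a logged warning.
    """
    if cm.k_star is None:
        raise ValueError("run spectral_significance first")
    if cm.k_star < 1:
        raise ValueError("k_star < 1: no significant eigenvalues to rotate")
    k = cm.k_star
    start = cm.ica_start
    V = cm.eigenvectors[:, start:start + k]
    evals = cm.eigenvalues[start:start + k]
    L = V.shape[0]

    if k == 1:
        S = V.copy()
    else:
        ica = FastICA(
            n_components=k,
            algorithm="parallel",
            whiten=False,
            fun="logcosh",
            max_iter=max_iter,
            tol=tol,
            random_state=seed,
        )
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            S = ica.fit_transform(V * np.sqrt(L))
        if any(issubclass(w.category, ConvergenceWarning) for w in caught):
            logger.warning("ICA did not converge in %d iterations; using unrotated eigenvectors", max_iter)
            S = V.copy()
        else:
            S = S / np.sqrt(L)
            # associate each component with the eigenmode it overlaps most
            overlap = np.abs(S.T @ V)  # k x k
            assigned: list[int] = []
            for j in range(k):  # eigen order
                cand = np.argsort(overlap[:, j])[::-1]
                comp = next(c for c in cand if c not in assigned)
                assigned.append(int(comp))
            S = S[:, assigned]

    # unit columns, oriented so the largest-|loading| entry is positive
    S = S / np.linalg.norm(S, axis=0, keepdims=True)
    for j in range(S.shape[1]):
        if S[np.argmax(np.abs(S[:, j])), j] < 0:
            S[:, j] = -S[:, j]
    cm.ic_loadings = S
    cm.ic_eigenvalues = evals
    return cm


@dataclass
class Sector:
    """One sector: palette label, member columns (1-based), member loadings."""

    label: str
    columns: list[int]
    loadings: dict[int, float]
    cutoff: float


@dataclass
class SectorAssignment:
    """Disjoint ordered sectors over alignment columns; the rest unassigned."""

    sectors: list[Sector]
    unassigned: list[int]
    L: int = 0

    def label_by_column(self) -> dict[int, str]:
        return {c: s.label for s in self.sectors for c in s.columns}

    def ordinal_by_column(self) -> dict[int, int]:
        return {c: i + 1 for i, s in enumerate(self.sectors) for c in s.columns}


def _loading_cutoff(x: np.ndarray, quantile: float, method: str) -> float:
    if method == "empirical":
        return float(np.quantile(x, quantile))
    if method != "fitted":
        raise ValueError(f"unknown cutoff method {method!r} (use 'fitted' or 'empirical')")
    # heavy-tailed location-scale t fit: the bulk of loadings is near zero,
    # so the fitted quantile separates the sector tail from the background
    try:
        df, loc, scale = scipy.stats.t.fit(x)
        cutoff = float(scipy.stats.t.ppf(quantile, df, loc=loc, scale=scale))
        if not np.isfinite(cutoff):
            raise ValueError("non-finite fitted cutoff")
        return cutoff
    except Exception:  # fit failure on degenerate inputs
        logger.warning("t-distribution fit failed; falling back to empirical quantile")
        return float(np.quantile(x, quantile))


def define_sectors(
    cm: CouplingMatrix,
    cutoff_quantile: float = 0.95,
    cutoff_method: str = "fitted",
    dominance_ratio: float = 2.0,
) -> SectorAssignment:
    """Threshold independent-component loadings into disjoint sectors.

    For each component a cutoff is placed at ``cutoff_quantile`` of a
    t-distribution fitted to that component's loadings (``cutoff_method=
    'empirical'`` uses the raw empirical quantile instead). Positions above
    the cutoff on at least one component are assigned to the component where
    their loading is maximal; sectors take palette labels in component order
    (red, blue, green, ...).

    A member must load *dominantly* on its component: its best loading must
    be at least ``dominance_ratio`` times its second-best (in magnitude).
    Conserved-but-uncoupled positions pick up small, roughly equal loadings
    on every component through their amplified sampling noise; the dominance
    requirement keeps them out of sectors. Set ``dominance_ratio=1`` (or
    ``0``) to disable.
    """
    if cm.k_star == 0 or cm.ic_loadings is None:
        if cm.ic_loadings is None and (cm.k_star or 0) > 0:
            raise ValueError("run independent_components first")
        return SectorAssignment(sectors=[], unassigned=list(range(1, cm.L + 1)), L=cm.L)
    S = cm.ic_loadings
    L, k = S.shape
    cutoffs = [_loading_cutoff(S[:, j], cutoff_quantile, cutoff_method) for j in range(k)]
    members: list[list[int]] = [[] for _ in range(k)]
    loadings: list[dict[int, float]] = [{} for _ in range(k)]
    unassigned: list[int] = []
    for pos in range(L):
        above = [j for j in range(k) if S[pos, j] > cutoffs[j]]
        if not above:
            unassigned.append(pos + 1)
            continue
        j = max(above, key=lambda jj: S[pos, jj])
        if k > 1 and dominance_ratio > 1:
            mags = np.sort(np.abs(S[pos]))[::-1]
            if mags[0] < dominance_ratio * mags[1]:
                unassigned.append(pos + 1)
                continue
        members[j].append(pos + 1)
        loadings[j][pos + 1] = float(S[pos, j])
    sectors = []
    for j in range(k):
        label = SECTOR_PALETTE[j % len(SECTOR_PALETTE)]
        if j >= len(SECTOR_PALETTE):
            label = f"{label}{j // len(SECTOR_PALETTE) + 1}"
        sectors.append(Sector(label=label, columns=members[j], loadings=loadings[j], cutoff=cutoffs[j]))
    return SectorAssignment(sectors=sectors, unassigned=unassigned, L=L)


# ---------------------------------------------------------------------------
# one-call pipeline
# ---------------------------------------------------------------------------

def run_sca(
    aln: Alignment,
    seed: int,
    q: np.ndarray | None = None,
    lam: float = 0.03,
    n_rand: int = 100,
    percentile: float = 0.95,
    cutoff_quantile: float = 0.95,
    cutoff_method: str = "fitted",
    dominance_ratio: float = 2.0,
    exclude_top: bool = False,
) -> tuple[FrequencyModel, CouplingMatrix, SectorAssignment]:
    """Frequencies -> coupling matrix -> significance -> ICA -> sectors."""
    fm = compute_frequencies(aln, q=q, lam=lam)
    cm = coupling_matrix(fm)
    spectral_significance(
        cm, aln, n_rand=n_rand, percentile=percentile, seed=seed,
        lam=lam, q=fm.q, exclude_top=exclude_top,
    )
    if cm.k_star and cm.k_star >= 1:
        independent_components(cm, seed=seed)
    assignment = define_sectors(
        cm, cutoff_quantile=cutoff_quantile, cutoff_method=cutoff_method,
        dominance_ratio=dominance_ratio,
    )
    return fm, cm, assignment
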