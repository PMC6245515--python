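"""Direct coupling analysis by pseudo-likelihood maximization.

A trimmed, reweighted alignment is modelled as draws from a pairwise
maximum-entropy (Potts) distribution

    P(A_1..A_L) = (1/Z) exp( sum_{i<j} e_ij(A_i, A_j) + sum_i h_i(A_i) )

over q = 21 states (20 amino acids + gap).  Fitting the full likelihood is
intractable, so the fields h and couplings e are estimated by maximizing the
L2-regularized pseudo-likelihood -- the product over sites of the exact
conditionals P(A_i | A_{-i}) -- with L-BFGS, which is the standard plmDCA
estimator.  Pairs are then ranked by direct information (DI): the mutual
information of the two-site "direct" distribution built from e_ij alone,
with auxiliary single-site fields chosen so its marginals reproduce the
empirical single-site frequencies.  An APC-corrected Frobenius norm of the
couplings is available as the usual alternative ranking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .msa import Q, Msa, SeqWeights


class ConvergenceError(RuntimeError):
    """Optimizer or fixed-point iteration failed to converge."""


# ---------------------------------------------------------------------------
# Frequencies


@dataclass
class SiteFrequencies:
    """Pseudocount-mixed weighted site and pair frequencies.

    f_i has shape (L, q); f_ij has shape (L, L, q, q) with the convention
    f_ij[i, j, a, b] = weighted frequency of (A_i = a, A_j = b).  Mixing with
    pseudocount lam gives f = (1-lam) f_obs + lam/q (lam/q^2 for pairs), so
    both normalizations are preserved.
    """

    f_i: np.ndarray
    f_ij: np.ndarray
    lam: float
    q: int = Q

    @property
    def L(self) -> int:
        return self.f_i.shape[0]


def site_frequencies(
    msa: Msa, weights: SeqWeights, lam: float = 0.1, q: int = Q
) -> SiteFrequencies:
    """Weighted single-site and pair frequencies with pseudocount ``lam``.

    ``q`` is the alphabet size: 21 for protein alignments (gap included),
    smaller for synthetic reduced-alphabet families.
    """
    if not 0 <= lam < 1:
        raise ValueError("pseudocount must be in [0, 1)")
    arr = msa.to_array()
    if arr.max() >= q:
        raise ValueError(f"alignment uses states outside alphabet of size {q}")
    n, L = arr.shape
    w = np.asarray(weights.weights, dtype=float)
    w = w / w.sum()
    onehot = np.zeros((n, L, q))
    rows = np.arange(n)[:, None]
    cols = np.arange(L)[None, :]
    onehot[rows, cols, arr] = 1.0
    f_i = np.einsum("s,sia->ia", w, onehot)
    f_ij = np.einsum("s,sia,sjb->ijab", w, onehot, onehot)
    f_i = (1 - lam) * f_i + lam / q
    f_ij = (1 - lam) * f_ij + lam / q**2
    # Diagonal blocks are single-site indicators, not free pair statistics.
    for i in range(L):
        f_ij[i, i] = np.diag(f_i[i])
    return SiteFrequencies(f_i=f_i, f_ij=f_ij, lam=lam, q=q)


# ---------------------------------------------------------------------------
# Potts model


def _pair_index(L: int) -> list[tuple[int, int]]:
    return [(i, j) for i in range(L) for j in range(i + 1, L)]


@dataclass
class PottsModel:
    """Fields and couplings of the pairwise maximum-entropy model.

    ``h`` has shape (L, q); ``e`` has shape (n_pairs, q, q) over pairs
    (i, j), i < j, in lexicographic order, with e[p][a, b] the coupling of
    state a at i with state b at j.  ``e_ji(b, a) = e_ij(a, b)`` by the
    symmetric extension.
    """

    h: np.ndarray
    e: np.ndarray
    gauge: str = "zero-sum"
    reg: tuple[float, float] = (0.0, 0.0)

    @property
    def L(self) -> int:
        return self.h.shape[0]

    @property
    def q(self) -> int:
        return self.h.shape[1]

    @property
    def pairs(self) -> list[tuple[int, int]]:
        return _pair_index(self.L)

    def coupling(self, i: int, j: int) -> np.ndarray:
        """e_ij as a (q, q) matrix for any i != j."""
        if i == j:
            raise ValueError("no self-coupling")
        if i < j:
            p = self.pairs.index((i, j))
            return self.e[p]
        p = self.pairs.index((j, i))
        return self.e[p].T

    def save(self, path) -> None:
        np.savez(path, h=self.h, e=self.e, reg=np.asarray(self.reg), gauge=self.gauge)

    @classmethod
    def load(cls, path) -> "PottsModel":
        data = np.load(path, allow_pickle=False)
        return cls(h=data["h"], e=data["e"], gauge=str(data["gauge"]),
                   reg=tuple(data["reg"]))


def to_zero_sum_gauge(h: np.ndarray, e: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Fix the gauge so couplings and fields have zero mean over states.

    The Potts parameterization is redundant; the zero-sum gauge is the
    standard representative: row/column means of every e_ij vanish, the
    removed means being absorbed into the fields, and each h_i is shifted to
    zero mean (an overall constant, absorbed by Z).
    """
    L, q = h.shape
    h = h.copy()
    pairs = _pair_index(L)
    e_zs = np.empty_like(e)
    for p, (i, j) in enumerate(pairs):
        eij = e[p]
        row = eij.mean(axis=1, keepdims=True)   # mean over b, per a
        col = eij.mean(axis=0, keepdims=True)   # mean over a, per b
        tot = eij.mean()
        e_zs[p] = eij - row - col + tot
        h[i] += (row[:, 0] - tot)
        h[j] += (col[0, :] - tot)
    h -= h.mean(axis=1, keepdims=True)
    return h, e_zs


def _plm_objective(x, arr, w, L, q, pairs, lam_h, lam_e):
    """Negative pseudo-log-likelihood (normalized by m_eff) and gradient."""
    n = arr.shape[0]
    n_pairs = len(pairs)
    h = x[: L * q].reshape(L, q)
    e = x[L * q :].reshape(n_pairs, q, q)

    # logits[s, i, a] = h_i(a) + sum_{j != i} e_ij(a, A_j^s)
    logits = np.broadcast_to(h, (n, L, q)).copy()
    for p, (i, j) in enumerate(pairs):
        logits[:, i, :] += e[p][:, arr[:, j]].T
        logits[:, j, :] += e[p][arr[:, i], :]

    m = logits.max(axis=2, keepdims=True)
    ex = np.exp(logits - m)
    zs = ex.sum(axis=2, keepdims=True)
    logz = (m + np.log(zs))[:, :, 0]
    probs = ex / zs                                     # (n, L, q)

    obs = np.take_along_axis(logits, arr[:, :, None].astype(np.intp), axis=2)[:, :, 0]
    nll = -(w[:, None] * (obs - logz)).sum()

    # Gradient: expectation minus observation, per conditional.
    onehot = np.zeros((n, L, q))
    onehot[np.arange(n)[:, None], np.arange(L)[None, :], arr] = 1.0
    diff = w[:, None, None] * (probs - onehot)          # (n, L, q)
    g_h = diff.sum(axis=0)
    g_e = np.empty_like(e)
    for p, (i, j) in enumerate(pairs):
        oh_i, oh_j = onehot[:, i, :], onehot[:, j, :]
        g_e[p] = diff[:, i, :].T @ oh_j + oh_i.T @ diff[:, j, :]

    nll += lam_h * (h**2).sum() + lam_e * (e**2).sum()
    g_h += 2 * lam_h * h
    g_e += 2 * lam_e * e
    return nll, np.concatenate([g_h.ravel(), g_e.ravel()])


def fit_plm(
    msa: Msa,
    weights: SeqWeights,
    reg: tuple[float, float] | None = None,
    max_iter: int = 500,
    tol: float = 1e-9,
    q: int = Q,
) -> PottsModel:
    """Fit the Potts model by L2-regularized pseudo-likelihood maximization.

    Parameters are initialized at zero and optimized with L-BFGS; the result
    is returned in the zero-sum gauge, so repeated fits of the same input are
    identical.  Default regularization is (lam_h, lam_e) = (0.01,
    0.01*(L-1)); the pseudo-likelihood is normalized by m_eff so these
    strengths are comparable across alignment depths.
    """
    arr = msa.to_array().astype(np.intp)
    if arr.max() >= q:
        raise ValueError(f"alignment uses states outside alphabet of size {q}")
    n, L = arr.shape
    if L < 2:
        raise ValueError("need at least two columns to fit couplings")
    w = np.asarray(weights.weights, dtype=float)
    w = w / w.sum()
    lam_h, lam_e = reg if reg is not None else (0.01, 0.01 * (L - 1))
    pairs = _pair_index(L)
    x0 = np.zeros(L * q + len(pairs) * q * q)

    res = minimize(
        _plm_objective,
        x0,
        args=(arr, w, L, q, pairs, lam_h, lam_e),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-6},
    )
    gnorm = float(np.abs(res.jac).max())
    if not res.success and gnorm > 1e-3:
        raise ConvergenceError(
            f"pseudo-likelihood optimization did not converge: "
            f"{res.message} (max |grad| = {gnorm:.2e})"
        )
    h = res.x[: L * q].reshape(L, q)
    e = res.x[L * q :].reshape(len(pairs), q, q)
    h, e = to_zero_sum_gauge(h, e)
    return PottsModel(h=h, e=e, gauge="zero-sum", reg=(lam_h, lam_e))


# ---------------------------------------------------------------------------
# Direct information


@dataclass
class DiMatrix:
    """Symmetric non-negative pair-score matrix with zero diagonal."""

    di: np.ndarray

    @property
    def L(self) -> int:
        return self.di.shape[0]


def _direct_distribution(
    eij: np.ndarray, fi: np.ndarray, fj: np.ndarray, tol: float = 1e-6, max_iter: int = 500
) -> np.ndarray:
    """Two-site direct distribution P ~ exp(e_ij) with matched marginals.

    Auxiliary fields are found by iterative proportional fitting (Sinkhorn in
    the probability domain): alternately rescale rows and columns of
    exp(e_ij) until the marginals match f_i and f_j.
    """
    W = np.exp(eij - eij.max())
    u = np.ones(W.shape[0])
    v = np.ones(W.shape[1])
    for _ in range(max_iter):
        u_new = fi / (W @ v)
        v_new = fj / (W.T @ u_new)
        P = (u_new[:, None] * W) * v_new[None, :]
        P /= P.sum()
        if (
            np.abs(P.sum(axis=1) - fi).max() < tol
            and np.abs(P.sum(axis=0) - fj).max() < tol
        ):
            return P
        u, v = u_new, v_new
    raise ConvergenceError("marginal-matching fixed point did not converge")


def direct_information(model: PottsModel, freqs: SiteFrequencies) -> DiMatrix:
    """Direct information for every pair.

    DI_ij = sum_{a,b} P^dir_ij(a,b) ln( P^dir_ij(a,b) / (f_i(a) f_j(b)) ),
    the KL divergence of the coupling-only two-site distribution from the
    factorized background; it is zero iff e_ij carries no direct coupling,
    and is invariant under gauge changes of the model.
    """
    if model.L != freqs.L or model.q != freqs.q:
        raise ValueError("model and frequencies have mismatched dimensions")
    L = model.L
    di = np.zeros((L, L))
    for p, (i, j) in enumerate(model.pairs):
        fi, fj = freqs.f_i[i], freqs.f_i[j]
        try:
            P = _direct_distribution(model.e[p], fi, fj)
        except ConvergenceError as exc:
            raise ConvergenceError(f"pair ({i}, {j}): {exc}") from exc
        ref = np.outer(fi, fj)
        mask = P > 0
        val = float((P[mask] * np.log(P[mask] / ref[mask])).sum())
        di[i, j] = di[j, i] = max(val, 0.0)
    return DiMatrix(di=di)


def apc_frobenius(model: PottsModel) -> DiMatrix:
    """Average-product-corrected Frobenius norm of the zero-sum couplings.

    The usual alternative contact score: F_ij = ||e_ij||_F over the 20 amino
    acid states (gap excluded), corrected by F_i. F_.j / F.. to remove
    phylogenetic/entropic background.
    """
    h, e = to_zero_sum_gauge(model.h, model.e)
    L = model.L
    # Gap state excluded from the norm only for the full protein alphabet.
    qe = model.q - 1 if model.q == Q else model.q
    F = np.zeros((L, L))
    for p, (i, j) in enumerate(model.pairs):
        F[i, j] = F[j, i] = np.linalg.norm(e[p][:qe, :qe])
    mean_i = F.sum(axis=1) / (L - 1)
    mean_all = F.sum() / (L * (L - 1))
    apc = np.outer(mean_i, mean_i) / mean_all
    out = F - apc
    np.fill_diagonal(out, 0.0)
    return DiMatrix(di=out)


# ---------------------------------------------------------------------------
# Contact ranking and I/O


@dataclass
class ContactSet:
    """Ranked residue pairs (i < j, score), descending by score."""

    pairs: list[tuple[int, int, float]]
    min_separation: int

    def __len__(self) -> int:
        return len(self.pairs)

    def indices(self) -> list[tuple[int, int]]:
        return [(i, j) for i, j, _ in self.pairs]


def rank_contacts(
    di: DiMatrix, L: int | None = None, min_separation: int = 5, k: int | None = None
) -> ContactSet:
    """Select the top-k pairs by score among pairs separated by at least
    ``min_separation`` in sequence.

    ``k`` defaults to 2L — the contact budget handed to the folding stage.
    Ties are broken by ascending (i, j) so the ranking is deterministic.
    """
    if min_separation < 1:
        raise ValueError("min_separation must be >= 1")
    L = L if L is not None else di.L
    if k is None:
        k = 2 * L
    cand = [
        (i, j, float(di.di[i, j]))
        for i in range(di.L)
        for j in range(i + min_separation, di.L)
    ]
    cand.sort(key=lambda t: (-t[2], t[0], t[1]))
    if len(cand) < k:
        warnings.warn(
            f"only {len(cand)} eligible pairs available (requested {k})",
            stacklevel=2,
        )
    return ContactSet(pairs=cand[:k], min_separation=min_separation)


def write_contacts(
    contacts: ContactSet, path, d_low: float = 0.0, d_high: float = 7.5
) -> None:
    """Write contacts as CASP RR-style lines ``i j d_low d_high score`` (1-based)."""
    with open(path, "w") as fh:
        fh.write("PFRMAT RR\n")
        for i, j, score in contacts.pairs:
            if i >= j:
                raise ValueError(f"invalid pair ordering ({i}, {j})")
            fh.write(f"{i + 1} {j + 1} {d_low:g} {d_high:g} {score:.6f}\n")


def read_contacts(path, min_separation: int = 1) -> ContactSet:
    """Read an RR-style contact file written by :func:`write_contacts`."""
    pairs = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts or not parts[0].lstrip("-").isdigit():
                continue
            i, j = int(parts[0]) - 1, int(parts[1]) - 1
            score = float(parts[4]) if len(parts) > 4 else 1.0
            pairs.append((i, j, score))
    return ContactSet(pairs=pairs, min_separation=min_separation)


def write_di_tsv(di: DiMatrix, path) -> None:
    """Upper-triangle DI scores as TSV (i, j, score; 0-based)."""
    with open(path, "w") as fh:
        fh.write("i\tj\tscore\n")
        for i in range(di.L):
            for j in range(i + 1, di.L):
                fh.write(f"{i}\t{j}\t{di.di[i, j]:.6g}\n")
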