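"""Synthetic data generators: planted Potts families, toy folds, feature
tables and mock trajectories.

Every pipeline stage can be exercised without external data.  Alignments are
sampled from Potts models with known planted couplings (exact enumeration
for tiny systems — the brute-force oracle — and Gibbs sampling otherwise);
folds are idealized hairpins and helix bundles built from canonical
secondary-structure torsions, with native contacts recomputed from their own
coordinates; feature tables either are pure noise or deterministically encode
the torsions they should predict; mock trajectories are seeded perturbations
of a base fold.  All generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .cg_sampler import BackboneConformation, Trajectory
from .msa import AMINO_ACIDS, Msa

#: Exact enumeration is used when the state space q**L is at most this size.
ENUMERATION_LIMIT = 2**21


# ---------------------------------------------------------------------------
# Planted Potts families


@dataclass
class PlantedPotts:
    """A Potts model with known coupled pairs, for oracle tests.

    Planted pairs (i, j, strength) receive the zero-sum ferromagnetic
    coupling e_ij(a, b) = strength * (delta_ab - 1/q); all other pairs are
    uncoupled.  ``fields`` (L, q) defaults to zero.
    """

    L: int
    q: int
    planted_pairs: list[tuple[int, int, float]]
    fields: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fields is None:
            self.fields = np.zeros((self.L, self.q))
        self.fields = np.asarray(self.fields, dtype=float)
        for i, j, s in self.planted_pairs:
            if not (0 <= i < j < self.L):
                raise ValueError(f"bad planted pair ({i}, {j})")
            if abs(i - j) < 2:
                raise ValueError("planted pairs must have |i-j| >= 2")
            if s <= 0:
                raise ValueError("coupling strength must be positive")

    def coupling_tensor(self) -> np.ndarray:
        """Full (L, L, q, q) coupling tensor (symmetric, zero diagonal)."""
        e = np.zeros((self.L, self.L, self.q, self.q))
        base = np.eye(self.q) - 1.0 / self.q
        for i, j, s in self.planted_pairs:
            e[i, j] = s * base
            e[j, i] = s * base.T
        return e

    def planted_indices(self) -> set[tuple[int, int]]:
        return {(i, j) for i, j, _ in self.planted_pairs}


def _enumerate_states(L: int, q: int) -> np.ndarray:
    """All q**L state vectors, shape (q**L, L)."""
    grids = np.unravel_index(np.arange(q**L), (q,) * L)
    return np.stack(grids, axis=1).astype(np.int64)


def potts_log_weights(model: PlantedPotts, states: np.ndarray) -> np.ndarray:
    """Unnormalized log-probability of each state row."""
    h = model.fields
    e = model.coupling_tensor()
    lw = h[np.arange(model.L)[None, :], states].sum(axis=1)
    for i, j, _ in model.planted_pairs:
        lw = lw + e[i, j][states[:, i], states[:, j]]
    return lw


@njit(cache=True)
def _gibbs_sample(h, e_full, n_samples, burn_in, thin, seed):
    np.random.seed(seed)
    L, q = h.shape
    state = np.empty(L, dtype=np.int64)
    for i in range(L):
        state[i] = np.random.randint(0, q)
    out = np.empty((n_samples, L), dtype=np.int64)
    total_sweeps = burn_in + n_samples * thin
    k = 0
    for sweep in range(total_sweeps):
        for i in range(L):
            logits = h[i].copy()
            for j in range(L):
                if j != i:
                    for a in range(q):
                        logits[a] += e_full[i, j, a, state[j]]
            m = logits.max()
            p = np.exp(logits - m)
            p /= p.sum()
            u = np.random.random()
            acc = 0.0
            choice = q - 1
            for a in range(q):
                acc += p[a]
                if u < acc:
                    choice = a
                    break
            state[i] = choice
        if sweep >= burn_in and (sweep - burn_in) % thin == 0:
            if k < n_samples:
                out[k] = state
                k += 1
    return out


def sample_potts_msa(model: PlantedPotts, n: int, seed: int = 0,
                     burn_in: int = 200, thin: int = 5) -> Msa:
    """Draw ``n`` aligned sequences from the planted Potts distribution.

    Tiny systems (q**L below :data:`ENUMERATION_LIMIT`) are sampled exactly
    by enumerating the state space; larger ones use seeded Gibbs sampling
    with burn-in and thinning.  States map onto the first q amino-acid
    letters, so the output is a gap-free :class:`~defold.msa.Msa`.
    """
    if n < 1:
        raise ValueError("need at least one sequence")
    rng = np.random.default_rng(seed)
    if model.q**model.L <= ENUMERATION_LIMIT:
        states = _enumerate_states(model.L, model.q)
        lw = potts_log_weights(model, states)
        p = np.exp(lw - lw.max())
        p /= p.sum()
        idx = rng.choice(states.shape[0], size=n, p=p)
        samples = states[idx]
    else:
        samples = _gibbs_sample(
            model.fields, model.coupling_tensor(), n, burn_in, thin,
            int(rng.integers(2**31 - 1)),
        )
    letters = AMINO_ACIDS[: model.q]
    seqs = ["".join(letters[a] for a in row) for row in samples]
    return Msa(sequences=seqs, query_index=0)


def mutual_information(msa: Msa, i: int, j: int) -> float:
    """Empirical MI of two columns (natural log), a model-free coupling probe."""
    arr = msa.to_array()
    a, b = arr[:, i], arr[:, j]
    n = arr.shape[0]
    mi = 0.0
    for x in np.unique(a):
        for y in np.unique(b):
            pxy = ((a == x) & (b == y)).sum() / n
            if pxy > 0:
                px = (a == x).sum() / n
                py = (b == y).sum() / n
                mi += pxy * np.log(pxy / (px * py))
    return float(mi)


# ---------------------------------------------------------------------------
# Toy folds


@dataclass
class ToyFold:
    """An idealized fold with known native contacts and torsions."""

    conformation: BackboneConformation
    native_contacts: list[tuple[int, int]] = field(default_factory=list)
    native_phi: np.ndarray | None = None
    native_psi: np.ndarray | None = None

    @property
    def L(self) -> int:
        return self.conformation.n_residues


HELIX_PHI, HELIX_PSI = -57.0, -47.0
STRAND_PHI, STRAND_PSI = -120.0, 120.0

_HYDROPHOBIC = "LIVFM"
_POLAR = "STNQK"


def native_contacts_of(conf: BackboneConformation, cutoff: float = 7.5,
                       min_separation: int = 3) -> list[tuple[int, int]]:
    """Pairs with CB-CB distance at or below ``cutoff``, |i-j| >= min_separation."""
    CB = conf.coords["CB"]
    L = conf.n_residues
    out = []
    for i in range(L):
        for j in range(i + min_separation, L):
            if np.linalg.norm(CB[i] - CB[j]) <= cutoff:
                out.append((i, j))
    return out


def make_toy_fold(kind: str, L: int = 16, seed: int = 0) -> ToyFold:
    """Deterministic idealized fold: ``hairpin`` or ``helix-bundle``.

    The hairpin is two extended strands joined by a tight two-residue turn;
    the helix bundle is two canonical alpha helices joined by a loop.  Native
    contacts and torsions are recomputed from the built coordinates, so they
    are self-consistent by construction.  ``seed`` only sets the (irrelevant
    for geometry) alternating hydrophobic/polar sequence phase.
    """
    if L < 8:
        raise ValueError("toy folds need at least 8 residues")
    rng = np.random.default_rng(seed)
    phase = int(rng.integers(2))
    seq = "".join(
        _HYDROPHOBIC[(i + phase) % len(_HYDROPHOBIC)] if i % 2 == 0
        else _POLAR[(i + phase) % len(_POLAR)]
        for i in range(L)
    )
    phi = np.full(L, STRAND_PHI)
    psi = np.full(L, STRAND_PSI)
    if kind == "hairpin":
        mid = L // 2
        # Type I'-like two-residue turn between the strands.
        phi[mid - 1], psi[mid - 1] = 60.0, 30.0
        phi[mid], psi[mid] = 90.0, 0.0
    elif kind == "helix-bundle":
        phi[:] = HELIX_PHI
        psi[:] = HELIX_PSI
        mid = L // 2
        for k, (p, s) in enumerate([(-120.0, 120.0), (60.0, 30.0), (-90.0, 0.0)]):
            if mid - 1 + k < L:
                phi[mid - 1 + k], psi[mid - 1 + k] = p, s
    else:
        raise ValueError(f"unknown toy fold kind: {kind!r}")
    conf = BackboneConformation(seq, phi, psi)
    m_phi, m_psi = conf.measured_torsions()
    return ToyFold(
        conformation=conf,
        native_contacts=native_contacts_of(conf),
        native_phi=np.where(np.isnan(m_phi), phi, m_phi),
        native_psi=np.where(np.isnan(m_psi), psi, m_psi),
    )


# ---------------------------------------------------------------------------
# Feature tables


def make_feature_table(L: int, rule: str = "random", seed: int = 0):
    """Per-residue feature table, shape (L, 24), values in [0, 1].

    ``random``: uniform noise.  ``angle-linked``: columns 0-3 encode
    (sin, cos) of target (phi, psi) mapped to [0, 1], the rest is noise, so a
    torsion predictor can recover the targets from features alone; returns
    ``(table, phi, psi)`` in that case.
    """
    rng = np.random.default_rng(seed)
    table = rng.uniform(size=(L, 24))
    if rule == "random":
        return table
    if rule == "angle-linked":
        phi = rng.uniform(-179.0, 180.0, size=L)
        psi = rng.uniform(-179.0, 180.0, size=L)
        rad_phi, rad_psi = np.deg2rad(phi), np.deg2rad(psi)
        table[:, 0] = (np.sin(rad_phi) + 1) / 2
        table[:, 1] = (np.cos(rad_phi) + 1) / 2
        table[:, 2] = (np.sin(rad_psi) + 1) / 2
        table[:, 3] = (np.cos(rad_psi) + 1) / 2
        return table, phi, psi
    raise ValueError(f"unknown feature rule: {rule!r}")


# ---------------------------------------------------------------------------
# Mock trajectories


def make_mock_trajectories(
    n_traj: int,
    n_frames: int,
    base: ToyFold,
    noise: float = 5.0,
    seed: int = 0,
) -> list[Trajectory]:
    """Seeded torsion-noise perturbations of a base fold.

    Every frame is the base fold with iid Gaussian torsion noise (degrees),
    letting the pooling/clustering stage be tested without running the
    sampler.  ``noise=0`` reproduces the base fold exactly in every frame.
    """
    if n_frames < 1:
        raise ValueError("need at least one frame")
    rng = np.random.default_rng(seed)
    conf = base.conformation
    out = []
    for t in range(n_traj):
        frames = []
        for _ in range(n_frames):
            dphi = rng.normal(0.0, noise, size=conf.n_residues) if noise else 0.0
            dpsi = rng.normal(0.0, noise, size=conf.n_residues) if noise else 0.0
            frames.append(
                BackboneConformation(conf.sequence, conf.phi + dphi,
                                     conf.psi + dpsi)
            )
        out.append(
            Trajectory(frames=frames, energies=np.zeros(n_frames),
                       capture_every=1, seed=seed + t, temperature=0.0,
                       acceptance_rate=1.0)
        )
    return out
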