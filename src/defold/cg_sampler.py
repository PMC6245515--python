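"""Coarse-grained backbone model and torsion-space Metropolis sampler.

Each residue carries three dynamic atoms (N, CA, C) plus derived O, H and CB
positions; the conformation is parameterized by its (phi, psi) torsions with
ideal bond geometry (see :mod:`defold.geometry`).  The energy is

    V = V_torsion + sum_ij V_ij + sum_i w_env(aa_i) * N_i + V_contact

with V_torsion the flat-bottom windows around predicted torsions, V_ij the
two-sigmoid pair potential over side-chain (CB-CB) and backbone hydrogen-bond
(H...O) distances, N_i a smooth count of side chains in the hemisphere above
CB_i capturing burial/desolvation, and V_contact the attractive wells on the
restrained contact pairs.

Conformation space is sampled by Metropolis Monte Carlo in torsion space:
single-torsion Gaussian proposals (sigma = 5 degrees), acceptance
min(1, exp(-dV/T)), targeting the Boltzmann distribution exp(-V/T) of the
restraint energy.  This replaces a molecular-dynamics integrator while
preserving the stationary ensemble the restraints define; it is the central
simplification of the sampler and is documented in the methods note.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from . import geometry
from .geometry import build_chain, derive_atoms, measure_torsions
from .pair_energies import (
    contact_energy_table,
    encode_sequence,
    kyte_doolittle_weights,
)
from .restraints import RestraintBundle


class SimulationError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Conformation


@dataclass
class BackboneConformation:
    """A backbone state: sequence plus (phi, psi) torsions in degrees.

    Coordinates are derived, cached lazily, and invalidated whenever the
    torsions change.  ``phi[0]`` and ``psi[-1]`` are undefined at the termini
    and held at 180 by convention.
    """

    sequence: str
    phi: np.ndarray
    psi: np.ndarray
    _cache: tuple | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=float).copy()
        self.psi = np.asarray(self.psi, dtype=float).copy()
        if not (len(self.sequence) == self.phi.size == self.psi.size):
            raise ValueError("sequence and torsion lengths disagree")
        encode_sequence(self.sequence)  # validates letters

    @property
    def n_residues(self) -> int:
        return len(self.sequence)

    def _build(self) -> tuple:
        if self._cache is None:
            N, CA, C = build_chain(self.phi, self.psi)
            O, H, CB = derive_atoms(N, CA, C, self.psi)
            self._cache = (N, CA, C, O, H, CB)
        return self._cache

    @property
    def coords(self) -> dict[str, np.ndarray]:
        N, CA, C, O, H, CB = self._build()
        return {"N": N, "CA": CA, "C": C, "O": O, "H": H, "CB": CB}

    def ca_coords(self) -> np.ndarray:
        return self._build()[1]

    def measured_torsions(self) -> tuple[np.ndarray, np.ndarray]:
        N, CA, C = self._build()[:3]
        return measure_torsions(N, CA, C)

    def copy(self) -> "BackboneConformation":
        return BackboneConformation(self.sequence, self.phi, self.psi)


def build_extended(sequence: str) -> BackboneConformation:
    """Fully extended chain: phi = psi = 180 everywhere."""
    if len(sequence) < 2:
        raise ValueError("need at least two residues")
    n = len(sequence)
    return BackboneConformation(sequence, np.full(n, 180.0), np.full(n, 180.0))


def set_torsions(
    conf: BackboneConformation, phi: np.ndarray, psi: np.ndarray
) -> BackboneConformation:
    """New conformation of the same sequence with the given torsions."""
    return BackboneConformation(conf.sequence, phi, psi)


# ---------------------------------------------------------------------------
# Energy kernels


@njit(cache=True)
def _sig(x):
    if x > 500.0:
        return 0.0
    if x < -500.0:
        return 1.0
    return 1.0 / (1.0 + np.exp(x))


@njit(cache=True)
def _circ_excess(angle, center, half_width):
    d = (angle - center) % 360.0
    if d > 180.0:
        d -= 360.0
    ex = abs(d) - half_width
    return ex if ex > 0.0 else 0.0


@njit(cache=True)
def _env_counts(CA, CB):
    """Smooth hemisphere burial count N_i for every residue.

    N_i sums, over residues j with |i - j| > 2, a distance switch centered at
    8 A (width 1 A) on the CB-CB distance times an angular switch
    S(-cos(theta) + 0.1, 1) that selects the hemisphere above CB_i along the
    CA->CB axis.
    """
    n = CA.shape[0]
    out = np.zeros(n)
    for i in range(n):
        ax = CB[i] - CA[i]
        nax = np.sqrt(ax[0] ** 2 + ax[1] ** 2 + ax[2] ** 2)
        for j in range(n):
            if abs(i - j) <= 2:
                continue
            d0 = CB[j, 0] - CB[i, 0]
            d1 = CB[j, 1] - CB[i, 1]
            d2 = CB[j, 2] - CB[i, 2]
            d = np.sqrt(d0 * d0 + d1 * d1 + d2 * d2)
            if d < 1e-9:
                continue
            cos_t = (ax[0] * d0 + ax[1] * d1 + ax[2] * d2) / (nax * d)
            out[i] += _sig(d - 8.0) * _sig(-cos_t + 0.1)
    return out


@njit(cache=True)
def _energy_terms(
    phi, psi, seq,
    tor_phi0, tor_psi0, tor_hw, tor_k,
    sc_e_in, sc_r_in, sc_w_in, sc_r_out, sc_w_out, eout_table,
    hb_e_in, hb_r_in, hb_w_in, hb_e_out, hb_r_out, hb_w_out,
    env_w,
    con_i, con_j, con_rc, con_depth, con_width,
    enable_pair, enable_env,
):
    n = phi.shape[0]
    N, CA, C = build_chain(phi, psi)
    O, H, CB = derive_atoms(N, CA, C, psi)

    tor = 0.0
    for i in range(n):
        if i > 0:
            ex = _circ_excess(phi[i], tor_phi0[i], tor_hw[i])
            tor += 0.5 * tor_k[i] * ex * ex
        if i < n - 1:
            ex = _circ_excess(psi[i], tor_psi0[i], tor_hw[i])
            tor += 0.5 * tor_k[i] * ex * ex

    pair = 0.0
    if enable_pair:
        for i in range(n):
            for j in range(i + 3, n):
                d0 = CB[j, 0] - CB[i, 0]
                d1 = CB[j, 1] - CB[i, 1]
                d2 = CB[j, 2] - CB[i, 2]
                d = np.sqrt(d0 * d0 + d1 * d1 + d2 * d2)
                pair += sc_e_in * _sig((d - sc_r_in) / sc_w_in)
                pair += eout_table[seq[i], seq[j]] * _sig((d - sc_r_out) / sc_w_out)
        # backbone hydrogen bonds: donor H_j, acceptor O_i, |i-j| >= 2
        for i in range(n):
            for j in range(1, n):
                if abs(i - j) < 2:
                    continue
                d0 = H[j, 0] - O[i, 0]
                d1 = H[j, 1] - O[i, 1]
                d2 = H[j, 2] - O[i, 2]
                d = np.sqrt(d0 * d0 + d1 * d1 + d2 * d2)
                pair += hb_e_in * _sig((d - hb_r_in) / hb_w_in)
                pair += hb_e_out * _sig((d - hb_r_out) / hb_w_out)

    env = 0.0
    if enable_env:
        counts = _env_counts(CA, CB)
        for i in range(n):
            env += env_w[i] * counts[i]

    contact = 0.0
    for k in range(con_i.shape[0]):
        a = con_i[k]
        b = con_j[k]
        d0 = CB[b, 0] - CB[a, 0]
        d1 = CB[b, 1] - CB[a, 1]
        d2 = CB[b, 2] - CB[a, 2]
        d = np.sqrt(d0 * d0 + d1 * d1 + d2 * d2)
        contact += -con_depth[k] * _sig((d - con_rc[k]) / con_width[k])

    return tor, pair, env, contact


@dataclass
class EnergyBreakdown:
    """Additive decomposition of the total energy."""

    torsion: float
    pairwise: float
    environment: float
    contact: float

    @property
    def total(self) -> float:
        return self.torsion + self.pairwise + self.environment + self.contact


@dataclass
class ForceFieldOptions:
    """Switches and tables for the non-restraint energy terms."""

    enable_pair: bool = True
    enable_env: bool = True
    env_magnitude: float = 0.1
    pair_table: np.ndarray | None = None

    def resolved_pair_table(self) -> np.ndarray:
        return (self.pair_table if self.pair_table is not None
                else contact_energy_table())


def _pack(conf: BackboneConformation, bundle: RestraintBundle,
          options: ForceFieldOptions):
    n = conf.n_residues
    if bundle.n_residues != n:
        raise ValueError("restraint bundle does not match sequence length")
    seq = encode_sequence(conf.sequence)
    t = bundle.torsions
    tor_phi0 = np.array([x.phi_center for x in t])
    tor_psi0 = np.array([x.psi_center for x in t])
    tor_hw = np.array([x.half_width for x in t])
    tor_k = np.array([x.k_tor for x in t])
    env_w = kyte_doolittle_weights(options.env_magnitude)[seq]
    if bundle.contacts:
        con = np.array(bundle.contacts, dtype=float)
        con_i = con[:, 0].astype(np.int64)
        con_j = con[:, 1].astype(np.int64)
        con_rc, con_depth, con_width = con[:, 2], con[:, 3], con[:, 4]
    else:
        con_i = np.empty(0, dtype=np.int64)
        con_j = np.empty(0, dtype=np.int64)
        con_rc = con_depth = con_width = np.empty(0)
    sc = bundle.sidechain
    hb = bundle.hbond
    return (
        seq, tor_phi0, tor_psi0, tor_hw, tor_k,
        sc.e_in, sc.r_in, sc.w_in, sc.r_out, sc.w_out,
        options.resolved_pair_table(),
        hb.e_in, hb.r_in, hb.w_in, hb.e_out, hb.r_out, hb.w_out,
        env_w, con_i, con_j, con_rc, con_depth, con_width,
        options.enable_pair, options.enable_env,
    )


def environment_count(conf: BackboneConformation, i: int | None = None):
    """Smooth burial count N_i (all residues, or one if ``i`` given)."""
    c = conf.coords
    counts = _env_counts(c["CA"], c["CB"])
    return counts if i is None else float(counts[i])


def total_energy(
    conf: BackboneConformation,
    bundle: RestraintBundle,
    options: ForceFieldOptions | None = None,
) -> EnergyBreakdown:
    """Full energy of a conformation under the restraint bundle."""
    options = options or ForceFieldOptions()
    args = _pack(conf, bundle, options)
    seq = args[0]
    tor, pair, env, contact = _energy_terms(conf.phi, conf.psi, seq, *args[1:])
    return EnergyBreakdown(torsion=tor, pairwise=pair, environment=env,
                           contact=contact)


# ---------------------------------------------------------------------------
# Sampler


@dataclass
class Trajectory:
    """Captured frames of one Metropolis run."""

    frames: list[BackboneConformation]
    energies: np.ndarray
    capture_every: int
    seed: int
    temperature: float
    acceptance_rate: float
    torsion_log: np.ndarray | None = None  # (n_steps, 2L) when recorded

    @property
    def n_frames(self) -> int:
        return len(self.frames)


def _free_torsion_indices(n: int, movable) -> np.ndarray:
    """Flat torsion indices 0..2n-1 (even = phi_i, odd = psi_i) that may move."""
    idx = []
    for i in range(n):
        if i > 0 and (movable is None or movable[2 * i]):
            idx.append(2 * i)
        if i < n - 1 and (movable is None or movable[2 * i + 1]):
            idx.append(2 * i + 1)
    if not idx:
        raise ValueError("no movable torsions")
    return np.array(idx, dtype=np.int64)


def run_simulation(
    conf0: BackboneConformation,
    bundle: RestraintBundle,
    steps: int,
    capture_every: int = 500,
    temperature: float = 1.0,
    seed: int = 0,
    proposal_sigma: float = 5.0,
    options: ForceFieldOptions | None = None,
    movable: np.ndarray | None = None,
    record_torsions: bool = False,
) -> Trajectory:
    """Metropolis Monte Carlo in torsion space.

    One step = one single-torsion Gaussian proposal (sigma in degrees)
    accepted with probability min(1, exp(-dV/temperature)).  Frames are
    captured every ``capture_every`` steps; runs are bit-reproducible for a
    fixed seed.  ``movable`` optionally masks torsions (length 2L, even
    entries phi, odd psi); ``record_torsions`` additionally logs the full
    torsion vector every step (for statistical checks on small systems).
    """
    if not steps >= capture_every >= 1:
        raise ValueError("need steps >= capture_every >= 1")
    options = options or ForceFieldOptions()
    args = _pack(conf0, bundle, options)
    seq = args[0]
    n = conf0.n_residues
    phi = conf0.phi.copy()
    psi = conf0.psi.copy()
    if not (np.isfinite(phi).all() and np.isfinite(psi).all()):
        raise SimulationError("non-finite torsions in the starting conformation")
    energy = float(sum(_energy_terms(phi, psi, seq, *args[1:])))
    if not np.isfinite(energy):
        raise SimulationError("non-finite energy at the starting conformation")

    free = _free_torsion_indices(n, movable)
    rng = np.random.default_rng(seed)
    frames: list[BackboneConformation] = []
    energies: list[float] = []
    log = np.empty((steps, 2 * n)) if record_torsions else None
    accepted = 0

    for step in range(1, steps + 1):
        t = int(free[rng.integers(free.size)])
        delta = rng.normal(0.0, proposal_sigma)
        res, is_psi = divmod(t, 2)
        arr = psi if is_psi else phi
        old = arr[res]
        new = (old + delta + 180.0) % 360.0 - 180.0
        arr[res] = 180.0 if new == -180.0 else new
        e_new = float(sum(_energy_terms(phi, psi, seq, *args[1:])))
        if e_new <= energy or rng.random() < np.exp(-(e_new - energy) / temperature):
            energy = e_new
            accepted += 1
        else:
            arr[res] = old
        if record_torsions:
            log[step - 1, 0::2] = phi
            log[step - 1, 1::2] = psi
        if step % capture_every == 0:
            frames.append(BackboneConformation(conf0.sequence, phi, psi))
            energies.append(energy)

    return Trajectory(
        frames=frames,
        energies=np.array(energies),
        capture_every=capture_every,
        seed=seed,
        temperature=temperature,
        acceptance_rate=accepted / steps,
        torsion_log=log,
    )


def run_ensemble(
    conf0: BackboneConformation,
    bundle: RestraintBundle,
    seeds: list[int],
    steps: int,
    capture_every: int = 500,
    temperature: float = 1.0,
    proposal_sigma: float = 5.0,
    options: ForceFieldOptions | None = None,
) -> list[Trajectory]:
    """Independent trajectories, one per seed (order-independent by design)."""
    if len(set(seeds)) != len(seeds):
        warnings.warn("duplicate seeds: trajectories will not be independent",
                      stacklevel=2)
    return [
        run_simulation(conf0, bundle, steps, capture_every=capture_every,
                       temperature=temperature, seed=s,
                       proposal_sigma=proposal_sigma, options=options)
        for s in seeds
    ]


def radius_of_gyration(conf: BackboneConformation) -> float:
    return geometry.radius_of_gyration(conf.ca_coords())
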