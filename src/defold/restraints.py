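"""Restraint potentials: torsion windows and sigmoid contact wells.

Predicted torsions become flat-bottom wells: zero penalty inside
[pred - delta, pred + delta] (delta = 20 degrees by default) and a harmonic
wall 0.5 * k_tor * excess^2 outside, computed on the circle.  Ranked
coevolutionary contacts become attractive sigmoid wells on CB-CB distances,
switching on below 7.5 A.  The general pair interaction is a sum of two
sigmoids

    V(r) = e_in / (1 + exp((r - r_in)/w_in)) + e_out / (1 + exp((r - r_out)/w_out))

whose published parameter profiles (side-chain pairs, backbone hydrogen
bonds) are carried here as named profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dca import ContactSet
from .geometry import circular_difference
from .pair_energies import contact_energy_table

CONTACT_CUTOFF = 7.5  #: A; CB-CB distance at/below which a pair is a contact


@dataclass
class TorsionRestraint:
    """Flat-bottom torsion window for one residue.

    ``phi_center/psi_center`` are the predicted angles (degrees); the allowed
    window is center +/- half_width, wrapped on the circle; outside it the
    penalty is 0.5 * k_tor * excess^2 (excess in degrees).
    """

    phi_center: float
    psi_center: float
    half_width: float = 20.0
    k_tor: float = 0.05

    def phi_range(self) -> tuple[float, float]:
        from .geometry import wrap_angle
        return (wrap_angle(self.phi_center - self.half_width),
                wrap_angle(self.phi_center + self.half_width))

    def psi_range(self) -> tuple[float, float]:
        from .geometry import wrap_angle
        return (wrap_angle(self.psi_center - self.half_width),
                wrap_angle(self.psi_center + self.half_width))


def torsion_ranges(
    phi_pred: np.ndarray,
    psi_pred: np.ndarray,
    delta: float = 20.0,
    k_tor: float = 0.05,
) -> list[TorsionRestraint]:
    """One flat-bottom window per residue around the predicted (phi, psi)."""
    if delta <= 0:
        raise ValueError("window half-width must be positive")
    phi_pred = np.asarray(phi_pred, dtype=float)
    psi_pred = np.asarray(psi_pred, dtype=float)
    if phi_pred.shape != psi_pred.shape:
        raise ValueError("phi and psi predictions must have equal length")
    return [
        TorsionRestraint(float(p), float(s), half_width=delta, k_tor=k_tor)
        for p, s in zip(phi_pred, psi_pred)
    ]


def flat_bottom_penalty(angle: float, center: float, half_width: float,
                        k: float) -> float:
    """Penalty of one torsion window: 0 inside, harmonic wall outside."""
    excess = abs(circular_difference(angle, center)) - half_width
    if excess <= 0:
        return 0.0
    return 0.5 * k * excess * excess


@dataclass
class ContactPotentialParams:
    """Parameters of the two-sigmoid pair potential (energies, Angstroms)."""

    e_in: float
    r_in: float
    w_in: float
    e_out: float
    r_out: float
    w_out: float
    role: str = "contact restraint"

    def __post_init__(self) -> None:
        if self.w_in <= 0 or self.w_out <= 0:
            raise ValueError("sigmoid widths must be positive")
        if self.r_in <= 0 or self.r_out <= 0:
            raise ValueError("sigmoid midpoints must be positive")


#: Side-chain pair profile: e_in = 3 soft repulsive core, attractive outer
#: well at r_out = 6.5 with depth set per pair by the contact-energy table.
SIDECHAIN_PROFILE = ContactPotentialParams(
    e_in=3.0, r_in=6.0, w_in=0.2, e_out=-1.0, r_out=6.5, w_out=0.2,
    role="side-chain pair",
)

#: Backbone hydrogen-bond profile (H...O distance).
HBOND_PROFILE = ContactPotentialParams(
    e_in=6.0, r_in=1.4, w_in=0.1, e_out=-4.0, r_out=2.5, w_out=0.125,
    role="backbone H-bond",
)


def two_sigmoid_potential(r, p: ContactPotentialParams):
    """Evaluate the two-sigmoid pair potential at distance(s) ``r``."""
    r = np.asarray(r, dtype=float)
    x_in = np.clip((r - p.r_in) / p.w_in, -500, 500)
    x_out = np.clip((r - p.r_out) / p.w_out, -500, 500)
    v = p.e_in / (1.0 + np.exp(x_in)) + p.e_out / (1.0 + np.exp(x_out))
    return v if v.ndim else float(v)


def contact_restraint_potential(r, r_c: float = CONTACT_CUTOFF,
                                depth: float = 2.0, width: float = 0.5):
    """Attractive contact well: -depth below r_c, 0 above, sigmoid switch.

    V(r_c) = -depth/2 exactly; the well stabilizes pairs whose CB-CB
    distance is at or below the 7.5 A contact cutoff.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    r = np.asarray(r, dtype=float)
    x = np.clip((r - r_c) / width, -500, 500)
    v = -depth / (1.0 + np.exp(x))
    return v if v.ndim else float(v)


@dataclass
class RestraintBundle:
    """Everything the sampler consumes: torsion windows + contact wells."""

    torsions: list[TorsionRestraint]
    contacts: list[tuple[int, int, float, float, float]]  # (i, j, r_c, depth, width)
    profile_name: str = "default"
    sidechain: ContactPotentialParams = field(
        default_factory=lambda: SIDECHAIN_PROFILE)
    hbond: ContactPotentialParams = field(default_factory=lambda: HBOND_PROFILE)

    @property
    def n_residues(self) -> int:
        return len(self.torsions)

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# TORSION\nresidue\tphi\tpsi\thalf_width\tk_tor\n")
            for i, t in enumerate(self.torsions):
                fh.write(f"{i}\t{t.phi_center:.2f}\t{t.psi_center:.2f}"
                         f"\t{t.half_width:.2f}\t{t.k_tor:.4f}\n")
            fh.write("# CONTACT\ni\tj\tr_c\tdepth\twidth\n")
            for i, j, r_c, depth, width in self.contacts:
                fh.write(f"{i}\t{j}\t{r_c:.2f}\t{depth:.3f}\t{width:.3f}\n")


def bundle(
    phi_pred: np.ndarray,
    psi_pred: np.ndarray,
    contacts: ContactSet | None,
    delta: float = 20.0,
    k_tor: float = 0.05,
    contact_depth: float = 2.0,
    contact_width: float = 0.5,
    r_c: float = CONTACT_CUTOFF,
    profile_name: str = "default",
) -> RestraintBundle:
    """Assemble the restraint bundle handed to the sampler.

    An empty or missing contact set yields a valid torsion-only bundle.
    Contact indices must address residues present in the prediction.
    """
    torsions = torsion_ranges(phi_pred, psi_pred, delta=delta, k_tor=k_tor)
    L = len(torsions)
    contact_terms: list[tuple[int, int, float, float, float]] = []
    if contacts is not None:
        for i, j, _score in contacts.pairs:
            if not (0 <= i < L and 0 <= j < L):
                raise ValueError(f"contact pair ({i}, {j}) outside chain of length {L}")
            contact_terms.append((i, j, r_c, contact_depth, contact_width))
    return RestraintBundle(torsions=torsions, contacts=contact_terms,
                           profile_name=profile_name)


def default_pair_table() -> np.ndarray:
    """The 20x20 attractive-depth table used by the side-chain profile."""
    return contact_energy_table()
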