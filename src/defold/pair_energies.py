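"""Residue-pair contact energies for the coarse-grained force field.

The attractive depth of the side-chain pair potential is a statistical
contact energy.  The 20x20 table used by default is built from the published
Miyazawa per-residue contact-energy scale (Miyazawa & Jernigan,
Macromolecules 18:534, 1985; shipped with Biopython) under the standard
additive approximation

    e(a, b) = -s * (m_a + m_b) / 2,

which captures the dominant hydrophobicity mode of statistical pair
potentials: strong attraction between large hydrophobics (F, M, I, L),
weak attraction between polar/charged residues.  The scale factor ``s``
puts the strongest pair near -3.6 energy units so that pair attraction,
hydrogen bonding and contact restraints act on comparable scales.
Any user-supplied 20x20 table (e.g. the full Miyazawa-Jernigan pair table)
can be passed wherever a ``pair_table`` argument is accepted.
"""

from __future__ import annotations

import numpy as np
from Bio.SeqUtils.ProtParamData import hw as _kyte_doolittle
from Bio.SeqUtils.ProtParamData import mi as _miyazawa_scale

from .msa import AMINO_ACIDS

_DEFAULT_SCALE = 0.4


def contact_energy_table(scale: float = _DEFAULT_SCALE) -> np.ndarray:
    """Additive 20x20 contact-energy table over :data:`~defold.msa.AMINO_ACIDS`.

    All entries are negative (contacts are attractive at the coarse-grained
    level); the excluded-volume repulsion is handled separately by the inner
    sigmoid of the pair potential.
    """
    m = np.array([_miyazawa_scale[a] for a in AMINO_ACIDS])
    return -scale * (m[:, None] + m[None, :]) / 2.0


def kyte_doolittle_weights(magnitude: float = 0.1) -> np.ndarray:
    """Per-residue burial weights from the sign of Kyte-Doolittle hydropathy.

    Hydrophobic residues get weight -magnitude (burial lowers the energy),
    hydrophilic ones +magnitude.  Indexed over :data:`~defold.msa.AMINO_ACIDS`.
    """
    kd = np.array([_kyte_doolittle[a] for a in AMINO_ACIDS])
    return -magnitude * np.sign(kd)


def encode_sequence(sequence: str) -> np.ndarray:
    """Map a 20-letter amino-acid sequence to indices into the tables."""
    idx = {a: i for i, a in enumerate(AMINO_ACIDS)}
    try:
        return np.array([idx[c] for c in sequence.upper()], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"invalid residue letter {exc.args[0]!r}") from exc
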