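"""Minimal PDB input/output for coarse-grained backbone models.

Written models carry N, CA, C, O and CB records per residue (H is derived
and omitted).  Reading uses Biopython's parser and extracts the CA trace,
which is all the evaluation metrics need.
"""

from __future__ import annotations

import warnings

import numpy as np
from Bio.PDB import PDBParser
from Bio.SeqUtils import seq3

from .cg_sampler import BackboneConformation

_ATOM_ELEMENTS = {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C"}


def _atom_line(serial: int, name: str, resname: str, resseq: int,
               xyz: np.ndarray) -> str:
    pad_name = f" {name:<3s}" if len(name) < 4 else name
    return (
        f"ATOM  {serial:5d} {pad_name} {resname} A{resseq:4d}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00          "
        f"{_ATOM_ELEMENTS[name]:>2s}\n"
    )


def write_pdb(conformations, path) -> None:
    """Write one or more conformations as a (multi-)MODEL PDB file."""
    if isinstance(conformations, BackboneConformation):
        conformations = [conformations]
    with open(path, "w") as fh:
        multi = len(conformations) > 1
        for m, conf in enumerate(conformations, start=1):
            if multi:
                fh.write(f"MODEL     {m:4d}\n")
            coords = conf.coords
            serial = 1
            for i, aa in enumerate(conf.sequence):
                resname = seq3(aa).upper()
                for name in ("N", "CA", "C", "O", "CB"):
                    fh.write(_atom_line(serial, name, resname, i + 1,
                                        coords[name][i]))
                    serial += 1
            if multi:
                fh.write("ENDMDL\n")
        fh.write("END\n")


def read_ca_trace(path, model_index: int = 0) -> np.ndarray:
    """CA coordinates of one model of a PDB file, shape (L, 3)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = PDBParser(QUIET=True).get_structure("ref", str(path))
    models = list(structure)
    chain_atoms = []
    for chain in models[model_index]:
        for residue in chain:
            if "CA" in residue:
                chain_atoms.append(residue["CA"].coord)
    if not chain_atoms:
        raise ValueError(f"no CA atoms found in {path}")
    return np.array(chain_atoms, dtype=float)


def read_ca_traces(path) -> list[np.ndarray]:
    """CA traces of every model in a multi-model PDB."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = PDBParser(QUIET=True).get_structure("traj", str(path))
    out = []
    for model in structure:
        atoms = [res["CA"].coord for chain in model for res in chain
                 if "CA" in res]
        out.append(np.array(atoms, dtype=float))
    return out
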