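"""Reading and writing coarse-grained Cα chains in PDB format.

The model represents a protein as one bead per residue, centred on the
Cα atom.  This module extracts those beads from PDB files and writes
trajectory snapshots back out as CA-only PDB files.  Residues are
re-indexed 1..n internally; the author numbering from the source file is
retained as display metadata only (see :attr:`Chain.original_ids`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionWarning

__all__ = ["Chain", "ChainError", "read_ca_chain", "write_snapshot"]


class ChainError(ValueError):
    """Raised for structurally unusable input (missing chain, gaps, too short)."""


@dataclass(frozen=True)
class Chain:
    """Ordered Cα coordinates of one protein conformation.

    Parameters
    ----------
    coords
        ``(n, 3)`` array of Cα positions in Å.
    label
        Free-text identifier (PDB id + chain id, or fixture name).
    original_ids
        Author residue identifiers (e.g. ``"A:16"``) aligned with the
        internal 1-based index; purely informational.
    """

    coords: np.ndarray
    label: str = ""
    original_ids: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ChainError(f"coords must be (n, 3), got {coords.shape}")
        if not np.all(np.isfinite(coords)):
            raise ChainError("coords contain non-finite values")
        if len(coords) < 3:
            raise ChainError(f"chain too short: {len(coords)} residues (need >= 3)")
        object.__setattr__(self, "coords", coords)
        if self.original_ids and len(self.original_ids) != len(coords):
            raise ChainError("original_ids length does not match coords")

    @property
    def n(self) -> int:
        return len(self.coords)

    @property
    def residue_ids(self) -> np.ndarray:
        """Internal 1-based consecutive residue indices."""
        return np.arange(1, self.n + 1)

    def with_coords(self, coords: np.ndarray, label: str | None = None) -> "Chain":
        """Copy of this chain with new coordinates (same length)."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != self.coords.shape:
            raise ChainError(
                f"replacement coords shape {coords.shape} != {self.coords.shape}"
            )
        return Chain(coords, self.label if label is None else label, self.original_ids)


def _best_ca(residue):
    """Pick the Cα atom of a residue: highest occupancy, then first listed."""
    if "CA" not in residue:
        return None
    atom = residue["CA"]
    if atom.is_disordered():
        best = max(
            atom.disordered_get_list(),
            key=lambda a: (a.get_occupancy() or 0.0),
        )
        return best
    return atom


def read_ca_chain(pdb_path, chain_id: str = "A", model_index: int = 0) -> Chain:
    """Read one chain's Cα trace from a PDB file.

    Residues are taken in file order.  Standard residues lacking a CA
    record abort the read (``"incomplete backbone"``): the coarse-grained
    model needs an unbroken bead chain.  Hetero residues (e.g. MSE) are
    accepted when they carry a CA atom and silently skipped otherwise
    (ligands, ions); waters are always skipped.  Alternate locations are
    resolved by highest occupancy, ties broken by file order.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PDBConstructionWarning)
        structure = PDBParser(QUIET=True).get_structure("s", str(pdb_path))
    models = list(structure)
    if not models:
        raise ChainError(f"no models found in {pdb_path}")
    try:
        model = models[model_index]
    except IndexError:
        raise ChainError(
            f"model {model_index} not found ({len(models)} model(s) present)"
        ) from None
    if chain_id not in model:
        available = ", ".join(c.id for c in model) or "none"
        raise ChainError(f"chain not found: {chain_id!r} (available: {available})")

    coords: list[np.ndarray] = []
    orig: list[str] = []
    for residue in model[chain_id]:
        hetflag, resseq, icode = residue.id
        if hetflag == "W":
            continue
        ca = _best_ca(residue)
        if ca is None:
            if hetflag == " ":
                raise ChainError(
                    "incomplete backbone: residue "
                    f"{residue.get_resname()} {chain_id}:{resseq}{icode.strip()} "
                    "has no CA atom"
                )
            continue  # hetero residue without CA: a ligand, not a bead
        coords.append(np.asarray(ca.get_coord(), dtype=float))
        orig.append(f"{chain_id}:{resseq}{icode.strip()}")

    if len(coords) < 3:
        raise ChainError(f"chain too short: {len(coords)} Cα atoms (need >= 3)")
    return Chain(np.array(coords), label=f"{pdb_path}|{chain_id}", original_ids=tuple(orig))


_ATOM_FMT = (
    "ATOM  {serial:5d}  CA  {resname:<3s} {chain}{resseq:4d}    "
    "{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}           C\n"
)


def write_snapshot(chain: Chain, out_path) -> None:
    """Write a chain as a CA-only PDB file (one ATOM record per residue)."""
    if chain.n == 0:  # defensive; Chain construction already forbids this
        raise ChainError("cannot write empty chain")
    lines = []
    for i, (x, y, z) in enumerate(chain.coords, start=1):
        lines.append(
            _ATOM_FMT.format(
                serial=i, resname="GLY", chain="A", resseq=i,
                x=x, y=y, z=z, occ=1.0, b=0.0,
            )
        )
    lines.append("TER\nEND\n")
    with open(out_path, "w") as fh:
        fh.writelines(lines)


def residue_mapping_table(chain: Chain):
    """Internal index → original author numbering, as a DataFrame.

    Lets users reconcile internal 1..n indices with PDB residue numbers
    (e.g. the ALA16 / LEU49 / ILE57 style labels used in the literature).
    """
    import pandas as pd

    orig = chain.original_ids or tuple(f":{i}" for i in chain.residue_ids)
    return pd.DataFrame({"index": chain.residue_ids, "original_id": list(orig)})
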