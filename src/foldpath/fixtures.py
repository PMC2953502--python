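"""Synthetic native structures for testing and demonstration.

Real native structures come from PDB files; these generators build small
idealised Cα chains with known contact topology so the whole pipeline can
run without any downloads:

* ``ideal_helix`` — canonical α-helix Cα geometry (rise 1.5 Å, radius
  2.3 Å, 100° twist per residue), giving the familiar (i, i+3) and
  (i, i+4) contacts at a 7 Å cutoff.
* ``extended`` — straight chain with 3.8 Å virtual bonds; no non-covalent
  contacts at 7 Å (2 × 3.8 = 7.6 Å).
* ``helix_hairpin`` — two 8-residue antiparallel helices joined by a
  4-residue turn, with designed inter-helix (non-local) native contacts;
  the smallest structure with both local and tertiary clusters.
* ``two_domain`` — two helical contact-dense blocks separated by an
  extended linker, giving a sparse inter-domain contact region.

All generators are deterministic given the spec.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .structures_io import Chain

__all__ = ["FixtureSpec", "make_fixture", "random_contact_map", "KINDS"]

KINDS = ("ideal_helix", "helix_hairpin", "extended", "two_domain")

HELIX_RISE = 1.5      # Å per residue along the axis
HELIX_RADIUS = 2.3    # Å, Cα distance from the helix axis
HELIX_TWIST = 100.0   # degrees per residue
VIRTUAL_BOND = 3.8    # Å, consecutive Cα distance


@dataclass(frozen=True)
class FixtureSpec:
    kind: str
    n: int
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown fixture kind {self.kind!r}; choose from {KINDS}")


def _helix_points(n: int, phase: float = 0.0) -> np.ndarray:
    t = np.deg2rad(HELIX_TWIST) * np.arange(n) + phase
    return np.column_stack(
        [HELIX_RADIUS * np.cos(t), HELIX_RADIUS * np.sin(t), HELIX_RISE * np.arange(n)]
    )


def _extended_points(n: int) -> np.ndarray:
    coords = np.zeros((n, 3))
    coords[:, 0] = VIRTUAL_BOND * np.arange(n)
    return coords


def _arc_bridge(p0: np.ndarray, p1: np.ndarray, n_residues: int) -> np.ndarray:
    """Place ``n_residues`` points on a circular arc from p0 to p1.

    The arc is chosen so every virtual bond (n_residues + 1 segments) has
    length 3.8 Å and bulges towards +z, away from the flanking helices.
    """
    nseg = n_residues + 1
    chord = float(np.linalg.norm(p1 - p0))
    if chord >= nseg * VIRTUAL_BOND:
        raise ValueError("endpoints too far apart for the requested turn length")

    def gap(phi):
        return VIRTUAL_BOND * np.sin(nseg * phi / 2) / np.sin(phi / 2) - chord

    phi = brentq(gap, 1e-9, 2 * np.pi / nseg - 1e-9)
    radius = VIRTUAL_BOND / (2 * np.sin(phi / 2))
    theta = nseg * phi

    e1 = (p1 - p0) / chord
    up = np.array([0.0, 0.0, 1.0])
    e2 = up - np.dot(up, e1) * e1
    if np.linalg.norm(e2) < 1e-9:  # chord parallel to z: bulge in +y instead
        e2 = np.array([0.0, 1.0, 0.0]) - e1 * e1[1]
    e2 /= np.linalg.norm(e2)
    mid = 0.5 * (p0 + p1)
    center = mid - radius * np.cos(theta / 2) * e2

    psi0 = np.arctan2(np.dot(p0 - center, e2), np.dot(p0 - center, e1))
    for sign in (1.0, -1.0):
        psis = psi0 + sign * theta * np.arange(nseg + 1) / nseg
        pts = center + radius * (np.cos(psis)[:, None] * e1 + np.sin(psis)[:, None] * e2)
        if np.allclose(pts[-1], p1, atol=1e-6) and max(
            np.dot(p - mid, e2) for p in pts
        ) > 0:
            return pts[1:-1]
    raise RuntimeError("arc construction failed")  # pragma: no cover


def _helix_hairpin(n: int) -> np.ndarray:
    # fixed 20-residue design: helices 1-8 and 13-20, turn 9-12; the
    # mirrored second helix sits 8 Å away so residues (1,19), (4,18),
    # (5,18) ... form genuine non-local contacts at the 7 Å cutoff
    if n != 20:
        raise ValueError("helix_hairpin is a fixed 20-residue design (n must be 20)")
    first = _helix_points(8)
    second = _helix_points(8, phase=np.deg2rad(200.0))[::-1].copy()
    second[:, 0] = 8.0 - second[:, 0]
    second[:, 2] += 1.5
    turn = _arc_bridge(first[-1], second[0], 4)
    return np.vstack([first, turn, second])


def _two_domain(n: int) -> np.ndarray:
    # two helical domains of (n - 4) // 2 residues with a 4-residue
    # extended linker: dense intra-domain contacts, sparse in between
    if n < 16:
        raise ValueError("two_domain needs n >= 16")
    n_dom = (n - 4) // 2
    first = _helix_points(n_dom)
    linker_dir = np.array([1.0, 0.0, 0.3])
    linker_dir /= np.linalg.norm(linker_dir)
    linker_start = first[-1]
    linker = np.array(
        [linker_start + VIRTUAL_BOND * (k + 1) * linker_dir for k in range(4)]
    )
    second = _helix_points(n - n_dom - 4)
    second = second + (linker[-1] + VIRTUAL_BOND * linker_dir - second[0])
    return np.vstack([first, linker, second])


def make_fixture(spec: FixtureSpec) -> Chain:
    """Generate the synthetic native chain described by ``spec``."""
    if spec.n < 3:
        raise ValueError(f"n={spec.n} too small (need >= 3)")
    builders = {
        "ideal_helix": _helix_points,
        "extended": _extended_points,
        "helix_hairpin": _helix_hairpin,
        "two_domain": _two_domain,
    }
    coords = builders[spec.kind](spec.n)
    return Chain(coords, label=f"{spec.kind}_{spec.n}")


def random_contact_map(n: int, rng: np.random.Generator, density: float = 0.2,
                       include_backbone: bool = True):
    """Synthetic random contact map for oracle checks.

    The pairs are drawn independently and need not correspond to any
    embeddable conformation — this is a test instrument for the matrix
    algebra, not a structure.  Covalent (i, i+1) pairs are included by
    default, matching maps measured from real conformations.
    """
    from .network_matrices import ContactMap, DEFAULT_CUTOFF

    pairs = set()
    for i in range(1, n + 1):
        for j in range(i + 1, n + 1):
            if (include_backbone and j == i + 1) or rng.random() < density:
                pairs.add((i, j))
    return ContactMap(n=n, pairs=frozenset(pairs), cutoff=DEFAULT_CUTOFF)
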