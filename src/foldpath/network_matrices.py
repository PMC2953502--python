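"""Contact maps, graph Laplacians and the matrices of the folding model.

Given a conformation, a binary contact map ``C`` marks residue pairs whose
Cα–Cα distance is within a cutoff (7 Å by default).  Three matrices derive
from it:

* the graph Laplacian ``L`` of the contact graph,
* the LQR state weight ``Q = L - L_bb + eps*I``, where ``L_bb`` is the
  Laplacian of the covalent backbone (the path graph 1–2–…–n) and ``eps``
  a small positive regulariser that restores positive definiteness, and
* the Gaussian-network connectivity matrix ``Gamma = -g * L`` (spring
  constant ``g``), which has one zero and n−1 negative eigenvalues for a
  connected chain.

``Q`` penalises squared deviations of non-covalent contact vectors from
their native values: ``L - L_bb`` equals the sum over non-covalent contact
pairs (i, j) of ``D_ij^T D_ij`` with ``D_ij`` the row vector holding −1 at
i and +1 at j.  That pairwise form is the oracle the tests check against.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .structures_io import Chain

__all__ = [
    "ContactMap",
    "compute_contact_map",
    "laplacian_from_contacts",
    "backbone_laplacian",
    "build_Q",
    "connectivity_matrix",
    "write_contact_pairs",
    "read_contact_pairs",
    "write_contact_matrix_csv",
]

DEFAULT_CUTOFF = 7.0  # Å


@dataclass(frozen=True)
class ContactMap:
    """Symmetric binary contact map stored as i < j pairs (1-based indices)."""

    n: int
    pairs: frozenset
    cutoff: float

    def __post_init__(self) -> None:
        for i, j in self.pairs:
            if not (1 <= i < j <= self.n):
                raise ValueError(f"invalid pair ({i}, {j}) for n={self.n}")

    def __contains__(self, pair) -> bool:
        i, j = pair
        return (min(i, j), max(i, j)) in self.pairs

    def as_matrix(self) -> np.ndarray:
        """Dense symmetric 0/1 matrix (zero diagonal)."""
        m = np.zeros((self.n, self.n))
        for i, j in self.pairs:
            m[i - 1, j - 1] = m[j - 1, i - 1] = 1.0
        return m

    def noncovalent_pairs(self) -> frozenset:
        return frozenset(p for p in self.pairs if p[1] - p[0] > 1)


def compute_contact_map(chain: Chain, cutoff: float = DEFAULT_CUTOFF) -> ContactMap:
    """All residue pairs with Cα–Cα distance <= cutoff (covalent ones included)."""
    if cutoff <= 0:
        raise ValueError(f"cutoff must be positive, got {cutoff}")
    dist = squareform(pdist(chain.coords))
    ii, jj = np.nonzero(np.triu(dist <= cutoff, k=1))
    pairs = frozenset(zip((ii + 1).tolist(), (jj + 1).tolist()))
    return ContactMap(n=chain.n, pairs=pairs, cutoff=float(cutoff))


def laplacian_from_contacts(cmap: ContactMap) -> np.ndarray:
    """Graph Laplacian: degree on the diagonal, −1 where a pair is in contact."""
    adjacency = cmap.as_matrix()
    return np.diag(adjacency.sum(axis=1)) - adjacency


def backbone_laplacian(n: int) -> np.ndarray:
    """Laplacian of the covalent backbone, i.e. the path graph 1–2–…–n."""
    lap = np.zeros((n, n))
    idx = np.arange(n - 1)
    lap[idx, idx + 1] = lap[idx + 1, idx] = -1.0
    deg = np.full(n, 2.0)
    deg[0] = deg[-1] = 1.0
    np.fill_diagonal(lap, deg)
    return lap


def build_Q(cmap: ContactMap, epsilon: float) -> np.ndarray:
    """State weighting matrix ``Q = L - L_bb + epsilon*I``.

    ``L`` is the Laplacian of the contact graph with the covalent
    backbone always included, so ``L - L_bb`` equals the sum of
    ``D_ij^T D_ij`` over the non-covalent contact pairs — positive
    semidefinite for every contact map, even a transient one in which a
    stretched virtual bond has left the geometric cutoff.  ``L - L_bb``
    alone has at least one zero eigenvalue (the translational mode), so
    no stabilising gain would exist; the ``epsilon`` shift makes Q
    strictly positive definite.  Row sums of Q all equal ``epsilon``.
    """
    if epsilon <= 0:
        raise ValueError(
            f"epsilon must be positive (got {epsilon}): Q would not be positive definite"
        )
    n = cmap.n
    adjacency = cmap.as_matrix()
    idx = np.arange(n - 1)
    adjacency[idx, idx + 1] = adjacency[idx + 1, idx] = 1.0
    lap = np.diag(adjacency.sum(axis=1)) - adjacency
    return lap - backbone_laplacian(n) + epsilon * np.eye(n)


def connectivity_matrix(
    cmap: ContactMap, spring_constant: float = 1.0, *, zero_tol: float = 1e-10
) -> np.ndarray:
    """Gaussian-network connectivity matrix Γ of a conformation.

    Γ = −spring_constant · L(contact graph ∪ covalent backbone).  For a
    connected graph Γ has exactly one zero eigenvalue (rigid translation)
    and n−1 negative ones; a second zero eigenvalue means the structure
    falls into disconnected pieces and the model's premise fails.
    """
    if spring_constant <= 0:
        raise ValueError(f"spring_constant must be positive, got {spring_constant}")
    n = cmap.n
    adjacency = cmap.as_matrix()
    idx = np.arange(n - 1)
    adjacency[idx, idx + 1] = adjacency[idx + 1, idx] = 1.0  # covalent bonds always present
    lap = np.diag(adjacency.sum(axis=1)) - adjacency
    gamma = -spring_constant * lap
    eigvals = np.linalg.eigvalsh(gamma)
    n_zero = int(np.sum(np.abs(eigvals) < zero_tol * max(1.0, abs(eigvals).max())))
    if n_zero != 1:
        raise ValueError(
            f"connectivity matrix has {n_zero} zero eigenvalues (expected exactly 1): "
            "contact graph is disconnected"
        )
    return gamma


# ---------------------------------------------------------------------------
# serialization (1-based indices in files)

def write_contact_pairs(cmap: ContactMap, chain: Chain, out_path) -> None:
    """Three-column text file: i, j, Cα–Cα distance in Å."""
    dist = squareform(pdist(chain.coords))
    with open(out_path, "w") as fh:
        fh.write("# i j distance_A\n")
        for i, j in sorted(cmap.pairs):
            fh.write(f"{i} {j} {dist[i - 1, j - 1]:.3f}\n")


def read_contact_pairs(path, n: int, cutoff: float = DEFAULT_CUTOFF) -> ContactMap:
    pairs = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            i, j = int(line.split()[0]), int(line.split()[1])
            pairs.add((min(i, j), max(i, j)))
    return ContactMap(n=n, pairs=frozenset(pairs), cutoff=cutoff)


def write_contact_matrix_csv(cmap: ContactMap, out_path) -> None:
    """Dense 0/1 matrix CSV with 1-based residue indices as header/index."""
    import pandas as pd

    labels = np.arange(1, cmap.n + 1)
    pd.DataFrame(cmap.as_matrix().astype(int), index=labels, columns=labels).to_csv(out_path)
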