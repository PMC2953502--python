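"""Quantities measured along a folding trajectory.

Fractional cluster contacts f(t), contact initiation/completion events,
radius of gyration, pair distances, the instantaneous energy and
entropy-penalty terms of the control objective, and contact-order
diagnostics (CO and effective contact order, ECO).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .folding_engine import FoldingTrajectory
from .network_matrices import ContactMap, build_Q
from .structures_io import Chain

__all__ = [
    "ClusterDefinition",
    "ContactEvent",
    "fraction_contacts",
    "contact_events",
    "events_frame",
    "radius_of_gyration",
    "pair_distance_series",
    "cost_decay_series",
    "effective_contact_order",
    "time_to_half_rg_gap",
    "load_clusters",
]


@dataclass(frozen=True)
class ClusterDefinition:
    """A rectangular region of the contact map, e.g. a turn or a β-pairing.

    The region is the set of unordered pairs {i, j} with one index in
    ``i_range`` and the other in ``j_range`` (both inclusive, 1-based).
    Secondary-structure clusters sit near the diagonal (e.g. an α-helix
    is the band i_range = j_range = helix residues); tertiary pairings
    such as β1–β4 are off-diagonal rectangles.
    """

    name: str
    i_range: tuple[int, int]
    j_range: tuple[int, int]

    def member_pairs(self, n: int) -> frozenset:
        (i0, i1), (j0, j1) = self.i_range, self.j_range
        if not (1 <= i0 <= i1 <= n and 1 <= j0 <= j1 <= n):
            raise ValueError(f"cluster {self.name!r} region outside [1, {n}]")
        pairs = set()
        for i in range(i0, i1 + 1):
            for j in range(j0, j1 + 1):
                if i != j:
                    pairs.add((min(i, j), max(i, j)))
        return frozenset(pairs)

    def native_pairs(self, native_map: ContactMap) -> frozenset:
        return self.member_pairs(native_map.n) & native_map.pairs


@dataclass(frozen=True)
class ContactEvent:
    """First formation (t_init) and final stabilisation (t_complete) of one pair."""

    pair: tuple[int, int]
    t_init: float
    t_complete: float
    is_native: bool


def _pair_distances(traj: FoldingTrajectory) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Distances for all i<j pairs at every recorded time: (T, n_pairs)."""
    coords = traj.coordinates
    n = traj.n
    ii, jj = np.triu_indices(n, k=1)
    diff = coords[:, ii, :] - coords[:, jj, :]
    dist = np.linalg.norm(diff, axis=-1)
    pairs = list(zip((ii + 1).tolist(), (jj + 1).tolist()))
    return dist, pairs


def fraction_contacts(traj: FoldingTrajectory, cluster: ClusterDefinition,
                      native_only: bool = False) -> pd.Series:
    """Fraction f(t) of a cluster's native contacts formed at each time.

    The numerator counts every pair inside the cluster's rectangle at
    distance <= cutoff — native or not — so f may exceed 1 when
    non-native contacts transiently form in the region.  With
    ``native_only=True`` only native pairs are counted and f <= 1.
    """
    from .network_matrices import compute_contact_map

    cutoff = traj.config.cutoff
    native_map = compute_contact_map(traj.native, cutoff)
    native_in_region = cluster.native_pairs(native_map)
    if not native_in_region:
        raise ValueError(f"empty cluster: {cluster.name!r} contains no native contacts")
    member = cluster.member_pairs(traj.n)
    dist, pairs = _pair_distances(traj)
    cols = [k for k, p in enumerate(pairs)
            if p in (native_in_region if native_only else member)]
    formed = (dist[:, cols] <= cutoff).sum(axis=1)
    return pd.Series(formed / len(native_in_region), index=traj.times, name=cluster.name)


def contact_events(traj: FoldingTrajectory, cutoff: float | None = None) -> list[ContactEvent]:
    """One event per residue pair that is ever in contact along the run.

    ``t_init`` is the first recorded time the pair's distance is within
    the cutoff; ``t_complete`` the first time after which it stays within
    the cutoff to the end of the trajectory.  Both are resolved on the
    recording grid.  Events are sorted by t_init, then by pair.
    """
    if len(traj.times) < 2:
        raise ValueError("trajectory must have at least 2 recorded times")
    cutoff = traj.config.cutoff if cutoff is None else cutoff
    from .network_matrices import compute_contact_map

    native_pairs = compute_contact_map(traj.native, cutoff).pairs
    dist, pairs = _pair_distances(traj)
    within = dist <= cutoff
    events = []
    for k, pair in enumerate(pairs):
        col = within[:, k]
        if not col.any():
            continue
        t_init = float(traj.times[int(np.argmax(col))])
        # last index where the pair is broken; stable from the next grid point
        broken = np.nonzero(~col)[0]
        stable_from = 0 if len(broken) == 0 else broken[-1] + 1
        if stable_from >= len(col):
            continue  # broken at the end: never completes
        t_complete = float(traj.times[stable_from])
        events.append(ContactEvent(pair, t_init, t_complete, pair in native_pairs))
    events.sort(key=lambda e: (e.t_init, e.pair))
    return events


def events_frame(events: list[ContactEvent]) -> pd.DataFrame:
    return pd.DataFrame({
        "i": [e.pair[0] for e in events],
        "j": [e.pair[1] for e in events],
        "t_init": [e.t_init for e in events],
        "t_complete": [e.t_complete for e in events],
        "is_native": [e.is_native for e in events],
        "sequence_separation": [e.pair[1] - e.pair[0] for e in events],
    })


def radius_of_gyration(chain_or_coords) -> float:
    """Rg = sqrt(mean squared distance of residues from their centroid), Å."""
    coords = chain_or_coords.coords if isinstance(chain_or_coords, Chain) \
        else np.asarray(chain_or_coords, dtype=float)
    centered = coords - coords.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum(centered ** 2, axis=1))))


def rg_series(traj: FoldingTrajectory) -> pd.Series:
    values = [radius_of_gyration(c) for c in traj.coordinates]
    return pd.Series(values, index=traj.times, name="Rg")


def time_to_half_rg_gap(traj: FoldingTrajectory) -> float:
    """First recorded time at which |Rg(t) − Rg_native| halves its initial value."""
    rg_native = radius_of_gyration(traj.native)
    gap = np.abs(rg_series(traj).to_numpy() - rg_native)
    if gap[0] == 0:
        return 0.0
    hit = np.nonzero(gap <= 0.5 * gap[0])[0]
    if len(hit) == 0:
        raise ValueError("Rg gap never halves along this trajectory")
    return float(traj.times[hit[0]])


def pair_distance_series(traj: FoldingTrajectory, i: int, j: int) -> pd.Series:
    """Cα–Cα distance between residues i and j at each recorded time."""
    n = traj.n
    if not (1 <= i <= n and 1 <= j <= n) or i == j:
        raise ValueError(f"need two distinct residues in [1, {n}], got ({i}, {j})")
    diff = traj.coordinates[:, i - 1, :] - traj.coordinates[:, j - 1, :]
    return pd.Series(np.linalg.norm(diff, axis=-1), index=traj.times,
                     name=f"d({i},{j})")


def cost_decay_series(traj: FoldingTrajectory) -> pd.DataFrame:
    """Instantaneous objective terms x'Qx and alpha·u'Pu along the run.

    Evaluated on the recording grid with the Q and K active in each
    cycle (u = −Kx, P = I); both decay to ~0 on a converged run.  Summed
    over the three Cartesian axes.
    """
    if not traj.gains:
        raise ValueError("trajectory has no recorded gains")
    cfg = traj.config
    state_term = np.empty(len(traj.times))
    control_term = np.empty(len(traj.times))
    q_cache = [build_Q(cm, cfg.epsilon) for cm in traj.contact_maps[:len(traj.gains)]]
    for t_idx, t in enumerate(traj.times):
        c = min(traj.cycle_index(t), len(traj.gains) - 1)
        x = traj.states[t_idx]  # (n, 3)
        Q, K = q_cache[c], traj.gains[c].K
        state_term[t_idx] = np.einsum("ia,ij,ja->", x, Q, x)
        u = -K @ x
        control_term[t_idx] = cfg.alpha * np.einsum("ia,ia->", u, u)
    return pd.DataFrame(
        {"time": traj.times, "state_term": state_term, "control_term": control_term}
    )


def effective_contact_order(i: int, j: int, formed, n: int) -> int:
    """Shortest path between residues i and j given already-formed contacts.

    Edges are the covalent bonds plus every formed contact, all of unit
    weight.  With no formed contacts this is the plain contact order
    |i − j|; each formed contact can only shorten paths, so ECO measures
    the residual loop that must close — a proxy for the entropic cost of
    making the (i, j) contact.
    """
    if not (1 <= i <= n and 1 <= j <= n):
        raise ValueError(f"residues must lie in [1, {n}]")
    graph = nx.path_graph(range(1, n + 1))
    graph.add_edges_from((min(a, b), max(a, b)) for a, b in formed)
    return int(nx.shortest_path_length(graph, i, j))


def load_clusters(path) -> list[ClusterDefinition]:
    """Cluster definitions from a small YAML file.

    Expected form::

        clusters:
          - {name: T2, i_start: 45, i_end: 52, j_start: 45, j_end: 52}
          - {name: beta1-4, i_start: 3, i_end: 10, j_start: 46, j_end: 56}
    """
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    entries = raw["clusters"] if isinstance(raw, dict) else raw
    return [
        ClusterDefinition(
            name=str(e["name"]),
            i_range=(int(e["i_start"]), int(e["i_end"])),
            j_range=(int(e["j_start"]), int(e["j_end"])),
        )
        for e in entries
    ]
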