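"""Nested-cluster orderings: spherical, core and hydrogen-bond expansion,
plus DCA pseudo-distances.

Each expansion mode turns a structure (or a DCA score matrix) and a start
residue into a deterministic permutation of all polymer residues; the
prefixes of that permutation are the nested clusters scored by ICA.  All
ties are broken toward the smaller residue key so orderings are reproducible
and invariant under rigid motion and input re-ordering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .structure import (HydrogenBond, Residue, ResidueKey, StructureModel,
                        distance_matrix)

logger = logging.getLogger("sipris.expansion")

__all__ = [
    "ResidueOrdering",
    "DcaScores",
    "spherical_ordering",
    "core_ordering",
    "hbond_ordering",
    "dca_pseudo_distances",
    "dca_spherical_ordering",
    "dca_core_ordering",
    "load_dca_scores",
    "predefined_counts",
]


@dataclass(frozen=True)
class ResidueOrdering:
    """A permutation of residues induced by an expansion mode.

    ``order[0]`` is the start residue; the prefix of length t is the cluster
    at step t.  For hydrogen-bond modes ``reachable_count`` records how many
    residues are connected to the start through the bond network; the rest
    are appended by spatial distance so that L is preserved.
    """

    start: ResidueKey
    order: Tuple[ResidueKey, ...]
    mode: str
    reachable_count: int

    def __post_init__(self):
        if self.order[0] != self.start:
            raise ValueError("ordering must begin at the start residue")
        if len(set(self.order)) != len(self.order):
            raise ValueError("ordering is not a permutation")
        if self.reachable_count > len(self.order):
            raise ValueError("reachable_count exceeds ordering length")

    def __len__(self):
        return len(self.order)


@dataclass
class DcaScores:
    """Symmetric direct-coupling score matrix with a residue-key map."""

    matrix: np.ndarray
    keys: List[ResidueKey]

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("DCA score matrix must be square")
        if m.shape[0] != len(self.keys):
            raise ValueError("key map length must match matrix size")
        if not np.allclose(m, m.T, equal_nan=True):
            raise ValueError("DCA score matrix must be symmetric")
        self.matrix = m


# ---------------------------------------------------------------------------
# distance-matrix based orderings (shared by structural and DCA modes)
# ---------------------------------------------------------------------------

def _ordered_indices(keys: Sequence[ResidueKey]) -> np.ndarray:
    # index permutation sorting residues by key; used for deterministic ties
    return np.array(sorted(range(len(keys)), key=lambda i: keys[i]))


def _spherical_from_dmat(dmat: np.ndarray, keys: Sequence[ResidueKey],
                         start: ResidueKey, mode: str) -> ResidueOrdering:
    idx = {k: i for i, k in enumerate(keys)}
    if start not in idx:
        raise KeyError(f"start residue {start} not in model")
    s = idx[start]
    rest = [i for i in range(len(keys)) if i != s]
    rest.sort(key=lambda i: (dmat[s, i], keys[i]))
    order = (keys[s],) + tuple(keys[i] for i in rest)
    return ResidueOrdering(start=start, order=order, mode=mode,
                           reachable_count=len(order))


def _core_from_dmat(dmat: np.ndarray, keys: Sequence[ResidueKey],
                    start: ResidueKey, k: int, mode: str) -> ResidueOrdering:
    """Core expansion on an arbitrary distance matrix.

    At every step the cluster core is the start residue R plus every cluster
    residue whose distance to its k-th closest current-cluster member
    (excluding itself) is below R's; the nearest non-member to any core
    residue joins next.  While the cluster has <= k members the core is the
    whole cluster (the k-th neighbor is undefined there).
    """
    if k < 1:
        raise ValueError("neighbor rank k must be >= 1")
    n = len(keys)
    idx = {kk: i for i, kk in enumerate(keys)}
    if start not in idx:
        raise KeyError(f"start residue {start} not in model")
    if k >= n:
        logger.warning("k=%d >= L=%d: core rule degenerates to whole-cluster "
                       "growth", k, n)
    s = idx[start]
    cluster = [s]
    in_cluster = np.zeros(n, dtype=bool)
    in_cluster[s] = True
    order = [s]
    while len(cluster) < n:
        members = np.array(cluster)
        if len(cluster) <= k:
            core = members
        else:
            sub = dmat[np.ix_(members, members)].copy()
            np.fill_diagonal(sub, np.inf)
            dk = np.sort(sub, axis=1)[:, k - 1]  # k-th closest cluster member
            dk_start = dk[0]  # cluster[0] is the start residue
            core = members[(dk < dk_start) | (members == s)]
        outside = np.flatnonzero(~in_cluster)
        d_to_core = dmat[np.ix_(outside, core)].min(axis=1)
        cand = sorted(zip(d_to_core, (keys[i] for i in outside), outside))
        nxt = cand[0][2]
        cluster.append(int(nxt))
        in_cluster[nxt] = True
        order.append(int(nxt))
    return ResidueOrdering(start=start, order=tuple(keys[i] for i in order),
                           mode=mode, reachable_count=n)


def spherical_ordering(model: StructureModel, start: ResidueKey,
                       metric: str = "min-atom") -> ResidueOrdering:
    """Start followed by the remaining residues by ascending distance to the
    start; the start is the center of every nested cluster."""
    dmat = distance_matrix(model, metric)
    return _spherical_from_dmat(dmat, model.keys(), start, "spherical")


def core_ordering(model: StructureModel, start: ResidueKey, k: int = 7,
                  metric: str = "min-atom") -> ResidueOrdering:
    """Core expansion with neighbor rank ``k`` (default 7, chosen to avoid
    both spherical- and tentacle-shaped growth)."""
    dmat = distance_matrix(model, metric)
    return _core_from_dmat(dmat, model.keys(), start, k, "core")


# ---------------------------------------------------------------------------
# hydrogen-bond network expansion
# ---------------------------------------------------------------------------

def hbond_ordering(model: StructureModel, start: ResidueKey, mode: str = "H",
                   bonds: Optional[Sequence[HydrogenBond]] = None,
                   metric: str = "min-atom") -> ResidueOrdering:
    """Greedy hydrogen-bond-network expansion.

    Mode ``H`` uses sidechain-to-sidechain and sidechain-to-backbone bonds;
    mode ``B`` additionally admits backbone-to-backbone bonds.  At each step
    the residue joined to the cluster by the shortest donor-acceptor bond is
    appended (ties toward the smaller key).  Residues unreachable through
    the network are appended afterwards by ascending spatial distance to the
    start, so the ordering length always equals L.
    """
    if mode not in ("H", "B"):
        raise ValueError("hydrogen-bond mode must be 'H' or 'B'")
    if start not in model:
        raise KeyError(f"start residue {start} not in model")
    if bonds is None:
        from .structure import detect_hbonds
        bonds = detect_hbonds(model, include_bb_bb=(mode == "B"))
    allowed = {"sc-sc", "sc-bb"} | ({"bb-bb"} if mode == "B" else set())
    adj: Dict[ResidueKey, Dict[ResidueKey, float]] = {}
    for b in bonds:
        if b.klass not in allowed:
            continue
        u, v = b.residues()
        if u not in model or v not in model:
            continue
        d = b.da_distance
        adj.setdefault(u, {})
        adj.setdefault(v, {})
        if d < adj[u].get(v, np.inf):
            adj[u][v] = d
            adj[v][u] = d
    order = [start]
    in_cluster = {start}
    while True:
        best: Optional[Tuple[float, ResidueKey]] = None
        for member in order:
            for nb, d in adj.get(member, {}).items():
                if nb in in_cluster:
                    continue
                cand = (d, nb)
                if best is None or cand < best:
                    best = cand
        if best is None:
            break
        order.append(best[1])
        in_cluster.add(best[1])
    reachable = len(order)
    remaining = [k for k in model.keys() if k not in in_cluster]
    if remaining:
        dmat = distance_matrix(model, metric)
        idx = {k: i for i, k in enumerate(model.keys())}
        s = idx[start]
        remaining.sort(key=lambda kk: (dmat[s, idx[kk]], kk))
        order.extend(remaining)
    return ResidueOrdering(start=start, order=tuple(order),
                           mode=f"hbond-{mode}", reachable_count=reachable)


# ---------------------------------------------------------------------------
# DCA pseudo-distances
# ---------------------------------------------------------------------------

def dca_pseudo_distances(scores: DcaScores) -> np.ndarray:
    """Rank-based monotone-decreasing transform of coupling scores.

    The strongest-coupled pair receives pseudo-distance 1, the next 2, and
    so on; ties are broken by ascending index pair.  Orderings built on the
    result are therefore invariant under any strictly increasing rescaling
    of the scores.  The diagonal is 0.
    """
    m = scores.matrix
    n = m.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    pairs = sorted(zip(-m[iu, ju], iu, ju))  # descending score, then (i, j)
    out = np.zeros((n, n))
    for rank, (_, i, j) in enumerate(pairs, start=1):
        out[i, j] = out[j, i] = float(rank)
    return out


def dca_spherical_ordering(scores: DcaScores, start: ResidueKey) -> ResidueOrdering:
    pdist = dca_pseudo_distances(scores)
    o = _spherical_from_dmat(pdist, scores.keys, start, "dca-spherical")
    return o


def dca_core_ordering(scores: DcaScores, start: ResidueKey,
                      k: int = 7) -> ResidueOrdering:
    pdist = dca_pseudo_distances(scores)
    return _core_from_dmat(pdist, scores.keys, start, k, "dca-core")


def load_dca_scores(text: str, chain: str = "A") -> DcaScores:
    """Read DCA scores from plain text.

    Two layouts are accepted: a full whitespace-separated matrix whose first
    row is a header of residue numbers, or a 3-column ``i j score`` pair
    list (residue numbers; missing pairs default to the minimum score).
    """
    lines = [ln for ln in text.splitlines() if ln.strip() and
             not ln.lstrip().startswith("#")]
    if not lines:
        raise ValueError("empty DCA input")
    first = lines[0].split()
    is_matrix = False
    if len(lines) == len(first) + 1:
        try:
            [int(v) for v in first]
            is_matrix = all(len(ln.split()) == len(first) for ln in lines[1:])
        except ValueError:
            is_matrix = False
    if not is_matrix:
        if any(len(ln.split()) != 3 for ln in lines):
            raise ValueError("DCA input is neither a header+matrix block nor "
                             "a 3-column pair list")
        triples = [(int(a), int(b), float(s))
                   for a, b, s in (ln.split() for ln in lines)]
        nums = sorted({i for i, _, _ in triples} | {j for _, j, _ in triples})
        idx = {r: i for i, r in enumerate(nums)}
        n = len(nums)
        mat = np.full((n, n), min(s for _, _, s in triples))
        for i, j, s in triples:
            mat[idx[i], idx[j]] = mat[idx[j], idx[i]] = s
        np.fill_diagonal(mat, 0.0)
    else:
        nums = [int(v) for v in first]
        rows = [[float(v) for v in ln.split()] for ln in lines[1:]]
        mat = np.asarray(rows)
        if mat.shape != (len(nums), len(nums)):
            raise ValueError("DCA matrix body does not match header length")
        mat = (mat + mat.T) / 2.0
    keys = [ResidueKey(chain, r) for r in nums]
    return DcaScores(matrix=mat, keys=keys)


# ---------------------------------------------------------------------------
# predefined clusters
# ---------------------------------------------------------------------------

def predefined_counts(cluster: Set[ResidueKey], pattern,
                      model: StructureModel) -> Tuple[int, int, int, int]:
    """Counts (x, m, y, n) for a predefined cluster against a pattern set.

    x = cluster size, m = pattern residues inside the cluster, y and n the
    complements over the model's L residues and the pattern's D residues.
    Pattern residues absent from the model are excluded from D with a
    logged warning.
    """
    keys = set(model.keys())
    bad = [c for c in cluster if c not in keys]
    if bad:
        raise ValueError(f"cluster residues not in model: {sorted(bad)[:5]}")
    pat_keys = {e.residue for e in pattern.entries}
    missing = pat_keys - keys
    if missing:
        logger.warning("%d pattern residue(s) absent from structure, dropped: %s",
                       len(missing), sorted(missing))
        pat_keys -= missing
    L, D = len(keys), len(pat_keys)
    x = len(cluster)
    m = len(cluster & pat_keys)
    return x, m, L - x, D - m
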