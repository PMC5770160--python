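"""Tests for the nested-cluster expansion orderings and DCA transforms."""

import numpy as np
import pytest

from sipris import expansion as ex
from sipris import (DcaScores, FixtureSpec, ResidueKey, make_dca_matrix,
                    make_hbond_graph, make_structure)
from sipris.expansion import (core_ordering, dca_pseudo_distances,
                              dca_spherical_ordering, hbond_ordering,
                              load_dca_scores, predefined_counts,
                              spherical_ordering)
from sipris.structure import Residue, StructureModel, distance_matrix


def _model_from_points(points, chain="A"):
    residues = [Residue(key=ResidueKey(chain, i + 1), name="ALA",
                        atoms={"CA": np.asarray(p, dtype=float)},
                        elements={"CA": "C"})
                for i, p in enumerate(points)]
    return StructureModel(residues=residues, ligands=[])


# ---------------------------------------------------------------------------
# spherical expansion
# ---------------------------------------------------------------------------

def test_spherical_ordering_on_a_line():
    model = _model_from_points([(0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 0, 0)])
    o = spherical_ordering(model, ResidueKey("A", 1))
    assert [k.seqnum for k in o.order] == [1, 2, 3, 4]


def test_spherical_ordering_matches_argsort_oracle(cloud12):
    start = cloud12.keys()[3]
    o = spherical_ordering(cloud12, start)
    dmat = distance_matrix(cloud12)
    keys = cloud12.keys()
    expect = [keys[3]] + [keys[i] for i in
                          sorted((i for i in range(12) if i != 3),
                                 key=lambda i: (dmat[3, i], keys[i]))]
    assert list(o.order) == expect
    assert len(set(o.order)) == len(cloud12)


def test_spherical_ordering_tie_goes_to_smaller_key():
    model = _model_from_points([(0, 0, 0), (2, 0, 0), (-2, 0, 0)])
    o = spherical_ordering(model, ResidueKey("A", 1))
    assert [k.seqnum for k in o.order] == [1, 2, 3]


def test_spherical_ordering_unknown_start():
    model = _model_from_points([(0, 0, 0), (1, 0, 0)])
    with pytest.raises(KeyError):
        spherical_ordering(model, ResidueKey("B", 9))


# ---------------------------------------------------------------------------
# core expansion
# ---------------------------------------------------------------------------

def oracle_core_ordering(dmat, keys, start_i, k):
    """Literal step-by-step re-implementation of the core rule."""
    n = len(keys)
    cluster = [start_i]
    while len(cluster) < n:
        if len(cluster) <= k:
            core = list(cluster)
        else:
            def dk(i):
                ds = sorted(dmat[i, j] for j in cluster if j != i)
                return ds[k - 1]
            core = [i for i in cluster if i == start_i or dk(i) < dk(start_i)]
        outside = [i for i in range(n) if i not in cluster]
        best = min(outside,
                   key=lambda i: (min(dmat[i, j] for j in core), keys[i]))
        cluster.append(best)
    return [keys[i] for i in cluster]


def test_core_first_appended_is_nearest_to_start(cloud12):
    start = cloud12.keys()[0]
    sph = spherical_ordering(cloud12, start)
    core = core_ordering(cloud12, start, k=7)
    assert core.order[:2] == sph.order[:2]


@pytest.mark.parametrize("k", [1, 2, 7])
def test_core_ordering_matches_literal_oracle(k):
    model = make_structure(FixtureSpec(n_residues=15, geometry="random-cloud",
                                       seed=21))
    keys = model.keys()
    dmat = distance_matrix(model)
    start = keys[4]
    got = core_ordering(model, start, k=k)
    expect = oracle_core_ordering(dmat, keys, 4, k)
    assert list(got.order) == expect


def test_core_k1_differs_from_spherical_on_helix(helix30):
    # with k=1 the cluster grows from its frontier, not radially
    start = helix30.keys()[0]
    sph = spherical_ordering(helix30, start)
    core = core_ordering(helix30, start, k=1)
    assert sph.order[:2] == core.order[:2]
    assert list(sph.order) != list(core.order)


def test_core_k_exceeding_L_falls_back_to_whole_cluster_growth(caplog):
    model = _model_from_points([(0, 0, 0), (1, 0, 0), (2.5, 0, 0)])
    o = core_ordering(model, ResidueKey("A", 1), k=10)
    assert len(set(o.order)) == 3


# ---------------------------------------------------------------------------
# hydrogen-bond expansion
# ---------------------------------------------------------------------------

def test_hbond_ordering_chain_graph_forced_order(helix30):
    keys = helix30.keys()
    edges = [(keys[0], keys[5], 2.9, "sc-sc"),
             (keys[5], keys[9], 3.1, "sc-bb")]
    bonds = make_hbond_graph(helix30, edges)
    o = hbond_ordering(helix30, keys[0], mode="H", bonds=bonds)
    assert o.order[:3] == (keys[0], keys[5], keys[9])
    assert o.reachable_count == 3
    assert len(o.order) == 30  # unreachable residues appended


def test_hbond_ordering_star_graph_greedy_by_bond_length(helix30):
    keys = helix30.keys()
    edges = [(keys[0], keys[10], 3.3, "sc-sc"),
             (keys[0], keys[20], 2.7, "sc-sc"),
             (keys[0], keys[15], 3.0, "sc-bb")]
    bonds = make_hbond_graph(helix30, edges)
    o = hbond_ordering(helix30, keys[0], mode="H", bonds=bonds)
    assert o.order[1:4] == (keys[20], keys[15], keys[10])


def test_hbond_ordering_matches_bruteforce_greedy():
    model = make_structure(FixtureSpec(n_residues=8, geometry="random-cloud",
                                       seed=6))
    keys = model.keys()
    rng = np.random.default_rng(2)
    edges = []
    pairs = [(0, 1), (1, 2), (0, 3), (3, 4), (2, 5), (5, 6), (4, 6), (1, 7)]
    for (i, j), d in zip(pairs, rng.uniform(2.6, 3.4, len(pairs))):
        edges.append((keys[i], keys[j], float(d), "sc-sc"))
    bonds = make_hbond_graph(model, edges)
    o = hbond_ordering(model, keys[0], mode="H", bonds=bonds)

    # independent greedy oracle
    adj = {}
    for a, b, d, _ in edges:
        adj.setdefault(a, []).append((b, d))
        adj.setdefault(b, []).append((a, d))
    cluster = [keys[0]]
    while True:
        cands = [(d, nb) for m in cluster for nb, d in adj.get(m, [])
                 if nb not in cluster]
        if not cands:
            break
        cluster.append(min(cands)[1])
    assert list(o.order[:len(cluster)]) == cluster
    assert o.reachable_count == len(cluster)


def test_hbond_mode_B_extends_reach_through_backbone_bonds(helix30):
    keys = helix30.keys()
    edges = [(keys[0], keys[3], 2.9, "sc-sc"),
             (keys[3], keys[6], 3.0, "bb-bb")]
    bonds = make_hbond_graph(helix30, edges)
    oh = hbond_ordering(helix30, keys[0], mode="H", bonds=bonds)
    ob = hbond_ordering(helix30, keys[0], mode="B", bonds=bonds)
    assert oh.reachable_count == 2
    assert ob.reachable_count == 3


# ---------------------------------------------------------------------------
# DCA pseudo-distances
# ---------------------------------------------------------------------------

def test_dca_pseudo_distances_monotone_and_rank_invariant():
    rng = np.random.default_rng(1)
    n = 10
    m = rng.normal(size=(n, n))
    m = (m + m.T) / 2
    keys = [ResidueKey("A", i + 1) for i in range(n)]
    scores = DcaScores(matrix=m, keys=keys)
    pd1 = dca_pseudo_distances(scores)
    assert np.allclose(pd1, pd1.T)
    iu, ju = np.triu_indices(n, 1)
    top = np.unravel_index(np.argmax(np.where(np.eye(n, dtype=bool), -np.inf, m)),
                           (n, n))
    assert pd1[top] == 1.0
    # strictly increasing rescale leaves pseudo-distances untouched
    scores2 = DcaScores(matrix=np.exp(3 * m), keys=keys)
    assert np.array_equal(pd1, dca_pseudo_distances(scores2))


def test_dca_spherical_ordering_equals_argsort_of_negated_scores():
    rng = np.random.default_rng(7)
    n = 10
    m = rng.normal(size=(n, n))
    m = (m + m.T) / 2
    keys = [ResidueKey("A", i + 1) for i in range(n)]
    scores = DcaScores(matrix=m, keys=keys)
    start = keys[2]
    o = dca_spherical_ordering(scores, start)
    expect = [keys[2]] + [keys[i] for i in
                          sorted((i for i in range(n) if i != 2),
                                 key=lambda i: -m[2, i])]
    assert list(o.order) == expect


def test_dca_noise_free_matrix_reproduces_structural_ordering(helix30):
    dca = make_dca_matrix(helix30, noise_sd=0.0, seed=0)
    start = helix30.keys()[10]
    assert dca_spherical_ordering(dca, start).order \
        == spherical_ordering(helix30, start).order


def test_load_dca_scores_matrix_and_pairlist_roundtrip():
    header = "10 11 12"
    body = ["0 1.5 0.2", "1.5 0 0.9", "0.2 0.9 0"]
    d1 = load_dca_scores("\n".join([header] + body))
    assert d1.matrix[0, 1] == 1.5
    assert [k.seqnum for k in d1.keys] == [10, 11, 12]
    pairs = "10 11 1.5\n10 12 0.2\n11 12 0.9\n"
    d2 = load_dca_scores(pairs)
    assert np.allclose(d1.matrix, d2.matrix)
    with pytest.raises(ValueError):
        DcaScores(matrix=np.ones((2, 3)), keys=[ResidueKey("A", 1)] * 2)


# ---------------------------------------------------------------------------
# shared ordering properties
# ---------------------------------------------------------------------------

def _all_orderings(model, start, bonds):
    return [spherical_ordering(model, start),
            core_ordering(model, start, k=3),
            hbond_ordering(model, start, mode="H", bonds=bonds)]


def test_orderings_are_permutations_and_rigid_motion_invariant():
    spec = FixtureSpec(n_residues=14, geometry="random-cloud", seed=30)
    model = make_structure(spec)
    keys = model.keys()
    bonds = make_hbond_graph(model, [(keys[0], keys[4], 2.8, "sc-sc"),
                                     (keys[4], keys[8], 3.2, "sc-bb")])
    ref = _all_orderings(model, keys[0], bonds)
    for o in ref:
        assert sorted(o.order) == sorted(keys)
        assert o.order[0] == keys[0]
    # rigid motion
    th = np.radians(75.0)
    R = np.array([[1, 0, 0],
                  [0, np.cos(th), -np.sin(th)],
                  [0, np.sin(th), np.cos(th)]])
    moved = StructureModel(residues=[
        Residue(key=r.key, name=r.name,
                atoms={a: R @ c + np.array([11.0, -4.0, 2.0])
                       for a, c in r.atoms.items()},
                elements=dict(r.elements))
        for r in model.residues], ligands=[])
    for o_ref, o_mv in zip(ref, _all_orderings(moved, keys[0], bonds)):
        assert o_ref.order == o_mv.order


def test_orderings_invariant_under_residue_input_reordering():
    spec = FixtureSpec(n_residues=10, geometry="random-cloud", seed=33)
    model = make_structure(spec)
    shuffled = StructureModel(residues=list(reversed(model.residues)),
                              ligands=[])
    start = model.keys()[0]
    assert spherical_ordering(model, start).order \
        == spherical_ordering(shuffled, start).order


# ---------------------------------------------------------------------------
# predefined counts
# ---------------------------------------------------------------------------

def test_predefined_counts_published_style_counts():
    """128 residues, 57-residue cluster containing 22 of 25 pattern
    residues -> (57, 22, 71, 3)."""
    from sipris.pattern_io import PatternEntry, PatternSet
    model = make_structure(FixtureSpec(n_residues=128,
                                       geometry="cubic-lattice", seed=0))
    keys = model.keys()
    cluster = set(keys[:57])
    pat_keys = keys[:22] + keys[60:63]
    pattern = PatternSet(entries=tuple(
        PatternEntry(residue=k, level=1, rank=i + 1, score=10.0 - i * 0.1)
        for i, k in enumerate(pat_keys)))
    assert predefined_counts(cluster, pattern, model) == (57, 22, 71, 3)


def test_predefined_counts_empty_cluster_and_missing_pattern(caplog):
    from sipris.pattern_io import PatternEntry, PatternSet
    model = make_structure(FixtureSpec(n_residues=20, seed=0))
    keys = model.keys()
    pattern = PatternSet(entries=(
        PatternEntry(residue=keys[0], level=1, rank=1, score=5.0),
        PatternEntry(residue=ResidueKey("Z", 999), level=1, rank=2, score=4.0),
    ))
    x, m, y, n = predefined_counts(set(), pattern, model)
    assert (x, m, y) == (0, 0, 20)
    assert n == 1  # the unmappable residue was dropped from D
    assert "absent from structure" in caplog.text


def test_predefined_counts_random_sets_match_set_algebra():
    from sipris.pattern_io import PatternEntry, PatternSet
    rng = np.random.default_rng(17)
    model = make_structure(FixtureSpec(n_residues=40, seed=3))
    keys = model.keys()
    for _ in range(10):
        cl = {keys[i] for i in rng.choice(40, rng.integers(0, 30),
                                          replace=False)}
        pi = [keys[i] for i in rng.choice(40, 8, replace=False)]
        pattern = PatternSet(entries=tuple(
            PatternEntry(residue=k, level=1, rank=j + 1, score=1.0)
            for j, k in enumerate(pi)))
        x, m, y, n = predefined_counts(cl, pattern, model)
        assert x == len(cl) and m == len(cl & set(pi))
        assert x + y == 40 and m + n == 8
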