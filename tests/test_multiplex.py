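"""Multiplex assembly, degree PMFs and interlayer mutual information."""

import numpy as np
import pytest

from muxvis import (build_multiplex, degree_pmf, hvg, interlayer_mi,
                    mi_matrix, network_avg_mi, nvg_naive, read_mi_matrix,
                    subject_network_mi, write_mi_matrix)
from muxvis.multiplex import MIMatrix, _mi_from_degrees

from conftest import brute_mi


def test_identical_columns_give_identical_layers(rng):
    col = rng.standard_normal(30)
    mvg = build_multiplex(np.column_stack([col] * 3))
    ref = mvg.layers[0].edge_set()
    assert all(l.edge_set() == ref for l in mvg.layers)


def test_per_column_layers_match_single_series_graphs():
    data = np.column_stack([[1, 2, 3, 4], [3, 1, 2, 4]])
    mvg = build_multiplex(data)
    assert mvg.layers[0].edge_set() == {(0, 1), (1, 2), (2, 3)}
    assert mvg.layers[1].edge_set() == nvg_naive([3, 1, 2, 4]).edge_set()


def test_two_point_series_layers_are_single_edges(rng):
    mvg = build_multiplex(rng.standard_normal((2, 5)))
    assert all(l.edge_set() == {(0, 1)} for l in mvg.layers)


def test_build_multiplex_input_errors(rng):
    with pytest.raises(ValueError, match="non-finite"):
        build_multiplex([[1.0, np.nan], [2.0, 3.0]])
    with pytest.raises(ValueError, match="label length"):
        build_multiplex(rng.standard_normal((5, 3)), roi_labels=["a"])
    with pytest.raises(ValueError):
        build_multiplex(np.empty((0, 2)))


def test_degree_pmf_examples():
    chain = nvg_naive([1, 2, 3, 4])
    assert degree_pmf(chain).as_dict() == {1: 0.5, 2: 0.5}
    k3 = nvg_naive([0, 1, 4])  # complete on 3 nodes
    assert degree_pmf(k3).as_dict() == {2: 1.0}
    assert degree_pmf(hvg([1, 3, 2, 4])).as_dict() == {1: 0.25, 2: 0.5, 3: 0.25}


def test_self_mi_is_entropy_ln2():
    chain = nvg_naive([1, 2, 3, 4])  # degree PMF {1: .5, 2: .5}
    assert interlayer_mi(chain, chain) == pytest.approx(np.log(2), abs=1e-15)


def test_mi_against_constant_degree_layer_is_zero(rng):
    k3 = nvg_naive([0, 1, 4])
    other = nvg_naive(rng.standard_normal(3))
    assert interlayer_mi(k3, other) == 0.0


def test_factorizing_joint_gives_zero_mi():
    assert _mi_from_degrees(np.array([1, 2, 2, 1]),
                            np.array([1, 2, 1, 2]), None) == 0.0


def test_mi_matches_brute_force_definition(rng):
    for _ in range(20):
        ka = rng.integers(1, 6, size=40)
        kb = rng.integers(1, 6, size=40)
        assert _mi_from_degrees(ka, kb, None) == pytest.approx(
            brute_mi(ka.tolist(), kb.tolist()), abs=1e-12)


def test_mi_base2_option():
    chain = nvg_naive([1, 2, 3, 4])
    assert interlayer_mi(chain, chain, base=2) == pytest.approx(1.0)


def test_mi_matrix_symmetry_diagonal_and_nonnegativity(rng):
    mvg = build_multiplex(rng.standard_normal((60, 5)))
    mm = mi_matrix(mvg)
    assert np.array_equal(mm.values, mm.values.T)
    assert np.all(mm.values >= 0)
    for a in range(5):
        assert mm.values[a, a] == pytest.approx(
            degree_pmf(mvg.layers[a]).entropy(), abs=1e-12)


def test_independent_long_layers_have_mi_below_self_mi(rng):
    data = rng.standard_normal((10_000, 2))
    mm = mi_matrix(build_multiplex(data))
    assert mm.values[0, 1] < min(mm.values[0, 0], mm.values[1, 1])


def test_identical_layers_network_average_is_entropy(rng):
    col = rng.standard_normal(40)
    mvg = build_multiplex(np.column_stack([col] * 3),
                          network_labels=["n"] * 3)
    mm = mi_matrix(mvg)
    h = degree_pmf(mvg.layers[0]).entropy()
    assert h > 0
    assert network_avg_mi(mm, "n") == pytest.approx(h, abs=1e-12)
    off = mm.values[np.triu_indices(3, k=1)]
    assert np.allclose(off, h)


def test_network_average_arithmetic_and_errors():
    vals = np.array([[0.7, 0.1, 0.2], [0.1, 0.8, 0.3], [0.2, 0.3, 0.9]])
    mm = MIMatrix(vals, ("a", "b", "c"), ("n", "n", "n"))
    assert network_avg_mi(mm, "n") == pytest.approx(0.2)
    with pytest.raises(KeyError):
        network_avg_mi(mm, "missing")
    single = MIMatrix(vals, ("a", "b", "c"), ("n", "n", "solo"))
    assert network_avg_mi(single, "n") == pytest.approx(0.1)  # 2-ROI network
    with pytest.raises(ValueError, match="single ROI"):
        network_avg_mi(single, "solo")


def test_subject_network_mi_matches_full_matrix_route(rng):
    data = rng.standard_normal((70, 6))
    nets = ["x", "x", "x", "y", "y", "y"]
    mvg = build_multiplex(data, network_labels=nets)
    mm = mi_matrix(mvg)
    fast = subject_network_mi(data, nets)
    for net in ("x", "y"):
        assert fast[net] == pytest.approx(network_avg_mi(mm, net), abs=1e-12)


def test_mi_matrix_roundtrip(tmp_path, rng):
    mm = mi_matrix(build_multiplex(rng.standard_normal((50, 4)),
                                   roi_labels=list("abcd"),
                                   network_labels=["p", "p", "q", "q"]))
    write_mi_matrix(mm, tmp_path / "mi.csv", tmp_path / "mi.json",
                    method="natural", n_nodes=50)
    back = read_mi_matrix(tmp_path / "mi.csv", tmp_path / "mi.json")
    assert np.allclose(back.values, mm.values)
    assert back.roi_labels == mm.roi_labels
    assert back.network_labels == mm.network_labels
    assert back.units == "nats"
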