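"""Table validation, I/O round-trips, splits, and graph checks."""

import numpy as np
import pandas as pd
import pytest

from dwmerge.exceptions import GraphError, SchemaError, ValidationError
from dwmerge.refl_io import (DatasetGraph, GraphEdge, ReflectionTable,
                             assign_test_set, duplicate_control_node,
                             read_reflection_table, split_friedel_halves,
                             validate_graph, write_reflection_table)


def test_read_write_round_trip(toy_table, tmp_path):
    path = tmp_path / "t.csv"
    write_reflection_table(toy_table, path)
    back = read_reflection_table(path)
    assert len(back) == len(toy_table)
    for col in toy_table.data.columns:
        a, b = toy_table.data[col], back.data[col]
        if a.dtype.kind == "f":
            np.testing.assert_allclose(a, b, rtol=1e-12)
        else:
            assert (a == b).all()


def test_missing_column_is_schema_error(toy_table, tmp_path):
    df = toy_table.data.drop(columns=["epsilon"])
    path = tmp_path / "bad.csv"
    df.to_csv(path, index=False)
    with pytest.raises(SchemaError, match="epsilon"):
        read_reflection_table(path)


def test_nonpositive_sigma_is_whole_file_error(toy_table):
    df = toy_table.data.copy()
    df.loc[3, "sigI"] = 0.0
    with pytest.raises(ValidationError, match="row: 3"):
        ReflectionTable.from_frame(df)


def test_duplicate_observation_rejected(toy_table):
    df = pd.concat([toy_table.data, toy_table.data.iloc[[0]]],
                   ignore_index=True)
    with pytest.raises(ValidationError, match="duplicate"):
        ReflectionTable.from_frame(df)


def test_inconsistent_centric_flag_rejected(toy_table):
    df = toy_table.data.copy()
    df.loc[0, "centric"] = not df.loc[0, "centric"]
    with pytest.raises(ValidationError, match="centric"):
        ReflectionTable.from_frame(df)


def test_split_friedel_halves_conserves_rows(toy_table):
    plus, minus = split_friedel_halves(toy_table)
    assert len(plus) + len(minus) == len(toy_table)
    assert set(plus.data["friedel_sign"]) == {"+"}
    assert set(minus.data["friedel_sign"]) == {"-"}
    assert all(ds.endswith("_plus") for ds in plus.data["dataset_id"])


def test_split_friedel_single_sign_warns(toy_table):
    only_plus = ReflectionTable(
        toy_table.data[toy_table.data["friedel_sign"] == "+"]
        .reset_index(drop=True))
    with pytest.warns(UserWarning, match="one Friedel sign"):
        plus, minus = split_friedel_halves(only_plus)
    assert len(minus) == 0


def test_split_friedel_empty_table():
    empty = ReflectionTable(pd.DataFrame(columns=list(
        ("h", "k", "l", "friedel_sign", "dataset_id", "image_id", "I", "sigI",
         "centric", "epsilon", "d"))))
    plus, minus = split_friedel_halves(empty)
    assert len(plus) == 0 and len(minus) == 0


def test_assign_test_set_size_determinism_and_seed_sensitivity(toy_table):
    train, test = assign_test_set(toy_table, 0.25, seed=7)
    assert len(test) == round(0.25 * len(toy_table))
    assert len(train) + len(test) == len(toy_table)
    train2, test2 = assign_test_set(toy_table, 0.25, seed=7)
    pd.testing.assert_frame_equal(test.data, test2.data)
    # over 20 seed pairs, the partitions should differ essentially always
    differs = 0
    for s in range(20):
        _, a = assign_test_set(toy_table, 0.25, seed=s)
        _, b = assign_test_set(toy_table, 0.25, seed=s + 100)
        differs += not a.data.equals(b.data)
    assert differs >= 18
    with pytest.raises(ValueError):
        assign_test_set(toy_table, 1.5, seed=0)


def test_validate_graph_orders_and_rejects(toy_table):
    g = validate_graph(DatasetGraph(["apo", "holo"],
                                    [GraphEdge("apo", "holo", 0.9)]), toy_table)
    assert g.order == ["apo", "holo"]
    with pytest.raises(GraphError, match="no rows"):
        validate_graph(DatasetGraph(["apo", "ghost"], []), toy_table)
    with pytest.raises(GraphError, match="more than one parent"):
        DatasetGraph(["a", "b", "c"],
                     [GraphEdge("a", "c", 0.5), GraphEdge("b", "c", 0.5)])
    with pytest.raises(GraphError):
        DatasetGraph(["a", "b"], [GraphEdge("a", "b", 1.0)])


def test_cycle_detection():
    df_rows = []
    for ds in ("a", "b"):
        df_rows.append((1, 0, 0, "+", ds, 0, 1.0, 0.1, False, 1, 2.0))
    t = ReflectionTable.from_frame(pd.DataFrame(df_rows, columns=[
        "h", "k", "l", "friedel_sign", "dataset_id", "image_id", "I", "sigI",
        "centric", "epsilon", "d"]))
    g = DatasetGraph(["a", "b"], [GraphEdge("a", "b", 0.5),
                                  GraphEdge("b", "a", 0.5)])
    with pytest.raises(GraphError, match="cycle"):
        validate_graph(g, t)


def test_chain_topological_order():
    nodes = list("abcde")
    rows = [(1, 0, 0, "+", ds, 0, 1.0, 0.1, False, 1, 2.0) for ds in nodes]
    t = ReflectionTable.from_frame(pd.DataFrame(rows, columns=[
        "h", "k", "l", "friedel_sign", "dataset_id", "image_id", "I", "sigI",
        "centric", "epsilon", "d"]))
    edges = [GraphEdge(a, b, 0.5) for a, b in zip(nodes[:-1], nodes[1:])]
    g = validate_graph(DatasetGraph(nodes, edges), t)
    assert g.order == nodes


def test_duplicate_control_node_round_trip(toy_table, toy_graph):
    n_apo = (toy_table.data["dataset_id"] == "apo").sum()
    t2, g2 = duplicate_control_node(toy_table, toy_graph, "apo",
                                    sigma_multiplier=2.0)
    ctrl = t2.data[t2.data["dataset_id"] == "apo_ctrl"]
    apo = t2.data[t2.data["dataset_id"] == "apo"]
    assert len(ctrl) == n_apo
    np.testing.assert_allclose(ctrl["sigI"].to_numpy(),
                               2.0 * apo["sigI"].to_numpy())
    assert g2.parent_of("apo_ctrl") == "apo"
    # removing the new node restores the original table
    restored = t2.data[t2.data["dataset_id"] != "apo_ctrl"]
    pd.testing.assert_frame_equal(restored.reset_index(drop=True),
                                  toy_table.data)
    # multiplier 1 leaves sigI unchanged
    t3, _ = duplicate_control_node(toy_table, toy_graph, "apo",
                                   sigma_multiplier=1.0)
    ctrl3 = t3.data[t3.data["dataset_id"] == "apo_ctrl"]
    np.testing.assert_allclose(ctrl3["sigI"].to_numpy(), apo["sigI"].to_numpy())
    with pytest.raises(GraphError):
        duplicate_control_node(toy_table, toy_graph, "nope")


def test_graph_config_round_trip(toy_graph):
    d = toy_graph.to_dict()
    back = DatasetGraph.from_dict(d)
    assert back.nodes == toy_graph.nodes
    assert back.edges == toy_graph.edges
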