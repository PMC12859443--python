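import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cogvec import (
    AlphabetCapacityError,
    SymbolAlphabet,
    build_inventory,
    build_model,
    encode_binary,
    encode_bitvector,
    kappa_partition,
    random_tree,
    read_phylip,
    simulate_cognate_dataset,
    simulate_matrix,
    state_to_symbol,
    symbol_to_state,
    write_phylip,
)
from cogvec.encoding import MISSING_CODE
from cogvec.simulate import SimulationConfig


def test_inventory_union_and_sort(toy_dataset):
    inv = build_inventory(toy_dataset)
    assert inv.classes["hand"] == ("a", "b", "c")
    assert inv.kappa("hand") == 3
    assert inv.kappa("stone") == 1


def test_inventory_drops_unattested_concept(toy_dataset):
    ds = toy_dataset
    ds.concepts.append("ghost")
    with pytest.warns(UserWarning, match="ghost"):
        inv = build_inventory(ds)
    assert "ghost" not in inv


def test_encode_binary_rows(toy_dataset):
    inv = build_inventory(toy_dataset)
    mat = encode_binary(toy_dataset, inv)
    cols = {col: j for j, col in enumerate(mat.columns)}
    l1 = mat.taxa.index("l1")
    l3 = mat.taxa.index("l3")
    # l1/hand = {a, b} over (a, b, c) -> 1 1 0
    assert [mat.data[l1, cols[("hand", c)]] for c in "abc"] == [1, 1, 0]
    # l3/water missing -> '-' on every water column
    water_cols = [j for (concept, _), j in cols.items() if concept == "water"]
    assert all(mat.data[l3, j] == MISSING_CODE for j in water_cols)


def test_binary_column_count_is_sum_of_kappas(toy_dataset):
    inv = build_inventory(toy_dataset)
    mat = encode_binary(toy_dataset, inv)
    assert mat.n_columns == sum(inv.kappa(c) for c in inv.concept_order)


@pytest.mark.parametrize(
    "state, expected",
    [({"C"}, 0), ({"A"}, 3), ({"A", "B", "C"}, 6), ({"B"}, 1), ({"A", "C"}, 4)],
)
def test_state_to_symbol_msb_convention(state, expected):
    assert state_to_symbol(state, ("A", "B", "C")) == expected


@pytest.mark.parametrize("kappa", [2, 3, 4, 5, 6])
def test_symbol_bijection_covers_index_range(kappa):
    order = tuple(f"k{i}" for i in range(kappa))
    seen = set()
    for r in range(1, kappa + 1):
        for combo in itertools.combinations(order, r):
            idx = state_to_symbol(set(combo), order)
            assert symbol_to_state(idx, order) == frozenset(combo)
            seen.add(idx)
    assert seen == set(range(2**kappa - 1))
    # the all-ones state sits exactly at the top index
    assert state_to_symbol(set(order), order) == 2**kappa - 2


def test_kappa_partition_grouping():
    from cogvec.encoding import ConceptInventory

    inv = ConceptInventory(
        {
            "c1": ("a", "b"),
            "c2": ("a", "b", "c"),
            "c3": ("x", "y"),
            "c4": ("z",),
            "c5": tuple("abcdefg"),
        }
    )
    part = kappa_partition(inv)
    assert part.subsets == {2: ["c1", "c3"], 3: ["c2"]}
    assert part.excluded_singleton == ["c4"]
    assert part.excluded_large == ["c5"]


def test_kappa_six_is_admissible_but_seven_is_not(toy_dataset):
    assert SymbolAlphabet().max_kappa() == 6
    inv = build_inventory(toy_dataset)
    with pytest.raises(AlphabetCapacityError):
        encode_bitvector(toy_dataset, inv, 7)


def test_encode_bitvector_entries(toy_dataset):
    inv = build_inventory(toy_dataset)
    mat = encode_bitvector(toy_dataset, inv, 3)
    assert mat.concepts == ["hand", "sun"]
    row = {t: i for i, t in enumerate(mat.taxa)}
    hand = mat.concepts.index("hand")
    # l1 {a,b} over (a,b,c): b=110 -> index 5; l2 {a}: 100 -> 3; l3 {c}: 001 -> 0
    assert mat.data[row["l1"], hand] == 5
    assert mat.data[row["l2"], hand] == 3
    assert mat.data[row["l3"], hand] == 0


def test_encode_bitvector_missing(toy_dataset):
    inv = build_inventory(toy_dataset)
    mat = encode_bitvector(toy_dataset, inv, 2)
    assert mat.concepts == ["water"]
    row = {t: i for i, t in enumerate(mat.taxa)}
    assert mat.data[row["l3"], 0] == MISSING_CODE


def test_popcount_consistency_between_encodings():
    config = SimulationConfig(seed=42, n_taxa=8, branch_mean=1.0,
                              concepts_per_kappa={2: 8, 3: 8})
    dataset, _ = simulate_cognate_dataset(config)
    inv = build_inventory(dataset)
    binary = encode_binary(dataset, inv)
    col_of = {}
    for j, (concept, cls) in enumerate(binary.columns):
        col_of.setdefault(concept, []).append(j)
    for kappa in (2, 3):
        bv = encode_bitvector(dataset, inv, kappa)
        for i, taxon in enumerate(bv.taxa):
            bi = binary.taxa.index(taxon)
            for j, concept in enumerate(bv.concepts):
                sym = bv.data[i, j]
                ones = int((binary.data[bi, col_of[concept]] == 1).sum())
                if sym == MISSING_CODE:
                    assert ones == 0
                else:
                    assert bin(sym + 1).count("1") == ones


@settings(max_examples=20, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_phylip_round_trip_bitvector(tmp_path_factory, seed):
    tree = random_tree(5, 0.3, seed=seed)
    model = build_model("MK", 3)
    mat = simulate_matrix(tree, model, 8, 0.2, seed=seed)
    path = tmp_path_factory.mktemp("phy") / "m.phy"
    write_phylip(mat, path)
    back = read_phylip(path, "bitvector", kappa=3)
    assert back == mat


def test_phylip_round_trip_binary(tmp_path, toy_dataset):
    inv = build_inventory(toy_dataset)
    mat = encode_binary(toy_dataset, inv)
    path = tmp_path / "b.phy"
    write_phylip(mat, path)
    back = read_phylip(path, "binary")
    assert np.array_equal(back.data, mat.data)
    assert back.taxa == mat.taxa
    header = path.read_text().splitlines()[0]
    assert header == f"{len(mat.taxa)} {mat.n_columns}"


def test_phylip_duplicate_taxa_rejected(tmp_path, toy_dataset):
    inv = build_inventory(toy_dataset)
    mat = encode_binary(toy_dataset, inv)
    mat.taxa[1] = mat.taxa[0]
    from cogvec import FormatError

    with pytest.raises(FormatError):
        write_phylip(mat, tmp_path / "dup.phy")
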