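"""Space-time tiles, the wavefront schedule and the tiled executor."""

import numpy as np
import pytest

from nusstile.bench import random_rna
from nusstile.fold import fold_reference
from nusstile.iterspace import (
    S1,
    S2,
    dependence_pairs,
    domain_size,
    enumerate_domain,
)
from nusstile.tiling import (
    TilingParams,
    enumerate_tiles,
    execute_tiled,
    lexicographic_ranks,
    partition_report,
    schedule_matrix,
    schedule_tuple,
    tile_of_instance,
    tile_stats,
    validate_schedule,
)


def test_tile_coordinates_examples():
    p40 = TilingParams(40, 16, 16)
    assert tile_of_instance(S1(30, 35, 2), p40) == (0, 0, 5, 0)
    assert tile_of_instance(S2(0, 39), p40) == (2, 2, 39, 2)
    assert tile_of_instance(S1(15, 16, 0), TilingParams(17, 16, 16)) == (0, 0, 1, 0)


def test_tile_of_instance_rejects_outside_domain():
    with pytest.raises(ValueError):
        tile_of_instance(S1(5, 3, 0), TilingParams(10))


def test_schedule_tuple_examples():
    p = TilingParams(40, 16, 16)
    assert schedule_tuple(S1(30, 35, 2), p) == (0, 0, 5, 0, 30, 35, 0, 2)
    p4 = TilingParams(4, 16, 16)
    assert schedule_tuple(S1(1, 2, 0), p4) < schedule_tuple(S2(1, 2), p4)


@pytest.mark.parametrize("n,ws,wt", [(9, 2, 3), (17, 16, 16), (23, 4, 4)])
def test_schedule_tuples_are_distinct(n, ws, wt):
    p = TilingParams(n, ws, wt)
    tuples = [schedule_tuple(x, p) for x in enumerate_domain(n)]
    assert len(set(tuples)) == len(tuples)
    mat = schedule_matrix(p)
    assert [tuple(int(v) for v in row) for row in mat] == tuples


def test_single_tile_for_n2():
    tiles = enumerate_tiles(TilingParams(2, 16, 16))
    assert len(tiles) == 1
    assert set(tiles[0].instances) == {S1(0, 1, 0), S2(0, 1)}


@pytest.mark.parametrize("n,ws,wt", [(7, 2, 2), (12, 3, 2), (17, 16, 16), (40, 16, 16)])
def test_tiles_partition_and_agree_with_coordinate_map(n, ws, wt):
    """Tiles generated from band bounds hold exactly the instances that
    tile_of_instance assigns to them, and together cover the domain once."""
    p = TilingParams(n, ws, wt)
    tiles = enumerate_tiles(p)
    seen = []
    for tile in tiles:
        assert tile.instances  # nonempty only
        for inst in tile.instances:
            assert tile_of_instance(inst, p) == (tile.ii, tile.jj, tile.i0, tile.tt)
        seen.extend(tile.instances)
    assert sorted(seen) == sorted(enumerate_domain(n))
    assert len(seen) == len(set(seen))
    keys = [(t.wavefront, t.jj, t.i0, t.tt) for t in tiles]
    assert keys == sorted(keys)
    assert partition_report(p).ok


def test_max_s1_count_bounded_by_widths():
    p = TilingParams(40, 16, 16)
    for tile in enumerate_tiles(p):
        s1_count = sum(1 for x in tile.instances if x.k is not None)
        assert s1_count <= p.ws * p.wt


def test_validate_schedule_small_cases():
    assert validate_schedule(TilingParams(20, 4, 4)).ok
    assert validate_schedule(TilingParams(3, 1, 1)).ok


def test_reversed_wavefront_order_is_caught():
    """Negating the serial wavefront coordinate breaks dependences, which
    the rank check must detect."""
    p = TilingParams(20, 4, 4)
    tuples = schedule_matrix(p)
    tuples[:, 0] *= -1
    ranks = lexicographic_ranks(tuples)
    si, di = dependence_pairs(p.n)
    assert (ranks[di] <= ranks[si]).any()


def test_validate_report_dict():
    rep = validate_schedule(TilingParams(10, 2, 2))
    d = rep.to_dict()
    assert d["valid"] and d["order_violations"] == 0 == d["wavefront_violations"]
    assert d["instances"] == domain_size(10)


@pytest.mark.parametrize(
    "length,ws,wt,threads",
    [(4, 2, 2, 1), (17, 3, 5, 1), (64, 16, 16, 1), (64, 2, 2, 3)],
)
def test_execute_tiled_equals_reference(length, ws, wt, threads):
    seq = random_rna(length, (length, ws, wt))
    ref = fold_reference(seq)
    out = execute_tiled(seq, TilingParams(length, ws, wt), threads=threads)
    assert np.array_equal(out, ref)


def test_execute_tiled_trivial_lengths():
    seq = random_rna(1, 0)
    assert execute_tiled(seq).shape == (1, 1)
    from nusstile.fold import RnaSequence

    seq = RnaSequence("GCGC")
    out = execute_tiled(seq, TilingParams(4, 2, 2))
    assert np.array_equal(out, fold_reference(seq))


def test_execute_tiled_shuffled_chains_are_deterministic():
    seq = random_rna(90, 5)
    ref = fold_reference(seq)
    p = TilingParams(90, 3, 3)
    for trial in range(5):
        out = execute_tiled(seq, p, rng=np.random.default_rng(trial))
        assert np.array_equal(out, ref)


def test_execute_tiled_param_mismatch():
    with pytest.raises(ValueError):
        execute_tiled(random_rna(10, 0), TilingParams(11))


def test_tile_stats_examples():
    st = tile_stats(TilingParams(2, 4, 4))
    assert st.n_tiles == 1 and st.max_instances == 2
    st64 = tile_stats(TilingParams(64, 4, 4))
    st128 = tile_stats(TilingParams(128, 4, 4))
    assert st64.max_instances == st128.max_instances  # saturation
    assert st64.max_s1_instances <= 16
    # closed-form totals agree with the domain size
    assert st64.total_instances == domain_size(64)
    assert st128.total_instances == domain_size(128)


def test_tiling_params_validation():
    with pytest.raises(ValueError):
        TilingParams(0)
    with pytest.raises(ValueError):
        TilingParams(10, 0, 4)
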