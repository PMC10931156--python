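"""ED statistics: LOD, dye ranking, reference ranges, Ward HCA."""

import numpy as np
import pytest

from _oracles import brute_force_ward, scipy_ward_partitions
from optonose.analysis import (
    DoseResponseSeries,
    EDClassification,
    build_reference_ranges,
    classify_by_ed,
    cluster_success_rate,
    estimate_lod,
    hca_ward,
    make_voc_condition_matrix,
    rank_sensitive_dyes,
)


def _series(concs, totals, blank_mean=47.75, blank_sd=2.0):
    n = len(concs)
    return DoseResponseSeries(
        voc_name="ethanol", concentrations=np.array(concs, float),
        total_ed=np.array(totals, float), per_spot_ed=np.zeros((n, 25)),
        blank_mean=blank_mean, blank_sd=blank_sd,
    )


# --- LOD ---------------------------------------------------------------

def test_lod_is_first_concentration_above_blank_plus_three_sigma():
    # blank 47.75, sigma 2 -> threshold 53.75; only 60 > 53.75
    s = _series([5.0, 10.0, 20.0], [48.0, 52.0, 60.0])
    assert estimate_lod(s) == 20.0
    assert s.lod_ppm == 20.0


def test_lod_not_reached_is_none():
    s = _series([5.0, 10.0], [48.0, 50.0])
    assert estimate_lod(s) is None
    assert s.lod_ppm is None


def test_lod_requires_sorted_concentrations():
    s = _series([10.0, 5.0], [48.0, 60.0])
    with pytest.raises(ValueError, match="ascending"):
        estimate_lod(s)


def test_lod_monotone_in_blank_sd():
    concs = [5.0, 10.0, 20.0, 50.0]
    totals = [50.0, 55.0, 62.0, 80.0]
    lods = []
    for sd in (0.5, 1.0, 2.0, 4.0, 8.0, 20.0):
        lod = estimate_lod(_series(concs, totals, blank_sd=sd))
        lods.append(np.inf if lod is None else lod)
    assert all(b >= a for a, b in zip(lods, lods[1:]))


def test_per_dye_lod_with_explicit_threshold():
    s = _series([5.0, 10.0, 20.0], [48.0, 52.0, 60.0])
    s.per_spot_ed[:, 4] = [1.0, 6.0, 12.0]
    assert estimate_lod(s, spot=4, threshold=5.0) == 10.0
    assert estimate_lod(s, spot=3, threshold=5.0) is None


# --- sensitive dyes ----------------------------------------------------

def test_single_responsive_dye_ranks_first():
    s = _series([10.0, 100.0], [50.0, 80.0])
    s.per_spot_ed[-1, 13] = 40.0
    assert rank_sensitive_dyes(s, 1)[0] == 13


def test_rank_all_returns_permutation_with_id_tiebreak(rng):
    s = _series([100.0], [80.0])
    s.per_spot_ed[0] = rng.uniform(0, 50, 25)
    s.per_spot_ed[0, [3, 17]] = 33.0  # tie broken by smaller dye id
    order = rank_sensitive_dyes(s, 25)
    assert sorted(order.tolist()) == list(range(25))
    assert list(order).index(3) < list(order).index(17)
    with pytest.raises(ValueError):
        rank_sensitive_dyes(s, 26)


def test_planted_sensitivity_order_is_recovered():
    s = _series([100.0], [80.0])
    planted = np.arange(25)[::-1].astype(float)  # dye 0 strongest
    s.per_spot_ed[0] = planted
    assert np.array_equal(rank_sensitive_dyes(s, 25), np.arange(25))


# --- reference ranges --------------------------------------------------

def test_reference_range_is_min_max():
    r = build_reference_ranges({"banana_ripe": [50.0, 60.0, 55.0]})
    assert r.ranges["banana_ripe"] == (50.0, 60.0)


def test_single_sample_gives_degenerate_range():
    r = build_reference_ranges({"blank": [42.0]})
    assert r.ranges["blank"] == (42.0, 42.0)


def test_empty_class_rejected():
    with pytest.raises(ValueError, match="no calibration samples"):
        build_reference_ranges({"blank": []})


def test_classify_unique_ambiguous_and_out_of_range():
    ranges = build_reference_ranges({
        "a": [0.0, 10.0], "b": [8.0, 30.0], "c": [100.0, 120.0],
    })
    assert classify_by_ed(5.0, ranges) == EDClassification("a", "unique")
    # 9.0 falls in both a (width 10) and b (width 22): narrowest wins
    assert classify_by_ed(9.0, ranges) == EDClassification("a", "ambiguous")
    assert classify_by_ed(500.0, ranges) == EDClassification(None, "out_of_range")


def test_disjoint_ranges_classify_training_samples_exactly():
    samples = {"u": [10.0, 20.0], "r": [40.0, 55.0], "o": [80.0, 95.0]}
    ranges = build_reference_ranges(samples)
    for label, vals in samples.items():
        for v in vals:
            assert classify_by_ed(v, ranges).label == label


# --- Ward HCA ----------------------------------------------------------

def test_duplicated_rows_merge_first_at_height_zero(rng):
    X = rng.uniform(0, 10, size=(6, 25))
    X[3] = X[0]
    link = hca_ward(X)
    assert link.merges[0, 2] == pytest.approx(0.0)
    assert {int(link.merges[0, 0]), int(link.merges[0, 1])} == {0, 3}


def test_linkage_has_n_minus_1_merges_and_27_row_panel():
    m = make_voc_condition_matrix(0)
    assert m["averaged"].shape == (27, 25)  # 9 VOCs x 3 concentrations
    link = hca_ward(m["averaged"], labels=m["condition_labels"])
    assert link.merges.shape == (26, 4)


def test_two_tight_pairs_split_apart():
    X = np.array([[0.0, 0.0], [0.1, 0.0], [10.0, 10.0], [10.1, 10.0]])
    link = hca_ward(X)
    cut = link.cut(2)
    assert cut[0] == cut[1] and cut[2] == cut[3] and cut[0] != cut[2]


def test_ward_matches_brute_force_oracle_on_random_instances(rng):
    for _ in range(25):
        n = int(rng.integers(3, 8))
        X = rng.normal(size=(n, int(rng.integers(2, 6))))
        link = hca_ward(X)
        oracle_parts, oracle_heights = brute_force_ward(X)
        assert np.allclose(link.merges[:, 2], oracle_heights, rtol=1e-8)
        assert scipy_ward_partitions(link.merges, n) == oracle_parts


def test_non_finite_matrix_rejected():
    X = np.zeros((4, 25))
    X[1, 3] = np.nan
    with pytest.raises(ValueError, match="non-finite"):
        hca_ward(X)
    with pytest.raises(ValueError):
        hca_ward(np.zeros((1, 25)))


# --- cluster success rate ----------------------------------------------

def test_success_rate_edge_cases(rng):
    X = rng.normal(size=(8, 4))
    link = hca_ward(X)
    same = ["x"] * 8
    assert cluster_success_rate(link, same, 1) == 1.0
    random_labels = rng.integers(0, 3, 8)
    assert cluster_success_rate(link, random_labels, 8) == 1.0  # singletons
    with pytest.raises(ValueError):
        cluster_success_rate(link, same, 9)


def test_separated_conditions_cluster_perfectly():
    m = make_voc_condition_matrix(7)
    link = hca_ward(m["replicates"], labels=m["replicate_labels"])
    assert cluster_success_rate(link, m["replicate_labels"], 27) == 1.0
    link_avg = hca_ward(m["averaged"], labels=m["condition_labels"])
    assert cluster_success_rate(link_avg, m["voc_labels"], 9) == 1.0
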