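"""Fuzzy TOPSIS: stage-by-stage examples, a transliteration oracle, and the
shipped worked-example regression."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from pcoscreen.datasets import iter_reference_profiles
from pcoscreen.fuzzy import TFN
from pcoscreen.topsis import (
    RATING_SCALE,
    WEIGHT_SCALE,
    DecisionMatrix,
    SeparationProfile,
    aggregate_ratings,
    aggregate_weights,
    closeness_coefficients,
    ideal_solutions,
    normalize_matrix,
    rank_alternatives,
    rank_channel,
    separation_distances,
    weight_matrix,
)


def toy_matrix():
    """Two alternatives, one criterion: H-rated vs L-rated."""
    return DecisionMatrix(
        alternatives=("A", "B"),
        criteria=("c1",),
        ratings=((RATING_SCALE["H"],), (RATING_SCALE["L"],)),
        weights=(TFN(1, 1, 1),),
    )


class TestAggregation:
    def test_single_rater_identity(self):
        grid = [[RATING_SCALE["H"], RATING_SCALE["M"]]]
        assert aggregate_ratings([grid]) == [list(grid[0])]

    def test_three_raters_min_mean_max(self):
        cell = [[RATING_SCALE["H"]]], [[RATING_SCALE["H"]]], [[RATING_SCALE["M"]]]
        [[agg]] = aggregate_ratings(cell)
        assert agg.as_tuple() == pytest.approx((0.4, (0.7 + 0.7 + 0.5) / 3, 0.8))

    def test_aggregate_weights_two_raters(self):
        [agg] = aggregate_weights([[WEIGHT_SCALE["VHR"]], [WEIGHT_SCALE["HR"]]])
        assert agg.as_tuple() == pytest.approx((6, 8, 10))

    def test_idempotent_on_identical_inputs(self):
        v = [WEIGHT_SCALE["R"], WEIGHT_SCALE["HR"]]
        assert [a.as_tuple() for a in aggregate_weights([v, v, v])] == [
            x.as_tuple() for x in v
        ]

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            aggregate_ratings([[[RATING_SCALE["H"]]], [[RATING_SCALE["H"], RATING_SCALE["M"]]]])

    def test_aggregate_lower_bounds_inputs(self):
        grids = [[[RATING_SCALE["H"]]], [[RATING_SCALE["VL"]]], [[RATING_SCALE["M"]]]]
        [[agg]] = aggregate_ratings(grids)
        assert all(agg.l <= g[0][0].l for g in grids)


class TestNormalisation:
    def test_divide_by_column_max_upper(self):
        dm = DecisionMatrix(("A",), ("c1",), ((TFN(0.6, 0.7, 0.8),),), (TFN(1, 1, 1),))
        cell = normalize_matrix(dm).ratings[0][0]
        assert cell.as_tuple() == pytest.approx((0.75, 0.875, 1.0))

    def test_identical_column_all_uppers_one(self):
        dm = DecisionMatrix(
            ("A", "B"), ("c1",),
            ((RATING_SCALE["M"],), (RATING_SCALE["M"],)), (TFN(1, 1, 1),),
        )
        assert all(row[0].u == pytest.approx(1.0) for row in normalize_matrix(dm).ratings)

    def test_idempotent_when_max_upper_is_one(self):
        dm = normalize_matrix(toy_matrix())
        again = normalize_matrix(dm)
        assert again.ratings == dm.ratings

    def test_zero_column_named(self):
        dm = DecisionMatrix(("A",), ("c9",), ((TFN(0, 0, 0),),), (TFN(1, 1, 1),))
        with pytest.raises(ValueError, match="c9"):
            normalize_matrix(dm)


class TestWeighting:
    def test_unit_weights_identity(self):
        dm = normalize_matrix(toy_matrix())
        assert weight_matrix(dm).ratings == dm.ratings

    def test_crisp_weight_promotion(self):
        dm = DecisionMatrix(
            ("A",), ("C11",), ((TFN(0.75, 0.875, 1.0),),), (TFN.crisp(0.074),)
        )
        cell = weight_matrix(dm).ratings[0][0]
        assert cell.as_tuple() == pytest.approx((0.0555, 0.06475, 0.074))

    def test_zero_weight_annihilates_criterion(self):
        dm = DecisionMatrix(
            ("A", "B"), ("c1", "c2"),
            ((RATING_SCALE["H"], RATING_SCALE["VL"]), (RATING_SCALE["L"], RATING_SCALE["VH"])),
            (TFN(1, 1, 1), TFN(0, 0, 0)),
        )
        weighted = weight_matrix(normalize_matrix(dm))
        ideals = ideal_solutions(weighted)
        prof = separation_distances(weighted, ideals)
        only_c1 = weight_matrix(normalize_matrix(DecisionMatrix(
            dm.alternatives, ("c1",),
            tuple((row[0],) for row in dm.ratings), (TFN(1, 1, 1),))))
        prof1 = separation_distances(only_c1, ideal_solutions(only_c1))
        assert prof.d_star == pytest.approx(prof1.d_star)


class TestIdealsAndSeparation:
    def test_ideals_from_toy(self):
        weighted = weight_matrix(normalize_matrix(toy_matrix()))
        ideals = ideal_solutions(weighted)
        assert ideals.fpis == pytest.approx((1.0,))
        assert ideals.fnis == pytest.approx((0.25,))

    def test_single_alternative_rejected(self):
        dm = DecisionMatrix(("A",), ("c1",), ((RATING_SCALE["H"],),), (TFN(1, 1, 1),))
        with pytest.raises(ValueError, match="two alternatives"):
            ideal_solutions(dm)

    def test_toy_separation_distances(self):
        weighted = weight_matrix(normalize_matrix(toy_matrix()))
        prof = separation_distances(weighted, ideal_solutions(weighted))
        assert prof.d_star == pytest.approx((0.1614, 0.6333), abs=1e-4)
        assert prof.d_minus == pytest.approx((0.6333, 0.1614), abs=1e-4)

    def test_alternative_at_fpis_has_zero_dstar(self):
        dm = DecisionMatrix(
            ("A", "B"), ("c1",),
            ((TFN.crisp(1.0),), (TFN.crisp(0.2),)), (TFN(1, 1, 1),),
        )
        prof = separation_distances(dm, ideal_solutions(dm))
        assert prof.d_star[0] == pytest.approx(0.0)

    def test_criterion_subset_shrinks_dstar(self):
        full = weight_matrix(normalize_matrix(DecisionMatrix(
            ("A", "B"), ("c1", "c2"),
            ((RATING_SCALE["H"], RATING_SCALE["M"]), (RATING_SCALE["L"], RATING_SCALE["VH"])),
            (TFN(1, 1, 1), TFN(1, 1, 1)),
        )))
        sub = DecisionMatrix(full.alternatives, full.criteria[:1],
                             tuple(r[:1] for r in full.ratings), full.weights[:1])
        d_full = separation_distances(full, ideal_solutions(full)).d_star
        ideals = ideal_solutions(full)
        d_sub = separation_distances(sub, type(ideals)(ideals.fpis[:1], ideals.fnis[:1])).d_star
        assert all(s <= f + 1e-12 for s, f in zip(d_sub, d_full))


class TestClosenessAndRanking:
    def test_reference_pcos_row_sums(self):
        profiles = {(ch, alt): (ds, dn) for ch, alt, ds, dn in iter_reference_profiles()}
        ds, dn = profiles[("physical", "P1")]
        assert ds == pytest.approx(31.33) and dn == pytest.approx(66.93)
        cc = closeness_coefficients(SeparationProfile(("P1",), (ds,), (dn,))).cc[0]
        assert cc == pytest.approx(0.681, abs=1e-3)

    def test_zero_dstar_gives_unit_cc(self):
        prof = closeness_coefficients(SeparationProfile(("A",), (0.0,), (1.0,)))
        assert prof.cc == (1.0,)

    def test_degenerate_configuration_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            closeness_coefficients(SeparationProfile(("A",), (0.0,), (0.0,)))

    def test_toy_ccs_sum_to_one(self):
        prof, order = rank_channel(toy_matrix())
        assert prof.cc == pytest.approx((0.797, 0.203), abs=1e-3)
        assert sum(prof.cc) == pytest.approx(1.0)
        assert order == ["A", "B"]

    def test_reference_channel_rankings(self):
        for channel, expected in (("physical", ["P1", "P3", "P2"]),
                                  ("mental", ["M1", "M3", "M2"])):
            rows = [(alt, ds, dn) for ch, alt, ds, dn in iter_reference_profiles()
                    if ch == channel]
            rows.sort()
            prof = closeness_coefficients(SeparationProfile(
                tuple(a for a, _, _ in rows),
                tuple(d for _, d, _ in rows),
                tuple(d for _, _, d in rows),
            ))
            assert rank_alternatives(prof) == expected

    def test_tie_break_by_declared_order(self):
        prof = SeparationProfile(("P1", "P2", "P3"), (1, 1, 1), (1, 1, 1), (0.5, 0.5, 0.5))
        assert rank_alternatives(prof) == ["P1", "P2", "P3"]


def transliterated_topsis(ratings, weights):
    """Direct tuple-based implementation of normalise → weight → ideals →
    distances → CC, independent of the package types."""
    m, n = len(ratings), len(ratings[0])
    cmax = [max(ratings[i][j][2] for i in range(m)) for j in range(n)]
    norm = [[tuple(x / cmax[j] for x in ratings[i][j]) for j in range(n)] for i in range(m)]
    v = [[tuple(norm[i][j][k] * weights[j][k] for k in range(3)) for j in range(n)]
         for i in range(m)]
    fpis = [max(v[i][j][2] for i in range(m)) for j in range(n)]
    fnis = [min(v[i][j][0] for i in range(m)) for j in range(n)]

    def dv(cell, c):
        return math.sqrt(sum((x - c) ** 2 for x in cell) / 3.0)

    d_star = [sum(dv(v[i][j], fpis[j]) for j in range(n)) for i in range(m)]
    d_minus = [sum(dv(v[i][j], fnis[j]) for j in range(n)) for i in range(m)]
    return [dm / (ds + dm) for ds, dm in zip(d_star, d_minus)]


_labels = sorted(RATING_SCALE)


@given(
    st.integers(2, 3), st.integers(1, 3), st.data()
)
def test_oracle_equivalence_small_matrices(m, n, data):
    """Pipeline CCs match the transliteration to 1e-12 on label-built matrices."""
    labels = data.draw(st.lists(st.sampled_from(_labels), min_size=m * n, max_size=m * n))
    wlabels = data.draw(st.lists(st.sampled_from(["LR", "R", "HR", "VHR"]),
                                 min_size=n, max_size=n))
    ratings = tuple(tuple(RATING_SCALE[labels[i * n + j]] for j in range(n)) for i in range(m))
    weights = tuple(WEIGHT_SCALE[w] for w in wlabels)
    dm = DecisionMatrix(tuple(f"a{i}" for i in range(m)), tuple(f"c{j}" for j in range(n)),
                        ratings, weights)
    expected = transliterated_topsis(
        [[c.as_tuple() for c in row] for row in ratings],
        [w.as_tuple() for w in weights],
    )
    prof, _ = rank_channel(dm)
    assert prof.cc == pytest.approx(expected, abs=1e-12)


def test_cc_invariant_to_uniform_weight_scaling():
    dm = DecisionMatrix(
        ("A", "B"), ("c1", "c2"),
        ((RATING_SCALE["H"], RATING_SCALE["M"]), (RATING_SCALE["L"], RATING_SCALE["VH"])),
        (TFN.crisp(0.2), TFN.crisp(0.8)),
    )
    scaled = DecisionMatrix(dm.alternatives, dm.criteria, dm.ratings,
                            tuple(w.scale(3.7) for w in dm.weights))
    assert rank_channel(dm)[0].cc == pytest.approx(rank_channel(scaled)[0].cc)
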