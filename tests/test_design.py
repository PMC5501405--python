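import itertools

import numpy as np
import pandas as pd
import pytest

from inhalerdce.design import (
    ChoiceSet,
    Design,
    block_design,
    coded_alternatives,
    d_efficiency,
    design_diagnostics,
    design_to_frame,
    mnl_information_matrix,
    random_design,
    read_design,
    search_design,
    write_design,
)
from inhalerdce.errors import ConfigError, SchemaError
from inhalerdce.schema import AttributeSpec, Profile, code_profile, coded_names


def binary_attr(name="switch", levels=("on", "off")):
    return AttributeSpec(name, "categorical", levels, reference_level=levels[1])


def make_design(attrs, pairs, n_blocks=1):
    sets = [
        ChoiceSet(i, 0, (Profile(a), Profile(b))) for i, (a, b) in enumerate(pairs)
    ]
    return Design(sets, list(attrs), n_blocks=n_blocks)


def brute_force_info(design, beta):
    """Loop-and-scalar reference for the MNL information matrix."""
    p = len(beta)
    M = np.zeros((p, p))
    for cs in design.choice_sets:
        X = np.array([code_profile(a, design.attributes) for a in cs.alternatives])
        expu = [np.exp(float(x @ beta)) for x in X]
        tot = sum(expu)
        probs = [e / tot for e in expu]
        for i in range(p):
            for j in range(p):
                xi_bar = sum(probs[k] * X[k, i] for k in range(len(probs)))
                xj_bar = sum(probs[k] * X[k, j] for k in range(len(probs)))
                M[i, j] += sum(
                    probs[k] * (X[k, i] - xi_bar) * (X[k, j] - xj_bar)
                    for k in range(len(probs))
                )
    return M


def det2(m):
    return m[0, 0] * m[1, 1] - m[0, 1] * m[1, 0]


class TestInformationMatrix:
    def test_binary_contrast_at_zero_prior_is_quarter_outer_product(self):
        a = binary_attr()
        d = make_design([a], [({"switch": "on"}, {"switch": "off"})])
        M = mnl_information_matrix(d, [0.0])
        diff = 1.0 - 0.0
        assert M == pytest.approx(np.array([[0.25 * diff * diff]]))

    def test_zero_prior_matches_equal_probability_oracle(self, tiny_attrs):
        rng = np.random.default_rng(0)
        d = random_design(tiny_attrs, 6, seed=4)
        beta = np.zeros(2)
        M = mnl_information_matrix(d, beta)
        assert M == pytest.approx(brute_force_info(d, beta), abs=1e-10)

    def test_nonzero_prior_matches_brute_force(self, tiny_attrs):
        rng = np.random.default_rng(1)
        for seed in range(3):
            d = random_design(tiny_attrs, 5, seed=seed)
            beta = rng.normal(0, 0.5, 2)
            M = mnl_information_matrix(d, beta)
            assert M == pytest.approx(brute_force_info(d, beta), abs=1e-10)

    def test_information_is_positive_semidefinite(self, attrs):
        for seed in range(4):
            d = random_design(attrs, 10, seed=seed)
            M = mnl_information_matrix(d, np.zeros(len(coded_names(attrs))))
            assert np.linalg.eigvalsh(M).min() >= -1e-10

    def test_dimension_mismatch_rejected(self, tiny_attrs):
        d = random_design(tiny_attrs, 3, seed=0)
        with pytest.raises(ValueError):
            mnl_information_matrix(d, np.zeros(5))


class TestDEfficiency:
    def test_no_contrast_design_scores_zero(self):
        # both sets vary only one of two attributes: the other column is
        # constant, the information matrix singular
        a, b = binary_attr("a", ("x", "y")), binary_attr("b", ("p", "q"))
        pairs = [
            ({"a": "x", "b": "p"}, {"a": "y", "b": "p"}),
            ({"a": "y", "b": "p"}, {"a": "x", "b": "p"}),
        ]
        d = make_design([a, b], pairs)
        assert d_efficiency(d) == 0.0

    def test_replicating_sets_preserves_per_set_efficiency(self, tiny_attrs):
        d = random_design(tiny_attrs, 4, seed=3)
        doubled_pairs = [
            (cs.alternatives[0].assignment, cs.alternatives[1].assignment)
            for cs in d.choice_sets
        ] * 2
        doubled = make_design(tiny_attrs, doubled_pairs)
        assert d_efficiency(doubled) == pytest.approx(d_efficiency(d), rel=1e-10)

    def test_matches_hand_determinant_on_two_attribute_design(self, tiny_attrs):
        rng = np.random.default_rng(7)
        for seed in range(3):
            d = random_design(tiny_attrs, 4, seed=seed)
            beta = rng.normal(0, 0.4, 2)
            M = brute_force_info(d, beta)
            expected = det2(M) ** (1 / 2) / d.n_sets if det2(M) > 0 else 0.0
            assert d_efficiency(d, beta) == pytest.approx(expected, abs=1e-10)


class TestSearch:
    def test_study_scale_search_yields_36_sets_in_3_blocks_of_12(self, design36):
        assert design36.n_sets == 36
        assert design36.block_sizes() == {0: 12, 1: 12, 2: 12}
        assert design36.diagnostics.duplicate_set_count == 0

    def test_search_beats_random_designs(self, attrs):
        found = search_design(attrs, 12, 1, seed=5, n_restarts=3)
        best_random = max(
            d_efficiency(random_design(attrs, 12, seed=s)) for s in range(50)
        )
        assert d_efficiency(found) >= best_random

    def test_two_set_binary_design_contrasts_both_levels(self):
        a = binary_attr()
        d = search_design([a], 2, 1, seed=0, n_restarts=2)
        for cs in d.choice_sets:
            levels = {p["switch"] for p in cs.alternatives}
            assert levels == {"on", "off"}
        assert d_efficiency(d) > 0

    def test_same_seed_reproduces_design(self, attrs):
        d1 = search_design(attrs, 6, 2, seed=9, n_restarts=2)
        d2 = search_design(attrs, 6, 2, seed=9, n_restarts=2)
        pd.testing.assert_frame_equal(design_to_frame(d1), design_to_frame(d2))

    def test_indivisible_blocks_rejected(self, attrs):
        with pytest.raises(ConfigError):
            search_design(attrs, 10, 3, seed=0)

    def test_level_balance_of_categorical_attributes(self, design36):
        balance = design36.diagnostics.level_balance
        for a in design36.attributes:
            counts = balance[a.name]
            assert sum(counts.values()) == 36 * 2
            if a.kind == "categorical":
                expected = 36 * 2 / len(a.levels)
                assert all(abs(v - expected) <= 2 for v in counts.values())


class TestBlocking:
    def test_blocks_conserve_sets(self, design36):
        ids = sorted(
            cs.set_id for b in range(3) for cs in design36.sets_in_block(b)
        )
        assert ids == sorted(cs.set_id for cs in design36.choice_sets)

    def test_single_block_keeps_assignment(self, tiny_attrs):
        d = random_design(tiny_attrs, 4, seed=1)
        b = block_design(d, 1, seed=3)
        assert all(cs.block_id == 0 for cs in b.choice_sets)
        assert [cs.set_id for cs in b.choice_sets] == [
            cs.set_id for cs in d.choice_sets
        ]

    def test_balanced_binary_four_sets_split_evenly(self):
        a = binary_attr()
        # two sets of each orientation: 4 "on" and 4 "off" overall
        pairs = [({"switch": "on"}, {"switch": "off"})] * 2 + [
            ({"switch": "off"}, {"switch": "on"})
        ] * 2
        d = make_design([a], pairs)
        blocked = block_design(d, 2, seed=0)
        for b in (0, 1):
            counts = {"on": 0, "off": 0}
            for cs in blocked.sets_in_block(b):
                for p in cs.alternatives:
                    counts[p["switch"]] += 1
            assert counts == {"on": 2, "off": 2}

    def test_indivisible_block_count_rejected(self, tiny_attrs):
        d = random_design(tiny_attrs, 5, seed=0)
        with pytest.raises(ConfigError):
            block_design(d, 2)


class TestDiagnostics:
    def test_orthogonal_toy_design_has_zero_cross_correlations(self):
        a, b = binary_attr("a", ("x", "y")), binary_attr("b", ("p", "q"))
        pairs = [
            ({"a": "x", "b": "p"}, {"a": "y", "b": "q"}),
            ({"a": "x", "b": "q"}, {"a": "y", "b": "p"}),
            ({"a": "y", "b": "p"}, {"a": "x", "b": "q"}),
            ({"a": "y", "b": "q"}, {"a": "x", "b": "p"}),
        ]
        d = make_design([a, b], pairs)
        diag = design_diagnostics(d)
        corr = diag.pairwise_correlation
        assert corr.loc["a[x]", "b[p]"] == pytest.approx(0.0, abs=1e-12)

    def test_constant_column_reported_missing_with_warning(self):
        a, b = binary_attr("a", ("x", "y")), binary_attr("b", ("p", "q"))
        pairs = [
            ({"a": "x", "b": "p"}, {"a": "y", "b": "p"}),
            ({"a": "y", "b": "p"}, {"a": "x", "b": "p"}),
        ]
        d = make_design([a, b], pairs)
        with pytest.warns(UserWarning, match="constant"):
            diag = design_diagnostics(d)
        assert np.isnan(diag.pairwise_correlation.loc["b[p]", "a[x]"])

    def test_duplicate_sets_counted(self, tiny_attrs):
        d = random_design(tiny_attrs, 3, seed=2)
        pairs = [
            (cs.alternatives[0].assignment, cs.alternatives[1].assignment)
            for cs in d.choice_sets
        ]
        # repeat the first question with the alternatives swapped
        pairs.append((pairs[0][1], pairs[0][0]))
        dup = make_design(tiny_attrs, pairs)
        assert design_diagnostics(dup).duplicate_set_count == 1


class TestChoiceSetInvariants:
    def test_identical_alternatives_rejected(self):
        a = binary_attr()
        with pytest.raises(SchemaError):
            ChoiceSet(0, 0, (Profile({"switch": "on"}), Profile({"switch": "on"})))

    def test_unequal_blocks_rejected(self, tiny_attrs):
        d = random_design(tiny_attrs, 3, seed=0)
        sets = d.choice_sets
        sets[0].block_id = 1
        with pytest.raises(SchemaError):
            Design(sets, tiny_attrs, n_blocks=2)


def test_design_csv_round_trip(tmp_path, design36):
    path = tmp_path / "design.csv"
    write_design(design36, path, tmp_path / "diag.json")
    back = read_design(path, design36.attributes)
    pd.testing.assert_frame_equal(
        design_to_frame(back)
        .sort_values(["set_id", "alt_id"])
        .reset_index(drop=True),
        design_to_frame(design36)
        .sort_values(["set_id", "alt_id"])
        .reset_index(drop=True),
    )
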