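"""Model container invariants, COBRA-JSON/SBML round-trips, factor discovery."""

import json

import numpy as np
import pytest
import scipy.sparse as sp

from fluxsens.errors import BoundOrderError, ModelFormatError, ModelValidationError
from fluxsens.fixtures import make_linear_chain_model, make_min_coupled_model
from fluxsens.model_io import (
    MetabolicModel,
    apply_intake_bounds,
    find_exchange_reactions,
    load_model,
    save_model,
)


def _toy(**overrides):
    kw = dict(
        metabolite_ids=["A", "B"],
        reaction_ids=["EX_A", "CONV", "GROW"],
        S=sp.csc_matrix(np.array([[-1.0, -1.0, 0.0], [0.0, 1.0, -1.0]])),
        lower_bounds=np.array([-10.0, 0.0, 0.0]),
        upper_bounds=np.array([0.0, 1000.0, 1000.0]),
        objective_coeffs=np.array([0.0, 0.0, 1.0]),
    )
    kw.update(overrides)
    return MetabolicModel(**kw)


class TestValidation:
    def test_valid_model_passes(self):
        assert _toy().validate().n_reactions == 3

    @pytest.mark.parametrize(
        "overrides",
        [
            {"lower_bounds": np.array([5.0, 0.0, 0.0])},  # lb > ub
            {"objective_coeffs": np.zeros(3)},  # no objective
            {"reaction_ids": ["EX_A", "EX_A", "GROW"]},  # duplicate ids
            {"metabolite_ids": ["A", "A"]},  # duplicate mets
            {"lower_bounds": np.zeros(2)},  # wrong length
        ],
    )
    def test_invariant_violations_raise(self, overrides):
        with pytest.raises(ModelValidationError):
            _toy(**overrides).validate()


class TestRoundTrip:
    def test_json_write_read_identity(self, tmp_path, min_coupled):
        path = tmp_path / "mc.json"
        save_model(min_coupled, path)
        back = load_model(path, format="cobra_json")
        assert back.equals(min_coupled)

    def test_sbml_read_matches_json(self, tmp_path, chain_11):
        # SBML fixture emitted through cobrapy's writer, read back via load_model
        import cobra.io

        from fluxsens.model_io import _to_cobra

        path = tmp_path / "chain.xml"
        cobra.io.write_sbml_model(_to_cobra(chain_11), str(path))
        back = load_model(path, format="sbml")
        assert back.equals(chain_11)

    def test_load_same_file_twice_identical(self, min_coupled_json):
        a = load_model(min_coupled_json)
        b = load_model(min_coupled_json)
        assert a.equals(b)

    def test_toy_fixture_dimensions(self, tmp_path):
        path = tmp_path / "toy.json"
        save_model(_toy(), path)
        model = load_model(path)
        assert model.n_metabolites == 2 and model.n_reactions == 3

    def test_inverted_bounds_in_file_rejected(self, tmp_path, min_coupled):
        path = tmp_path / "bad.json"
        save_model(min_coupled, path)
        doc = json.loads(path.read_text())
        doc["reactions"][0]["lower_bound"] = 5.0
        doc["reactions"][0]["upper_bound"] = 0.0
        path.write_text(json.dumps(doc))
        with pytest.raises(ModelValidationError):
            load_model(path)

    def test_garbage_file_is_format_error(self, tmp_path):
        path = tmp_path / "junk.json"
        path.write_text("not json at all {{{")
        with pytest.raises(ModelFormatError):
            load_model(path)


class TestExchangeDiscovery:
    def test_single_nonzero_column_rule(self):
        # one boundary column (single nonzero) and one internal A->B column
        model = MetabolicModel(
            metabolite_ids=["A", "B"],
            reaction_ids=["EX_A", "CONV"],
            S=sp.csc_matrix(np.array([[-1.0, -1.0], [0.0, 1.0]])),
            lower_bounds=np.array([-10.0, 0.0]),
            upper_bounds=np.array([0.0, 1000.0]),
            objective_coeffs=np.array([0.0, 1.0]),
        )
        assert find_exchange_reactions(model) == [0]

    def test_biomass_drain_counts_as_boundary(self):
        # a drain column with a single nonzero entry is structurally a boundary
        # reaction, but intake_only excludes it (lower bound is zero)
        assert find_exchange_reactions(_toy()) == [0, 2]
        assert find_exchange_reactions(_toy(), intake_only=True) == [0]

    def test_intake_only_excludes_zero_lower_bound(self):
        model = _toy(lower_bounds=np.array([0.0, 0.0, 0.0]))
        assert find_exchange_reactions(model, intake_only=True) == []

    def test_min_coupled_both_intakes_in_order(self, min_coupled):
        assert find_exchange_reactions(min_coupled, intake_only=True) == [0, 1]

    def test_invariant_under_metabolite_row_permutation(self, chain_11):
        perm = [2, 0, 1]
        shuffled = MetabolicModel(
            metabolite_ids=[chain_11.metabolite_ids[i] for i in perm],
            reaction_ids=list(chain_11.reaction_ids),
            S=chain_11.S.toarray()[perm],
            lower_bounds=chain_11.lower_bounds,
            upper_bounds=chain_11.upper_bounds,
            objective_coeffs=chain_11.objective_coeffs,
        )
        assert find_exchange_reactions(shuffled) == find_exchange_reactions(chain_11)

    def test_id_pattern_override(self, min_coupled):
        assert find_exchange_reactions(min_coupled, id_pattern=r"^EX_") == [0, 1]


class TestApplyIntakeBounds:
    def test_single_bound_update_leaves_rest(self, min_coupled):
        out = apply_intake_bounds(min_coupled, [1], [-5.0])
        assert out.lower_bounds[1] == -5.0
        assert out.lower_bounds[0] == min_coupled.lower_bounds[0]
        assert (out.S != min_coupled.S).nnz == 0

    def test_input_model_not_mutated(self, min_coupled):
        before = min_coupled.lower_bounds.copy()
        apply_intake_bounds(min_coupled, [0, 1], [-1.0, -2.0])
        assert np.array_equal(min_coupled.lower_bounds, before)

    def test_identity_values_give_equal_model(self, min_coupled):
        out = apply_intake_bounds(min_coupled, [0, 1], min_coupled.lower_bounds[[0, 1]])
        assert out.equals(min_coupled)

    def test_bound_ordering_enforced(self, min_coupled):
        # ub is 0: -10 is fine, +1 is not
        apply_intake_bounds(min_coupled, [0], [-10.0])
        with pytest.raises(BoundOrderError):
            apply_intake_bounds(min_coupled, [0], [1.0])

    def test_readback_identity(self, min_coupled):
        values = np.array([-3.25, -7.5])
        out = apply_intake_bounds(min_coupled, [0, 1], values)
        assert np.array_equal(out.lower_bounds[[0, 1]], values)
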