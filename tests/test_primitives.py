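import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from causal_emergence import (
    InterventionDistribution,
    TransitionMatrix,
    cp_scores,
    degeneracy_coefficient,
    determinism_coefficient,
    effective_information,
    make_block_model,
    make_permutation,
    necessity,
    sufficiency,
    system_necessity,
    system_sufficiency,
)
from conftest import random_tpm


def mutual_information(tm, pc):
    """Independent oracle: I(C;E) from the explicit joint p(c,e) = pc(c)P(e|c)."""
    joint = pc.weights[:, None] * tm.probs
    pe = joint.sum(axis=0)
    mi = 0.0
    for c in range(tm.n):
        for e in range(tm.n):
            if joint[c, e] > 0:
                mi += joint[c, e] * math.log2(joint[c, e] / (pc.weights[c] * pe[e]))
    return mi


class TestSufficiencyNecessity:
    def test_copy_gate_self_loop(self):
        copy = make_permutation(2)  # both states map to themselves with p = 1
        assert sufficiency(copy, 1, 1) == 1.0
        assert necessity(copy, 1, 1) == 1.0

    def test_uniform_tpm_closed_forms(self, uniform4):
        for c in range(4):
            for e in range(4):
                assert sufficiency(uniform4, c, e) == 0.25
                assert necessity(uniform4, c, e) == pytest.approx(0.75)

    def test_direct_row_read(self):
        tm = TransitionMatrix(tuple("abcd"), [[0.7, 0.1, 0.1, 0.1]] * 4)
        assert sufficiency(tm, 0, 0) == 0.7

    def test_necessity_hand_average_over_alternatives(self):
        tm = TransitionMatrix(
            ("a", "b", "c"), [[1, 0, 0], [1, 0, 0], [0, 0, 1]]
        )
        # alternatives to cause 0 are 1 (leads to e=0) and 2 (does not)
        assert necessity(tm, 0, 0) == pytest.approx(0.5)

    def test_necessity_needs_alternative_causes(self):
        tm = TransitionMatrix(("a",), [[1.0]])
        with pytest.raises(ValueError):
            necessity(tm, 0, 0)
        two = make_permutation(2)
        point = InterventionDistribution([1.0, 0.0])
        with pytest.raises(ValueError, match="all mass"):
            necessity(two, 0, 0, point)


class TestSystemAverages:
    def test_permutation_is_fully_sufficient_and_necessary(self, perm8):
        assert system_sufficiency(perm8) == pytest.approx(1.0)
        assert system_necessity(perm8) == pytest.approx(1.0)

    def test_uniform_tpm_closed_forms(self, uniform4):
        assert system_sufficiency(uniform4) == pytest.approx(0.25)
        assert system_necessity(uniform4) == pytest.approx(0.75)

    def test_all_rows_to_one_state(self):
        tm = TransitionMatrix(("a", "b"), [[1, 0], [1, 0]])
        assert system_sufficiency(tm) == pytest.approx(1.0)
        assert system_necessity(tm) == pytest.approx(0.0)


class TestCoefficients:
    def test_permutation_determinism_degeneracy(self, perm8):
        assert determinism_coefficient(perm8) == pytest.approx(1.0)
        assert degeneracy_coefficient(perm8) == pytest.approx(0.0, abs=1e-12)

    def test_uniform_determinism_zero(self):
        tm = TransitionMatrix(tuple("abcdefgh"), np.full((8, 8), 1 / 8))
        assert determinism_coefficient(tm) == pytest.approx(0.0, abs=1e-12)
        assert degeneracy_coefficient(tm) == pytest.approx(0.0, abs=1e-12)

    def test_cycle_plus_block_hand_values(self, cycle_block):
        # 4 one-hot rows and 4 rows with entropy 2 bits over log2(8) = 3
        assert determinism_coefficient(cycle_block) == pytest.approx(2 / 3)
        assert degeneracy_coefficient(cycle_block) == pytest.approx(0.0, abs=1e-12)

    def test_all_to_one_state_fully_degenerate(self):
        tm = TransitionMatrix(("a", "b"), [[1, 0], [1, 0]])
        assert degeneracy_coefficient(tm) == pytest.approx(1.0)


class TestCpScores:
    def test_permutation(self, perm8):
        s = cp_scores(perm8)
        assert s.cp_primitive == pytest.approx(1.0)
        assert s.cp_info == pytest.approx(1.0)
        assert s.ei == pytest.approx(3.0)

    def test_uniform(self, uniform4):
        s = cp_scores(uniform4)
        assert s.cp_primitive == pytest.approx(0.0, abs=1e-12)
        assert s.cp_info == pytest.approx(0.0, abs=1e-12)

    def test_cycle_plus_block_microscale(self, cycle_block):
        assert cp_scores(cycle_block).cp_info == pytest.approx(2 / 3)

    def test_block_model_ei_one_bit(self, block_model):
        s = cp_scores(block_model)
        assert s.determinism == pytest.approx(1 / 3)
        assert s.degeneracy == pytest.approx(0.0, abs=1e-12)
        assert s.ei == pytest.approx(1.0)

    def test_single_state_convention(self):
        s = cp_scores(TransitionMatrix(("a",), [[1.0]]))
        assert s.cp_primitive == s.cp_info == s.effectiveness == s.ei == 0.0
        assert s.specificity == 1.0 - s.degeneracy

    @pytest.mark.parametrize("n", range(2, 17))
    def test_permutation_and_uniform_extremes(self, n):
        rng = np.random.default_rng(n)
        perm = make_permutation(n, rng.permutation(n))
        assert cp_scores(perm).cp_primitive == pytest.approx(1.0)
        assert cp_scores(perm).cp_info == pytest.approx(1.0)
        unif = TransitionMatrix(tuple(str(i) for i in range(n)), np.full((n, n), 1 / n))
        assert cp_scores(unif).cp_primitive == pytest.approx(0.0, abs=1e-9)
        assert cp_scores(unif).cp_info == pytest.approx(0.0, abs=1e-9)

    def test_invariants_on_random_tpms(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            n = int(rng.integers(2, 9))
            s = cp_scores(random_tpm(rng, n))
            assert s.specificity == 1.0 - s.degeneracy
            assert abs(s.cp_info - s.effectiveness) < 1e-12
            assert abs(s.ei - s.effectiveness * math.log2(n)) < 1e-9
            for value in (s.suff_sys, s.nec_sys, s.determinism, s.degeneracy):
                assert -1e-12 <= value <= 1 + 1e-12


class TestEffectiveInformation:
    def test_matches_mutual_information_oracle(self):
        rng = np.random.default_rng(1234)
        for _ in range(200):
            n = int(rng.integers(2, 9))
            tm = random_tpm(rng, n)
            pc = InterventionDistribution.uniform(n)
            assert effective_information(tm, pc) == pytest.approx(
                mutual_information(tm, pc), abs=1e-9
            )

    def test_matches_oracle_under_nonuniform_pc(self):
        rng = np.random.default_rng(99)
        for _ in range(20):
            n = int(rng.integers(2, 7))
            tm = random_tpm(rng, n)
            pc = InterventionDistribution(rng.dirichlet(np.ones(n)))
            assert effective_information(tm, pc) == pytest.approx(
                mutual_information(tm, pc), abs=1e-9
            )

    def test_block_model_and_uniform(self, block_model, uniform4):
        assert effective_information(block_model) == pytest.approx(1.0)
        assert effective_information(uniform4) == pytest.approx(0.0, abs=1e-12)


@settings(deadline=None, derandomize=True, max_examples=40)
@given(
    seed=st.integers(0, 2**16),
    n=st.integers(2, 8),
    lam=st.floats(0.0, 1.0, allow_nan=False),
)
def test_blending_toward_uniform_never_increases_determinism(seed, n, lam):
    """Row-wise convex mixing with the uniform TPM cannot sharpen rows."""
    rng = np.random.default_rng(seed)
    tm = random_tpm(rng, n)
    blended = TransitionMatrix(
        tm.labels, (1 - lam) * tm.probs + lam * np.full((n, n), 1 / n)
    )
    assert determinism_coefficient(blended) <= determinism_coefficient(tm) + 1e-9
    assert system_sufficiency(blended) <= system_sufficiency(tm) + 1e-9
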