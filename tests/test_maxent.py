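"""Maximum-entropy model fitting, scoring, and serialization."""

import itertools
import math

import numpy as np
import pytest

from splicedelta.maxent import (
    FitError,
    FragmentChainModel,
    MarginalConstraint,
    MEMModel,
    ModelSchemaError,
    TrainingSet,
    adjacent_pair_spec,
    empirical_marginals,
    fit_mem,
    load_model,
    save_model,
    score_log_odds,
    train_from_kmers,
)

BASES = "ACGT"


class TestEmpiricalMarginals:
    def test_identical_kmers_give_point_masses(self):
        (c,) = empirical_marginals(["GTAAGT"] * 4, [(0,)])
        expected = np.zeros(4)
        expected[BASES.index("G")] = 1.0
        np.testing.assert_array_equal(c.table, expected)

    def test_pairwise_table_equals_hand_count(self):
        kmers = ["AC", "AC", "AG", "TC"]
        (c,) = empirical_marginals(kmers, [(0, 1)])
        # hand enumeration: AC x2, AG x1, TC x1 out of 4
        assert c.table[0, 1] == pytest.approx(0.5)  # A,C
        assert c.table[0, 2] == pytest.approx(0.25)  # A,G
        assert c.table[3, 1] == pytest.approx(0.25)  # T,C
        assert c.table.sum() == pytest.approx(1.0)

    def test_uniform_sample_marginals_near_quarter(self):
        rng = np.random.default_rng(11)
        n = 8000
        kmers = ["".join(BASES[i] for i in row) for row in rng.integers(0, 4, (n, 5))]
        constraints = empirical_marginals(kmers, [(i,) for i in range(5)])
        se = math.sqrt(0.25 * 0.75 / n)
        for c in constraints:
            np.testing.assert_allclose(c.table, 0.25, atol=3 * se + 1e-12)

    def test_empty_input_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            empirical_marginals([], [(0,)])


class TestFitMem:
    def test_single_position_constraints_give_product_of_marginals(self):
        tables = [
            np.array([0.5, 0.2, 0.2, 0.1]),
            np.array([0.1, 0.1, 0.7, 0.1]),
            np.array([0.25, 0.25, 0.25, 0.25]),
        ]
        constraints = [MarginalConstraint((i,), t) for i, t in enumerate(tables)]
        model = fit_mem(constraints, 3)
        expected = tables[0][:, None, None] * tables[1][None, :, None] * tables[2][None, None, :]
        np.testing.assert_allclose(model.probs, expected, atol=1e-12)
        assert model.max_residual <= 1e-6

    def test_no_constraints_is_uniform(self):
        model = fit_mem([], 3)
        np.testing.assert_allclose(model.probs, 0.25**3, atol=1e-15)

    def test_mixed_constraints_match_convex_solver_oracle(self):
        # L=3, one pairwise + one single constraint: compare against the
        # exponential-family dual solved by generic convex optimization over
        # all 64 probabilities (minimize log Z(lam) - lam.b, BFGS)
        from scipy.optimize import minimize
        from scipy.special import logsumexp

        rng = np.random.default_rng(3)
        kmers = ["".join(BASES[i] for i in row) for row in rng.integers(0, 4, (200, 3))]
        constraints = empirical_marginals(kmers, [(0, 1), (2,)], pseudocount=1.0)
        model = fit_mem(constraints, 3, tol=1e-12)

        A_rows, b_vals = [], []
        idx = np.arange(64).reshape(4, 4, 4)
        for c in constraints:
            for cell in itertools.product(range(4), repeat=len(c.positions)):
                mask = np.zeros(64)
                sel = [slice(None)] * 3
                for pos, val in zip(c.positions, cell):
                    sel[pos] = val
                mask[idx[tuple(sel)].ravel()] = 1.0
                A_rows.append(mask)
                b_vals.append(c.table[cell])
        A = np.array(A_rows)
        b = np.array(b_vals)

        def dual(lam):
            logits = A.T @ lam
            logZ = logsumexp(logits)
            p = np.exp(logits - logZ)
            return logZ - lam @ b, A @ p - b

        res = minimize(dual, np.zeros(len(b)), jac=True, method="BFGS",
                       options={"gtol": 1e-12, "maxiter": 2000})
        logits = A.T @ res.x
        p_star = np.exp(logits - logsumexp(logits))
        tv = 0.5 * np.abs(model.probs.ravel() - p_star).sum()
        assert tv < 1e-5

    def test_nonconvergence_raises_with_residual(self):
        # inconsistent constraints cannot all be matched
        c1 = MarginalConstraint((0,), np.array([1.0, 0.0, 0.0, 0.0]))
        c2 = MarginalConstraint((0,), np.array([0.0, 1.0, 0.0, 0.0]))
        with pytest.raises(FitError) as err:
            fit_mem([c1, c2], 2, tol=1e-9, max_iter=5)
        assert err.value.residual > 0


@pytest.fixture(scope="module")
def fitted():
    rng = np.random.default_rng(5)
    # biased sample so the model is far from uniform
    probs = np.array([0.5, 0.3, 0.1, 0.1])
    kmers = ["".join(BASES[i] for i in rng.choice(4, 4, p=probs)) for _ in range(300)]
    return kmers, train_from_kmers(kmers, (1, 2, 3, 4))


class TestModelProperties:

    def test_probabilities_sum_to_one_exact_enumeration(self, fitted):
        _, model = fitted
        assert float(model.probs.sum()) == pytest.approx(1.0, abs=1e-9)

    def test_entropy_dominates_empirical(self, fitted):
        kmers, model = fitted
        counts: dict[str, int] = {}
        for k in kmers:
            counts[k] = counts.get(k, 0) + 1
        emp = np.array(list(counts.values()), dtype=float)
        emp /= emp.sum()
        emp_entropy = -(emp * np.log2(emp)).sum()
        assert model.entropy() >= emp_entropy - 1e-9

    def test_adding_a_constraint_never_increases_entropy(self, fitted):
        kmers, _ = fitted
        singles = empirical_marginals(kmers, [(i,) for i in range(4)])
        more = empirical_marginals(kmers, adjacent_pair_spec(4))
        m1 = fit_mem(singles, 4)
        m2 = fit_mem(more, 4)
        assert m2.entropy() <= m1.entropy() + 1e-9

    def test_fragment_chain_sums_to_one(self):
        rng = np.random.default_rng(9)
        kmers = ["".join(BASES[i] for i in row) for row in rng.integers(0, 4, (150, 11))]
        model = train_from_kmers(kmers, tuple(range(1, 12)), fragment_length=5)
        assert isinstance(model, FragmentChainModel)
        total = sum(
            model.prob("".join(w)) for w in itertools.product(BASES, repeat=11)
        ) if False else None
        # 4^11 enumeration is too large; use the telescoping identity on a
        # random slice instead: summing over the final fragment's fresh
        # positions conditioned on any prefix must give 1.
        s_last, m_last = model.fragments[-1]
        prev_end = model.fragments[-2][0] + len(model.fragments[-2][1])
        overlap = tuple(range(0, prev_end - s_last))
        marg = m_last.marginal(overlap)
        cond_sums = m_last.probs.reshape(marg.shape + (-1,)).sum(axis=-1) / np.where(marg > 0, marg, 1)
        np.testing.assert_allclose(cond_sums[marg > 0], 1.0, atol=1e-9)

    def test_fragment_chain_small_window_exact_sum(self):
        rng = np.random.default_rng(13)
        kmers = ["".join(BASES[i] for i in row) for row in rng.integers(0, 4, (120, 6))]
        model = train_from_kmers(kmers, tuple(range(1, 7)), fragment_length=4, fragment_overlap=2)
        total = sum(model.prob("".join(w)) for w in itertools.product(BASES, repeat=6))
        assert total == pytest.approx(1.0, abs=1e-9)


class TestScoring:
    def test_signal_equals_decoy_scores_zero(self):
        rng = np.random.default_rng(1)
        kmers = ["".join(BASES[i] for i in row) for row in rng.integers(0, 4, (50, 3))]
        m = train_from_kmers(kmers, (1, 2, 3))
        for w in ("ACG", "TTT", "GAT"):
            assert score_log_odds(m, m, w) == pytest.approx(0.0, abs=1e-12)

    def test_log2_arithmetic(self):
        signal = MEMModel((1,), np.array([0.5, 0.25, 0.125, 0.125]))
        decoy = MEMModel((1,), np.array([0.25, 0.25, 0.25, 0.25]))
        assert score_log_odds(signal, decoy, "A") == pytest.approx(1.0)
        assert score_log_odds(signal, decoy, "C") == pytest.approx(0.0)
        assert score_log_odds(signal, decoy, "G") == pytest.approx(-1.0)

    def test_table_lookup_oracle(self):
        rng = np.random.default_rng(2)
        sig_kmers = ["".join(BASES[i] for i in rng.choice(4, 4, p=[0.4, 0.3, 0.2, 0.1])) for _ in range(200)]
        dec_kmers = ["".join(BASES[i] for i in row) for row in rng.integers(0, 4, (200, 4))]
        sig = train_from_kmers(sig_kmers, (1, 2, 3, 4), pseudocount=0.1)
        dec = train_from_kmers(dec_kmers, (1, 2, 3, 4), pseudocount=0.1)
        for w in ("AAAA", "ACGT", "TGCA"):
            expected = math.log2(sig.prob(w)) - math.log2(dec.prob(w))
            assert score_log_odds(sig, dec, w) == pytest.approx(expected, abs=1e-12)

    def test_length_mismatch_is_contract_error(self):
        m = MEMModel((1,), np.full(4, 0.25))
        with pytest.raises(ValueError, match="length"):
            score_log_odds(m, m, "AC")


class TestSerialization:
    def test_round_trip_scores_identical(self, tmp_path):
        rng = np.random.default_rng(21)
        kmers = ["".join(BASES[i] for i in row) for row in rng.integers(0, 4, (100, 5))]
        model = train_from_kmers(kmers, (1, 2, 3, 4, 5), pseudocount=0.2)
        path = tmp_path / "m.json"
        save_model(model, path)
        loaded = load_model(path)
        windows = ["".join(BASES[i] for i in row) for row in rng.integers(0, 4, (100, 5))]
        for w in windows:
            assert loaded.prob(w) == pytest.approx(model.prob(w), abs=1e-12)

    def test_fragment_chain_round_trip(self, tmp_path):
        rng = np.random.default_rng(22)
        kmers = ["".join(BASES[i] for i in row) for row in rng.integers(0, 4, (80, 12))]
        model = train_from_kmers(kmers, tuple(range(1, 13)), fragment_length=5, pseudocount=0.2)
        path = tmp_path / "m.json"
        save_model(model, path)
        loaded = load_model(path)
        for row in rng.integers(0, 4, (30, 12)):
            w = "".join(BASES[i] for i in row)
            assert loaded.log2_prob(w) == pytest.approx(model.log2_prob(w), abs=1e-10)

    def test_truncated_file_is_schema_error(self, tmp_path):
        path = tmp_path / "m.json"
        path.write_text('{"type": "full", "window_spec": [1, 2], "probs": [0.5, 0.5]}')
        with pytest.raises(ModelSchemaError, match="expected 16"):
            load_model(path)

    def test_external_unnormalized_table_renormalized_with_warning(self, tmp_path):
        path = tmp_path / "m.json"
        probs = [0.2501] * 4  # off by 4e-4, inside the 1e-3 tolerance
        path.write_text(
            '{"type": "full", "window_spec": [1], "probs": %s}' % probs
        )
        with pytest.warns(UserWarning, match="renormaliz"):
            model = load_model(path)
        assert float(model.probs.sum()) == pytest.approx(1.0, abs=1e-12)

    def test_grossly_unnormalized_rejected(self, tmp_path):
        path = tmp_path / "m.json"
        path.write_text('{"type": "full", "window_spec": [1], "probs": [0.5, 0.5, 0.5, 0.5]}')
        with pytest.raises(ModelSchemaError, match="sum"):
            load_model(path)


def test_training_set_validates_lengths():
    with pytest.raises(ValueError, match="length"):
        TrainingSet(("ACG",), ("ACGT",), (1, 2, 3))
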