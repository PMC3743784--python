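from itertools import combinations

import numpy as np
import pandas as pd
import pytest

import mikana as mk
from mikana.regression import RegressionProblem
from mikana.selection import _Fitter


def synthetic_problem(rng, n_genes=8, m=40, kind="time_series",
                      signal=None, noise=0.0, target=0):
    """Build a RegressionProblem directly from random expression states.

    ``signal`` maps candidate-gene index -> weight; the response is the
    weighted Hill combination plus basal/degradation terms plus Gaussian
    noise (time-series kind) or zeros (steady-state kind).
    """
    genes = [f"G{i}" for i in range(n_genes)]
    states = rng.uniform(50, 2000, size=(n_genes, m))
    k = np.full(n_genes, 400.0)
    candidates = [j for j in range(n_genes) if j != target]
    hills = np.stack([mk.hill_basis(states[j], k[j], 2.0) for j in candidates])
    if kind == "time_series":
        response = np.zeros(m)
        if signal:
            for g, w in signal.items():
                response += w * hills[candidates.index(g)]
        response += -0.5 * (-(-states[target]))  # degradation: -0.5 * x
        response += noise * rng.standard_normal(m)
    else:
        response = np.zeros(m)
    design = np.column_stack(
        [hills.T, np.ones(m), -states[target]])
    meta = pd.DataFrame({"sample_id": [f"r{i}" for i in range(m)],
                         "origin": [kind] * m})
    return RegressionProblem(
        target=target, response=response, design=design,
        candidate_genes=candidates,
        labels=[f"hill:{genes[j]}" for j in candidates] + ["basal", "degradation"],
        k_values=k, row_meta=meta, genes=genes,
    )


def exhaustive_best_cost(problem, config):
    """Independent brute-force oracle: evaluate the selection cost of every
    candidate subset via plain least squares and return the minimum."""
    m = problem.n_rows
    p = problem.n_candidates
    w = problem.row_weights
    X_h = problem.design[:, :-2] * w[:, None]
    ss_only = (problem.row_meta["origin"] == "steady_state").all()
    if ss_only:
        y = -problem.design[:, -1] * w
        struct = (problem.design[:, -2] * w)[:, None]
    else:
        y = problem.response * w
        struct = np.column_stack([problem.design[:, -2] * w,
                                  problem.design[:, -1] * w])
    rms = np.sqrt(np.mean(y ** 2))
    floor = m * (config.rss_rel_floor * rms) ** 2
    best = np.inf
    for size in range(p + 1):
        for sub in combinations(range(p), size):
            X = np.column_stack([X_h[:, list(sub)], struct])
            if np.linalg.matrix_rank(X) < X.shape[1]:
                continue
            coef, *_ = np.linalg.lstsq(X, y, rcond=None)
            rss = max(float(((y - X @ coef) ** 2).sum()), floor, 1e-300)
            cost = 0.5 * m * np.log(rss / m) + size * (
                0.5 * np.log(m) + config.complexity_gamma * np.log(p))
            best = min(best, cost)
    return best


class TestSelection:
    def test_single_regressor_recovered_exactly(self):
        """Noise-free response 2*f(x_3) - 0.5*x_target selects exactly gene 3
        with the right coefficients."""
        rng = np.random.default_rng(0)
        prob = synthetic_problem(rng, signal={3: 2.0})
        res = mk.select_model(prob)
        assert [prob.candidate_genes[c] for c in res.selected] == [3]
        assert res.coefficients[0] == pytest.approx(2.0, rel=1e-6)
        assert res.degradation == pytest.approx(0.5, rel=1e-6)
        assert res.basal == pytest.approx(0.0, abs=1e-8)

    def test_matches_exhaustive_best_subset(self):
        """The iterative search attains the same minimum cost as brute-force
        enumeration of all subsets on small noisy problems."""
        config = mk.SelectionConfig()
        rng = np.random.default_rng(1)
        for trial in range(40):
            signal = {int(rng.integers(1, 8)): float(rng.uniform(0.5, 3))}
            prob = synthetic_problem(
                rng, m=30, signal=signal, noise=float(rng.uniform(0, 30)))
            res = mk.select_model(prob, config)
            oracle = exhaustive_best_cost(prob, config)
            assert res.cost == pytest.approx(oracle, abs=1e-6), f"trial {trial}"

    def test_pure_noise_rarely_selects_anything(self):
        """With an independent-Gaussian response, the selected Hill set is
        empty in the vast majority of repetitions (m and p sized so the
        best-of-p chi-square stays below the complexity threshold)."""
        rng = np.random.default_rng(2)
        empty = 0
        n_rep = 100
        for _ in range(n_rep):
            prob = synthetic_problem(rng, n_genes=6, m=2000, noise=50.0)
            res = mk.select_model(prob)
            if not res.selected:
                empty += 1
        assert empty >= 0.95 * n_rep

    def test_refit_identity(self):
        """Reported coefficients equal the (weighted) least-squares solution
        on exactly the selected columns plus the structural terms."""
        rng = np.random.default_rng(3)
        prob = synthetic_problem(rng, signal={2: 1.5, 5: -1.0}, noise=5.0)
        res = mk.select_model(prob)
        w = prob.row_weights
        cols = [prob.design[:, c] * w for c in res.selected]
        X = np.column_stack(cols + [prob.design[:, -2] * w,
                                    prob.design[:, -1] * w])
        coef, *_ = np.linalg.lstsq(X, prob.response * w, rcond=None)
        assert np.allclose(coef[:len(res.selected)], res.coefficients)
        assert coef[-1] == pytest.approx(res.degradation)

    def test_cost_trace_non_increasing(self):
        rng = np.random.default_rng(4)
        prob = synthetic_problem(rng, signal={1: 2.0, 4: 1.0}, noise=10.0)
        res = mk.select_model(prob)
        trace = np.asarray(res.cost_trace)
        assert np.all(np.diff(trace) <= 0)

    def test_deterministic(self):
        rng = np.random.default_rng(5)
        prob = synthetic_problem(rng, signal={3: 1.0}, noise=20.0)
        r1 = mk.select_model(prob)
        r2 = mk.select_model(prob)
        assert r1.selected == r2.selected
        assert np.array_equal(r1.coefficients, r2.coefficients)

    def test_too_few_rows_rejected(self):
        rng = np.random.default_rng(6)
        prob = synthetic_problem(rng, m=1)
        with pytest.raises(ValueError):
            mk.select_model(prob)

    def test_duplicated_column_dropped_not_fatal(self):
        """A duplicated candidate column (perfect collinearity) is resolved
        by dropping the later-indexed column."""
        rng = np.random.default_rng(7)
        prob = synthetic_problem(rng, signal={2: 2.0})
        prob.design[:, 4] = prob.design[:, 2]
        res = mk.select_model(prob)
        assert [prob.candidate_genes[c] for c in res.selected] == [2]

    def test_steady_state_problem_normalises_degradation_out(self):
        """Pure steady-state problems report lambda = 1 by convention and
        flag it as unidentified."""
        rng = np.random.default_rng(8)
        states = rng.uniform(50, 2000, size=(6, 30))
        genes = [f"G{i}" for i in range(6)]
        k = np.full(6, 400.0)
        target = 0
        cands = [1, 2, 3, 4, 5]
        hills = np.stack([mk.hill_basis(states[j], k[j], 2.0) for j in cands])
        # construct steady states satisfying x_0 = 3*f(x_2) * lam-free scale
        states[0] = 800.0 * hills[cands.index(2)] + 50.0
        hills = np.stack([mk.hill_basis(states[j], k[j], 2.0) for j in cands])
        design = np.column_stack([hills.T, np.ones(30), -states[0]])
        prob = RegressionProblem(
            target=0, response=np.zeros(30), design=design,
            candidate_genes=cands,
            labels=[f"hill:{genes[j]}" for j in cands] + ["basal", "degradation"],
            k_values=k,
            row_meta=pd.DataFrame({"sample_id": [f"s{i}" for i in range(30)],
                                   "origin": ["steady_state"] * 30}),
            genes=genes,
        )
        res = mk.select_model(prob)
        assert res.degradation == 1.0
        assert not res.degradation_identified
        assert [prob.candidate_genes[c] for c in res.selected] == [2]
        assert res.coefficients[0] == pytest.approx(800.0, rel=1e-6)
        assert res.basal == pytest.approx(50.0, rel=1e-4)
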