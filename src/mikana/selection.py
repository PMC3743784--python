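"""Iterative forward-backward subset selection over Hill basis terms.

For each target gene the candidate set is one Hill term per possible
regulator; the basal (constant transcription) and degradation terms are
structural (always in the model, never selectable, never edges).  The selection loop repeatedly applies the single best
add-or-drop move — adding the basis function making the largest marginal
improvement, removing the one doing the least damage — and, when no single
move improves, tries one-for-one swaps before stopping.  Model size is
governed by a description-length (BIC-style) cost

    C(S) = (m/2) ln(RSS(S) / m) + (|S|/2) ln(m)

with m rows and |S| selected Hill terms; the returned model is the
minimum-cost state encountered.

Pure steady-state problems have an identically-zero response, for which the
unconstrained joint fit is degenerate (the trivial all-zero solution).
There the degradation coefficient is constrained to 1 — equivalently the
regression x_i = sum_j (w_ij / lambda_i) f(x_j) with the degradation rate
normalised out; only the ratios w/lambda are identified, which leaves edge
presence and sign untouched.

Combined problems inherit a milder form of the same degeneracy: their
steady-state rows are homogeneous, so whenever the time-series rows are
noise-dominated the joint fit can collapse all coefficients toward zero and
the knockdown evidence is lost.  The selection search therefore profiles
the degradation rate: lambda is first estimated from the time-series rows'
own decay (structural basal + degradation fit), the subset search runs with
lambda pinned (which makes the steady-state rows fully informative), and
the selected support is then refitted jointly, iterating the lambda
estimate until the support stabilises.  On exactly-realisable data this
converges to the exact joint fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .regression import RegressionProblem

__all__ = ["SelectionConfig", "SelectionResult", "select_model"]

_RSS_FLOOR = 1e-300  # guards log(0) on numerically exact fits


@dataclass(frozen=True)
class SelectionConfig:
    """Tunables of the selection loop.

    ``min_improvement`` is the absolute cost decrease required to accept a
    move (guards cycling on ties); ``allow_swaps`` enables the one-for-one
    exchange pass used when no single move improves; ``max_terms`` caps the
    selected set (default: no cap beyond the candidate count).
    """

    min_improvement: float = 1e-9
    allow_swaps: bool = True
    max_terms: int | None = None
    max_steps: int = 10_000
    #: residual floor relative to the response RMS: RSS values below
    #: m * (rss_rel_floor * rms(y))^2 are treated as an exact fit, so the
    #: complexity penalty (not floating-point noise) decides between models
    #: that both fit to machine precision
    rss_rel_floor: float = 1e-8
    #: extended-BIC model-space weight gamma: each selected term additionally
    #: costs gamma * ln(p) (p = candidate count).  gamma = 0 recovers the
    #: plain BIC compromise, which over-admits when the candidate count is
    #: comparable to the row count, as it is in a genes-wide regression
    complexity_gamma: float = 0.5
    #: joint pair additions/removals are explored (when single moves and
    #: swaps are exhausted) only for candidate sets up to this size: the
    #: scan is quadratic in the candidate count, and the regime where local
    #: search must match exhaustive enumeration is the small one
    pair_move_max_candidates: int = 12


@dataclass
class SelectionResult:
    """Outcome of the selection loop for one target gene."""

    selected: list[int]              # Hill column indices, ascending
    coefficients: np.ndarray         # one weight per selected Hill column
    basal: float                     # fitted constant transcription term
    degradation: float               # fitted lambda (1.0 when normalised out)
    degradation_identified: bool     # False for pure steady-state problems
    cost: float
    cost_trace: list[float] = field(default_factory=list)
    rss: float = float("nan")

    def coefficient_map(self, problem: RegressionProblem) -> dict[int, float]:
        """Map regulator gene index -> fitted weight."""
        return {
            problem.candidate_genes[c]: float(w)
            for c, w in zip(self.selected, self.coefficients)
        }


def _cost(rss: float, n_terms: int, m: int, p: int,
          gamma: float, floor: float = 0.0) -> float:
    rss = max(rss, floor, _RSS_FLOOR)
    penalty = 0.5 * np.log(m) + gamma * np.log(max(p, 1))
    return 0.5 * m * np.log(rss / m) + n_terms * penalty


class _Fitter:
    """Least-squares fits of column subsets with rank-deficiency handling.

    Three fitting regimes, decided by the row composition:

    - ``constrained`` (steady-state rows only): degradation pinned to 1;
    - ``joint`` (time-series rows only): basal and degradation free;
    - ``profiled`` (mixed rows): the search fits with the degradation rate
      pinned at ``lam_hat`` (updated between search passes via
      :meth:`set_lam`), the final model is refitted jointly.

    Mixed problems additionally carry structural noise weights: measurement
    noise of level sigma/x enters a steady-state identity row at scale
    ``lambda * x`` and a time-difference row at scale ``sqrt(2) * x / dt``
    (differencing amplifies it), so rows are scaled by the inverse of these
    known propagation factors (the common noise level cancels).  Without
    this, whichever block is noisier dilutes the other's evidence under the
    single least-squares cost.  The weights are recomputed whenever the
    profiled degradation rate is updated, and any fixed positive row
    weighting leaves exactly-realisable problems exact.
    """

    def __init__(self, problem: RegressionProblem, rss_rel_floor: float = 1e-8,
                 gamma: float = 1.0):
        from .regression import TIME_SERIES

        self.p = problem
        self.m = problem.n_rows
        self.n_candidates = problem.n_candidates
        self.constrained = problem.is_steady_state_only()
        self.rss_rel_floor = rss_rel_floor
        self.gamma = gamma
        origins = problem.row_meta["origin"].to_numpy() if self.m else np.array([])
        self.ts_mask = origins == TIME_SERIES
        self.profiled = (not self.constrained) and 0 < self.ts_mask.sum() < self.m
        # raw (delta-t-weighted) rows
        w0 = problem.row_weights
        self._rX = problem.design[:, :-2] * w0[:, None]
        self._rb = problem.design[:, -2] * w0
        self._rd = problem.design[:, -1] * w0
        if self.constrained:
            # degradation coefficient pinned to 1: residual = c + H w - x_target
            self._ry = -problem.design[:, -1] * w0
        else:
            self._ry = problem.response * w0
        self.lam_hat = self._initial_lam() if self.profiled else None
        self._rescale()

    def _initial_lam(self) -> float:
        """Degradation pilot from the time-series rows' own decay."""
        mask = self.ts_mask if self.ts_mask.sum() >= 2 else np.ones(self.m, bool)
        X0 = np.column_stack([self._rb[mask], self._rd[mask]])
        coef, *_ = np.linalg.lstsq(X0, self._ry[mask], rcond=None)
        return max(float(coef[1]), 0.0)

    def _rescale(self) -> None:
        scale = np.ones(self.m)
        if self.profiled:
            # |x_target| per row: the degradation column is -x * dt-weight
            w0 = self.p.row_weights
            x_abs = np.abs(self.p.design[:, -1])
            x_ss = float(np.median(x_abs[~self.ts_mask]))
            x_ts = float(np.median(x_abs[self.ts_mask]))
            # rates slower than the observed time span are unresolvable
            lam_floor = 1.0 / max(float(w0[self.ts_mask].sum()), 1e-12)
            s_ss = max(self.lam_hat, lam_floor) * max(x_ss, 1e-12)
            s_ts = np.sqrt(2.0) * max(x_ts, 1e-12)
            scale[~self.ts_mask] = 1.0 / s_ss
            scale[self.ts_mask] = 1.0 / s_ts
        self.X_hill = self._rX * scale[:, None]
        self.basal = self._rb * scale
        self.degr = self._rd * scale
        self.y = self._ry * scale
        rms = float(np.sqrt(np.mean(self.y ** 2))) if self.m else 0.0
        self.rss_floor = self.m * (self.rss_rel_floor * rms) ** 2

    def set_lam(self, lam: float) -> None:
        """Update the profiled degradation rate and its noise weights."""
        self.lam_hat = lam
        self._rescale()

    def fit(self, subset: tuple[int, ...], joint: bool = False):
        """Return (rss, hill_coefs, basal, lambda, effective_subset).

        ``joint`` forces the free-degradation fit regardless of regime
        (used for the final refit of profiled problems).  Rank deficiency
        is resolved by dropping later-indexed dependent columns until the
        design has full column rank.
        """
        subset = tuple(subset)
        pinned = self.profiled and not joint
        y = self.y - self.lam_hat * self.degr if pinned else self.y
        while True:
            cols = [self.X_hill[:, list(subset)]] if subset else []
            if self.constrained or pinned:
                X = np.column_stack(cols + [self.basal[:, None]])
            else:
                X = np.column_stack(
                    cols + [self.basal[:, None], self.degr[:, None]])
            ncol = X.shape[1]
            coef, res, rank, _ = np.linalg.lstsq(X, y, rcond=None)
            if rank < ncol and subset:
                subset = subset[:-1]  # drop the latest-indexed column
                continue
            r = y - X @ coef
            rss = float(r @ r)
            n_hill = len(subset)
            if self.constrained:
                return rss, coef[:n_hill], float(coef[n_hill]), 1.0, subset
            if pinned:
                return (rss, coef[:n_hill], float(coef[n_hill]),
                        self.lam_hat, subset)
            return (rss, coef[:n_hill], float(coef[n_hill]),
                    float(coef[n_hill + 1]), subset)

    def cost(self, subset: tuple[int, ...]) -> float:
        rss, _, _, _, eff = self.fit(subset)
        return _cost(rss, len(eff), self.m, self.n_candidates,
                     self.gamma, self.rss_floor)


def _greedy_search(fitter: _Fitter, config: SelectionConfig):
    """One pass of the add/drop/swap search; returns (best_set, trace)."""
    p = fitter.n_candidates
    cap = p if config.max_terms is None else min(p, config.max_terms)
    current: tuple[int, ...] = ()
    cur_cost = fitter.cost(current)
    trace = [cur_cost]
    best_set, best_cost = current, cur_cost
    for _ in range(config.max_steps):
        move, move_cost = None, cur_cost - config.min_improvement
        # forward: largest marginal improvement (ties -> lowest column index)
        if len(current) < cap:
            for j in range(p):
                if j in current:
                    continue
                c = fitter.cost(tuple(sorted(current + (j,))))
                if c < move_cost:
                    move, move_cost = tuple(sorted(current + (j,))), c
        # backward: least damage (only accepted if it lowers the cost)
        for j in current:
            c = fitter.cost(tuple(k for k in current if k != j))
            if c < move_cost:
                move, move_cost = tuple(k for k in current if k != j), c
        # deeper neighbourhood, only when no single move improves:
        # one-for-one swaps, then joint pair additions and pair removals
        # (a pair of complementary regressors can improve the fit where
        # neither does alone)
        if move is None and config.allow_swaps:
            for j_out in current:
                base = tuple(k for k in current if k != j_out)
                for j_in in range(p):
                    if j_in in current:
                        continue
                    cand = tuple(sorted(base + (j_in,)))
                    c = fitter.cost(cand)
                    if c < move_cost:
                        move, move_cost = cand, c
        if move is None and config.allow_swaps \
                and p <= config.pair_move_max_candidates:
            outside = [j for j in range(p) if j not in current]
            if len(current) + 2 <= cap:
                for i, j1 in enumerate(outside):
                    for j2 in outside[i + 1:]:
                        cand = tuple(sorted(current + (j1, j2)))
                        c = fitter.cost(cand)
                        if c < move_cost:
                            move, move_cost = cand, c
            inside = list(current)
            for i, j1 in enumerate(inside):
                for j2 in inside[i + 1:]:
                    cand = tuple(k for k in current if k not in (j1, j2))
                    c = fitter.cost(cand)
                    if c < move_cost:
                        move, move_cost = cand, c
        if move is None:
            break
        current, cur_cost = move, move_cost
        trace.append(cur_cost)
        if cur_cost < best_cost:
            best_set, best_cost = current, cur_cost
    return best_set, trace


def select_model(
    problem: RegressionProblem, config: SelectionConfig | None = None
) -> SelectionResult:
    """Run the iterative add/drop(/swap) selection on one regression problem."""
    config = config or SelectionConfig()
    if problem.n_rows < 2:
        raise ValueError("need at least 2 rows for model selection")
    fitter = _Fitter(problem, rss_rel_floor=config.rss_rel_floor,
                     gamma=config.complexity_gamma)

    best_set, trace = _greedy_search(fitter, config)
    if fitter.profiled:
        # iterate the profiled degradation rate: refit the selected support
        # jointly, update lambda-hat, re-run the search until stable
        for _ in range(3):
            _, _, _, lam_joint, _ = fitter.fit(best_set, joint=True)
            if lam_joint <= 0.0:
                break  # keep the decay-based pilot
            if abs(lam_joint - fitter.lam_hat) <= 1e-9 * (1.0 + fitter.lam_hat):
                break
            fitter.set_lam(lam_joint)
            new_set, trace = _greedy_search(fitter, config)
            if new_set == best_set:
                break
            best_set = new_set

    rss, coefs, basal, lam, eff = fitter.fit(best_set, joint=fitter.profiled)
    eff = tuple(sorted(eff))
    if eff != best_set:  # rank-deficiency pruned columns during the final fit
        rss, coefs, basal, lam, eff = fitter.fit(eff, joint=fitter.profiled)
    # drop exactly-zero coefficients so every edge maps to a nonzero weight
    keep = [i for i, w in enumerate(coefs) if w != 0.0]
    selected = [eff[i] for i in keep]
    coefs = coefs[keep] if len(keep) else np.zeros(0)
    return SelectionResult(
        selected=list(selected),
        coefficients=np.asarray(coefs, dtype=float),
        basal=basal,
        degradation=lam,
        degradation_identified=not fitter.constrained,
        cost=_cost(rss, len(selected), fitter.m, fitter.n_candidates,
                   fitter.gamma, fitter.rss_floor),
        cost_trace=trace,
        rss=rss,
    )
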