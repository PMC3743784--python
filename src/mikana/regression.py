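"""Assembly of per-gene regression problems from expression datasets.

The inference model writes each gene's dynamics as a weighted sum of Hill
basis terms of candidate regulators minus first-order degradation:

    dx_i/dt = sum_j w_ij f(x_j) - lambda_i x_i,   f(x) = x^n / (K^n + x^n).

Three data regimes map onto the same column structure (one Hill column per
candidate regulator, plus two structural columns: a constant basal-
transcription term and the degradation column ``-x_i``; the structural
columns are always in the fitted model and never count as edges):

- steady state:   0 = sum_j w_ij f(x_j) - lambda_i x_i   per knockdown
  equilibrium (the sample that perturbed gene *i* itself is excluded, since
  the perturbation strength there is unknown);
- time series:    (x_i(t_{k+1}) - x_i(t_k)) / (t_{k+1} - t_k) on the left,
  regressors evaluated at t_k, within replicates only;
- combined:       the row-wise stack of both, sharing one column structure —
  the right-hand sides of the two regimes are identical, which is what makes
  the simultaneous fit possible.

Rows carry fitting weights that normalise measurement-noise propagation:
a finite-difference row is weighted by its time step (equivalently, fitted
in integrated Δx units), since differencing amplifies expression noise by
1/Δt while steady-state rows carry it at the expression scale.  Without
this, densely sampled noisy time courses drown the knockdown rows in a
combined fit.  For a uniform grid the weighting is a no-op for pure
time-series problems (a common row scale shifts the selection cost by a
constant), so it only matters where the two row types meet.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasets import ExpressionDataset, STEADY_STATE, TIME_SERIES

__all__ = [
    "BasisConfig",
    "RegressionProblem",
    "InsufficientDataError",
    "hill_basis",
    "build_ss_problem",
    "build_ts_problem",
    "build_combined_problem",
]


class InsufficientDataError(ValueError):
    """Not enough rows to pose the regression."""


@dataclass(frozen=True)
class BasisConfig:
    """Hill-basis configuration.

    ``half_saturation_rule`` is either ``"median"`` (per regressor gene, the
    median of that gene's expression over the rows entering the problem,
    floored at ``k_floor``) or ``"fixed"`` (a single constant ``k_fixed`` for
    every gene).  ``hill_n`` is the Hill exponent.
    """

    hill_n: float = 2.0
    half_saturation_rule: str = "median"
    k_fixed: float | None = None
    k_floor: float = 1e-6
    #: weight finite-difference rows by their time step so that measurement
    #: noise enters steady-state and time-series rows at the same scale in a
    #: combined fit; set False for plain unweighted stacking
    ts_row_scaling: bool = True

    def __post_init__(self) -> None:
        if self.hill_n <= 0:
            raise ValueError("hill_n must be > 0")
        if self.half_saturation_rule not in ("median", "fixed"):
            raise ValueError("half_saturation_rule must be 'median' or 'fixed'")
        if self.half_saturation_rule == "fixed":
            if self.k_fixed is None or self.k_fixed <= 0:
                raise ValueError("fixed rule requires k_fixed > 0")


def hill_basis(x, k: float, n: float):
    """Hill activation ``x^n / (k^n + x^n)`` in [0, 1); x is floored at 0."""
    if np.any(np.asarray(k) <= 0):
        raise ValueError("half-saturation constant k must be > 0")
    xf = np.maximum(np.asarray(x, dtype=float), 0.0)
    xn = xf ** n
    return xn / (np.asarray(k, dtype=float) ** n + xn)


@dataclass
class RegressionProblem:
    """Response vector and candidate-regressor design for one target gene.

    Columns are ordered: one Hill column per candidate regulator gene
    (ascending gene index, target excluded — self-regulation is collinear
    with degradation), then the basal (constant) column, then the
    degradation column ``-x_target``.  The last two are structural: always
    fitted, never selectable, never edges.
    """

    target: int
    response: np.ndarray
    design: np.ndarray
    candidate_genes: list[int]
    labels: list[str]
    k_values: np.ndarray
    row_meta: pd.DataFrame
    genes: list[str]
    row_weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.response = np.asarray(self.response, dtype=float)
        self.design = np.asarray(self.design, dtype=float)
        if self.design.shape[0] != self.response.shape[0]:
            raise ValueError("design row count must equal response length")
        if self.design.shape[1] != len(self.candidate_genes) + 2:
            raise ValueError(
                "expect one Hill column per candidate + basal + degradation")
        if self.target in self.candidate_genes:
            raise ValueError("target gene must not be its own candidate")
        if self.row_weights is None:
            self.row_weights = np.ones(self.design.shape[0])
        else:
            self.row_weights = np.asarray(self.row_weights, dtype=float)
            if self.row_weights.shape != (self.design.shape[0],):
                raise ValueError("row_weights must have one entry per row")
            if np.any(self.row_weights <= 0):
                raise ValueError("row_weights must be strictly positive")

    @property
    def n_rows(self) -> int:
        return self.design.shape[0]

    @property
    def n_candidates(self) -> int:
        return len(self.candidate_genes)

    @property
    def basal_column(self) -> int:
        return self.design.shape[1] - 2

    @property
    def degradation_column(self) -> int:
        return self.design.shape[1] - 1

    def is_steady_state_only(self) -> bool:
        """True when every row is a steady-state (zero-response) row."""
        return bool((self.row_meta["origin"] == STEADY_STATE).all())


def _median_k(states: np.ndarray, basis: BasisConfig) -> np.ndarray:
    """Per-gene half-saturation constants for the rows at hand."""
    n_genes = states.shape[0]
    if basis.half_saturation_rule == "fixed":
        return np.full(n_genes, float(basis.k_fixed))
    med = np.median(np.maximum(states, 0.0), axis=1)
    return np.maximum(med, basis.k_floor)


def _assemble(
    target: int,
    states: np.ndarray,
    response: np.ndarray,
    row_meta: pd.DataFrame,
    genes: list[str],
    basis: BasisConfig,
    row_weights: np.ndarray | None = None,
) -> RegressionProblem:
    """Shared column construction: Hill columns from the per-row states
    (columns of ``states``), then the degradation column ``-x_target``."""
    n_genes = states.shape[0]
    k = _median_k(states, basis)
    candidates = [j for j in range(n_genes) if j != target]
    hill_cols = [hill_basis(states[j], k[j], basis.hill_n) for j in candidates]
    basal = np.ones(states.shape[1])
    degr = -states[target]
    design = np.column_stack(hill_cols + [basal, degr])
    labels = [f"hill:{genes[j]}" for j in candidates] + ["basal", "degradation"]
    return RegressionProblem(
        target=target, response=response, design=design,
        candidate_genes=candidates, labels=labels, k_values=k,
        row_meta=row_meta.reset_index(drop=True), genes=list(genes),
        row_weights=row_weights,
    )


def _ss_rows(data: ExpressionDataset, target: int):
    """Retained steady-state sample columns (perturbed-target row removed)."""
    genes = data.genes
    keep = data.meta["perturbed_gene"] != genes[target]
    states = data.values[:, keep.to_numpy()]
    meta = data.meta.loc[keep, ["sample_id"]].copy()
    meta["origin"] = STEADY_STATE
    return states, meta


def _ts_rows(data: ExpressionDataset, target: int):
    """Consecutive time-pair rows within each replicate; regressors at the
    left time point, response the forward difference of the target gene."""
    states_cols, resp, meta_rows, dts = [], [], [], []
    for rep, grp in data.meta.groupby("replicate", sort=True):
        idx = grp.index.to_numpy()
        t = grp["time_h"].astype(float).to_numpy()
        if len(idx) < 2:
            raise InsufficientDataError(
                f"replicate {rep!r} has {len(idx)} time point(s); need >= 2"
            )
        for k in range(len(idx) - 1):
            left, right = idx[k], idx[k + 1]
            dt = t[k + 1] - t[k]
            states_cols.append(data.values[:, left])
            dts.append(dt)
            resp.append((data.values[target, right] - data.values[target, left]) / dt)
            meta_rows.append({
                "sample_id": f"{data.meta.at[left, 'sample_id']}"
                             f"->{data.meta.at[right, 'sample_id']}",
                "origin": TIME_SERIES,
            })
    states = np.column_stack(states_cols) if states_cols else np.zeros((data.n_genes, 0))
    return (states, np.asarray(resp, dtype=float), pd.DataFrame(meta_rows),
            np.asarray(dts, dtype=float))


def build_ss_problem(
    data: ExpressionDataset, target: int, basis: BasisConfig | None = None
) -> RegressionProblem:
    """Steady-state regression (zero response) for one target gene."""
    basis = basis or BasisConfig()
    if (data.meta["kind"] != STEADY_STATE).any():
        raise ValueError("dataset must contain only steady-state samples")
    target = data.gene_index(target)
    states, meta = _ss_rows(data, target)
    if states.shape[1] == 0:
        raise InsufficientDataError(
            f"no steady-state rows remain for target {data.genes[target]}"
        )
    response = np.zeros(states.shape[1])
    return _assemble(target, states, response, meta, data.genes, basis)


def build_ts_problem(
    data: ExpressionDataset, target: int, basis: BasisConfig | None = None
) -> RegressionProblem:
    """Finite-difference time-series regression for one target gene."""
    basis = basis or BasisConfig()
    if (data.meta["kind"] != TIME_SERIES).any():
        raise ValueError("dataset must contain only time-series samples")
    if data.is_empty():
        raise InsufficientDataError("empty time-series dataset")
    target = data.gene_index(target)
    states, response, meta, dts = _ts_rows(data, target)
    weights = dts if basis.ts_row_scaling else None
    return _assemble(target, states, response, meta, data.genes, basis,
                     row_weights=weights)


def build_combined_problem(
    ss: ExpressionDataset | None,
    ts: ExpressionDataset | None,
    target: int,
    basis: BasisConfig | None = None,
) -> RegressionProblem:
    """Stack of time-series and steady-state rows with one shared column
    structure (median half-saturations computed over all retained rows)."""
    basis = basis or BasisConfig()
    ss_empty = ss is None or ss.is_empty()
    ts_empty = ts is None or ts.is_empty()
    if ss_empty and ts_empty:
        raise InsufficientDataError("both datasets empty")
    if ts_empty:
        return build_ss_problem(ss, target, basis)
    if ss_empty:
        return build_ts_problem(ts, target, basis)
    if ss.genes != ts.genes:
        raise ValueError("gene lists of the two datasets disagree")
    target = ts.gene_index(target)
    ts_states, ts_resp, ts_meta, dts = _ts_rows(ts, target)
    ss_states, ss_meta = _ss_rows(ss, target)
    states = np.concatenate([ts_states, ss_states], axis=1)
    response = np.concatenate([ts_resp, np.zeros(ss_states.shape[1])])
    meta = pd.concat([ts_meta, ss_meta], ignore_index=True)
    weights = None
    if basis.ts_row_scaling:
        weights = np.concatenate([dts, np.ones(ss_states.shape[1])])
    return _assemble(target, states, response, meta, ts.genes, basis,
                     row_weights=weights)
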