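"""Network-inference model and results objects.

:class:`MIKANA` is built from expression data (steady-state knockdown
samples, time-series samples, or both) and a mode:

- ``"ss"``       — steady-state regression per gene (ssMIKANA);
- ``"ts"``       — finite-difference time-series regression (tsMIKANA);
- ``"combined"`` — simultaneous fit of the stacked rows (cMIKANA).

``fit()`` runs the per-gene regression assembly and iterative subset
selection and returns a :class:`MIKANAResults` carrying the fitted
coefficients, degradation rates, per-gene cost traces, the derived signed
network (edge j -> i for every selected Hill term, sign = sign(w_ij)), and a
``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import ExpressionDataset
from .network import GeneNetwork
from .regression import (
    BasisConfig,
    RegressionProblem,
    build_combined_problem,
    build_ss_problem,
    build_ts_problem,
)
from .selection import SelectionConfig, SelectionResult, select_model

__all__ = ["MIKANA", "MIKANAResults", "infer_network", "MODES"]

MODES = ("ss", "ts", "combined")


class MIKANA:
    """ODE-regression gene-network inference model.

    Parameters
    ----------
    steady_state, time_series : ExpressionDataset or None
        Input data; which are required depends on ``mode``.  Gene lists must
        agree when both are given.
    mode : {"ss", "ts", "combined"}
    basis : BasisConfig, optional
        Hill exponent and half-saturation rule (default: n = 2, per-gene
        data median).
    selection : SelectionConfig, optional
        Cost/stopping tunables of the subset-selection loop.
    """

    def __init__(
        self,
        steady_state: ExpressionDataset | None = None,
        time_series: ExpressionDataset | None = None,
        mode: str = "combined",
        basis: BasisConfig | None = None,
        selection: SelectionConfig | None = None,
    ):
        if mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        self.mode = mode
        self.basis = basis or BasisConfig()
        self.selection = selection or SelectionConfig()
        self.steady_state = self._only(steady_state, "steady_state")
        self.time_series = self._only(time_series, "time_series")
        if mode == "ss" and self._empty(self.steady_state):
            raise ValueError("mode 'ss' requires steady-state data")
        if mode == "ts" and self._empty(self.time_series):
            raise ValueError("mode 'ts' requires time-series data")
        if mode == "combined" and self._empty(self.steady_state) \
                and self._empty(self.time_series):
            raise ValueError("mode 'combined' requires at least one dataset")
        self.genes = self._aligned_genes()

    @staticmethod
    def _only(data: ExpressionDataset | None, kind_attr: str):
        if data is None:
            return None
        return getattr(data, kind_attr)()

    @staticmethod
    def _empty(data: ExpressionDataset | None) -> bool:
        return data is None or data.is_empty()

    def _aligned_genes(self) -> list[str]:
        ss, ts = self.steady_state, self.time_series
        if not self._empty(ss) and not self._empty(ts):
            if ss.genes != ts.genes:
                offenders = sorted(set(ss.genes) ^ set(ts.genes))
                raise ValueError(
                    "gene sets of steady-state and time-series data disagree; "
                    f"offending genes: {offenders[:10]}"
                )
            return list(ss.genes)
        return list(ss.genes if not self._empty(ss) else ts.genes)

    @classmethod
    def from_dataframes(
        cls,
        expression: pd.DataFrame,
        meta: pd.DataFrame,
        mode: str = "combined",
        **kwargs,
    ) -> "MIKANA":
        """Build from a genes x samples DataFrame plus a metadata table
        (columns as in :data:`mikana.datasets.META_COLUMNS`)."""
        meta = meta.set_index("sample_id", drop=False).loc[expression.columns]
        data = ExpressionDataset(
            values=expression.to_numpy(dtype=float),
            genes=list(expression.index),
            meta=meta.reset_index(drop=True),
        )
        return cls(steady_state=data, time_series=data, mode=mode, **kwargs)

    # -- fitting ---------------------------------------------------------
    def build_problem(self, target: int) -> RegressionProblem:
        if self.mode == "ss":
            return build_ss_problem(self.steady_state, target, self.basis)
        if self.mode == "ts":
            return build_ts_problem(self.time_series, target, self.basis)
        return build_combined_problem(
            self.steady_state, self.time_series, target, self.basis
        )

    def fit(self) -> "MIKANAResults":
        """Model selection gene by gene; returns the fitted results object."""
        per_gene: dict[int, SelectionResult] = {}
        edges: dict[tuple[int, int], int] = {}
        weights: dict[tuple[int, int], float] = {}
        for i in range(len(self.genes)):
            problem = self.build_problem(i)
            result = select_model(problem, self.selection)
            per_gene[i] = result
            for j, w in result.coefficient_map(problem).items():
                edges[(j, i)] = 1 if w > 0 else -1
                weights[(j, i)] = w
        network = GeneNetwork(
            n_genes=len(self.genes), edges=edges, weights=weights,
            names=tuple(self.genes),
        )
        return MIKANAResults(model=self, network=network, per_gene=per_gene)


@dataclass
class MIKANAResults:
    """Fitted inference results.

    ``network`` is the inferred signed, weighted :class:`GeneNetwork`;
    ``per_gene`` maps target-gene index to its :class:`SelectionResult`
    (selected regulators, coefficients, fitted degradation rate, cost trace).
    """

    model: MIKANA
    network: GeneNetwork
    per_gene: dict[int, SelectionResult] = field(default_factory=dict)

    @property
    def genes(self) -> list[str]:
        return self.model.genes

    @property
    def degradation_rates(self) -> pd.Series:
        """Fitted lambda_i per gene (1.0 by convention in 'ss' mode, where
        only the ratios w/lambda are identified)."""
        return pd.Series(
            {self.genes[i]: r.degradation for i, r in self.per_gene.items()},
            name="lambda",
        )

    @property
    def basal_rates(self) -> pd.Series:
        """Fitted constant (basal transcription) term per gene."""
        return pd.Series(
            {self.genes[i]: r.basal for i, r in self.per_gene.items()},
            name="basal",
        )

    @property
    def cost_traces(self) -> dict[str, list[float]]:
        return {self.genes[i]: r.cost_trace for i, r in self.per_gene.items()}

    def to_edge_frame(self) -> pd.DataFrame:
        """Long-format edge table: parent, child, weight, sign."""
        rows = [
            {
                "parent": self.genes[a], "child": self.genes[b],
                "weight": self.network.weights[(a, b)], "sign": s,
            }
            for (a, b), s in sorted(self.network.edges.items())
        ]
        return pd.DataFrame(rows, columns=["parent", "child", "weight", "sign"])

    def score(self, truth: GeneNetwork):
        """Edge-wise sensitivity/FDR against a ground-truth network."""
        from .evaluate import score_edges

        return score_edges(self.network, truth)

    def summary(self) -> str:
        lines = [
            "MIKANA network inference results",
            "=" * 48,
            f"mode:            {self.model.mode}",
            f"genes:           {len(self.genes)}",
            f"inferred edges:  {self.network.n_edges}",
            f"Hill exponent:   {self.model.basis.hill_n}",
            f"half-saturation: {self.model.basis.half_saturation_rule}",
            "",
            f"{'gene':<16}{'#regulators':>12}{'lambda':>12}{'cost':>14}",
            "-" * 54,
        ]
        for i, r in self.per_gene.items():
            lam = f"{r.degradation:.4g}" if r.degradation_identified else "n/a"
            lines.append(
                f"{self.genes[i]:<16}{len(r.selected):>12}{lam:>12}"
                f"{r.cost:>14.4f}"
            )
        return "\n".join(lines)


def infer_network(
    ss: ExpressionDataset | None,
    ts: ExpressionDataset | None,
    mode: str,
    basis: BasisConfig | None = None,
    selection: SelectionConfig | None = None,
) -> MIKANAResults:
    """Functional entry point: build a :class:`MIKANA` model and fit it."""
    return MIKANA(
        steady_state=ss, time_series=ts, mode=mode,
        basis=basis, selection=selection,
    ).fit()
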