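"""End-to-end simulation studies: noise sweep, matched-budget comparison,
and edge-directionality analysis.

Each study draws ground-truth networks and kinetic models per simulation
index, simulates knockdown (steady-state) and broad-perturbation
(time-series) expression data, adds measurement noise, runs the requested
inference modes, and scores the inferred networks against the truth.  All
randomness derives deterministically from ``(base_seed, simulation index,
condition)``, and arms of a matched comparison share the same network,
kinetic model and reference state.

Full-scale defaults (100 genes, 50 simulations) are expensive; the
``desk_scale`` presets (30 genes, 10 simulations) give the same qualitative
orderings in minutes on one CPU.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasets import ExpressionDataset
from .evaluate import directionality_proportions, score_edges
from .kinetics import (
    StabilityError,
    add_noise,
    find_reference_state,
    sample_parameters,
    simulate_steady_state_dataset,
    simulate_timeseries,
    well_specified_instance,
)
from .model import infer_network
from .network import GeneNetwork, TopologyConfig, generate_scale_free
from .regression import BasisConfig

__all__ = [
    "ExperimentDesign",
    "ExperimentResult",
    "derive_seed",
    "simulate_instance",
    "run_noise_sweep",
    "run_budget_comparison",
    "run_directionality_study",
]

DESIGN_KINDS = ("noise_sweep", "budget_comparison", "directionality")


def derive_seed(base_seed: int, *keys: int) -> int:
    """Deterministic child seed from a base seed and integer keys (< 2^31)."""
    ss = np.random.SeedSequence([int(base_seed), *[int(k) for k in keys]])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass(frozen=True)
class ExperimentDesign:
    """Configuration of one simulation study.

    ``generator`` selects the data-generating model: ``"saturating"`` (the
    benchmark kinetics, deliberately of a different functional form than the
    inference regression) or ``"linear_hill"`` (the well-specified oracle,
    used for noiseless sanity limits).
    """

    design_kind: str
    n_genes: int = 100
    n_simulations: int = 50
    noise_levels: tuple[float, ...] = (0.1,)
    timepoint_counts: tuple[int, ...] = (10,)
    replicate_counts: tuple[int, ...] = (3,)
    ss_sample_counts: tuple[int, ...] = ()
    k_av: float = 3.0
    base_seed: int = 0
    generator: str = "saturating"

    def __post_init__(self) -> None:
        if self.design_kind not in DESIGN_KINDS:
            raise ValueError(f"design_kind must be one of {DESIGN_KINDS}")
        if not self.noise_levels or not self.timepoint_counts \
                or not self.replicate_counts:
            raise ValueError("condition lists must be non-empty")
        if any(not 0.0 <= lv <= 1.0 for lv in self.noise_levels):
            raise ValueError("noise levels must lie in [0, 1]")
        if self.generator not in ("saturating", "linear_hill"):
            raise ValueError("generator must be 'saturating' or 'linear_hill'")

    @classmethod
    def full_scale(cls, design_kind: str, base_seed: int = 0) -> "ExperimentDesign":
        if design_kind == "noise_sweep":
            return cls(design_kind, 100, 50,
                       (0.01, 0.03, 0.05, 0.08, 0.10, 0.13, 0.15, 0.18, 0.20),
                       (10,), (3,), base_seed=base_seed)
        if design_kind == "budget_comparison":
            return cls(design_kind, 100, 50, (0.10,), (5, 10, 20, 40), (3,),
                       base_seed=base_seed)
        return cls("directionality", 100, 50, (0.10,), (10,), (10,),
                   base_seed=base_seed)

    @classmethod
    def desk_scale(cls, design_kind: str, base_seed: int = 0) -> "ExperimentDesign":
        """30-gene, 10-simulation preset.  The matched-budget list is
        (5, 10, 15) time points because the combined arm needs 2T distinct
        knockdown targets, capped by the 30-gene network."""
        if design_kind == "noise_sweep":
            return cls(design_kind, 30, 10, (0.10,), (10,), (3,),
                       base_seed=base_seed)
        if design_kind == "budget_comparison":
            return cls(design_kind, 30, 10, (0.10,), (5, 10, 15), (3,),
                       base_seed=base_seed)
        return cls("directionality", 30, 10, (0.10,), (10,), (10,),
                   base_seed=base_seed)


@dataclass
class ExperimentResult:
    """Raw per-simulation scores plus per-condition mean/sd summary."""

    design: ExperimentDesign
    raw: pd.DataFrame
    summary: pd.DataFrame
    failures: pd.DataFrame

    def to_tsv(self, out_dir) -> None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.raw.to_csv(out / "raw.tsv", sep="\t", index=False)
        self.summary.to_csv(out / "summary.tsv", sep="\t", index=False)
        self.failures.to_csv(out / "failures.tsv", sep="\t", index=False)
        with open(out / "provenance.tsv", "w") as fh:
            for k, v in vars(self.design).items():
                fh.write(f"{k}\t{v}\n")

    def plot(self, x: str, y: str = "sensitivity", hue: str = "mode", ax=None):
        """Simple per-condition mean line plot of the summary table."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for key, grp in self.summary.groupby(hue):
            ax.plot(grp[x], grp[f"{y}_mean"], marker="o", label=str(key))
        ax.set_xlabel(x)
        ax.set_ylabel(y)
        ax.legend(title=hue)
        return ax


# ---------------------------------------------------------------------------
# instance generation
# ---------------------------------------------------------------------------

def simulate_instance(design: ExperimentDesign, sim: int, max_tries: int = 20):
    """Ground-truth network + kinetic model with a settled reference state.

    Draws are retried with fresh derived seeds when a sampled model fails to
    settle, so every simulation index yields a stable instance
    deterministically.
    """
    for attempt in range(max_tries):
        seed = derive_seed(design.base_seed, sim, attempt)
        try:
            if design.generator == "linear_hill":
                model = well_specified_instance(
                    design.n_genes,
                    int(round(design.k_av * design.n_genes / 2.0)),
                    seed=seed,
                )
                return model
            net = generate_scale_free(TopologyConfig(
                n_genes=design.n_genes, k_av=design.k_av, seed=seed,
            ))
            model = sample_parameters(net, seed=derive_seed(seed, 1))
            find_reference_state(model, seed=derive_seed(seed, 2))
            return model
        except StabilityError:
            continue
    raise StabilityError(
        f"no stable instance for simulation {sim} after {max_tries} tries"
    )


def _basis_for(design: ExperimentDesign, model) -> BasisConfig:
    if design.generator == "linear_hill":
        return BasisConfig(hill_n=model.n, half_saturation_rule="fixed",
                           k_fixed=model.k)
    return BasisConfig()


def _rho_range(design: ExperimentDesign) -> tuple[float, float]:
    # the well-specified oracle keeps initial perturbations inside the
    # positive basin of its Hill-squared dynamics
    return (-0.5, 0.5) if design.generator == "linear_hill" else (-1.0, 1.0)


def _score_row(result, truth: GeneNetwork, **extra) -> dict:
    s = result.score(truth)
    return {
        **extra, "tp": s.tp, "fp": s.fp, "fn": s.fn,
        "sensitivity": s.sensitivity, "fdr": s.fdr,
        "n_inferred": result.network.n_edges, "n_truth": truth.n_edges,
    }


def _summarise(raw: pd.DataFrame, by: list[str]) -> pd.DataFrame:
    agg = raw.groupby(by, as_index=False).agg(
        sensitivity_mean=("sensitivity", "mean"),
        sensitivity_sd=("sensitivity", "std"),
        fdr_mean=("fdr", "mean"),
        fdr_sd=("fdr", "std"),
        n_sims=("sensitivity", "size"),
    )
    return agg


# ---------------------------------------------------------------------------
# studies
# ---------------------------------------------------------------------------

def run_noise_sweep(design: ExperimentDesign) -> ExperimentResult:
    """Sn/FDR of the three inference modes across measurement-noise levels."""
    if design.design_kind != "noise_sweep":
        raise ValueError("design_kind must be 'noise_sweep'")
    T = design.timepoint_counts[0]
    R = design.replicate_counts[0]
    rows, fails = [], []
    for sim in range(design.n_simulations):
        try:
            model = simulate_instance(design, sim)
            basis = _basis_for(design, model)
            truth = model.network
            ss_clean = simulate_steady_state_dataset(
                model, list(range(design.n_genes)),
                seed=derive_seed(design.base_seed, sim, 101),
            )
            ts_clean = simulate_timeseries(
                model, T, R, seed=derive_seed(design.base_seed, sim, 102),
                rho_range=_rho_range(design),
            )
            for c, level in enumerate(design.noise_levels):
                ss = add_noise(ss_clean, level,
                               seed=derive_seed(design.base_seed, sim, 200 + c))
                ts = add_noise(ts_clean, level,
                               seed=derive_seed(design.base_seed, sim, 300 + c))
                for mode in ("ss", "ts", "combined"):
                    res = infer_network(
                        ss if mode != "ts" else None,
                        ts if mode != "ss" else None,
                        mode=mode, basis=basis,
                    )
                    rows.append(_score_row(
                        res, truth, sim=sim, noise_level=level, mode=mode,
                    ))
        except StabilityError as exc:
            fails.append({"sim": sim, "error": str(exc)})
    raw = pd.DataFrame(rows)
    return ExperimentResult(
        design=design, raw=raw,
        summary=_summarise(raw, ["noise_level", "mode"]),
        failures=pd.DataFrame(fails, columns=["sim", "error"]),
    )


def run_budget_comparison(design: ExperimentDesign) -> ExperimentResult:
    """tsMIKANA (T points x R replicates) vs cMIKANA (T points x 1 replicate
    + (R-1)T knockdowns) at identical total sample budgets."""
    if design.design_kind != "budget_comparison":
        raise ValueError("design_kind must be 'budget_comparison'")
    R = design.replicate_counts[0]
    level = design.noise_levels[0]
    for T in design.timepoint_counts:
        if (R - 1) * T > design.n_genes:
            raise ValueError(
                f"budget T={T} needs {(R - 1) * T} distinct knockdown targets "
                f"but the network has only {design.n_genes} genes"
            )
    rows, fails = [], []
    for sim in range(design.n_simulations):
        try:
            model = simulate_instance(design, sim)
            basis = _basis_for(design, model)
            truth = model.network
            for c, T in enumerate(design.timepoint_counts):
                budget = R * T
                # ts arm: R replicates of T points
                ts_multi = simulate_timeseries(
                    model, T, R,
                    seed=derive_seed(design.base_seed, sim, 400 + c),
                    rho_range=_rho_range(design),
                )
                ts_multi = add_noise(
                    ts_multi, level,
                    seed=derive_seed(design.base_seed, sim, 500 + c))
                # combined arm: 1 replicate + (R-1)*T knockdowns
                ts_single = simulate_timeseries(
                    model, T, 1,
                    seed=derive_seed(design.base_seed, sim, 400 + c),
                    rho_range=_rho_range(design),
                )
                rng = np.random.default_rng(
                    derive_seed(design.base_seed, sim, 600 + c))
                targets = rng.choice(
                    design.n_genes, size=(R - 1) * T, replace=False)
                ss = simulate_steady_state_dataset(
                    model, [int(t) for t in targets],
                    seed=derive_seed(design.base_seed, sim, 700 + c),
                )
                ts_single = add_noise(
                    ts_single, level,
                    seed=derive_seed(design.base_seed, sim, 800 + c))
                ss = add_noise(
                    ss, level, seed=derive_seed(design.base_seed, sim, 900 + c))
                assert ts_multi.n_samples == ts_single.n_samples + ss.n_samples \
                    == budget, "arms must consume identical sample budgets"
                res_ts = infer_network(None, ts_multi, mode="ts", basis=basis)
                res_c = infer_network(ss, ts_single, mode="combined", basis=basis)
                rows.append(_score_row(res_ts, truth, sim=sim, budget=budget,
                                       arm="ts", mode="ts"))
                rows.append(_score_row(res_c, truth, sim=sim, budget=budget,
                                       arm="combined", mode="combined"))
        except StabilityError as exc:
            fails.append({"sim": sim, "error": str(exc)})
    raw = pd.DataFrame(rows)
    return ExperimentResult(
        design=design, raw=raw,
        summary=_summarise(raw, ["budget", "arm"]),
        failures=pd.DataFrame(fails, columns=["sim", "error"]),
    )


def run_directionality_study(design: ExperimentDesign) -> ExperimentResult:
    """Forward vs reversed recovery proportions of true edges per mode."""
    if design.design_kind != "directionality":
        raise ValueError("design_kind must be 'directionality'")
    T = design.timepoint_counts[0]
    R = design.replicate_counts[0]
    level = design.noise_levels[0]
    rows, fails = [], []
    for sim in range(design.n_simulations):
        try:
            model = simulate_instance(design, sim)
            basis = _basis_for(design, model)
            truth = model.network
            ss = simulate_steady_state_dataset(
                model, list(range(design.n_genes)),
                seed=derive_seed(design.base_seed, sim, 101))
            ts = simulate_timeseries(
                model, T, R, seed=derive_seed(design.base_seed, sim, 102),
                rho_range=_rho_range(design))
            ss = add_noise(ss, level, seed=derive_seed(design.base_seed, sim, 201))
            ts = add_noise(ts, level, seed=derive_seed(design.base_seed, sim, 202))
            for mode in ("ss", "ts", "combined"):
                res = infer_network(
                    ss if mode != "ts" else None,
                    ts if mode != "ss" else None,
                    mode=mode, basis=basis,
                )
                fwd, rev = directionality_proportions(res.network, truth)
                rows.append({
                    "sim": sim, "mode": mode, "forward": fwd, "reversed": rev,
                    "n_inferred": res.network.n_edges, "n_truth": truth.n_edges,
                })
        except StabilityError as exc:
            fails.append({"sim": sim, "error": str(exc)})
    raw = pd.DataFrame(rows)
    summary = raw.groupby("mode", as_index=False).agg(
        forward_mean=("forward", "mean"), forward_sd=("forward", "std"),
        reversed_mean=("reversed", "mean"), reversed_sd=("reversed", "std"),
        n_sims=("forward", "size"),
    )
    return ExperimentResult(
        design=design, raw=raw, summary=summary,
        failures=pd.DataFrame(fails, columns=["sim", "error"]),
    )
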