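import networkx as nx
import numpy as np
import pytest

import mikana as mk
from mikana.kinetics import KineticRanges, StabilityError


def one_gene_model(v=500.0, lam=0.5, basal=0.1):
    net = mk.GeneNetwork(n_genes=1, edges={})
    return mk.KineticModel(
        network=net, v=np.array([v]), lam=np.array([lam]),
        basal=np.array([basal]), theta=np.array([1000.0]),
        phi=np.array([1000.0]),
    )


class TestParameterSampling:
    def test_deterministic_and_within_ranges(self):
        net = mk.random_uniform_network(1000, 1500, seed=1)
        ranges = KineticRanges()
        m1 = mk.sample_parameters(net, seed=7, ranges=ranges)
        m2 = mk.sample_parameters(net, seed=7, ranges=ranges)
        assert np.array_equal(m1.lam, m2.lam) and np.array_equal(m1.v, m2.v)
        for arr, (lo, hi) in [
            (m1.v, ranges.v), (m1.lam, ranges.lam),
            (m1.basal, ranges.basal), (m1.theta, ranges.saturation),
        ]:
            assert arr.min() >= lo and arr.max() <= hi
        assert np.array_equal(m1.theta, m1.phi)

    def test_sampled_models_mostly_stable(self):
        """Most sampled 20-gene models settle to a finite, non-negative
        reference state from random initial conditions."""
        ok = 0
        n_models = 30
        for seed in range(n_models):
            net = mk.generate_scale_free(
                mk.TopologyConfig(n_genes=20, k_av=3, seed=seed))
            model = mk.sample_parameters(net, seed=seed + 500)
            try:
                x = mk.find_reference_state(model, seed=seed + 900)
            except StabilityError:
                continue
            if np.all(np.isfinite(x)) and np.all(x >= 0):
                ok += 1
        assert ok >= 0.9 * n_models


class TestRegulationRate:
    def test_unregulated_gene_rate_is_basal(self):
        model = one_gene_model(basal=0.13)
        assert mk.regulation_rate(0, np.array([100.0]), model) == pytest.approx(0.13)

    def test_single_activator_saturates_at_basal_plus_one(self):
        net = mk.GeneNetwork(n_genes=2, edges={(0, 1): 1})
        model = mk.KineticModel(
            network=net, v=np.ones(2) * 100, lam=np.ones(2) * 0.5,
            basal=np.ones(2) * 0.1, theta=np.ones(2) * 500, phi=np.ones(2) * 500,
        )
        g = mk.regulation_rate(1, np.array([1e12, 100.0]), model)
        assert g == pytest.approx(1.1, rel=1e-6)

    def test_monotone_in_regulators(self, kinetic_model):
        """Raising an inhibitor never raises g_i; raising an activator
        never lowers it (checked over many random states)."""
        model = kinetic_model
        rng = np.random.default_rng(0)
        for _ in range(200):
            x = rng.uniform(0, 3000, size=model.n_genes)
            g0 = model.regulation(x)
            for gene in range(model.n_genes):
                for z in model.network.parents(gene, sign=-1):
                    xp = x.copy()
                    xp[z] *= 1.5
                    assert model.regulation(xp)[gene] <= g0[gene] + 1e-12
                for a in model.network.parents(gene, sign=1):
                    xp = x.copy()
                    xp[a] *= 1.5
                    assert model.regulation(xp)[gene] >= g0[gene] - 1e-12


class TestReferenceState:
    def test_isolated_gene_closed_form(self):
        """One unregulated gene: dx/dt = V*b - lam*x has the closed-form
        steady state V*b/lam, which the integrator must match."""
        model = one_gene_model(v=500.0, lam=0.5, basal=0.1)
        x = mk.find_reference_state(model, seed=1)
        assert x[0] == pytest.approx(500.0 * 0.1 / 0.5, rel=1e-6)

    def test_residual_below_tolerance_and_deterministic(self, kinetic_model):
        model = kinetic_model
        x1 = mk.find_reference_state(model, seed=42)
        resid = np.abs(model.rhs(x1)).max()
        assert resid < 1e-6 * np.abs(x1).max()
        x2 = mk.find_reference_state(model, seed=42)
        assert np.array_equal(x1, x2)


class TestKnockdown:
    def test_zero_knockdown_returns_reference(self, kinetic_model):
        x = mk.simulate_knockdown(kinetic_model, 0, 0.0)
        assert np.allclose(x, kinetic_model.x_ref, rtol=1e-4)

    def test_full_knockdown_clamps_to_zero(self, kinetic_model):
        x = mk.simulate_knockdown(kinetic_model, 2, 1.0)
        assert x[2] == 0.0

    def test_invalid_fraction_rejected(self, kinetic_model):
        with pytest.raises(ValueError):
            mk.simulate_knockdown(kinetic_model, 0, 1.5)

    def test_unreachable_genes_unaffected(self, kinetic_model):
        """Genes with no directed path from the knocked-down gene stay at
        their reference level (reachability via the ground-truth graph)."""
        model = kinetic_model
        g = model.network.to_networkx()
        target = 0
        reachable = nx.descendants(g, target) | {target}
        unreachable = [i for i in range(model.n_genes) if i not in reachable]
        if not unreachable:
            pytest.skip("every gene reachable from the chosen target")
        x = mk.simulate_knockdown(model, target, 0.8)
        for j in unreachable:
            assert x[j] == pytest.approx(model.x_ref[j], rel=1e-4)


class TestSteadyStateDataset:
    def test_one_sample_per_target_with_recorded_fraction(self, kinetic_model):
        data = mk.simulate_steady_state_dataset(
            kinetic_model, list(range(10)), seed=3)
        assert data.n_samples == 10
        perturbed = list(data.meta["perturbed_gene"])
        assert sorted(perturbed) == sorted(kinetic_model.network.gene_names)
        frac = data.meta["knockdown_fraction"].to_numpy(dtype=float)
        assert np.all((frac >= 0) & (frac <= 1))

    def test_empty_target_list_is_valid(self, kinetic_model):
        data = mk.simulate_steady_state_dataset(kinetic_model, [], seed=3)
        assert data.is_empty()

    def test_duplicate_targets_rejected_without_explicit_fractions(self, kinetic_model):
        with pytest.raises(ValueError):
            mk.simulate_steady_state_dataset(kinetic_model, [0, 0], seed=3)


class TestTimeSeries:
    def test_shape_and_strictly_increasing_times(self, kinetic_model):
        data = mk.simulate_timeseries(kinetic_model, 10, 3, seed=4)
        assert data.n_samples == 30
        for _, grp in data.meta.groupby("replicate"):
            t = grp["time_h"].to_numpy(dtype=float)
            assert t[0] == 0.0
            assert np.all(np.diff(t) > 0)

    def test_unperturbed_replicate_stays_at_reference(self, kinetic_model):
        data = mk.simulate_timeseries(
            kinetic_model, 6, 1, seed=4, rho_range=(0.0, 0.0))
        assert np.allclose(
            data.values, kinetic_model.x_ref[:, None], rtol=1e-4)

    def test_typical_gene_near_settled_at_horizon(self, kinetic_model):
        """With the fixed-interval design and a long course, the median
        gene's relative change over the final interval is small (the
        slowest genes may still be relaxing, as in a real time course)."""
        data = mk.simulate_timeseries(kinetic_model, 20, 1, seed=9)
        vals = data.values
        rel = np.abs(vals[:, -1] - vals[:, -2]) / np.maximum(vals[:, -1], 1e-9)
        assert np.median(rel) < 0.05

    def test_replicates_use_distinct_perturbations(self, kinetic_model):
        data = mk.simulate_timeseries(kinetic_model, 4, 2, seed=5)
        rep0 = data.values[:, :4]
        rep1 = data.values[:, 4:]
        assert not np.allclose(rep0[:, 0], rep1[:, 0])


class TestNoise:
    def test_zero_level_is_identity(self, kinetic_model):
        data = mk.simulate_timeseries(kinetic_model, 4, 1, seed=5)
        noisy = mk.add_noise(data, 0.0, seed=6)
        assert np.array_equal(noisy.values, data.values)

    def test_negative_level_rejected(self, kinetic_model):
        data = mk.simulate_timeseries(kinetic_model, 4, 1, seed=5)
        with pytest.raises(ValueError):
            mk.add_noise(data, -0.1, seed=6)

    def test_signal_proportional_scale(self):
        """10% noise on 1e5 values of 1000: mean ~1000, sd ~100; the
        relative perturbation has sd ~ the level."""
        genes = [f"G{i}" for i in range(100)]
        values = np.full((100, 1000), 1000.0)
        from .conftest import make_ss_dataset
        data = make_ss_dataset(values, genes, [genes[i % 100] for i in range(1000)])
        noisy = mk.add_noise(data, 0.10, seed=8)
        assert noisy.values.mean() == pytest.approx(1000.0, abs=2.0)
        assert noisy.values.std() == pytest.approx(100.0, abs=2.0)
        rel = (noisy.values - data.values) / data.values
        assert rel.std() == pytest.approx(0.10, abs=0.01)

    def test_original_unmodified_and_deterministic(self, kinetic_model):
        data = mk.simulate_timeseries(kinetic_model, 4, 1, seed=5)
        before = data.values.copy()
        n1 = mk.add_noise(data, 0.2, seed=9)
        n2 = mk.add_noise(data, 0.2, seed=9)
        assert np.array_equal(data.values, before)
        assert np.array_equal(n1.values, n2.values)
        assert (n1.meta["noise_level"] == 0.2).all()


class TestWellSpecifiedInstance:
    def test_positive_reference_state(self, oracle_model):
        assert oracle_model.x_ref is not None
        assert np.all(oracle_model.x_ref > 0)
        assert oracle_model.network.n_edges == 15

    def test_euler_trajectory_satisfies_difference_identity(self, oracle_model):
        """The discrete-time trajectory must satisfy the forward-difference
        relation exactly: (x_{k+1}-x_k)/dt == rhs(x_k)."""
        times = np.linspace(0.0, 5.0, 8)
        x0 = oracle_model.x_ref * 1.3
        traj = oracle_model.trajectory(x0, times)
        for k in range(len(times) - 1):
            fd = (traj[:, k + 1] - traj[:, k]) / (times[k + 1] - times[k])
            assert np.allclose(fd, oracle_model.rhs(traj[:, k]), rtol=1e-10)

    def test_knockdown_fixed_point_residual(self, oracle_model):
        x = mk.simulate_knockdown(oracle_model, 3, 0.6)
        resid = np.abs(oracle_model.rhs(x))
        resid[3] = 0.0  # clamped coordinate
        assert resid.max() < 1e-6 * np.abs(x).max()
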