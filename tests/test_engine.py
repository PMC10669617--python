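"""Latent propagation, least-squares latent solve, metrics, variance
scaling, and the gradient-descent fit."""

import numpy as np
import pytest

from sapm import (
    BoldDataset,
    Connection,
    FitConfig,
    GroundTruth,
    LatentInput,
    NetworkModel,
    Paradigm,
    UnstableNetworkError,
    build_matrices,
    fit_metrics,
    fit_sapm,
    forward_signals,
    latent_basis,
    normalize_region_variance,
    simulate_network_dataset,
    solve_latent_timecourses,
)

from conftest import random_parameters, random_small_network


def _dataset(values, regions=None, run_len=None):
    values = np.asarray(values, dtype=float)
    t = values.shape[1]
    run_len = run_len or t
    runs = [(s, run_len) for s in range(0, t, run_len)]
    regions = regions or [f"R{i}" for i in range(values.shape[0])]
    return BoldDataset(data=values, runs=runs, regions=regions)


class TestLatentBasis:
    def test_zero_region_block_is_direct_feedthrough(self, chain_network):
        d = {c.pair: 1.0 for c in chain_network.connections}
        db = {c.pair: 0.0 for c in chain_network.connections}
        m = build_matrices(chain_network, d, db)
        basis = latent_basis(m)
        expected = np.zeros((4, 1))
        expected[0] = 1.0  # latent targets region A
        expected[3] = 1.0  # latent's own row
        assert np.allclose(basis.m_eigv, expected)

    def test_two_region_chain_hand_solution(self):
        # L -> A -> B with DB(A->B) = 0.5: propagation gives (A=1, B=0.5, L=1)
        model = NetworkModel(
            regions=["A", "B"],
            connections=[Connection("A", "B")],
            latents=[LatentInput(name="L", kind="variable", target_region="A")],
        )
        m = build_matrices(model, {("A", "B"): 1.0}, {("A", "B"): 0.5})
        basis = latent_basis(m)
        assert np.allclose(basis.m_eigv[:, 0], [1.0, 0.5, 1.0])

    def test_columns_are_unit_eigenvectors(self, pain_network):
        rng = np.random.default_rng(5)
        d, db = random_parameters(pain_network, rng)
        m = build_matrices(pain_network, d, db)
        basis = latent_basis(m)
        for k in range(basis.m_eigv.shape[1]):
            x = basis.m_eigv[:, k]
            assert np.max(np.abs(m.m_output @ x - x)) <= 1e-8 * max(np.max(np.abs(x)), 1.0)
            lat_rows = x[pain_network.n_regions :]
            expected = np.zeros(pain_network.n_latents)
            expected[k] = 1.0
            assert np.allclose(lat_rows, expected)

    def test_matches_generic_eigensolver_on_random_networks(self):
        """Closed-form linear-solve construction agrees with a numerical
        eigendecomposition restricted to unit eigenvalues."""
        rng = np.random.default_rng(17)
        checked = 0
        while checked < 100:
            model = random_small_network(rng)
            d, db = random_parameters(model, rng)
            m = build_matrices(model, d, db)
            try:
                basis = latent_basis(m)
            except UnstableNetworkError:
                continue
            w, v = np.linalg.eig(m.m_output)
            unit = np.nonzero(np.abs(w - 1.0) < 1e-8)[0]
            assert len(unit) >= model.n_latents
            nr = model.n_regions
            for k in range(model.n_latents):
                # rescale each numeric eigenvector to the latent-k gauge
                best = None
                for idx in unit:
                    vec = np.real_if_close(v[:, idx])
                    if abs(vec[nr + k]) > 1e-10:
                        cand = vec / vec[nr + k]
                        lat = np.zeros(model.n_latents)
                        lat[k] = 1.0
                        if np.allclose(cand[nr:], lat, atol=1e-8):
                            best = cand
                            break
                if best is not None:
                    assert np.max(np.abs(best - basis.m_eigv[:, k])) <= 1e-8 * max(
                        1.0, np.max(np.abs(best))
                    )
            checked += 1

    def test_unstable_network_raises(self):
        # DB(A->B) = DB(B->A) = 1 makes (I - A) singular
        model = NetworkModel(
            regions=["A", "B"],
            connections=[Connection("A", "B"), Connection("B", "A")],
            latents=[LatentInput(name="L", kind="variable", target_region="A")],
        )
        m = build_matrices(
            model, {("A", "B"): 1.0, ("B", "A"): 1.0}, {("A", "B"): 1.0, ("B", "A"): 1.0}
        )
        with pytest.raises(UnstableNetworkError):
            latent_basis(m)


class TestForwardSignals:
    def test_linearity_and_idempotent_propagation(self, ring_network):
        rng = np.random.default_rng(3)
        d, db = random_parameters(ring_network, rng, db_scale=0.4)
        m = build_matrices(ring_network, d, db)
        basis = latent_basis(m)
        latents = rng.standard_normal((2, 30))
        s_out, s_in = forward_signals(m, basis, latents)
        # S_output is a fixed point of M_output, hence also of its square
        assert np.allclose(m.m_output @ s_out, s_out, atol=1e-10)
        assert np.allclose(m.m_output @ (m.m_output @ s_out), s_out, atol=1e-10)
        assert np.allclose(s_in, m.m_input @ s_out)
        s_out2, s_in2 = forward_signals(m, basis, 2.0 * latents)
        assert np.allclose(s_in2, 2.0 * s_in)

    def test_impulse_latent_propagates_basis_column(self, chain_network):
        d = {c.pair: 1.0 for c in chain_network.connections}
        db = {c.pair: 0.5 for c in chain_network.connections}
        m = build_matrices(chain_network, d, db)
        basis = latent_basis(m)
        latents = np.zeros((1, 10))
        latents[0, 4] = 1.0
        s_out, _ = forward_signals(m, basis, latents)
        assert np.allclose(s_out[:, 4], basis.m_eigv[:, 0])
        assert np.allclose(np.delete(s_out, 4, axis=1), 0.0)

    def test_zero_latents_give_zero_signals(self, chain_network):
        d = {c.pair: 1.0 for c in chain_network.connections}
        db = {c.pair: 0.2 for c in chain_network.connections}
        m = build_matrices(chain_network, d, db)
        basis = latent_basis(m)
        s_out, s_in = forward_signals(m, basis, np.zeros((1, 7)))
        assert not s_out.any() and not s_in.any()


class TestSolveLatents:
    def test_exact_recovery_on_consistent_system(self, ring_network):
        rng = np.random.default_rng(8)
        d, db = random_parameters(ring_network, rng, db_scale=0.4)
        m = build_matrices(ring_network, d, db)
        basis = latent_basis(m)
        true_latents = rng.standard_normal((2, 50))
        _, s_in = forward_signals(m, basis, true_latents)
        data = _dataset(s_in, regions=list(ring_network.regions))
        solved = solve_latent_timecourses(m, basis, data)
        assert np.max(np.abs(solved - true_latents)) <= 1e-6 * np.max(np.abs(true_latents))

    def test_zero_data_zero_amplitude_gives_zero(self):
        model = NetworkModel(
            regions=["A", "B"],
            connections=[Connection("A", "B")],
            latents=[
                LatentInput(name="var", kind="variable", target_region="B"),
                LatentInput(
                    name="fix", kind="fixed", target_region="A", template=np.sin(np.arange(20.0))
                ),
            ],
        )
        m = build_matrices(model, {("A", "B"): 1.0}, {("A", "B"): 0.3})
        basis = latent_basis(m)
        data = _dataset(np.zeros((2, 20)), regions=["A", "B"])
        solved = solve_latent_timecourses(m, basis, data, fixed_amplitudes={"fix": 0.0})
        assert not solved.any()

    def test_residual_orthogonal_to_design(self, pain_network):
        """Normal equations: the residual of the latent solve has no
        component along the variable-latent columns of M1."""
        rng = np.random.default_rng(21)
        d, db = random_parameters(pain_network, rng)
        m = build_matrices(pain_network, d, db)
        basis = latent_basis(m)
        data = _dataset(
            rng.standard_normal((10, 200)), regions=list(pain_network.regions), run_len=40
        )
        amps = {"int0": 0.7}
        solved = solve_latent_timecourses(m, basis, data, fixed_amplitudes=amps)
        m1 = m.m_input @ basis.m_eigv
        s_in = m1 @ solved
        resid = s_in - data.data
        var_cols = m1[:, 1:]  # int1, int2 are the variable latents
        inner = var_cols.T @ resid
        scale = np.linalg.norm(var_cols) * np.linalg.norm(resid)
        assert np.max(np.abs(inner)) <= 1e-6 * scale
        # cross-check against an independent generic least-squares routine
        target = data.data - np.outer(m1[:, 0], 0.7 * _tile_template(pain_network, data))
        expected, *_ = np.linalg.lstsq(var_cols, target, rcond=None)
        assert np.allclose(solved[1:], expected, atol=1e-8)

    def test_fixed_row_is_amplitude_times_template(self, pain_network):
        rng = np.random.default_rng(22)
        d, db = random_parameters(pain_network, rng)
        m = build_matrices(pain_network, d, db)
        basis = latent_basis(m)
        data = _dataset(
            rng.standard_normal((10, 200)), regions=list(pain_network.regions), run_len=40
        )
        solved = solve_latent_timecourses(m, basis, data, fixed_amplitudes={"int0": 1.3})
        template = _tile_template(pain_network, data)
        assert np.allclose(solved[0], 1.3 * template)


def _tile_template(model, data):
    (fixed,) = [l for l in model.latents if l.is_fixed]
    template = fixed.template
    if template.size != data.n_timepoints:
        template = np.tile(template, data.n_timepoints // template.size)
    return template


class TestFitMetrics:
    def test_perfect_fit(self):
        x = np.random.default_rng(0).standard_normal((3, 20))
        m = fit_metrics(x, x)
        assert m.err_ssqd == 0.0
        assert m.r2_total == 1.0 and m.r2_average == 1.0

    def test_zero_prediction_gives_zero_r2(self):
        x = np.random.default_rng(1).standard_normal((3, 20))
        m = fit_metrics(np.zeros_like(x), x)
        assert m.r2_total == pytest.approx(0.0)
        assert m.r2_average == pytest.approx(0.0)

    def test_matches_elementwise_oracle(self):
        rng = np.random.default_rng(2)
        pred = rng.standard_normal((3, 20))
        data = rng.standard_normal((3, 20))
        m = fit_metrics(pred, data, regions=["a", "b", "c"])
        # brute-force double loop
        err = 0.0
        per = {}
        for i, name in enumerate(["a", "b", "c"]):
            ss_res = ss_dat = 0.0
            for t in range(20):
                ss_res += (pred[i, t] - data[i, t]) ** 2
                ss_dat += data[i, t] ** 2
            err += ss_res
            per[name] = 1 - ss_res / ss_dat
        assert m.err_ssqd == pytest.approx(err, rel=1e-12)
        total = sum((data[i, t] ** 2) for i in range(3) for t in range(20))
        assert m.r2_total == pytest.approx(1 - err / total, rel=1e-12)
        for name in per:
            assert m.r2_per_region[name] == pytest.approx(per[name], rel=1e-12)
        assert m.r2_average == pytest.approx(np.mean(list(per.values())), rel=1e-12)

    def test_zero_variance_region_excluded_and_reported(self):
        data = np.vstack([np.zeros(10), np.ones(10)])
        pred = np.vstack([np.zeros(10), np.ones(10)])
        m = fit_metrics(pred, data, regions=["silent", "active"])
        assert m.excluded_regions == ["silent"]
        assert "silent" not in m.r2_per_region
        assert m.r2_average == pytest.approx(1.0)


class TestVarianceNormalization:
    def test_equal_variance_data_unchanged(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal((3, 100))
        x = x / x.std(axis=1, keepdims=True)
        ds = _dataset(x)
        scaled, factors = normalize_region_variance(ds)
        assert all(abs(f - 1) < 1e-12 for f in factors.values())
        assert np.allclose(scaled.data, ds.data)

    def test_variances_equalized_to_the_mean(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal((2, 2000))
        x[0] *= 1.0 / x[0].std()
        x[1] *= 2.0 / x[1].std()
        ds = _dataset(x)
        scaled, factors = normalize_region_variance(ds)
        target = np.var(ds.data, axis=1).mean()
        assert np.var(scaled.data, axis=1) == pytest.approx([target, target], rel=1e-10)
        assert factors["R0"] == pytest.approx(np.sqrt(target / np.var(x[0])))
        assert factors["R1"] == pytest.approx(np.sqrt(target / np.var(x[1])))

    def test_zero_variance_region_raises_with_name(self):
        ds = _dataset(np.vstack([np.ones(10), np.arange(10.0)]), regions=["flat", "ok"])
        with pytest.raises(ValueError, match="flat"):
            normalize_region_variance(ds)


class TestFitSAPM:
    def test_deterministic_given_seed(self, ring_network):
        rng = np.random.default_rng(30)
        truth = GroundTruth(
            model=ring_network,
            d_values={c.pair: 1.0 for c in ring_network.connections},
            db_values={c.pair: s * 0.5 for c, s in zip(ring_network.connections, [1, -1, 1, -1])},
            noise_sd=0.3,
            seed=12,
        )
        data, _ = simulate_network_dataset(truth, Paradigm(n_runs=2))
        cfg = FitConfig(n_starts=3, explore_iters=5, refine_iters=20, seed=77)
        fit1 = fit_sapm(data, ring_network, cfg)
        fit2 = fit_sapm(data, ring_network, cfg)
        assert fit1.db_values == fit2.db_values  # bitwise identical
        assert fit1.d_values == fit2.d_values

    def test_objective_and_invariants(self, ring_network):
        truth = GroundTruth(
            model=ring_network,
            d_values={c.pair: 1.0 for c in ring_network.connections},
            db_values={c.pair: s * 0.5 for c, s in zip(ring_network.connections, [1, -1, 1, -1])},
            noise_sd=0.2,
            seed=13,
        )
        data, _ = simulate_network_dataset(truth, Paradigm(n_runs=2))
        fit = fit_sapm(data, ring_network, FitConfig(n_starts=4, explore_iters=8, refine_iters=40, seed=5))
        # b = db / d
        for pair in fit.connections:
            assert fit.b_values[pair] == pytest.approx(
                fit.db_values[pair] / fit.d_values[pair], rel=1e-12
            )
        # S_input = M_input S_output at the fitted parameters
        m = build_matrices(ring_network, fit.d_values, fit.db_values)
        assert np.allclose(fit.s_input, m.m_input @ fit.s_output, rtol=1e-8, atol=1e-10)
        # S_output is a fixed point of M_output
        assert np.allclose(m.m_output @ fit.s_output, fit.s_output, atol=1e-8)

    def test_nonfinite_data_rejected(self, ring_network):
        data = _dataset(np.full((4, 20), np.nan), regions=list(ring_network.regions))
        with pytest.raises(ValueError, match="non-finite"):
            fit_sapm(data, ring_network)

    def test_db_invariant_under_region_variance_scaling(self, ring_network):
        """Rescaling regional variances changes fitted D values by the
        predicted factors but leaves DB values (nearly) unchanged."""
        truth = GroundTruth(
            model=ring_network,
            d_values={c.pair: 1.0 for c in ring_network.connections},
            db_values={c.pair: s * 0.4 for c, s in zip(ring_network.connections, [1, -1, 1, -1])},
            noise_sd=0.2,
            seed=40,
        )
        data, _ = simulate_network_dataset(truth, Paradigm(n_runs=3))
        gains = np.array([1.0, 3.0, 0.5, 2.0])
        rescaled = BoldDataset(
            data=data.data * gains[:, None], runs=data.runs, regions=data.regions
        )
        cfg = FitConfig(n_starts=4, explore_iters=10, refine_iters=60, seed=9)
        fit_raw = fit_sapm(data, ring_network, cfg)
        fit_scaled = fit_sapm(rescaled, ring_network, cfg)
        db_raw = fit_raw.db_array()
        db_scaled = fit_scaled.db_array()
        # paired fits with a shared seed: identical normalized data modulo
        # numerical scaling, so DB values agree tightly
        assert np.allclose(db_raw, db_scaled, atol=1e-6)
        # the fits in normalized space are identical (the descent is
        # equivariant to a global data rescaling)
        assert np.allclose(fit_raw.d_array(), fit_scaled.d_array(), atol=1e-9)
        # original-unit D values differ by the target region's gain, up to
        # the global factor from the change in the dataset's mean variance
        d_raw = np.array(
            [fit_raw.d_values_original_units()[c] for c in fit_raw.connections]
        )
        d_scaled = np.array(
            [fit_scaled.d_values_original_units()[c] for c in fit_scaled.connections]
        )
        target_gain = np.array(
            [gains[ring_network.region_index(t)] for _, t in fit_raw.connections]
        )
        c_global = np.sqrt(
            np.var(rescaled.data, axis=1).mean() / np.var(data.data, axis=1).mean()
        )
        assert np.allclose(d_scaled * c_global / target_gain, d_raw, rtol=1e-6)

    def test_objective_monotone_over_accepted_steps(self, ring_network):
        """The accepted objective never increases within a descent."""
        from sapm.engine import _Workspace, _descend

        rng = np.random.default_rng(55)
        truth = GroundTruth(
            model=ring_network,
            d_values={c.pair: 1.0 for c in ring_network.connections},
            db_values={c.pair: 0.3 for c in ring_network.connections},
            noise_sd=0.5,
            seed=2,
        )
        data, _ = simulate_network_dataset(truth, Paradigm(n_runs=2))
        ws = _Workspace(ring_network, data.data, {})
        ws.lambda_l1 = 0.5
        cfg = FitConfig()
        theta = np.concatenate([np.ones(4), rng.uniform(-0.2, 0.2, 4)])
        objs = [ws.objective(theta)]
        cur, step = theta, cfg.step_init
        for _ in range(25):
            cur, obj, step, used = _descend(ws, cur, 1, step, cfg)
            if used == 0:
                break
            objs.append(obj)
        assert all(b <= a + 1e-12 for a, b in zip(objs, objs[1:]))
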