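import numpy as np
import pandas as pd
import pytest

from sigmatch import signatures
from sigmatch.signatures import (
    DegenerateSignalError,
    NumericalError,
    call_degs,
    characteristic_direction,
)
from tests.conftest import make_experiment


def two_class(mu_c, mu_t, noise, n_per_class, rng):
    """Replicated experiment around the two class means."""
    mu_c, mu_t = np.asarray(mu_c, float), np.asarray(mu_t, float)
    p = len(mu_c)
    ctrl = mu_c[:, None] + noise * rng.standard_normal((p, n_per_class))
    trt = mu_t[:, None] + noise * rng.standard_normal((p, n_per_class))
    return make_experiment(np.hstack([ctrl, trt]), n_control=n_per_class)


class TestCharacteristicDirection:
    def test_identity_limit_noise_free(self):
        # gamma=1 with zero noise: direction is the normalized mean difference
        exp = two_class([0, 0, 0], [0, 0, 2], 0.0, 3, np.random.default_rng(0))
        b = characteristic_direction(exp, gamma=1.0)
        np.testing.assert_allclose(b, [0, 0, 1], atol=1e-12)

    def test_gamma_one_matches_mean_difference_with_noise(self):
        rng = np.random.default_rng(1)
        exp = two_class(np.zeros(50), rng.normal(size=50), 0.5, 4, rng)
        b = characteristic_direction(exp, gamma=1.0)
        ctrl = exp.values[:, :4].mean(axis=1)
        trt = exp.values[:, 4:].mean(axis=1)
        d = trt - ctrl
        d = d / np.linalg.norm(d)
        # chord-based angle avoids the arccos precision floor near 0
        angle = 2 * np.arcsin(np.linalg.norm(b - d) / 2)
        assert angle < 1e-8

    def test_two_gene_shrunk_inverse_oracle(self):
        # hand-computed 2x2 linear algebra against the implementation
        rng = np.random.default_rng(2)
        exp = two_class([0.0, 0.0], [1.0, 2.0], 0.8, 4, rng)
        gamma = 0.5
        ctrl, trt = exp.values[:, :4], exp.values[:, 4:]
        d = trt.mean(axis=1) - ctrl.mean(axis=1)
        Ec = ctrl - ctrl.mean(axis=1, keepdims=True)
        Et = trt - trt.mean(axis=1, keepdims=True)
        pooled = (Ec @ Ec.T + Et @ Et.T) / (8 - 2)
        nu = np.trace(pooled) / 2
        shrunk = (1 - gamma) * pooled + gamma * nu * np.eye(2)
        det = shrunk[0, 0] * shrunk[1, 1] - shrunk[0, 1] * shrunk[1, 0]
        inv = np.array([[shrunk[1, 1], -shrunk[0, 1]],
                        [-shrunk[1, 0], shrunk[0, 0]]]) / det
        expected = inv @ d
        expected = expected / np.linalg.norm(expected)
        if expected @ d < 0:
            expected = -expected
        b = characteristic_direction(exp, gamma=gamma)
        np.testing.assert_allclose(b, expected, atol=1e-10)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        exp = two_class(np.zeros(20), rng.normal(size=20), 1.0, 3, rng)
        b = characteristic_direction(exp)
        perm = rng.permutation(20)
        exp_p = make_experiment(exp.values[perm], n_control=3)
        b_p = characteristic_direction(exp_p)
        np.testing.assert_allclose(b_p, b[perm], atol=1e-12)

    def test_scale_invariance(self):
        rng = np.random.default_rng(4)
        exp = two_class(np.zeros(30), rng.normal(size=30), 1.0, 3, rng)
        b = characteristic_direction(exp)
        exp_scaled = make_experiment(exp.values * 37.5, n_control=3)
        b_s = characteristic_direction(exp_scaled)
        np.testing.assert_allclose(b_s, b, atol=1e-9)

    def test_unit_norm_and_orientation(self):
        rng = np.random.default_rng(5)
        for gamma in (0.1, 0.5, 0.9, 1.0):
            exp = two_class(np.zeros(40), rng.normal(size=40), 1.0, 3, rng)
            b = characteristic_direction(exp, gamma=gamma)
            assert abs(np.linalg.norm(b) - 1.0) < 1e-9
            d = exp.values[:, 3:].mean(axis=1) - exp.values[:, :3].mean(axis=1)
            assert b @ d >= 0

    def test_zero_difference_is_degenerate(self):
        exp = make_experiment([[1.0, 1.0], [2.0, 2.0], [0.0, 0.0]], n_control=1)
        with pytest.raises(DegenerateSignalError):
            characteristic_direction(exp, gamma=1.0)

    def test_gamma_zero_singular_instructs_regularization(self):
        rng = np.random.default_rng(6)
        exp = two_class(np.zeros(10), rng.normal(size=10), 1.0, 2, rng)
        with pytest.raises(NumericalError, match="gamma > 0"):
            characteristic_direction(exp, gamma=0.0)

    def test_gamma_zero_full_rank_matches_direct_solve(self):
        rng = np.random.default_rng(7)
        exp = two_class([0.0, 0.0], [1.0, -1.0], 1.0, 6, rng)
        b = characteristic_direction(exp, gamma=0.0)
        ctrl, trt = exp.values[:, :6], exp.values[:, 6:]
        d = trt.mean(axis=1) - ctrl.mean(axis=1)
        Ec = ctrl - ctrl.mean(axis=1, keepdims=True)
        Et = trt - trt.mean(axis=1, keepdims=True)
        pooled = (Ec @ Ec.T + Et @ Et.T) / 10
        expected = np.linalg.solve(pooled, d)
        expected /= np.linalg.norm(expected)
        if expected @ d < 0:
            expected = -expected
        np.testing.assert_allclose(b, expected, atol=1e-9)


class TestCallDegs:
    def test_tiny_alpha_empties_both_sets(self):
        b = np.random.default_rng(0).normal(size=100)
        up, down = call_degs(b, [f"g{i}" for i in range(100)], alpha=1e-300)
        assert up == frozenset() and down == frozenset()

    def test_iid_normal_call_rate_matches_binomial(self):
        # G=10,000 iid standard-normal coefficients at alpha=0.01:
        # |up|+|down| ~ Binomial(G, alpha)
        G, alpha = 10_000, 0.01
        rng = np.random.default_rng(123)
        b = rng.standard_normal(G)
        up, down = call_degs(b, [f"g{i}" for i in range(G)], alpha=alpha)
        n_called = len(up) + len(down)
        tol = 3 * np.sqrt(G * alpha * (1 - alpha))
        assert abs(n_called - G * alpha) <= tol

    def test_outlier_lands_in_up_set(self):
        rng = np.random.default_rng(9)
        b = 0.01 * rng.standard_normal(200)
        b[17] = 10.0
        up, _ = call_degs(b, [f"g{i}" for i in range(200)])
        assert "g17" in up

    def test_signs_partition_calls(self):
        rng = np.random.default_rng(10)
        b = rng.standard_normal(500)
        up, down = call_degs(b, [f"g{i}" for i in range(500)], alpha=0.2)
        idx = {f"g{i}": v for i, v in enumerate(b)}
        assert all(idx[g] > 0 for g in up)
        assert all(idx[g] < 0 for g in down)
        assert not up & down

    def test_constant_coefficients_degenerate(self):
        with pytest.raises(DegenerateSignalError):
            call_degs(np.ones(10), [f"g{i}" for i in range(10)])


class TestBuildLibrary:
    def _metadata(self, sig_ids, drug_ids):
        return pd.DataFrame(
            {
                "signature_id": sig_ids,
                "drug_id": drug_ids,
                "cell_line": ["CL1"] * len(sig_ids),
                "dose": ["1uM"] * len(sig_ids),
                "time": ["6h"] * len(sig_ids),
            }
        )

    def test_counts_and_order(self):
        rng = np.random.default_rng(11)
        exps = {}
        for d in ("drugB", "drugA"):
            for c in range(3):
                exps[f"{d}_c{c}"] = two_class(
                    np.zeros(20), rng.normal(size=20), 1.0, 3, rng
                )
        meta = self._metadata(list(exps), [s.split("_")[0] for s in exps])
        lib = signatures.build_signature_library(exps, meta)
        assert len(lib) == 6
        assert [s.signature_id for s in lib] == sorted(exps)
        assert len({s.drug_id for s in lib}) == 2

    def test_empty_library(self):
        lib = signatures.build_signature_library({}, self._metadata([], []))
        assert lib == []

    def test_key_mismatch_lists_offenders(self):
        rng = np.random.default_rng(12)
        exps = {"s1": two_class(np.zeros(5), rng.normal(size=5), 1.0, 3, rng)}
        meta = self._metadata(["s2"], ["d"])
        with pytest.raises(Exception, match="s1"):
            signatures.build_signature_library(exps, meta)

    def test_null_calibration_on_label_permuted_data(self):
        # coefficients from pure-noise experiments: DEG call fraction at
        # alpha should average alpha over seeded permutations
        alpha, G, runs = 0.01, 978, 30
        rng = np.random.default_rng(77)
        fracs = []
        for _ in range(runs):
            values = rng.standard_normal((G, 6))
            classes = rng.permutation(["control"] * 3 + ["treatment"] * 3)
            exp = make_experiment(values, n_control=3)
            exp.sample_class = list(classes)
            b = characteristic_direction(exp)
            up, down = call_degs(b, exp.gene_ids, alpha=alpha)
            fracs.append((len(up) + len(down)) / G)
        se = np.std(fracs, ddof=1) / np.sqrt(runs)
        assert abs(np.mean(fracs) - alpha) <= 3 * se
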