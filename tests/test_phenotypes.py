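"""Synthetic phenotype maps: sampling, evaluation, noise, effect sizes."""

import numpy as np
import pytest

from attnmap.genotypes import GenotypeMatrix
from attnmap.phenotypes import (EpistasisSpec, add_noise, evaluate_map,
                                sample_epistasis_spec, sample_multi_env_specs,
                                true_effect_sizes)


def brute_force_map(spec, G):
    """Independent term-by-term oracle for the synthetic map."""
    out = []
    for row in G.values:
        x = dict(zip(G.locus_ids, row))
        y = spec.beta0
        y += spec.epsilon * sum(c * x[l] for l, c in spec.linear_coeffs.items())
        y += (1 - spec.epsilon) * sum(
            c * x[i] * x[j] * x[k] * x[l] for (i, j, k, l), c in spec.quad_terms)
        out.append(y)
    return np.array(out)


class TestSpecSampling:
    def test_counts_match_causal_loci(self, small_panel):
        spec = sample_epistasis_spec(small_panel.locus_ids, 10, 0.3, seed=1)
        assert len(spec.causal_loci) == 10
        assert len(spec.linear_coeffs) == 10
        assert len(spec.quad_terms) == 10

    def test_quadruplets_distinct_and_sorted(self, small_panel):
        spec = sample_epistasis_spec(small_panel.locus_ids, 8, 0.0, seed=2)
        quads = [q for q, _ in spec.quad_terms]
        assert len(set(quads)) == len(quads)
        for q in quads:
            assert list(q) == sorted(q) and len(set(q)) == 4

    def test_determinism(self, small_panel):
        a = sample_epistasis_spec(small_panel.locus_ids, 6, 0.5, seed=3)
        b = sample_epistasis_spec(small_panel.locus_ids, 6, 0.5, seed=3)
        assert a.to_json() == b.to_json()

    def test_too_few_causal_loci_for_quartics(self, small_panel):
        with pytest.raises(ValueError):
            sample_epistasis_spec(small_panel.locus_ids, 3, 0.5, seed=0)

    def test_exponential_coefficients_signed(self, small_panel):
        spec = sample_epistasis_spec(small_panel.locus_ids, 10, 0.5,
                                     coeff_dist="exponential", seed=4)
        coeffs = list(spec.linear_coeffs.values())
        assert any(c < 0 for c in coeffs) and any(c > 0 for c in coeffs)

    def test_serialization_roundtrip(self, tmp_path, small_panel):
        spec = sample_epistasis_spec(small_panel.locus_ids, 6, 0.25, seed=5)
        path = tmp_path / "spec.json"
        spec.save(path)
        back = EpistasisSpec.load(path)
        assert back == spec


class TestEvaluateMap:
    def test_single_linear_term(self):
        G = GenotypeMatrix(np.array([[1, 1, -1, -1]]), list("abcd"))
        spec = EpistasisSpec(["a", "b", "c", "d"], 0.0,
                             {"a": 0.5, "b": 0.0, "c": 0.0, "d": 0.0},
                             [(("a", "b", "c", "d"), 0.0)], epsilon=1.0)
        assert evaluate_map(spec, G)[0] == pytest.approx(0.5)

    def test_quartic_sign_algebra(self):
        # (+1)(-1)(+1)(-1) = +1, so a quartic coefficient of 2 contributes 2
        G = GenotypeMatrix(np.array([[1, -1, 1, -1]]), list("abcd"))
        spec = EpistasisSpec(["a", "b", "c", "d"], 0.0,
                             {l: 0.0 for l in "abcd"},
                             [(("a", "b", "c", "d"), 2.0)], epsilon=0.0)
        assert evaluate_map(spec, G)[0] == pytest.approx(2.0)

    def test_matches_brute_force_oracle(self, small_panel):
        spec = sample_epistasis_spec(small_panel.locus_ids, 10, 0.3, seed=6)
        assert np.allclose(evaluate_map(spec, small_panel),
                           brute_force_map(spec, small_panel), atol=1e-12)

    def test_unknown_locus_named_in_error(self, small_panel):
        spec = sample_epistasis_spec(small_panel.locus_ids, 6, 0.5, seed=7)
        G2 = GenotypeMatrix(small_panel.values,
                            [f"other{j}" for j in range(small_panel.n_loci)])
        with pytest.raises(KeyError, match=spec.causal_loci[0]):
            evaluate_map(spec, G2)

    def test_multilinearity_single_flip(self, small_panel):
        # flipping one allele changes y by twice the sum of terms containing it
        spec = sample_epistasis_spec(small_panel.locus_ids, 10, 0.4, seed=8)
        y0 = evaluate_map(spec, small_panel)
        locus = spec.causal_loci[0]
        j = small_panel.locus_index(locus)
        flipped = GenotypeMatrix(np.array(small_panel.values),
                                 small_panel.locus_ids)
        flipped.values[:, j] *= -1
        y1 = evaluate_map(spec, flipped)
        delta, _ = true_effect_sizes(spec, small_panel, locus)
        x = small_panel.values[:, j]
        assert np.allclose(y1 - y0, -x * delta, atol=1e-12)

    def test_variance_decomposition_at_extremes(self, small_panel):
        spec0 = sample_epistasis_spec(small_panel.locus_ids, 10, 0.0, seed=9)
        spec1 = EpistasisSpec(spec0.causal_loci, spec0.beta0,
                              spec0.linear_coeffs, spec0.quad_terms, 1.0)
        y0 = evaluate_map(spec0, small_panel)
        y1 = evaluate_map(spec1, small_panel)
        X = small_panel.values.astype(float)
        lin_idx = [small_panel.locus_index(l) for l in spec0.causal_loci]
        lin = X[:, lin_idx] @ np.array(
            [spec0.linear_coeffs[l] for l in spec0.causal_loci])
        assert np.allclose(y1, lin, atol=1e-12)  # eps=1: no quartic part
        assert abs(np.corrcoef(y0, lin)[0, 1]) < 0.999  # eps=0: not the linear part


class TestNoise:
    def test_noise_sd_scaling(self, rng):
        base = rng.normal(0, 5.0, size=200_000)
        ph = add_noise(base, 0.2, seed=1)
        eta = ph.observed_values - ph.noise_free_values
        assert eta.std() == pytest.approx(0.2 * base.std(), rel=0.02)

    def test_variance_additivity(self, rng):
        base = rng.normal(0, 2.0, size=100_000)
        ph = add_noise(base, 0.2, seed=2)
        assert ph.observed_values.var() == pytest.approx(1.04 * base.var(), rel=0.02)

    def test_zero_noise_fraction(self, rng):
        base = rng.normal(size=50)
        ph = add_noise(base, 0.0, seed=3)
        assert (ph.observed_values == ph.noise_free_values).all()

    def test_constant_vector_gets_zero_noise(self):
        ph = add_noise(np.full(10, 3.0), 0.2, seed=4)
        assert (ph.observed_values == 3.0).all()


class TestTrueEffectSizes:
    def test_purely_linear_map_gives_2beta(self, small_panel):
        spec = sample_epistasis_spec(small_panel.locus_ids, 10, 1.0, seed=10)
        locus = spec.causal_loci[3]
        delta, avg = true_effect_sizes(spec, small_panel, locus)
        expected = 2.0 * spec.linear_coeffs[locus]
        assert np.allclose(delta, expected, atol=1e-12)
        assert avg == pytest.approx(expected)

    def test_non_causal_locus_is_zero(self, small_panel):
        spec = sample_epistasis_spec(small_panel.locus_ids, 4, 1.0, seed=11)
        non_causal = next(l for l in small_panel.locus_ids
                          if l not in spec.causal_loci)
        delta, avg = true_effect_sizes(spec, small_panel, non_causal)
        assert (delta == 0).all() and avg == 0.0

    def test_matches_brute_force_reevaluation(self, small_panel):
        spec = sample_epistasis_spec(small_panel.locus_ids, 10, 0.3, seed=12)
        locus = spec.causal_loci[0]
        delta, avg = true_effect_sizes(spec, small_panel, locus)
        j = small_panel.locus_index(locus)
        Gp = GenotypeMatrix(np.array(small_panel.values), small_panel.locus_ids)
        Gp.values[:, j] = 1
        y_plus = brute_force_map(spec, Gp)
        Gp.values[:, j] = -1
        y_minus = brute_force_map(spec, Gp)
        assert np.allclose(delta, y_plus - y_minus, atol=1e-12)
        assert avg == pytest.approx((y_plus - y_minus).mean())


class TestMultiEnvSpecs:
    def test_all_ones_correlation_gives_identical_coefficients(self, small_panel):
        C = np.ones((3, 3))
        specs = sample_multi_env_specs(["a", "b", "c"], small_panel.locus_ids,
                                       8, 0.3, C, seed=1)
        for s in specs[1:]:
            assert np.allclose(list(s.linear_coeffs.values()),
                               list(specs[0].linear_coeffs.values()))
            assert s.causal_loci == specs[0].causal_loci
            assert [q for q, _ in s.quad_terms] == [q for q, _ in specs[0].quad_terms]

    def test_identity_correlation_decorrelates(self):
        locus_ids = [f"l{j}" for j in range(400)]
        specs = sample_multi_env_specs(["a", "b"], locus_ids, 300, 0.3,
                                       np.eye(2), seed=2)
        a = np.array(list(specs[0].linear_coeffs.values()))
        b = np.array(list(specs[1].linear_coeffs.values()))
        assert abs(np.corrcoef(a, b)[0, 1]) < 0.1

    def test_kernel_correlations_recovered(self):
        temps = [23, 25, 27, 30, 33, 35, 37]
        C = np.exp(-np.abs(np.subtract.outer(temps, temps)) / 10.0)
        locus_ids = [f"l{j}" for j in range(400)]
        specs = sample_multi_env_specs([f"T{t}" for t in temps], locus_ids,
                                       300, 0.3, C, seed=3)
        coef = np.array([list(s.linear_coeffs.values()) for s in specs])
        emp = np.corrcoef(coef)
        assert np.abs(emp - C).max() < 0.1

    def test_non_psd_rejected(self, small_panel):
        C = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValueError):
            sample_multi_env_specs(["a", "b"], small_panel.locus_ids, 6, 0.3,
                                   C, seed=4)
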