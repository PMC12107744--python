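import numpy as np
import pytest

from dracoon.simulate import (
    DEFAULTS,
    apply_perturbation,
    generate_tree_grn,
    graph_covariance,
    nearest_positive_definite,
    network_genes,
    simulate_benchmark,
    simulate_expression,
    start_benchmark,
    sweep,
)


class TestTreeGRN:
    @pytest.mark.parametrize("n_tf,n_tg", [(3, 7), (1, 1), (10, 40)])
    def test_tree_properties(self, n_tf, n_tg):
        edges = generate_tree_grn(n_tf, n_tg, seed=0)
        genes = network_genes(edges)
        assert len(genes) == n_tf + n_tg
        assert len(edges) == n_tf + n_tg - 1
        in_deg = {g: 0 for g in genes}
        for _, child in edges:
            in_deg[child] += 1
        roots = [g for g, d in in_deg.items() if d == 0]
        assert roots == ["TF1"]
        assert all(d == 1 for g, d in in_deg.items() if g != "TF1")
        # every TG is regulated by a TF
        assert all(s.startswith("TF") for s, _ in edges)

    def test_single_edge_case(self):
        assert generate_tree_grn(1, 1, seed=3) == [("TF1", "TG1")]

    def test_deterministic_per_seed(self):
        assert generate_tree_grn(5, 20, seed=11) == generate_tree_grn(5, 20, seed=11)


class TestGraphCovariance:
    def test_distance_decay(self):
        edges = [("TF1", "TF2"), ("TF2", "TG1"), ("TF1", "TG2")]
        genes, sigma = graph_covariance(edges, rho=0.8)
        i = {g: k for k, g in enumerate(genes)}
        assert sigma[i["TF1"], i["TF2"]] == pytest.approx(0.8)      # d = 1
        assert sigma[i["TF1"], i["TG1"]] == pytest.approx(0.64)     # d = 2
        assert sigma[i["TG1"], i["TG2"]] == pytest.approx(0.8**3)   # d = 3
        assert np.diag(sigma) == pytest.approx(np.ones(4))

    def test_positive_definite_for_tree(self):
        edges = generate_tree_grn(3, 7, seed=1)
        _, sigma = graph_covariance(edges, rho=0.8)
        assert np.linalg.eigvalsh(sigma).min() > 0

    def test_rho_bounds(self):
        with pytest.raises(ValueError, match="rho"):
            graph_covariance([("TF1", "TG1")], rho=1.0)

    def test_nearest_pd_repair(self):
        bad = np.array([[1.0, 0.9, 0.9], [0.9, 1.0, -0.9], [0.9, -0.9, 1.0]])
        fixed = nearest_positive_definite(bad)
        assert np.linalg.eigvalsh(fixed).min() > 0
        assert np.diag(fixed) == pytest.approx(np.ones(3))


class TestSimulateExpression:
    def test_moments_at_large_m(self):
        edges = generate_tree_grn(4, 12, seed=2)
        ds = simulate_expression(edges, m_samples=10_000, rho=0.8, mu=6.0,
                                 sigma=1.0, seed=0)
        means = ds.values.mean(axis=1)
        assert np.abs(means - 6.0).max() < 4 * 1.0 / np.sqrt(10_000) * 3
        g, sigma_true = graph_covariance(edges, 0.8)
        emp = np.corrcoef(ds.values)
        s, t = edges[0]
        i = {x: k for k, x in enumerate(g)}
        assert emp[i[s], i[t]] == pytest.approx(0.8, abs=0.03)

    def test_deterministic_per_seed(self):
        edges = generate_tree_grn(2, 4, seed=5)
        d1 = simulate_expression(edges, 50, seed=9)
        d2 = simulate_expression(edges, 50, seed=9)
        np.testing.assert_array_equal(d1.values, d2.values)


class TestPerturbations:
    def test_counts_and_truth_consistency(self):
        b = simulate_benchmark(perturbation="knockdown", perturb_fraction=0.1,
                               n_tf=20, n_tg=80, seed=1)
        assert len(b.perturbed_genes) == 10  # round(0.1 * 100)
        assert len(b.truth_edges) > 0
        assert b.truth_edges <= set(b.network)
        assert all(
            e[0] in b.perturbed_genes or e[1] in b.perturbed_genes
            for e in b.truth_edges
        )
        # TFs are prioritized: 10 perturbed of 20 TFs -> all are TFs
        assert all(g.startswith("TF") for g in b.perturbed_genes)

    def test_knockdown_lowers_case_mean(self):
        lower = 0
        for seed in range(10):
            b = simulate_benchmark(perturbation="knockdown",
                                   knockdown_factor=0.1, seed=seed)
            case = b.dataset.sample_mask("case")
            ctrl = b.dataset.sample_mask("control")
            g = sorted(b.perturbed_genes)[0]
            x = b.dataset.expression_of(g)
            lower += x[case].mean() < x[ctrl].mean()
        assert lower == 10  # mean drops from mu to 0.1*mu, far beyond noise

    def test_diff_expr_shifts_case_mean_up(self):
        b = simulate_benchmark(perturbation="diff_expr", de_shift=2.0, seed=3)
        case = b.dataset.sample_mask("case")
        ctrl = b.dataset.sample_mask("control")
        for g in b.perturbed_genes:
            x = b.dataset.expression_of(g)
            assert x[case].mean() - x[ctrl].mean() > 0.5

    def test_inversion_flips_case_correlation_sign(self):
        b = simulate_benchmark(perturbation="inversion", m_samples=10_000,
                               n_tf=5, n_tg=15, seed=4)
        case = b.dataset.sample_mask("case")
        ctrl = b.dataset.sample_mask("control")
        for s, t in sorted(b.truth_edges):
            x, y = b.dataset.expression_of(s), b.dataset.expression_of(t)
            r_case = np.corrcoef(x[case], y[case])[0, 1]
            r_ctrl = np.corrcoef(x[ctrl], y[ctrl])[0, 1]
            assert r_ctrl > 0.5 and r_case < -0.5

    def test_loss_of_coexpr_zeroes_case_correlation(self):
        b = simulate_benchmark(perturbation="loss_of_coexpr",
                               m_samples=10_000, n_tf=5, n_tg=15, seed=4)
        case = b.dataset.sample_mask("case")
        for s, t in sorted(b.truth_edges):
            x, y = b.dataset.expression_of(s), b.dataset.expression_of(t)
            assert abs(np.corrcoef(x[case], y[case])[0, 1]) < 0.1

    def test_unperturbed_covariance_entries_preserved(self):
        """Cutting / flipping perturbed edges must not disturb correlations
        among genes whose connecting paths avoid perturbed edges."""
        b = simulate_benchmark(perturbation="inversion", m_samples=10_000,
                               n_tf=5, n_tg=15, seed=8)
        case = b.dataset.sample_mask("case")
        touched = {g for e in b.truth_edges for g in e}
        clean = [(s, t) for s, t in b.network
                 if s not in touched and t not in touched]
        for s, t in clean:
            x, y = b.dataset.expression_of(s), b.dataset.expression_of(t)
            r_case = np.corrcoef(x[case], y[case])[0, 1]
            assert r_case == pytest.approx(DEFAULTS["rho"], abs=0.05)

    def test_none_perturbation_is_null(self):
        b = simulate_benchmark(perturbation="none", seed=0)
        assert b.truth_edges == set() and b.perturbed_genes == set()

    def test_parameter_validation(self):
        draft = start_benchmark(n_tf=2, n_tg=6, m_samples=20, seed=0)
        with pytest.raises(ValueError, match="perturb_fraction"):
            apply_perturbation(draft, "knockdown", perturb_fraction=1.5)
        draft = start_benchmark(n_tf=2, n_tg=6, m_samples=20, seed=0)
        with pytest.raises(ValueError, match="knockdown_factor"):
            apply_perturbation(draft, "knockdown", perturb_fraction=0.2,
                               knockdown_factor=2.0)
        with pytest.raises(ValueError, match="case_ratio"):
            start_benchmark(case_ratio=0.0)

    def test_full_determinism_per_seed(self):
        b1 = simulate_benchmark(perturbation="mixed", seed=42)
        b2 = simulate_benchmark(perturbation="mixed", seed=42)
        np.testing.assert_array_equal(b1.dataset.values, b2.dataset.values)
        assert b1.truth_edges == b2.truth_edges
        assert b1.params["perturbation_types"] == b2.params["perturbation_types"]


class TestSweep:
    def test_single_cell_grid(self):
        tab = sweep(case_ratios=[0.5], perturb_fractions=[0.1],
                    perturbations=["knockdown"], n_sims=1, n_runs=1, seed=0,
                    n_perm=100, n_tf=3, n_tg=9, m_samples=40)
        assert len(tab) == 1
        assert {"perturbation", "case_ratio", "perturb_fraction", "mcc"} <= set(
            tab.columns
        )

    def test_row_count_arithmetic(self):
        tab = sweep(case_ratios=[0.3, 0.5], perturb_fractions=[0.1],
                    perturbations=["knockdown", "inversion"], n_sims=2,
                    n_runs=2, seed=1, n_perm=50, n_tf=3, n_tg=9, m_samples=40)
        assert len(tab) == 2 * 1 * 2 * 2 * 2

    def test_sweep_deterministic(self):
        kw = dict(case_ratios=[0.5], perturb_fractions=[0.2],
                  perturbations=["mixed"], n_sims=1, n_runs=2, seed=9,
                  n_perm=100, n_tf=3, n_tg=9, m_samples=40)
        t1, t2 = sweep(**kw), sweep(**kw)
        assert t1.equals(t2)
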