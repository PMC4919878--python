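"""Maximum-likelihood fitting: closed forms, oracle grids, recovery, profiles."""

import json
import math

import numpy as np
import pytest
from scipy.stats import binomtest

from branchprior.brldist import (
    CompoundDirichletParams,
    ExpParams,
    compound_dirichlet_loglik,
    exponential_loglik,
)
from branchprior.fitting import (
    fit_compound_dirichlet,
    fit_exponential,
    profile_loglik,
    write_report,
)
from branchprior.simulate import SimulationSpec, simulate_trees
from branchprior.treeio import BranchLengthSample, harvest_sample

from conftest import random_sample


def cd_samples(n_trees, n_tips, params, seed):
    spec = SimulationSpec(n_tips=n_tips, n_trees=n_trees, generator=params, seed=seed)
    return [harvest_sample(t) for t in simulate_trees(spec)]


class TestFitExponential:
    def test_one_over_mean(self):
        sample = BranchLengthSample(np.array([0.25] * 4), np.array([]))
        fit = fit_exponential([sample])
        assert fit.params.rate == pytest.approx(4.0, rel=1e-15)
        assert fit.converged and fit.n_branches == 4

    def test_informed_rate_magnitude(self):
        """Two trees whose pooled mean branch length is 0.01046 give a rate of
        ~95.6 — the magnitude typical of informed rates fit to intraspecific
        mtDNA trees."""
        pooled_mean = 0.01046
        samples = [
            BranchLengthSample(np.full(4, pooled_mean), np.full(1, pooled_mean)),
            BranchLengthSample(np.full(5, pooled_mean), np.full(2, pooled_mean)),
        ]
        fit = fit_exponential(samples)
        assert fit.params.rate == pytest.approx(1 / pooled_mean, rel=1e-12)
        assert round(fit.params.rate, 1) == 95.6

    def test_recovers_generating_rate(self):
        spec = SimulationSpec(n_tips=8, n_trees=1000, generator=ExpParams(40.0), seed=13)
        samples = [harvest_sample(t) for t in simulate_trees(spec)]
        fit = fit_exponential(samples)
        n = fit.n_branches
        se = 40.0 / math.sqrt(n)  # asymptotic SE of the rate MLE
        assert abs(fit.params.rate - 40.0) < 3 * se

    def test_loglik_matches_density_module(self):
        rng = np.random.default_rng(3)
        samples = [random_sample(rng) for _ in range(5)]
        fit = fit_exponential(samples)
        direct = sum(exponential_loglik(fit.params, s) for s in samples)
        assert fit.loglik == pytest.approx(direct, rel=1e-12)

    def test_empty_and_degenerate_inputs(self):
        with pytest.raises(ValueError):
            fit_exponential([])


class TestFitCompoundDirichlet:
    TRUTH = CompoundDirichletParams(alpha_T=1.0, beta_T=2.5, alpha=0.3, c=1.6)

    def test_alpha_only_matches_grid_search(self):
        """The optimizer's alpha agrees with a 10,000-point log-space grid."""
        samples = cd_samples(30, 10, self.TRUTH, seed=2)
        fit = fit_compound_dirichlet(samples, mode="alpha_only")
        grid = np.exp(np.linspace(math.log(0.01), math.log(20), 10_000))
        prof = profile_loglik(samples, "compound_dirichlet", "alpha", grid)
        lls = np.array([ll for _, ll in prof])
        best = grid[np.argmax(lls)]
        step = math.log(grid[1]) - math.log(grid[0])
        assert abs(math.log(fit.params.alpha) - math.log(best)) <= step
        assert fit.loglik >= lls.max() - 1e-9

    def test_joint_beats_grid(self):
        """Joint fit dominates every node of a 100x100 (alpha, c) grid."""
        rng_seeds = range(5)
        a_grid = np.exp(np.linspace(math.log(0.02), math.log(10), 100))
        c_grid = np.exp(np.linspace(math.log(0.05), math.log(10), 100))
        for seed in rng_seeds:
            samples = cd_samples(15, 8, self.TRUTH, seed=1000 + seed)
            fit = fit_compound_dirichlet(samples, mode="joint")
            best = -np.inf
            for c in c_grid:
                prof = profile_loglik(
                    samples, "compound_dirichlet", "alpha", a_grid, fixed={"c": c}
                )
                best = max(best, max(ll for _, ll in prof))
            assert fit.loglik >= best - 1e-6

    def test_joint_recovery_moderate_scale(self):
        truth = CompoundDirichletParams(alpha_T=1.0, beta_T=2.5, alpha=0.11, c=1.35)
        samples = cd_samples(300, 20, truth, seed=8)
        fit = fit_compound_dirichlet(samples, mode="joint")
        assert fit.converged
        assert fit.params.alpha == pytest.approx(0.11, rel=0.10)
        assert fit.params.c == pytest.approx(1.35, rel=0.15)

    def test_c_unbiased_when_exchangeable(self):
        """Generated with c=1, the joint c estimate shows no systematic
        deviation from 1 (sign test across 200 replicates)."""
        truth = CompoundDirichletParams(alpha_T=1.0, beta_T=2.5, alpha=0.5, c=1.0)
        above = 0
        for rep in range(200):
            samples = cd_samples(12, 10, truth, seed=20_000 + rep)
            fit = fit_compound_dirichlet(samples, mode="joint")
            if fit.params.c > 1.0:
                above += 1
        assert binomtest(above, 200, 0.5).pvalue > 0.01

    def test_consistency_error_shrinks_with_tree_count(self):
        """Median absolute error of (alpha, c) decreases as trees grow 10 -> 1,000."""
        errors = {}
        for n_trees in (10, 100, 1000):
            errs = []
            for seed in range(5):
                samples = cd_samples(n_trees, 12, self.TRUTH, seed=500 + seed)
                fit = fit_compound_dirichlet(samples, mode="joint")
                errs.append(
                    abs(fit.params.alpha - self.TRUTH.alpha)
                    + abs(fit.params.c - self.TRUTH.c)
                )
            errors[n_trees] = float(np.median(errs))
        assert errors[10] > errors[100] > errors[1000]

    def test_mode_defaults_and_fixed_params(self):
        samples = cd_samples(20, 8, self.TRUTH, seed=4)
        a_only = fit_compound_dirichlet(samples, mode="alpha_only")
        assert a_only.free_params == ("alpha",)
        assert a_only.params.c == 1.0  # default fixed c
        c_only = fit_compound_dirichlet(samples, mode="c_only", fixed={"alpha": 0.3})
        assert c_only.free_params == ("c",)
        assert c_only.params.alpha == 0.3
        fixed_bT = fit_compound_dirichlet(
            samples, mode="joint", fixed={"alpha_T": 2.0, "beta_T": 5.0}
        )
        assert fixed_bT.params.alpha_T == 2.0 and fixed_bT.params.beta_T == 5.0
        # default beta_T is the closed-form gamma-rate MLE with known shape
        mean_T = np.mean([s.T for s in samples])
        assert a_only.params.beta_T == pytest.approx(1.0 / mean_T, rel=1e-12)

    def test_loglik_matches_density_module(self):
        samples = cd_samples(10, 7, self.TRUTH, seed=6)
        fit = fit_compound_dirichlet(samples, mode="joint")
        direct = sum(compound_dirichlet_loglik(fit.params, s) for s in samples)
        assert fit.loglik == pytest.approx(direct, rel=1e-9)

    def test_c_unidentifiable_without_internal_branches(self, star_sample):
        for mode in ("joint", "c_only"):
            with pytest.raises(ValueError, match="unidentifiable"):
                fit_compound_dirichlet([star_sample], mode=mode)
        # alpha_only is still fine on star trees
        fit = fit_compound_dirichlet([star_sample], mode="alpha_only")
        assert fit.converged

    def test_nonconvergence_is_flagged(self, quartet_sample, monkeypatch):
        import branchprior.fitting as fitting

        monkeypatch.setattr(fitting, "MAX_ITER", 2)
        fit = fit_compound_dirichlet([quartet_sample], mode="joint")
        assert fit.converged is False

    def test_unknown_mode_rejected(self, quartet_sample):
        with pytest.raises(ValueError, match="mode"):
            fit_compound_dirichlet([quartet_sample], mode="both")


class TestProfileLoglik:
    def test_alpha_profile_argmax_near_optimizer(self):
        truth = CompoundDirichletParams(1.0, 2.5, 0.3, 1.5)
        samples = cd_samples(40, 10, truth, seed=9)
        fit = fit_compound_dirichlet(samples, mode="alpha_only")
        grid = np.exp(np.linspace(math.log(0.02), math.log(5), 400))
        prof = profile_loglik(samples, "compound_dirichlet", "alpha", grid)
        values, lls = zip(*prof)
        best = values[int(np.argmax(lls))]
        step = math.log(values[1] / values[0])
        assert abs(math.log(best / fit.params.alpha)) <= step

    def test_exponential_profile_peaks_at_closed_form(self, quartet_sample):
        mle = quartet_sample.n / quartet_sample.T
        grid = np.linspace(0.5, 12.0, 500)
        prof = profile_loglik([quartet_sample], "exponential", "rate", grid)
        values, lls = zip(*prof)
        assert abs(values[int(np.argmax(lls))] - mle) <= grid[1] - grid[0]

    def test_c_profile_on_star_sample_errors(self, star_sample):
        with pytest.raises(ValueError, match="unidentifiable"):
            profile_loglik([star_sample], "compound_dirichlet", "c", [0.5, 1.0, 2.0])

    def test_grid_validation(self, quartet_sample):
        with pytest.raises(ValueError, match="empty"):
            profile_loglik([quartet_sample], "exponential", "rate", [])
        with pytest.raises(ValueError, match="> 0"):
            profile_loglik([quartet_sample], "exponential", "rate", [-1.0, 1.0])
        with pytest.raises(ValueError, match="sorted"):
            profile_loglik([quartet_sample], "exponential", "rate", [2.0, 1.0])


def test_write_report_roundtrip(tmp_path, quartet_sample):
    fits = [
        fit_exponential([quartet_sample]),
        fit_compound_dirichlet([quartet_sample], mode="alpha_only"),
    ]
    tsv, js = tmp_path / "r.tsv", tmp_path / "r.json"
    write_report(fits, tsv)
    write_report(fits, js, fmt="json")
    lines = tsv.read_text().strip().splitlines()
    assert len(lines) == 3 and lines[0].startswith("distribution\t")
    data = json.loads(js.read_text())
    assert data[0]["distribution"] == "exponential"
    assert data[1]["mode"] == "alpha_only"
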