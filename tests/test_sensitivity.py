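"""DSA tornado ranking, distribution moment matching, and Monte Carlo PSA."""

import numpy as np
import pytest

from waitcea.config import ModelRun
from waitcea.costs import discount_lump
from waitcea.outcomes import evaluate_run
from waitcea.sensitivity import (
    DistributionSpec,
    DsaSpec,
    default_distributions,
    list_parameter_paths,
    moment_match,
    resolve_path,
    run_dsa,
    run_psa,
    with_path_set,
)


def _simple_run(direct_early=100_000.0, n=10.0):
    return ModelRun.model_validate(
        {
            "cohorts": [
                {
                    "name": "demo",
                    "subgroups": [
                        {
                            "kind": "RWT",
                            "n_patients": n,
                            "utilities": {"u_wait": 0.5, "u_post_early": 0.8, "u_post_delayed": 0.7},
                            "timeline": {"t_early": 0.2, "t_delayed": 1.2,
                                         "t_death_counterfactual": 15.0, "t_death_early": 15.0},
                            "costs": {"direct_early": direct_early, "direct_delayed": 40_000,
                                      "indirect_patient_early": 1_000, "indirect_patient_delayed": 3_000,
                                      "incurrence_time_early": 0.2, "incurrence_time_delayed": 1.2},
                        },
                        {
                            "kind": "AMS",
                            "n_patients": 5,
                            "utilities": {"u_wait": 0.5, "u_post_early": 0.8,
                                          "u_post_delayed": 0.7, "u_missed": 0.4},
                            "timeline": {"t_early": 0.2, "t_delayed": 0.2,
                                         "t_death_counterfactual": 10.0, "t_death_early": 15.0},
                            "costs": {"direct_early": 100_000,
                                      "indirect_patient_delayed": 20_000,
                                      "incurrence_time_early": 0.2},
                        },
                    ],
                }
            ],
            "discount": {"annual_rate": 0.035},
            "economy": {"gdp_per_capita": 56_000, "wtp_threshold": 56_000},
        }
    )


class TestParameterPaths:
    def test_resolve_and_set_round_trip(self, egypt_run):
        path = "cochlear_implantation/RWT/costs/direct_early"
        value = resolve_path(egypt_run, path)
        bumped = with_path_set(egypt_run, path, value * 2)
        assert resolve_path(bumped, path) == pytest.approx(value * 2)
        assert resolve_path(egypt_run, path) == value  # original untouched

    def test_malformed_path_rejected(self, egypt_run):
        with pytest.raises(KeyError):
            resolve_path(egypt_run, "cochlear_implantation/RWT/nope")

    def test_enumeration_covers_every_subgroup(self, egypt_run):
        paths = list_parameter_paths(egypt_run)
        prefixes = {"/".join(p.split("/")[:2]) for p in paths}
        expected = {
            f"{c.name}/{sg.kind.value}" for c in egypt_run.cohorts for sg in c.subgroups
        }
        assert prefixes == expected

    def test_lifesaving_tie_propagates_through_set(self, egypt_run):
        path = "open_heart_surgery/MA/timeline/t_early"
        moved = with_path_set(egypt_run, path, 0.5)
        tl = moved.subgroup("open_heart_surgery", "MA").timeline
        assert tl.t_death_counterfactual == 0.5 and tl.t_delayed == 0.5


class TestDsa:
    def test_unused_parameter_has_zero_bar_width(self):
        """A waiting-list utility on a missed-surgery subgroup enters no
        formula; its tornado bar must be exactly flat."""
        run = _simple_run()
        spec = DsaSpec(parameter_paths=["demo/AMS/utilities/u_wait"])
        entry = run_dsa(run, spec).entries[0]
        assert entry.bar_width == 0.0

    def test_cost_perturbation_propagates_linearly(self):
        """±δ on a lump direct cost moves the composite cost numerator by
        exactly ±δ × its discounted population contribution while ΔQALYs
        stay fixed (closed-form propagation)."""
        run = _simple_run()
        base = evaluate_run(run).composite
        dq = base.total_delta_qalys
        path = "demo/RWT/costs/direct_early"
        delta = 0.10
        contrib = 10.0 * discount_lump(100_000.0, 0.2, 0.035)
        result = run_dsa(run, DsaSpec(parameter_paths=[path], relative_delta=delta))
        e = result.entries[0]
        icer_base = base.icer_societal.value
        assert e.icer_high - icer_base == pytest.approx(delta * contrib / dq, rel=1e-9)
        assert icer_base - e.icer_low == pytest.approx(delta * contrib / dq, rel=1e-9)

    def test_ranking_matches_brute_force_widths(self):
        run = _simple_run()
        paths = [
            "demo/RWT/costs/direct_early",
            "demo/RWT/costs/indirect_patient_early",   # 100× smaller lump
            "demo/AMS/utilities/u_wait",               # no influence at all
        ]
        result = run_dsa(run, DsaSpec(parameter_paths=paths))
        ordered = [e.parameter_path for e in result.entries]
        assert ordered == paths  # constructed to be strictly decreasing influence

    def test_bar_widths_vanish_as_delta_shrinks(self):
        run = _simple_run()
        paths = ["demo/RWT/costs/direct_early", "demo/RWT/utilities/u_post_early"]
        widths = []
        for delta in (0.10, 0.01, 0.001):
            res = run_dsa(run, DsaSpec(parameter_paths=paths, relative_delta=delta))
            widths.append(max(e.bar_width for e in res.entries))
        assert widths[0] > widths[1] > widths[2]
        assert widths[2] < widths[0] / 50

    def test_invariant_breaking_perturbation_flagged_not_clamped(self):
        run = _simple_run()
        # raising t_delayed 10% above t_death_counterfactual is impossible
        run2 = with_path_set(run, "demo/RWT/timeline/t_delayed", 14.0)
        res = run_dsa(run2, DsaSpec(parameter_paths=["demo/RWT/timeline/t_delayed"]))
        assert res.entries[0].infeasible

    def test_entries_sorted_by_width_descending(self, egypt_run):
        res = run_dsa(egypt_run, DsaSpec(parameter_paths=list_parameter_paths(egypt_run)))
        widths = [e.bar_width for e in res.entries if not e.infeasible]
        assert widths == sorted(widths, reverse=True)


class TestMomentMatch:
    def test_zero_spread_degenerates_to_point_mass(self):
        params = moment_match(DistributionSpec("beta", 0.5, 0.0))
        assert params == {"family": "degenerate", "value": 0.5}

    def test_beta_infeasible_moments_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            moment_match(DistributionSpec("beta", 0.5, 0.6))

    @pytest.mark.parametrize(
        "family,mean,spread",
        [("gamma", 100.0, 20.0), ("beta", 0.7, 0.1), ("normal", 12.0, 1.2)],
    )
    def test_sampled_moments_recover_inputs(self, family, mean, spread):
        from waitcea.sensitivity import _sample

        rng = np.random.default_rng(11)
        draws = _sample(rng, moment_match(DistributionSpec(family, mean, spread)), 100_000)
        se_mean = spread / np.sqrt(draws.size)
        assert abs(draws.mean() - mean) < 3 * se_mean
        assert abs(draws.std(ddof=1) - spread) < 0.05 * spread


class TestPsa:
    def test_degenerate_spreads_reproduce_base_case_exactly(self, egypt_run):
        base = evaluate_run(egypt_run).composite
        psa = run_psa(egypt_run, default_distributions(egypt_run, spread_fraction=0.0),
                      n_draws=200, seed=3)
        assert psa.n_rejected == 0
        assert np.all(psa.delta_qalys == psa.delta_qalys[0])
        assert psa.delta_qalys[0] == pytest.approx(base.total_delta_qalys, rel=1e-12)
        assert psa.delta_cost_societal[0] == pytest.approx(
            base.costs.delta_total_societal, rel=1e-12
        )

    def test_same_seed_bitwise_reproducible(self, egypt_run):
        dists = default_distributions(egypt_run)
        a = run_psa(egypt_run, dists, n_draws=500, seed=9)
        b = run_psa(egypt_run, dists, n_draws=500, seed=9)
        assert np.array_equal(a.delta_qalys, b.delta_qalys)
        assert np.array_equal(a.delta_cost_societal, b.delta_cost_societal)

    def test_mean_qalys_near_deterministic_for_small_spreads(self, egypt_run):
        base = evaluate_run(egypt_run).composite
        psa = run_psa(egypt_run, default_distributions(egypt_run, spread_fraction=0.02),
                      n_draws=5000, seed=21)
        se = psa.delta_qalys.std(ddof=1) / np.sqrt(psa.n_draws)
        assert abs(psa.mean_delta_qalys - base.total_delta_qalys) < 3 * se

    def test_ceac_monotone_in_wtp_for_positive_qaly_draws(self, egypt_run):
        """With QALY gains held at base case (cost-only sampling) every
        draw gains QALYs, and the acceptability curve must be
        non-decreasing in willingness to pay."""
        dists = {
            path: spec
            for path, spec in default_distributions(egypt_run).items()
            if "/costs/" in path
        }
        psa = run_psa(egypt_run, dists, n_draws=1000, seed=4)
        assert np.all(psa.delta_qalys > 0)
        grid = np.linspace(0, 200_000, 21)
        curve = psa.ceac(grid)
        assert np.all(np.diff(curve) >= 0)

    def test_excessive_rejection_aborts_with_diagnostic(self):
        """Sampling a counterfactual death date sitting just under the
        early-arm one with a huge spread inverts the ordering in most
        draws; the PSA must refuse and name the offender."""
        run = _simple_run()
        path = "demo/AMS/timeline/t_death_counterfactual"
        dists = {path: DistributionSpec("normal", 10.0, 25.0)}
        with pytest.raises(RuntimeError, match="t_death_counterfactual"):
            run_psa(run, dists, n_draws=500, seed=2)

    def test_sampling_the_lifesaving_tie_is_refused(self, egypt_run):
        dists = {
            "open_heart_surgery/MA/timeline/t_death_counterfactual":
                DistributionSpec("normal", 0.2, 0.02)
        }
        with pytest.raises(ValueError, match="tie"):
            run_psa(egypt_run, dists, n_draws=10, seed=0)
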