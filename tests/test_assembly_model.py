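"""Closed-form yield, Monte-Carlo oracle agreement, and pathway comparison."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cotransl.assembly_model import (
    AssemblyPathway,
    balanced_tree,
    compare_pathways,
    sequential_tree,
    yield_vs_n,
)


class TestClosedForm:
    def test_no_failure_modes_give_unit_yield(self):
        for tree in (sequential_tree(5), balanced_tree(8)):
            pw = AssemblyPathway(tree, specificity=1.0, hazard=0.0)
            assert pw.closed_form_yield().yield_ == 1.0

    def test_sequential_chain_of_four(self):
        pw = AssemblyPathway.sequential(4, specificity=0.9, hazard=0.1, wait=1.0)
        res = pw.closed_form_yield()
        # exposures: subunits 1,1,2,3 + intermediates 1,1 = 9 time units
        assert res.total_exposure == 9.0
        assert res.yield_ == pytest.approx(0.9 ** 3 * math.exp(-0.9))
        assert res.yield_ == pytest.approx(0.2964, abs=1e-4)

    def test_balanced_four_beats_sequential(self):
        pw = AssemblyPathway.balanced(4, specificity=0.9, hazard=0.1, wait=1.0)
        res = pw.closed_form_yield()
        assert res.total_exposure == 6.0
        assert res.yield_ == pytest.approx(0.9 ** 3 * math.exp(-0.6))
        assert res.yield_ == pytest.approx(0.4001, abs=1e-4)

    def test_yield_decomposes_into_components(self):
        pw = AssemblyPathway.sequential(6, specificity=0.85, hazard=0.05)
        res = pw.closed_form_yield()
        assert res.yield_ == pytest.approx(
            res.specificity_component * res.hazard_component
        )

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            AssemblyPathway.sequential(4, hazard=-0.1)
        with pytest.raises(ValueError):
            AssemblyPathway.sequential(4, wait=-1.0)
        with pytest.raises(ValueError):
            AssemblyPathway.sequential(4, specificity=0.0)
        with pytest.raises(ValueError):
            AssemblyPathway.sequential(4, dwell_factor=0.5)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        n=st.integers(2, 16),
        s=st.floats(0.5, 1.0),
        lam=st.floats(0.0, 0.5),
        tau=st.floats(0.0, 2.0),
        balanced=st.booleans(),
    )
    def test_yield_in_unit_interval(self, n, s, lam, tau, balanced):
        maker = AssemblyPathway.balanced if balanced else AssemblyPathway.sequential
        y = maker(n, specificity=s, hazard=lam, wait=tau).closed_form_yield().yield_
        assert 0.0 <= y <= 1.0

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(n=st.integers(2, 12), s=st.floats(0.5, 0.99), lam=st.floats(0.01, 0.3))
    def test_monotone_in_specificity_and_hazard(self, n, s, lam):
        base = AssemblyPathway.sequential(n, specificity=s, hazard=lam).closed_form_yield().yield_
        higher_s = AssemblyPathway.sequential(n, specificity=min(1.0, s + 0.01), hazard=lam)
        higher_lam = AssemblyPathway.sequential(n, specificity=s, hazard=lam + 0.1)
        assert higher_s.closed_form_yield().yield_ >= base
        assert higher_lam.closed_form_yield().yield_ <= base


class TestYieldVsN:
    def test_single_subunit_trivial(self):
        curve = yield_vs_n(0.9, 0.1, 1.0, n_range=[1])
        assert curve["yield"][0] == 1.0

    def test_lambda_zero_sequential_is_exactly_geometric(self):
        s = 0.92
        curve = yield_vs_n(s, 0.0, 1.0, n_range=range(1, 20))
        assert np.allclose(curve["yield"], s ** (curve["n"] - 1))
        assert curve["log_yield_slope"] == pytest.approx(math.log(s), rel=1e-6)

    def test_quadratic_exposure_curvature(self):
        # sequential exposure sum is n(n-1)/2 + (n-1): log Y curvature = -lam*tau/2
        s, lam, tau = 0.9, 0.2, 1.5
        curve = yield_vs_n(s, lam, tau, n_range=range(2, 20))
        coeffs = np.polyfit(curve["n"], np.log(curve["yield"]), 2)
        assert coeffs[0] == pytest.approx(-lam * tau / 2, rel=0.01)

    def test_out_of_range_n_rejected(self):
        with pytest.raises(ValueError):
            yield_vs_n(0.9, 0.0, 1.0, n_range=[70])


class TestMonteCarlo:
    def test_certain_success(self):
        pw = AssemblyPathway.balanced(4, specificity=1.0, hazard=0.0)
        res = pw.simulate(n_trials=500, seed=0)
        assert res.yield_ == 1.0

    def test_deterministic_mode_matches_closed_form_chain4(self):
        pw = AssemblyPathway.sequential(4, specificity=0.9, hazard=0.1, wait=1.0)
        mc = pw.simulate(n_trials=20_000, seed=1)
        assert abs(mc.yield_ - 0.2964) <= 3 * mc.se

    @pytest.mark.parametrize("seed,n,s,lam,balanced", [
        (1, 3, 0.95, 0.05, False),
        (2, 6, 0.9, 0.1, True),
        (3, 8, 0.8, 0.02, False),
        (4, 5, 0.99, 0.2, True),
    ])
    def test_oracle_agreement_spot_checks(self, seed, n, s, lam, balanced):
        maker = AssemblyPathway.balanced if balanced else AssemblyPathway.sequential
        pw = maker(n, specificity=s, hazard=lam, wait=1.0)
        cf = pw.closed_form_yield().yield_
        mc = pw.simulate(n_trials=20_000, seed=seed)
        se = max(mc.se, 1e-4)
        assert abs(mc.yield_ - cf) <= 3 * se

    def test_exponential_waits_reduce_yield_on_balanced_tree(self):
        # E[max(Exp, Exp)] exceeds the deterministic wait, inflating orphan
        # exposure on branched topologies
        pw = AssemblyPathway.balanced(8, specificity=1.0, hazard=0.2, wait=1.0)
        det = pw.closed_form_yield().yield_
        mc = pw.simulate(n_trials=40_000, seed=7, waits="exponential")
        assert mc.yield_ <= det + 2 * mc.se

    def test_seeded_reproducibility(self):
        pw = AssemblyPathway.sequential(5, specificity=0.9, hazard=0.1)
        a = pw.simulate(n_trials=5_000, seed=42)
        b = pw.simulate(n_trials=5_000, seed=42)
        assert a.successes == b.successes


class TestCotranslationalCapture:
    def test_capture_never_decreases_yield(self):
        for delta in (1.0, 2.0, 10.0):
            base = AssemblyPathway.sequential(4, specificity=0.8, hazard=0.2)
            cap = AssemblyPathway.sequential(
                4, specificity=0.8, hazard=0.2, cotranslational=["S2"], dwell_factor=delta
            )
            assert cap.closed_form_yield().yield_ >= base.closed_form_yield().yield_

    def test_neutral_capture_changes_only_captured_leaf_exposure(self):
        base = AssemblyPathway.sequential(4, specificity=0.8, hazard=0.2, wait=1.0)
        cap = AssemblyPathway.sequential(
            4,
            specificity=0.8,
            hazard=0.2,
            wait=1.0,
            cotranslational=["S4"],
            dwell_factor=1.0,
            translation_wait=1.0,
        )
        rb, rc = base.closed_form_yield(), cap.closed_form_yield()
        assert rc.specificity_component == pytest.approx(rb.specificity_component)
        assert rc.exposures["S4"] == 0.0
        changed = {k for k in rb.exposures if rb.exposures[k] != rc.exposures[k]}
        assert changed == {"S4"}

    def test_dwell_factor_boosts_join_odds(self):
        pw = AssemblyPathway.sequential(
            2, specificity=0.5, cotranslational=["S2"], dwell_factor=3.0
        )
        assert pw.s_eff_cotranslational == pytest.approx(1.5 / 2.0)
        assert pw.closed_form_yield().yield_ == pytest.approx(0.75)

    def test_translation_limited_wait_shortens_schedule(self):
        slow = AssemblyPathway.sequential(3, hazard=0.1, wait=2.0)
        fast = AssemblyPathway.sequential(
            3, hazard=0.1, wait=2.0, cotranslational=["S3"], translation_wait=0.1
        )
        assert fast.closed_form_yield().total_exposure < slow.closed_form_yield().total_exposure

    def test_unknown_flagged_subunit_rejected(self):
        with pytest.raises(ValueError):
            AssemblyPathway.sequential(3, cotranslational=["NOPE"])


class TestComparePathways:
    @pytest.mark.parametrize("n", [2, 4, 8, 16, 32, 64])
    def test_balanced_at_least_sequential_under_hazard(self, n):
        kw = dict(specificity=0.95, hazard=0.05, wait=1.0)
        cmp_res = compare_pathways(
            AssemblyPathway.balanced(n, **kw), AssemblyPathway.sequential(n, **kw)
        )
        assert cmp_res.yield_a >= cmp_res.yield_b

    def test_equal_without_hazard(self):
        kw = dict(specificity=0.9, hazard=0.0)
        cmp_res = compare_pathways(
            AssemblyPathway.balanced(8, **kw), AssemblyPathway.sequential(8, **kw)
        )
        assert cmp_res.yield_a == pytest.approx(cmp_res.yield_b)
        assert cmp_res.differing_component == "none"

    def test_mismatched_sizes_rejected(self):
        with pytest.raises(ValueError):
            compare_pathways(AssemblyPathway.sequential(3), AssemblyPathway.sequential(4))

    def test_reports_differing_component(self):
        a = AssemblyPathway.sequential(4, specificity=0.9, hazard=0.1)
        b = AssemblyPathway.balanced(4, specificity=0.9, hazard=0.1)
        assert compare_pathways(a, b).differing_component == "hazard"


def test_yaml_roundtrip(tmp_path):
    import yaml

    spec = {
        "tree": [["A", "B"], ["C", "D"]],
        "specificity": 0.9,
        "hazard": 0.1,
        "wait": 1.0,
        "cotranslational": ["B"],
        "dwell_factor": 2.0,
    }
    path = tmp_path / "pathway.yaml"
    path.write_text(yaml.safe_dump(spec))
    pw = AssemblyPathway.from_yaml(path)
    assert pw.n_subunits == 4 and pw.n_joins == 3
    assert "B" in pw.cotranslational
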