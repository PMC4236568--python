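"""Demography compilation: windows, epochs, invariants."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from silkabc.models import (
    MODEL_IDS,
    ScaledParameters,
    compile_model,
    direction_variant,
    validate_parameters,
)


def make_params(**over):
    base = dict(theta1=0.0312, ratio_theta2=0.146392, ratio_thetaA=0.98953,
                ratio_thetaB1=0.94133, ratio_thetaB2=0.015339,
                tauD=0.00373, tau1=0.0025, tau2=0.001992)
    base.update(over)
    return ScaledParameters(**base)


class TestValidation:
    def test_published_mode_parameters_are_valid(self, map_params):
        assert validate_parameters(map_params, "C_at_bottleneck") == []

    @pytest.mark.parametrize("over, fragment", [
        (dict(tau1=0.01, tauD=0.005, tau2=0.001), "recovery predates split"),
        (dict(ratio_thetaB2=0.0), "non-positive size"),
        (dict(theta1=-1.0), "non-positive size"),
        (dict(tauD=0.0), "non-positive time"),
    ])
    def test_violations_are_reported_not_raised(self, over, fragment):
        violations = validate_parameters(make_params(**over), "A_no_flow")
        assert any(fragment in v for v in violations)

    def test_model_a_rejects_migration(self):
        p = make_params(mig_rate_wd=5.0)
        assert validate_parameters(p, "A_no_flow")
        assert validate_parameters(p, "C_at_bottleneck") == []

    def test_compile_raises_on_invalid(self):
        with pytest.raises(ValueError, match="recovery predates split"):
            compile_model(make_params(tau1=0.01, tauD=0.005), "A_no_flow")


class TestCompiledWindows:
    def test_model_a_has_no_migration_anywhere(self):
        spec = compile_model(make_params(), "A_no_flow")
        assert all(e.m_dom == 0 and e.m_wild == 0 for e in spec.epochs)
        assert spec.migration_window() is None

    def test_model_c_window_spans_bottleneck(self):
        p = make_params(mig_rate_wd=5.0, mig_rate_dw=10.0)
        spec = compile_model(p, "C_at_bottleneck")
        boundaries = sorted({e.start for e in spec.epochs})
        assert boundaries == [0.0, 0.001992, 0.0025, 0.00373]
        assert spec.migration_window() == (0.001992, 0.00373)

    def test_model_d_window_precedes_recovery(self):
        p = make_params(tau2=0.002, mig_rate_wd=3.0, mig_rate_dw=3.0)
        spec = compile_model(p, "D_after_bottleneck")
        assert spec.migration_window() == (0.0, 0.002)

    def test_model_b_window_is_whole_divergence(self):
        p = make_params(mig_rate_wd=3.0, mig_rate_dw=3.0)
        spec = compile_model(p, "B_continuous")
        assert spec.migration_window() == (0.0, p.tauD)

    def test_population_sizes_per_epoch(self):
        p = make_params(mig_rate_wd=1.0, mig_rate_dw=1.0)
        spec = compile_model(p, "C_at_bottleneck")
        by_start = {e.start: e for e in spec.epochs}
        assert by_start[0.0].size_dom == p.ratio_theta2
        assert by_start[0.0].size_wild == 1.0
        assert by_start[p.tau2].size_dom == p.ratio_thetaB2
        assert by_start[p.tau1].size_wild == p.ratio_thetaB1
        assert by_start[p.tauD].ancestral
        assert by_start[p.tauD].size_dom == p.ratio_thetaA

    def test_c_window_converges_to_b_as_tau2_vanishes(self):
        p = make_params(tau2=1e-12, mig_rate_wd=2.0, mig_rate_dw=2.0)
        c = compile_model(p, "C_at_bottleneck")
        b = compile_model(p, "B_continuous")
        lo_c, hi_c = c.migration_window()
        lo_b, hi_b = b.migration_window()
        assert hi_c == hi_b == p.tauD
        assert lo_c == pytest.approx(lo_b, abs=1e-12)

    def test_alternative_window_rules(self):
        p = make_params(mig_rate_wd=1.0, mig_rate_dw=1.0)
        assert compile_model(p, "C_at_bottleneck",
                             c_window="tau1").migration_window() == \
            (p.tau1, p.tauD)
        assert compile_model(p, "C_at_bottleneck",
                             c_window="min").migration_window() == \
            (min(p.tau1, p.tau2), p.tauD)


positive = st.floats(min_value=1e-3, max_value=10, allow_nan=False)
times = st.floats(min_value=1e-4, max_value=0.1, allow_nan=False)


@settings(max_examples=60, deadline=None)
@given(r2=positive, ra=positive, rb1=positive, rb2=positive,
       tauD=times, f1=st.floats(0.05, 0.95), f2=st.floats(0.05, 0.95),
       model=st.sampled_from(MODEL_IDS))
def test_epochs_tile_backward_time(r2, ra, rb1, rb2, tauD, f1, f2, model):
    """Compiled epochs partition [0, inf); spans up to the split sum to
    tauD; the model id is recoverable from the migration pattern."""
    p = ScaledParameters(theta1=0.03, ratio_theta2=r2, ratio_thetaA=ra,
                         ratio_thetaB1=rb1, ratio_thetaB2=rb2,
                         tauD=tauD, tau1=f1 * tauD, tau2=f2 * tauD,
                         mig_rate_wd=0.0 if model == "A_no_flow" else 5.0,
                         mig_rate_dw=0.0 if model == "A_no_flow" else 5.0)
    spec = compile_model(p, model)
    assert spec.epochs[0].start == 0.0
    assert math.isinf(spec.epochs[-1].end)
    for a, b in zip(spec.epochs[:-1], spec.epochs[1:]):
        assert a.end == b.start
    pre_split = [e for e in spec.epochs if not e.ancestral]
    assert sum(e.span for e in pre_split) == pytest.approx(tauD)
    # model identity from the migration pattern
    window = spec.migration_window()
    if model == "A_no_flow":
        assert window is None
    elif model == "B_continuous":
        assert window == (0.0, p.tauD)
    elif model == "C_at_bottleneck":
        assert window == (p.tau2, p.tauD)
    else:
        assert window == (0.0, p.tau2)


class TestDirectionVariants:
    def test_bidirectional_keeps_both_rates(self):
        p = make_params(mig_rate_wd=5.0, mig_rate_dw=10.0)
        spec = direction_variant(p, "DIR_bi")
        active = [e for e in spec.epochs if e.m_dom or e.m_wild]
        assert all(e.m_dom == 5.0 and e.m_wild == 10.0 for e in active)

    def test_one_way_variants_zero_the_other_rate(self):
        p = make_params(mig_rate_wd=5.0, mig_rate_dw=10.0)
        d2w = direction_variant(p, "DIR_d_to_w")
        assert d2w.params.mig_rate_wd == 0.0
        assert d2w.params.mig_rate_dw == 10.0
        w2d = direction_variant(p, "DIR_w_to_d")
        assert w2d.params.mig_rate_wd == 5.0
        assert w2d.params.mig_rate_dw == 0.0

    def test_variant_without_its_rate_raises(self):
        p = make_params(mig_rate_wd=5.0, mig_rate_dw=0.0)
        with pytest.raises(ValueError):
            direction_variant(p, "DIR_d_to_w")
        with pytest.raises(ValueError):
            direction_variant(make_params(), "DIR_bi")


class TestExports:
    def test_epoch_table_round_trips_by_eye(self):
        spec = compile_model(make_params(mig_rate_wd=1.0, mig_rate_dw=2.0),
                             "C_at_bottleneck")
        table = spec.to_table()
        assert table.splitlines()[0].startswith("start\tend")
        assert len(table.splitlines()) == len(spec.epochs) + 1

    def test_ms_command_mentions_every_event(self):
        p = make_params(mig_rate_wd=1.0, mig_rate_dw=2.0)
        cmd = compile_model(p, "C_at_bottleneck").to_ms_command(17, 15, 18.7)
        assert "-I 2 17 15" in cmd
        assert "-ej 0.00373" in cmd
        assert "-em 0.001992" in cmd
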