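"""Core fiber-burden arithmetic: loading, counting rules, concentration,
analytical sensitivity, field planning and Poisson intervals."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from fiberburden import (
    MIL,
    CountingSession,
    FiberRecord,
    FilterPrep,
    InfeasiblePlanError,
    InvalidInputError,
    InvalidPreparationError,
    MineralClass,
    StopReason,
    analytical_sensitivity,
    apply_counting_rules,
    ash_load,
    compute_concentration,
    plan_fields,
    poisson_interval,
    tissue_mass_on_filter,
)


def _fiber(length, mineral=MineralClass.AMOSITE, field=0):
    return FiberRecord(field, length, min(0.2, length / 2), mineral)


def _session(n_f, n_fields, length=3.0):
    fibers = tuple(_fiber(length, field=i % n_fields) for i in range(n_f))
    return CountingSession(n_fields_examined=n_fields, fibers=fibers)


# ---------------------------------------------------------------- loading

@pytest.mark.parametrize(
    "mass_mg, susp_ml, filt_ml, expected_g",
    [
        (100.0, 100.0, 20.0, 0.020),   # reference aliquot
        (100.0, 100.0, 100.0, 0.100),  # whole suspension filtered
        (250.0, 100.0, 10.0, 0.025),
    ],
)
def test_tissue_mass_is_proportional_to_filtered_fraction(
    mass_mg, susp_ml, filt_ml, expected_g
):
    prep = FilterPrep(mass_mg, susp_ml, filt_ml, 222.0, 1e-4)
    assert tissue_mass_on_filter(prep) == pytest.approx(expected_g)


@pytest.mark.parametrize(
    "filt_ml, expected_load, expected_flag",
    [
        (20.0, 20.0 / 2.22, False),  # ~9 mg/cm²: the routine load
        (0.0, 0.0, False),           # procedural blank
        (40.0, 40.0 / 2.22, True),   # ~18 mg/cm² exceeds the 15 limit
    ],
)
def test_ash_load_and_overload_flag(filt_ml, expected_load, expected_flag):
    prep = FilterPrep(100.0, 100.0, filt_ml, 222.0, 1e-4)
    load = ash_load(prep)
    assert load.load_mg_per_cm2 == pytest.approx(expected_load)
    assert load.exceeds_limit is expected_flag


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(dry_mass_ashed_mg=0),
        dict(suspension_volume_ml=-1),
        dict(filtered_volume_ml=150.0),   # more than the suspension
        dict(active_area_mm2=0),
        dict(field_area_mm2=300.0),       # field larger than the filter
    ],
)
def test_invalid_preparations_are_rejected(kwargs):
    base = dict(
        dry_mass_ashed_mg=100.0, suspension_volume_ml=100.0,
        filtered_volume_ml=20.0, active_area_mm2=222.0, field_area_mm2=1e-4,
    )
    with pytest.raises(InvalidPreparationError):
        FilterPrep(**{**base, **kwargs})


# ---------------------------------------------------------- counting rules

def test_counting_rules_enumerated_cases():
    assert apply_counting_rules([]) == 0
    mixed = [
        _fiber(0.8, MineralClass.CHRYSOTILE),
        _fiber(3.0, MineralClass.AMOSITE),
        _fiber(5.0, MineralClass.NON_ASBESTOS),
    ]
    assert apply_counting_rules(mixed) == 1
    assert apply_counting_rules([_fiber(2.0)] * 50) == 50


def test_exactly_one_micron_is_not_counted():
    assert apply_counting_rules([_fiber(1.0)]) == 0
    assert apply_counting_rules([_fiber(1.0 + 1e-9)]) == 1


_fiber_strategy = st.builds(
    _fiber,
    length=st.floats(0.3, 30.0, allow_nan=False),
    mineral=st.sampled_from(list(MineralClass)),
)


@given(st.lists(_fiber_strategy, max_size=40), st.randoms())
@settings(max_examples=200, deadline=None)
def test_counting_rules_match_brute_force_and_ignore_order(fibers, rnd):
    brute = len(
        [
            f
            for f in fibers
            if f.mineral_class is not MineralClass.NON_ASBESTOS
            and f.length_um > 1.0
        ]
    )
    assert apply_counting_rules(fibers) == brute
    shuffled = list(fibers)
    rnd.shuffle(shuffled)
    assert apply_counting_rules(shuffled) == brute


def test_fiber_record_rejects_impossible_geometry():
    with pytest.raises(InvalidInputError):
        FiberRecord(0, 1.0, 2.0, MineralClass.AMOSITE)  # wider than long
    with pytest.raises(InvalidInputError):
        FiberRecord(-1, 2.0, 0.2, MineralClass.AMOSITE)


def test_session_rejects_fiber_outside_examined_fields():
    with pytest.raises(InvalidInputError):
        CountingSession(n_fields_examined=5, fibers=(_fiber(2.0, field=5),))


# ------------------------------------------------- concentration formula

def test_concentration_hand_example(reference_prep):
    # 9 fibers, 100 fields: C = 9*222/(100*1e-4*0.02) = 9.99e6 ff/g
    result = compute_concentration(_session(9, 100), reference_prep)
    assert result.concentration == pytest.approx(9.99e6)
    assert result.n_counted == 9


def test_concentration_equals_count_times_sensitivity(reference_prep):
    for n_f, n_fields in [(1, 50), (7, 123), (50, 1110)]:
        result = compute_concentration(_session(n_f, n_fields), reference_prep)
        sens = analytical_sensitivity(reference_prep, n_fields)
        assert result.concentration == n_f * sens
        assert result.analytical_sensitivity == sens


def test_single_fiber_gives_the_analytical_sensitivity(reference_prep):
    result = compute_concentration(_session(1, 200), reference_prep)
    assert result.concentration == result.analytical_sensitivity


def test_poisson_cv_at_fifty_fibers(reference_prep):
    result = compute_concentration(_session(50, 300), reference_prep)
    assert result.poisson_cv_percent == pytest.approx(100 / math.sqrt(50))
    assert round(result.poisson_cv_percent) == 14
    assert result.poisson_sd == pytest.approx(
        result.concentration / math.sqrt(50)
    )


def test_zero_count_reports_zero_with_upper_limit(reference_prep):
    session = CountingSession(n_fields_examined=500)
    result = compute_concentration(session, reference_prep)
    assert result.concentration == 0.0
    assert result.poisson_sd == 0.0
    assert result.below_sensitivity
    assert result.ci_low == 0.0
    # one-sided 95% exact upper bound for zero counts is -ln(0.05) ~ 3.0
    assert result.ci_high == pytest.approx(
        3.0 * result.analytical_sensitivity, rel=0.01
    )


def test_ci_brackets_the_estimate(reference_prep):
    for n_f in (1, 5, 50):
        r = compute_concentration(_session(n_f, 100), reference_prep)
        assert r.ci_low <= r.concentration <= r.ci_high


def test_normal_interval_option(reference_prep):
    r = compute_concentration(
        _session(50, 100), reference_prep, interval_method="normal"
    )
    z = stats.norm.ppf(0.975)
    sens = r.analytical_sensitivity
    assert r.ci_low == pytest.approx((50 - z * math.sqrt(50)) * sens)
    assert r.ci_high == pytest.approx((50 + z * math.sqrt(50)) * sens)


def test_blank_prep_cannot_yield_a_concentration():
    blank = FilterPrep(100.0, 100.0, 0.0, 222.0, 1e-4)
    with pytest.raises(InvalidInputError):
        compute_concentration(_session(1, 10), blank)


@given(
    scale=st.floats(0.1, 10.0),
    n_f=st.integers(1, 60),
    n_fields=st.integers(1, 2000),
)
@settings(max_examples=100, deadline=None)
def test_concentration_scaling_homogeneity(scale, n_f, n_fields):
    """C scales like A and like 1/(N_fields * a * p_TS)."""
    base = FilterPrep(100.0, 100.0, 20.0, 222.0, 1e-4)
    session = _session(n_f, n_fields)
    c0 = compute_concentration(session, base).concentration
    bigger_filter = FilterPrep(100.0, 100.0, 20.0, 222.0 * scale, 1e-4)
    assert compute_concentration(session, bigger_filter).concentration == (
        pytest.approx(c0 * scale)
    )
    bigger_field = FilterPrep(100.0, 100.0, 20.0, 222.0, 1e-4 * scale)
    assert compute_concentration(session, bigger_field).concentration == (
        pytest.approx(c0 / scale)
    )
    more_tissue = FilterPrep(100.0 * scale, 100.0, 20.0, 222.0, 1e-4)
    assert compute_concentration(session, more_tissue).concentration == (
        pytest.approx(c0 / scale)
    )


# -------------------------------------------- analytical sensitivity / plan

def test_analytical_sensitivity_hand_value(reference_prep):
    # 222/(1000 * 1e-4 * 0.02) = 1.11e5 ff/g = 0.111 mil ff/g
    assert analytical_sensitivity(reference_prep, 1000) == pytest.approx(1.11e5)


def test_doubling_fields_halves_sensitivity(reference_prep, as_of):
    assert as_of(200) == pytest.approx(as_of(100) / 2)
    assert all(as_of(n + 1) < as_of(n) for n in range(1, 50))


def test_plan_fields_boundary_and_ceiling(reference_prep, as_of):
    assert plan_fields(as_of(100), reference_prep) == 100
    assert plan_fields(as_of(100) * 0.999, reference_prep) == 101


def test_plan_fields_for_recommended_sensitivity(reference_prep):
    # AS <= 0.1 mil ff/g requires 1110 fields with the reference prep
    assert plan_fields(0.1 * MIL, reference_prep) == 1110


def test_plan_fields_matches_smallest_integer_search(reference_prep, as_of):
    rng = np.random.default_rng(2024)
    for _ in range(50):
        target = float(rng.uniform(0.05, 50)) * MIL
        n = plan_fields(target, reference_prep)
        assert as_of(n) <= target
        assert n == 1 or as_of(n - 1) > target


def test_plan_fields_infeasible_target(reference_prep):
    # the filter holds A/a = 2.22e6 fields; ask for far more
    tiny = analytical_sensitivity(reference_prep, 10_000_000)
    with pytest.raises(InfeasiblePlanError):
        plan_fields(tiny, reference_prep)


# ------------------------------------------------------- Poisson interval

def test_poisson_interval_zero_and_containment():
    lo, hi = poisson_interval(0, 0.95)
    assert lo == 0.0 and hi > 0
    lo, hi = poisson_interval(50, 0.95)
    assert lo < 50 < hi


def _grid_invert_poisson(n, level, grid_step=1e-4):
    """Oracle: scan a fine grid of means, keep those whose central
    tail probabilities do not reject the observed count."""
    alpha = 1 - level
    mus = np.arange(grid_step, n * 4 + 20, grid_step)
    upper_tail = stats.poisson.sf(n - 1, mus)  # P(X >= n)
    lower_tail = stats.poisson.cdf(n, mus)     # P(X <= n)
    accepted = mus[(upper_tail >= alpha / 2) & (lower_tail >= alpha / 2)]
    return accepted[0], accepted[-1]


@pytest.mark.parametrize("n", [1, 3, 10, 25])
def test_poisson_interval_matches_cdf_grid_inversion(n):
    lo, hi = poisson_interval(n, 0.95)
    glo, ghi = _grid_invert_poisson(n, 0.95)
    assert lo == pytest.approx(glo, abs=1e-3)
    assert hi == pytest.approx(ghi, abs=1e-3)


def test_poisson_interval_coverage_is_conservative():
    """Exact intervals cover the true mean with probability >= the
    nominal level; checked analytically over the count distribution."""
    for mean in (0.5, 3.0, 12.0, 44.0):
        nmax = int(mean + 12 * math.sqrt(mean) + 30)
        cov = sum(
            stats.poisson.pmf(n, mean)
            for n in range(nmax)
            if poisson_interval(n, 0.95)[0] <= mean <= poisson_interval(n, 0.95)[1]
        )
        assert cov >= 0.95


def test_poisson_interval_rejects_bad_level():
    with pytest.raises(InvalidInputError):
        poisson_interval(5, 1.5)
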