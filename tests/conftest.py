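import pytest

from fiberburden import FilterPrep, analytical_sensitivity


@pytest.fixture
def reference_prep() -> FilterPrep:
    """The laboratory's standard preparation: 100 mg dry tissue ashed,
    suspended in 100 mL, 20 mL filtered onto a 222 mm² membrane,
    0.0001 mm² field at x12,000."""
    return FilterPrep(
        dry_mass_ashed_mg=100.0,
        suspension_volume_ml=100.0,
        filtered_volume_ml=20.0,
        active_area_mm2=222.0,
        field_area_mm2=1.0e-4,
        magnification=12000,
    )


@pytest.fixture
def as_of(reference_prep):
    """Analytical sensitivity of the reference prep at a given field count."""
    return lambda n: analytical_sensitivity(reference_prep, n)
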