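import numpy as np
import pytest

from helmept.phantom import (
    CompartmentSpec,
    FieldModel,
    PhantomGeometry,
    apply_contrast,
    make_field,
    make_label_volume,
)


@pytest.fixture(scope="session")
def two_ring():
    """Small two-ring cylinder with analytic fields: (labels, compartments, model, signal)."""
    geometry = PhantomGeometry(
        shape=(24, 24, 24),
        spacing=(2.0, 2.0, 2.0),
        outer_diameter_mm=40.0,
        ring_widths_mm=(10.0, 10.0),
        height_mm=40.0,
    )
    compartments = [
        CompartmentSpec(label=1, sigma=0.2, eps_r=50.0, i0=1.0, fvf=0.1),
        CompartmentSpec(label=2, sigma=0.7, eps_r=50.0, i0=0.8, fvf=0.4),
    ]
    model = FieldModel()
    labels = make_label_volume(geometry, compartments)
    field = make_field(labels, compartments, model)
    signal = apply_contrast(field, labels, compartments)
    return labels, compartments, model, signal


@pytest.fixture(scope="session")
def noiseless_study():
    """Noiseless five-ring reconstruction shared by acceptance and unit tests."""
    from helmept.experiments import noiseless_accuracy_study

    return noiseless_accuracy_study()
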