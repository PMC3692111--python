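import numpy as np
import pytest

from memoir.fixtures import BundleSpec, make_helical_bundle
from memoir.io_formats import SequenceRecord
from memoir.membrane_annotate import annotate_template


@pytest.fixture(scope="session")
def bundle():
    """Default 4-helix bundle fixture with its construction slab."""
    structure, slab = make_helical_bundle(BundleSpec())
    return structure, slab


@pytest.fixture(scope="session")
def annotated_bundle(bundle):
    """Bundle annotated with its known construction slab (no grid search)."""
    structure, slab = bundle
    return annotate_template(structure, slab=slab)


@pytest.fixture(scope="session")
def fitted_bundle(bundle):
    """Bundle annotated with a fitted slab (exercises the grid search once)."""
    structure, _ = bundle
    return annotate_template(structure)


@pytest.fixture(scope="session")
def bundle_target(bundle):
    structure, _ = bundle
    return SequenceRecord("target", structure.sequence())
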