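import pytest

from dsdesign import fixtures
from dsdesign.counter import criteria_cases, quadrastable_instance
from dsdesign.predict import intersecting_cases


@pytest.fixture(scope="session")
def simple_ds():
    return fixtures.SIMPLE_CIRCUIT.design_space()


@pytest.fixture(scope="session")
def simple_pvals():
    return dict(fixtures.SIMPLE_CIRCUIT.default_parameters)


@pytest.fixture(scope="session")
def memory_ds():
    return fixtures.MEMORY_CIRCUIT.design_space()


@pytest.fixture(scope="session")
def memory_valid(memory_ds):
    return memory_ds.valid_cases()


@pytest.fixture(scope="session")
def memory_criteria(memory_ds):
    """Stable cases with X1 and X2 uncoupled from the repressor X3."""
    return criteria_cases(memory_ds)


@pytest.fixture(scope="session")
def memory_ensembles(memory_ds, memory_criteria):
    """All valid stable intersections of 2..21 criteria cases."""
    return intersecting_cases(memory_ds, range(2, 22), memory_criteria)


@pytest.fixture(scope="session")
def quadrastable_sets(memory_ensembles):
    return [tuple(e.case_numbers) for e in memory_ensembles if len(e.cases) == 4]


@pytest.fixture(scope="session")
def quadrastable_instance_point(memory_ds, quadrastable_sets):
    """(pvals, attractors-by-quadrant, members) for one predicted
    one-attractor-per-quadrant instance."""
    return quadrastable_instance(memory_ds, quadrastable_sets[0])
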