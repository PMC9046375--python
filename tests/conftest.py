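import numpy as np
import pytest

from richroster import FixtureSpec, render_roster, roster_ids
from richroster.survey import layout_panels, seeded_order


@pytest.fixture(scope="session")
def fixture_spec():
    return FixtureSpec()


@pytest.fixture(scope="session")
def roster(fixture_spec):
    return roster_ids(fixture_spec.n_recipients)


@pytest.fixture(scope="session")
def layout(fixture_spec, roster):
    return layout_panels(
        seeded_order(roster, fixture_spec.seed),
        fixture_spec.n_panels,
        fixture_spec.n_rows,
        fixture_spec.n_cols,
    )


@pytest.fixture(scope="session")
def portraits(fixture_spec):
    return render_roster(fixture_spec)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
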