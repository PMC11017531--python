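import pytest
from hypothesis import HealthCheck, settings
from hypothesis import strategies as st

from prevcal import ConfusionMatrix, PerformanceProfile

settings.register_profile(
    "prevcal",
    derandomize=True,
    max_examples=150,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("prevcal")


# unit-interval floats without NaN/inf/negative-zero surprises
unit_floats = st.floats(
    min_value=0.0, max_value=1.0, allow_nan=False, allow_infinity=False
)
interior_floats = st.floats(
    min_value=1e-6, max_value=1.0 - 1e-6, allow_nan=False, allow_infinity=False
)


@st.composite
def profiles(draw, interior_prevalence: bool = True, interior_senspe: bool = False):
    """Random (Sen, Spe, Pre, N) profiles with integer N."""
    sen_spe = interior_floats if interior_senspe else unit_floats
    sen = draw(sen_spe)
    spe = draw(sen_spe)
    pre = draw(interior_floats if interior_prevalence else unit_floats)
    n = draw(st.integers(min_value=10, max_value=10**6))
    return PerformanceProfile(sen, spe, pre, n)


@st.composite
def integer_matrices(draw, min_total: int = 1):
    """Random integer confusion matrices with at least min_total instances."""
    cells = [draw(st.integers(min_value=0, max_value=5000)) for _ in range(4)]
    if sum(cells) < min_total:
        cells[draw(st.integers(min_value=0, max_value=3))] += min_total
    return ConfusionMatrix(*cells, strict_integer=True)


@pytest.fixture
def ad_full():
    """Fig-11-style full test set: sen 0.680, spe 0.850, pre 0.600, N 2000."""
    return ConfusionMatrix(816, 384, 120, 680)


@pytest.fixture
def ad_in_domain():
    """Fig-11-style in-domain set: sen 0.710, spe 0.890, pre 0.900, N 1000."""
    return ConfusionMatrix(639, 261, 11, 89)
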