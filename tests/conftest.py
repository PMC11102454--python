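import numpy as np
import pytest

from nanopbpk import PBPKParameters, PhysiologyTable
from nanopbpk.parameters import OrganParameters


@pytest.fixture(scope="session")
def phys() -> PhysiologyTable:
    return PhysiologyTable.default()


@pytest.fixture(scope="session")
def ref_params() -> PBPKParameters:
    return PBPKParameters.reference()


@pytest.fixture(scope="session")
def unit_phys() -> PhysiologyTable:
    """Minimal symmetric physiology: 7 systemic organs with Q = 1 mL/h and
    unit volumes everywhere, for hand-evaluated algebra."""
    organs = ("lung", "liver", "spleen", "kidney", "heart", "bone", "brain", "other")
    return PhysiologyTable(
        organs=organs,
        Q={o: (7.0 if o == "lung" else 1.0) for o in organs},
        V_vasc={o: 1.0 for o in organs},
        V_extra={o: 1.0 for o in organs},
        V_art=1.0,
        V_ven=1.0,
        cardiac_output=7.0,
    )


@pytest.fixture(scope="session")
def inert_params(unit_phys) -> PBPKParameters:
    """All transport and uptake switched off (closed circulatory loop)."""
    return PBPKParameters({o: OrganParameters(PA=0.0, P=1.0) for o in unit_phys.organs})


def random_parameter_sets(n: int, seed: int) -> list[PBPKParameters]:
    """Seeded random-but-physiological parameter sets for property tests."""
    rng = np.random.default_rng(seed)
    base = PBPKParameters.reference()
    sets = []
    for _ in range(n):
        values = {}
        for name in base.flat_names():
            v = base.get_value(name)
            if v > 0 and not name.endswith(".n_H"):
                values[name] = v * rng.lognormal(0.0, 0.5)
        sets.append(base.with_values(values))
    return sets
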