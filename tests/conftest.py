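import math

import numpy as np
import pytest

from picocell.annotation import load_metabolite_db
from picocell.morphometrics import densify_polygon


@pytest.fixture(scope="session")
def db():
    """The bundled metabolite/lipid reference table."""
    return load_metabolite_db()


@pytest.fixture(scope="session")
def db_by_name(db):
    return {record.name: record for record in db}


def rhombus(a: float, b: float, step: float = 0.05) -> np.ndarray:
    """Densified rhombus with half-diagonals a (x) and b (y)."""
    return densify_polygon([(a, 0), (0, b), (-a, 0), (0, -b)], step)


def kite(tip1_deg: float, tip2_deg: float, length: float = 10.0,
         step: float = 0.1) -> np.ndarray:
    """Densified kite whose two axis tips open at the given full angles."""
    t1 = math.radians(tip1_deg / 2)
    t2 = math.radians(tip2_deg / 2)
    x = length * math.tan(t2) / (math.tan(t1) + math.tan(t2))
    y = x * math.tan(t1)
    return densify_polygon([(0, 0), (x, y), (length, 0), (x, -y)], step)
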