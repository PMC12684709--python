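import numpy as np
import pytest

from intermaps import (GeometryConfig, classify_interface, parse_structure,
                       select_partners)
from intermaps.fixtures import MotifSpec, make_mini_complex, make_motif


@pytest.fixture(scope="session")
def default_config():
    return GeometryConfig()


@pytest.fixture
def classify_motif():
    """Build a motif, parse it and run the full classifier."""

    def _run(klass, seed=0, distance=None, config=None, sasa=False):
        pdb_text, gt = make_motif(MotifSpec(klass, distance=distance), seed)
        st = parse_structure(pdb_text)
        sel = select_partners(st, "A", "B")
        report = classify_interface(st, sel, config, compute_sasa=sasa)
        return report, gt, st

    return _run


@pytest.fixture(scope="session")
def mini_complex_16():
    pdb_text, gt = make_mini_complex(16, seed=11)
    st = parse_structure(pdb_text)
    sel = select_partners(st, "A", "B")
    report = classify_interface(st, sel, compute_sasa=False)
    return report, gt, st


def random_rotation(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)]])
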