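"""Shared fixtures: expensive simulations are run once per session."""
import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

_cache: dict = {}


def _memo(key, fn):
    if key not in _cache:
        _cache[key] = fn()
    return _cache[key]


@pytest.fixture(scope="session")
def paced_trace():
    """Factory: steady-pacing trace (100 beats), memoised per condition."""
    from lqt8sim import cell_protocols as cp

    def get(cell_class, variant, pcl=1000.0, record_last=8):
        return _memo(("pace", cell_class, variant, pcl, record_last),
                     lambda: cp.pace(cell_class, variant, pcl, 100,
                                     record_last=record_last))
    return get


@pytest.fixture(scope="session")
def endo_apd(paced_trace):
    """Factory: final-beat APD90 of an ENDO cell at PCL 1,000 ms."""
    from lqt8sim import cell_protocols as cp

    def get(variant):
        return _memo(("apd", variant),
                     lambda: cp.apd90(paced_trace("ENDO", variant)))
    return get


@pytest.fixture(scope="session")
def transmural_run():
    """Factory: 10-beat transmural-cable run at PCL 1,000 ms."""
    from lqt8sim import monodomain_tissue as mt

    def get(variant):
        return _memo(("cable", variant),
                     lambda: mt.run_s1_train(variant, 1000.0, n_beats=10,
                                             tail_ms=600.0, rec_dt=0.5))
    return get


@pytest.fixture(scope="session")
def homogeneous_cv():
    """Factory: conduction velocity on the homogeneous MCELL cable."""
    from lqt8sim import monodomain_tissue as mt

    def get(variant, d_coeff=None, dx=None):
        def run():
            geo = mt.build_homogeneous_cable(
                "MCELL", n=int(round(24.75 / (dx or 0.15))), dx=dx or 0.15)
            params = mt.TissueParams(d_coeff or 0.0385, dx or 0.15)
            st = mt.run_s1_train(variant, 1000.0, n_beats=2, geometry=geo,
                                 params=params, tail_ms=600.0)
            return mt.measure_cv(st)
        return _memo(("cv", variant, d_coeff, dx), run)
    return get


@pytest.fixture(scope="session")
def afterdep_grid(paced_trace):
    """Afterdepolarization events per (variant, class) at PCL 500 ms."""
    from lqt8sim import cell_protocols as cp
    from lqt8sim.constants import CELL_CLASSES, VARIANT_ORDER

    def build():
        return {(var, cls): cp.detect_afterdepolarizations(
                    paced_trace(cls, var, 500.0))
                for var in VARIANT_ORDER for cls in CELL_CLASSES}
    return _memo(("adgrid",), build)


@pytest.fixture(scope="session")
def fold_ratios():
    """Simulated peak-density fold ratios for the shipped variant table."""
    from lqt8sim import ical_variants as iv
    return _memo(("folds",), iv.peak_density_folds)


@pytest.fixture(scope="session")
def mpcl_values():
    """MPCL scan results for WT and R858H (minutes; shared)."""
    from lqt8sim import monodomain_tissue as mt

    def build():
        return {var: mt.find_mpcl(var) for var in ("R858H", "WT")}
    return _memo(("mpcl",), build)
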