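import numpy as np
import pytest

from cardiotwin import phantom as ph
from cardiotwin import surface as sf
from cardiotwin import uvc as uv
from cardiotwin import volmesh as vm


@pytest.fixture(scope="session")
def template():
    return sf.build_template()


@pytest.fixture(scope="session")
def phantom_study():
    """Default-geometry phantom, short cycle to keep rasterization cheap."""
    params = ph.PhantomParams(n_frames=8, es_frame=3)
    return ph.make_phantom(params, participant_id="fixture")


@pytest.fixture(scope="session")
def lv_fiber_run():
    """Idealized LV wall mesh with coordinates and default-law fibers."""
    mesh = vm.idealized_lv_mesh()
    coords = uv.compute_uvc(mesh)
    fibers = uv.compute_fibers(mesh, coords)
    return mesh, coords, fibers


@pytest.fixture(scope="session")
def fitted_phantom():
    """One seeded phantom fitted at ED and ES (shared by slow tests)."""
    from cardiotwin import contours as ct
    from cardiotwin import core_io as cio
    from cardiotwin import frames as fr

    rng = np.random.default_rng(11)
    st = ph.make_phantom(ph.random_phantom_params(rng, n_frames=8),
                         participant_id="fitted")
    tmpl = sf.build_template()
    out = {}
    es = fr.pick_es(st.bundle)
    for tag, frame in (("ed", 0), ("es", es)):
        contours, lms = [], {}
        for view in cio.CineView:
            cs, lm, _ = ct.extract_view(st.bundle.get(view), frame)
            contours.extend(cs)
            lms[view] = lm
        res = sf.fit_surface_multiscale(tmpl, contours, lms)
        out[tag] = sf.generate_rv_epicardium(res.mesh)
    return st, out["ed"], out["es"], es
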