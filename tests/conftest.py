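import numpy as np
import pytest

import visacuity as va


@pytest.fixture(scope="session")
def fixture_spec() -> va.RetinaSpec:
    """The package's default ground-truth retina (~30 mm^2, ~213k cells)."""
    return va.default_retina_spec()


@pytest.fixture(scope="session")
def fixture_retina(fixture_spec) -> va.SyntheticRetina:
    """One realised draw of the default retina, shared across tests."""
    return va.make_retina_truth(fixture_spec, seed=1)


@pytest.fixture(scope="session")
def fixture_fractionator(fixture_retina, fixture_spec):
    """A standard ~200-site fractionator run on the shared retina."""
    design = va.design_sampling(fixture_spec.polygon, (60.0, 60.0), 200, seed=2)
    sites, est = va.run_fractionator(fixture_retina.cells, fixture_spec.polygon, design)
    return design, sites, est


@pytest.fixture(scope="session")
def mini_spec() -> va.RetinaSpec:
    """A small homogeneous-plus-one-area retina for cheap Monte-Carlo tests."""
    return va.RetinaSpec(
        outline=va.ellipse_outline(1.2, 1.0, n=64),
        baseline_density=2_000.0,
        areas=(
            va.GaussianArea(center=(0.3, 0.0), axes=(0.3, 0.2), orientation_deg=0.0, amplitude=5_000.0),
        ),
    )


def integrate_density(spec: va.RetinaSpec, resolution: float = 0.01) -> float:
    """Independent numerical integral of a spec's intensity field (cells)."""
    import shapely

    poly = spec.polygon
    minx, miny, maxx, maxy = poly.bounds
    xs = np.arange(minx + resolution / 2, maxx, resolution)
    ys = np.arange(miny + resolution / 2, maxy, resolution)
    xx, yy = np.meshgrid(xs, ys)
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    inside = shapely.contains_xy(poly, pts[:, 0], pts[:, 1])
    return float(spec.density(pts[inside]).sum() * resolution**2)
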