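"""Shared fixtures: phantoms and light registration settings.

Heavy objects are session-scoped so each phantom or population is built
once per run.
"""

import logging

import numpy as np
import pytest

from neotemplate.phantom import (PhantomSpec, generate_head_phantom,
                                 generate_population)
from neotemplate.preprocess import clean_background, extract_head_mask
from neotemplate.registration import AffineParams, SynParams

logging.getLogger("neotemplate").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def phantom64():
    """Default 64³ / 2 mm head phantom with two fontanel gaps (seed 1)."""
    return generate_head_phantom(PhantomSpec(seed=1))


@pytest.fixture(scope="session")
def phantom64_nogaps():
    return generate_head_phantom(PhantomSpec(seed=1, fontanel_gaps=()))


@pytest.fixture(scope="session")
def small_spec():
    """48³ / 2.5 mm spec used for registration and template tests."""
    return PhantomSpec(grid_shape=(48, 48, 48), spacing=(2.5, 2.5, 2.5),
                       head_radii=(40.0, 48.0, 44.0), nuisance_blobs=0,
                       seed=7)


@pytest.fixture(scope="session")
def phantom48(small_spec):
    return generate_head_phantom(small_spec)


@pytest.fixture(scope="session")
def clean_ct48(phantom48):
    return clean_background(phantom48.ct, phantom48.masks["head"])


@pytest.fixture(scope="session")
def population5(small_spec):
    """Five cleaned subjects perturbed around the 48³ mean anatomy."""
    pop = generate_population(small_spec, 5, rigid_sd=(2.0, 3.0),
                              warp_sd=2.0, seed=13)
    cleaned = [clean_background(s.ct, extract_head_mask(s.ct)) for s in pop]
    return pop, cleaned


@pytest.fixture(scope="session")
def warp_case():
    """Phantom at 1.25 mm spacing warped by a known smooth field whose mean
    in-head displacement exceeds 3 voxels (max < 6 mm)."""
    from neotemplate.phantom import _world_coords
    from neotemplate.transforms import (DiffeoTransform, apply_transform,
                                        invert_displacement_field)
    from neotemplate.volume import Volume

    spec = PhantomSpec(grid_shape=(56, 56, 56), spacing=(1.25, 1.25, 1.25),
                       head_radii=(26.0, 30.0, 28.0), skull_thickness=3.0,
                       scalp_thickness=3.0, csf_thickness=3.0,
                       gm_thickness=5.0, nuisance_blobs=0, seed=4)
    ps = generate_head_phantom(spec)
    grid = Volume(np.zeros(ps.ct.shape), ps.ct.spacing, ps.ct.origin)
    xyz = _world_coords(grid)
    ext = 70.0
    w = np.stack([3.0 + 1.5 * np.sin(2 * np.pi * xyz[2] / (2 * ext)),
                  -2.5 + 1.2 * np.cos(2 * np.pi * xyz[0] / (2 * ext)),
                  2.0 + 1.0 * np.sin(2 * np.pi * xyz[1] / (2 * ext))], -1)
    winv = invert_displacement_field(w, grid)
    warped = apply_transform(ps.ct, DiffeoTransform(w, winv, grid),
                             fill=-1000.0)
    mask = ps.masks["head"].as_bool()
    pts = grid.index_to_world(np.argwhere(mask)[::80].astype(float))
    targets = DiffeoTransform(winv, w, grid).map_points(pts)
    return ps, grid, warped, pts, targets


@pytest.fixture(scope="session")
def warp_recovery(warp_case):
    """Affine + diffeomorphic recovery of the known warp."""
    from neotemplate.registration import affine_register, syn_register
    from neotemplate.transforms import apply_transform

    ps, grid, warped, pts, targets = warp_case
    aff = affine_register(
        warped, ps.ct, metric="CC",
        params=AffineParams(levels=(4, 2), smooth_vox=(2.0, 1.0),
                            max_iter=(60, 40)))
    aligned = apply_transform(warped, aff, reference=ps.ct, fill=-1000.0)
    dif = syn_register(aligned, ps.ct, metric="CC")
    return aff, aligned, dif


@pytest.fixture(scope="session")
def light_affine():
    return AffineParams(levels=(4, 2), smooth_vox=(2.0, 1.0),
                        max_iter=(60, 40))


@pytest.fixture(scope="session")
def light_syn():
    return SynParams(levels=(4, 2), smooth_vox=(2.0, 1.0),
                     iterations=(40, 25))
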