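"""Shared fixtures: small slab geometries and cached forward solutions."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from nirdot.forward import compute_jacobian, sensitivity_mask
from nirdot.headmodel import build_layered_head
from nirdot.pipeline import (
    PipelineConfig,
    build_task_design,
    default_activation_center,
)
from nirdot.probe import ProbeLayout, default_prefrontal_layout, fit_layout_to_head

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def homog_slab():
    """Homogeneous slab (mu_a=0.01, mu_s'=1.0 everywhere) for analytic oracles."""
    head = build_layered_head(
        grid_shape=(55, 35, 30), voxel_size=2.0,
        layer_thicknesses=(0.0, 0.0, 0.0, None), geometry="slab",
    )
    for w in (690.0, 830.0):
        head.mu_a[(4, w)] = 0.01
        head.mu_s_prime[(4, w)] = 1.0
    return head


@pytest.fixture(scope="session")
def layered_slab():
    """Layered slab (scalp 6 / CSF 2 / gray 6 / white) for Jacobian tests."""
    return build_layered_head(
        grid_shape=(30, 30, 15), voxel_size=2.0,
        layer_thicknesses=(6.0, 2.0, 6.0, None), geometry="slab",
    )


@pytest.fixture(scope="session")
def slab_layout():
    """One source, a 14 mm and a 30 mm detector on the layered slab surface."""
    return ProbeLayout(
        [[16.0, 30.0, 30.0]],
        [[30.0, 30.0, 30.0], [46.0, 30.0, 30.0]],
        {},
        [(0, 0), (0, 1)],
    )


@pytest.fixture(scope="session")
def slab_jacobian(layered_slab, slab_layout):
    return compute_jacobian(layered_slab, slab_layout)


@pytest.fixture(scope="session")
def hemi_setup():
    """Default end-to-end geometry: 4 mm hemisphere, prefrontal array,
    Jacobian, sensitivity mask, SWG design, central gray activation site."""
    cfg = PipelineConfig()
    head = build_layered_head(
        cfg.grid_shape, cfg.voxel_size, cfg.layer_thicknesses,
        geometry=cfg.geometry, dome_radius=cfg.dome_radius,
    )
    layout = fit_layout_to_head(default_prefrontal_layout(cfg.sd_range), head)
    jac = compute_jacobian(head, layout)
    return {
        "cfg": cfg,
        "head": head,
        "layout": layout,
        "jacobian": jac,
        "mask": sensitivity_mask(jac, cfg.attenuation_factor),
        "design": build_task_design(cfg),
        "center": np.asarray(default_activation_center(head)),
    }
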