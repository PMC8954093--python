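"""Shared synthetic inputs, generated once per session."""

from __future__ import annotations

import pytest

from dicomizer import fixtures as fx


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    return tmp_path_factory.mktemp("inputs")


@pytest.fixture(scope="session")
def clsm_small(fixture_dir):
    """2-channel, 3-plane, 12-bit confocal-like stack."""
    return fx.make_clsm_volume(
        fixture_dir / "clsm_small.ome.tif", channels=2, z_planes=3, xy=32, bit_depth=12, seed=11
    )


@pytest.fixture(scope="session")
def em_mrc_small(fixture_dir):
    """7-section 8-bit MRC stack."""
    return fx.make_em_stack(fixture_dir / "em_small.mrc", n_slices=7, xy=16, container="mrc", seed=12)


@pytest.fixture(scope="session")
def em_tiff_small(fixture_dir):
    return fx.make_em_stack(fixture_dir / "em_small.tif", n_slices=4, xy=16, container="tiff", seed=13)


@pytest.fixture(scope="session")
def wsi_small(fixture_dir):
    """3-level 2×-spaced pyramid with 2 focal planes."""
    return fx.make_wsi_pyramid(
        fixture_dir / "wsi_small.ome.tif", n_levels=3, level_ratio=2,
        base_wh=(1024, 640), z_planes=2, seed=14,
    )


@pytest.fixture(scope="session")
def unrecognized_wsi(fixture_dir):
    """Single-level tiled RGB TIFF without OME metadata or reduced pages."""
    return fx.make_unrecognized_wsi(fixture_dir / "flat.tif", base_wh=(1400, 1100), seed=15)
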