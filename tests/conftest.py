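"""Shared phantom fixtures (generated once per session, never stored on disk)."""

import numpy as np
import pytest

from cryptobud import (
    CryptSpec,
    NoiseSpec,
    build_compartment_masks,
    generate_crypt_volume,
)


def _phantom(patterning: str, noise: NoiseSpec, seed: int):
    spec = CryptSpec(
        length=150.0,
        basal_width=40.0,
        wall_thickness=16.0,
        patterning=patterning,
        noise=noise,
        voxel_size=1.0,
    )
    volume, truth = generate_crypt_volume(spec, seed=seed)
    masks = build_compartment_masks(
        volume.channel("dapi"),
        volume.channel("bcat"),
        volume.channel("ecad"),
        voxel_size=spec.voxel_size,
    )
    return spec, volume, truth, masks


@pytest.fixture(scope="session")
def he_noiseless():
    return _phantom("HE", NoiseSpec(0.0, 0.0), seed=101)


@pytest.fixture(scope="session")
def ho_noiseless():
    return _phantom("HO", NoiseSpec(0.0, 0.0), seed=102)


@pytest.fixture(scope="session")
def he_noisy():
    return _phantom("HE", NoiseSpec(), seed=103)


@pytest.fixture(scope="session")
def ho_noisy():
    return _phantom("HO", NoiseSpec(), seed=104)
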