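"""Compartment mask algebra, axial regions and intensity quantitation."""

import numpy as np
import pandas as pd
import pytest

from cryptobud import (
    CompartmentMasks,
    axial_regions,
    build_compartment_masks,
    cytosol_mask,
    integrated_intensity,
    intensity_projection,
    membrane_mask,
    nuclear_mask,
    region_profile,
    subtract_nuclear_background,
    whole_cell_mask,
)
from cryptobud.compartmental import CongruenceError, axial_coordinates
from cryptobud.synthetic import LABEL_MEMBRANE, LABEL_NUCLEUS


# ---------------------------------------------------------------------------
# nuclear mask
# ---------------------------------------------------------------------------

def test_nuclear_mask_counts_nuclei(ho_noiseless):
    """Connected components of the segmented nuclei equal the true count."""
    from scipy import ndimage

    spec, volume, truth, masks = ho_noiseless
    n_found = ndimage.label(masks.nucleus)[1]
    assert n_found == truth.nucleus_count


def test_nuclear_mask_empty_channel_warns():
    with pytest.warns(UserWarning, match="empty"):
        mask = nuclear_mask(np.zeros((10, 10, 10)))
    assert not mask.any()


def test_nuclear_mask_recovery_at_default_noise(he_noisy):
    """>= 95% of true nuclear voxels are recovered at default noise."""
    _, _, truth, masks = he_noisy
    true_nuc = truth.labels == LABEL_NUCLEUS
    recovered = (masks.nucleus & true_nuc).sum() / true_nuc.sum()
    assert recovered >= 0.95


# ---------------------------------------------------------------------------
# membrane / whole-cell / cytosol algebra
# ---------------------------------------------------------------------------

def test_membrane_or_and_not_semantics():
    # 12 voxels bright only in bcat, 12 only in ecad, 2 inside the nucleus
    bcat = np.zeros((4, 6, 6))
    ecad = np.zeros((4, 6, 6))
    nuclear = np.zeros((4, 6, 6), bool)
    bcat[1, 1:4, 1:5] = 200.0
    ecad[2, 1:4, 1:5] = 200.0
    nuclear[1, 1, 1] = True
    mask = membrane_mask(bcat, ecad, nuclear, smoothing_sigma=0.0)
    assert mask[1, 2, 2] and mask[2, 2, 2]       # OR captures either channel
    assert not mask[1, 1, 1]                     # NOT removes nuclear voxels


def test_membrane_mask_congruence_error():
    with pytest.raises(CongruenceError):
        membrane_mask(np.zeros((3, 4, 4)), np.zeros((3, 5, 4)),
                      np.zeros((3, 4, 4), bool))


def test_membrane_recovery_on_phantom(he_noisy):
    """Jaccard overlap with the true membrane >= 0.8 at default noise."""
    _, _, truth, masks = he_noisy
    true_mem = truth.labels == LABEL_MEMBRANE
    jaccard = (masks.membrane & true_mem).sum() / (masks.membrane | true_mem).sum()
    assert jaccard >= 0.8


def test_whole_cell_fills_shell():
    # hollow E-cadherin shell around a nucleus -> solid filled body
    ecad = np.zeros((9, 9, 9))
    ecad[1:8, 1:8, 1] = ecad[1:8, 1:8, 7] = 200.0
    ecad[1:8, 1, 1:8] = ecad[1:8, 7, 1:8] = 200.0
    ecad[1, 1:8, 1:8] = ecad[7, 1:8, 1:8] = 200.0
    nuclear = np.zeros((9, 9, 9), bool)
    nuclear[4, 4, 4] = True
    cell = whole_cell_mask(nuclear, ecad, smoothing_sigma=0.0)
    assert cell[4, 4, 2:7].all()           # interior filled
    assert (cell & nuclear).sum() == nuclear.sum()   # superset of nuclei


def test_whole_cell_contains_nuclei(he_noisy):
    _, _, _, masks = he_noisy
    assert not (masks.nucleus & ~masks.whole_cell).any()


def test_whole_cell_volume_close_to_true_epithelium(ho_noiseless):
    _, _, truth, masks = ho_noiseless
    epithelium = (truth.labels >= LABEL_NUCLEUS).sum()
    assert masks.whole_cell.sum() == pytest.approx(epithelium, rel=0.10)


def test_cytosol_set_identities(he_noisy):
    _, _, _, masks = he_noisy
    cyt = cytosol_mask(masks.whole_cell, masks.nucleus, masks.membrane)
    assert not (cyt & masks.nucleus).any()
    assert not (cyt & masks.membrane).any()
    expected = masks.whole_cell.sum() - (
        masks.whole_cell & (masks.nucleus | masks.membrane)
    ).sum()
    assert cyt.sum() == expected


def test_cytosol_empty_when_cell_is_covered():
    cell = np.zeros((3, 3, 3), bool)
    cell[1, 1, :] = True
    nuc = np.zeros_like(cell)
    nuc[1, 1, 0] = True
    mem = np.zeros_like(cell)
    mem[1, 1, 1:] = True
    assert not cytosol_mask(cell, nuc, mem).any()


def test_compartment_partition_on_random_phantoms():
    """Nucleus/membrane/cytosol disjoint and inside the whole cell."""
    from cryptobud import CryptSpec, generate_crypt_volume

    for seed in (1, 2):
        spec = CryptSpec(length=80.0, patterning="HE" if seed == 1 else "HO",
                         voxel_size=1.5)
        volume, _ = generate_crypt_volume(spec, seed=seed)
        masks = build_compartment_masks(
            volume.channel("dapi"), volume.channel("bcat"),
            volume.channel("ecad"), voxel_size=1.5,
        )
        assert not (masks.nucleus & masks.membrane).any()
        assert not (masks.nucleus & masks.cytosol).any()
        assert not (masks.membrane & masks.cytosol).any()
        union = masks.nucleus | masks.membrane | masks.cytosol
        assert not (union & ~masks.whole_cell).any()


def test_mask_algebra_idempotent(he_noisy):
    spec, volume, _, masks = he_noisy
    again = build_compartment_masks(
        volume.channel("dapi"), volume.channel("bcat"), volume.channel("ecad"),
        voxel_size=spec.voxel_size,
    )
    for comp in ("nucleus", "membrane", "cytosol", "whole_cell"):
        assert np.array_equal(masks.compartment(comp), again.compartment(comp))


# ---------------------------------------------------------------------------
# axial regions
# ---------------------------------------------------------------------------

def test_axial_regions_even_division_straight_crypt():
    """Straight 100 um crypt, k=5: boundaries at 20/40/60/80 um."""
    mask = np.zeros((100, 9, 9), bool)
    mask[:, 3:6, 3:6] = True
    axis = np.array([[0, 4.5, 4.5], [100, 4.5, 4.5]], float)
    regions = axial_regions(mask, axis=axis, k=5, voxel_size=1.0)
    # voxel centered at z+0.5 um belongs to bin floor((z+0.5)/20)+1
    for z in range(100):
        expected = min(int((z + 0.5) / 20.0), 4) + 1
        assert (regions[z][mask[z]] == expected).all()
    counts = np.bincount(regions[mask].ravel())[1:]
    assert counts.max() - counts.min() <= 9  # within one slice of voxels


def test_axial_regions_k1_is_whole_crypt():
    mask = np.zeros((20, 5, 5), bool)
    mask[2:18, 1:4, 1:4] = True
    regions = axial_regions(mask, k=1)
    assert set(np.unique(regions[mask])) == {1}
    assert (regions[~mask] == 0).all()


def test_axial_regions_rejects_bad_k():
    mask = np.ones((5, 5, 5), bool)
    with pytest.raises(ValueError):
        axial_regions(mask, k=0)


def test_axial_coordinates_span_mask_extent():
    mask = np.zeros((60, 7, 7), bool)
    mask[5:55, 2:5, 2:5] = True
    arc, total = axial_coordinates(mask)
    assert total == pytest.approx(50.0, abs=2.0)
    assert arc[mask].min() == pytest.approx(0.0, abs=1.0)
    assert arc[mask].max() == pytest.approx(total, abs=1.0)


# ---------------------------------------------------------------------------
# integrated intensity
# ---------------------------------------------------------------------------

def _toy_masks_and_regions():
    shape = (10, 4, 4)
    nuc = np.zeros(shape, bool)
    mem = np.zeros(shape, bool)
    cyt = np.zeros(shape, bool)
    nuc[:, 0, 0] = True
    mem[:, 1, 1] = True
    cyt[:, 2, 2] = True
    cell = nuc | mem | cyt
    masks = CompartmentMasks(nucleus=nuc, membrane=mem, cytosol=cyt, whole_cell=cell)
    regions = np.zeros(shape, np.int32)
    regions[:5][cell[:5]] = 1
    regions[5:][cell[5:]] = 2
    return masks, regions


def test_integrated_intensity_uniform_value():
    masks, regions = _toy_masks_and_regions()
    channel = np.full((10, 4, 4), 7.0)
    prof = integrated_intensity(channel, masks, regions, channel_name="ecad")
    for _, row in prof.iterrows():
        assert row["integrated_intensity"] == pytest.approx(7.0 * row["voxel_count"])


def test_integrated_intensity_equivariant_under_mask_swap():
    masks, regions = _toy_masks_and_regions()
    rng = np.random.default_rng(0)
    channel = rng.uniform(0, 100, size=(10, 4, 4))
    prof = integrated_intensity(channel, masks, regions)
    swapped = CompartmentMasks(nucleus=masks.membrane, membrane=masks.nucleus,
                               cytosol=masks.cytosol, whole_cell=masks.whole_cell)
    prof_swapped = integrated_intensity(channel, swapped, regions)
    a = prof.set_index(["region", "compartment"])["integrated_intensity"]
    b = prof_swapped.set_index(["region", "compartment"])["integrated_intensity"]
    for region in ("region1", "region2"):
        assert a[(region, "nucleus")] == b[(region, "membrane")]
        assert a[(region, "membrane")] == b[(region, "nucleus")]


def test_intensity_conservation(he_noisy):
    """Sum over regions x compartments equals the channel total in the union."""
    spec, volume, _, masks = he_noisy
    regions = axial_regions(masks.whole_cell, voxel_size=spec.voxel_size)
    channel = volume.channel("ecad").astype(float)
    prof = integrated_intensity(channel, masks, regions)
    union = masks.nucleus | masks.membrane | masks.cytosol
    assert prof["integrated_intensity"].sum() == pytest.approx(
        channel[union].sum(), rel=1e-12
    )


def test_integrated_intensity_congruence_error():
    masks, regions = _toy_masks_and_regions()
    with pytest.raises(CongruenceError):
        integrated_intensity(np.zeros((9, 4, 4)), masks, regions)


# ---------------------------------------------------------------------------
# nuclear background subtraction
# ---------------------------------------------------------------------------

def _profile_row(region, comp, channel, total, count):
    return {"region": region, "compartment": comp, "channel": channel,
            "integrated_intensity": total, "voxel_count": count}


def test_background_subtraction_worked_example():
    """Nuclear mean 5 over a 100-voxel membrane at 1000 total -> 500."""
    prof = pd.DataFrame([
        _profile_row("bottom", "nucleus", "ecad", 250.0, 50),
        _profile_row("bottom", "membrane", "ecad", 1000.0, 100),
        _profile_row("bottom", "cytosol", "ecad", 300.0, 80),
    ])
    out = subtract_nuclear_background(prof, channel="ecad")
    mem = out[(out.compartment == "membrane")]["integrated_intensity"].iloc[0]
    cyt = out[(out.compartment == "cytosol")]["integrated_intensity"].iloc[0]
    assert mem == pytest.approx(1000.0 - 5.0 * 100)
    assert cyt == pytest.approx(0.0)       # 300 - 400 clamps at zero


def test_background_subtraction_zero_background_identity():
    prof = pd.DataFrame([
        _profile_row("top2", "nucleus", "ecad", 0.0, 40),
        _profile_row("top2", "membrane", "ecad", 800.0, 90),
        _profile_row("top2", "cytosol", "ecad", 100.0, 60),
    ])
    out = subtract_nuclear_background(prof, channel="ecad")
    pd.testing.assert_frame_equal(out, prof)


def test_background_subtraction_clamp_warns():
    prof = pd.DataFrame([
        _profile_row("bottom", "nucleus", "ecad", 1000.0, 10),
        _profile_row("bottom", "membrane", "ecad", 50.0, 100),
    ])
    with pytest.warns(UserWarning, match="clamped"):
        out = subtract_nuclear_background(prof)
    assert out[out.compartment == "membrane"]["integrated_intensity"].iloc[0] == 0.0


def test_background_subtraction_no_nuclear_voxels_warns():
    prof = pd.DataFrame([
        _profile_row("bottom", "nucleus", "ecad", 0.0, 0),
        _profile_row("bottom", "membrane", "ecad", 50.0, 100),
    ])
    with pytest.warns(UserWarning, match="no nuclear voxels"):
        out = subtract_nuclear_background(prof)
    assert out[out.compartment == "membrane"]["integrated_intensity"].iloc[0] == 50.0


# ---------------------------------------------------------------------------
# intensity projection
# ---------------------------------------------------------------------------

def test_projection_constant_full_depth():
    mask = np.ones((6, 3, 3), bool)
    proj = intensity_projection(np.full((6, 3, 3), 9.0), mask)
    assert np.allclose(proj, 9.0)


def test_projection_empty_columns_are_zero():
    mask = np.zeros((6, 3, 3), bool)
    mask[:, 0, 0] = True
    proj = intensity_projection(np.full((6, 3, 3), 4.0), mask)
    assert proj[0, 0] == pytest.approx(4.0)
    assert proj[1, 1] == 0.0


def test_projection_single_voxel_depth():
    mask = np.zeros((6, 2, 2), bool)
    mask[3, 1, 0] = True
    channel = np.arange(24, dtype=float).reshape(6, 2, 2)
    proj = intensity_projection(channel, mask)
    assert proj[1, 0] == pytest.approx(channel[3, 1, 0])


# ---------------------------------------------------------------------------
# axial staining trends (noiseless HE phantom)
# ---------------------------------------------------------------------------

def test_he_phantom_recovers_axial_signatures(he_noiseless):
    """Basal nuclear β-catenin exceeds mid-crypt; E-cadherin rises toward the
    top in both the membrane and cytosol compartments."""
    spec, volume, _, masks = he_noiseless
    regions = axial_regions(masks.whole_cell, voxel_size=spec.voxel_size)
    prof = region_profile(
        {"bcat": volume.channel("bcat"), "ecad": volume.channel("ecad")},
        masks, regions,
    )
    prof["mean"] = prof["integrated_intensity"] / prof["voxel_count"]
    order = ["bottom", "middle1", "middle2", "top1", "top2"]

    nuc_bcat = (prof[(prof.channel == "bcat") & (prof.compartment == "nucleus")]
                .set_index("region")["mean"].reindex(order))
    assert nuc_bcat["bottom"] > nuc_bcat["middle1"]
    assert nuc_bcat["bottom"] > nuc_bcat["middle2"]

    for comp in ("membrane", "cytosol"):
        ecad = (prof[(prof.channel == "ecad") & (prof.compartment == comp)]
                .set_index("region")["mean"].reindex(order))
        assert (np.diff(ecad.values) > 0).all(), f"{comp} E-cadherin not increasing"
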