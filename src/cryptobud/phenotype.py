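"""Heterogeneous (HE) vs homogeneous (HO) crypt phenotype classification.

Whole-mount colonic crypts fall into two populations by their membrane
E-cadherin topography: HE crypts carry "bands" or "rings" of low-E-cadherin
cells in the lower half plus small clusters of jointly high
E-cadherin/β-catenin cells at the base, while HO crypts stain uniformly
along the whole length.  The paper-scale observation is qualitative; the
operational rule implemented here is:

    HE  iff  (>= 1 low band in the bottom half) AND (>= 1 basal cluster
             high in BOTH channels);  HO otherwise.

A band is a maximal contiguous run (>= 3 bins of a >= 20-bin axial profile)
of membrane E-cadherin below ``theta_low`` (default 0.6) times the crypt
median; a basal high cluster is a connected component in the bottom axial
fifth exceeding ``theta_high`` (default 1.5) times the crypt median in both
membrane channels.  High-cluster co-expression reflects the observation that
the banding always occurs together with high β-catenin, which motivates the
conjunctive rule; a band without a cluster is called HO and flagged in the
evidence.  Both thresholds are configurable and recorded in every call.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .compartmental import CompartmentMasks, axial_coordinates, build_compartment_masks
from .io import VolumeImage

THETA_LOW = 0.6
THETA_HIGH = 1.5
N_PROFILE_BINS = 40
MIN_BAND_BINS = 3
MIN_CLUSTER_VOXELS = 8


class ProfileResolutionError(ValueError):
    """Raised when an axial profile is too coarse for band detection."""


@dataclass
class Band:
    """A contiguous low-E-cadherin run along the crypt axis."""

    start_frac: float        # axial extent, fractions of crypt length
    end_frac: float
    depth_ratio: float       # band median / crypt median


@dataclass
class PhenotypeCall:
    crypt_id: str
    label: str                       # "HE" or "HO"
    low_band_detected: bool
    bands: list = field(default_factory=list)
    basal_high_cluster_count: int = 0
    band_depth_ratio: Optional[float] = None
    theta_low: float = THETA_LOW
    theta_high: float = THETA_HIGH
    note: str = ""


# ---------------------------------------------------------------------------
# Detections
# ---------------------------------------------------------------------------

def axial_profile(
    channel: np.ndarray,
    mask: np.ndarray,
    axis: Optional[np.ndarray] = None,
    n_bins: int = N_PROFILE_BINS,
    voxel_size: float = 1.0,
) -> np.ndarray:
    """Median masked intensity per axial bin, base -> top (NaN for empty bins)."""
    arc, total = axial_coordinates(mask, axis=axis, voxel_size=voxel_size)
    mask = np.asarray(mask, bool)
    bins = np.minimum((arc[mask] / total * n_bins).astype(int), n_bins - 1)
    values = np.asarray(channel, float)[mask]
    profile = np.full(n_bins, np.nan)
    for b in range(n_bins):
        sel = bins == b
        if sel.any():
            profile[b] = np.median(values[sel])
    return profile


def detect_low_ecad_bands(
    profile: Sequence[float],
    theta_low: float = THETA_LOW,
    min_run: int = MIN_BAND_BINS,
) -> list[Band]:
    """Find low membrane-E-cadherin bands in the bottom half of the profile.

    Bands are maximal contiguous runs of at least ``min_run`` bins, within
    the bottom half of the axis, whose value is below ``theta_low`` times the
    crypt-wide median of the profile.
    """
    profile = np.asarray(profile, float)
    if profile.ndim != 1 or len(profile) < 20:
        raise ProfileResolutionError(
            f"band detection needs an axial profile of >= 20 bins, got "
            f"{profile.shape}"
        )
    median = np.nanmedian(profile)
    n = len(profile)
    half = n // 2
    low = np.zeros(n, bool)
    valid = ~np.isnan(profile)
    low[:half] = valid[:half] & (profile[:half] < theta_low * median)
    bands: list[Band] = []
    i = 0
    while i < half:
        if low[i]:
            j = i
            while j + 1 < half and low[j + 1]:
                j += 1
            if j - i + 1 >= min_run:
                depth = float(np.nanmedian(profile[i:j + 1]) / median)
                bands.append(Band(start_frac=i / n, end_frac=(j + 1) / n,
                                  depth_ratio=depth))
            i = j + 1
        else:
            i += 1
    return bands


def detect_basal_high_clusters(
    ecad: np.ndarray,
    bcat: np.ndarray,
    membrane: np.ndarray,
    arc: np.ndarray,
    total_length: float,
    theta_high: float = THETA_HIGH,
    min_cluster_voxels: int = MIN_CLUSTER_VOXELS,
) -> int:
    """Count basal clusters jointly high in E-cadherin AND β-catenin.

    Clusters are connected components of membrane voxels in the bottom axial
    fifth whose intensity exceeds ``theta_high`` times the crypt-wide
    membrane median in BOTH channels, of at least ``min_cluster_voxels``.
    """
    ecad = np.asarray(ecad, float)
    bcat = np.asarray(bcat, float)
    membrane = np.asarray(membrane, bool)
    if ecad.shape != bcat.shape or ecad.shape != membrane.shape:
        raise ValueError("channel and mask volumes must be congruent")
    if not membrane.any():
        return 0
    med_e = np.median(ecad[membrane])
    med_b = np.median(bcat[membrane])
    bottom = membrane & (arc < total_length / 5.0)
    hot = bottom & (ecad > theta_high * med_e) & (bcat > theta_high * med_b)
    labelled, n = ndimage.label(hot)
    if n == 0:
        return 0
    sizes = np.bincount(labelled.ravel())[1:]
    return int(np.sum(sizes >= min_cluster_voxels))


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def classify_crypt(
    bands: list[Band],
    cluster_count: int,
    crypt_id: str = "",
    theta_low: float = THETA_LOW,
    theta_high: float = THETA_HIGH,
) -> PhenotypeCall:
    """Combine detections into an HE/HO call with populated evidence."""
    low_band = len(bands) > 0
    label = "HE" if (low_band and cluster_count >= 1) else "HO"
    note = ""
    if low_band and cluster_count == 0:
        note = "ambiguous: low band without a co-high basal cluster"
    elif cluster_count >= 1 and not low_band:
        note = "ambiguous: basal cluster without a low band"
    return PhenotypeCall(
        crypt_id=crypt_id,
        label=label,
        low_band_detected=low_band,
        bands=list(bands),
        basal_high_cluster_count=int(cluster_count),
        band_depth_ratio=min((b.depth_ratio for b in bands), default=None),
        theta_low=theta_low,
        theta_high=theta_high,
        note=note,
    )


def phenotype_crypt(
    volume: VolumeImage,
    masks: Optional[CompartmentMasks] = None,
    crypt_id: str = "",
    axis: Optional[np.ndarray] = None,
    theta_low: float = THETA_LOW,
    theta_high: float = THETA_HIGH,
    n_bins: int = N_PROFILE_BINS,
    min_cluster_voxels: int = MIN_CLUSTER_VOXELS,
    smoothing_sigma: float = 0.5,
    min_object_um3: float = 30.0,
) -> PhenotypeCall:
    """End-to-end phenotype call for one crypt stack.

    Builds the compartment masks if not supplied, computes the axial membrane
    E-cadherin profile, runs band and cluster detection, and classifies.
    """
    vs = volume.voxel_size
    if masks is None:
        masks = build_compartment_masks(
            volume.channel("dapi"), volume.channel("bcat"), volume.channel("ecad"),
            voxel_size=vs, smoothing_sigma=smoothing_sigma,
            min_object_um3=min_object_um3,
        )
    ecad = volume.channel("ecad").astype(float)
    bcat = volume.channel("bcat").astype(float)
    profile = axial_profile(ecad, masks.membrane, axis=axis, n_bins=n_bins,
                            voxel_size=vs)
    bands = detect_low_ecad_bands(profile, theta_low=theta_low)
    arc_mem, total_mem = axial_coordinates(masks.membrane, axis=axis, voxel_size=vs)
    clusters = detect_basal_high_clusters(
        ecad, bcat, masks.membrane, arc_mem, total_mem,
        theta_high=theta_high, min_cluster_voxels=min_cluster_voxels,
    )
    return classify_crypt(bands, clusters, crypt_id=crypt_id,
                          theta_low=theta_low, theta_high=theta_high)


def summarize_population(
    calls: Sequence[PhenotypeCall],
) -> tuple[int, int, float]:
    """(HE count, HO count, HE fraction in percent) over a set of calls."""
    if len(calls) == 0:
        raise ValueError("no phenotype calls to summarize")
    he = sum(1 for c in calls if c.label == "HE")
    ho = len(calls) - he
    return he, ho, 100.0 * he / len(calls)
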