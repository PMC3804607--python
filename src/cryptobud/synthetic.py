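"""Synthetic 3D crypt phantoms and annotated crypt populations.

The generator emulates the imaged objects of the analysis: isolated
whole-mount colonic crypts — tubular epithelial monolayers around a narrow
lumen, closed by a hemispherical cap at the base and open at the top —
rendered into three fluorescence channels (DAPI nuclei, β-catenin,
E-cadherin) on a cubic-voxel grid, together with a voxel-exact ground-truth
label volume.  Crypt populations are drawn from region/age presets whose
length statistics and budding-stage frequencies encode the measured values
for mouse colon (proximal 133±28 µm, middle 160±32 µm, distal 154±21 µm, and
the per-age stage-frequency table), so parameter-recovery tests have a known
truth without any raw data download.

Geometry model: a capped cylinder with a single-cell epithelial wall; cells
are wedge prisms around the lumen (angular sectors × axial bands), each with
one ellipsoidal nucleus.  A budding daughter is a second, thinner capsule
branching downward-and-outward from the division point on the parent axis;
the two branch lengths below the division point (parent side and daughter
side) are the quantities entering the asymmetry index.

Phenotype patterning: heterogeneous (HE) crypts carry a contiguous
low-E-cadherin band in the bottom half, small clusters of jointly high
E-cadherin/β-catenin cells at the base, elevated basal nuclear β-catenin and
an E-cadherin level rising toward the crypt top; homogeneous (HO) crypts have
uniform membrane staining.  Noise is Gaussian read noise plus signal-scaled
(Poisson-like) variance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage

from .io import VolumeImage
from .morphometry import CryptAnnotation, classify_stage

# Base signal levels (arbitrary units on the 16-bit scale).
DAPI_NUCLEUS = 200.0
BCAT_MEMBRANE = 150.0
BCAT_CYTOSOL = 20.0
BCAT_NUCLEUS = 10.0
BCAT_NUCLEUS_BASAL = 60.0   # elevated basal nuclear β-catenin in HE crypts
ECAD_MEMBRANE = 160.0
ECAD_CYTOSOL = 15.0

CELL_HEIGHT_UM = 8.0        # axial extent of one epithelial cell
CELL_WIDTH_UM = 8.0         # tangential extent at mid-wall
NUCLEUS_RADII_UM = (3.0, 2.5, 3.0)   # (radial, tangential, axial) semi-axes

# Ground-truth label codes.
LABEL_BACKGROUND = 0
LABEL_LUMEN = 1
LABEL_NUCLEUS = 2
LABEL_MEMBRANE = 3
LABEL_CYTOSOL = 4


class SizingError(ValueError):
    """Raised when a requested volume cannot hold the requested geometry."""


class PresetLookupError(KeyError):
    """Raised for unknown population preset names."""


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BudSpec:
    """Daughter-bud geometry: division-point height (fraction of parent
    length, measured from the base) and daughter branch length in µm."""

    division_height_fraction: float
    daughter_length: float


@dataclass(frozen=True)
class NoiseSpec:
    gaussian_sd: float = 2.0     # read noise, intensity units
    photon_scale: float = 1.0    # variance per unit signal (Poisson-like)


@dataclass(frozen=True)
class HEPatternSpec:
    """Parameters of the heterogeneous (HE) staining phenotype."""

    band_interval: tuple[float, float] = (0.02, 0.22)  # fractions of crypt height
    band_factor: float = 0.3       # membrane/cytosol E-cadherin attenuation in band
    n_clusters: int = 2            # high E-cadherin/β-catenin basal cell clusters
    cluster_cells: int = 2         # adjacent cells per cluster
    cluster_factor: float = 2.2    # intensity gain of cluster-cell membranes
    gradient: tuple[float, float] = (0.7, 1.3)  # E-cadherin base->top factor


@dataclass(frozen=True)
class CryptSpec:
    """Complete description of one synthetic crypt."""

    length: float = 150.0            # µm, base to top along the axis
    basal_width: float = 40.0        # µm, outer diameter near the base
    wall_thickness: float = 16.0     # µm, epithelial monolayer thickness
    bud: Optional[BudSpec] = None
    patterning: str = "HO"           # "HE" or "HO"
    noise: NoiseSpec = NoiseSpec()
    voxel_size: float = 1.0          # µm per voxel edge (cubic voxels)
    he: HEPatternSpec = HEPatternSpec()

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"length must be positive, got {self.length}")
        if self.basal_width <= 0:
            raise ValueError(f"basal_width must be positive, got {self.basal_width}")
        if not self.wall_thickness < self.basal_width / 2:
            raise ValueError(
                f"wall_thickness {self.wall_thickness} must be below "
                f"basal_width/2 = {self.basal_width / 2}"
            )
        if self.patterning not in ("HE", "HO"):
            raise ValueError(f"patterning must be 'HE' or 'HO', got {self.patterning}")
        if self.voxel_size <= 0:
            raise ValueError(f"voxel_size must be positive, got {self.voxel_size}")
        if self.bud is not None:
            if not (0.0 < self.bud.division_height_fraction < 1.0):
                raise ValueError(
                    "bud division_height_fraction must lie in (0, 1), got "
                    f"{self.bud.division_height_fraction}"
                )
            if self.bud.daughter_length <= 0:
                raise ValueError("bud daughter_length must be positive")


@dataclass(frozen=True)
class PopulationPreset:
    """Region/age preset: length statistics plus stage frequencies.

    ``stage_frequencies`` is ordered (stage0, stage1, stage2, stage3) and
    sums to one.
    """

    name: str
    region: str
    age: float
    length_mean: float
    length_sd: float
    stage_frequencies: tuple[float, float, float, float]
    n_default: int

    def __post_init__(self) -> None:
        s = sum(self.stage_frequencies)
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"stage frequencies of {self.name} sum to {s}, not 1")
        if self.length_sd < 0:
            raise ValueError("length_sd must be non-negative")


@dataclass
class GroundTruth:
    """Voxel- and geometry-level truth paired with a generated crypt."""

    stage: int
    length: float
    width: float
    patterning: str
    branch_lengths: Optional[tuple[float, float]] = None  # (parent side, daughter)
    front_height: Optional[float] = None
    labels: Optional[np.ndarray] = None     # voxel compartment codes
    band_interval: Optional[tuple[float, float]] = None
    cluster_count: int = 0
    nucleus_count: Optional[int] = None
    voxel_size: float = 1.0


# ---------------------------------------------------------------------------
# Region/age presets
# ---------------------------------------------------------------------------

# Crypt length mean ± sd per colon region, µm.
_REGION_LENGTHS = {
    "proximal": (133.0, 28.0),
    "middle": (160.0, 32.0),
    "distal": (154.0, 21.0),
    # No printed length statistics exist for the pooled-regions rows; the
    # pooled preset uses the mean of the three regional presets.
    "total": (149.0, 27.0),
}

# Stage percentages (S1, S2, S3, S0) per age (weeks) and region column,
# and the total crypt count per age.
_STAGE_TABLE = {
    2.3: {"total_counted": 517,
          "D": (9.5, 16.4, 2.1, 72.0), "M": (10.2, 7.2, 1.8, 80.7),
          "P": (20.4, 14.2, 7.4, 58.0), "T": (13.2, 12.8, 3.7, 70.4)},
    4.0: {"total_counted": 646,
          "D": (10.0, 14.4, 16.8, 58.8), "M": (5.7, 10.1, 8.1, 76.1),
          "P": (4.7, 11.4, 7.4, 76.5), "T": (7.1, 12.1, 11.3, 69.5)},
    7.0: {"total_counted": 552,
          "D": (5.9, 12.7, 31.2, 50.2), "M": (10.6, 4.8, 6.7, 77.9),
          "P": (3.6, 7.9, 25.2, 63.3), "T": (7.1, 8.5, 20.5, 63.9)},
    40.0: {"total_counted": 571,
           "D": (2.6, 0.4, 4.8, 92.2), "M": (7.6, 0.0, 0.0, 92.4),
           "P": (2.6, 1.3, 2.6, 93.6), "T": (3.5, 0.7, 3.0, 92.8)},
}

_REGION_TO_COLUMN = {"proximal": "P", "middle": "M", "distal": "D", "total": "T"}


def _build_presets() -> dict[str, PopulationPreset]:
    presets = {}
    for age, row in _STAGE_TABLE.items():
        for region, col in _REGION_TO_COLUMN.items():
            s1, s2, s3, s0 = row[col]
            total = s0 + s1 + s2 + s3
            freqs = (s0 / total, s1 / total, s2 / total, s3 / total)
            mean, sd = _REGION_LENGTHS[region]
            n = row["total_counted"]
            name = f"{region}-{age:g}"
            presets[name] = PopulationPreset(
                name=name, region=region, age=age,
                length_mean=mean, length_sd=sd,
                stage_frequencies=freqs,
                n_default=n if region == "total" else max(1, round(n / 3)),
            )
    return presets


PRESETS: dict[str, PopulationPreset] = _build_presets()


def get_preset(name: str) -> PopulationPreset:
    """Look up a population preset such as ``"proximal-4"`` or ``"total-40"``."""
    key = name.strip().lower()
    if "-" in key:
        region, _, age = key.rpartition("-")
        try:
            key = f"{region}-{float(age):g}"
        except ValueError:
            pass
    if key not in PRESETS:
        raise PresetLookupError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        )
    return PRESETS[key]


# ---------------------------------------------------------------------------
# Volume rendering
# ---------------------------------------------------------------------------

def _daughter_frame(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal basis perpendicular to the daughter axis direction."""
    ref = np.array([0.0, 1.0, 0.0]) if abs(u[0]) > 0.9 else np.array([1.0, 0.0, 0.0])
    e1 = np.cross(u, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(u, e1)
    return e1, e2


def _cell_fields(dist, theta, axial_um, outer_r, wall, voxel_size):
    """Membrane and nucleus predicates for a wedge-prism cell packing.

    ``dist`` is the distance to the tube skeleton, ``theta`` the azimuth
    about the axis, ``axial_um`` the axial coordinate from the structure base
    in µm.  Returns (membrane, nucleus, sector, band) arrays.
    """
    mid_r = outer_r - wall / 2.0
    n_theta = max(6, int(round(2 * np.pi * mid_r / CELL_WIDTH_UM)))
    cell_arc = 2 * np.pi * mid_r / n_theta
    theta_pos = (theta + np.pi) / (2 * np.pi) * n_theta
    sector = np.floor(theta_pos).astype(np.int32) % n_theta
    frac = theta_pos - np.floor(theta_pos)
    band = np.floor(axial_um / CELL_HEIGHT_UM).astype(np.int32)
    ax_frac = axial_um - band * CELL_HEIGHT_UM

    membrane = (
        (dist > outer_r - voxel_size)
        | (dist < outer_r - wall + voxel_size)
        | (frac * cell_arc < voxel_size)
        | (ax_frac < voxel_size)
    )

    a_r, a_t, a_a = NUCLEUS_RADII_UM
    dr = dist - mid_r
    dt = (frac - 0.5) * cell_arc
    da = ax_frac - CELL_HEIGHT_UM / 2.0
    nucleus = (dr / a_r) ** 2 + (dt / a_t) ** 2 + (da / a_a) ** 2 <= 1.0
    return membrane, nucleus, sector, band, n_theta


def generate_crypt_volume(
    spec: CryptSpec,
    seed: int | np.random.SeedSequence = 0,
    shape: Optional[tuple[int, int, int]] = None,
) -> tuple[VolumeImage, GroundTruth]:
    """Render one crypt into a 3-channel volume plus ground-truth labels.

    The volume is sized automatically to hold the requested geometry with a
    small margin; passing ``shape`` overrides the sizing and raises
    :class:`SizingError` naming the offending dimension when too small.
    Output is reproducible bit-for-bit for a given ``(spec, seed)``.
    """
    rng = np.random.default_rng(seed)
    vs = spec.voxel_size
    L = spec.length
    R = spec.basal_width / 2.0
    w = spec.wall_thickness
    margin = 6.0

    # Daughter geometry (downward-and-outward capsule from the division point).
    bud = spec.bud
    if bud is not None:
        h_front = bud.division_height_fraction * L
        Rd = 0.7 * R
        wd = 0.7 * w
        alpha = np.deg2rad(35.0)
        phi = rng.uniform(0, 2 * np.pi)
        skel_len = max(bud.daughter_length - Rd, vs)
        u = np.array([-np.cos(alpha),
                      np.sin(alpha) * np.cos(phi),
                      np.sin(alpha) * np.sin(phi)])
        down_reach = skel_len * np.cos(alpha) + Rd
        lateral_reach = skel_len * np.sin(alpha) + Rd
    else:
        h_front = None
        down_reach = 0.0
        lateral_reach = 0.0

    z0 = margin + max(0.0, down_reach - (h_front or 0.0) + vs)
    need_z = int(np.ceil((z0 + L + margin) / vs))
    half_xy = max(R, lateral_reach) + margin
    need_xy = int(np.ceil(2 * half_xy / vs))

    if shape is None:
        nz, ny, nx = need_z, need_xy, need_xy
    else:
        nz, ny, nx = shape
        for name, have, need in (("z", nz, need_z), ("y", ny, need_xy), ("x", nx, need_xy)):
            if have < need:
                raise SizingError(
                    f"volume dimension {name}={have} voxels is too small for the "
                    f"requested geometry (needs >= {need} at {vs} µm/voxel)"
                )

    zc = (np.arange(nz) + 0.5) * vs
    yc = (np.arange(ny) + 0.5) * vs
    xc = (np.arange(nx) + 0.5) * vs
    cy, cx = ny * vs / 2.0, nx * vs / 2.0
    Z = zc[:, None, None]
    Y = yc[None, :, None] - cy
    X = xc[None, None, :] - cx

    # Parent capsule: skeleton from (z0 + R) up to (z0 + L) on the central axis.
    rho = np.sqrt(Y**2 + X**2)
    below_cap = np.maximum(0.0, (z0 + R) - Z)
    dist_p = np.sqrt(rho**2 + below_cap**2)
    in_height = Z <= z0 + L
    shell_p = (dist_p >= R - w) & (dist_p <= R) & in_height
    lumen_p = (dist_p < R - w) & in_height

    theta_p = np.arctan2(np.broadcast_to(Y, (nz, ny, nx)),
                         np.broadcast_to(X, (nz, ny, nx)))
    axial_p = np.broadcast_to(Z - z0, (nz, ny, nx))
    mem_p, nuc_p, sector_p, band_p, n_theta = _cell_fields(
        dist_p, theta_p, np.maximum(axial_p, 0.0), R, w, vs
    )

    if bud is not None:
        S = np.array([z0 + h_front, 0.0, 0.0])   # division point on the axis
        P = np.stack(np.broadcast_arrays(Z, Y, X), axis=-1)
        V = P - S
        t = np.clip(np.einsum("...i,i->...", V, u), 0.0, skel_len)
        N = S + t[..., None] * u
        dist_d = np.linalg.norm(P - N, axis=-1)
        shell_d = (dist_d >= Rd - wd) & (dist_d <= Rd)
        lumen_d = dist_d < Rd - wd
        e1, e2 = _daughter_frame(u)
        theta_d = np.arctan2(np.einsum("...i,i->...", V, e2),
                             np.einsum("...i,i->...", V, e1))
        # daughter axial coordinate measured from its base tip
        axial_d = (skel_len + Rd) - np.einsum("...i,i->...", V, u)
        mem_d, nuc_d, _, _, _ = _cell_fields(
            dist_d, theta_d, np.maximum(axial_d, 0.0), Rd, wd, vs
        )
    else:
        shell_d = np.zeros((nz, ny, nx), bool)
        lumen_d = shell_d
        mem_d = nuc_d = shell_d

    lumen = (lumen_p | lumen_d)
    epithelium = (shell_p | shell_d) & ~lumen

    own_p = shell_p & epithelium
    own_d = shell_d & epithelium & ~shell_p
    nucleus = (own_p & nuc_p) | (own_d & nuc_d)
    # cells clipped at the cap or rim can leave sliver nuclei of a few voxels;
    # real nuclei are whole, so fragments below a quarter of the nominal
    # nucleus volume revert to cytosol
    nominal = 4.0 / 3.0 * np.pi * np.prod(NUCLEUS_RADII_UM)
    min_nuc_voxels = int(round(0.25 * nominal / vs**3))
    comp, n_comp = ndimage.label(nucleus)
    if n_comp:
        sizes = np.bincount(comp.ravel())
        nucleus &= sizes[comp] >= min_nuc_voxels
    membrane = ((own_p & mem_p) | (own_d & mem_d)) & ~nucleus
    cytosol = epithelium & ~nucleus & ~membrane

    labels = np.zeros((nz, ny, nx), np.uint8)
    labels[lumen] = LABEL_LUMEN
    labels[cytosol] = LABEL_CYTOSOL
    labels[membrane] = LABEL_MEMBRANE
    labels[nucleus] = LABEL_NUCLEUS

    # Height fraction along the parent, for axial patterning.
    tfrac = np.clip((np.broadcast_to(Z, (nz, ny, nx)) - z0) / L, 0.0, 1.0)

    dapi = np.where(nucleus, DAPI_NUCLEUS, 0.0)
    bcat = (membrane * BCAT_MEMBRANE + cytosol * BCAT_CYTOSOL
            + nucleus * BCAT_NUCLEUS).astype(float)
    he = spec.he
    band_interval = None
    n_clusters = 0
    if spec.patterning == "HE":
        g_lo, g_hi = he.gradient
        grad = g_lo + (g_hi - g_lo) * tfrac
        band_interval = he.band_interval
        in_band = (tfrac >= band_interval[0]) & (tfrac < band_interval[1])
        band_fac = np.where(in_band, he.band_factor, 1.0)
        ecad = (membrane * ECAD_MEMBRANE + cytosol * ECAD_CYTOSOL) * grad * band_fac
        # elevated nuclear β-catenin in the basal fifth
        basal_nuc = nucleus & (tfrac < 0.2)
        bcat = np.where(basal_nuc, BCAT_NUCLEUS_BASAL, bcat)
        # jointly high E-cadherin/β-catenin basal cell clusters (parent wall,
        # first full cell band above the cap, well-separated sectors)
        n_clusters = he.n_clusters
        cluster_mask = np.zeros((nz, ny, nx), bool)
        starts = (np.arange(n_clusters) * (n_theta // max(1, n_clusters)))
        for s0_sector in starts:
            sectors = (s0_sector + np.arange(he.cluster_cells)) % n_theta
            cluster_mask |= own_p & (band_p == 1) & np.isin(sector_p, sectors)
        cm = cluster_mask & membrane
        ecad = np.where(cm, he.cluster_factor * ECAD_MEMBRANE, ecad)
        bcat = np.where(cm, he.cluster_factor * BCAT_MEMBRANE, bcat)
    else:
        ecad = membrane * ECAD_MEMBRANE + cytosol * ECAD_CYTOSOL

    channels = np.stack([dapi, bcat, ecad]).astype(np.float64)
    if spec.noise.gaussian_sd > 0 or spec.noise.photon_scale > 0:
        sd = np.sqrt(spec.noise.gaussian_sd**2
                     + spec.noise.photon_scale * channels)
        channels = channels + rng.standard_normal(channels.shape) * sd
    data = np.clip(np.rint(channels), 0, 65535).astype(np.uint16)

    n_nuclei = int(ndimage.label(labels == LABEL_NUCLEUS)[1])
    stage = classify_stage(L, front_height=h_front, has_bud=bud is not None)
    truth = GroundTruth(
        stage=stage,
        length=L,
        width=spec.basal_width,
        patterning=spec.patterning,
        branch_lengths=(h_front, bud.daughter_length) if bud is not None else None,
        front_height=h_front,
        labels=labels,
        band_interval=band_interval,
        cluster_count=n_clusters,
        nucleus_count=n_nuclei,
        voxel_size=vs,
    )
    volume = VolumeImage(data=data, voxel_size=vs)
    return volume, truth


# ---------------------------------------------------------------------------
# Populations
# ---------------------------------------------------------------------------

def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(np.asarray(x) + 0.5).astype(int)


def _stage_counts(preset: PopulationPreset, n: int) -> np.ndarray:
    """Deterministic per-stage counts: round(n * frequency), residual assigned
    to the most frequent stage so the counts always sum to n."""
    freqs = np.asarray(preset.stage_frequencies)
    counts = _round_half_up(n * freqs)
    counts[np.argmax(freqs)] += n - counts.sum()
    return counts


def _truncated_normal(rng, mean, sd, n):
    """Normal draws rejected at <= 0 (crypt lengths admit no negative support)."""
    out = rng.normal(mean, sd, size=n)
    while True:
        bad = out <= 0
        if not bad.any():
            return out
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))


def _draw_branch_ratio(rng, asymmetric: bool) -> float:
    if asymmetric:
        r = rng.uniform(1.15, 2.5)
    else:
        r = rng.uniform(0.985, 1.015)
    return 1.0 / r if rng.random() < 0.5 else r


#: Mixture weight of clearly-asymmetric events in the asymmetric-budding
#: preset: the mean of the two measured cohort values (89.9% and 90.4% of
#: budding crypts above the 1% AI cutoff).
ASYMMETRIC_FRACTION = 0.902


def draw_branch_pairs(
    n: int,
    seed: int | np.random.SeedSequence = 0,
    asymmetric_fraction: float = ASYMMETRIC_FRACTION,
) -> np.ndarray:
    """Draw ``(parent-branch, daughter-branch)`` length pairs (µm) from the
    asymmetric-budding preset.

    Events are a mixture of asymmetric budding (branch-length ratio in
    [1.15, 2.5], AI >= 6.9%) and near-symmetric fission-like events (ratio
    within 1.5% of unity, AI < 1%).
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = np.random.default_rng(seed)
    base = rng.uniform(15.0, 75.0, size=n)
    asym = rng.random(n) < asymmetric_fraction
    ratios = np.array([_draw_branch_ratio(rng, a) for a in asym])
    return np.column_stack([base, base * ratios])


def _spec_for_stage(rng, stage: int, length: float, preset: PopulationPreset,
                    voxel_size: float, noise: NoiseSpec) -> tuple[CryptSpec, GroundTruth]:
    width = float(_truncated_normal(rng, 40.0, 5.0, 1)[0])
    wall = 0.4 * width
    bud = None
    branch = None
    front = None
    if stage > 0:
        lo, hi = {1: (0.05, 0.245), 2: (0.255, 0.495), 3: (0.505, 0.90)}[stage]
        f = rng.uniform(lo, hi)
        front = f * length
        ratio = _draw_branch_ratio(rng, rng.random() < ASYMMETRIC_FRACTION)
        daughter = front * ratio
        bud = BudSpec(division_height_fraction=f, daughter_length=daughter)
        branch = (front, daughter)
    patterning = "HE" if rng.random() < 0.6 else "HO"
    spec = CryptSpec(
        length=length, basal_width=width, wall_thickness=wall, bud=bud,
        patterning=patterning, noise=noise, voxel_size=voxel_size,
    )
    truth = GroundTruth(
        stage=stage, length=length, width=width, patterning=patterning,
        branch_lengths=branch, front_height=front, voxel_size=voxel_size,
    )
    return spec, truth


def generate_population(
    preset: PopulationPreset | str,
    n: Optional[int] = None,
    seed: int | np.random.SeedSequence = 0,
    exact_counts: bool = False,
    voxel_size: float = 1.0,
    noise: NoiseSpec = NoiseSpec(),
) -> list[tuple[CryptSpec, GroundTruth]]:
    """Draw an annotated crypt population from a region/age preset.

    Lengths come from a positive-truncated normal with the preset's mean and
    sd; stages are multinomial draws from the preset's stage frequencies.
    With ``exact_counts`` the per-stage composition is deterministic:
    ``round(n * frequency)`` crypts per stage (residual, if any, assigned to
    the most frequent stage), shuffled into a reproducible order.
    """
    if isinstance(preset, str):
        preset = get_preset(preset)
    if n is None:
        n = preset.n_default
    if n < 1:
        raise ValueError("population size must be at least 1")
    rng = np.random.default_rng(seed)
    if exact_counts:
        counts = _stage_counts(preset, n)
        stages = np.repeat(np.arange(4), counts)
        stages = rng.permutation(stages)
    else:
        stages = rng.choice(4, size=n, p=preset.stage_frequencies)
    lengths = _truncated_normal(rng, preset.length_mean, preset.length_sd, n)
    return [
        _spec_for_stage(rng, int(s), float(l), preset, voxel_size, noise)
        for s, l in zip(stages, lengths)
    ]


def generate_cohort(
    seed: int | np.random.SeedSequence = 0,
    n: int = 32,
    n_he: int = 20,
    length_mean: float = 150.0,
    length_sd: float = 25.0,
    voxel_size: float = 2.0,
    noise: NoiseSpec = NoiseSpec(),
) -> list[CryptSpec]:
    """Specs for the whole-mount immunofluorescence cohort: 32 non-budding
    crypts, 20 heterogeneous and 12 homogeneous, in a seed-shuffled order.

    Rendered at 2 µm voxels by default, which preserves the cell-scale
    patterning while keeping a 32-volume cohort cheap to generate.
    """
    if not (0 <= n_he <= n):
        raise ValueError("n_he must lie between 0 and n")
    rng = np.random.default_rng(seed)
    patterns = np.array(["HE"] * n_he + ["HO"] * (n - n_he))
    patterns = rng.permutation(patterns)
    lengths = _truncated_normal(rng, length_mean, length_sd, n)
    specs = []
    for patt, length in zip(patterns, lengths):
        width = float(_truncated_normal(rng, 40.0, 5.0, 1)[0])
        specs.append(
            CryptSpec(length=float(length), basal_width=width,
                      wall_thickness=0.4 * width, patterning=str(patt),
                      noise=noise, voxel_size=voxel_size)
        )
    return specs


# ---------------------------------------------------------------------------
# Synthetic annotations
# ---------------------------------------------------------------------------

def _jittered_polyline(rng, start: np.ndarray, total_length: float,
                       n_segments: int = 6, direction: int = +1) -> np.ndarray:
    """Polyline of exact total length from ``start``, predominantly along z."""
    weights = rng.dirichlet(np.ones(n_segments)) * total_length
    pts = [np.asarray(start, float)]
    for wlen in weights:
        d = np.array([direction * 1.0, rng.normal(0, 0.25), rng.normal(0, 0.25)])
        d /= np.linalg.norm(d)
        pts.append(pts[-1] + wlen * d)
    return np.asarray(pts)


def _point_at_arc(polyline: np.ndarray, arc: float) -> np.ndarray:
    seg = np.linalg.norm(np.diff(polyline, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    arc = min(max(arc, 0.0), cum[-1])
    i = int(np.searchsorted(cum, arc, side="right") - 1)
    i = min(i, len(seg) - 1)
    t = (arc - cum[i]) / seg[i] if seg[i] > 0 else 0.0
    return polyline[i] + t * (polyline[i + 1] - polyline[i])


def synthetic_annotation(
    spec: CryptSpec,
    truth: GroundTruth,
    seed: int | np.random.SeedSequence = 0,
    crypt_id: str = "",
    region: str = "",
    age: Optional[float] = None,
) -> CryptAnnotation:
    """Emulate a manual annotation of a generated crypt.

    The axis polyline is a jittered 3D path whose summed segment length
    equals the true crypt length; for budding crypts the two branch polylines
    (division point down to each base) have the true branch lengths; the
    basal-width segment spans the true width.
    """
    rng = np.random.default_rng(seed)
    base = rng.uniform(0, 50, size=3)
    axis = _jittered_polyline(rng, base, truth.length)
    branches = None
    if truth.branch_lengths is not None:
        h, d = truth.branch_lengths
        division = _point_at_arc(axis, h)
        # parent branch: division point back down to the base, exact length h
        below = [division]
        seg = np.linalg.norm(np.diff(axis, axis=0), axis=1)
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        for i in range(len(axis) - 1, -1, -1):
            if cum[i] < h - 1e-12:
                below.append(axis[i])
        parent_branch = np.asarray(below)
        daughter_branch = _jittered_polyline(rng, division, d, n_segments=4,
                                             direction=-1)
        branches = (parent_branch, daughter_branch)
    # width chord drawn near the base, roughly perpendicular to the axis
    seg_dir = np.array([0.0, np.cos(0.3), np.sin(0.3)])
    p0 = axis[0] + rng.normal(0, 0.5, 3)
    width_segment = np.stack([p0, p0 + truth.width * seg_dir])
    return CryptAnnotation(
        axis=axis, branches=branches, basal_width_segment=width_segment,
        crypt_id=crypt_id, region=region, age=age,
    )


def generate_annotated_population(
    preset: PopulationPreset | str,
    n: Optional[int] = None,
    seed: int | np.random.SeedSequence = 0,
    exact_counts: bool = False,
) -> list[tuple[CryptSpec, GroundTruth, CryptAnnotation]]:
    """Population plus emulated manual annotations for every crypt."""
    if isinstance(preset, str):
        preset = get_preset(preset)
    ss = np.random.SeedSequence(
        entropy=seed.entropy if isinstance(seed, np.random.SeedSequence) else seed,
        spawn_key=(7,),
    )
    pop = generate_population(preset, n=n, seed=seed, exact_counts=exact_counts)
    out = []
    for i, ((spec, truth), child) in enumerate(zip(pop, ss.spawn(len(pop)))):
        ann = synthetic_annotation(
            spec, truth, seed=child, crypt_id=f"{preset.name}-{i:05d}",
            region=preset.region, age=preset.age,
        )
        out.append((spec, truth, ann))
    return out
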