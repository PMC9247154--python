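"""Synthetic phantoms for tomographic image-quality analysis of bone.

Generates reconstructed-image-space volumes (no projection physics): a label
map is painted from geometric primitives, per-phase mean grey values are
assigned, a Gaussian point-spread blur is applied in physical units, and
additive Gaussian noise is clipped to the declared bit depth.  The pre-blur
label map is returned alongside the volume and serves as ground truth for
edge fits, CNR regions, histogram peaks and morphometry.

Also generates 1D edge profiles (Gaussian-CDF edges), unconfined-compression
force-displacement records with quadratic bone-volume-fraction scaling, and
drying/rehydration weight time-series — each seeded and reproducible.
"""
from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.special import ndtr


class PhantomConfigurationError(ValueError):
    """Raised when a phantom specification is internally inconsistent."""


# ---------------------------------------------------------------------------
# Geometry primitives (voxel index coordinates, (z, y, x) ordering)
# ---------------------------------------------------------------------------

class Primitive:
    """Base class for phantom geometry; subclasses paint a boolean region."""

    def indicator(self, shape: tuple[int, int, int], rng: np.random.Generator) -> np.ndarray:
        raise NotImplementedError


@dataclass(frozen=True)
class Everywhere(Primitive):
    """Covers the full volume; conventionally the background base layer."""

    def indicator(self, shape, rng):
        return np.ones(shape, dtype=bool)


@dataclass(frozen=True)
class HalfSpace(Primitive):
    """Voxels with index >= ``cut`` (side='high') along one axis."""

    axis: int
    cut: float
    side: str = "high"

    def indicator(self, shape, rng):
        idx = np.arange(shape[self.axis])
        sel = idx >= self.cut if self.side == "high" else idx < self.cut
        shp = [1, 1, 1]
        shp[self.axis] = shape[self.axis]
        return np.broadcast_to(sel.reshape(shp), shape).copy()


@dataclass(frozen=True)
class Box(Primitive):
    lo: tuple[float, float, float]
    hi: tuple[float, float, float]

    def indicator(self, shape, rng):
        zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
        return (
            (zz >= self.lo[0]) & (zz < self.hi[0])
            & (yy >= self.lo[1]) & (yy < self.hi[1])
            & (xx >= self.lo[2]) & (xx < self.hi[2])
        )


@dataclass(frozen=True)
class Cylinder(Primitive):
    """z-aligned (hollow) cylinder; ``inner_radius`` > 0 gives an annulus."""

    center: tuple[float, float]  # (y, x)
    radius: float
    inner_radius: float = 0.0
    z_range: tuple[float, float] | None = None

    def indicator(self, shape, rng):
        zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
        r2 = (yy - self.center[0]) ** 2 + (xx - self.center[1]) ** 2
        sel = (r2 <= self.radius**2) & (r2 >= self.inner_radius**2)
        if self.z_range is not None:
            sel = sel & (zz >= self.z_range[0]) & (zz < self.z_range[1])
        return np.broadcast_to(sel, shape).copy()


@dataclass(frozen=True)
class Sphere(Primitive):
    center: tuple[float, float, float]
    radius: float

    def indicator(self, shape, rng):
        zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
        r2 = (
            (zz - self.center[0]) ** 2
            + (yy - self.center[1]) ** 2
            + (xx - self.center[2]) ** 2
        )
        return (r2 <= self.radius**2) & np.ones(shape, dtype=bool)


@dataclass(frozen=True)
class SphereCloud(Primitive):
    """Seeded random spheres inside a cylindrical region (e.g. air voids)."""

    region: Cylinder
    n: int
    radius: float
    radius_jitter: float = 0.25
    margin: float = 3.0   # clearance from the region surface, voxels

    def indicator(self, shape, rng):
        mask = np.zeros(shape, dtype=bool)
        zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
        cy, cx = self.region.center
        z_lo, z_hi = self.region.z_range or (0, shape[0])
        clearance = self.radius + self.margin
        placed = 0
        # rejection-sample centers inside the (shrunk) cylinder
        for _ in range(self.n * 20):
            if placed >= self.n:
                break
            cz = rng.uniform(z_lo + clearance, z_hi - clearance)
            py = rng.uniform(cy - self.region.radius, cy + self.region.radius)
            px = rng.uniform(cx - self.region.radius, cx + self.region.radius)
            if (py - cy) ** 2 + (px - cx) ** 2 > (self.region.radius - clearance) ** 2:
                continue
            r = self.radius * float(
                np.clip(rng.normal(1.0, self.radius_jitter), 0.3, 2.0)
            )
            # cap so the jittered sphere keeps its clearance from the surface
            radial = np.hypot(py - cy, px - cx)
            r = min(
                r,
                self.region.radius - self.margin - radial,
                cz - z_lo - self.margin,
                z_hi - cz - self.margin,
            )
            if r <= 0.5:
                continue
            mask |= (zz - cz) ** 2 + (yy - py) ** 2 + (xx - px) ** 2 <= r**2
            placed += 1
        return mask


@dataclass
class RodLattice(Primitive):
    """Regular three-axis rod lattice with seeded per-rod radius jitter.

    The mean rod radius is calibrated by bisection on the actual voxel grid so
    that the achieved volume fraction inside ``region`` matches
    ``target_fraction``; the achieved value is stored on the instance after
    painting and recorded in the phantom metadata.
    """

    region: Cylinder
    target_fraction: float
    spacing: float = 16.0
    radius_jitter: float = 0.10
    achieved_fraction: float | None = field(default=None, compare=False)

    def indicator(self, shape, rng):
        if not 0.0 <= self.target_fraction <= 1.0:
            raise PhantomConfigurationError(
                f"target_fraction must lie in [0, 1], got {self.target_fraction}"
            )
        region_mask = self.region.indicator(shape, rng) & np.ones(shape, bool)
        n_region = int(region_mask.sum())
        if n_region == 0:
            raise PhantomConfigurationError("rod lattice region is empty")
        s = float(self.spacing)
        ncell = int(np.ceil(max(shape) / s)) + 1
        jitter = np.clip(
            rng.normal(1.0, self.radius_jitter, size=(3, ncell, ncell)), 0.5, 1.5
        )

        nz, ny, nx = shape

        def cross_section(n_a, n_b, jit):
            # squared distance of each (a, b) voxel center to its cell's rod
            # axis, plus that rod's jitter factor; rods sit at cell centers
            a = np.arange(n_a, dtype=float)[:, None]
            b = np.arange(n_b, dtype=float)[None, :]
            ia = (a // s).astype(int)
            ib = (b // s).astype(int)
            da = a - (ia + 0.5) * s
            db = b - (ib + 0.5) * s
            return da**2 + db**2, jit[ia, ib]

        d2_z, j_z = cross_section(ny, nx, jitter[0])   # rods along z: (y, x)
        d2_y, j_y = cross_section(nz, nx, jitter[1])   # rods along y: (z, x)
        d2_x, j_x = cross_section(nz, ny, jitter[2])   # rods along x: (z, y)

        def union(r):
            mz = d2_z <= (r * j_z) ** 2
            my = d2_y <= (r * j_y) ** 2
            mx = d2_x <= (r * j_x) ** 2
            return mz[None, :, :] | my[:, None, :] | mx[:, :, None]

        def frac(r):
            return float((union(r) & region_mask).sum()) / n_region

        lo, hi = 0.0, 0.49 * s
        if self.target_fraction > 0 and frac(hi) < self.target_fraction:
            raise PhantomConfigurationError(
                "target_fraction unreachable at this rod spacing"
            )
        for _ in range(40):
            mid = 0.5 * (lo + hi)
            if frac(mid) < self.target_fraction:
                lo = mid
            else:
                hi = mid
        r = 0.5 * (lo + hi)
        mask = union(r) & region_mask
        self.achieved_fraction = float(mask.sum()) / n_region
        return mask


# ---------------------------------------------------------------------------
# Volume phantom
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Phase:
    label: str
    primitive: Primitive
    grey: float


@dataclass
class Volume:
    """A reconstructed 3D grey-value image, (z, y, x) ordering.

    voxel_size is the isotropic voxel edge length in micrometres.
    """

    data: np.ndarray
    voxel_size: float
    bit_depth: int = 16
    provenance: str = ""

    def __post_init__(self):
        if self.data.ndim != 3:
            raise ValueError("volume data must be a 3D (z, y, x) array")
        if not self.voxel_size > 0:
            raise ValueError("voxel_size must be strictly positive")
        if self.bit_depth not in (8, 16, 32):
            raise ValueError("bit_depth must be 8, 16 or 32")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def grey_max(self) -> float:
        return float(2**self.bit_depth - 1)


@dataclass(frozen=True)
class PhantomSpec:
    """Declarative synthetic-specimen description (ground truth included)."""

    shape: tuple[int, int, int]
    phases: tuple[Phase, ...]
    voxel_size: float = 7.15      # µm, matching the imaging setup emulated
    blur_sigma: float = 5.0       # µm, Gaussian point-spread
    noise_sigma: float = 0.0      # grey-value units, additive
    bit_depth: int = 16
    seed: int = 0

    def digest(self) -> str:
        raw = repr(self).encode()
        return hashlib.sha1(raw).hexdigest()[:12]


@dataclass
class PhantomResult:
    volume: Volume
    label_map: np.ndarray            # uint8 phase indices, pre-blur
    phase_table: list[dict]          # label, index, grey, voxel count
    metadata: dict


def generate_volume(spec: PhantomSpec, overlap: str = "later-wins") -> PhantomResult:
    """Render a phantom volume and its ground-truth label map.

    Later phases overwrite earlier ones where primitives overlap
    (``overlap='later-wins'``); with ``overlap='error'`` any overlap among
    non-base phases raises :class:`PhantomConfigurationError`.  The label map
    is a partition: every voxel carries exactly one phase index.
    """
    if spec.blur_sigma < 0:
        raise ValueError("blur_sigma must be >= 0")
    if spec.noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    if len(spec.phases) == 0:
        raise PhantomConfigurationError("at least one phase is required")
    if len(spec.phases) > 250:
        raise PhantomConfigurationError("too many phases for a uint8 label map")

    rng = np.random.default_rng(spec.seed)
    paint_rngs = rng.spawn(len(spec.phases))
    noise_rng = rng

    sentinel = 255
    labels = np.full(spec.shape, sentinel, dtype=np.uint8)
    claimed = np.zeros(spec.shape, dtype=bool)
    for i, phase in enumerate(spec.phases):
        sel = phase.primitive.indicator(spec.shape, paint_rngs[i])
        if overlap == "error" and i > 0:
            if np.any(sel & claimed):
                raise PhantomConfigurationError(
                    f"phase '{phase.label}' overlaps an earlier phase and "
                    "overlap='error' was requested"
                )
            claimed |= sel
        labels[sel] = i
    if np.any(labels == sentinel) and len(spec.phases) <= sentinel:
        raise PhantomConfigurationError(
            "phases do not cover the volume; start with a full-cover base "
            "phase (e.g. Everywhere background)"
        )

    lut = np.array([p.grey for p in spec.phases], dtype=np.float64)
    grey = lut[labels]

    if spec.blur_sigma > 0:
        sigma_vox = spec.blur_sigma / spec.voxel_size
        grey = ndimage.gaussian_filter(grey, sigma=sigma_vox, mode="reflect")
    if spec.noise_sigma > 0:
        grey = grey + noise_rng.normal(0.0, spec.noise_sigma, size=spec.shape)

    grey_max = 2**spec.bit_depth - 1
    grey = np.clip(grey, 0, grey_max)
    if spec.bit_depth == 8:
        data = np.rint(grey).astype(np.uint8)
    elif spec.bit_depth == 16:
        data = np.rint(grey).astype(np.uint16)
    else:
        data = grey.astype(np.float32)

    counts = np.bincount(labels.ravel(), minlength=len(spec.phases))
    phase_table = [
        {"index": i, "label": p.label, "grey": p.grey, "voxels": int(counts[i])}
        for i, p in enumerate(spec.phases)
    ]
    metadata: dict = {
        "seed": spec.seed,
        "blur_sigma_um": spec.blur_sigma,
        "noise_sigma": spec.noise_sigma,
        "voxel_size_um": spec.voxel_size,
        "spec_digest": spec.digest(),
    }
    for i, p in enumerate(spec.phases):
        ach = getattr(p.primitive, "achieved_fraction", None)
        if ach is not None:
            metadata[f"achieved_fraction_{p.label}"] = ach

    vol = Volume(
        data=data,
        voxel_size=spec.voxel_size,
        bit_depth=spec.bit_depth,
        provenance=f"phantom:{spec.digest()}",
    )
    return PhantomResult(vol, labels, phase_table, metadata)


# ---------------------------------------------------------------------------
# Preset phantom configurations (grey means chosen to reproduce the
# qualitative hydration-state orderings of neutron images; see docs/methods.md)
# ---------------------------------------------------------------------------

TIBIA_GREYS = {
    # background, soft tissue fixed; cortex mean approaches background with
    # hydration; free heavy water appears only in the fully rehydrated state.
    # All means sit >= 4 noise SDs inside the 16-bit range so the additive
    # Gaussian noise model is not truncated by clipping.
    "dry": {"background": 9000, "soft_tissue": 42000, "cortex": 32000, "canal": 13000},
    "rehydrated_12h": {"background": 9000, "soft_tissue": 42000, "cortex": 25000, "canal": 13000},
    "rehydrated_40h": {"background": 9000, "soft_tissue": 42000, "cortex": 20000, "d2o": 16000},
}

PLUG_GREYS = {
    # dry: air voids present, bone/marrow contrast collapses (peak merging);
    # soaked/rehydrated: voids filled, bone/marrow well separated
    "dry": {"background": 6000, "marrow": 29000, "bone": 26000, "void": 9000},
    "soaked": {"background": 6000, "marrow": 38000, "bone": 22000},
    "rehydrated": {"background": 6000, "marrow": 37000, "bone": 23000},
}

TIBIA_NOISE_SD = 2250.6   # background grey-value SD, neutron tibia scans
PLUG_NOISE_SD = 1192.4    # background grey-value SD, neutron plug scans


def tibia_phantom(
    state: str = "dry",
    shape: tuple[int, int, int] = (48, 96, 96),
    noise_sigma: float = TIBIA_NOISE_SD,
    blur_sigma: float = 5.0,
    seed: int = 0,
) -> PhantomSpec:
    """Proximal-tibia-style phantom: cortical shell, soft tissue, canal.

    ``state`` selects grey means emulating dry / rehydrated neutron contrast.
    """
    if state not in TIBIA_GREYS:
        raise ValueError(f"unknown state {state!r}; choose from {sorted(TIBIA_GREYS)}")
    g = TIBIA_GREYS[state]
    cy, cx = shape[1] / 2, shape[2] / 2
    phases = [Phase("background", Everywhere(), g["background"])]
    phases.append(Phase("soft_tissue", Cylinder((cy, cx), radius=0.42 * shape[1]), g["soft_tissue"]))
    phases.append(Phase("cortex", Cylinder((cy, cx), radius=0.36 * shape[1]), g["cortex"]))
    inner_label = "d2o" if "d2o" in g else "canal"
    phases.append(Phase(inner_label, Cylinder((cy, cx), radius=0.24 * shape[1]), g[inner_label]))
    return PhantomSpec(
        shape=shape,
        phases=tuple(phases),
        blur_sigma=blur_sigma,
        noise_sigma=noise_sigma,
        seed=seed,
    )


def plug_phantom(
    state: str = "soaked",
    shape: tuple[int, int, int] = (72, 96, 96),
    trabecular_fraction: float = 0.25,
    spacing: float = 16.0,
    noise_sigma: float = PLUG_NOISE_SD,
    blur_sigma: float = 5.0,
    n_voids: int = 100,
    void_radius: float = 5.0,
    seed: int = 0,
    greys: dict | None = None,
) -> PhantomSpec:
    """Trabecular-bone-plug phantom: rod-lattice bone in a marrow cylinder.

    Neutron-style grey means by hydration ``state``; pass ``greys`` to
    override (e.g. X-ray-style levels for morphometry, where bone is the
    brightest phase).
    """
    if greys is None:
        if state not in PLUG_GREYS:
            raise ValueError(f"unknown state {state!r}; choose from {sorted(PLUG_GREYS)}")
        greys = PLUG_GREYS[state]
    cy, cx = shape[1] / 2, shape[2] / 2
    region = Cylinder((cy, cx), radius=0.42 * shape[1])
    phases = [
        Phase("background", Everywhere(), greys["background"]),
        Phase("marrow", region, greys["marrow"]),
        Phase(
            "bone",
            RodLattice(region=region, target_fraction=trabecular_fraction, spacing=spacing),
            greys["bone"],
        ),
    ]
    if "void" in greys and n_voids > 0:
        phases.append(
            Phase("void", SphereCloud(region=region, n=n_voids, radius=void_radius), greys["void"])
        )
    return PhantomSpec(
        shape=shape,
        phases=tuple(phases),
        blur_sigma=blur_sigma,
        noise_sigma=noise_sigma,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# 1D edge profiles
# ---------------------------------------------------------------------------

def generate_edge_profile(
    mu: float,
    sigma: float,
    levels: tuple[float, float] = (0.0, 1.0),
    n_points: int = 200,
    noise_sigma: float = 0.0,
    seed: int | None = None,
    x_range: tuple[float, float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample a Gaussian-CDF edge: low + (high-low)·Φ((x−µ)/σ) + noise.

    Returns (abscissa, values).  This is the forward model whose inverse the
    edge-fitting routine estimates; it doubles as the fitting oracle.
    """
    if sigma <= 0:
        raise ValueError("sigma must be strictly positive")
    if n_points < 8:
        raise ValueError("n_points must be >= 8")
    low, high = levels
    if x_range is None:
        x_range = (mu - 8.0 * sigma, mu + 8.0 * sigma)
    x = np.linspace(x_range[0], x_range[1], n_points)
    y = low + (high - low) * ndtr((x - mu) / sigma)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sigma, size=n_points)
    return x, y


# ---------------------------------------------------------------------------
# Compression curves
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Geometry:
    """Cylindrical plug geometry used for stress/strain normalization."""

    diameter_mm: float = 6.0
    height_mm: float = 10.0

    def __post_init__(self):
        if self.diameter_mm <= 0 or self.height_mm <= 0:
            raise ValueError("specimen geometry must be strictly positive")

    @property
    def area_mm2(self) -> float:
        return np.pi * (self.diameter_mm / 2.0) ** 2


@dataclass(frozen=True)
class SyntheticCurveSpec:
    """Compression-curve generator: quadratic BV/TV scaling of E and strength.

    stress model (noise-free): linear elastic ramp of slope E up to
    0.7·σp/E strain, a parabolic cap peaking at σp, then linear softening
    losing ``post_peak_drop``·σp by the terminal strain.
    """

    bvtv: float = 0.25
    modulus_scale: float = 8000.0    # MPa at BV/TV = 1 (E = scale · bvtv²)
    strength_scale: float = 300.0    # MPa at BV/TV = 1 (σp = scale · bvtv²)
    post_peak_drop: float = 0.3      # fraction of peak stress lost after failure
    noise_sigma: float = 0.0         # MPa, added to stress samples
    geometry: Geometry = Geometry()
    displacement_rate_mm_s: float = 1.0
    n_points: int = 500
    seed: int = 0


@dataclass
class CompressionCurve:
    data: pd.DataFrame               # time_s, force_N, displacement_mm
    geometry: Geometry
    truth: dict                      # generator ground truth (MPa, strains)


def _stress_model(strain, E, sigma_p, post_peak_drop, strain_end):
    eps1 = 0.7 * sigma_p / E
    eps_f = 1.3 * sigma_p / E
    a = E / (2.0 * (eps_f - eps1))
    stress = np.where(
        strain <= eps1,
        E * strain,
        np.where(
            strain <= eps_f,
            sigma_p - a * (strain - eps_f) ** 2,
            sigma_p - post_peak_drop * sigma_p * (strain - eps_f) / max(strain_end - eps_f, 1e-12),
        ),
    )
    return stress, eps1, eps_f


def generate_compression_curve(spec: SyntheticCurveSpec) -> CompressionCurve:
    """Simulate one unconfined compression test as a force-displacement log."""
    if not 0 < spec.bvtv <= 1:
        raise ValueError("bvtv must lie in (0, 1]")
    E = spec.modulus_scale * spec.bvtv**2
    sigma_p = spec.strength_scale * spec.bvtv**2
    eps_f = 1.3 * sigma_p / E
    strain_end = 2.0 * eps_f
    strain = np.linspace(0.0, strain_end, spec.n_points)
    stress, eps1, eps_f = _stress_model(
        strain, E, sigma_p, spec.post_peak_drop, strain_end
    )
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        stress = stress + rng.normal(0.0, spec.noise_sigma, size=stress.shape)

    geom = spec.geometry
    displacement = strain * geom.height_mm
    force = stress * geom.area_mm2     # MPa · mm² = N
    time = displacement / spec.displacement_rate_mm_s

    # analytic toughness of the noise-free model up to the peak
    a = E / (2.0 * (eps_f - eps1))
    toughness = 0.5 * E * eps1**2 + sigma_p * (eps_f - eps1) - a * (eps_f - eps1) ** 3 / 3.0
    truth = {
        "modulus_MPa": E,
        "peak_stress_MPa": sigma_p,
        "failure_strain": eps_f,
        "toughness_MJ_m3": toughness,
        "linear_limit_strain": eps1,
        "has_peak": spec.post_peak_drop > 0,
    }
    df = pd.DataFrame(
        {"time_s": time, "force_N": force, "displacement_mm": displacement}
    )
    return CompressionCurve(df, geom, truth)


# ---------------------------------------------------------------------------
# Weight series (drying / rehydration kinetics)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WeightSeriesSpec:
    """Drying + rehydration weight kinetics for one specimen.

    Drying approaches (1 − loss_fraction)·initial_weight exponentially.
    Rehydration regains the lost weight as a two-component exponential
    (fast + slow pool); defaults are calibrated so that ≈48.9% of the lost
    weight is regained 3 h into rehydration and ≈81.9% at 48 h.
    """

    initial_weight: float = 0.5          # g, typical Ø6 × 10 mm plug
    loss_fraction: float = 0.10          # asymptotic drying loss
    drying_rate: float = 1.1689          # 1/h → 97% of the loss within 3 h
    rehydration_fast_fraction: float = 0.4524
    rehydration_fast_rate: float = 3.0       # 1/h
    rehydration_slow_rate: float = 0.02307   # 1/h
    drying_times: tuple[float, ...] = (3.0, 6.0, 9.0, 12.0, 15.0)     # h
    rehydration_times: tuple[float, ...] = tuple(float(t) for t in range(3, 49, 3))
    noise_sigma: float = 0.0             # g
    seed: int = 0

    def __post_init__(self):
        if self.initial_weight <= 0:
            raise ValueError("initial_weight must be positive")
        if not 0.0 <= self.loss_fraction < 1.0:
            raise ValueError("loss_fraction must lie in [0, 1)")
        if any(t < 0 for t in self.drying_times + self.rehydration_times):
            raise ValueError("sampling times must be non-negative")


def _regained_fraction(tau, spec: WeightSeriesSpec):
    a = spec.rehydration_fast_fraction
    return 1.0 - a * np.exp(-spec.rehydration_fast_rate * tau) - (1.0 - a) * np.exp(
        -spec.rehydration_slow_rate * tau
    )


def generate_weight_series(spec: WeightSeriesSpec, specimen: str = "S1") -> pd.DataFrame:
    """One specimen's weight log: columns specimen, time_h, stage, weight_g.

    Stages: ``initial`` (t = 0), ``drying`` samples, ``post-dry`` (last drying
    sample), ``rehydration`` samples (clock restarts after post-dry).
    """
    rng = np.random.default_rng(spec.seed)
    w0 = spec.initial_weight
    rows = [(specimen, 0.0, "initial", w0)]

    def w_dry(t):
        return w0 - w0 * spec.loss_fraction * (1.0 - np.exp(-spec.drying_rate * t))

    d_times = sorted(spec.drying_times)
    for i, t in enumerate(d_times):
        stage = "post-dry" if i == len(d_times) - 1 else "drying"
        rows.append((specimen, t, stage, float(w_dry(t))))

    t_dry_end = d_times[-1] if d_times else 0.0
    w_d = float(w_dry(t_dry_end))
    for tau in sorted(spec.rehydration_times):
        w = w_d + (w0 - w_d) * float(_regained_fraction(tau, spec))
        rows.append((specimen, t_dry_end + tau, "rehydration", w))

    df = pd.DataFrame(rows, columns=["specimen", "time_h", "stage", "weight_g"])
    if spec.noise_sigma > 0:
        df["weight_g"] = df["weight_g"] + rng.normal(0.0, spec.noise_sigma, len(df))
    return df


def generate_weight_cohort(
    n: int,
    base: WeightSeriesSpec | None = None,
    loss_sd: float = 0.029,
    kinetics_jitter: float = 0.2,
    seed: int = 0,
) -> list[pd.DataFrame]:
    """Cohort of weight logs with specimen-to-specimen variation.

    Loss fractions are drawn from N(base.loss_fraction, loss_sd), clipped to
    (0.005, 0.6); drying/rehydration rates and the fast-pool fraction get a
    relative jitter of ``kinetics_jitter`` so that the regained-fraction
    statistics scatter across specimens as real cohorts do.  Each specimen
    gets an independent sub-seed.
    """
    if base is None:
        base = WeightSeriesSpec()
    rng = np.random.default_rng(seed)
    sub_seeds = rng.integers(0, 2**31 - 1, size=n)
    losses = np.clip(rng.normal(base.loss_fraction, loss_sd, size=n), 0.005, 0.6)

    def jit():
        return float(np.clip(rng.normal(1.0, kinetics_jitter), 0.5, 1.5))

    logs = []
    for i in range(n):
        spec_i = WeightSeriesSpec(
            initial_weight=base.initial_weight,
            loss_fraction=float(losses[i]),
            drying_rate=base.drying_rate * jit(),
            rehydration_fast_fraction=float(
                np.clip(base.rehydration_fast_fraction * jit(), 0.1, 0.9)
            ),
            rehydration_fast_rate=base.rehydration_fast_rate * jit(),
            rehydration_slow_rate=base.rehydration_slow_rate * jit(),
            drying_times=base.drying_times,
            rehydration_times=base.rehydration_times,
            noise_sigma=base.noise_sigma,
            seed=int(sub_seeds[i]),
        )
        logs.append(generate_weight_series(spec_i, specimen=f"S{i + 1}"))
    return logs
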