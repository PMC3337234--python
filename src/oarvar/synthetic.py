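"""Synthetic multi-observer contour cohorts with known ground truth.

Truth organs are star-shaped superellipsoids (optionally perturbed by
low-order spherical harmonics).  Each simulated observer applies a
multiplicative radial bias, a systematic shift, and a smooth zero-mean
random surface field built from spherical-harmonic coefficients (bands up
to degree 6), with a region-dependent amplitude.  Surfaces are sliced into
closed polygons on an axial z lattice, mimicking contouring on CT slices.

Everything is deterministic per (config, seed): every structure draws from
its own child generator keyed by (seed, patient, scan, observer, organ).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from functools import lru_cache
from typing import Mapping

import numpy as np

from .contours import ContourSlice, Delineation, DelineationSet, Polygon2D

logger = logging.getLogger(__name__)

ANGULAR_SAMPLES = 64  # polygon vertices per slice
_MIN_RADIUS = 0.5  # mm, clip for noise-driven negative radii


# ---------------------------------------------------------------------------
# real spherical harmonics
# ---------------------------------------------------------------------------


def _complex_sph_harm(l: np.ndarray, m: np.ndarray, theta: np.ndarray, phi: np.ndarray):
    try:
        from scipy.special import sph_harm_y

        return sph_harm_y(l, m, theta, phi)
    except ImportError:  # pragma: no cover - older scipy
        from scipy.special import sph_harm

        return sph_harm(m, l, phi, theta)


def _real_sh_basis(
    ls: np.ndarray, ms: np.ndarray, theta: np.ndarray, phi: np.ndarray
) -> np.ndarray:
    """Real orthonormal SH basis matrix, shape (n_terms, n_points).

    Evaluates each unique (l, |m|) pair once and assembles the real basis
    (cos-type for m > 0, sin-type for m < 0) from real and imaginary parts.
    """
    ls = np.asarray(ls)
    ms = np.asarray(ms)
    absm = np.abs(ms)
    keys = ls * 1000 + absm
    uniq, inverse = np.unique(keys, return_inverse=True)
    y = _complex_sph_harm(
        (uniq // 1000)[:, None], (uniq % 1000)[:, None], theta[None, :], phi[None, :]
    )
    yk = y[inverse]
    m_col = ms[:, None]
    sign = (-1.0) ** m_col
    return np.where(
        m_col == 0,
        np.real(yk),
        np.where(
            m_col > 0,
            np.sqrt(2.0) * sign * np.real(yk),
            np.sqrt(2.0) * sign * np.imag(yk),
        ),
    )


def _real_sph_harm(l: int, m: int, theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Single real orthonormal spherical harmonic; theta polar, phi azimuth."""
    theta = np.asarray(theta, dtype=float)
    phi = np.asarray(phi, dtype=float)
    shape = np.broadcast(theta, phi).shape
    t = np.broadcast_to(theta, shape).ravel()
    p = np.broadcast_to(phi, shape).ravel()
    basis = _real_sh_basis(np.asarray([l]), np.asarray([m]), t, p)
    return basis[0].reshape(shape)


def _band_indices(max_degree: int) -> tuple[np.ndarray, np.ndarray]:
    ls, ms = [], []
    for l in range(1, max_degree + 1):
        for m in range(-l, l + 1):
            ls.append(l)
            ms.append(m)
    return np.asarray(ls), np.asarray(ms)


@lru_cache(maxsize=8)
def _cached_table_basis(
    max_degree: int, n_theta: int, n_phi: int
) -> np.ndarray:
    """SH basis on the fixed (theta-grid x slice azimuths) lattice.

    The lattice is identical for every simulated structure, so the basis is
    computed once per (degree, resolution) and reused; only the random
    coefficients vary per structure.
    """
    ls, ms = _band_indices(max_degree)
    theta_grid = np.linspace(0.0, math.pi, n_theta + 1)
    phi = 2.0 * math.pi * np.arange(n_phi) / n_phi
    TH, PH = np.meshgrid(theta_grid, phi, indexing="ij")
    return _real_sh_basis(ls, ms, TH.ravel(), PH.ravel())


class SmoothAngularField:
    """Zero-mean random field on the sphere with unit pointwise variance.

    Coefficients for degrees 1..max_degree are i.i.d. normal; by the
    addition theorem the pointwise variance is exactly uniform over the
    sphere, so a single scale factor fixes it to 1.
    """

    def __init__(self, rng: np.random.Generator, max_degree: int = 6):
        if max_degree < 1:
            raise ValueError("max_degree must be >= 1")
        self.max_degree = max_degree
        self._l, self._m = _band_indices(max_degree)
        coeff_sd = math.sqrt(4.0 * math.pi / len(self._l))
        self._c = rng.normal(0.0, coeff_sd, size=len(self._l))
        self.coeffs = list(zip(self._l.tolist(), self._m.tolist(), self._c.tolist()))

    def __call__(self, theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
        theta = np.asarray(theta, dtype=float)
        phi = np.asarray(phi, dtype=float)
        shape = np.broadcast(theta, phi).shape
        t = np.broadcast_to(theta, shape).ravel()
        p = np.broadcast_to(phi, shape).ravel()
        basis = _real_sh_basis(self._l, self._m, t, p)
        return (self._c @ basis).reshape(shape)

    def table(self, n_theta: int, n_phi: int) -> np.ndarray:
        """Field values on the cached (theta-grid x azimuth) lattice."""
        basis = _cached_table_basis(self.max_degree, n_theta, n_phi)
        return (self._c @ basis).reshape(n_theta + 1, n_phi)


# ---------------------------------------------------------------------------
# truth shapes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TruthShape:
    """Star-shaped organ template: superellipsoid radii plus SH perturbation."""

    organ: str
    laterality: str
    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]
    exponent: float = 2.0
    sh_coeffs: tuple[tuple[int, int, float], ...] = ()

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.semi_axes):
            raise ValueError(f"semi-axes must be positive, got {self.semi_axes}")
        if self.exponent <= 0:
            raise ValueError("exponent must be positive")

    def radius(self, theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
        """Radial function r(theta, phi) about the centre, mm."""
        theta = np.asarray(theta, dtype=float)
        phi = np.asarray(phi, dtype=float)
        st = np.sin(theta)
        u = np.stack([st * np.cos(phi), st * np.sin(phi), np.cos(theta)], axis=-1)
        e = self.exponent
        a = np.asarray(self.semi_axes)
        r = np.sum(np.abs(u / a) ** e, axis=-1) ** (-1.0 / e)
        if self.sh_coeffs:
            pert = np.zeros_like(r)
            for l, m, c in self.sh_coeffs:
                pert += c * _real_sph_harm(l, m, theta, phi)
            r = r + pert
        if np.any(r <= 0):
            raise ValueError(f"radial function of {self.organ} is not positive")
        return r

    def max_radius_bound(self) -> float:
        return float(max(self.semi_axes) + sum(abs(c) for _, _, c in self.sh_coeffs))


def realize_truth(
    template: TruthShape,
    patient_jitter_sd: float,
    seed: int | np.random.Generator,
) -> TruthShape:
    """Per-patient realization: semi-axes scaled by a common log-normal factor."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if patient_jitter_sd == 0:
        return template
    for attempt in range(10):
        factor = float(np.exp(rng.normal(0.0, patient_jitter_sd)))
        axes = tuple(a * factor for a in template.semi_axes)
        if all(a > 0 for a in axes):
            return replace(template, semi_axes=axes)
        logger.warning("jitter produced non-positive axes, resampling (%d)", attempt)
    raise RuntimeError("could not realize positive semi-axes after 10 retries")


def true_volume_cm3(shape: TruthShape, n_theta: int = 96, n_phi: int = 192) -> float:
    """Quadrature volume of a star-shaped surface: V = (1/3) ∫ r^3 dΩ."""
    nodes, weights = np.polynomial.legendre.leggauss(n_theta)
    theta = np.arccos(nodes)  # nodes are cos(theta)
    phi = 2.0 * math.pi * np.arange(n_phi) / n_phi
    T, P = np.meshgrid(theta, phi, indexing="ij")
    r3 = shape.radius(T, P) ** 3
    dphi = 2.0 * math.pi / n_phi
    integral = float(np.sum(weights[:, None] * r3) * dphi)
    return integral / 3.0 / 1000.0


# ---------------------------------------------------------------------------
# observer model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ObserverModel:
    """Systematic and random deviations of one simulated observer.

    ``volume_bias`` is a multiplicative *radial* scale (volume scales with
    its cube).  ``noise_sd_by_region`` maps region labels to surface-noise
    SDs in mm; the ``"default"`` entry covers unlisted regions.
    ``noise_correlation_scale`` is the angular scale (degrees) of the smooth
    noise field; smaller scale = higher harmonic content (capped at band 6).
    """

    observer_id: str
    volume_bias: float = 1.0
    systematic_shift: tuple[float, float, float] = (0.0, 0.0, 0.0)
    noise_sd_by_region: Mapping[str, float] = None  # type: ignore[assignment]
    noise_correlation_scale: float = 30.0
    cap_cos: float = 0.5  # |cos(theta)| above which a direction is cranial/caudal

    def __post_init__(self) -> None:
        if self.volume_bias <= 0:
            raise ValueError("volume_bias must be positive")
        sds = dict(self.noise_sd_by_region or {"default": 0.0})
        sds.setdefault("default", 0.0)
        if any(v < 0 for v in sds.values()):
            raise ValueError("noise sds must be >= 0")
        object.__setattr__(self, "noise_sd_by_region", sds)

    @property
    def max_degree(self) -> int:
        return int(np.clip(round(180.0 / self.noise_correlation_scale), 1, 6))

    def region_sd(self, theta: np.ndarray, phi: np.ndarray, laterality: str) -> np.ndarray:
        """Noise SD for each surface direction, from the regional map."""
        regions = direction_region(theta, phi, laterality, self.cap_cos)
        sds = self.noise_sd_by_region
        out = np.full(regions.shape, sds["default"], dtype=float)
        for name, value in sds.items():
            if name != "default":
                out[regions == name] = value
        return out


def direction_region(
    theta: np.ndarray, phi: np.ndarray, laterality: str, cap_cos: float = 0.5
) -> np.ndarray:
    """Region label of a surface direction (mirrors the analysis quadrants).

    Cranial/caudal where |cos(theta)| exceeds ``cap_cos``; elsewhere the
    axial quadrant around the centre, with medial facing the midline.
    """
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    phi = np.atleast_1d(np.asarray(phi, dtype=float))
    ct = np.cos(theta)
    ux = np.sin(theta) * np.cos(phi)
    uy = np.sin(theta) * np.sin(phi)
    medial_sign = -1.0 if laterality in ("left", "midline") else 1.0
    out = np.empty(np.broadcast(ct, ux).shape, dtype=object)
    lateral_first = np.abs(ux) >= np.abs(uy)
    out[lateral_first & (medial_sign * ux >= 0)] = "medial"
    out[lateral_first & (medial_sign * ux < 0)] = "lateral"
    out[~lateral_first & (uy < 0)] = "anterior"
    out[~lateral_first & (uy >= 0)] = "posterior"
    out[ct >= cap_cos] = "cranial"
    out[ct <= -cap_cos] = "caudal"
    return out


def simulate_observer(
    truth: TruthShape,
    model: ObserverModel,
    slice_spacing: float,
    seed: int | np.random.Generator,
) -> Delineation:
    """One observer's delineation of one truth shape.

    Surface radius = ``volume_bias * r(theta, phi) + noise``, shifted by the
    systematic shift, then sliced at the global z lattice (multiples of
    ``slice_spacing``) with 64 polygon vertices per slice.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    uses_noise = any(v > 0 for v in model.noise_sd_by_region.values())
    phi = 2.0 * math.pi * np.arange(ANGULAR_SAMPLES) / ANGULAR_SAMPLES

    # The azimuths are fixed, so the (smooth) noise term is precomputed on a
    # dense theta grid per azimuth and linearly interpolated during the
    # slice-radius bisection; direct evaluation per iteration is ~100x slower.
    n_theta = 256
    theta_grid = np.linspace(0.0, math.pi, n_theta + 1)
    if uses_noise:
        noise = SmoothAngularField(rng, model.max_degree)
        TH, PH = np.meshgrid(theta_grid, phi, indexing="ij")
        noise_table = noise.table(n_theta, ANGULAR_SAMPLES) * model.region_sd(
            TH, PH, truth.laterality
        )
    else:
        noise_table = np.zeros((n_theta + 1, ANGULAR_SAMPLES))
    cols = np.arange(ANGULAR_SAMPLES)
    clip_count = 0

    def radius(theta: np.ndarray) -> np.ndarray:
        """Observer surface radius at (theta[j], phi[j]) per azimuth j."""
        nonlocal clip_count
        r = model.volume_bias * truth.radius(theta, phi)
        x = theta / math.pi * n_theta
        i0 = np.clip(np.floor(x).astype(int), 0, n_theta - 1)
        w = x - i0
        r = r + noise_table[i0, cols] * (1.0 - w) + noise_table[i0 + 1, cols] * w
        clip_count += int(np.count_nonzero(r < _MIN_RADIUS))
        return np.maximum(r, _MIN_RADIUS)

    cx, cy, cz = (c + s for c, s in zip(truth.center, model.systematic_shift))
    r_bound = model.volume_bias * truth.max_radius_bound() + float(
        np.abs(noise_table).max()
    )
    k_lo = math.floor((cz - r_bound) / slice_spacing)
    k_hi = math.ceil((cz + r_bound) / slice_spacing)

    slices = []
    for k in range(k_lo, k_hi + 1):
        z = k * slice_spacing
        dz = z - cz
        pole_idx = 0 if dz >= 0 else n_theta
        r_pole = (
            model.volume_bias
            * float(truth.radius(np.asarray(theta_grid[pole_idx]), np.asarray(0.0)))
            + float(noise_table[pole_idx].mean())
        )
        if abs(dz) >= r_pole - 1e-6:
            continue
        rho = _solve_slice_radii(radius, dz, phi, r_bound)
        verts = tuple(
            (cx + r * math.cos(p), cy + r * math.sin(p))
            for r, p in zip(rho, phi)
        )
        slices.append(ContourSlice(z=z, polygons=(Polygon2D(verts),)))
    if clip_count:
        logger.warning(
            "%s/%s: noise drove %d radius samples below %.1f mm; clipped",
            truth.organ, model.observer_id, clip_count, _MIN_RADIUS,
        )

    return Delineation(
        patient_id="",
        scan_time="plan",
        observer_id=model.observer_id,
        organ=truth.organ,
        laterality=truth.laterality,
        slice_spacing=slice_spacing,
        slices=tuple(slices),
    )


def _solve_slice_radii(radius, dz: float, phi: np.ndarray, rho_hi: float) -> np.ndarray:
    """Vectorized bisection for the in-plane radii of one z slice.

    Solves sqrt(rho^2 + dz^2) = R(theta(rho), phi) per azimuth; the root is
    unique for star-shaped surfaces and stable for small smooth noise.
    """
    lo = np.zeros_like(phi)
    hi = np.full_like(phi, rho_hi + 1.0)
    for _ in range(26):
        mid = 0.5 * (lo + hi)
        theta = np.arctan2(mid, dz)
        g = np.sqrt(mid**2 + dz**2) - radius(theta)
        lo = np.where(g < 0, mid, lo)
        hi = np.where(g < 0, hi, mid)
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortConfig:
    n_patients: int
    observers: tuple[ObserverModel, ...]
    organs: tuple[TruthShape, ...]
    scan_times: tuple[str, ...] = ("plan", "rep")
    size_jitter_sd: float = 0.1
    slice_spacing: float = 2.0
    seed: int = 0
    exclusions: tuple[tuple[str, str], ...] = ()  # (patient_id, organ)

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("need >= 2 patients")
        if len(self.observers) < 2:
            raise ValueError("need >= 2 observers")

    def patient_ids(self) -> list[str]:
        return [f"p{i + 1:02d}" for i in range(self.n_patients)]


@dataclass(frozen=True)
class GroundTruth:
    """Injected simulation parameters for recovery tests."""

    seed: int
    true_volumes: dict[tuple[str, str], float]  # (patient, organ) -> cm^3
    observer_bias: dict[str, float]
    observer_shift: dict[str, tuple[float, float, float]]
    observer_noise_sd: dict[str, dict[str, float]]
    log_variance_components: dict[str, dict[str, float]]  # organ -> components
    analytic_icc: dict[str, float]


def _noise_volume_variance(
    truth: TruthShape, model: ObserverModel, n_theta: int = 48, n_phi: int = 96
) -> float:
    """Var(log V) induced by one observer's surface noise (first order).

    dV = ∫ s(u) f(u) r^2 dΩ with f a random SH series; the variance is the
    coefficient variance times the sum of squared projections of s * r^2
    onto each harmonic, evaluated by quadrature.
    """
    if not any(v > 0 for v in model.noise_sd_by_region.values()):
        return 0.0
    nodes, weights = np.polynomial.legendre.leggauss(n_theta)
    theta = np.arccos(nodes)
    phi = 2.0 * math.pi * np.arange(n_phi) / n_phi
    T, P = np.meshgrid(theta, phi, indexing="ij")
    W = weights[:, None] * (2.0 * math.pi / n_phi)
    r2 = truth.radius(T, P) ** 2
    s = model.region_sd(T, P, truth.laterality)
    ls, ms = _band_indices(model.max_degree)
    coeff_var = 4.0 * math.pi / len(ls)
    basis = _real_sh_basis(ls, ms, T.ravel(), P.ravel())
    proj = basis @ (W * s * r2).ravel()
    var_dv = coeff_var * float(np.sum(proj**2))
    v_mm3 = true_volume_cm3(truth, n_theta, n_phi) * 1000.0
    return var_dv / v_mm3**2


def analytic_ground_truth(
    config: CohortConfig, truths: dict[tuple[str, str], TruthShape]
) -> GroundTruth:
    """Ground-truth record with the log-scale variance decomposition.

    On the log-volume scale the injected components are
    sigma2_patient = 9 * jitter_sd^2 (a common radial factor cubes into the
    volume), sigma2_observer = sample variance of 3*log(bias), and the
    residual is the noise-induced volume variance averaged over structures.
    The analytic ICC is their patient share; the pipeline estimates it from
    raw volumes, which agrees to first order for small variances.
    """
    biases = {m.observer_id: m.volume_bias for m in config.observers}
    log_effects = 3.0 * np.log(np.asarray(list(biases.values())))
    s2_obs = float(np.var(log_effects, ddof=1))
    s2_pat = 9.0 * config.size_jitter_sd**2

    organs = {t.organ: t for t in config.organs}
    components: dict[str, dict[str, float]] = {}
    icc: dict[str, float] = {}
    for organ, template in organs.items():
        res = float(
            np.mean([_noise_volume_variance(template, m) for m in config.observers])
        )
        comp = {
            "sigma2_patient": s2_pat,
            "sigma2_observer": s2_obs,
            "sigma2_residual": res,
        }
        total = s2_pat + s2_obs + res
        components[organ] = comp
        icc[organ] = s2_pat / total if total > 0 else 0.0

    return GroundTruth(
        seed=config.seed,
        true_volumes={k: true_volume_cm3(t) for k, t in truths.items()},
        observer_bias=biases,
        observer_shift={m.observer_id: m.systematic_shift for m in config.observers},
        observer_noise_sd={m.observer_id: dict(m.noise_sd_by_region) for m in config.observers},
        log_variance_components=components,
        analytic_icc=icc,
    )


def generate_cohort(config: CohortConfig) -> tuple[DelineationSet, GroundTruth]:
    """Full factorial patients x scans x observers x organs, minus exclusions."""
    excluded = set(config.exclusions)
    patients = config.patient_ids()
    organ_index = {t.organ: i for i, t in enumerate(config.organs)}

    truths: dict[tuple[str, str], TruthShape] = {}
    delins = []
    for ip, pid in enumerate(patients):
        for template in config.organs:
            rng = np.random.default_rng([config.seed, 1, ip, organ_index[template.organ]])
            truths[(pid, template.organ)] = realize_truth(
                template, config.size_jitter_sd, rng
            )
    for ip, pid in enumerate(patients):
        for it, scan_time in enumerate(config.scan_times):
            for io, model in enumerate(config.observers):
                for template in config.organs:
                    organ = template.organ
                    if (pid, organ) in excluded:
                        continue
                    rng = np.random.default_rng(
                        [config.seed, 2, ip, it, io, organ_index[organ]]
                    )
                    d = simulate_observer(
                        truths[(pid, organ)], model, config.slice_spacing, rng
                    )
                    delins.append(
                        replace(d, patient_id=pid, scan_time=scan_time)
                    )

    metadata = {
        "generator": "oarvar.synthetic",
        "seed": config.seed,
        "n_patients": config.n_patients,
        "scan_times": list(config.scan_times),
        "observers": [m.observer_id for m in config.observers],
        "organs": [t.organ for t in config.organs],
        "excluded": [list(e) for e in config.exclusions],
        "slice_spacing_mm": config.slice_spacing,
    }
    return (
        DelineationSet(delins, metadata),
        analytic_ground_truth(config, truths),
    )


# ---------------------------------------------------------------------------
# default study-like cohort
# ---------------------------------------------------------------------------


def default_observers(noise_scale: float = 1.0) -> tuple[ObserverModel, ...]:
    """Five observers with mild biases, shifts and regional noise."""
    regional = lambda s: {  # noqa: E731
        "default": 1.0 * s, "cranial": 2.2 * s, "caudal": 1.8 * s, "medial": 1.4 * s,
    }
    return (
        ObserverModel("obs1", 0.97, (0.5, 0.0, 0.0), regional(noise_scale)),
        ObserverModel("obs2", 0.99, (0.0, -0.5, 0.0), regional(noise_scale)),
        ObserverModel("obs3", 1.00, (0.0, 0.0, 0.0), regional(noise_scale)),
        ObserverModel("obs4", 1.01, (-0.5, 0.5, 0.0), regional(noise_scale)),
        ObserverModel("obs5", 1.03, (0.0, 0.0, 1.0), regional(noise_scale)),
    )


def default_organs() -> tuple[TruthShape, ...]:
    """Seven star-shaped stand-ins for the studied head-and-neck structures."""
    return (
        TruthShape("spinal_cord", "midline", (0.0, 60.0, -20.0), (5.5, 5.5, 90.0), 4.0),
        TruthShape("parotid_left", "left", (48.0, 10.0, 40.0), (14.0, 18.0, 25.0)),
        TruthShape("parotid_right", "right", (-48.0, 10.0, 40.0), (15.0, 17.0, 26.0)),
        TruthShape("submandibular_left", "left", (25.0, -10.0, 10.0), (11.0, 13.0, 16.0)),
        TruthShape("submandibular_right", "right", (-25.0, -10.0, 10.0), (11.0, 14.0, 15.0)),
        TruthShape("thyroid_cartilage", "midline", (0.0, -40.0, -10.0), (16.0, 14.0, 12.0), 3.0),
        TruthShape("glottic_larynx", "midline", (0.0, -45.0, -25.0), (13.0, 12.0, 9.0)),
    )


def default_cohort_config(seed: int = 0, noise_scale: float = 1.0) -> CohortConfig:
    """The study-like 5 observers x 6 patients x 2 scans x 7 organs design.

    One organ of one patient is excluded on both scans (all observers),
    yielding 410 structures.
    """
    return CohortConfig(
        n_patients=6,
        observers=default_observers(noise_scale),
        organs=default_organs(),
        size_jitter_sd=0.1,
        slice_spacing=2.0,
        seed=seed,
        exclusions=(("p04", "parotid_right"),),
    )
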