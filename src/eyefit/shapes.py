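"""Ground-truth test eye geometries.

Six retinal shapes are used to exercise the adaptive model: three regular
ellipsoidal eyes (emmetropic, myopic, hyperopic) and three pathological
variants (pointed posterior, retinal detachment, staphyloma). Regular
shapes are axis-aligned ellipsoids whose full diameters follow the
per-diopter growth rates of axial refractive error: width 0.14, height
0.10 and length 0.30 mm per diopter (growth for myopia, shrinkage for
hyperopia). Pathological shapes start from the -12 D highly myopic
ellipsoid, since high myopia is the main risk factor for detachment,
staphyloma and posterior pointing.

Every shape is star-shaped about the eye center, so it is represented by
its radial function R(u) over unit directions u; the implicit function is
``f(p) = |p| - R(p/|p|)`` (negative inside). Meshes are built by radially
displacing a subdivided icosphere, which places vertices exactly on the
surface and keeps the mesh watertight until it is half-cropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh

from .geometry import EllipsoidParams

__all__ = [
    "REFRACTION_RATES_MM_PER_DIOPTER",
    "PATHOLOGY_DIOPTERS",
    "EyeShapeSpec",
    "EyeShapeSurface",
    "apply_refraction_scaling",
    "build_shape",
    "lower_half",
    "default_specs",
    "SHAPE_NAMES",
]

# full-diameter growth per diopter of myopia (width, height, length)
REFRACTION_RATES_MM_PER_DIOPTER = np.array([0.14, 0.10, 0.30])

#: refractive error assumed for all pathological shapes
PATHOLOGY_DIOPTERS = -12.0

#: emmetropic full diameters (width, height, length) mm. The emmetropic
#: globe is oblate (length smallest), consistent with MRI morphometry of
#: the retinal surface; with the per-diopter rates this ordering makes the
#: -12 D myopic eye nearly spherical and the +6 D hyperopic eye the most
#: oblate of the three regular shapes.
DEFAULT_BASE_DIMENSIONS = (23.5, 23.0, 21.0)

SHAPE_NAMES = ("emmetropic", "myopic", "hyperopic", "pointed", "detached", "staphyloma")


@dataclass(frozen=True)
class EyeShapeSpec:
    """Parameters generating one test eye shape.

    ``base_dimensions`` are emmetropic full diameters (width, height,
    length) in mm; ``diopters`` is the signed refractive error applied to
    them; ``pathology_params`` holds the shape-specific knobs (amplitudes
    in mm, angles in degrees).
    """

    name: str
    base_dimensions: tuple = DEFAULT_BASE_DIMENSIONS
    diopters: float = 0.0
    pathology_params: dict = field(default_factory=dict)

    def __post_init__(self):
        dims = np.asarray(self.base_dimensions, dtype=float)
        if dims.shape != (3,) or np.any(dims < 15.0) or np.any(dims > 40.0):
            raise ValueError("base dimensions must be three diameters in [15, 40] mm")
        if any(v < 0 for v in self.pathology_params.values() if np.isscalar(v)):
            raise ValueError("pathology amplitudes must be non-negative")

    @property
    def scaled_dimensions(self) -> np.ndarray:
        return apply_refraction_scaling(self.base_dimensions, self.diopters)

    @property
    def semi_axes(self) -> np.ndarray:
        return self.scaled_dimensions / 2.0


def apply_refraction_scaling(base, diopters: float) -> np.ndarray:
    """Scale (width, height, length) diameters by the signed refractive error.

    Myopia (negative diopters) enlarges the globe at the stated mm/diopter
    rates, most strongly in length; hyperopia shrinks it at the same rates.
    """
    dims = np.asarray(base, dtype=float) - REFRACTION_RATES_MM_PER_DIOPTER * diopters
    if np.any(dims <= 0):
        raise ValueError("refraction scaling produced a non-positive dimension")
    return dims


class EyeShapeSurface:
    """A test eye: radial function + implicit + triangle mesh.

    ``radial(dirs)`` returns the distance from the eye center to the
    surface along unit directions; ``implicit(points)`` is negative
    inside. ``ellipsoid`` is set when the shape is exactly an ellipsoid.
    """

    def __init__(self, spec: EyeShapeSpec, radial_fn, ellipsoid: EllipsoidParams | None = None,
                 base_ellipsoid: EllipsoidParams | None = None, mesh: trimesh.Trimesh | None = None,
                 subdivisions: int = 5):
        self.spec = spec
        self._radial_fn = radial_fn
        self.ellipsoid = ellipsoid
        self.base_ellipsoid = base_ellipsoid if base_ellipsoid is not None else ellipsoid
        self._mesh = mesh
        self._subdivisions = subdivisions

    def radial(self, dirs: np.ndarray) -> np.ndarray:
        dirs = np.atleast_2d(np.asarray(dirs, dtype=float))
        return self._radial_fn(dirs)

    def implicit(self, points: np.ndarray) -> np.ndarray:
        """Signed value |p| - R(p/|p|); negative inside the eye."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        rho = np.linalg.norm(pts, axis=1)
        safe = np.maximum(rho, 1e-12)
        dirs = pts / safe[:, None]
        dirs[rho < 1e-12] = (0.0, 0.0, 1.0)
        vals = rho - self.radial(dirs)
        return vals if np.asarray(points).ndim == 2 else vals[0]

    @property
    def anterior_pole(self) -> np.ndarray:
        """The surface point on the +z (anterior) visual axis."""
        r = float(self.radial(np.array([[0.0, 0.0, 1.0]]))[0])
        return np.array([0.0, 0.0, r])

    def sample(self, n_u: int, n_v: int, crop_depth: float = 0.0) -> np.ndarray:
        """Radial (theta, phi) grid sampling with anterior cropping."""
        theta = np.linspace(0.0, np.pi, n_u)
        phi = np.linspace(0.0, 2.0 * np.pi, n_v, endpoint=False)
        tt, pp = np.meshgrid(theta, phi, indexing="ij")
        st = np.sin(tt)
        dirs = np.column_stack(
            [(st * np.cos(pp)).ravel(), (st * np.sin(pp)).ravel(), np.cos(tt).ravel()]
        )
        pts = dirs * self.radial(dirs)[:, None]
        z_max = pts[:, 2].max()
        keep = pts[:, 2] <= z_max - crop_depth + 1e-12
        if not np.any(keep):
            raise ValueError("crop removed every sampled point")
        return pts[keep]

    @property
    def mesh(self) -> trimesh.Trimesh:
        if self._mesh is None:
            ico = trimesh.creation.icosphere(subdivisions=self._subdivisions)
            dirs = np.asarray(ico.vertices)
            dirs = dirs / np.linalg.norm(dirs, axis=1)[:, None]
            verts = dirs * self.radial(dirs)[:, None]
            self._mesh = trimesh.Trimesh(vertices=verts, faces=ico.faces, process=False)
        return self._mesh

    def lower_half(self) -> "EyeShapeSurface":
        """Clip the mesh at the coronal plane z = 0, keeping the posterior
        half (the printed-phantom geometry)."""
        clipped = trimesh.intersections.slice_mesh_plane(
            self.mesh, plane_normal=[0.0, 0.0, -1.0], plane_origin=[0.0, 0.0, 0.0]
        )
        return EyeShapeSurface(
            self.spec, self._radial_fn, ellipsoid=self.ellipsoid,
            base_ellipsoid=self.base_ellipsoid, mesh=clipped,
        )


def lower_half(surface: EyeShapeSurface) -> EyeShapeSurface:
    """Functional alias for :meth:`EyeShapeSurface.lower_half`."""
    return surface.lower_half()


def _ellipsoid_radial(semi: np.ndarray):
    def radial(dirs):
        return 1.0 / np.sqrt(((dirs / semi) ** 2).sum(axis=1))

    return radial


def _angle_from(dirs: np.ndarray, axis: np.ndarray) -> np.ndarray:
    return np.arccos(np.clip(dirs @ axis, -1.0, 1.0))


def _mollifier(psi: np.ndarray, half_angle: float) -> np.ndarray:
    """Smooth bump: 1 at psi=0, exactly 0 for psi >= half_angle."""
    out = np.zeros_like(psi)
    inside = psi < half_angle
    x2 = (psi[inside] / half_angle) ** 2
    out[inside] = np.exp(1.0 - 1.0 / (1.0 - x2))
    return out


def _build_regular(spec: EyeShapeSpec) -> EyeShapeSurface:
    semi = spec.semi_axes
    ell = EllipsoidParams(semi, np.eye(3), np.zeros(3))
    return EyeShapeSurface(spec, _ellipsoid_radial(semi), ellipsoid=ell)


def _build_pointed(spec: EyeShapeSpec) -> EyeShapeSurface:
    """Posterior paraboloid cap joined tangentially to the myopic ellipsoid.

    The cap's apex extends ``apex_extension`` mm beyond the ellipsoid pole;
    the junction ring (where depth and slope match, making the composite
    C1) follows from the apex depth. With normalized transverse radius
    s^2 = (x/a)^2 + (y/b)^2 the cap is z = -(A - B s^2).
    """
    a, b, c = spec.semi_axes
    apex = c + float(spec.pathology_params.get("apex_extension", 1.2))
    # tangency: B = c/(2 sqrt(1-s_j^2)), A = c (1 - s_j^2/2)/sqrt(1-s_j^2)
    kap = apex / c
    # with t = sqrt(1 - s_j^2): kap = (1 + t^2)/(2 t)  =>  t = kap - sqrt(kap^2 - 1)
    t = kap - np.sqrt(kap**2 - 1.0) if kap > 1.0 else 1.0
    s_j2 = 1.0 - t**2
    B = c / (2.0 * t)
    ell_radial = _ellipsoid_radial(spec.semi_axes)

    def radial(dirs):
        r = ell_radial(dirs)
        u = dirs
        k = (u[:, 0] / a) ** 2 + (u[:, 1] / b) ** 2
        uz = u[:, 2]
        in_cap = (uz < 0.0) & ((r**2) * k < s_j2)
        if np.any(in_cap):
            kc, uzc = k[in_cap], uz[in_cap]
            # ray t*u meets the paraboloid z = -(A - B s^2)
            with np.errstate(divide="ignore", invalid="ignore"):
                tc = (uzc + np.sqrt(uzc**2 + 4.0 * apex * B * kc)) / (2.0 * B * kc)
            tc = np.where(kc < 1e-14, -apex / uzc, tc)
            r[in_cap] = tc
        return r

    base = EllipsoidParams(spec.semi_axes, np.eye(3), np.zeros(3))
    return EyeShapeSurface(spec, radial, base_ellipsoid=base)


def _build_staphyloma(spec: EyeShapeSpec) -> EyeShapeSurface:
    amp = float(spec.pathology_params.get("amplitude", 1.0))
    half = np.deg2rad(float(spec.pathology_params.get("support_deg", 45.0)))
    axis = np.array([0.0, 0.0, -1.0])
    ell_radial = _ellipsoid_radial(spec.semi_axes)

    def radial(dirs):
        psi = _angle_from(dirs, axis)
        return ell_radial(dirs) + amp * _mollifier(psi, half)

    base = EllipsoidParams(spec.semi_axes, np.eye(3), np.zeros(3))
    return EyeShapeSurface(spec, radial, base_ellipsoid=base)


def _build_detached(spec: EyeShapeSpec) -> EyeShapeSurface:
    depth = float(spec.pathology_params.get("depth", 0.3))
    half = np.deg2rad(float(spec.pathology_params.get("radius_deg", 20.0)))
    off = np.deg2rad(float(spec.pathology_params.get("offset_deg", 30.0)))
    axis = np.array([np.sin(off), 0.0, -np.cos(off)])
    ell_radial = _ellipsoid_radial(spec.semi_axes)

    def radial(dirs):
        psi = _angle_from(dirs, axis)
        dome = np.zeros_like(psi)
        inside = psi < half
        dome[inside] = depth * np.cos(0.5 * np.pi * psi[inside] / half) ** 2
        return ell_radial(dirs) - dome

    base = EllipsoidParams(spec.semi_axes, np.eye(3), np.zeros(3))
    return EyeShapeSurface(spec, radial, base_ellipsoid=base)


_BUILDERS = {
    "emmetropic": _build_regular,
    "myopic": _build_regular,
    "hyperopic": _build_regular,
    "pointed": _build_pointed,
    "detached": _build_detached,
    "staphyloma": _build_staphyloma,
}


def default_specs(base_dimensions=DEFAULT_BASE_DIMENSIONS) -> dict:
    """The six named shape presets used throughout the experiments."""
    return {
        "emmetropic": EyeShapeSpec("emmetropic", base_dimensions, 0.0),
        "myopic": EyeShapeSpec("myopic", base_dimensions, PATHOLOGY_DIOPTERS),
        "hyperopic": EyeShapeSpec("hyperopic", base_dimensions, +6.0),
        "pointed": EyeShapeSpec("pointed", base_dimensions, PATHOLOGY_DIOPTERS),
        "detached": EyeShapeSpec("detached", base_dimensions, PATHOLOGY_DIOPTERS),
        "staphyloma": EyeShapeSpec("staphyloma", base_dimensions, PATHOLOGY_DIOPTERS),
    }


def build_shape(spec: EyeShapeSpec) -> EyeShapeSurface:
    """Construct the ground-truth surface for a shape specification."""
    try:
        builder = _BUILDERS[spec.name]
    except KeyError:
        raise ValueError(f"unknown shape name {spec.name!r}") from None
    return builder(spec)
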