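"""Parametric choanocyte-chamber geometry.

The model chamber is a rigid sphere of radius ``R`` (in units of the
flagellar length ``L``) with

* a single large outlet, the *apopyle*: a spherical cap of half-opening
  angle ``theta_a`` about the +z axis, removed from the wall (the cap
  triangles are retained separately as a flux-integration surface, not a
  no-slip boundary);
* many tiny inlets, *prosopyles*: small patches carved out of the wall so
  the open-area fraction is about 1e-3 of the full sphere;
* a concentric *reticulum* shell at radius ``R`` minus the collar length
  (8.2 um, converted with the physical flagellar length), perforated by one
  circular aperture per flagellum so the flagella pass through;
* a *cone-cell* ring: a conical frustum joining the reticulum rim to the
  wall rim at the apopyle, which blocks backflow around the outlet.

Flagellar bases sit on a deterministic Fibonacci spiral restricted to the
spherical zone outside the apopyle cap; beat-plane rotations and phases are
the only seeded randomness, so ensemble members share one lattice.

Lengths are in units of ``L``; the apopyle axis is +z and polar angles are
measured from it.  Triangles derived from a sphere carry their exact
spherical patch area (solid angle times radius squared), so zone areas and
flux closure are exact regardless of mesh resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh

__all__ = [
    "ChamberSpec",
    "SurfaceMesh",
    "FlagellumLayout",
    "REGIONS",
    "fibonacci_zone_points",
    "build_chamber_mesh",
    "place_flagella",
]

REGIONS = {"wall": 0, "reticulum": 1, "cone": 2, "apopyle_surface": 3}
_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


@dataclass(frozen=True)
class ChamberSpec:
    """Chamber parameters in units of the flagellar length L."""

    radius: float = 1.5
    theta_a_deg: float = 30.0
    n_flagella: int = 143
    amplitude: float = 0.14
    prosopyle_area_fraction: float = 1e-3  # per-prosopyle area / 4 pi R^2
    max_prosopyles: int | None = None  # optional hard cap on the count
    prosopyle_spacing: float = 0.4  # min centre spacing, units of L (~ one cell body)
    reticulum_offset_um: float = 8.2
    flagellum_length_um: float = 13.0
    cone_present: bool = True
    subdivisions: int = 2
    reticulum_subdivisions: int | None = None
    aperture_radius_factor: float = 1.2  # reticulum aperture radius, units of A
    cone_segments: int = 24

    def __post_init__(self):
        if not 0.0 < self.theta_a_deg <= 90.0:
            raise ValueError("theta_a must lie in (0, 90] degrees")
        if self.radius <= 1.0:
            raise ValueError("chamber radius must exceed the flagellar length")
        if self.n_flagella < 1:
            raise ValueError("need at least one flagellum")
        if self.reticulum_radius <= 0.0:
            raise ValueError(
                "chamber too small for the collar length: reticulum radius "
                f"{self.reticulum_radius:.3f} <= 0"
            )
        if self.subdivisions < 2:
            raise ValueError("subdivisions < 2 is too coarse to carve prosopyles")

    @property
    def theta_a(self):
        return np.radians(self.theta_a_deg)

    @property
    def reticulum_radius(self):
        """Reticulum shell radius in units of L (collar length below the wall)."""
        return self.radius - self.reticulum_offset_um / self.flagellum_length_um

    @property
    def available_area(self):
        """Wall area outside the apopyle cap, 2 pi R^2 (1 + cos theta_a)."""
        return 2.0 * np.pi * self.radius**2 * (1.0 + np.cos(self.theta_a))


@dataclass
class SurfaceMesh:
    """Triangle soup with region labels and exact per-triangle areas."""

    vertices: np.ndarray  # (V, 3)
    triangles: np.ndarray  # (F, 3) int
    region: np.ndarray  # (F,) int, values of REGIONS
    areas: np.ndarray  # (F,)
    normals: np.ndarray  # (F, 3) outward unit normals
    prosopyle_area: float = 0.0
    prosopyle_centers: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))

    @property
    def centroids(self):
        return self.vertices[self.triangles].mean(axis=1)

    def region_mask(self, name):
        return self.region == REGIONS[name]

    @property
    def noslip_mask(self):
        return self.region != REGIONS["apopyle_surface"]

    def area_of(self, name):
        return float(self.areas[self.region_mask(name)].sum())

    def export_vtk(self, path):
        """Write the labelled mesh as a legacy-ASCII VTK PolyData file."""
        v, f = self.vertices, self.triangles
        with open(path, "w") as fh:
            fh.write("# vtk DataFile Version 3.0\nchoanopump surface mesh\nASCII\n")
            fh.write("DATASET POLYDATA\n")
            fh.write(f"POINTS {len(v)} double\n")
            for p in v:
                fh.write(f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}\n")
            fh.write(f"POLYGONS {len(f)} {4 * len(f)}\n")
            for tri in f:
                fh.write(f"3 {tri[0]} {tri[1]} {tri[2]}\n")
            fh.write(f"CELL_DATA {len(f)}\nSCALARS region int 1\nLOOKUP_TABLE default\n")
            fh.write("\n".join(str(int(r)) for r in self.region) + "\n")

    def export_obj(self, path):
        trimesh.Trimesh(self.vertices, self.triangles, process=False).export(path)


@dataclass
class FlagellumLayout:
    """Base lattice plus seeded beat-plane angles and phases."""

    base_points: np.ndarray  # (N, 3)
    radial_axes: np.ndarray  # (N, 3) inward unit vectors
    psi: np.ndarray  # (N,) beat-plane rotations
    phases: np.ndarray  # (N,)
    seed: int

    @property
    def n(self):
        return len(self.base_points)

    def beat_directions(self):
        """Unit vector of the lateral beat direction for each flagellum."""
        out = np.empty_like(self.radial_axes)
        for i, axis in enumerate(self.radial_axes):
            t1, t2 = _tangent_frame(axis)
            out[i] = np.cos(self.psi[i]) * t1 + np.sin(self.psi[i]) * t2
        return out


def _tangent_frame(axis):
    ref = np.array([0.0, 0.0, 1.0])
    if abs(axis @ ref) > 0.99:
        ref = np.array([1.0, 0.0, 0.0])
    t1 = np.cross(axis, ref)
    t1 /= np.linalg.norm(t1)
    t2 = np.cross(axis, t1)
    return t1, t2


def fibonacci_zone_points(n, theta_min):
    """n quasi-uniform unit vectors with polar angle in (theta_min, pi].

    Deterministic golden-angle spiral on the zone z in [-1, cos(theta_min));
    the half-step offset keeps every point strictly outside the cap.  A
    single point sits at the pole opposite the cap (symmetry convention).
    """
    if n == 1:
        return np.array([[0.0, 0.0, -1.0]])
    z_max = np.cos(theta_min)
    i = np.arange(n)
    z = z_max - (i + 0.5) * (z_max + 1.0) / n
    rho = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
    az = i * _GOLDEN_ANGLE
    return np.column_stack([rho * np.cos(az), rho * np.sin(az), z])


def place_flagella(spec: ChamberSpec, seed=0, safety=0.75) -> FlagellumLayout:
    """Seeded flagellum placement on the chamber wall.

    The base lattice is deterministic (Fibonacci spiral on the available
    zone); only the beat-plane rotations ``psi`` and phases are drawn from
    the seeded generator, so ensemble realisations share one lattice.
    Raises when the bases are overpacked, i.e. the minimum pairwise spacing
    falls below ``2 A * safety`` (beat envelopes would interpenetrate badly).
    """
    dirs = fibonacci_zone_points(spec.n_flagella, spec.theta_a)
    base = spec.radius * dirs
    if spec.n_flagella > 1:
        d2 = np.sum((base[:, None, :] - base[None, :, :]) ** 2, axis=-1)
        np.fill_diagonal(d2, np.inf)
        min_spacing = np.sqrt(d2.min())
        if min_spacing < 2.0 * spec.amplitude * safety:
            raise ValueError(
                f"overpacked: {spec.n_flagella} flagella give base spacing "
                f"{min_spacing:.3f} < {2 * spec.amplitude * safety:.3f}"
            )
    rng = np.random.default_rng(seed)
    psi = rng.uniform(0.0, 2.0 * np.pi, spec.n_flagella)
    phases = rng.uniform(0.0, 2.0 * np.pi, spec.n_flagella)
    return FlagellumLayout(base, -dirs, psi, phases, seed)


def _spherical_areas(vertices, faces, radius):
    """Exact spherical patch area per face (Van Oosterom-Strackee)."""
    tri = vertices[faces] / radius  # unit sphere
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    num = np.abs(np.einsum("ij,ij->i", a, np.cross(b, c)))
    den = 1.0 + np.einsum("ij,ij->i", a, b) + np.einsum("ij,ij->i", b, c) + np.einsum("ij,ij->i", c, a)
    omega = 2.0 * np.arctan2(num, den)
    return omega * radius**2


def _polar_of(points):
    r = np.linalg.norm(points, axis=-1)
    return np.arccos(np.clip(points[..., 2] / r, -1.0, 1.0))


def _split_by_polar(verts, faces, theta, depth=3):
    """Partition unit-sphere faces at the cone ``polar = theta``.

    Faces straddling the rim are subdivided up to ``depth`` times (new
    vertices appended to ``verts``, projected to the sphere) so the cap
    boundary is resolved well below one element size; subtrees that end up
    entirely on one side coalesce back to their parent triangle.  Returns
    (outside, inside) face lists, where outside means polar angle > theta.
    """

    def midpoint(i, j):
        m = verts[i] + verts[j]
        m /= np.linalg.norm(m)
        verts.append(m)
        return len(verts) - 1

    def classify(face, d):
        """List of (side, face) leaves, coalesced when single-sided."""
        vp = _polar_of(np.asarray([verts[i] for i in face]))
        if np.all(vp > theta):
            return [(True, face)]
        if np.all(vp < theta):
            return [(False, face)]
        if d == 0:
            cen = np.mean([verts[i] for i in face], axis=0)
            side = _polar_of(cen / np.linalg.norm(cen)) > theta
            return [(bool(side), face)]
        i, j, k = face
        ij, jk, ki = midpoint(i, j), midpoint(j, k), midpoint(k, i)
        leaves = []
        for child in ((i, ij, ki), (ij, j, jk), (ki, jk, k), (ij, jk, ki)):
            leaves.extend(classify(child, d - 1))
        sides = {s for s, _ in leaves}
        if len(sides) == 1:
            return [(sides.pop(), face)]
        return leaves

    outside, inside = [], []
    for face in faces:
        for side, leaf in classify(tuple(face), depth):
            (outside if side else inside).append(tuple(leaf))
    return outside, inside


def _subdivide_carve(verts, face, depth):
    """Split a spherical triangle, carving one small central child.

    Keeps the three corner children at each level and recurses into the
    middle child; at full depth the middle child is dropped (the prosopyle).
    Returns (kept_faces, carved_face) as vertex-index triples; new vertices
    are appended to ``verts`` (a list) on the unit sphere.
    """
    kept = []

    def midpoint(i, j):
        m = verts[i] + verts[j]
        m = m / np.linalg.norm(m)
        verts.append(m)
        return len(verts) - 1

    def recurse(tri, d):
        i, j, k = tri
        ij, jk, ki = midpoint(i, j), midpoint(j, k), midpoint(k, i)
        kept.extend([(i, ij, ki), (ij, j, jk), (ki, jk, k)])
        middle = (ij, jk, ki)
        if d == 1:
            return middle
        return recurse(middle, d - 1)

    carved = recurse(tuple(face), depth)
    return kept, carved


def _carve_prosopyles(unit_verts, wall_faces, spec, base_dirs, rng):
    """Perforate the wall with as many prosopyles as fit.

    Each prosopyle is a centred child triangle carved from a wall face at a
    subdivision depth that puts the individual hole area within a factor of
    two of ``prosopyle_area_fraction * 4 pi R^2`` (about 2.5 um across at
    the defaults).  Hole sites are wall triangles away from the apopyle rim
    and from flagellar-base exclusion zones (so carving does not reduce the
    flagellar density); as many sites as fit are used subject to a minimum
    centre-to-centre spacing of ``prosopyle_spacing`` (about one choanocyte
    cell body, since inlets sit at junctions between cells), which makes
    the wall porosity independent of mesh resolution and of the flagellum
    count.  The seeded shuffle randomises which admissible packing is used.
    """
    verts = [v for v in unit_verts]
    hole_target = spec.prosopyle_area_fraction * 4.0 * np.pi  # solid angle
    centroids = np.array([np.mean([verts[i] for i in f], axis=0) for f in wall_faces])
    centroids /= np.linalg.norm(centroids, axis=1, keepdims=True)
    polar = _polar_of(centroids)
    excl = spec.aperture_radius_factor * spec.amplitude / spec.radius
    cos_d = centroids @ base_dirs.T
    near_base = np.arccos(np.clip(cos_d.max(axis=1), -1, 1)) < excl
    ok = (polar > spec.theta_a + 0.1) & ~near_base
    if not ok.any():
        ok = polar > spec.theta_a + 0.1
    candidates = list(np.nonzero(ok)[0])
    rng.shuffle(candidates)

    omegas = _spherical_areas(np.asarray(unit_verts), np.asarray(wall_faces), 1.0)
    carved_omega = 0.0
    centers = []
    kept_faces = []
    removed_idx = set()
    limit = spec.max_prosopyles if spec.max_prosopyles is not None else len(candidates)
    min_spacing = spec.prosopyle_spacing / spec.radius  # chord on the unit sphere
    for fi in candidates:
        if len(removed_idx) >= limit:
            break
        if centers and np.min(
            np.linalg.norm(np.asarray(centers) / spec.radius - centroids[fi], axis=1)
        ) < min_spacing:
            continue
        depth = max(0, int(np.ceil(np.log(omegas[fi] / (2.0 * hole_target)) / np.log(4.0))))
        hole = omegas[fi] / 4.0**depth
        if hole < 0.5 * hole_target:
            continue  # face too small to host a full-size prosopyle
        if depth == 0:
            carved = wall_faces[fi]  # the whole face is one prosopyle
            kept = []
        else:
            kept, carved = _subdivide_carve(verts, wall_faces[fi], depth)
        removed_idx.add(fi)
        kept_faces.extend(kept)
        carved_tri = np.asarray(verts)[list(carved)]
        centers.append(np.mean(carved_tri, axis=0) * spec.radius)
        carved_omega += _spherical_areas(
            np.asarray(verts), np.asarray([carved]), 1.0
        )[0]
    if not removed_idx:
        raise ValueError("mesh resolution too coarse to carve prosopyles")
    faces = [f for i, f in enumerate(wall_faces) if i not in removed_idx]
    faces.extend(kept_faces)
    return np.asarray(verts), np.asarray(faces), carved_omega, np.asarray(centers)


def build_chamber_mesh(spec: ChamberSpec, prosopyle_seed=0) -> SurfaceMesh:
    """Build the triangulated chamber scene described in the module docstring.

    The prosopyle sites are drawn from ``prosopyle_seed`` (kept separate from
    the flagellum seed so ensemble members share identical geometry).  The
    returned mesh contains wall, reticulum and cone regions (no-slip) plus
    the apopyle cap as a pure flux surface.
    """
    rng = np.random.default_rng(prosopyle_seed)
    base_dirs = fibonacci_zone_points(spec.n_flagella, spec.theta_a)

    ico = trimesh.creation.icosphere(subdivisions=spec.subdivisions, radius=1.0)
    unit_vert_list = [v / np.linalg.norm(v) for v in np.asarray(ico.vertices)]
    wall_faces, cap_faces = _split_by_polar(
        unit_vert_list, np.asarray(ico.faces), spec.theta_a
    )
    unit_verts = np.asarray(unit_vert_list)
    cap_faces = np.asarray(cap_faces)

    wall_verts, wall_faces, carved_omega, holes = _carve_prosopyles(
        unit_verts, list(wall_faces), spec, base_dirs, rng
    )

    parts = []  # (vertices, faces, region, areas, normals)

    def add_sphere_part(verts_unit, fcs, radius, region):
        v = verts_unit * radius
        areas = _spherical_areas(v, fcs, radius)
        c = v[fcs].mean(axis=1)
        normals = c / np.linalg.norm(c, axis=1, keepdims=True)
        parts.append((v, fcs, np.full(len(fcs), REGIONS[region]), areas, normals))

    add_sphere_part(wall_verts, wall_faces, spec.radius, "wall")
    add_sphere_part(unit_verts, cap_faces, spec.radius, "apopyle_surface")

    # reticulum shell with one aperture per flagellum
    r_ret = spec.reticulum_radius
    sub_ret = spec.reticulum_subdivisions
    if sub_ret is None:
        sub_ret = max(spec.subdivisions - 1, 1)
    ret = trimesh.creation.icosphere(subdivisions=sub_ret, radius=1.0)
    ret_vert_list = [v / np.linalg.norm(v) for v in np.asarray(ret.vertices)]
    ret_faces, _ = _split_by_polar(ret_vert_list, np.asarray(ret.faces), spec.theta_a)
    rv = np.asarray(ret_vert_list)
    rf = np.asarray(ret_faces)
    rc = rv[rf].mean(axis=1)
    rc /= np.linalg.norm(rc, axis=1, keepdims=True)
    aperture_angle = spec.aperture_radius_factor * spec.amplitude / r_ret
    ang_to_base = np.arccos(np.clip(rc @ base_dirs.T, -1, 1)).min(axis=1)
    keep = ang_to_base > aperture_angle
    if keep.any():
        add_sphere_part(rv, rf[keep], r_ret, "reticulum")

    if spec.cone_present:
        parts.append(_cone_frustum(spec))

    # merge parts with vertex offsets
    all_v, all_f, all_r, all_a, all_n = [], [], [], [], []
    offset = 0
    for v, f, r, a, n in parts:
        all_v.append(v)
        all_f.append(np.asarray(f) + offset)
        all_r.append(r)
        all_a.append(a)
        all_n.append(n)
        offset += len(v)
    mesh = SurfaceMesh(
        vertices=np.vstack(all_v),
        triangles=np.vstack(all_f),
        region=np.concatenate(all_r),
        areas=np.concatenate(all_a),
        normals=np.vstack(all_n),
        prosopyle_area=carved_omega * spec.radius**2,
        prosopyle_centers=holes,
    )
    return mesh


def _cone_frustum(spec):
    """Triangulated cone-cell ring from the reticulum rim to the wall rim."""
    th = spec.theta_a
    r0, z0 = spec.reticulum_radius * np.sin(th), spec.reticulum_radius * np.cos(th)
    r1, z1 = spec.radius * np.sin(th), spec.radius * np.cos(th)
    nseg = spec.cone_segments
    az = np.linspace(0.0, 2.0 * np.pi, nseg, endpoint=False)
    ring0 = np.column_stack([r0 * np.cos(az), r0 * np.sin(az), np.full(nseg, z0)])
    ring1 = np.column_stack([r1 * np.cos(az), r1 * np.sin(az), np.full(nseg, z1)])
    verts = np.vstack([ring0, ring1])
    faces = []
    for i in range(nseg):
        j = (i + 1) % nseg
        faces.append((i, nseg + i, nseg + j))
        faces.append((i, nseg + j, j))
    faces = np.asarray(faces)
    tri = verts[faces]
    cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    areas = 0.5 * np.linalg.norm(cross, axis=1)
    normals = cross / np.linalg.norm(cross, axis=1, keepdims=True)
    # orient away from the z axis (outward through the conical ring)
    c = tri.mean(axis=1)
    radial = c.copy()
    radial[:, 2] = 0.0
    flip = np.einsum("ij,ij->i", normals, radial) < 0
    normals[flip] *= -1.0
    return verts, faces, np.full(len(faces), REGIONS["cone"]), areas, normals
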