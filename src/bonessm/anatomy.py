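"""Anatomical coordinate frame, axis/circle fitting and morphometric measurements.

The distal humerus is measured in a landmark-based frame: the x-axis joins the
most prominent points of the medial and lateral epicondyles (the
transepicondylar line, TEL), the y-axis runs along the shaft direction in the
sagittal plane through the trochlear groove center, and z completes a
right-handed system pointing anteriorly.  The flexion-extension axis ("C line")
is the axis of a least-squares cylinder fitted through the articular surface.
Thirteen parameters (widths, ratios, angles, and six circle-fit radii) are
computed per bone, mirroring standard distal-humerus morphometry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, fields as _dc_fields

import numpy as np
from scipy.optimize import least_squares

from .mesh import TriangleMesh, MeshError

__all__ = [
    "LandmarkSet",
    "CoordinateFrame",
    "ArticularAxis",
    "MeasurementSet",
    "fit_cylinder",
    "fit_circle",
    "detect_landmarks",
    "build_frame",
    "shaft_direction",
    "measure",
    "radius_profile",
    "ARTICULAR_LANDMARK_NAMES",
]

ARTICULAR_LANDMARK_NAMES = (
    "medial_trochlear_ridge",
    "trochlear_groove",
    "lateral_trochlear_ridge",
    "trochlea_capitellum_groove",
    "capitellum_apex",
)


class FitError(RuntimeError):
    """Raised when a geometric least-squares fit cannot be performed."""


@dataclass
class LandmarkSet:
    """Named anatomical landmarks of one distal humerus (mm).

    The epicondyle points and the five articular registration landmarks lie on
    the bone surface; the trochlear-groove and capitellum centers are
    section-circle centers and therefore lie on the articular axis, inside the
    bone.
    """

    medial_epicondyle: np.ndarray
    lateral_epicondyle: np.ndarray
    trochlear_groove_center: np.ndarray
    capitellum_center: np.ndarray
    articular_registration: dict  # name -> (3,) point, keys ARTICULAR_LANDMARK_NAMES

    def __post_init__(self) -> None:
        for f in ("medial_epicondyle", "lateral_epicondyle", "trochlear_groove_center", "capitellum_center"):
            setattr(self, f, np.asarray(getattr(self, f), dtype=float))
        self.articular_registration = {
            k: np.asarray(v, dtype=float) for k, v in self.articular_registration.items()
        }
        if np.allclose(self.medial_epicondyle, self.lateral_epicondyle):
            raise ValueError("medial and lateral epicondyles coincide")

    def registration_points(self) -> np.ndarray:
        """The five articular registration landmarks as a (5, 3) array."""
        return np.array([self.articular_registration[k] for k in ARTICULAR_LANDMARK_NAMES])

    def all_points(self) -> dict:
        out = {
            "medial_epicondyle": self.medial_epicondyle,
            "lateral_epicondyle": self.lateral_epicondyle,
            "trochlear_groove_center": self.trochlear_groove_center,
            "capitellum_center": self.capitellum_center,
        }
        out.update(self.articular_registration)
        return out

    def transformed(self, rotation: np.ndarray, translation=(0, 0, 0)) -> "LandmarkSet":
        R = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        return LandmarkSet(
            R @ self.medial_epicondyle + t,
            R @ self.lateral_epicondyle + t,
            R @ self.trochlear_groove_center + t,
            R @ self.capitellum_center + t,
            {k: R @ v + t for k, v in self.articular_registration.items()},
        )


@dataclass
class CoordinateFrame:
    """Right-handed orthonormal measurement frame (axes are unit row vectors)."""

    origin: np.ndarray
    x_axis: np.ndarray
    y_axis: np.ndarray
    z_axis: np.ndarray

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, float)
        for name in ("x_axis", "y_axis", "z_axis"):
            v = np.asarray(getattr(self, name), float)
            setattr(self, name, v / np.linalg.norm(v))
        R = np.stack([self.x_axis, self.y_axis, self.z_axis])
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-9):
            raise ValueError("frame axes are not orthonormal")
        if np.dot(np.cross(self.x_axis, self.y_axis), self.z_axis) < 0:
            raise ValueError("frame is not right-handed")

    def to_local(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, float))
        return (points - self.origin) @ np.stack([self.x_axis, self.y_axis, self.z_axis]).T


@dataclass
class ArticularAxis:
    """Flexion-extension axis: cylinder-fit axis through the articular surface."""

    point: np.ndarray
    direction: np.ndarray
    radius: float
    rms_residual: float = 0.0

    def __post_init__(self) -> None:
        self.point = np.asarray(self.point, float)
        d = np.asarray(self.direction, float)
        self.direction = d / np.linalg.norm(d)
        if self.radius <= 0:
            raise ValueError("cylinder radius must be positive")

    def station(self, t: float) -> np.ndarray:
        return self.point + t * self.direction


@dataclass
class MeasurementSet:
    """The thirteen distal-humerus parameters plus component widths (mm / deg)."""

    Wtel: float
    Wcline: float
    Wtro: float
    Wcap: float
    MT_width: float
    LT_width: float
    RT: float
    RTC: float
    ATC: float
    Agro: float
    R1: float
    R2: float
    R3: float
    R4: float
    R5: float
    R6: float

    def __post_init__(self) -> None:
        for name in ("Wtel", "Wcline", "Wtro", "Wcap", "MT_width", "LT_width", "R1", "R2", "R3", "R4", "R5", "R6"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("ATC", "Agro"):
            if not 0.0 <= getattr(self, name) <= 90.0:
                raise ValueError(f"{name} must be an acute angle in degrees")

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in _dc_fields(self)}


# ---------------------------------------------------------------------------
# least-squares primitives
# ---------------------------------------------------------------------------


def _axis_distances(points: np.ndarray, point: np.ndarray, direction: np.ndarray) -> np.ndarray:
    d = direction / np.linalg.norm(direction)
    rel = points - point
    return np.linalg.norm(rel - np.outer(rel @ d, d), axis=1)


def fit_cylinder(points: np.ndarray, init_direction: np.ndarray | None = None) -> ArticularAxis:
    """Least-squares cylinder fit: minimize sum((distance-to-axis - r)^2).

    Initialized from the principal directions of the point cloud (each of the
    three is tried unless ``init_direction`` is given; the lowest-residual
    solution wins).  Returns the axis with the RMS radial residual.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 6:
        raise FitError("cylinder fit needs at least 6 three-dimensional points")
    center = pts.mean(axis=0)
    rel = pts - center
    _, svals, Vt = np.linalg.svd(rel, full_matrices=False)
    if svals[1] < 1e-9 * max(svals[0], 1.0):
        raise FitError("cylinder fit is degenerate: points are (nearly) collinear")
    # planar point sets leave the radial objective unbounded/ill-posed
    if svals[2] < 1e-9 * svals[0]:
        raise FitError("cylinder fit is degenerate: points are coplanar")

    inits = [np.asarray(init_direction, float)] if init_direction is not None else list(Vt)

    def residual(x, return_parts=False):
        c, w, r = x[:3], x[3:6], x[6]
        nw = np.linalg.norm(w)
        if nw < 1e-12:
            return np.full(len(pts) + 1, 1e6)
        d = _axis_distances(pts, c, w)
        # gauge fixing: keep the axis point at the centroid's axial station
        # (full weight: the flat gauge direction otherwise leaves the normal
        # equations near-singular and the solver stop point ill-defined)
        gauge = np.dot(c - center, w / nw)
        out = np.concatenate([d - r, [gauge]])
        return (out, d) if return_parts else out

    best = None
    for w0 in inits:
        d0 = _axis_distances(pts, center, w0)
        x0 = np.concatenate([center, w0, [max(d0.mean(), 1e-3)]])
        sol = least_squares(residual, x0, method="lm", max_nfev=4000, xtol=1e-15, ftol=1e-15, gtol=1e-15)
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not np.isfinite(best.cost):
        raise FitError("cylinder fit failed to converge")
    c, w, r = best.x[:3], best.x[3:6], abs(best.x[6])
    c, w, r = _polish_cylinder(pts, center, c, w, r)
    w = w / np.linalg.norm(w)
    d = _axis_distances(pts, c, w)
    r = float(d.mean()) if r == 0 else float(r)
    rms = float(np.sqrt(np.mean((d - r) ** 2)))
    # place the axis point at the centroid's axial station
    c = c + np.dot(center - c, w) * w
    return ArticularAxis(point=c, direction=w, radius=r, rms_residual=rms)


def _polish_cylinder(pts, center, c, w, r, iters: int = 12):
    """Gauss-Newton polish with analytic Jacobian.

    The solver's stop point inside the flat convergence basin is not
    bit-reproducible; a few quadratically convergent steps land every start
    point on the same optimum to machine precision.
    """
    for _ in range(iters):
        nw = np.linalg.norm(w)
        what = w / nw
        rel = pts - c
        axial = rel @ what
        P = rel - np.outer(axial, what)
        d = np.linalg.norm(P, axis=1)
        d = np.maximum(d, 1e-12)
        Phat = P / d[:, None]
        res = np.concatenate([d - r, [np.dot(c - center, what)]])
        Jc = -Phat
        Jw = -(axial / nw)[:, None] * Phat
        Jr = -np.ones((len(pts), 1))
        g_c = what[None, :]
        g_w = ((c - center) - np.dot(c - center, what) * what)[None, :] / nw
        J = np.block([[Jc, Jw, Jr], [g_c, g_w, np.zeros((1, 1))]])
        step, *_ = np.linalg.lstsq(J, -res, rcond=None)
        c = c + step[:3]
        w = w + step[3:6]
        r = r + step[6]
        if np.abs(step).max() < 1e-13:
            break
    return c, w, abs(r)


def fit_circle(points: np.ndarray):
    """Circle fit in the plane: Pratt algebraic fit + geometric refinement.

    Parameters are (k, 2) planar points; returns ``(center (2,), radius)``.
    Raises :class:`FitError` for fewer than 3 or (nearly) collinear points.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
        raise FitError("circle fit needs at least 3 planar points")
    centered = pts - pts.mean(axis=0)
    svals = np.linalg.svd(centered, compute_uv=False)
    if svals[1] < 1e-9 * max(svals[0], 1.0):
        raise FitError("circle fit is degenerate: points are collinear")

    # Pratt fit: solve A (a,b,c,d)^T = 0 with constraint b^2+c^2-4ad=1
    x, y = pts[:, 0], pts[:, 1]
    z = x * x + y * y
    A = np.column_stack([z, x, y, np.ones_like(x)])
    B = np.array([[0, 0, 0, -2.0], [0, 1, 0, 0], [0, 0, 1, 0], [-2.0, 0, 0, 0]])
    M = A.T @ A
    evals, evecs = np.linalg.eig(np.linalg.solve(B, M))
    evals, evecs = np.real(evals), np.real(evecs)
    # the fit is the eigenvector of the smallest nonnegative eigenvalue; an
    # exact fit has eigenvalue 0, so tolerate small negative round-off
    ok = evals > -1e-9 * max(np.abs(evals).max(), 1.0)
    if not ok.any():
        raise FitError("Pratt circle fit failed")
    v = evecs[:, np.where(ok, evals, np.inf).argmin()]
    a, b, c, dcoef = v
    if abs(a) < 1e-14:
        raise FitError("circle fit is degenerate: points are collinear")
    cx, cy = -b / (2 * a), -c / (2 * a)
    r2 = (b * b + c * c - 4 * a * dcoef) / (4 * a * a)
    if r2 <= 0:
        raise FitError("Pratt circle fit produced a non-positive radius")
    r0 = np.sqrt(r2)

    def residual(p):
        return np.hypot(x - p[0], y - p[1]) - p[2]

    sol = least_squares(
        residual, np.array([cx, cy, r0]), method="lm", max_nfev=1000, xtol=1e-15, ftol=1e-15, gtol=1e-15
    )
    cx, cy, r = sol.x
    # deterministic Gauss-Newton polish (see _polish_cylinder)
    for _ in range(8):
        dx, dy = x - cx, y - cy
        d = np.maximum(np.hypot(dx, dy), 1e-12)
        res = d - r
        J = np.column_stack([-dx / d, -dy / d, -np.ones_like(d)])
        step, *_ = np.linalg.lstsq(J, -res, rcond=None)
        cx, cy, r = cx + step[0], cy + step[1], r + step[2]
        if np.abs(step).max() < 1e-14:
            break
    return np.array([cx, cy]), float(abs(r))


# ---------------------------------------------------------------------------
# sections and radius profile along the articular axis
# ---------------------------------------------------------------------------


def _section_points(mesh: TriangleMesh, origin: np.ndarray, normal: np.ndarray, face_mask=None) -> np.ndarray:
    """Points of the mesh/plane intersection (restricted to ``face_mask`` faces)."""
    import trimesh.intersections as _ti

    tm = mesh.to_trimesh()
    lines = _ti.mesh_plane(tm, plane_normal=normal, plane_origin=origin)
    if face_mask is not None:
        lines_all, fidx = _ti.mesh_plane(
            tm, plane_normal=normal, plane_origin=origin, return_faces=True
        )
        lines = lines_all[np.asarray(face_mask, bool)[fidx]]
    if len(lines) == 0:
        return np.empty((0, 3))
    return lines.reshape(-1, 3)


def _plane_basis(direction: np.ndarray):
    d = direction / np.linalg.norm(direction)
    ref = np.array([0.0, 0.0, 1.0]) if abs(d[2]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(d, ref)
    u /= np.linalg.norm(u)
    v = np.cross(d, u)
    return u, v


def _section_circle(mesh, axis, t, u, v, face_mask, min_points=8):
    d = axis.direction
    pts = _section_points(mesh, axis.point + t * d, d, face_mask)
    if len(pts) < min_points:
        return np.nan, None
    uv = np.column_stack([(pts - axis.point) @ u, (pts - axis.point) @ v])
    try:
        c2, r = fit_circle(uv)
    except FitError:
        return np.nan, None
    return r, axis.point + t * d + c2[0] * u + c2[1] * v


def radius_profile(
    mesh: TriangleMesh,
    axis: ArticularAxis,
    face_mask: np.ndarray,
    step: float = 0.5,
    min_points: int = 8,
):
    """Circle-fit radius of articular cross-sections along the axis.

    Sections are planes perpendicular to the C line, stepped every ``step`` mm
    across the extent of the masked faces.  Returns ``(stations t, radii,
    centers (k,3))`` with NaN radii where a section had too few points.
    """
    d = axis.direction
    u, v = _plane_basis(d)
    vert_mask = np.zeros(mesh.n_vertices, bool)
    vert_mask[np.unique(mesh.faces[face_mask])] = True
    t_all = (mesh.vertices[vert_mask] - axis.point) @ d
    t_lo, t_hi = t_all.min(), t_all.max()
    stations = np.arange(t_lo + step, t_hi - step / 2, step)
    radii = np.full(len(stations), np.nan)
    centers = np.full((len(stations), 3), np.nan)
    for i, t in enumerate(stations):
        r, c = _section_circle(mesh, axis, t, u, v, face_mask, min_points)
        radii[i] = r
        if c is not None:
            centers[i] = c
    return stations, radii, centers


def articular_stations(mesh, axis, face_mask, step: float = 0.5, fine_step: float = 0.15):
    """The five articular stations, refined by fine re-sectioning.

    A coarse radius profile locates the ridge/groove/ridge/groove/capitellum
    extremum pattern; each station is then re-sectioned at ``fine_step`` in a
    narrow window and refined by a local parabola, which removes the bias the
    asymmetric profile curvature would otherwise introduce.  Returns
    ``(t (5,), radii (5,), centers (5, 3))``.
    """
    stations, radii, centers = radius_profile(mesh, axis, face_mask, step=step)
    st, _ = _profile_stations(stations, radii)
    u, v = _plane_basis(axis.direction)
    kinds = [+1, -1, +1, -1, +1]
    out_t = np.empty(5)
    out_r = np.empty(5)
    out_c = np.empty((5, 3))
    for j, (tk, kind) in enumerate(zip(st, kinds)):
        ts = tk + np.arange(-4, 5) * fine_step
        rr, cc = [], []
        for t in ts:
            r, c = _section_circle(mesh, axis, t, u, v, face_mask)
            rr.append(r)
            cc.append(c)
        rr = np.asarray(rr)
        ok = np.isfinite(rr)
        if ok.sum() < 3:
            out_t[j], out_r[j] = tk, radii[np.abs(stations - tk).argmin()]
            out_c[j] = centers[np.abs(stations - tk).argmin()]
            continue
        i = int(np.where(ok, rr, -np.inf).argmax()) if kind > 0 else int(np.where(ok, rr, np.inf).argmin())
        # least-squares parabola over the whole fine window averages out the
        # per-section circle-fit noise from mesh faceting
        a, b, cpar = np.polyfit(ts[ok], rr[ok], 2)
        if kind * a < 0 and abs(a) > 1e-12:
            xv = float(np.clip(-b / (2 * a), ts[0], ts[-1]))
            out_t[j], out_r[j] = xv, float(a * xv**2 + b * xv + cpar)
        else:
            out_t[j], out_r[j] = ts[i], rr[i]
        out_c[j] = cc[i] if cc[i] is not None else centers[np.abs(stations - tk).argmin()]
    return out_t, out_r, out_c


def _profile_stations(stations: np.ndarray, radii: np.ndarray):
    """Locate the five articular stations as alternating extrema of the profile.

    Expected pattern along the axis from medial to lateral: maximum (medial
    trochlear ridge), minimum (trochlear groove), maximum (lateral trochlear
    ridge), minimum (trochlea-capitellum groove), maximum (capitellum apex).
    """
    ok = np.isfinite(radii)
    s, r = stations[ok], radii[ok]
    if len(s) < 7:
        raise FitError("radius profile has too few valid sections")
    # smooth lightly to suppress faceting noise before extremum search
    kernel = np.array([0.25, 0.5, 0.25])
    rs = np.convolve(np.pad(r, 1, mode="edge"), kernel, mode="valid")
    idx = []
    kinds = []
    for i in range(1, len(s) - 1):
        if rs[i] >= rs[i - 1] and rs[i] > rs[i + 1]:
            idx.append(i)
            kinds.append(+1)
        elif rs[i] <= rs[i - 1] and rs[i] < rs[i + 1]:
            idx.append(i)
            kinds.append(-1)
    # collapse runs of same-kind extrema to the most extreme one
    merged = []
    for i, k in zip(idx, kinds):
        if merged and merged[-1][1] == k:
            j = merged[-1][0]
            if (k > 0 and rs[i] > rs[j]) or (k < 0 and rs[i] < rs[j]):
                merged[-1] = (i, k)
        else:
            merged.append((i, k))
    def refine(i):
        # sub-step quadratic refinement of the extremum position and value
        x0, x1, x2 = s[i - 1], s[i], s[i + 1]
        y0, y1, y2 = r[i - 1], r[i], r[i + 1]
        denom = (x0 - x1) * (x0 - x2) * (x1 - x2)
        a = (x2 * (y1 - y0) + x1 * (y0 - y2) + x0 * (y2 - y1)) / denom
        b = (x2**2 * (y0 - y1) + x1**2 * (y2 - y0) + x0**2 * (y1 - y2)) / denom
        if abs(a) < 1e-12:
            return x1, y1
        xv = float(np.clip(-b / (2 * a), x0, x2))
        c = y1 - a * x1**2 - b * x1
        return xv, float(a * xv**2 + b * xv + c)

    pattern = [+1, -1, +1, -1, +1]
    for start in range(0, max(1, len(merged) - 4)):
        window = merged[start : start + 5]
        if len(window) == 5 and [k for _, k in window] == pattern:
            refined = [refine(i) for i, _ in window]
            return np.array([t for t, _ in refined]), np.array([v for _, v in refined])
    raise FitError(
        "could not locate the five articular stations "
        "(ridge/groove/ridge/groove/capitellum pattern not found in radius profile)"
    )


# ---------------------------------------------------------------------------
# landmark detection
# ---------------------------------------------------------------------------


def articular_face_mask(mesh: TriangleMesh, label: str = "articular") -> np.ndarray:
    if mesh.vertex_labels is None:
        raise MeshError("mesh carries no vertex labels")
    vmask = mesh.vertex_labels == label
    return vmask[mesh.faces].all(axis=1)


def detect_landmarks(mesh: TriangleMesh, side: str = "left") -> LandmarkSet:
    """Two-pass prominence search for the anatomical landmarks.

    Pass 1 fits the articular cylinder axis (provisional medio-lateral
    direction; the medial end is recognised as the larger-radius end) and takes
    the epicondyles as the extreme surface points along it.  Pass 2 re-extracts
    the epicondyles along the refined transepicondylar direction, then locates
    the groove/ridge/capitellum stations on the C-line radius profile.  For a
    right-sided bone, mirror to left-sided orientation first
    (:func:`bonessm.mesh.mirror_to_left`) and pass ``side="left"``.
    """
    if side not in ("left", "right"):
        raise ValueError("side must be 'left' or 'right'")
    if side == "right":
        from .mesh import mirror_to_left, Plane

        plane = Plane(mesh.centroid, np.array([1.0, 0.0, 0.0]))
        lm = detect_landmarks(mirror_to_left(mesh, plane), side="left")
        from .mesh import reflection_matrix

        refl = reflection_matrix(plane.normal)
        return lm.transformed(refl, plane.point - refl @ plane.point)

    fmask = articular_face_mask(mesh)
    if not fmask.any():
        raise MeshError("no articular-labeled faces; cannot detect landmarks")
    vmask = np.zeros(mesh.n_vertices, bool)
    vmask[np.unique(mesh.faces[fmask])] = True
    art_pts = mesh.vertices[vmask]

    axis = fit_cylinder(art_pts)
    # orient the axis medial -> lateral: the medial (trochlear) end has the
    # larger section radius than the lateral (capitellum taper) end
    t = (art_pts - axis.point) @ axis.direction
    rad = _axis_distances(art_pts, axis.point, axis.direction)
    lo, hi = np.quantile(t, [0.15, 0.85])
    r_low = np.quantile(rad[t <= lo], 0.9)
    r_high = np.quantile(rad[t >= hi], 0.9)
    direction = axis.direction if r_low >= r_high else -axis.direction
    axis = ArticularAxis(axis.point, direction, axis.radius, axis.rms_residual)

    # shaft direction (proximal), orthogonalized against the articular axis
    y_prov = shaft_direction(mesh)
    y_prov -= (y_prov @ axis.direction) * axis.direction
    y_prov /= np.linalg.norm(y_prov)

    from .mesh import closest_points

    def _prominence(direction, points):
        """Apex surface point along a direction: a quadratic cap is fitted to
        the near-extreme band and its stationary point (re-projected onto the
        surface) is the sub-vertex apex estimate."""
        proj = points @ direction
        i_max = int(proj.argmax())
        ties = np.nonzero(proj >= proj[i_max] - 0.1)[0]
        spread = np.linalg.norm(points[ties] - points[i_max], axis=1)
        if (spread > 2.0).any():
            warnings.warn(
                "ambiguous prominence: tie within 0.1 mm at distant locations "
                f"(spread {spread.max():.1f} mm)",
                stacklevel=3,
            )
        band = points[proj >= proj[i_max] - 1.0]
        apex = band.mean(axis=0)
        if len(band) >= 8:
            u, v = _plane_basis(direction)
            bu, bv = (band - apex) @ u, (band - apex) @ v
            H = np.column_stack([np.ones_like(bu), bu, bv, bu**2, bu * bv, bv**2])
            coef, *_ = np.linalg.lstsq(H, proj[proj >= proj[i_max] - 1.0], rcond=None)
            A2 = np.array([[2 * coef[3], coef[4]], [coef[4], 2 * coef[5]]])
            if np.linalg.det(A2) > 1e-12 and coef[3] < 0 and coef[5] < 0:
                uv = np.linalg.solve(A2, -coef[1:3])
                reach = max(np.hypot(bu, bv).max(), 1e-9)
                if np.hypot(*uv) <= reach:  # stationary point within the band
                    apex = apex + uv[0] * u + uv[1] * v
        return closest_points(apex[None, :], mesh)[0][0]

    def extreme_points(direction):
        return _prominence(-direction, mesh.vertices), _prominence(direction, mesh.vertices)

    # epicondyle prominence is taken along the medio-lateral (C-line) axis —
    # the TEL is *defined by* the prominent points, so projecting along it
    # would bias the apexes.  Pass 2 repeats the search with the prominence
    # direction re-orthogonalized against the refined shaft direction; the
    # search is a fixed point thereafter.
    ml = axis.direction
    medial, lateral = extreme_points(ml)  # pass 1
    ml2 = ml - (ml @ y_prov) * y_prov
    ml2 /= np.linalg.norm(ml2)
    medial, lateral = extreme_points(ml2)  # pass 2

    st, sr, centers = articular_stations(mesh, axis, fmask, step=0.5)
    groove_center, cap_center = centers[1], centers[4]

    # five articular registration landmarks: distal pole of each station ring
    distal = -y_prov
    reg = {}
    tv = (mesh.vertices - axis.point) @ axis.direction
    for name, tk in zip(ARTICULAR_LANDMARK_NAMES, st):
        near = vmask & (np.abs(tv - tk) < 0.8)
        if not near.any():
            near = vmask & (np.abs(tv - tk) < 1.6)
        cand = mesh.vertices[near]
        proj = cand @ distal
        band = cand[proj >= proj.max() - 0.35]
        # keep the pole on the station plane, flatten faceting in-plane
        pole = band.mean(axis=0)
        pole += (tk - (pole - axis.point) @ axis.direction) * axis.direction
        reg[name] = closest_points(pole[None, :], mesh)[0][0]

    return LandmarkSet(medial, lateral, groove_center, cap_center, reg)


# ---------------------------------------------------------------------------
# frame construction and measurement
# ---------------------------------------------------------------------------


def shaft_direction(mesh: TriangleMesh, min_height: float = 25.0) -> np.ndarray:
    """Principal inertia direction of the shaft portion of the bone.

    The shaft is taken as all vertices farther than ``min_height`` mm from the
    articular centroid along the articular-to-shaft direction; the returned
    unit vector points proximally (away from the articulation).
    """
    try:
        fmask = articular_face_mask(mesh)
        vmask = np.zeros(mesh.n_vertices, bool)
        vmask[np.unique(mesh.faces[fmask])] = True
        c_art = mesh.vertices[vmask].mean(axis=0)
        rest = mesh.vertices[~vmask]
    except MeshError:
        c_art = mesh.centroid
        rest = mesh.vertices
    d = rest.mean(axis=0) - c_art
    d /= np.linalg.norm(d)
    # iterate: select shaft points along the current estimate, then fit a line
    # through cross-section band centroids.  Band centroids are insensitive to
    # the asymmetry of the shaft cross-section (ridges), which would bias a
    # raw principal-axis fit under an oblique selection cut.
    for _ in range(3):
        h = (mesh.vertices - c_art) @ d
        shaft_pts = mesh.vertices[h > min_height]
        if len(shaft_pts) < 30:
            shaft_pts = mesh.vertices[h > 0.5 * h.max()]
        hs = (shaft_pts - c_art) @ d
        lo, hi = np.quantile(hs, [0.08, 0.92])  # trim the cut and cap ends
        edges = np.linspace(lo, hi, 11)
        centroids = []
        for a, b in zip(edges[:-1], edges[1:]):
            sel = (hs >= a) & (hs < b)
            if sel.sum() >= 5:
                centroids.append(shaft_pts[sel].mean(axis=0))
        centroids = np.asarray(centroids)
        if len(centroids) < 3:
            rel = shaft_pts - shaft_pts.mean(axis=0)
        else:
            rel = centroids - centroids.mean(axis=0)
        _, _, Vt = np.linalg.svd(rel, full_matrices=False)
        new = Vt[0] if Vt[0] @ d > 0 else -Vt[0]
        converged = abs(new @ d) > 1.0 - 1e-12
        d = new
        if converged:
            break
    return d


def build_frame(landmarks: LandmarkSet, shaft_dir: np.ndarray) -> CoordinateFrame:
    """Construct the measurement frame from landmarks and the shaft direction.

    x: medial -> lateral epicondyle (TEL); y: shaft direction orthogonalized
    against x (proximal); z = x cross y, oriented anteriorly; origin: the TEL
    point in the sagittal plane through the trochlear groove center.
    """
    shaft_dir = np.asarray(shaft_dir, float)
    x = landmarks.lateral_epicondyle - landmarks.medial_epicondyle
    x = x / np.linalg.norm(x)
    cosang = abs(np.dot(x, shaft_dir / np.linalg.norm(shaft_dir)))
    if cosang > np.cos(np.radians(10.0)):
        raise ValueError("shaft direction is nearly parallel to the epicondylar line")
    y = shaft_dir - (shaft_dir @ x) * x
    y = y / np.linalg.norm(y)
    z = np.cross(x, y)
    gc = landmarks.trochlear_groove_center
    origin = landmarks.medial_epicondyle + ((gc - landmarks.medial_epicondyle) @ x) * x
    # anterior check: the articular axis (groove center) lies anterior and
    # distal to the TEL; flip medial/lateral if the handedness disagrees
    if (gc - origin) @ z < 0:
        x, z = -x, -z
        origin = landmarks.medial_epicondyle + ((gc - landmarks.medial_epicondyle) @ x) * x
        warnings.warn("frame orientation flipped: landmarks imply opposite handedness", stacklevel=2)
    return CoordinateFrame(origin=origin, x_axis=x, y_axis=y, z_axis=z)


def _acute_angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    c = abs(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def measure(
    mesh: TriangleMesh,
    landmarks: LandmarkSet,
    frame: CoordinateFrame,
    axis: ArticularAxis,
    step: float | None = None,
) -> MeasurementSet:
    """Compute the thirteen distal-humerus parameters (plus component widths).

    Widths are extents along the C line; R1-R5 are circle-fit radii of
    sections perpendicular to the C line at the five articular stations (R5 is
    the largest capitellar sagittal radius); R6 is the largest circle-fit
    radius of the anterior capitellum outline on transverse sections.  All
    inputs must be expressed in the same coordinate space.
    """
    fmask = articular_face_mask(mesh)
    if not fmask.any():
        raise MeshError("no articular-labeled faces; cannot measure")
    d = axis.direction
    if (landmarks.lateral_epicondyle - landmarks.medial_epicondyle) @ d < 0:
        d = -d  # orient medial -> lateral

    wtel = float(np.linalg.norm(landmarks.medial_epicondyle - landmarks.lateral_epicondyle))

    vmask = np.zeros(mesh.n_vertices, bool)
    vmask[np.unique(mesh.faces[fmask])] = True
    t_art = (mesh.vertices[vmask] - axis.point) @ d
    t_med_edge, t_lat_edge = float(t_art.min()), float(t_art.max())
    wcline = t_lat_edge - t_med_edge
    if step is None:
        # section spacing proportional to the articular extent, so the
        # measurement is scale-equivariant and ratios are scale-invariant
        step = wcline / 84.0

    oriented_axis = ArticularAxis(axis.point, d, axis.radius, axis.rms_residual)
    stations, radii, _ = radius_profile(mesh, oriented_axis, fmask, step=step)
    st, sr, _ = articular_stations(mesh, oriented_axis, fmask, step=step, fine_step=0.3 * step)
    t1, t2, t3, t4, t5 = (float(v) for v in st)

    wtro = t3 - t1
    wcap = t_lat_edge - t4
    mt = t2 - t_med_edge
    lt = t4 - t2
    for name, val in (("Wtro", wtro), ("Wcap", wcap), ("MT", mt), ("LT", lt)):
        if val <= 0:
            raise FitError(f"articular station ordering is inconsistent ({name} <= 0)")

    # R5: largest sagittal radius over the capitellum stations
    cap_mask = np.isfinite(radii) & (stations > t4 + 0.5 * step)
    r5 = float(np.nanmax(radii[cap_mask])) if cap_mask.any() else float(sr[4])

    # R6: largest circle-fit radius of the anterior capitellum outline on
    # transverse sections (planes perpendicular to the frame y-axis)
    r6 = _transverse_capitellum_radius(mesh, frame, oriented_axis, fmask, t4, t_lat_edge, step)

    atc = _acute_angle_deg(landmarks.lateral_epicondyle - landmarks.medial_epicondyle, d)

    # Agro in the sagittal (y-z) plane
    v = landmarks.trochlear_groove_center - frame.origin
    v_sag = v - (v @ frame.x_axis) * frame.x_axis
    agro = _acute_angle_deg(v_sag, frame.y_axis)

    return MeasurementSet(
        Wtel=wtel,
        Wcline=wcline,
        Wtro=wtro,
        Wcap=wcap,
        MT_width=mt,
        LT_width=lt,
        RT=mt / lt,
        RTC=wtro / wcap,
        ATC=atc,
        Agro=agro,
        R1=float(sr[0]),
        R2=float(sr[1]),
        R3=float(sr[2]),
        R4=float(sr[3]),
        R5=r5,
        R6=r6,
    )


def _transverse_capitellum_radius(mesh, frame, axis, fmask, t4, t_lat, step):
    d = axis.direction
    # capitellum window along the axis: the central cap, away from the
    # groove-side inflection and the lateral edge taper
    t_lo = t4 + 0.2 * (t_lat - t4)
    t_hi = t_lat - 0.2 * (t_lat - t4)
    axis_y = float(axis.point @ frame.y_axis)
    best = 0.0
    for dy in np.arange(-4 * step, 4 * step + step / 2, step):
        origin = frame.origin + (axis_y + dy - frame.origin @ frame.y_axis) * frame.y_axis
        pts = _section_points(mesh, origin, frame.y_axis, fmask)
        if len(pts) < 8:
            continue
        tv = (pts - axis.point) @ d
        anterior = (pts - axis.point) @ frame.z_axis > 0
        sel = (tv > t_lo) & (tv < t_hi) & anterior
        if sel.sum() < 8:
            continue
        uv = np.column_stack([(pts[sel] - frame.origin) @ frame.x_axis, (pts[sel] - frame.origin) @ frame.z_axis])
        try:
            _, r = fit_circle(uv)
        except FitError:
            continue
        best = max(best, r)
    if best <= 0:
        raise FitError("could not measure the transverse capitellum radius (R6)")
    return float(best)


def write_landmarks(landmarks: LandmarkSet, path) -> None:
    """Write landmarks as labeled-point text: ``name x y z`` per line (mm)."""
    from pathlib import Path

    lines = [f"{k} {v[0]:.6f} {v[1]:.6f} {v[2]:.6f}" for k, v in landmarks.all_points().items()]
    Path(path).write_text("\n".join(lines) + "\n")


def read_landmarks(path) -> LandmarkSet:
    """Read a labeled-point text file written by :func:`write_landmarks`."""
    from pathlib import Path

    pts = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, *coords = line.split()
        if len(coords) != 3:
            raise ValueError(f"malformed landmark line: {line!r}")
        pts[name] = np.array([float(c) for c in coords])
    required = ("medial_epicondyle", "lateral_epicondyle", "trochlear_groove_center", "capitellum_center")
    missing = [k for k in required + ARTICULAR_LANDMARK_NAMES if k not in pts]
    if missing:
        raise ValueError(f"landmark file {path} is missing: {missing}")
    return LandmarkSet(
        pts["medial_epicondyle"],
        pts["lateral_epicondyle"],
        pts["trochlear_groove_center"],
        pts["capitellum_center"],
        {k: pts[k] for k in ARTICULAR_LANDMARK_NAMES},
    )
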