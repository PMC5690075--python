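"""Parameterized anatomical eye phantom and voxelization.

The globe is built from simple solids (spherical shells, an ellipsoidal lens,
an annular ciliary body, a cylindrical optic-nerve stub and a spherical-cap
tumor dome) whose dimensions all scale with the outer sclera radius.  The
printed facts are honoured exactly — 48 mm brain water box, 9 mm tumor depth
extent, gaze rotation about the globe center with the tumor re-centered on
the beam axis — while the remaining proportions are documented defaults from
standard ophthalmic anatomy, overridable per instance.

The beam travels along +X; at zero gaze the cornea faces the beam (-X) and
the tumor dome sits against the posterior retina.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .materials import TissueMaterial, tissue_table

#: Default proportions, in mm at the reference outer sclera radius of
#: 12.25 mm; every entry scales linearly with the radius.
DEFAULT_PROPORTIONS = {
    "sclera_thickness": 1.0,
    "retina_thickness": 0.5,
    "cornea_half_angle_deg": 40.0,  # anterior cap replaced by cornea
    "lens_center_offset": 5.8,      # anterior of globe center, on the axis
    "lens_semi_axis_axial": 2.25,
    "lens_semi_axis_transverse": 4.5,
    "aqueous_boundary_offset": 5.0,  # interior anterior of this plane is aqueous
    "ciliary_axial": (4.6, 7.0),     # axial band (anterior offsets)
    "ciliary_radial_inner": 8.0,
    "nerve_radius": 1.75,
    "nerve_tilt_deg": 15.0,          # away from the posterior pole, nasal
    "nerve_length": 10.0,
    "tumor_base_radius": 7.0,
    "tumor_height": 9.0,             # axial extent of the dome
}

REFERENCE_RADIUS = 12.25
BRAIN_BOX_SIDE = 48.0

#: Voxel labels, in look-up priority order (innermost structure wins).
STRUCTURES = (
    "tumor",
    "lens",
    "optic_nerve",
    "ciliary_body",
    "cornea",
    "retina",
    "sclera",
    "aqueous_humor",
    "vitreous_humor",
    "brain",
)
LABELS = {name: i + 1 for i, name in enumerate(STRUCTURES)}
LABELS["air"] = 0

AIR_DENSITY = 1.2048e-3
AIR_WER = 1.06e-3


class EyeGeometryError(ValueError):
    pass


@dataclass(frozen=True)
class EyeModel:
    """Parameterized eye with a posterior tumor dome, gaze-rotated.

    The eye frame has its origin at the globe center with the optical axis
    along X (posterior positive).  ``gaze_angle`` rotates the eye rigidly
    about the globe center in the vertical (X-Y) plane; the whole model is
    then translated so the tumor centroid lies on the beam axis at the same
    depth as in the unrotated eye.
    """

    sclera_outer_radius: float = REFERENCE_RADIUS
    gaze_angle: float = 0.0  # degrees, positive = eye rotated up
    brain_box_side: float = BRAIN_BOX_SIDE
    proportions: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (9.0 <= self.sclera_outer_radius <= 16.0):
            raise EyeGeometryError("sclera radius outside the 9-16 mm range")
        if abs(self.gaze_angle) > 60.0:
            raise EyeGeometryError("|gaze angle| must be <= 60 degrees")
        p = dict(DEFAULT_PROPORTIONS)
        p.update(self.proportions)
        object.__setattr__(self, "proportions", p)

    # -- scaled dimensions ---------------------------------------------------
    @property
    def scale(self) -> float:
        return self.sclera_outer_radius / REFERENCE_RADIUS

    def dim(self, key) -> float:
        v = self.proportions[key]
        if "deg" in key:
            return v
        if isinstance(v, tuple):
            return tuple(x * self.scale for x in v)
        return v * self.scale

    @property
    def inner_radius(self) -> float:
        """Radius of the inner retina surface."""
        return self.sclera_outer_radius - self.dim("sclera_thickness") - self.dim(
            "retina_thickness"
        )

    # -- tumor geometry (eye frame) ------------------------------------------
    @property
    def tumor_cap(self):
        """(ball center x, ball radius, base plane x, apex x), eye frame."""
        h = self.dim("tumor_height")
        b = self.dim("tumor_base_radius")
        r_d = (b * b + h * h) / (2 * h)
        apex_x = self.inner_radius
        return apex_x - r_d, r_d, apex_x - h, apex_x

    @property
    def tumor_centroid_x(self) -> float:
        """Axial centroid of the tumor dome in the eye frame."""
        cx, r_d, base_x, apex_x = self.tumor_cap
        x = np.linspace(base_x, apex_x, 400)
        area = np.pi * np.clip(r_d**2 - (x - cx) ** 2, 0.0, None)
        return float(np.trapezoid(area * x, x) / np.trapezoid(area, x))

    # -- frames ----------------------------------------------------------------
    @property
    def rotation(self) -> np.ndarray:
        """World-from-eye rotation (about Z; positive gaze tilts the
        anterior pole up, hence the posterior tumor down)."""
        th = np.deg2rad(self.gaze_angle)
        c, s = np.cos(th), np.sin(th)
        return np.array([[c, s, 0.0], [-s, c, 0.0], [0.0, 0.0, 1.0]])

    @property
    def translation(self) -> np.ndarray:
        """World position of the globe center after re-centering the tumor."""
        c_t = self.tumor_centroid_x
        # unrotated anchor: tumor base plane at x = 0 (the isocenter)
        anchor = np.array([c_t - self.tumor_cap[2], 0.0, 0.0])
        centroid_world = self.rotation @ np.array([c_t, 0.0, 0.0])
        return anchor - centroid_world

    def world_to_eye(self, pts: np.ndarray) -> np.ndarray:
        return (pts - self.translation) @ self.rotation

    # -- structure membership tests (eye-frame points, shape (n, 3)) ----------
    def _masks(self, pe: np.ndarray) -> dict[str, np.ndarray]:
        R = self.sclera_outer_radius
        r2 = np.einsum("ij,ij->i", pe, pe)
        r = np.sqrt(r2)
        in_globe = r <= R
        shell_in = R - self.dim("sclera_thickness")
        retina_in = self.inner_radius
        interior = r <= retina_in

        # anterior cap angle from the -X axis
        with np.errstate(invalid="ignore", divide="ignore"):
            cos_ant = np.where(r > 0, -pe[:, 0] / np.maximum(r, 1e-12), 0.0)
        cap = cos_ant >= np.cos(np.deg2rad(self.dim("cornea_half_angle_deg")))

        sclera = in_globe & (r > shell_in) & ~cap
        cornea = in_globe & (r > retina_in) & cap
        retina = in_globe & (r <= shell_in) & (r > retina_in) & ~cap

        # lens ellipsoid
        lc = -self.dim("lens_center_offset")
        la = self.dim("lens_semi_axis_axial")
        lt = self.dim("lens_semi_axis_transverse")
        lens = ((pe[:, 0] - lc) / la) ** 2 + (pe[:, 1] / lt) ** 2 + (
            pe[:, 2] / lt
        ) ** 2 <= 1.0

        # ciliary ring
        ax_lo, ax_hi = self.dim("ciliary_axial")
        rho = np.sqrt(pe[:, 1] ** 2 + pe[:, 2] ** 2)
        ciliary = (
            interior
            & (pe[:, 0] >= -ax_hi)
            & (pe[:, 0] <= -ax_lo)
            & (rho >= self.dim("ciliary_radial_inner"))
        )

        # optic nerve stub, tilted off the posterior pole toward +Z
        tilt = np.deg2rad(self.dim("nerve_tilt_deg"))
        n_hat = np.array([np.cos(tilt), 0.0, np.sin(tilt)])
        proj = pe @ n_hat
        perp2 = r2 - proj**2
        nerve = (
            (perp2 <= self.dim("nerve_radius") ** 2)
            & (proj >= retina_in - 1.0 * self.scale)
            & (proj <= retina_in + self.dim("nerve_length"))
        )

        # tumor dome
        cx, r_d, base_x, _ = self.tumor_cap
        tumor = (
            interior
            & (pe[:, 0] >= base_x)
            & ((pe[:, 0] - cx) ** 2 + pe[:, 1] ** 2 + pe[:, 2] ** 2 <= r_d**2)
        )

        aqueous = interior & (pe[:, 0] <= -self.dim("aqueous_boundary_offset"))
        vitreous = interior
        return {
            "tumor": tumor,
            "lens": lens,
            "optic_nerve": nerve,
            "ciliary_body": ciliary,
            "cornea": cornea,
            "retina": retina,
            "sclera": sclera,
            "aqueous_humor": aqueous,
            "vitreous_humor": vitreous,
        }

    def label_points(self, pts_world: np.ndarray) -> np.ndarray:
        """Structure label for each world-frame point (n, 3)."""
        pe = self.world_to_eye(np.asarray(pts_world, float))
        masks = self._masks(pe)
        out = np.zeros(len(pe), dtype=np.uint8)
        # brain water box: anterior face just behind the globe-center plane
        g = self.translation
        half = self.brain_box_side / 2.0
        brain = (
            (pts_world[:, 0] >= g[0] + 2.0 * self.scale)
            & (pts_world[:, 0] <= g[0] + 2.0 * self.scale + self.brain_box_side)
            & (np.abs(pts_world[:, 1] - g[1]) <= half)
            & (np.abs(pts_world[:, 2] - g[2]) <= half)
        )
        out[brain] = LABELS["brain"]
        for name in reversed(STRUCTURES[:-1]):  # lowest priority first
            out[masks[name]] = LABELS[name]
        return out


def build_eye(
    sclera_outer_radius: float = REFERENCE_RADIUS,
    gaze_angle: float = 0.0,
    **proportions,
) -> EyeModel:
    """Construct the parameterized eye (see EyeModel)."""
    return EyeModel(
        sclera_outer_radius=sclera_outer_radius,
        gaze_angle=gaze_angle,
        proportions=proportions,
    )


# ---------------------------------------------------------------------------
# Voxelization
# ---------------------------------------------------------------------------

@dataclass
class LabeledGrid:
    """Voxelized phantom: per-voxel label, density and water-equivalent ratio.

    Arrays are indexed [ix, iy, iz]; ``origin`` is the center of voxel
    (0, 0, 0) in world coordinates (mm).
    """

    voxel_size: np.ndarray  # (3,), mm
    origin: np.ndarray  # (3,), mm
    labels: np.ndarray  # uint8
    density: np.ndarray
    wer: np.ndarray
    label_names: dict[str, int] = field(default_factory=lambda: dict(LABELS))

    @property
    def shape(self):
        return self.labels.shape

    def axis_coords(self, axis: int) -> np.ndarray:
        n = self.shape[axis]
        return self.origin[axis] + np.arange(n) * self.voxel_size[axis]

    def mask(self, structure: str) -> np.ndarray:
        return self.labels == self.label_names[structure]

    def volume_mm3(self, structure: str) -> float:
        return float(self.mask(structure).sum() * np.prod(self.voxel_size))

    def structure_names(self):
        present = np.unique(self.labels)
        inv = {v: k for k, v in self.label_names.items()}
        return [inv[v] for v in present if v != 0]


MAX_GRID_VOXELS = 64_000_000


def voxelize(
    eye: EyeModel,
    voxel_size: float = 0.2,
    shape: tuple[int, int, int] = (200, 200, 200),
    center: np.ndarray | None = None,
    tissues: dict[str, TissueMaterial] | None = None,
) -> LabeledGrid:
    """Voxelize the eye onto a regular grid centered on the globe.

    The label of each voxel is decided at its center by the innermost
    containing structure; density and WER are filled from the tissue table
    (brain counts as water).
    """
    if voxel_size <= 0:
        raise EyeGeometryError("voxel size must be positive")
    shape = tuple(int(n) for n in shape)
    if np.prod(shape) > MAX_GRID_VOXELS:
        raise MemoryError(f"grid {shape} exceeds the configured voxel cap")
    if center is None:
        center = eye.translation
    vs = np.full(3, float(voxel_size))
    origin = np.asarray(center, float) - vs * (np.asarray(shape) - 1) / 2.0
    xs = origin[0] + np.arange(shape[0]) * vs[0]
    ys = origin[1] + np.arange(shape[1]) * vs[1]
    zs = origin[2] + np.arange(shape[2]) * vs[2]

    labels = np.empty(shape, dtype=np.uint8)
    for ix, x in enumerate(xs):  # slice-wise to bound memory
        yy, zz = np.meshgrid(ys, zs, indexing="ij")
        pts = np.column_stack(
            [np.full(yy.size, x), yy.ravel(), zz.ravel()]
        )
        labels[ix] = eye.label_points(pts).reshape(len(ys), len(zs))

    tis = tissues or tissue_table()
    density = np.full(shape, AIR_DENSITY)
    wer = np.full(shape, AIR_WER)
    for name, lab in LABELS.items():
        if name == "air":
            continue
        m = labels == lab
        if not m.any():
            continue
        if name == "brain":
            density[m], wer[m] = 1.0, 1.0
        else:
            density[m], wer[m] = tis[name].density, tis[name].wer
    return LabeledGrid(vs, origin, labels, density, wer)


# ---------------------------------------------------------------------------
# Simple water targets for commissioning-style runs
# ---------------------------------------------------------------------------

def water_box_grid(
    size_mm=(25.0, 25.0, 25.0),
    voxel_mm=(0.25, 0.5, 0.5),
    center=(0.0, 0.0, 0.0),
) -> LabeledGrid:
    """A uniform water box (labelled 'brain' for bookkeeping)."""
    size = np.asarray(size_mm, float)
    vs = np.asarray(voxel_mm, float)
    shape = tuple(np.maximum(np.round(size / vs).astype(int), 1))
    origin = np.asarray(center, float) - vs * (np.asarray(shape) - 1) / 2.0
    labels = np.full(shape, LABELS["brain"], dtype=np.uint8)
    return LabeledGrid(vs, origin, labels, np.ones(shape), np.ones(shape))


def thin_layer_grid(
    field_mm=(60.0, 60.0),
    pixel_mm=0.25,
    thickness_mm=1.0,
    center=(0.0, 0.0, 0.0),
) -> LabeledGrid:
    """A thin water layer for transverse profile scoring (film-like)."""
    ny = max(int(round(field_mm[0] / pixel_mm)), 1)
    nz = max(int(round(field_mm[1] / pixel_mm)), 1)
    vs = np.array([thickness_mm, pixel_mm, pixel_mm])
    shape = (1, ny, nz)
    origin = np.asarray(center, float) - vs * (np.asarray(shape) - 1) / 2.0
    labels = np.full(shape, LABELS["brain"], dtype=np.uint8)
    return LabeledGrid(vs, origin, labels, np.ones(shape), np.ones(shape))


def export_metaimage(grid: LabeledGrid, array: np.ndarray, basename: str) -> None:
    """Write a MetaImage-style text header plus raw data file."""
    raw = f"{basename}.raw"
    arr = np.ascontiguousarray(array.astype(np.float32))
    arr.tofile(raw)
    with open(f"{basename}.mhd", "w") as fh:
        fh.write("ObjectType = Image\nNDims = 3\nBinaryData = True\n")
        fh.write("BinaryDataByteOrderMSB = False\n")
        fh.write(f"DimSize = {arr.shape[0]} {arr.shape[1]} {arr.shape[2]}\n")
        fh.write(
            "ElementSpacing = "
            f"{grid.voxel_size[0]} {grid.voxel_size[1]} {grid.voxel_size[2]}\n"
        )
        fh.write(f"Offset = {grid.origin[0]} {grid.origin[1]} {grid.origin[2]}\n")
        fh.write("ElementType = MET_FLOAT\n")
        fh.write(f"ElementDataFile = {raw.split('/')[-1]}\n")


def read_metaimage(basename: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Read back a grid written by :func:`export_metaimage`.

    Returns (array, voxel_size, origin)."""
    import os

    header: dict[str, str] = {}
    with open(f"{basename}.mhd") as fh:
        for line in fh:
            k, _, v = line.partition("=")
            header[k.strip()] = v.strip()
    shape = tuple(int(x) for x in header["DimSize"].split())
    vs = np.array([float(x) for x in header["ElementSpacing"].split()])
    origin = np.array([float(x) for x in header["Offset"].split()])
    raw = os.path.join(os.path.dirname(basename) or ".", header["ElementDataFile"])
    arr = np.fromfile(raw, dtype=np.float32).reshape(shape)
    return arr, vs, origin
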