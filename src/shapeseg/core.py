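"""Volumes, binary masks and triangle meshes, with standard-format I/O.

Conventions used throughout the toolkit:

* voxel arrays are indexed ``[i, j, k]`` with the *x* axis fastest
  (MetaImage order); the world coordinate of index ``(i, j, k)`` is
  ``origin + (i, j, k) * spacing`` (node-centered, all distances in mm);
* masks are strictly binary ``{0, 1}`` and stored as unsigned 8-bit;
* mesh vertices live in world millimetres.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk
from scipy import ndimage
from skimage import measure

from .errors import (
    CorruptFileError,
    DegenerateInputError,
    DimensionError,
    FormatError,
    TopologyError,
)

_VOLUME_EXTS = {".mhd", ".mha", ".nii", ".nii.gz"}


def _split_ext(path: str) -> str:
    p = str(path).lower()
    if p.endswith(".nii.gz"):
        return ".nii.gz"
    return os.path.splitext(p)[1]


@dataclass
class Volume:
    """A 3-D scalar image on a regular axis-aligned grid."""

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise DimensionError(f"expected 3-D voxel grid, got ndim={self.voxels.ndim}")
        if min(self.voxels.shape) < 2:
            raise DimensionError("grid dimensions must be >= 2 per axis")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or len(self.origin) != 3:
            raise DimensionError("spacing and origin must have 3 components")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing components must be positive, got {self.spacing}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("voxel values must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        """World coordinate (mm) of fractional voxel indices, shape (..., 3)."""
        return np.asarray(self.origin) + np.asarray(idx, dtype=float) * np.asarray(self.spacing)

    def world_to_index(self, xyz: np.ndarray) -> np.ndarray:
        """Fractional voxel index of world points, shape (..., 3)."""
        return (np.asarray(xyz, dtype=float) - np.asarray(self.origin)) / np.asarray(self.spacing)

    def same_grid(self, other: "Volume") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )


@dataclass
class LabelMask(Volume):
    """A binary segmentation mask; voxel values restricted to {0, 1}."""

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels)
        if not np.isin(vox, (0, 1)).all():
            raise ValueError("mask values must be exactly in {0, 1}")
        self.voxels = vox.astype(np.uint8)
        super().__post_init__()

    @property
    def volume_mm3(self) -> float:
        return float(self.voxels.sum()) * float(np.prod(self.spacing))


@dataclass
class SurfaceMesh:
    """Triangulated surface in world millimetres."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if len(self.faces) and self.faces.max() >= len(self.vertices):
            raise DimensionError("face index out of range")
        if len(self.faces) and (
            (self.faces[:, 0] == self.faces[:, 1])
            | (self.faces[:, 1] == self.faces[:, 2])
            | (self.faces[:, 0] == self.faces[:, 2])
        ).any():
            raise TopologyError("degenerate face repeats a vertex")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def edges(self) -> np.ndarray:
        e = np.vstack([self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]])
        return np.sort(e, axis=1)

    def is_closed(self) -> bool:
        """True when every undirected edge is shared by exactly two faces."""
        e = self.edges()
        _, counts = np.unique(e, axis=0, return_counts=True)
        return bool((counts == 2).all())

    def euler_characteristic(self) -> int:
        n_edges = len(np.unique(self.edges(), axis=0))
        return self.n_vertices - n_edges + len(self.faces)

    def vertex_normals(self) -> np.ndarray:
        """Area-weighted outward vertex normals (unit length)."""
        v, f = self.vertices, self.faces
        fn = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
        normals = np.zeros_like(v)
        for c in range(3):
            np.add.at(normals, f[:, c], fn)
        norm = np.linalg.norm(normals, axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        return normals / norm

    def bounding_box_diagonal(self) -> float:
        return float(np.linalg.norm(self.vertices.max(0) - self.vertices.min(0)))

    def to_trimesh(self):
        import trimesh

        return trimesh.Trimesh(self.vertices.copy(), self.faces.copy(), process=False)


# ---------------------------------------------------------------------------
# volume I/O (MetaImage + NIfTI via SimpleITK)
# ---------------------------------------------------------------------------


def _check_axis_aligned(img: sitk.Image) -> None:
    d = np.asarray(img.GetDirection()).reshape(3, 3)
    if not np.allclose(d, np.eye(3), atol=1e-6):
        raise FormatError(
            "only axis-aligned volumes are supported; direction matrix is not the identity"
        )


def read_volume(path: str) -> Volume:
    """Read a MetaImage (.mhd/.mha) or NIfTI (.nii/.nii.gz) volume.

    Intensities are returned unmodified; spacing and origin are taken from
    the header.  Non-axis-aligned orientation matrices are rejected.
    """
    ext = _split_ext(path)
    if ext not in _VOLUME_EXTS:
        raise FormatError(f"unsupported volume extension {ext!r} for {path}")
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:  # SimpleITK wraps header/size mismatches here
        raise CorruptFileError(f"cannot read {path}: {exc}") from exc
    if img.GetDimension() != 3:
        raise FormatError(f"expected a 3-D volume, got {img.GetDimension()}-D")
    _check_axis_aligned(img)
    arr = sitk.GetArrayFromImage(img)  # (z, y, x)
    voxels = np.ascontiguousarray(arr.transpose(2, 1, 0))
    return Volume(voxels, tuple(img.GetSpacing()), tuple(img.GetOrigin()))


def read_mask(path: str) -> LabelMask:
    vol = read_volume(path)
    return LabelMask(vol.voxels, vol.spacing, vol.origin)


def write_volume(vol: Volume, path: str) -> None:
    """Write a volume losslessly in MetaImage or NIfTI format."""
    ext = _split_ext(path)
    if ext not in _VOLUME_EXTS:
        raise FormatError(f"unsupported volume extension {ext!r} for {path}")
    arr = np.ascontiguousarray(vol.voxels.transpose(2, 1, 0))
    img = sitk.GetImageFromArray(arr)
    img.SetSpacing([float(s) for s in vol.spacing])
    img.SetOrigin([float(o) for o in vol.origin])
    try:
        sitk.WriteImage(img, str(path))
    except RuntimeError as exc:
        raise IOError(f"cannot write {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# mesh I/O (PLY via trimesh, legacy-VTK polydata hand-rolled)
# ---------------------------------------------------------------------------


def read_mesh(path: str) -> SurfaceMesh:
    ext = os.path.splitext(str(path).lower())[1]
    if ext == ".ply":
        import trimesh

        tm = trimesh.load(str(path), file_type="ply", process=False)
        return SurfaceMesh(np.asarray(tm.vertices), np.asarray(tm.faces))
    if ext == ".vtk":
        return _read_vtk_polydata(path)
    raise FormatError(f"unsupported mesh extension {ext!r}")


def write_mesh(mesh: SurfaceMesh, path: str, binary: bool = True) -> None:
    ext = os.path.splitext(str(path).lower())[1]
    if ext == ".ply":
        mesh.to_trimesh().export(str(path), encoding="binary" if binary else "ascii")
        return
    if ext == ".vtk":
        _write_vtk_polydata(mesh, path)
        return
    raise FormatError(f"unsupported mesh extension {ext!r}")


def _write_vtk_polydata(mesh: SurfaceMesh, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nshapeseg surface\nASCII\nDATASET POLYDATA\n")
        fh.write(f"POINTS {mesh.n_vertices} float\n")
        for p in mesh.vertices:
            fh.write(f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}\n")
        nf = len(mesh.faces)
        fh.write(f"POLYGONS {nf} {4 * nf}\n")
        for f in mesh.faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")


def _read_vtk_polydata(path: str) -> SurfaceMesh:
    with open(path) as fh:
        tokens = fh.read().split()
    up = [t.upper() for t in tokens]
    if "POLYDATA" not in up:
        raise FormatError(f"{path} is not a legacy VTK polydata file")
    try:
        ip = up.index("POINTS")
        n_pts = int(tokens[ip + 1])
        coords = np.array(tokens[ip + 3 : ip + 3 + 3 * n_pts], dtype=float).reshape(-1, 3)
        if_ = up.index("POLYGONS")
        total = int(tokens[if_ + 2])
        flat = np.array(tokens[if_ + 3 : if_ + 3 + total], dtype=int)
    except (ValueError, IndexError) as exc:
        raise CorruptFileError(f"malformed VTK polydata in {path}") from exc
    faces = []
    pos = 0
    while pos < len(flat):
        cnt = flat[pos]
        if cnt != 3:
            raise FormatError("only triangle polygons are supported")
        faces.append(flat[pos + 1 : pos + 4])
        pos += cnt + 1
    return SurfaceMesh(coords, np.array(faces))


# ---------------------------------------------------------------------------
# voxel mask <-> triangle surface
# ---------------------------------------------------------------------------


def mask_to_surface(mask: LabelMask, iso: float = 0.5, pad_border: bool = False) -> SurfaceMesh:
    """Extract the closed isosurface of a binary mask (marching cubes).

    Vertices are returned in world mm.  Foreground touching the grid border
    prevents a closed surface; set ``pad_border=True`` to zero-pad first.
    """
    if not 0.0 < iso < 1.0:
        raise ValueError("iso level must lie in (0, 1)")
    vox = mask.voxels
    if vox.sum() == 0:
        raise DegenerateInputError("mask contains no foreground voxels")
    touches = (
        vox[0].any() or vox[-1].any()
        or vox[:, 0].any() or vox[:, -1].any()
        or vox[:, :, 0].any() or vox[:, :, -1].any()
    )
    offset = np.zeros(3)
    if touches:
        if not pad_border:
            raise DegenerateInputError(
                "foreground touches the grid border; pass pad_border=True to auto-pad"
            )
        vox = np.pad(vox, 1)
        offset = -np.asarray(mask.spacing)
    verts, faces, _, _ = measure.marching_cubes(
        vox.astype(np.float32), level=iso, spacing=mask.spacing
    )
    verts = verts + np.asarray(mask.origin) + offset
    return SurfaceMesh(verts, faces)


def surface_to_mask(
    mesh: SurfaceMesh,
    shape: tuple[int, int, int],
    spacing=(1.0, 1.0, 1.0),
    origin=(0.0, 0.0, 0.0),
) -> LabelMask:
    """Voxelize a closed surface: voxel = 1 iff its center lies inside.

    Uses a z-column parity fill: for every (i, j) column of voxel centers the
    triangle crossings are collected and interior runs filled between
    successive crossing pairs.  Columns are jittered by a sub-nanometre
    epsilon so rays never pass exactly through mesh vertices or edges.
    """
    if not mesh.is_closed():
        raise TopologyError("surface_to_mask requires a closed (watertight) mesh")
    nx, ny, nz = shape
    spacing = np.asarray(spacing, dtype=float)
    origin = np.asarray(origin, dtype=float)
    # triangle vertices in fractional index coordinates
    tri = (mesh.vertices[mesh.faces] - origin) / spacing  # (n_tri, 3, 3)
    out = np.zeros(shape, dtype=np.uint8)
    eps = (1e-7, 2.3e-7)

    cols: list[np.ndarray] = []
    zs: list[np.ndarray] = []
    for t in tri:
        lo = np.floor(t[:, :2].min(0)).astype(int)
        hi = np.ceil(t[:, :2].max(0)).astype(int)
        i0, j0 = np.maximum(lo, 0)
        i1, j1 = np.minimum(hi, (nx - 1, ny - 1))
        if i1 < i0 or j1 < j0:
            continue
        ii, jj = np.meshgrid(
            np.arange(i0, i1 + 1), np.arange(j0, j1 + 1), indexing="ij"
        )
        px = ii.ravel() + eps[0]
        py = jj.ravel() + eps[1]
        # barycentric coordinates in the xy projection
        ax, ay = t[0, 0], t[0, 1]
        bx, by = t[1, 0], t[1, 1]
        cx, cy = t[2, 0], t[2, 1]
        det = (by - cy) * (ax - cx) + (cx - bx) * (ay - cy)
        if abs(det) < 1e-14:  # triangle edge-on to the z axis: no crossing
            continue
        w0 = ((by - cy) * (px - cx) + (cx - bx) * (py - cy)) / det
        w1 = ((cy - ay) * (px - cx) + (ax - cx) * (py - cy)) / det
        w2 = 1.0 - w0 - w1
        inside = (w0 >= 0) & (w1 >= 0) & (w2 >= 0)
        if not inside.any():
            continue
        z = w0[inside] * t[0, 2] + w1[inside] * t[1, 2] + w2[inside] * t[2, 2]
        cols.append(ii.ravel()[inside] * ny + jj.ravel()[inside])
        zs.append(z)
    if not cols:
        return LabelMask(out, tuple(spacing), tuple(origin))
    col = np.concatenate(cols)
    z = np.concatenate(zs)
    order = np.lexsort((z, col))
    col, z = col[order], z[order]
    starts = np.flatnonzero(np.r_[True, col[1:] != col[:-1]])
    ends = np.r_[starts[1:], len(col)]
    flat = out.reshape(nx * ny, nz)
    for s, e in zip(starts, ends):
        c = col[s]
        crossings = z[s:e]
        n_pairs = len(crossings) // 2
        for p in range(n_pairs):
            k0 = int(np.ceil(crossings[2 * p]))
            k1 = int(np.floor(crossings[2 * p + 1]))
            if k1 >= 0 and k0 < nz:
                flat[c, max(k0, 0) : min(k1, nz - 1) + 1] = 1
    return LabelMask(out, tuple(spacing), tuple(origin))


def resample_volume(vol: Volume, new_spacing) -> Volume:
    """Trilinear resample onto a grid with the requested spacing (same extent)."""
    new_spacing = np.asarray(new_spacing, dtype=float)
    factors = np.asarray(vol.spacing) / new_spacing
    data = ndimage.zoom(vol.voxels.astype(float), factors, order=1, mode="nearest")
    return Volume(data, tuple(new_spacing), vol.origin)
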