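"""Discrete 3D phantom geometry: a stented, contrast-filled tube in gel.

The experimental object being modelled is a plastic tube (inner diameter
5-13 mm) embedded in a solid gel block with muscle-like relaxation times,
filled with a gadolinium chelate solution, and holding a cylindrical
wire-mesh stent.  The tube/stent axis is aligned with the grid z axis,
which is also the B0 direction of the scanner.

The rasterizer produces a :class:`LabelVolume`: an integer voxel grid with

====  =================
0     background gel
1     tube wall (plastic, signal-free)
2     lumen fluid (Gd solution)
3     stent strut (metal, signal-free susceptibility source)
====  =================

Strut micro-geometry of commercial stents is proprietary and is not
reproduced; stents are modelled as counter-wound helix families (mesh and
covered designs), ring-and-bridge cages (slotted-tube designs) or a single
helix (coil designs).  Artifact severity is controlled by the material
parameters, not by per-product cell patterns.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .materials import MaterialProps, get_material

__all__ = [
    "LABEL_GEL",
    "LABEL_WALL",
    "LABEL_LUMEN",
    "LABEL_STRUT",
    "TubeSpec",
    "StentSpec",
    "LabelVolume",
    "rasterize_phantom",
    "load_phantom_config",
]

LABEL_GEL = 0
LABEL_WALL = 1
LABEL_LUMEN = 2
LABEL_STRUT = 3

#: Stent designs the rasterizer knows how to build.
DESIGNS = ("mesh", "slotted_tube", "coil", "covered")


@dataclass
class TubeSpec:
    """Plastic tube filled with Gd solution, embedded in gel.

    Relaxation defaults: the gel mimics muscle at 1.5 T (T1 870 ms); the
    lumen T1 is derived from the Gd concentration via the longitudinal
    relaxivity unless given explicitly.  T2* values are pre-artifact
    baselines; susceptibility-induced dephasing is added by the simulator.
    """

    inner_diameter: float  # mm
    wall_thickness: float  # mm; <0.3 for small tubes, ~1 for 10/13 mm tubes
    length: float  # mm
    lumen_T1: float | None = None  # ms; None -> from gd_concentration
    lumen_T2star: float = 100.0  # ms
    background_T1: float = 870.0  # ms, muscle-like gel
    background_T2star: float = 50.0  # ms
    gd_concentration: float = 25.0  # mmol/L
    r1_relaxivity: float = 4.5  # L/(mmol*s) at 1.5 T
    solvent_T1: float = 3000.0  # ms, water

    def __post_init__(self) -> None:
        if self.inner_diameter <= 0 or self.length <= 0 or self.wall_thickness < 0:
            raise ValueError("tube dimensions must be positive")
        if self.gd_concentration < 0:
            raise ValueError("gd_concentration must be >= 0")


@dataclass
class StentSpec:
    """Geometry and material of one stent.

    ``n_helical_wires`` counts wire starts per winding direction for mesh
    designs (the rasterizer lays down the same number counter-wound), bridge
    bars for slotted tubes, and helix starts for coils.  Zero wires yields
    an unstented tube, useful as a control.
    """

    id: int
    name: str
    material: MaterialProps
    nominal_diameter: float  # mm
    length: float  # mm
    strut_radius: float = 0.1  # mm
    n_helical_wires: int = 8
    design: str = "mesh"

    def __post_init__(self) -> None:
        if self.design not in DESIGNS:
            raise ValueError(f"design must be one of {DESIGNS}, got {self.design!r}")
        if self.length <= 0 or self.nominal_diameter <= 0:
            raise ValueError("stent dimensions must be positive")
        if not (0 < self.strut_radius < 0.3):
            raise ValueError("strut_radius must be in (0, 0.3) mm")
        if self.n_helical_wires < 0:
            raise ValueError("n_helical_wires must be >= 0")


@dataclass
class LabelVolume:
    """Labelled voxel grid of the phantom.

    Axes are (x, y, z) with the tube axis along z (parallel to B0).  Voxel
    (i, j, k) is centred at physical position ``(i - (nx-1)/2, j - (ny-1)/2,
    k) * voxel_size``; the tube axis passes through x = y = 0.
    """

    labels: np.ndarray  # int8, shape (nx, ny, nz)
    voxel_size: float  # mm, isotropic
    stent_extent: tuple[int, int]  # half-open z-index interval of the stent
    lumen_radius: float  # mm
    tube: TubeSpec | None = None
    stent: StentSpec | None = None
    #: fraction of a strut voxel actually occupied by wire (wire
    #: cross-section over voxel cross-section, capped at 1).  Struts are
    #: sub-voxel on realistic grids; the simulator scales both the missing
    #: signal and the susceptibility source by this fraction so results
    #: converge with grid refinement instead of inflating the wire.
    strut_fill: float = 1.0

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def axis_index(self) -> tuple[float, float]:
        """(x, y) voxel index of the tube axis (may be fractional)."""
        nx, ny, _ = self.labels.shape
        return ((nx - 1) / 2.0, (ny - 1) / 2.0)

    def to_nifti(self, path: str | Path) -> None:
        """Write the label map as an integer NIfTI with voxel size in the header."""
        import nibabel as nib

        affine = np.diag([self.voxel_size] * 3 + [1.0])
        img = nib.Nifti1Image(self.labels.astype(np.int16), affine)
        img.header.set_zooms((self.voxel_size,) * 3)
        nib.save(img, str(path))


def _axis_coords(n: int, voxel: float) -> np.ndarray:
    return (np.arange(n) - (n - 1) / 2.0) * voxel


def rasterize_phantom(
    tube: TubeSpec,
    stent: StentSpec | None,
    grid_voxel: float = 0.25,
    pad: float = 5.0,
) -> LabelVolume:
    """Rasterize tube + stent onto a fine isotropic grid.

    Parameters
    ----------
    tube, stent
        Declarative phantom description.  ``stent=None`` (or a stent with
        zero wires) produces an unstented control tube.
    grid_voxel
        Fine-grid voxel edge in mm.  Should be well below the acquisition
        voxel; a value above twice the strut radius is accepted but the
        struts then occupy single-voxel chains.
    pad
        Gel margin around the tube outer wall, mm (>= 5 recommended so the
        susceptibility field decays inside the grid).

    Notes
    -----
    A stent wider than the tube is clamped to the tube inner diameter with
    a warning (constrained expansion — e.g. a 6 mm stent deployed in a 5 mm
    tube).  A wall thinner than one voxel is omitted with a warning.
    """
    if grid_voxel <= 0:
        raise ValueError("grid_voxel must be positive")
    if pad < 0:
        raise ValueError("pad must be >= 0")
    if stent is not None and stent.length > tube.length:
        raise ValueError(
            f"stent length {stent.length} mm exceeds tube length {tube.length} mm"
        )

    r_in = tube.inner_diameter / 2.0
    r_out = r_in + tube.wall_thickness
    half_xy = r_out + pad

    nx = ny = int(np.ceil(2 * half_xy / grid_voxel))
    nz = int(np.round(tube.length / grid_voxel))
    x = _axis_coords(nx, grid_voxel)
    y = _axis_coords(ny, grid_voxel)
    rr = np.hypot(x[:, None], y[None, :])  # in-plane radius, mm

    labels = np.zeros((nx, ny, nz), dtype=np.int8)
    lumen2d = rr <= r_in
    labels[lumen2d, :] = LABEL_LUMEN

    if tube.wall_thickness >= grid_voxel:
        wall2d = (rr > r_in) & (rr <= r_out)
        labels[wall2d, :] = LABEL_WALL
    elif tube.wall_thickness > 0:
        warnings.warn(
            f"tube wall ({tube.wall_thickness} mm) thinner than one voxel "
            f"({grid_voxel} mm); wall omitted",
            stacklevel=2,
        )

    if stent is None or stent.n_helical_wires == 0:
        mid = nz // 2
        extent = (mid, mid) if stent is None else _centered_extent(stent.length, grid_voxel, nz)
        return LabelVolume(labels, grid_voxel, extent, r_in, tube, stent)

    fill = min(1.0, np.pi * stent.strut_radius**2 / grid_voxel**2)

    r_stent_nominal = stent.nominal_diameter / 2.0
    if r_stent_nominal > r_in + grid_voxel:
        warnings.warn(
            f"stent diameter {stent.nominal_diameter} mm exceeds tube inner "
            f"diameter {tube.inner_diameter} mm; clamping to the tube",
            stacklevel=2,
        )
    r_strut = min(r_stent_nominal, r_in) - stent.strut_radius
    if r_strut <= 0:
        raise ValueError("stent too small: strut radius exceeds stent radius")

    z0_idx, z1_idx = _centered_extent(stent.length, grid_voxel, nz)
    strut_mask = _strut_mask(
        stent, (nx, ny, nz), grid_voxel, r_strut, (z0_idx, z1_idx)
    )
    labels[strut_mask] = LABEL_STRUT

    return LabelVolume(
        labels, grid_voxel, (z0_idx, z1_idx), r_in, tube, stent, strut_fill=fill
    )


def _centered_extent(length_mm: float, voxel: float, nz: int) -> tuple[int, int]:
    n_slices = int(np.round(length_mm / voxel))
    z0 = (nz - n_slices) // 2
    return (z0, z0 + n_slices)


def _mark_points(
    mask: np.ndarray,
    pts_x: np.ndarray,
    pts_y: np.ndarray,
    pts_z: np.ndarray,
    voxel: float,
    shape: tuple[int, int, int],
) -> None:
    """Set mask voxels nearest to physical curve samples (x, y in mm, z in index)."""
    nx, ny, nz = shape
    ix = np.round(pts_x / voxel + (nx - 1) / 2.0).astype(int)
    iy = np.round(pts_y / voxel + (ny - 1) / 2.0).astype(int)
    iz = np.round(pts_z).astype(int)
    ok = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny) & (iz >= 0) & (iz < nz)
    mask[ix[ok], iy[ok], iz[ok]] = True


def _strut_mask(
    stent: StentSpec,
    shape: tuple[int, int, int],
    voxel: float,
    r_strut: float,
    extent: tuple[int, int],
) -> np.ndarray:
    """Voxel mask of the strut cage for the requested design."""
    nx, ny, nz = shape
    z0, z1 = extent
    mask = np.zeros(shape, dtype=bool)
    n = stent.n_helical_wires
    pitch_mm = stent.length / 6.0
    pitch_vox = pitch_mm / voxel

    # sample curves 4x finer than the grid so strut chains stay connected
    zs = np.arange(z0, z1, 0.25)
    if stent.design in ("mesh", "covered", "coil"):
        hands = (1.0, -1.0) if stent.design in ("mesh", "covered") else (1.0,)
        for hand in hands:
            for j in range(n):
                theta = 2 * np.pi * (hand * (zs - z0) / pitch_vox + j / n)
                _mark_points(
                    mask,
                    r_strut * np.cos(theta),
                    r_strut * np.sin(theta),
                    zs,
                    voxel,
                    shape,
                )
    elif stent.design == "slotted_tube":
        # ring-and-bridge cage: circumferential rings every pitch plus n
        # axial bars; bar angles are symmetric under y -> -y, so the cage is
        # mirror-symmetric about the tube axis up to rasterization
        x = _axis_coords(nx, voxel)
        y = _axis_coords(ny, voxel)
        rr = np.hypot(x[:, None], y[None, :])
        shell2d = np.abs(rr - r_strut) <= max(stent.strut_radius, 0.55 * voxel)
        ring_zs = np.arange(z0, z1, max(pitch_vox, 1.0))
        for zr in ring_zs:
            mask[:, :, int(round(zr))] |= shell2d
        mask[:, :, min(z1 - 1, nz - 1)] |= shell2d  # closing ring
        ang = np.arctan2(y[None, :], x[:, None] + 0.0)
        half_width = max(stent.strut_radius, 0.55 * voxel) / r_strut
        for k in range(n):
            bar_angle = 2 * np.pi * k / n
            d = np.angle(np.exp(1j * (ang - bar_angle)))
            bar2d = shell2d & (np.abs(d) <= half_width)
            mask[:, :, z0:z1] |= bar2d[:, :, None]
    mask[:, :, :z0] = False
    mask[:, :, z1:] = False
    return mask


# ---------------------------------------------------------------------------
# declarative configs


def _tube_from_dict(d: dict) -> TubeSpec:
    return TubeSpec(**d)


def _stent_from_dict(d: dict) -> StentSpec:
    d = dict(d)
    mat = d.pop("material")
    if isinstance(mat, str):
        material = get_material(mat)
    else:
        material = MaterialProps(**mat)
    return StentSpec(material=material, **d)


def load_phantom_config(path: str | Path) -> tuple[TubeSpec, StentSpec | None]:
    """Load a phantom description from a YAML or JSON file.

    The file holds a mapping with keys ``tube`` (TubeSpec fields) and
    optionally ``stent`` (StentSpec fields; ``material`` may be a registry
    name or a mapping of MaterialProps fields).
    """
    path = Path(path)
    text = path.read_text()
    cfg = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    tube = _tube_from_dict(cfg["tube"])
    stent = _stent_from_dict(cfg["stent"]) if "stent" in cfg else None
    return tube, stent
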