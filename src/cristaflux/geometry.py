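"""Discretized spatial models of mitochondrial cristae.

A model is a uniform Cartesian grid of cells classified as matrix (solid,
represented by a single well-mixed pool), external solute domain (crista
lumens plus a thin boundary layer standing in for the OM gap/cytosol), and
Dirichlet cells (the outermost ring, where cytosolic concentrations are
held fixed).  Membrane surface elements are the faces separating matrix
cells from external cells; each face is labelled IBM (inner boundary
membrane, facing the boundary layer) or crista membrane (facing a lumen),
giving an exact surface-area ledger S_IM = S_IBM + S_CRIS.

Crista junctions (CJs) are open apertures: gaps in the membrane where a
lumen communicates with the boundary layer.  In 3-D the narrow (20 nm)
tubular CJ is modelled as a short neck channel through the membrane plane.

Default building blocks mirror the simulated morphology: 20 nm wide crista
lumens spaced 20 nm apart in 2-D; 150 nm wide lamellar cristae with 20 nm
lumens in 3-D.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SpatialModel",
    "Midline",
    "GeometryError",
    "build_uniform_2d",
    "build_no_crista_2d",
    "build_variable_2d",
    "build_lamellar_3d",
    "build_no_crista_3d",
    "surface_ledger",
    "external_components",
]

# Cell classes
MATRIX = 0
EXTERNAL = 1
DIRICHLET = 2

# Region labels for external cells
LAYER = 0  # boundary layer (OM gap / cytosol side)

# Canonical dimensions, μm
LUMEN_W = 0.02  # crista lumen width
WALL = 0.02  # matrix wall between adjacent cristae
PITCH = LUMEN_W + WALL
BOUNDARY_LAYER = 0.02  # gap between IBM and the Dirichlet outer boundary
CRISTA_W_3D = 0.15  # lamellar crista width
DEPTH_2D = 1.0  # unit depth used to express 2-D areas/volumes


class GeometryError(ValueError):
    """Raised for inconsistent geometric specifications."""


def _check_h(h: float, boundary_layer: float) -> None:
    # The canonical 20 nm building blocks must rasterize exactly, otherwise
    # lumen widths and boundary layers become asymmetric.
    for name, d in (("lumen width", LUMEN_W), ("wall", WALL),
                    ("boundary layer", boundary_layer)):
        if abs(d / h - round(d / h)) > 1e-6:
            raise GeometryError(
                f"grid spacing {h} um does not divide the {name} ({d} um); "
                "use a spacing such as 0.01, 0.005, 0.004, 0.002 or 0.001 um")


@dataclass
class Midline:
    """Sampling path along a crista lumen centreline.

    ``cells`` are flat cell indices ordered from the CJ opening (or the
    sealed tip for detached cristae); ``x`` are distances (μm) from the
    opening at the cell centres; ``length`` is the crista length.
    """

    cells: np.ndarray
    x: np.ndarray
    length: float
    label: str = ""


@dataclass
class SpatialModel:
    """A discretized crista geometry with its membrane-surface ledger."""

    dim: int
    h: float
    cell_type: np.ndarray  # int8 array, MATRIX/EXTERNAL/DIRICHLET
    region: np.ndarray  # int32: -1 matrix, 0 layer, >=1 crista id
    face_cells: np.ndarray  # flat index of the external cell at each membrane face
    face_is_ibm: np.ndarray  # bool per face
    face_crista: np.ndarray  # crista id per face (0 for IBM faces)
    face_area: np.ndarray  # μm² per face
    matrix_volume: float  # μm³
    midlines: dict = field(default_factory=dict)
    depth: float = DEPTH_2D  # out-of-plane depth for 2-D models, μm
    meta: dict = field(default_factory=dict)

    @property
    def shape(self):
        return self.cell_type.shape

    @property
    def cell_volume(self) -> float:
        return self.h**2 * self.depth if self.dim == 2 else self.h**3

    @property
    def n_cristae(self) -> int:
        return int(self.region.max())

    def external_mask(self) -> np.ndarray:
        return self.cell_type != MATRIX

    def free_mask(self) -> np.ndarray:
        return self.cell_type == EXTERNAL


def surface_ledger(model: SpatialModel) -> tuple[float, float, float]:
    """Return (S_IBM, S_CRIS, S_IM) in μm², summed over membrane elements."""
    s_ibm = float(model.face_area[model.face_is_ibm].sum())
    s_cris = float(model.face_area[~model.face_is_ibm].sum())
    return s_ibm, s_cris, s_ibm + s_cris


def _idx(coord: float, h: float) -> int:
    return int(round(coord / h))


def _collect_faces(model: SpatialModel) -> None:
    """Find matrix|external faces and classify them by the external region."""
    ct, rg = model.cell_type, model.region
    dim = model.dim
    face_cells, face_ibm, face_cr = [], [], []
    ext = ct != MATRIX
    for axis in range(dim):
        lo = tuple(slice(0, -1) if a == axis else slice(None) for a in range(dim))
        hi = tuple(slice(1, None) if a == axis else slice(None) for a in range(dim))
        mat_lo = (~ext[lo]) & ext[hi]
        mat_hi = ext[lo] & (~ext[hi])
        # external cell is on the "hi" side
        idx = np.argwhere(mat_lo)
        if idx.size:
            idx[:, axis] += 1
            flat = np.ravel_multi_index(idx.T, ct.shape)
            face_cells.append(flat)
            r = rg.reshape(-1)[flat]
            face_ibm.append(r == LAYER)
            face_cr.append(np.where(r > 0, r, 0))
        # external cell is on the "lo" side
        idx = np.argwhere(mat_hi)
        if idx.size:
            flat = np.ravel_multi_index(idx.T, ct.shape)
            face_cells.append(flat)
            r = rg.reshape(-1)[flat]
            face_ibm.append(r == LAYER)
            face_cr.append(np.where(r > 0, r, 0))
    if face_cells:
        model.face_cells = np.concatenate(face_cells)
        model.face_is_ibm = np.concatenate(face_ibm)
        model.face_crista = np.concatenate(face_cr).astype(np.int32)
    else:
        model.face_cells = np.empty(0, dtype=np.int64)
        model.face_is_ibm = np.empty(0, dtype=bool)
        model.face_crista = np.empty(0, dtype=np.int32)
    area = model.h * model.depth if dim == 2 else model.h**2
    model.face_area = np.full(model.face_cells.shape, area)


def _finalize(model: SpatialModel) -> SpatialModel:
    # Dirichlet cells: outermost ring of external cells
    ct = model.cell_type
    ring = np.zeros(ct.shape, dtype=bool)
    for axis in range(model.dim):
        sl0 = tuple(0 if a == axis else slice(None) for a in range(model.dim))
        sl1 = tuple(-1 if a == axis else slice(None) for a in range(model.dim))
        ring[sl0] = True
        ring[sl1] = True
    ct[ring & (ct == EXTERNAL)] = DIRICHLET
    _collect_faces(model)
    model.matrix_volume = float((ct == MATRIX).sum()) * model.cell_volume
    return model


# ---------------------------------------------------------------------------
# 2-D builders


def _column_midline(model, ix_center, j0, j1, from_top: bool, label, length, extra=()):
    """Midline along a lumen column; j0..j1 inclusive index range (y)."""
    js = np.arange(j0, j1 + 1)
    if from_top:
        js = js[::-1]
    cells = np.ravel_multi_index((np.full(js.shape, ix_center), js), model.shape)
    x = (np.arange(js.size) + 0.5) * model.h
    return Midline(cells=cells, x=x, length=length, label=label)


def build_uniform_2d(
    L_CRIS: float,
    cj_config: str,
    domain_w: float = 0.76,
    domain_h: float | None = None,
    h: float = 0.002,
    boundary_layer: float = BOUNDARY_LAYER,
) -> SpatialModel:
    """Array of parallel 2-D cristae spanning the domain width.

    Cristae are ``LUMEN_W`` wide at ``PITCH`` spacing (crista count =
    floor(domain_w / PITCH)), oriented vertically between the top and
    bottom inner boundary membranes.  ``cj_config`` is one of ``"none"``,
    ``"one_end"`` (open at the top IBM) or ``"both_ends"``.  The domain
    height defaults to the minimum that accommodates the cristae, their
    sealed tips, and the boundary layer.
    """
    if cj_config not in ("none", "one_end", "both_ends"):
        raise GeometryError(f"unknown cj_config {cj_config!r}")
    _check_h(h, boundary_layer)
    if L_CRIS < 0:
        raise GeometryError("L_CRIS must be >= 0")
    tip_walls = {"both_ends": 0, "one_end": 1, "none": 2}[cj_config]
    min_h = L_CRIS + tip_walls * WALL + 2 * boundary_layer
    if domain_h is None:
        domain_h = min_h
    elif domain_h < min_h - 1e-9:
        raise GeometryError(
            f"crista of length {L_CRIS} with config {cj_config!r} does not fit "
            f"in domain height {domain_h} (needs >= {min_h})"
        )
    nx, ny = _idx(domain_w, h), _idx(domain_h, h)
    ct = np.full((nx, ny), EXTERNAL, dtype=np.int8)
    rg = np.zeros((nx, ny), dtype=np.int32)
    j_lo, j_hi = _idx(boundary_layer, h), _idx(domain_h - boundary_layer, h)
    ct[:, j_lo:j_hi] = MATRIX
    rg[:, j_lo:j_hi] = -1
    n_cristae = int(np.floor(domain_w / PITCH + 1e-9))
    model = SpatialModel(2, h, ct, rg, None, None, None, None, 0.0)
    n_lumen = _idx(L_CRIS, h)
    j_top = _idx(domain_h - boundary_layer, h)  # exclusive upper lumen index
    if cj_config == "both_ends":
        jb, jt = j_lo, j_top
    elif cj_config == "one_end":
        jb, jt = j_top - n_lumen, j_top
    else:
        jb, jt = j_lo + _idx(WALL, h), j_lo + _idx(WALL, h) + n_lumen
    offset = (domain_w - n_cristae * PITCH) / 2.0
    for k in range(n_cristae):
        x0 = offset + k * PITCH + WALL / 2.0
        i0, i1 = _idx(x0, h), _idx(x0 + LUMEN_W, h)
        if n_lumen > 0:
            ct[i0:i1, jb:jt] = EXTERNAL
            rg[i0:i1, jb:jt] = k + 1
            ic = (i0 + i1) // 2
            model.midlines[k + 1] = _column_midline(
                model, ic, jb, jt - 1, from_top=(cj_config != "both_ends"),
                label=f"crista-{k + 1}", length=L_CRIS,
            )
    model.meta = {
        "builder": "uniform_2d", "L_CRIS": L_CRIS, "cj_config": cj_config,
        "domain_w": domain_w, "domain_h": domain_h, "h": h,
        "n_cristae": n_cristae if n_lumen > 0 else 0,
    }
    return _finalize(model)


def build_no_crista_2d(
    domain_w: float = 0.76,
    domain_h: float = 0.30,
    h: float = 0.002,
    boundary_layer: float = BOUNDARY_LAYER,
) -> SpatialModel:
    """Crista-free reference model (defines J_MAX); S_CRIS = 0."""
    m = build_uniform_2d(0.0, "both_ends", domain_w, domain_h, h, boundary_layer)
    m.meta["builder"] = "no_crista_2d"
    return m


def build_variable_2d(
    L_CRIS: float,
    h: float = 0.002,
    boundary_layer: float = BOUNDARY_LAYER,
) -> SpatialModel:
    """Variable-topology model: trunk with CJs at both ends plus two branches.

    The trunk (crista 1) spans the matrix slab with openings at both IBMs.
    Two side branches hang from the top IBM (each with its own CJ) and join
    the trunk through short transverse connectors at their far ends:
    branch 2 has length L_CRIS/3, branch 3 has length L_CRIS/4.
    """
    if L_CRIS <= 0:
        raise GeometryError("L_CRIS must be > 0")
    _check_h(h, boundary_layer)
    domain_h = L_CRIS + 2 * boundary_layer
    domain_w = 5 * PITCH  # trunk + one branch either side + margins
    nx, ny = _idx(domain_w, h), _idx(domain_h, h)
    ct = np.full((nx, ny), EXTERNAL, dtype=np.int8)
    rg = np.zeros((nx, ny), dtype=np.int32)
    j_lo, j_hi = _idx(boundary_layer, h), _idx(domain_h - boundary_layer, h)
    ct[:, j_lo:j_hi] = MATRIX
    rg[:, j_lo:j_hi] = -1
    model = SpatialModel(2, h, ct, rg, None, None, None, None, 0.0)

    xc = domain_w / 2.0
    cols = {1: xc - LUMEN_W / 2.0, 2: xc - PITCH - LUMEN_W / 2.0,
            3: xc + PITCH - LUMEN_W / 2.0}
    lengths = {1: L_CRIS, 2: L_CRIS / 3.0, 3: L_CRIS / 4.0}
    for cid, x0 in cols.items():
        i0, i1 = _idx(x0, h), _idx(x0 + LUMEN_W, h)
        if cid == 1:
            jb, jt = j_lo, j_hi
        else:
            jb, jt = j_hi - _idx(lengths[cid], h), j_hi
        ct[i0:i1, jb:jt] = EXTERNAL
        rg[i0:i1, jb:jt] = cid
        ic = (i0 + i1) // 2
        model.midlines[cid] = _column_midline(
            model, ic, jb, jt - 1, from_top=(cid != 1),
            label={1: "trunk", 2: "branch-third", 3: "branch-quarter"}[cid],
            length=lengths[cid],
        )
    # transverse connectors from each branch foot to the trunk
    for cid in (2, 3):
        i_trunk = (_idx(cols[1], h), _idx(cols[1] + LUMEN_W, h))
        i_br = (_idx(cols[cid], h), _idx(cols[cid] + LUMEN_W, h))
        jb = j_hi - _idx(lengths[cid], h)
        i0 = min(i_br[1], i_trunk[1])
        i1 = max(i_br[0], i_trunk[0])
        jcon0, jcon1 = jb, jb + _idx(LUMEN_W, h)
        ct[i0:i1, jcon0:jcon1] = EXTERNAL
        rg[i0:i1, jcon0:jcon1] = cid
    model.meta = {
        "builder": "variable_2d", "L_CRIS": L_CRIS, "domain_w": domain_w,
        "domain_h": domain_h, "h": h, "branch_lengths": [L_CRIS / 3, L_CRIS / 4],
    }
    return _finalize(model)


# ---------------------------------------------------------------------------
# 3-D builders


def build_lamellar_3d(
    L_CRIS: float,
    cj_mode,
    h: float = 0.005,
    n_cristae: int = 4,
    boundary_layer: float = BOUNDARY_LAYER,
) -> SpatialModel:
    """Stack of lamellar cristae attached to the top IBM face.

    Each crista is a slab ``CRISTA_W_3D`` (150 nm) wide with a 20 nm lumen,
    at 40 nm pitch.  ``cj_mode`` selects the attachment: ``"none"``
    (detached), ``"narrow"`` (one 20 nm tubular CJ, modelled as a 20 nm
    neck channel), ``"wide"`` (slit CJ equal in width to the crista), or an
    integer n (n equally spaced 20 nm CJs on the cis side).  The matrix box
    is wrapped in a boundary layer; its entire outer surface is IBM, which
    keeps S_CRIS/S_IBM in the 1.0–1.8 band across nominal crista lengths.
    """
    if isinstance(cj_mode, (int, np.integer)) and not isinstance(cj_mode, bool):
        n_cjs = int(cj_mode)
        if n_cjs < 1:
            raise GeometryError("number of cis CJs must be >= 1")
        mode = "n_cis"
    elif cj_mode in ("none", "narrow", "wide"):
        mode = cj_mode
        n_cjs = {"none": 0, "narrow": 1, "wide": 0}[mode]
    else:
        raise GeometryError(f"unknown cj_mode {cj_mode!r}")
    if L_CRIS <= 0:
        raise GeometryError("L_CRIS must be > 0")
    _check_h(h, boundary_layer)

    wall, bl = WALL, boundary_layer
    X = n_cristae * PITCH + wall  # walls between/around lumens
    Y = CRISTA_W_3D + 2 * wall
    tip_walls = 2 if mode == "none" else 1
    Z = L_CRIS + tip_walls * wall + 2 * bl
    W, H = X + 2 * bl, Y + 2 * bl
    nx, ny, nz = _idx(W, h), _idx(H, h), _idx(Z, h)
    ct = np.full((nx, ny, nz), EXTERNAL, dtype=np.int8)
    rg = np.zeros((nx, ny, nz), dtype=np.int32)
    # matrix box
    bx0, bx1 = _idx(bl, h), _idx(bl + X, h)
    by0, by1 = _idx(bl, h), _idx(bl + Y, h)
    bz0, bz1 = _idx(bl, h), _idx(Z - bl, h)
    ct[bx0:bx1, by0:by1, bz0:bz1] = MATRIX
    rg[bx0:bx1, by0:by1, bz0:bz1] = -1
    model = SpatialModel(3, h, ct, rg, None, None, None, None, 0.0)

    y0, y1 = _idx(bl + wall, h), _idx(bl + wall + CRISTA_W_3D, h)
    z_top = bz1  # exclusive top lumen index (= matrix top plane)
    n_lum = _idx(L_CRIS, h)
    neck = _idx(wall, h)
    for k in range(n_cristae):
        x0 = _idx(bl + wall + k * PITCH, h)
        x1 = x0 + _idx(LUMEN_W, h)
        if mode == "none":
            zb = bz0 + _idx(wall, h)
            zt = zb + n_lum
            ct[x0:x1, y0:y1, zb:zt] = EXTERNAL
            rg[x0:x1, y0:y1, zb:zt] = k + 1
        else:
            zb, zt = z_top - n_lum, z_top
            # body of the lumen, below the neck region
            ct[x0:x1, y0:y1, zb:zt - neck] = EXTERNAL
            rg[x0:x1, y0:y1, zb:zt - neck] = k + 1
            if mode == "wide":
                ct[x0:x1, y0:y1, zt - neck:zt] = EXTERNAL
                rg[x0:x1, y0:y1, zt - neck:zt] = k + 1
            else:  # n equally spaced narrow neck channels across the width
                span = CRISTA_W_3D / n_cjs
                for q in range(n_cjs):
                    yc = bl + wall + (q + 0.5) * span
                    a0 = _idx(yc - LUMEN_W / 2.0, h)
                    a1 = a0 + _idx(LUMEN_W, h)
                    ct[x0:x1, a0:a1, zt - neck:zt] = EXTERNAL
                    rg[x0:x1, a0:a1, zt - neck:zt] = k + 1
        ic, jc = (x0 + x1) // 2, (y0 + y1) // 2
        zs = np.arange(zb, zt)
        if mode != "none":
            zs = zs[::-1]
        else:
            zs = zs[::-1]  # measure from the top (IBM-proximal) tip
        cells = np.ravel_multi_index(
            (np.full(zs.shape, ic), np.full(zs.shape, jc), zs), ct.shape
        )
        model.midlines[k + 1] = Midline(
            cells=cells, x=(np.arange(zs.size) + 0.5) * h,
            length=L_CRIS, label=f"lamella-{k + 1}",
        )
    model.meta = {
        "builder": "lamellar_3d", "L_CRIS": L_CRIS, "cj_mode": mode,
        "n_cjs": n_cjs, "h": h, "n_cristae": n_cristae,
    }
    return _finalize(model)


def build_no_crista_3d(
    h: float = 0.005,
    n_cristae: int = 4,
    box_z: float = 0.30,
    boundary_layer: float = BOUNDARY_LAYER,
) -> SpatialModel:
    """Crista-free 3-D reference box with the same cross-section."""
    _check_h(h, boundary_layer)
    wall, bl = WALL, boundary_layer
    X = n_cristae * PITCH + wall
    Y = CRISTA_W_3D + 2 * wall
    Z = box_z + 2 * bl
    nx, ny, nz = _idx(X + 2 * bl, h), _idx(Y + 2 * bl, h), _idx(Z, h)
    ct = np.full((nx, ny, nz), EXTERNAL, dtype=np.int8)
    rg = np.zeros((nx, ny, nz), dtype=np.int32)
    ct[_idx(bl, h):_idx(bl + X, h), _idx(bl, h):_idx(bl + Y, h),
       _idx(bl, h):_idx(Z - bl, h)] = MATRIX
    rg[ct == MATRIX] = -1
    model = SpatialModel(3, h, ct, rg, None, None, None, None, 0.0)
    model.meta = {"builder": "no_crista_3d", "h": h}
    return _finalize(model)


# ---------------------------------------------------------------------------
# Diagnostics / export


def external_components(model: SpatialModel) -> np.ndarray:
    """Label face-connected components of the external domain (0 = matrix)."""
    from scipy import ndimage

    structure = ndimage.generate_binary_structure(model.dim, 1)
    labels, _ = ndimage.label(model.external_mask(), structure=structure)
    return labels


def save_npz(model: SpatialModel, path) -> None:
    np.savez_compressed(
        path, cell_type=model.cell_type, region=model.region, h=model.h,
        dim=model.dim,
    )


def save_vtk(model: SpatialModel, path, fields: dict | None = None) -> None:
    """Write cell classification (and optional cell fields) as legacy VTK."""
    shape = model.shape + (1,) if model.dim == 2 else model.shape
    n = int(np.prod(shape))
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\ncristaflux model\nASCII\n")
        fh.write("DATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {shape[0] + 1} {shape[1] + 1} {shape[2] + 1}\n")
        fh.write("ORIGIN 0 0 0\n")
        fh.write(f"SPACING {model.h} {model.h} {model.h}\n")
        fh.write(f"CELL_DATA {n}\n")
        arrays = {"cell_type": model.cell_type.astype(float)}
        arrays.update(fields or {})
        for name, arr in arrays.items():
            fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
            flat = np.asarray(arr).reshape(shape, order="C").flatten(order="F")
            np.savetxt(fh, flat, fmt="%.6g")
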