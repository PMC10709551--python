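"""Parametric vessel networks voxelized to classified lattices.

Networks are unions of capsules (cylinders with hemispherical joins);
smooth junction blending comes from the union of overlapping capsules.
Segment ends may carry axis-aligned planar caps that are stamped as
velocity-inlet or pressure-outlet site planes, and the idealized circle of
Willis builder produces the 3-inlet / 6-outlet network with removable
posterior communicating arteries.

Grid convention: 0-based indices, site centers at origin + (i + 1/2) dx,
right-handed axes.  Every non-periodic domain is padded by at least one
SOLID layer so the 19-point neighbourhood of any fluid site is defined.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .errors import GeometryError
from .lbm_core import D3Q19

SOLID, FLUID, INLET, OUTLET = 0, 1, 2, 3

_EPS = 1e-9


# --------------------------------------------------------------------------
# network specification
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SegmentSpec:
    """A straight vessel segment: two endpoints (m), radius (m).

    ``radius_end`` enables a linear taper.  ``cap_start`` / ``cap_end`` are
    ``(role, name)`` with role in {"inlet", "outlet", "closed"}; a capped
    end is closed flat at the endpoint plane (and the segment axis must be
    axis-aligned there), an uncapped end gets a hemispherical closure for
    smooth blending into junctions.
    """

    start: tuple
    end: tuple
    radius: float
    radius_end: float = None
    label: str = ""
    cap_start: tuple = None
    cap_end: tuple = None

    def __post_init__(self):
        p0 = np.asarray(self.start, float)
        p1 = np.asarray(self.end, float)
        if np.allclose(p0, p1):
            raise GeometryError(f"segment {self.label!r}: endpoints coincide")
        if self.radius <= 0 or (self.radius_end is not None
                                and self.radius_end <= 0):
            raise GeometryError(f"segment {self.label!r}: radius must be > 0")

    @property
    def r0(self):
        return self.radius

    @property
    def r1(self):
        return self.radius if self.radius_end is None else self.radius_end

    @property
    def min_radius(self):
        return min(self.r0, self.r1)

    def mirrored(self, axis, center):
        """Reflect through the plane ``x[axis] = center``."""
        p0 = list(self.start)
        p1 = list(self.end)
        p0[axis] = 2 * center - p0[axis]
        p1[axis] = 2 * center - p1[axis]
        return replace(self, start=tuple(p0), end=tuple(p1))


@dataclass(frozen=True)
class VesselNetworkSpec:
    """A list of segments plus the labels of removable segments."""

    segments: tuple
    removable: frozenset = frozenset()

    def __post_init__(self):
        names = [c[1] for s in self.segments
                 for c in (s.cap_start, s.cap_end)
                 if c is not None and c[0] in ("inlet", "outlet")]
        if len(names) != len(set(names)):
            raise GeometryError("iolet cap names must be unique")

    @property
    def inlet_names(self):
        return [c[1] for s in self.segments
                for c in (s.cap_start, s.cap_end)
                if c is not None and c[0] == "inlet"]

    @property
    def outlet_names(self):
        return [c[1] for s in self.segments
                for c in (s.cap_start, s.cap_end)
                if c is not None and c[0] == "outlet"]

    def remove(self, *labels):
        """Drop the named segments (they must be flagged removable)."""
        labels = set(labels)
        unknown = labels - {s.label for s in self.segments}
        if unknown:
            raise GeometryError(f"no such segment(s): {sorted(unknown)}")
        not_removable = labels - set(self.removable)
        if not_removable:
            raise GeometryError(
                f"segment(s) not flagged removable: {sorted(not_removable)}")
        return VesselNetworkSpec(
            segments=tuple(s for s in self.segments if s.label not in labels),
            removable=self.removable - frozenset(labels))

    def mirrored(self, axis, center):
        return VesselNetworkSpec(
            segments=tuple(s.mirrored(axis, center) for s in self.segments),
            removable=self.removable)


class CoWVariant(enum.Enum):
    """Circle-of-Willis anatomical variants examined by the pipeline."""

    FULL = "full"
    NO_PCOA_LEFT = "no_pcoa_left"
    NO_PCOA_RIGHT = "no_pcoa_right"


# --------------------------------------------------------------------------
# fixture builders
# --------------------------------------------------------------------------

def build_tube(radius, length):
    """Straight tube along +y: one inlet, one outlet."""
    if radius <= 0 or length <= 0:
        raise GeometryError("tube dimensions must be positive")
    seg = SegmentSpec(start=(0.0, 0.0, 0.0), end=(0.0, length, 0.0),
                      radius=radius, label="tube",
                      cap_start=("inlet", "in"), cap_end=("outlet", "out"))
    return VesselNetworkSpec(segments=(seg,))


def build_symmetric_bifurcation(parent_radius, daughter_radius, angle,
                                parent_length=None, daughter_length=None,
                                riser_length=None):
    """Parent tube along +y splitting into two mirror-symmetric daughters.

    Each daughter runs at ``angle`` (radians) from the parent axis, then
    turns back to +y for a short riser so the outlet caps are axis-aligned.
    """
    if parent_radius <= 0 or daughter_radius <= 0:
        raise GeometryError("radii must be positive")
    if angle <= 0 or angle >= np.pi / 2:
        raise GeometryError("daughter angle must lie in (0, pi/2)")
    Lp = 6 * parent_radius if parent_length is None else parent_length
    Ld = 6 * daughter_radius if daughter_length is None else daughter_length
    Lr = 4 * daughter_radius if riser_length is None else riser_length
    off = Ld * np.sin(angle)
    if off < daughter_radius:
        raise GeometryError(
            "daughters overlap degenerately: lateral offset "
            f"{off:.3g} m < daughter radius {daughter_radius:.3g} m")
    yj = Lp
    yd = yj + Ld * np.cos(angle)
    segs = [SegmentSpec((0.0, 0.0, 0.0), (0.0, Lp, 0.0), parent_radius,
                        label="parent", cap_start=("inlet", "in"))]
    for sgn, side in ((-1.0, "left"), (1.0, "right")):
        segs.append(SegmentSpec((0.0, yj, 0.0), (sgn * off, yd, 0.0),
                                daughter_radius, label=f"daughter-{side}"))
        segs.append(SegmentSpec((sgn * off, yd, 0.0),
                                (sgn * off, yd + Lr, 0.0),
                                daughter_radius, label=f"riser-{side}",
                                cap_end=("outlet", side)))
    return VesselNetworkSpec(segments=tuple(segs))


#: Default vessel radii for the idealized circle of Willis (m).  These are
#: literature-typical calibres, configurable per call.
COW_RADII = {
    "ICA": 2.0e-3, "BA": 1.6e-3, "MCA": 1.4e-3,
    "PCA": 1.2e-3, "ACA": 1.2e-3, "PCoA": 0.7e-3, "ACoA": 0.7e-3,
}


def build_idealized_cow(variant=CoWVariant.FULL, scale=1.0, radii=None):
    """Idealized planar circle of Willis with removable PCoA segments.

    Inlets: BA (basilar, posterior midline), LICA/RICA (internal carotids,
    entering vertically from below).  Outlets: L/R PCA, MCA, ACA.  The ring
    is mirror-symmetric about the midline; the two posterior communicating
    arteries join each carotid terminus to the ipsilateral PCA and are the
    removable segments defining the anatomical variants.
    """
    r = dict(COW_RADII)
    if radii:
        r.update(radii)
    mm = 1.0e-3 * scale

    def P(x, y, z=5.0):
        return (x * mm, y * mm, z * mm)

    segs = [
        SegmentSpec(P(10, 1), P(10, 6), r["BA"], label="BA",
                    cap_start=("inlet", "BA")),
        SegmentSpec(P(10, 6), P(6, 9), r["PCA"], label="P1-L"),
        SegmentSpec(P(10, 6), P(14, 9), r["PCA"], label="P1-R"),
        SegmentSpec(P(6, 9), P(1, 9), r["PCA"], label="LPCA",
                    cap_end=("outlet", "LPCA")),
        SegmentSpec(P(14, 9), P(19, 9), r["PCA"], label="RPCA",
                    cap_end=("outlet", "RPCA")),
        SegmentSpec(P(4, 14), P(4, 9), r["PCoA"], label="PCoA-L"),
        SegmentSpec(P(16, 14), P(16, 9), r["PCoA"], label="PCoA-R"),
        SegmentSpec(P(4, 14, 0), P(4, 14, 5), r["ICA"], label="LICA",
                    cap_start=("inlet", "LICA")),
        SegmentSpec(P(16, 14, 0), P(16, 14, 5), r["ICA"], label="RICA",
                    cap_start=("inlet", "RICA")),
        SegmentSpec(P(4, 14), P(1, 14), r["MCA"], label="LMCA",
                    cap_end=("outlet", "LMCA")),
        SegmentSpec(P(16, 14), P(19, 14), r["MCA"], label="RMCA",
                    cap_end=("outlet", "RMCA")),
        SegmentSpec(P(4, 14), P(7, 19), r["ACA"], label="A1-L"),
        SegmentSpec(P(16, 14), P(13, 19), r["ACA"], label="A1-R"),
        SegmentSpec(P(7, 19), P(13, 19), r["ACoA"], label="ACoA"),
        SegmentSpec(P(7, 19), P(7, 24), r["ACA"], label="LACA",
                    cap_end=("outlet", "LACA")),
        SegmentSpec(P(13, 19), P(13, 24), r["ACA"], label="RACA",
                    cap_end=("outlet", "RACA")),
    ]
    spec = VesselNetworkSpec(segments=tuple(segs),
                             removable=frozenset({"PCoA-L", "PCoA-R"}))
    if variant == CoWVariant.NO_PCOA_LEFT:
        spec = spec.remove("PCoA-L")
    elif variant == CoWVariant.NO_PCOA_RIGHT:
        spec = spec.remove("PCoA-R")
    return spec


# --------------------------------------------------------------------------
# voxel domain
# --------------------------------------------------------------------------

@dataclass
class InletPort:
    id: int
    name: str
    axis: int
    direction: np.ndarray        # inward unit normal (float, 3)
    coords: np.ndarray           # (n, 3) grid indices of INLET sites
    measure_comp: np.ndarray = None  # comp indices of interior fluid layer
    distances: np.ndarray = None     # in-plane wall distance per site (m)
    d_ref: float = None              # cap inradius (m) normalizing weights


@dataclass
class OutletPort:
    id: int
    name: str
    axis: int
    direction: np.ndarray        # outward unit normal (float, 3)
    coords: np.ndarray
    measure_comp: np.ndarray = None


def _d3q19_structure():
    st = np.zeros((3, 3, 3), dtype=bool)
    for c in D3Q19.directions:
        st[tuple(np.asarray(c) + 1)] = True
    return st


@dataclass
class VoxelDomain:
    """Classified voxel lattice with compiled streaming links.

    ``labels`` holds the per-site class; inlet and outlet sites carry an
    iolet id in ``iolet_id``.  ``compile_links`` builds the pull-streaming
    index arrays consumed by the solver kernel (see _kernels for the link
    encoding).
    """

    labels: np.ndarray           # (nx, ny, nz) uint8
    dx: float
    origin: np.ndarray = None    # physical position of grid index (0,0,0)
    periodic: tuple = (False, False, False)
    inlets: list = field(default_factory=list)
    outlets: list = field(default_factory=list)
    iolet_id: np.ndarray = None

    # compiled (set by compile_links)
    comp_index: np.ndarray = None
    comp_coords: np.ndarray = None
    pull: np.ndarray = None
    link_inlet_site: np.ndarray = None
    inlet_weights: np.ndarray = None
    inlet_site_port: np.ndarray = None
    outlet_sites: np.ndarray = None
    outlet_interior: np.ndarray = None

    @classmethod
    def from_labels(cls, labels, dx, origin=None, periodic=(False,) * 3,
                    inlet_ports=(), outlet_ports=()):
        """Build and link-compile a domain from a label grid.

        ``inlet_ports`` / ``outlet_ports``: iterables of
        ``(name, coords(n,3), normal int 3-vector)`` with the normal inward
        for inlets and outward for outlets.  Sites listed there must be
        labelled INLET / OUTLET in ``labels``.
        """
        labels = np.ascontiguousarray(labels, dtype=np.uint8)
        if origin is None:
            origin = np.zeros(3)
        dom = cls(labels=labels, dx=float(dx),
                  origin=np.asarray(origin, float), periodic=tuple(periodic))
        dom.iolet_id = np.full(labels.shape, -1, dtype=np.int32)
        next_id = 0
        for name, coords, normal in inlet_ports:
            coords = np.asarray(coords, dtype=np.int64)
            normal = np.asarray(normal)
            axis = int(np.argmax(np.abs(normal)))
            _check_planar(coords, axis, name)
            dom.iolet_id[tuple(coords.T)] = next_id
            dom.inlets.append(InletPort(
                id=next_id, name=name, axis=axis,
                direction=normal.astype(float) / np.linalg.norm(normal),
                coords=coords))
            next_id += 1
        for name, coords, normal in outlet_ports:
            coords = np.asarray(coords, dtype=np.int64)
            normal = np.asarray(normal)
            axis = int(np.argmax(np.abs(normal)))
            _check_planar(coords, axis, name)
            dom.iolet_id[tuple(coords.T)] = next_id
            dom.outlets.append(OutletPort(
                id=next_id, name=name, axis=axis,
                direction=normal.astype(float) / np.linalg.norm(normal),
                coords=coords))
            next_id += 1
        dom.compile_links()
        return dom

    # -- basic queries ----------------------------------------------------

    @property
    def shape(self):
        return self.labels.shape

    @property
    def n_comp(self):
        return len(self.comp_coords)

    @property
    def fluid_site_count(self):
        """Number of non-solid sites (fluid plus iolet caps)."""
        return int((self.labels != SOLID).sum())

    def port(self, name):
        for p in self.inlets + self.outlets:
            if p.name == name:
                return p
        raise KeyError(name)

    def inlet_slice(self, inlet_id):
        return self._inlet_slices[inlet_id]

    def outlet_slice(self, outlet_id):
        return self._outlet_slices[outlet_id]

    def site_centers(self, coords):
        """Physical positions (m) of grid index triples."""
        return self.origin + (np.asarray(coords, float) + 0.5) * self.dx

    def wall_adjacent_comp(self):
        """Comp indices of FLUID sites with >= 1 SOLID neighbour."""
        wall = (self.pull[1:] == -1).any(axis=0)
        is_fluid = self.labels[tuple(self.comp_coords.T)] == FLUID
        return np.nonzero(wall & is_fluid)[0]

    # -- link compilation -------------------------------------------------

    def compile_links(self):
        labels = self.labels
        shape = np.array(labels.shape)
        comp_mask = (labels == FLUID) | (labels == OUTLET)
        self.comp_index = np.full(labels.shape, -1, dtype=np.int32)
        self.comp_index[comp_mask] = np.arange(comp_mask.sum(),
                                               dtype=np.int32)
        self.comp_coords = np.argwhere(comp_mask).astype(np.int64)
        n = len(self.comp_coords)

        # global inlet-site table, port-major
        inlet_table_index = np.full(labels.shape, -1, dtype=np.int32)
        self._inlet_slices = {}
        rows = 0
        for port in self.inlets:
            m = len(port.coords)
            inlet_table_index[tuple(port.coords.T)] = np.arange(
                rows, rows + m, dtype=np.int32)
            self._inlet_slices[port.id] = slice(rows, rows + m)
            rows += m
        self.inlet_weights = np.ones(rows)
        self.inlet_site_port = np.concatenate(
            [np.full(len(p.coords), p.id, dtype=np.int32)
             for p in self.inlets]) if rows else np.empty(0, dtype=np.int32)

        q = D3Q19.q
        self.pull = np.empty((q, n), dtype=np.int32)
        self.link_inlet_site = np.full((q, n), -1, dtype=np.int32)
        self.pull[0] = np.arange(n, dtype=np.int32)
        for i in range(1, q):
            src = self.comp_coords - D3Q19.directions[i]
            oob = np.zeros(n, dtype=bool)
            for a in range(3):
                if self.periodic[a]:
                    src[:, a] %= shape[a]
                else:
                    oob |= (src[:, a] < 0) | (src[:, a] >= shape[a])
            src_c = np.clip(src, 0, shape - 1)
            lab = labels[tuple(src_c.T)].copy()
            lab[oob] = SOLID
            col = self.comp_index[tuple(src_c.T)]
            col[(lab != FLUID) & (lab != OUTLET)] = -1
            col[lab == INLET] = -2
            self.pull[i] = col
            sel = lab == INLET
            self.link_inlet_site[i, sel] = \
                inlet_table_index[tuple(src_c[sel].T)]

        # outlet site and interior-neighbour tables, port-major
        self._outlet_slices = {}
        sites, interior = [], []
        rows = 0
        for port in self.outlets:
            inward = -np.rint(port.direction).astype(np.int64)
            nb = port.coords + inward
            if np.any(labels[tuple(nb.T)] != FLUID):
                raise GeometryError(
                    f"outlet {port.name!r}: interior neighbour of a cap "
                    "site is not FLUID")
            s = self.comp_index[tuple(port.coords.T)]
            t = self.comp_index[tuple(nb.T)]
            sites.append(s)
            interior.append(t)
            port.measure_comp = t
            self._outlet_slices[port.id] = slice(rows, rows + len(s))
            rows += len(s)
        self.outlet_sites = (np.concatenate(sites).astype(np.int32)
                             if sites else np.empty(0, dtype=np.int32))
        self.outlet_interior = (np.concatenate(interior).astype(np.int32)
                                if interior else np.empty(0, dtype=np.int32))

        for port in self.inlets:
            inward = np.rint(port.direction).astype(np.int64)
            nb = port.coords + inward
            t = self.comp_index[tuple(nb.T)]
            if np.any(t < 0):
                raise GeometryError(
                    f"inlet {port.name!r}: interior neighbour of a cap "
                    "site is not a computational site")
            port.measure_comp = t

    # -- geometry exchange ------------------------------------------------

    def save_mask(self, path):
        """Write the label mask plus iolet metadata to an .npz container."""
        meta = []
        for kind, ports in (("inlet", self.inlets), ("outlet", self.outlets)):
            for p in ports:
                meta.append((kind, p.name, *np.rint(p.direction).astype(int)))
        np.savez_compressed(
            path, labels=self.labels, iolet_id=self.iolet_id,
            dx=self.dx, origin=self.origin,
            periodic=np.asarray(self.periodic),
            iolet_meta=np.array(meta, dtype=object))

    @classmethod
    def load_mask(cls, path):
        z = np.load(path, allow_pickle=True)
        labels = z["labels"]
        iolet_id = z["iolet_id"]
        inlet_ports, outlet_ports = [], []
        for i, (kind, name, nx_, ny_, nz_) in enumerate(z["iolet_meta"]):
            coords = np.argwhere(iolet_id == i)
            normal = np.array([int(nx_), int(ny_), int(nz_)])
            (inlet_ports if kind == "inlet" else outlet_ports).append(
                (str(name), coords, normal))
        return cls.from_labels(labels, float(z["dx"]), origin=z["origin"],
                               periodic=tuple(bool(b) for b in z["periodic"]),
                               inlet_ports=inlet_ports,
                               outlet_ports=outlet_ports)


def _check_planar(coords, axis, name):
    if len(coords) == 0:
        raise GeometryError(f"iolet {name!r} has no sites")
    if not np.all(coords[:, axis] == coords[0, axis]):
        raise GeometryError(f"iolet {name!r} sites are not coplanar")


def periodic_box(shape, dx):
    """Fully periodic all-fluid domain (validation fixture)."""
    labels = np.full(shape, FLUID, dtype=np.uint8)
    return VoxelDomain.from_labels(labels, dx, periodic=(True, True, True))


# --------------------------------------------------------------------------
# voxelization
# --------------------------------------------------------------------------

def voxelize(network, dx, pad=2):
    """Voxelize a vessel network: a site is FLUID iff its center lies in
    the union of (flat-capped) capsules; caps become INLET/OUTLET planes.

    Refuses under-resolved segments (radius < 3 dx) and disconnected fluid
    regions.  The grid origin is snapped to a multiple of dx so that
    mirror-symmetric networks voxelize to mirror-symmetric masks.
    """
    if not network.segments:
        raise GeometryError("empty network")
    for s in network.segments:
        if s.min_radius < 3 * dx - _EPS:
            raise GeometryError(
                f"segment {s.label!r} under-resolved: radius "
                f"{s.min_radius:.3g} m < 3 dx; need dx <= "
                f"{s.min_radius / 3:.3g} m")

    lo = np.full(3, np.inf)
    hi = np.full(3, -np.inf)
    for s in network.segments:
        r = max(s.r0, s.r1)
        p0 = np.asarray(s.start)
        p1 = np.asarray(s.end)
        lo = np.minimum(lo, np.minimum(p0, p1) - r)
        hi = np.maximum(hi, np.maximum(p0, p1) + r)
    origin = (np.floor(lo / dx) - pad) * dx
    shape = np.ceil((hi - origin) / dx + pad).astype(int) + 1

    labels = np.full(tuple(shape), SOLID, dtype=np.uint8)
    seg_masks = []
    for s in network.segments:
        box, mask = _capsule_mask(s, origin, dx, shape)
        seg_masks.append((box, mask))
        view = labels[box[0][0]:box[0][1], box[1][0]:box[1][1],
                      box[2][0]:box[2][1]]
        view[mask] = FLUID

    inlet_ports, outlet_ports = [], []
    cap_geometry = {}
    for s, (box, mask) in zip(network.segments, seg_masks):
        for which, cap in (("start", s.cap_start), ("end", s.cap_end)):
            if cap is None or cap[0] == "closed":
                continue
            role, name = cap
            coords, normal = _stamp_cap(labels, s, which, origin, dx)
            labels[tuple(coords.T)] = INLET if role == "inlet" else OUTLET
            (inlet_ports if role == "inlet" else outlet_ports).append(
                (name, coords, normal))
            p_cap = np.asarray(s.start if which == "start" else s.end, float)
            r_cap = s.r0 if which == "start" else s.r1
            cap_geometry[name] = (p_cap, r_cap)

    _check_connectivity(labels)
    dom = VoxelDomain.from_labels(labels, dx, origin=origin,
                                  inlet_ports=inlet_ports,
                                  outlet_ports=outlet_ports)
    # analytic in-plane wall distances for parametric caps (exact for the
    # circular cap of a capsule, unlike the nearest-solid-site estimate)
    for port in dom.inlets:
        p_cap, r_cap = cap_geometry[port.name]
        centers = dom.site_centers(port.coords)
        inplane = np.delete(centers - p_cap, port.axis, axis=1)
        port.distances = r_cap - np.linalg.norm(inplane, axis=1)
        port.d_ref = r_cap
    ensure_inlet_weights(dom)
    return dom


def _capsule_mask(seg, origin, dx, shape):
    """Boolean mask of sites inside one (possibly flat-capped) capsule,
    restricted to the segment's bounding box within the grid."""
    p0 = np.asarray(seg.start, float)
    p1 = np.asarray(seg.end, float)
    rmax = max(seg.r0, seg.r1)
    lo_idx = np.maximum(
        np.floor((np.minimum(p0, p1) - rmax - origin) / dx).astype(int) - 1, 0)
    hi_idx = np.minimum(
        np.ceil((np.maximum(p0, p1) + rmax - origin) / dx).astype(int) + 1,
        shape)
    box = [(lo_idx[a], hi_idx[a]) for a in range(3)]
    ax = [origin[a] + (np.arange(lo_idx[a], hi_idx[a]) + 0.5) * dx
          for a in range(3)]
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    P = np.stack([X, Y, Z], axis=-1)

    v = p1 - p0
    L = np.linalg.norm(v)
    e = v / L
    w = P - p0
    t = w @ e
    t_cl = np.clip(t, 0.0, L)
    closest = p0 + t_cl[..., None] * e
    d2 = ((P - closest) ** 2).sum(axis=-1)
    r_t = seg.r0 + (seg.r1 - seg.r0) * (t_cl / L)
    mask = d2 <= r_t ** 2 + _EPS
    if seg.cap_start is not None:
        mask &= t >= -_EPS
    if seg.cap_end is not None:
        mask &= t <= L + _EPS
    return box, mask


def _stamp_cap(labels, seg, which, origin, dx):
    """Identify the single site layer forming a flat cap of ``seg``.

    Returns the layer's grid coordinates and the cap normal (inward for
    inlets-by-convention: the vector pointing from the cap into the
    segment; callers flip it for outlets).
    """
    p0 = np.asarray(seg.start, float)
    p1 = np.asarray(seg.end, float)
    if which == "start":
        p_cap, inward = p0, (p1 - p0)
        r_cap = seg.r0
    else:
        p_cap, inward = p1, (p0 - p1)
        r_cap = seg.r1
    inward = inward / np.linalg.norm(inward)
    axis = int(np.argmax(np.abs(inward)))
    if abs(abs(inward[axis]) - 1.0) > 1e-6:
        raise GeometryError(
            f"segment {seg.label!r}: capped end is not axis-aligned")
    sign = int(np.sign(inward[axis]))
    normal = np.zeros(3, dtype=int)
    normal[axis] = sign

    # first layer of in-capsule sites inward of the cap plane
    cap_coord = p_cap[axis]
    centers = origin[axis] + (np.arange(labels.shape[axis]) + 0.5) * dx
    t = sign * (centers - cap_coord)
    candidates = np.nonzero((t >= -_EPS) & (t < dx - 1e-6 * dx))[0]
    if len(candidates) == 0:
        raise GeometryError(f"segment {seg.label!r}: cap layer is empty")
    k = candidates[0]
    sl = [slice(None)] * 3
    sl[axis] = slice(k, k + 1)
    layer = labels[tuple(sl)]
    idx = np.argwhere(layer == FLUID)
    idx[:, axis] += k
    # keep only sites within the cap disc
    pos = origin + (idx + 0.5) * dx
    inplane = np.delete(pos - p_cap, axis, axis=1)
    keep = (inplane ** 2).sum(axis=1) <= r_cap ** 2 + _EPS
    coords = idx[keep]
    if len(coords) == 0:
        raise GeometryError(f"segment {seg.label!r}: cap disc is empty")
    if which == "end" and seg.cap_end[0] == "outlet" or \
       which == "start" and seg.cap_start[0] == "outlet":
        normal = -normal  # outward for outlets
    return coords, normal


def _check_connectivity(labels):
    mask = labels != SOLID
    lab, ncomp = ndimage.label(mask, structure=_d3q19_structure())
    if ncomp != 1:
        sizes = np.bincount(lab.ravel())[1:]
        raise GeometryError(
            f"fluid region is disconnected: {ncomp} components with "
            f"sizes {sorted(sizes.tolist(), reverse=True)}")


# --------------------------------------------------------------------------
# inlet weighting
# --------------------------------------------------------------------------

def inlet_wall_distance(domain, inlet_id):
    """In-plane distance (m) from each inlet site center to the nearest
    SOLID site center within the cap plane."""
    port = next(p for p in domain.inlets if p.id == inlet_id)
    axis = port.axis
    k = port.coords[0, axis]
    sl = [slice(None)] * 3
    sl[axis] = slice(int(k), int(k) + 1)
    layer = domain.labels[tuple(sl)]
    solid = np.argwhere(layer == SOLID)
    solid[:, axis] += int(k)
    if len(solid) == 0:
        return None  # unwalled plane (periodic fixture): uniform weighting
    inplane = [a for a in range(3) if a != axis]
    tree = cKDTree(solid[:, inplane] * domain.dx)
    d, _ = tree.query(port.coords[:, inplane] * domain.dx)
    return d


def inlet_weights(distances, d_max=None):
    """Parabolic cap weighting w = 1 - (1 - d/d_max)^2.

    Zero at the wall, one at distance ``d_max`` from it.  ``d_max``
    defaults to the largest site distance; when the cap's true inradius is
    known (parametric caps) passing it instead makes a circular cap
    reconstruct the Poiseuille parabola exactly.
    """
    d = np.asarray(distances, float)
    if d_max is None:
        d_max = d.max()
    if d_max <= 0:
        raise GeometryError("all inlet sites lie at the wall")
    return np.clip(1.0 - (1.0 - d / d_max) ** 2, 0.0, 1.0)


def ensure_inlet_weights(domain):
    """Fill the domain's per-inlet-site weight table from wall distances.

    Uses the port's analytic distances when the cap came from a parametric
    network; otherwise falls back to the in-plane nearest-solid search.
    An unwalled (periodic-fixture) plane gets uniform weight one.
    """
    for port in domain.inlets:
        d = port.distances
        if d is None:
            d = inlet_wall_distance(domain, port.id)
        sl = domain.inlet_slice(port.id)
        domain.inlet_weights[sl] = (1.0 if d is None
                                    else inlet_weights(d, port.d_ref))
    return domain
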