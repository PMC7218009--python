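"""Dendritic morphology: trees, SWC i/o, synthetic arbors, and site bands.

A motoneuron is represented as a tree of frustum-shaped ``Section`` objects
(a collapsed soma, the dendritic arbor, and the axonal hillock + initial
segment).  Path lengths are measured in micrometres from the soma centre;
the public band-selection API uses millimetres, matching the convention for
the dendritic path distance ``D_path`` used to place PIC channel hot-spots.

Electrotonic distances are computed against a passive-parameter set: the
local space constant is lambda(x) = sqrt(R_m(x) * d(x) / (4 * R_i)) with
``d`` the local diameter, so a site's lambda-distance is the path integral
of 1/lambda from the soma.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import EmptyBandError, ParameterError, StructuralError, SWCParseError

SOMA = "soma"
DENDRITE = "dendrite"
HILLOCK = "hillock"
INITIAL_SEGMENT = "initial_segment"

# fixed axon stub geometry appended to every cell (μm)
HILLOCK_LENGTH = 20.0
HILLOCK_DIAM_PROX = 13.0
HILLOCK_DIAM_DIST = 3.3
IS_LENGTH = 30.0
IS_DIAM = 3.3

# default collapsed-soma geometry: cylinder with length == diameter (μm)
DEFAULT_SOMA_DIAM = 48.8


@dataclass(frozen=True)
class Section:
    """One unbranched frustum of membrane.

    Diameters taper linearly from ``diam_prox`` at the parent end to
    ``diam_dist`` at the far end.  ``parent is None`` only for the soma.
    """

    id: int
    parent: int | None
    kind: str
    length: float  # μm
    diam_prox: float  # μm
    diam_dist: float  # μm

    def diam_at(self, arc: float) -> float:
        """Local diameter at normalized arc position ``arc`` in [0, 1]."""
        return self.diam_prox + (self.diam_dist - self.diam_prox) * arc

    @property
    def area(self) -> float:
        """Lateral membrane area (μm²), cylinder-at-mean-diameter convention."""
        return math.pi * 0.5 * (self.diam_prox + self.diam_dist) * self.length


class NeuriteTree:
    """A branched morphology: exactly one soma root plus dendrites/axon stub.

    Sections are stored in topological order (every parent precedes its
    children).  Construction validates the tree invariants.
    """

    def __init__(self, sections: Sequence[Section]):
        if not sections:
            raise StructuralError("tree has no sections")
        by_id = {}
        roots = []
        for s in sections:
            if s.id in by_id:
                raise StructuralError(f"duplicate section id {s.id}")
            if s.length <= 0:
                raise StructuralError(f"section {s.id}: non-positive length")
            if s.diam_prox <= 0 or s.diam_dist <= 0:
                raise StructuralError(f"section {s.id}: non-positive diameter")
            if s.parent is None:
                roots.append(s)
            elif s.parent not in by_id:
                raise StructuralError(
                    f"section {s.id}: parent {s.parent} undefined or out of order"
                )
            by_id[s.id] = s
        if len(roots) != 1:
            raise StructuralError(f"expected exactly one root, found {len(roots)}")
        if roots[0].kind != SOMA:
            raise StructuralError("root section must be the soma")
        self.sections: tuple[Section, ...] = tuple(sections)
        self._by_id = by_id
        self.root = roots[0].id
        self._path_start = self._compute_path_starts()

    def _compute_path_starts(self) -> dict[int, float]:
        """Path length (μm) from soma centre to each section's proximal end."""
        start: dict[int, float] = {}
        for s in self.sections:
            if s.parent is None:
                start[s.id] = 0.0
            else:
                p = self._by_id[s.parent]
                if p.kind == SOMA:
                    # children attach at the soma surface; count the half-length
                    start[s.id] = p.length / 2.0
                else:
                    start[s.id] = start[p.id] + p.length
        return start

    def __getitem__(self, sec_id: int) -> Section:
        return self._by_id[sec_id]

    def __contains__(self, sec_id: int) -> bool:
        return sec_id in self._by_id

    def children(self, sec_id: int) -> list[Section]:
        return [s for s in self.sections if s.parent == sec_id]

    def path_length(self, sec_id: int, arc: float = 1.0) -> float:
        """Path length (μm) from the soma centre to ``arc`` along a section."""
        s = self._by_id[sec_id]
        if s.kind == SOMA:
            return 0.0
        return self._path_start[sec_id] + arc * s.length

    @property
    def soma(self) -> Section:
        return self._by_id[self.root]

    def dendrite_sections(self) -> list[Section]:
        return [s for s in self.sections if s.kind == DENDRITE]

    def total_dendritic_area(self) -> float:
        """Summed dendritic membrane area (μm²)."""
        return sum(s.area for s in self.dendrite_sections())

    def max_dendritic_path(self) -> float:
        """Path length (μm) from soma centre to the farthest dendritic tip."""
        return max(
            (self.path_length(s.id, 1.0) for s in self.dendrite_sections()),
            default=0.0,
        )

    def total_area(self) -> float:
        return sum(s.area for s in self.sections)


@dataclass
class SiteSet:
    """Dendritic sites selected within a path-length band.

    ``sites`` holds ``(section id, normalized arc midpoint, membrane area μm²)``
    tuples; ``electrotonic_lengths`` holds the matching lambda-distances.
    """

    band_center: float  # mm
    band_halfwidth: float  # mm
    sites: list[tuple[int, float, float]]
    electrotonic_lengths: list[float] = field(default_factory=list)

    @property
    def total_area(self) -> float:
        return sum(a for (_, _, a) in self.sites)

    @property
    def mean_electrotonic_length(self) -> float:
        return float(np.mean(self.electrotonic_lengths))


# ---------------------------------------------------------------------------
# SWC i/o
# ---------------------------------------------------------------------------

def _soma_from_points(points: list[tuple[float, float, float, float]]) -> Section:
    """Collapse soma sample points to a single equivalent-area cylinder.

    A lone point is treated as a sphere of the given radius; chains of
    points contribute frusta.  The cylinder has length == diameter so that
    pi*d*L matches the sampled area.
    """
    if len(points) == 1:
        r = points[0][3]
        area = 4.0 * math.pi * r * r
    else:
        area = 0.0
        for (x0, y0, z0, r0), (x1, y1, z1, r1) in zip(points, points[1:]):
            seg = math.dist((x0, y0, z0), (x1, y1, z1))
            area += math.pi * (r0 + r1) * seg
        if area <= 0.0:
            r = points[0][3]
            area = 4.0 * math.pi * r * r
    d = math.sqrt(area / math.pi)
    return Section(id=0, parent=None, kind=SOMA, length=d, diam_prox=d, diam_dist=d)


def load_swc(path) -> NeuriteTree:
    """Load a standard 7-column SWC file into a :class:`NeuriteTree`.

    Soma samples (type 1) are collapsed to a single equivalent-area section;
    every other sample becomes one frustum section from its parent sample.
    The fixed axonal hillock and initial segment are appended to the soma.

    Raises
    ------
    SWCParseError
        On malformed rows (names the line number).
    StructuralError
        On undefined parents or multiple soma clusters.
    """
    rows: dict[int, tuple[int, float, float, float, float, int]] = {}
    order: list[int] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 7:
                raise SWCParseError(f"line {lineno}: expected 7 columns, got {len(parts)}")
            try:
                nid = int(parts[0])
                ntype = int(parts[1])
                x, y, z, r = (float(v) for v in parts[2:6])
                parent = int(parts[6])
            except ValueError as exc:
                raise SWCParseError(f"line {lineno}: {exc}") from None
            if r <= 0:
                raise SWCParseError(f"line {lineno}: non-positive radius")
            if nid in rows:
                raise SWCParseError(f"line {lineno}: duplicate node id {nid}")
            rows[nid] = (ntype, x, y, z, r, parent)
            order.append(nid)

    if not rows:
        raise SWCParseError("empty SWC file")

    soma_pts = []
    soma_ids = set()
    n_soma_roots = 0
    for nid in order:
        ntype, x, y, z, r, parent = rows[nid]
        if ntype == 1:
            if parent == -1:
                n_soma_roots += 1
            elif parent not in soma_ids:
                raise StructuralError(f"soma node {nid} attached to non-soma parent")
            soma_pts.append((x, y, z, r))
            soma_ids.add(nid)
    if n_soma_roots == 0:
        raise StructuralError("no soma root (type-1 node with parent -1)")
    if n_soma_roots > 1:
        raise StructuralError(f"multiple somas: {n_soma_roots} soma roots")

    sections: list[Section] = [_soma_from_points(soma_pts)]
    sec_of_node: dict[int, int] = {nid: 0 for nid in soma_ids}
    next_id = 1
    for nid in order:
        ntype, x, y, z, r, parent = rows[nid]
        if ntype == 1:
            continue
        if parent == -1:
            raise StructuralError(f"node {nid}: non-soma node has no parent")
        if parent not in rows:
            raise StructuralError(f"node {nid}: parent id {parent} undefined")
        ptype, px, py, pz, pr, _ = rows[parent]
        length = math.dist((x, y, z), (px, py, pz))
        if length <= 0.0:
            # coincident sample; attach children through the parent instead
            sec_of_node[nid] = sec_of_node.get(parent, 0)
            continue
        if parent in soma_ids:
            parent_sec = 0
            diam_prox = 2.0 * r  # no taper information across the soma boundary
        else:
            if parent not in sec_of_node:
                raise StructuralError(f"node {nid}: parent id {parent} undefined")
            parent_sec = sec_of_node[parent]
            diam_prox = 2.0 * pr
        sections.append(
            Section(
                id=next_id,
                parent=parent_sec,
                kind=DENDRITE,
                length=length,
                diam_prox=diam_prox,
                diam_dist=2.0 * r,
            )
        )
        sec_of_node[nid] = next_id
        next_id += 1

    sections = _append_axon_stub(sections, next_id)
    return NeuriteTree(sections)


def _append_axon_stub(sections: list[Section], next_id: int) -> list[Section]:
    sections = list(sections)
    sections.append(
        Section(
            id=next_id,
            parent=0,
            kind=HILLOCK,
            length=HILLOCK_LENGTH,
            diam_prox=HILLOCK_DIAM_PROX,
            diam_dist=HILLOCK_DIAM_DIST,
        )
    )
    sections.append(
        Section(
            id=next_id + 1,
            parent=next_id,
            kind=INITIAL_SEGMENT,
            length=IS_LENGTH,
            diam_prox=IS_DIAM,
            diam_dist=IS_DIAM,
        )
    )
    return sections


def write_swc(tree: NeuriteTree, path) -> None:
    """Write a tree as 7-column SWC (topology- and length-preserving).

    Each non-soma section maps to one sample placed at its distal end; the
    soma maps to a single sphere sample of equivalent area.  Synthetic 3-D
    coordinates are laid out deterministically (lengths are exact; spatial
    embedding is arbitrary).  The axonal hillock / initial segment are
    written with SWC type 2 (axon) and are re-appended on load, so
    ``load_swc(write_swc(tree))`` round-trips dendritic topology and lengths.
    """
    soma = tree.soma
    # sphere with the same area as the collapsed cylinder
    r_soma = math.sqrt(soma.area / (4.0 * math.pi))
    node_of_sec = {tree.root: 1}
    pos_of_sec = {tree.root: np.zeros(3)}
    lines = [f"1 1 0.0 0.0 0.0 {r_soma:.9f} -1"]
    next_node = 2
    # deterministic direction per child index so siblings do not overlap
    for s in tree.sections:
        if s.kind == SOMA or s.kind in (HILLOCK, INITIAL_SEGMENT):
            continue
        siblings = [c.id for c in tree.children(s.parent) if c.kind == DENDRITE]
        k = siblings.index(s.id)
        theta = 2.399963 * (s.id + k)  # golden-angle spread
        phi = 0.7 * ((k % 5) - 2)
        u = np.array(
            [math.cos(theta) * math.cos(phi), math.sin(theta) * math.cos(phi), math.sin(phi)]
        )
        p = pos_of_sec[s.parent] + u * s.length
        pos_of_sec[s.id] = p
        lines.append(
            f"{next_node} 3 {p[0]:.9f} {p[1]:.9f} {p[2]:.9f} "
            f"{s.diam_dist / 2.0:.9f} {node_of_sec[s.parent]}"
        )
        node_of_sec[s.id] = next_node
        next_node += 1
    with open(path, "w") as fh:
        fh.write("# picloop morphology export\n")
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Synthetic arbor generator
# ---------------------------------------------------------------------------

def generate_synthetic_tree(
    n_stems: int = 10,
    max_path: float = 1.8,
    stem_diam: float = 13.0,
    taper: float = 0.3,
    branch_depth: int = 3,
    seed: int = 1,
    soma_diam: float = DEFAULT_SOMA_DIAM,
    min_diam: float = 0.4,
) -> NeuriteTree:
    """Generate a parametric adult-cat-scale motoneuron arbor.

    Each of ``n_stems`` stem dendrites runs from the soma out to at least
    ``max_path`` (mm) of dendritic path, splitting into two Rall-compatible
    children (d_parent^1.5 = sum d_child^1.5) at ``branch_depth`` seeded
    branch points.  Diameters taper linearly by fraction ``taper`` per mm of
    arc within a section.  The construction is fully deterministic for a
    given seed.

    Parameters
    ----------
    n_stems : number of stem dendrites (adult cat alpha-motoneurons: 8-12).
    max_path : minimum soma-to-tip dendritic path length, mm.
    stem_diam : stem diameter at the soma, μm.
    taper : fractional diameter loss per mm of arc (0.4 = 40%/mm).
    branch_depth : number of binary branch orders per stem.
    seed : RNG seed for branch-point jitter.

    Raises
    ------
    ParameterError
        If the parameters would produce zero- or negative-diameter segments.
    """
    if n_stems < 1:
        raise ParameterError("n_stems must be >= 1")
    if max_path <= 0:
        raise ParameterError("max_path must be positive")
    if branch_depth < 0:
        raise ParameterError("branch_depth must be >= 0")
    max_path_um = max_path * 1000.0
    rng = np.random.default_rng(seed)

    soma = Section(0, None, SOMA, soma_diam, soma_diam, soma_diam)
    sections: list[Section] = [soma]
    next_id = [1]

    def taper_diam(d0: float, length_um: float) -> float:
        d1 = d0 * (1.0 - taper * length_um / 1000.0)
        if d1 <= 0.0:
            raise ParameterError(
                f"taper {taper}/mm over {length_um:.0f} μm yields non-positive diameter"
            )
        return max(d1, min_diam)

    def grow(parent_id: int, start_path: float, d0: float, depth: int) -> None:
        """Recursively grow from ``start_path`` (μm along the dendrite)."""
        if depth < branch_depth:
            # branch points spread between start and ~70% of remaining reach
            frac = (depth + 1) / (branch_depth + 1)
            nominal = frac * max_path_um * 0.75
            jitter = 1.0 + 0.12 * (rng.random() - 0.5)
            bp = max(nominal * jitter, start_path + 30.0)
            length = bp - start_path
            d1 = taper_diam(d0, length)
            sec = Section(next_id[0], parent_id, DENDRITE, length, d0, d1)
            sections.append(sec)
            next_id[0] += 1
            d_child = d1 / 2.0 ** (2.0 / 3.0)  # Rall symmetric split
            if d_child <= 0:
                raise ParameterError("branching yields non-positive child diameter")
            d_child = max(d_child, min_diam)
            for _ in range(2):
                grow(sec.id, bp, d_child, depth + 1)
        else:
            # terminal branch out to (at least) max_path with seeded overshoot
            tip = max_path_um * (1.0 + 0.08 * rng.random())
            length = max(tip - start_path, 30.0)
            d1 = taper_diam(d0, length)
            sec = Section(next_id[0], parent_id, DENDRITE, length, d0, d1)
            sections.append(sec)
            next_id[0] += 1

    half_soma = soma_diam / 2.0
    for _ in range(n_stems):
        grow(0, half_soma, stem_diam, 0)

    sections = _append_axon_stub(sections, next_id[0])
    return NeuriteTree(sections)


# ---------------------------------------------------------------------------
# Electrotonic metrics and band selection
# ---------------------------------------------------------------------------

def _path_chain(tree: NeuriteTree, sec_id: int) -> list[Section]:
    """Sections from (just below) the soma down to ``sec_id``, inclusive."""
    chain = []
    s = tree[sec_id]
    while s.kind != SOMA:
        chain.append(s)
        if s.parent is None:
            break
        s = tree[s.parent]
    chain.reverse()
    return chain


def electrotonic_path(tree: NeuriteTree, site: tuple[int, float], passive) -> float:
    """Lambda-normalized path distance from the soma centre to a site.

    ``site`` is ``(section id, normalized arc position)``.  Integrates
    dx / lambda(x) along the soma-to-site path with
    lambda(x) = sqrt(R_m(x) * d(x) / (4 * R_i)); the collapsed soma itself
    contributes nothing (isopotential).
    """
    sec_id, arc = site
    if sec_id not in tree:
        raise KeyError(f"section {sec_id} not in tree")
    sec = tree[sec_id]
    if sec.kind == SOMA:
        return 0.0
    total = 0.0
    for s in _path_chain(tree, sec_id):
        a1 = arc if s.id == sec_id else 1.0
        length = s.length * a1
        n = max(int(math.ceil(length / 2.0)), 1)  # ~2 μm quadrature steps
        x = (np.arange(n) + 0.5) * (length / n)  # μm from section start
        d_um = s.diam_prox + (s.diam_dist - s.diam_prox) * (x / s.length)
        path_um = tree.path_length(s.id, 0.0) + x
        rm = passive.rm_at(path_um)  # Ω·cm²
        lam_cm = np.sqrt(rm * (d_um * 1e-4) / (4.0 * passive.ri))
        total += float(np.sum((length / n) * 1e-4 / lam_cm))
    return total


def iter_segments(tree: NeuriteTree, seg_um: float = 20.0) -> Iterable[tuple[int, float, float, float]]:
    """Yield (section id, arc midpoint, path μm at midpoint, area μm²) for
    each dendritic sub-segment of at most ``seg_um`` arc length."""
    for s in tree.dendrite_sections():
        n = max(int(math.ceil(s.length / seg_um)), 1)
        for i in range(n):
            arc = (i + 0.5) / n
            d_mid = s.diam_at(arc)
            area = math.pi * d_mid * (s.length / n)
            yield s.id, arc, tree.path_length(s.id, arc), area


def select_band(
    tree: NeuriteTree,
    center: float,
    halfwidth: float,
    passive,
    seg_um: float = 20.0,
) -> SiteSet:
    """Select dendritic sites whose path length falls within a band.

    ``center`` and ``halfwidth`` are in mm measured from the soma centre.
    All branches are included: any discretized sub-segment whose midpoint
    path length lies in [center - halfwidth, center + halfwidth] becomes a
    site.  Raises :class:`EmptyBandError` if nothing qualifies.
    """
    lo = (center - halfwidth) * 1000.0
    hi = (center + halfwidth) * 1000.0
    sites = []
    lam = []
    for sec_id, arc, path_um, area in iter_segments(tree, seg_um):
        if lo <= path_um <= hi:
            sites.append((sec_id, arc, area))
            lam.append(electrotonic_path(tree, (sec_id, arc), passive))
    if not sites:
        raise EmptyBandError(
            f"band {center}±{halfwidth} mm contains no dendritic membrane"
        )
    return SiteSet(
        band_center=center,
        band_halfwidth=halfwidth,
        sites=sites,
        electrotonic_lengths=lam,
    )
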