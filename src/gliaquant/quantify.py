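"""3D morphometrics on binary masks.

Features: volume / coverage / object count, surface voxels, local thickness
via an anisotropy-aware Euclidean distance map sampled on the centerline,
3D-thinning skeleton topology (trees, branches, junctions, endpoints, triple
and quadruple points, calibrated branch lengths) and apicobasal texture.

Conventions that matter for comparability with the upstream tool:

* surface is reported in µm³ (surface-voxel count x voxel volume) exactly as
  the reference output prints it, even though it is dimensionally a volume; a
  conventional µm² estimate is emitted alongside.
* thickness is the mean EDM value over skeleton voxels, i.e. a *radius*-like
  quantity (centerline-to-surface distance); no factor 2 is applied.
* junctions are counted as 26-connected clusters of high-degree voxels, not
  as raw voxels, to avoid double-counting thick junctions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import networkx as nx
import numpy as np
import pandas as pd
from scipy import ndimage

from . import zonation
from .segment import STRUCTURE_26, BinaryMask
from .volume_io import VolumetricImage, max_projection, write_stack
from .zonation import ZonationProfile, apicobasal_profile

__all__ = [
    "Skeleton",
    "FeatureRecord",
    "compute_volume_coverage",
    "compute_surface",
    "compute_edm_thickness",
    "skeletonize_3d",
    "skeleton_statistics",
    "apicobasal_texture",
    "quantify_stack",
    "write_quantification_csvs",
    "QUANT_COLUMNS",
]

QUANT_COLUMNS = ["Volume [um3]", "PercCov [%]", "SurfaceVol [um3]", "Thickness [um]"]

_NEIGHBOR_OFFSETS = np.array(
    [(dz, dy, dx)
     for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
     if (dz, dy, dx) != (0, 0, 0)],
    dtype=np.int64,
)


@dataclass
class Branch:
    voxels: list[tuple[int, int, int]]
    length_um: float
    junction_ids: tuple[int, ...] = ()  # incident junction clusters (may repeat)
    is_cycle: bool = False


@dataclass
class Skeleton:
    """1-voxel-wide centerline with its branch/junction graph."""

    voxels: np.ndarray
    voxel_size: tuple[float, float, float]
    branches: list[Branch] = field(default_factory=list)
    junction_clusters: list[list[tuple[int, int, int]]] = field(default_factory=list)
    endpoints: list[tuple[int, int, int]] = field(default_factory=list)
    n_trees: int = 0

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())

    def to_image(self) -> VolumetricImage:
        return VolumetricImage((self.voxels * 255).astype(np.uint8),
                               self.voxel_size, name="skeleton")


@dataclass
class FeatureRecord:
    """Whole-stack morphometrics (one row of the quantification table)."""

    name: str = ""
    image_height_um: float = 0.0      # I_N
    cell_height_um: float = 0.0       # MG_N
    n_objects: int = 0                # N_N
    volume_um3: float = 0.0           # V_N
    coverage_pct: float = 0.0         # VC_N, in [0, 100]
    surface_um3: float = 0.0          # S_N (voxel count x voxel volume)
    surface_um2: float = 0.0          # conventional area estimate (extra)
    sv_ratio: float = 0.0             # S:V, in [0, 1]
    thickness_um: float = 0.0         # T_N: mean EDM over skeleton
    thickness_max_um: float = 0.0
    skeleton_length_um: float = 0.0   # L_N
    n_junctions: int = 0              # J_N
    n_endpoints: int = 0              # EP_N
    mean_branch_length_um: float = 0.0  # BL
    max_branch_length_um: float = 0.0
    n_trees: int = 0
    n_branches: int = 0
    n_triple_points: int = 0
    n_quadruple_points: int = 0
    skeleton_voxels: int = 0

    def validate(self) -> None:
        assert 0.0 <= self.coverage_pct <= 100.0
        assert 0.0 <= self.sv_ratio <= 1.0
        assert self.volume_um3 >= 0.0 and self.skeleton_length_um >= 0.0


def ensure_binary(mask: BinaryMask | VolumetricImage) -> BinaryMask:
    if isinstance(mask, BinaryMask):
        return mask
    vals = np.unique(mask.voxels)
    binary_like = np.all(np.isin(vals, (0, 1))) or np.all(np.isin(vals, (0, 255)))
    if not binary_like:
        raise ValueError(
            "quantification needs a binary (segmented) input; run a segmentation "
            "pipeline first")
    return BinaryMask((np.asarray(mask.voxels) > 0).astype(np.uint8),
                      mask.voxel_size)


# ---------------------------------------------------------------------------
# Volume / surface / thickness
# ---------------------------------------------------------------------------

def compute_volume_coverage(mask: BinaryMask) -> tuple[float, float, int]:
    """Returns ``(V_um3, coverage_pct, n_objects)``; objects are 26-connected."""
    fg = int(mask.voxels.sum())
    dx, dy, dz = mask.voxel_size
    volume = fg * dx * dy * dz
    coverage = 100.0 * fg / mask.voxels.size
    _, n_objects = ndimage.label(mask.voxels, structure=STRUCTURE_26)
    return float(volume), float(coverage), int(n_objects)


def compute_surface(mask: BinaryMask) -> tuple[float, float, float]:
    """Surface voxels: foreground with a 6-face background neighbor or on the border.

    Returns ``(S_um3, sv_ratio, S_um2)``. ``S_um3`` is the surface-voxel count
    times the voxel volume (reference-tool convention); ``S_um2`` sums the
    exposed face areas as a conventional area.
    """
    vox = mask.voxels.astype(bool)
    fg = int(vox.sum())
    if fg == 0:
        return 0.0, 0.0, 0.0
    padded = np.pad(vox, 1, constant_values=False)
    dx, dy, dz = mask.voxel_size
    face_areas = {0: dx * dy, 1: dx * dz, 2: dy * dz}  # area exposed along z, y, x
    exposed_any = np.zeros_like(vox)
    area = 0.0
    for axis in range(3):
        for shift in (-1, 1):
            nb = np.roll(padded, shift, axis=axis)[1:-1, 1:-1, 1:-1]
            exposed = vox & ~nb
            exposed_any |= exposed
            area += exposed.sum() * face_areas[axis]
    surf = int(exposed_any.sum())
    return float(surf * dx * dy * dz), float(surf / fg), float(area)


def compute_edm_thickness(
    mask: BinaryMask, skeleton: "Skeleton | None" = None
) -> tuple[np.ndarray, float, float]:
    """Anisotropic EDM of the foreground and centerline-sampled thickness.

    Returns ``(edm_um, mean_thickness_um, max_thickness_um)`` where thickness
    statistics are taken over skeleton voxels. With an empty skeleton the
    thickness is reported as 0 with a warning.
    """
    dx, dy, dz = mask.voxel_size
    if not mask.voxels.any():
        return np.zeros(mask.shape, dtype=np.float64), 0.0, 0.0
    edm = ndimage.distance_transform_edt(mask.voxels, sampling=(dz, dy, dx))
    if skeleton is None:
        skeleton = skeletonize_3d(mask)
    skel = skeleton.voxels.astype(bool)
    if not skel.any():
        warnings.warn("empty skeleton: thickness undefined, reporting 0", stacklevel=2)
        return edm, 0.0, 0.0
    vals = edm[skel]
    return edm, float(vals.mean()), float(vals.max())


# ---------------------------------------------------------------------------
# Skeletonization and graph statistics
# ---------------------------------------------------------------------------

def _step_length_um(delta: np.ndarray, voxel_size: tuple[float, float, float]) -> float:
    dx, dy, dz = voxel_size
    return float(np.sqrt((delta[0] * dz) ** 2 + (delta[1] * dy) ** 2
                         + (delta[2] * dx) ** 2))


def skeletonize_3d(mask: BinaryMask, prune_below_um: float = 0.0) -> Skeleton:
    """Homotopy-preserving 3D thinning to a 1-voxel centerline, plus the graph.

    ``prune_below_um`` iteratively removes terminal branches shorter than the
    given calibrated length (spurious-branch pruning; off by default).
    """
    from ._thinning import thin_3d

    vox = mask.voxels.astype(bool)
    if not vox.any():
        return Skeleton(np.zeros(mask.shape, dtype=np.uint8), mask.voxel_size)
    skel = thin_3d(vox)  # layer-by-layer topology-preserving thinning
    skeleton = _build_graph(skel, mask.voxel_size)
    skeleton = _cleanup_tip_forks(skeleton)
    if prune_below_um > 0:
        for _ in range(16):
            pruned = _prune_once(skeleton, prune_below_um)
            if pruned is None:
                break
            skeleton = pruned
    return skeleton


def _cleanup_tip_forks(skeleton: Skeleton, max_vox: int = 3,
                       max_rounds: int = 5) -> Skeleton:
    """Remove thinning artifacts: terminal micro-branches at blunt tube ends.

    Thinning a blunt-ended tube can leave a 1-3 voxel "fork" at the tip. Such
    twigs (terminal, attached to a junction, at most ``max_vox`` voxels) are
    not resolvable branches and are always removed; this is independent of the
    optional user-level spur pruning.
    """
    for _ in range(max_rounds):
        drop: set[tuple[int, int, int]] = set()
        for br in skeleton.branches:
            if (not br.is_cycle and len(br.junction_ids) == 1
                    and len(br.voxels) <= max_vox):
                drop.update(br.voxels)
        if not drop:
            return skeleton
        vox = skeleton.voxels.astype(bool).copy()
        for c in drop:
            vox[c] = False
        skeleton = _build_graph(vox, skeleton.voxel_size)
    return skeleton


def _prune_once(skeleton: Skeleton, min_um: float) -> Skeleton | None:
    """Remove all terminal branches shorter than ``min_um``; None when stable."""
    to_drop: set[tuple[int, int, int]] = set()
    for br in skeleton.branches:
        terminal = len(br.junction_ids) <= 1 and not br.is_cycle
        if terminal and br.length_um < min_um and len(skeleton.branches) > 1:
            to_drop.update(br.voxels)
    if not to_drop:
        return None
    vox = skeleton.voxels.astype(bool).copy()
    for c in to_drop:
        vox[c] = False
    if not vox.any():
        return Skeleton(vox.astype(np.uint8), skeleton.voxel_size)
    return _build_graph(vox, skeleton.voxel_size)


def _build_graph(skel: np.ndarray, voxel_size: tuple[float, float, float]) -> Skeleton:
    skel = skel.astype(bool)
    neighbor_count = ndimage.convolve(skel.astype(np.uint8),
                                      STRUCTURE_26.astype(np.uint8),
                                      mode="constant", cval=0) - 1
    neighbor_count[~skel] = 0

    _, n_trees = ndimage.label(skel, structure=STRUCTURE_26)
    junction_mask = skel & (neighbor_count > 2)
    endpoint_mask = skel & (neighbor_count == 1)
    endpoints = [tuple(int(v) for v in c) for c in np.argwhere(endpoint_mask)]

    jc_labels, n_jc = ndimage.label(junction_mask, structure=STRUCTURE_26)
    junction_clusters: list[list[tuple[int, int, int]]] = [[] for _ in range(n_jc)]
    for c in np.argwhere(junction_mask):
        junction_clusters[jc_labels[tuple(c)] - 1].append(tuple(int(v) for v in c))

    seg_mask = skel & ~junction_mask
    seg_labels, n_seg = ndimage.label(seg_mask, structure=STRUCTURE_26)

    branches: list[Branch] = []
    for sid in range(1, n_seg + 1):
        coords = [tuple(int(v) for v in c) for c in np.argwhere(seg_labels == sid)]
        branches.append(_trace_branch(coords, jc_labels, voxel_size, skel.shape))

    out = Skeleton(skel.astype(np.uint8), voxel_size, branches=branches,
                   junction_clusters=junction_clusters, endpoints=endpoints,
                   n_trees=int(n_trees))
    return out


def _trace_branch(
    coords: list[tuple[int, int, int]],
    jc_labels: np.ndarray,
    voxel_size: tuple[float, float, float],
    shape: tuple[int, int, int],
) -> Branch:
    """Calibrated path length of one branch segment plus its junction links."""
    cset = set(coords)
    g = nx.Graph()
    g.add_nodes_from(coords)
    for c in coords:
        ca = np.array(c)
        for off in _NEIGHBOR_OFFSETS:
            nb = tuple(int(v) for v in ca + off)
            if nb in cset and nb > c:
                g.add_edge(c, nb, weight=_step_length_um(off, voxel_size))

    # incident junction clusters: nearest junction voxel adjacent to any segment voxel
    incident: dict[int, float] = {}
    for c in coords:
        ca = np.array(c)
        for off in _NEIGHBOR_OFFSETS:
            nb = ca + off
            if np.any(nb < 0) or np.any(nb >= shape):
                continue
            jid = jc_labels[tuple(nb)]
            if jid > 0:
                step = _step_length_um(off, voxel_size)
                if jid not in incident or step < incident[jid]:
                    incident[jid] = step

    tips = [n for n, d in g.degree() if d <= 1]
    if len(coords) == 1:
        length = 0.0
    elif len(tips) == 2:
        length = nx.shortest_path_length(g, tips[0], tips[1], weight="weight")
    elif len(tips) == 0:
        # clean cycle: every voxel has internal degree 2, edges enumerated once
        length = sum(d["weight"] for _, _, d in g.edges(data=True))
    else:
        # rare post-thinning residue: fall back to the spanning-tree length
        length = sum(d["weight"]
                     for _, _, d in nx.minimum_spanning_edges(g, data=True))

    length += sum(incident.values())
    junction_ids = tuple(sorted(incident))
    return Branch(voxels=coords, length_um=float(length),
                  junction_ids=junction_ids, is_cycle=(len(tips) == 0 and len(coords) > 1))


def skeleton_statistics(skeleton: Skeleton) -> dict[str, Any]:
    """The nine skeleton summary fields plus derived totals."""
    lengths = [b.length_um for b in skeleton.branches]
    incident_count = [0] * len(skeleton.junction_clusters)
    for b in skeleton.branches:
        for jid in b.junction_ids:
            incident_count[jid - 1] += 1
    n_triple = sum(1 for c in incident_count if c == 3)
    n_quadruple = sum(1 for c in incident_count if c == 4)
    return {
        "n_trees": skeleton.n_trees,
        "n_branches": len(skeleton.branches),
        "n_junctions": len(skeleton.junction_clusters),
        "n_endpoints": len(skeleton.endpoints),
        "n_triple_points": n_triple,
        "n_quadruple_points": n_quadruple,
        "max_branch_length_um": float(max(lengths)) if lengths else 0.0,
        "mean_branch_length_um": float(np.mean(lengths)) if lengths else 0.0,
        "total_length_um": float(np.sum(lengths)) if lengths else 0.0,
        "sum_voxels": skeleton.n_voxels,
    }


# ---------------------------------------------------------------------------
# Texture and the full feature record
# ---------------------------------------------------------------------------

def apicobasal_texture(
    original: VolumetricImage, mask: BinaryMask, skeleton: Skeleton
) -> tuple[ZonationProfile, ZonationProfile, ZonationProfile]:
    """Apicobasal profiles of the original, segmented and skeletonized image."""
    if not (original.shape == mask.shape == skeleton.voxels.shape):
        raise ValueError("original, mask and skeleton must share the same shape")
    return (apicobasal_profile(original),
            apicobasal_profile(mask),
            apicobasal_profile(skeleton.voxels))


def quantify_stack(
    mask: BinaryMask | VolumetricImage,
    original: VolumetricImage | None = None,
    name: str = "",
    sigma_um: float = 0.0,
    prune_below_um: float = 0.0,
) -> FeatureRecord:
    """All morphometrics for one segmented stack."""
    mask = ensure_binary(mask)
    volume, coverage, n_objects = compute_volume_coverage(mask)
    s_um3, sv_ratio, s_um2 = compute_surface(mask)
    skeleton = skeletonize_3d(mask, prune_below_um=prune_below_um)
    if mask.voxels.any():
        _, t_mean, t_max = compute_edm_thickness(mask, skeleton)
    else:
        warnings.warn("empty mask: reporting a row of zeros", stacklevel=2)
        t_mean = t_max = 0.0
    stats = skeleton_statistics(skeleton)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        image_height, cell_height = zonation.measure_heights(mask, sigma_um)

    rec = FeatureRecord(
        name=name,
        image_height_um=image_height,
        cell_height_um=cell_height,
        n_objects=n_objects,
        volume_um3=volume,
        coverage_pct=coverage,
        surface_um3=s_um3,
        surface_um2=s_um2,
        sv_ratio=sv_ratio,
        thickness_um=t_mean,
        thickness_max_um=t_max,
        skeleton_length_um=stats["total_length_um"],
        n_junctions=stats["n_junctions"],
        n_endpoints=stats["n_endpoints"],
        mean_branch_length_um=stats["mean_branch_length_um"],
        max_branch_length_um=stats["max_branch_length_um"],
        n_trees=stats["n_trees"],
        n_branches=stats["n_branches"],
        n_triple_points=stats["n_triple_points"],
        n_quadruple_points=stats["n_quadruple_points"],
        skeleton_voxels=stats["sum_voxels"],
    )
    rec.validate()
    return rec


def write_quantification_csvs(
    records: list[FeatureRecord], out_dir: str | Path
) -> dict[str, Path]:
    """Write ``QuantificationResults.csv`` (bit-exact headers) and ``SkeletonStats.csv``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    quant = pd.DataFrame({
        "Image": [r.name for r in records],
        QUANT_COLUMNS[0]: [r.volume_um3 for r in records],
        QUANT_COLUMNS[1]: [r.coverage_pct for r in records],
        QUANT_COLUMNS[2]: [r.surface_um3 for r in records],
        QUANT_COLUMNS[3]: [r.thickness_um for r in records],
        "Surface [um2]": [r.surface_um2 for r in records],
        "SV ratio": [r.sv_ratio for r in records],
        "ImageHeight [um]": [r.image_height_um for r in records],
        "CellHeight [um]": [r.cell_height_um for r in records],
        "Objects": [r.n_objects for r in records],
    })
    qpath = out / "QuantificationResults.csv"
    quant.to_csv(qpath, index=False)

    skel = pd.DataFrame({
        "Image": [r.name for r in records],
        "max branch length": [r.max_branch_length_um for r in records],
        "mean branch length": [r.mean_branch_length_um for r in records],
        "# of trees": [r.n_trees for r in records],
        "# of branches": [r.n_branches for r in records],
        "# of junctions": [r.n_junctions for r in records],
        "# of endpoints": [r.n_endpoints for r in records],
        "# of triple points": [r.n_triple_points for r in records],
        "# of quadruple points": [r.n_quadruple_points for r in records],
        "sum of voxels": [r.skeleton_voxels for r in records],
    })
    spath = out / "SkeletonStats.csv"
    skel.to_csv(spath, index=False)
    return {"quantification": qpath, "skeleton_stats": spath}


def write_quantification_tree(
    mask: BinaryMask,
    original: VolumetricImage,
    out_dir: str | Path,
    name: str = "stack",
    prune_below_um: float = 0.0,
) -> dict[str, Path]:
    """Write the per-stack output folders: outZone/, QuantEDM/, QuantSkel/."""
    out = Path(out_dir)
    skeleton = skeletonize_3d(mask, prune_below_um=prune_below_um)
    edm, _, _ = compute_edm_thickness(mask, skeleton)

    edm_dir = out / "QuantEDM"
    skel_dir = out / "QuantSkel"
    zone_dir = out / "outZone"
    for d in (edm_dir, skel_dir, zone_dir):
        d.mkdir(parents=True, exist_ok=True)

    edm_img = VolumetricImage(edm.astype(np.float32), mask.voxel_size,
                              name=f"EDM_{name}")
    write_stack(edm_img, edm_dir / f"EDM_{name}.tif")
    write_stack(max_projection(edm_img), edm_dir / f"MAX_EDM_{name}.tif")
    skel_img = skeleton.to_image()
    skel_img.name = f"Skel_{name}"
    write_stack(skel_img, skel_dir / f"Skel_{name}.tif")
    write_stack(max_projection(skel_img), skel_dir / f"MAX_Skel_{name}.tif")

    prof_orig, prof_mask, prof_skel = apicobasal_texture(original, mask, skeleton)
    prof_orig.name, prof_mask.name, prof_skel.name = (
        f"{name}_original", f"{name}_segmented", f"{name}_skeleton")
    zonation.export_zonation([prof_mask], zone_dir)
    zonation.export_zonation([prof_skel], skel_dir)
    return {"QuantEDM": edm_dir, "QuantSkel": skel_dir, "outZone": zone_dir}
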