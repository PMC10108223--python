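"""Topology-preserving 3D thinning to a 1-voxel-wide centerline.

Layer-by-layer removal: each cycle visits the six border directions in turn
and deletes border voxels that are *simple* (their removal changes neither
object nor background topology) and not curve endpoints, until stable.

Simplicity uses the local characterization of Bertrand & Malandain: a voxel
is simple iff its 26-neighborhood contains exactly one 26-connected
foreground component, and the background restricted to the 18-neighborhood
has exactly one 6-connected component touching a face neighbor.

Endpoint protection covers true curve ends (exactly one neighbor) and
"chorded tips" (exactly two mutually adjacent neighbors): a near-1D chain
whose tip carries a diagonal chord is contractible voxel-by-voxel while
staying simple, so without the second rule a sequential pass could eat an
entire centerline. With it, erosion stops once a chain is minimal.

The checks are evaluated in vectorized batches (label propagation over the
fixed 3x3x3 adjacency graphs); voxels whose neighborhood changed earlier in
the same sub-iteration are re-checked live so deletions remain individually
topology-safe.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = ["thin_3d"]

_BIG = 127

# 26 neighbor offsets in raster order
_OFFSETS = np.array(
    [(dz, dy, dx)
     for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
     if (dz, dy, dx) != (0, 0, 0)],
    dtype=np.int64,
)

# 26-adjacency among the 26 neighbor positions
_A26 = np.zeros((26, 26), dtype=bool)
for _i in range(26):
    for _j in range(26):
        if _i != _j and np.max(np.abs(_OFFSETS[_i] - _OFFSETS[_j])) == 1:
            _A26[_i, _j] = True

# 18-neighborhood (face + edge offsets) and 6-adjacency among those positions
_IDX18 = np.array([i for i, o in enumerate(_OFFSETS) if np.abs(o).sum() <= 2])
_OFF18 = _OFFSETS[_IDX18]
_A6 = np.zeros((len(_IDX18), len(_IDX18)), dtype=bool)
for _i in range(len(_IDX18)):
    for _j in range(len(_IDX18)):
        if _i != _j and np.abs(_OFF18[_i] - _OFF18[_j]).sum() == 1:
            _A6[_i, _j] = True
_FACE_IN18 = np.array([i for i, o in enumerate(_OFF18) if np.abs(o).sum() == 1])

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)
_STRUCT6 = ndimage.generate_binary_structure(3, 1)


def _count_components(active: np.ndarray, adj: np.ndarray) -> np.ndarray:
    """Connected-component count of induced subgraphs, batched over rows."""
    n, m = active.shape
    labels = np.where(active, np.arange(m, dtype=np.int8), _BIG)
    for _ in range(m):
        spread = np.where(adj[None, :, :], labels[:, None, :], _BIG).min(axis=2)
        new = np.minimum(labels, np.where(active, spread, _BIG))
        if np.array_equal(new, labels):
            break
        labels = new
    roots = active & (labels == np.arange(m, dtype=np.int8))
    return roots.sum(axis=1), labels


def _neighborhoods(fg: np.ndarray, coords: np.ndarray) -> np.ndarray:
    return fg[
        coords[:, 0, None] + _OFFSETS[:, 0],
        coords[:, 1, None] + _OFFSETS[:, 1],
        coords[:, 2, None] + _OFFSETS[:, 2],
    ]  # (N, 26)


def _batch_protected(nb: np.ndarray) -> np.ndarray:
    """Curve-end protection: <=1 neighbor, or 2 mutually adjacent neighbors."""
    counts = nb.sum(axis=1)
    pairs = np.einsum("ni,ij,nj->n", nb, _A26, nb) // 2
    return (counts <= 1) | ((counts == 2) & (pairs == 1))


def _batch_simple(fg: np.ndarray, coords: np.ndarray,
                  nb: np.ndarray | None = None) -> np.ndarray:
    """Vectorized simple-point test for candidate coords (in padded space)."""
    if nb is None:
        nb = _neighborhoods(fg, coords)
    c_star, _ = _count_components(nb, _A26)

    bg18 = ~nb[:, _IDX18]
    _, labels18 = _count_components(bg18, _A6)
    face_labels = labels18[:, _FACE_IN18]  # (N, 6); _BIG where foreground
    sorted_fl = np.sort(face_labels, axis=1)
    distinct = (sorted_fl[:, :1] != _BIG).astype(np.int64).ravel()
    for k in range(1, sorted_fl.shape[1]):
        distinct += ((sorted_fl[:, k] != _BIG)
                     & (sorted_fl[:, k] != sorted_fl[:, k - 1]))
    return (c_star == 1) & (distinct == 1)


def _live_deletable(fg: np.ndarray, c: np.ndarray) -> bool:
    """Re-check one voxel against the current volume (protection + simplicity)."""
    cube = fg[c[0] - 1:c[0] + 2, c[1] - 1:c[1] + 2, c[2] - 1:c[2] + 2].copy()
    cube[1, 1, 1] = False
    n = int(cube.sum())
    if n <= 1:
        return False
    if n == 2:
        pts = np.argwhere(cube)
        if np.max(np.abs(pts[0] - pts[1])) == 1:
            return False  # chorded tip
    _, n_fg = ndimage.label(cube, structure=_STRUCT26)
    if n_fg != 1:
        return False
    bg = ~cube
    bg[1, 1, 1] = False
    bg[::2, ::2, ::2] = False  # drop the 8 corners: restrict to 18-neighborhood
    lab, _ = ndimage.label(bg, structure=_STRUCT6)
    faces = {lab[0, 1, 1], lab[2, 1, 1], lab[1, 0, 1], lab[1, 2, 1],
             lab[1, 1, 0], lab[1, 1, 2]} - {0}
    return len(faces) == 1


_DIRECTIONS = [(-1, 0, 0), (1, 0, 0), (0, -1, 0), (0, 1, 0), (0, 0, -1), (0, 0, 1)]


def thin_3d(volume: np.ndarray, max_cycles: int = 500) -> np.ndarray:
    """Thin a binary volume to its 1-voxel centerline (curve ends preserved)."""
    fg = np.pad(np.asarray(volume, dtype=bool), 1)
    for _ in range(max_cycles):
        deleted_any = False
        for d in _DIRECTIONS:
            border = fg & ~np.roll(fg, -np.array(d), axis=(0, 1, 2))
            coords = np.argwhere(border)
            if coords.size == 0:
                continue
            nb = _neighborhoods(fg, coords)
            # scan-time: only true curve ends are protected; chorded tips may
            # erode (they are pre-existing geometry). The stronger protection
            # applies in the live re-check, where cascades would start.
            ok = (nb.sum(axis=1) > 1) & _batch_simple(fg, coords, nb)
            coords = coords[ok]
            if coords.size == 0:
                continue
            pass_deleted = np.zeros_like(fg)
            for c in coords:
                z, y, x = c
                if pass_deleted[z - 1:z + 2, y - 1:y + 2, x - 1:x + 2].any():
                    if not _live_deletable(fg, c):
                        continue
                fg[z, y, x] = False
                pass_deleted[z, y, x] = True
                deleted_any = True
        if not deleted_any:
            break
    return fg[1:-1, 1:-1, 1:-1]
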