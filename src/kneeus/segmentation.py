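"""Automatic seed generation and seeded cartilage segmentation.

The localized bone surface is translated along the scan lines to plant
seeds: foreground (cartilage) half a mean knee-cartilage thickness (MKT)
above the surface, background two MKT above (soft tissue) and two MKT
below (bone shadow). Three interchangeable seeded backends segment the
enhanced image: a random walker (Dirichlet problem on the intensity-
weighted lattice), a marker-controlled watershed of the gradient
magnitude, and an s-t min-cut with hard seed terminals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy import ndimage
from scipy.sparse.csgraph import breadth_first_order, maximum_flow
from scipy.sparse.linalg import spsolve
from skimage import filters, measure, segmentation as sk_seg

from .enhancement import EnhancedImage
from .localization import BoneSurface
from .phantom import MEAN_CARTILAGE_THICKNESS_MM
from ._util import round_half_up

FG = 1
BG = 2

BACKENDS = ("rw", "watershed", "graphcut")


class SeedError(ValueError):
    """Raised when no usable seed geometry can be derived from the surface."""


@dataclass(frozen=True)
class SeedParams:
    """Seed-translation distances derived from the MKT prior (mm)."""

    mkt_mm: float = MEAN_CARTILAGE_THICKNESS_MM
    spacing_mm: float = 0.15
    dilate_px: int = 1  # seed polylines are dilated to short bands
    # interpolate the surface across "not found" columns before seeding;
    # cartilage is laterally continuous, and seed gaps let boundary-only
    # cuts sever the band
    bridge_gaps: bool = True

    def __post_init__(self):
        if self.mkt_mm <= 0 or self.spacing_mm <= 0:
            raise ValueError("mkt_mm and spacing_mm must be positive")

    @property
    def fg_offset_px(self) -> int:
        return int(round_half_up((self.mkt_mm / 2.0) / self.spacing_mm))

    @property
    def bg_offset_px(self) -> int:
        return int(round_half_up((2.0 * self.mkt_mm) / self.spacing_mm))


@dataclass(frozen=True)
class RWParams:
    """Random-walker edge sensitivity ``rw_beta`` and optional prior weight."""

    rw_beta: float = 130.0
    rw_gamma: float = 0.0

    def __post_init__(self):
        if self.rw_beta <= 0 or self.rw_gamma < 0:
            raise ValueError("rw_beta must be positive, rw_gamma non-negative")


@dataclass(frozen=True)
class GCParams:
    """Graph-cut boundary-weight scale; the model is boundary-only with hard seeds."""

    gc_lambda: float = 1.0  # overall n-link scale (no effect with hard seeds)
    gc_sigma: float = 0.1

    def __post_init__(self):
        if self.gc_lambda <= 0 or self.gc_sigma <= 0:
            raise ValueError("gc parameters must be positive")


@dataclass(frozen=True)
class SeedImage:
    """Label grid: 0 unlabeled, 1 foreground/cartilage, 2 background."""

    labels: np.ndarray

    @property
    def fg(self) -> np.ndarray:
        return self.labels == FG

    @property
    def bg(self) -> np.ndarray:
        return self.labels == BG


@dataclass(frozen=True)
class SegmentationResult:
    mask: np.ndarray  # bool cartilage mask
    seeds: SeedImage
    backend: str
    probabilities: np.ndarray | None = None  # RW only
    found: bool = True  # False => "no cartilage found"


def generate_seeds(
    surface: BoneSurface,
    shape: tuple[int, int],
    params: SeedParams | None = None,
    backend: str = "rw",
) -> SeedImage:
    """Translate the bone surface into foreground/background seed bands.

    Foreground: surface shifted up by round((MKT/2)/spacing) px (into the
    cartilage); background: shifted up and down by round((2*MKT)/spacing) px
    (soft tissue and shadow). With ``bridge_gaps`` (default) the surface is
    linearly interpolated across "not found" columns before translation;
    otherwise sentinel columns produce no seeds. Translations are clipped
    to the grid; foreground overwrites background on collision.
    """
    if params is None:
        params = SeedParams()
    if backend not in BACKENDS:
        raise SeedError(f"unknown backend {backend!r}; expected one of {BACKENDS}")
    n_rows, n_cols = shape
    valid = surface.valid
    if not valid.any():
        raise SeedError("no bone surface found: all columns are sentinel")
    labels = np.zeros(shape, dtype=np.uint8)
    if params.bridge_gaps:
        cols = np.arange(n_cols)
        rows = np.round(
            np.interp(cols, np.nonzero(valid)[0], surface.rows[valid])
        ).astype(int)
    else:
        cols = np.nonzero(valid)[0]
        rows = surface.rows[valid]

    def plant(row_offsets, value):
        for off in row_offsets:
            rr = np.clip(rows + off, 0, n_rows - 1)
            labels[rr, cols] = value

    half = params.dilate_px
    bg_offs = [-params.bg_offset_px + d for d in range(-half, half + 1)]
    bg_offs += [params.bg_offset_px + d for d in range(-half, half + 1)]
    fg_offs = [-params.fg_offset_px + d for d in range(-half, half + 1)]
    plant(bg_offs, BG)
    plant(fg_offs, FG)  # foreground wins collisions

    seeds = SeedImage(labels=labels)
    if not seeds.fg.any():
        raise SeedError("foreground seed band is empty after clipping")
    if not seeds.bg.any():
        raise SeedError("background seed band is empty after clipping")
    return seeds


def _lattice_edges(shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """4-connected lattice edge list (i, j) over flattened pixel indices."""
    n_rows, n_cols = shape
    idx = np.arange(n_rows * n_cols).reshape(shape)
    e1 = np.c_[idx[:-1, :].ravel(), idx[1:, :].ravel()]
    e2 = np.c_[idx[:, :-1].ravel(), idx[:, 1:].ravel()]
    edges = np.vstack([e1, e2])
    return edges[:, 0], edges[:, 1]


def random_walker(
    image: EnhancedImage | np.ndarray,
    seeds: SeedImage,
    params: RWParams | None = None,
) -> SegmentationResult:
    """Seeded random-walker segmentation.

    Edge weights ``exp(-beta * (g_i - g_j)**2 / max (g_i - g_j)**2)`` on the
    4-connected lattice; the foreground probability of each unlabeled pixel
    solves the combinatorial Dirichlet problem with seeds fixed to 1 (fg)
    and 0 (bg); with ``rw_gamma > 0`` a uniform prior is blended in through
    the regularized system. Mask = probability >= 0.5.
    """
    if params is None:
        params = RWParams()
    g = image.values if isinstance(image, EnhancedImage) else np.asarray(image, dtype=float)
    if g.shape != seeds.labels.shape:
        raise ValueError("image and seed shapes differ")
    if not (seeds.fg.any() and seeds.bg.any()):
        raise SeedError("both seed classes must be present")
    n = g.size
    flat = g.ravel()
    ei, ej = _lattice_edges(g.shape)
    grad2 = (flat[ei] - flat[ej]) ** 2
    norm = grad2.max()
    if norm <= 0:
        norm = 1.0
    w = np.exp(-params.rw_beta * grad2 / norm)
    adj = sp.coo_matrix((np.r_[w, w], (np.r_[ei, ej], np.r_[ej, ei])), shape=(n, n)).tocsr()
    lap = sp.diags(np.asarray(adj.sum(axis=1)).ravel()) - adj

    labels = seeds.labels.ravel()
    seeded = labels > 0
    x_s = (labels[seeded] == FG).astype(float)
    lap_uu = lap[~seeded][:, ~seeded]
    b = lap[~seeded][:, seeded]
    if params.rw_gamma > 0:
        n_u = lap_uu.shape[0]
        system = (lap_uu + params.rw_gamma * sp.identity(n_u)).tocsc()
        rhs = -b @ x_s + params.rw_gamma * 0.5  # uniform prior
    else:
        system = lap_uu.tocsc()
        rhs = -b @ x_s
    x_u = spsolve(system, rhs)

    prob = np.empty(n)
    prob[seeded] = x_s
    prob[~seeded] = np.clip(x_u, 0.0, 1.0)
    prob = prob.reshape(g.shape)
    return SegmentationResult(
        mask=prob >= 0.5, seeds=seeds, backend="rw", probabilities=prob
    )


def watershed_segment(
    image: EnhancedImage | np.ndarray, seeds: SeedImage
) -> SegmentationResult:
    """Marker-controlled watershed of the gradient magnitude.

    Minima are imposed at the internal (fg) and external (bg) markers and
    the Sobel gradient relief is flooded; the mask is the catchment basin
    grown from the internal marker.
    """
    g = image.values if isinstance(image, EnhancedImage) else np.asarray(image, dtype=float)
    if g.shape != seeds.labels.shape:
        raise ValueError("image and seed shapes differ")
    if not (seeds.fg.any() and seeds.bg.any()):
        raise SeedError("both marker classes must be present")
    relief = filters.sobel(g)
    basins = sk_seg.watershed(relief, markers=seeds.labels.astype(np.int32))
    return SegmentationResult(mask=basins == FG, seeds=seeds, backend="watershed")


def graphcut_segment(
    image: EnhancedImage | np.ndarray,
    seeds: SeedImage,
    params: GCParams | None = None,
) -> SegmentationResult:
    """s-t min-cut segmentation with hard seed terminals.

    n-links ``exp(-(g_i - g_j)**2 / (2*gc_sigma**2))`` on the 4-connected
    lattice; seeds are tied to their terminal with effectively infinite
    capacity and unseeded pixels carry no regional term (boundary-only
    model). The mask is the source side of the minimum cut; by max-flow
    duality the cut cost equals the flow value.
    """
    if params is None:
        params = GCParams()
    g = image.values if isinstance(image, EnhancedImage) else np.asarray(image, dtype=float)
    if g.shape != seeds.labels.shape:
        raise ValueError("image and seed shapes differ")
    if not (seeds.fg.any() and seeds.bg.any()):
        raise SeedError("both terminal seed sets must be non-empty")
    n = g.size
    flat = g.ravel()
    ei, ej = _lattice_edges(g.shape)
    w = params.gc_lambda * np.exp(-((flat[ei] - flat[ej]) ** 2) / (2.0 * params.gc_sigma**2))

    cap_scale = 10_000
    caps = np.round(w * cap_scale).astype(np.int64)
    source = n
    sink = n + 1
    hard = min(int(caps.sum()) + cap_scale + 1, 2**31 - 1)  # exceeds any finite cut

    fg_idx = np.nonzero(seeds.labels.ravel() == FG)[0]
    bg_idx = np.nonzero(seeds.labels.ravel() == BG)[0]
    rows = np.r_[ei, ej, np.full(fg_idx.size, source), bg_idx]
    cols = np.r_[ej, ei, fg_idx, np.full(bg_idx.size, sink)]
    vals = np.r_[caps, caps, np.full(fg_idx.size, hard), np.full(bg_idx.size, hard)]
    graph = sp.csr_matrix(
        (vals.astype(np.int64), (rows, cols)), shape=(n + 2, n + 2)
    ).astype(np.int32)

    flow = maximum_flow(graph, source, sink)
    residual = graph - flow.flow
    # source side of the min cut = nodes reachable in the residual network
    reach = breadth_first_order(
        (residual > 0).astype(np.int8), source, directed=True, return_predecessors=False
    )
    mask = np.zeros(n + 2, dtype=bool)
    mask[reach] = True
    return SegmentationResult(mask=mask[:n].reshape(g.shape), seeds=seeds, backend="graphcut")


def _postprocess(mask: np.ndarray, surface: BoneSurface | None) -> tuple[np.ndarray, bool]:
    """Clip below the bone surface, close small gaps, keep the largest component."""
    mask = np.asarray(mask, dtype=bool).copy()
    if surface is not None:
        cols = np.nonzero(surface.valid)[0]
        for c in cols:
            mask[surface.rows[c]:, c] = False  # cartilage sits strictly above bone
    mask = ndimage.binary_closing(mask, structure=np.ones((3, 3), dtype=bool))
    labeled = measure.label(mask, connectivity=1)
    if labeled.max() == 0:
        return np.zeros_like(mask), False
    largest = np.argmax(np.bincount(labeled.ravel())[1:]) + 1
    mask = labeled == largest
    if surface is not None:
        for c in np.nonzero(surface.valid)[0]:
            mask[surface.rows[c]:, c] = False
    return mask, bool(mask.any())


def segment(
    image: EnhancedImage | np.ndarray,
    surface: BoneSurface,
    backend: str = "rw",
    seed_params: SeedParams | None = None,
    rw_params: RWParams | None = None,
    gc_params: GCParams | None = None,
) -> SegmentationResult:
    """Seed from the bone surface, run the chosen backend, post-process.

    ``image`` is normally the enhanced map; pass the raw B-mode pixels to
    reproduce the unenhanced ablation. Post-processing keeps the largest
    4-connected component above the bone surface and closes 3x3 gaps. An
    empty final mask yields a result with ``found=False``.
    """
    if backend not in BACKENDS:
        raise SeedError(f"unknown backend {backend!r}; expected one of {BACKENDS}")
    g = image.values if isinstance(image, EnhancedImage) else np.asarray(image, dtype=float)
    seeds = generate_seeds(surface, g.shape, seed_params, backend=backend)
    if backend == "rw":
        res = random_walker(g, seeds, rw_params)
    elif backend == "watershed":
        res = watershed_segment(g, seeds)
    else:
        res = graphcut_segment(g, seeds, gc_params)
    mask, found = _postprocess(res.mask, surface)
    return SegmentationResult(
        mask=mask, seeds=seeds, backend=backend, probabilities=res.probabilities, found=found
    )
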