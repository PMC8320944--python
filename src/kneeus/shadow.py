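"""Bone-shadow enhancement via confidence and transmission maps.

The confidence map (CM) treats the local-phase bone image as an acoustic
medium: each pixel's value is the equilibrium probability that a random
walk on an 8-connected lattice, started at that pixel, reaches the
transducer row (top, fixed to 1) rather than the bottom row (fixed to 0).
Edge weights decay with the attenuated intensity difference between
neighbors, so the bright bone line acts as a barrier and confidence
collapses beneath it — the acoustic shadow.

A smooth signal-transmission map US_A is then fitted to CM by minimizing a
fidelity term plus an edge-weighted smoothness penalty, and the enhanced
bone-shadow image BSE inverts the scattering/attenuation composition
``CM = US_A * BSE + (1 - US_A) * rho`` for BSE.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import spsolve

from ._util import minmax_normalize


class ShadowNumericError(RuntimeError):
    """Raised when a sparse solve fails or produces non-finite values."""


@dataclass(frozen=True)
class ShadowParams:
    """Constants of the confidence-map walk and the transmission fit.

    ``cm_eta`` is the depth-attenuation exponent, ``cm_beta`` the edge
    sensitivity and ``cm_gamma`` the extra penalty on horizontal (and,
    scaled by sqrt(2), diagonal) steps of the walk. ``lam`` weighs fidelity
    against smoothness in the transmission fit; ``rho_fraction`` sets the
    tissue echogenicity rho as a fraction of max(CM); ``delta`` is the
    tissue attenuation exponent of the shadow inversion.
    """

    lam: float = 2.0
    rho_fraction: float = 0.90
    delta: float = 1.0
    epsilon: float = 1e-4
    cm_eta: float = 2.0
    cm_beta: float = 90.0
    cm_gamma: float = 0.03
    # cube-root compression of LP before the walk: LP is a product of
    # squared-derivative maps, so without compression typical bone ridges
    # are orders of magnitude below the map maximum and present no barrier
    lp_gamma: float = 1.0 / 3.0
    eps_smooth: float = 1e-3
    dj_filters: str = "first_difference"

    def __post_init__(self):
        if self.lam <= 0 or self.delta <= 0 or self.cm_beta <= 0 or self.cm_gamma < 0:
            raise ValueError("invalid shadow parameters")
        if not (0 < self.rho_fraction <= 1):
            raise ValueError("rho_fraction must be in (0, 1]")


@dataclass(frozen=True)
class ShadowSet:
    """Confidence map, transmission map, and raw + normalized shadow images."""

    cm: np.ndarray  # in [0, 1]; row 0 == 1, last row == 0
    usa: np.ndarray  # in [eps, 1]
    bse: np.ndarray  # min-max normalized to [0, 1]
    bse_raw: np.ndarray  # un-normalized inversion output
    rho: float


def compute_confidence_map(lp: np.ndarray, params: ShadowParams | None = None) -> np.ndarray:
    """Random-walk confidence of reaching the transducer row.

    Solves the Dirichlet problem on the 8-connected lattice with the top row
    fixed to 1 and the bottom row to 0; node intensities are depth-attenuated
    by ``exp(-eta * depth)`` and edge weights are
    ``exp(-beta * (|c_i - c_j| + penalty))`` with penalty 0 for vertical,
    gamma for horizontal and gamma*sqrt(2) for diagonal steps.
    """
    if params is None:
        params = ShadowParams()
    lp = np.asarray(lp, dtype=float)
    n_rows, n_cols = lp.shape
    depth = (np.arange(n_rows, dtype=float) / (n_rows - 1))[:, None]
    c = np.power(np.clip(lp, 0.0, None), params.lp_gamma) * np.exp(-params.cm_eta * depth)

    idx = np.arange(n_rows * n_cols).reshape(n_rows, n_cols)
    beta, gamma = params.cm_beta, params.cm_gamma
    rows_i, rows_j, weights = [], [], []

    def add_edges(src, dst, penalty):
        w = np.exp(-beta * (np.abs(c[src] - c[dst]) + penalty))
        rows_i.append(idx[src].ravel())
        rows_j.append(idx[dst].ravel())
        weights.append(w.ravel())

    vert = (slice(0, n_rows - 1), slice(None)), (slice(1, n_rows), slice(None))
    horiz = (slice(None), slice(0, n_cols - 1)), (slice(None), slice(1, n_cols))
    diag_r = (slice(0, n_rows - 1), slice(0, n_cols - 1)), (slice(1, n_rows), slice(1, n_cols))
    diag_l = (slice(0, n_rows - 1), slice(1, n_cols)), (slice(1, n_rows), slice(0, n_cols - 1))
    add_edges(*vert, 0.0)
    add_edges(*horiz, gamma)
    add_edges(*diag_r, gamma * np.sqrt(2.0))
    add_edges(*diag_l, gamma * np.sqrt(2.0))

    i = np.concatenate(rows_i)
    j = np.concatenate(rows_j)
    w = np.concatenate(weights)
    n = n_rows * n_cols
    adj = sp.coo_matrix((np.r_[w, w], (np.r_[i, j], np.r_[j, i])), shape=(n, n)).tocsr()
    lap = sp.diags(np.asarray(adj.sum(axis=1)).ravel()) - adj

    boundary_value = np.zeros(n)
    boundary_value[idx[0]] = 1.0
    is_boundary = np.zeros(n, dtype=bool)
    is_boundary[idx[0]] = True
    is_boundary[idx[-1]] = True
    interior = ~is_boundary

    lap_ii = lap[interior][:, interior]
    lap_ib = lap[interior][:, is_boundary]
    rhs = -lap_ib @ boundary_value[is_boundary]
    try:
        x = spsolve(lap_ii.tocsc(), rhs)
    except Exception as exc:  # pragma: no cover - degenerate weights
        raise ShadowNumericError(f"confidence-map solve failed: {exc}") from exc
    if not np.all(np.isfinite(x)):
        raise ShadowNumericError("confidence-map solution is not finite")

    cm = np.empty(n)
    cm[is_boundary] = boundary_value[is_boundary]
    cm[interior] = np.clip(x, 0.0, 1.0)
    return cm.reshape(n_rows, n_cols)


def _difference_operators(shape: tuple[int, int], kind: str) -> list[sp.csr_matrix]:
    """Sparse forward-difference operators (Neumann boundary rows are zero)."""
    n_rows, n_cols = shape
    n = n_rows * n_cols
    idx = np.arange(n).reshape(shape)
    ops = []
    for src, dst in (
        ((slice(0, n_rows - 1), slice(None)), (slice(1, n_rows), slice(None))),
        ((slice(None), slice(0, n_cols - 1)), (slice(None), slice(1, n_cols))),
    ):
        a = idx[src].ravel()
        b = idx[dst].ravel()
        rows = np.arange(a.size)
        d = sp.coo_matrix(
            (np.r_[-np.ones(a.size), np.ones(b.size)], (np.r_[rows, rows], np.r_[a, b])),
            shape=(a.size, n),
        ).tocsr()
        ops.append(d)
    if kind == "second_difference":
        ops = [d @ d.T @ d for d in ops]  # pragma: no cover - optional variant
    return ops


def estimate_transmission(cm: np.ndarray, params: ShadowParams | None = None) -> np.ndarray:
    """Edge-preserving smooth transmission map fitted to the confidence map.

    Minimizes ``lam/2 * ||u - cm||**2 + sum_j ||W_j o (D_j u)||_1`` with
    ``W_j = exp(-|D_j cm|**2)``; the l1 term is majorized by the weighted-l2
    form ``W_j (D_j u)**2 / (|D_j cm| + eps_smooth)``, giving a single
    sparse SPD solve. Large gradients of cm get small weights, so sharp
    shadow boundaries are preserved. Result clipped to [epsilon, 1].
    """
    if params is None:
        params = ShadowParams()
    cm = np.asarray(cm, dtype=float)
    n = cm.size
    ops = _difference_operators(cm.shape, params.dj_filters)
    system = sp.identity(n) * params.lam
    for d in ops:
        g = d @ cm.ravel()
        wj = np.exp(-np.abs(g) ** 2)
        aj = wj / (np.abs(g) + params.eps_smooth)
        system = system + 2.0 * (d.T @ sp.diags(aj) @ d)
    try:
        u = spsolve(system.tocsc(), params.lam * cm.ravel())
    except Exception as exc:  # pragma: no cover
        raise ShadowNumericError(f"transmission solve failed: {exc}") from exc
    if not np.all(np.isfinite(u)):
        raise ShadowNumericError("transmission solution is not finite")
    return np.clip(u.reshape(cm.shape), params.epsilon, 1.0)


def enhance_shadow(
    cm: np.ndarray,
    usa: np.ndarray,
    params: ShadowParams | None = None,
    normalize: bool = True,
) -> np.ndarray:
    """Invert the scattering/attenuation composition for the shadow image.

    ``BSE = (CM - rho) / max(US_A, eps)**delta + rho`` with
    ``rho = rho_fraction * max(CM)``. With delta = 1 and US_A > eps the
    composition ``US_A*BSE + (1 - US_A)*rho`` reproduces CM exactly. The
    raw inversion can leave [0, 1]; by default the returned map is min-max
    normalized for downstream masking (pass ``normalize=False`` for the raw
    values).
    """
    if params is None:
        params = ShadowParams()
    cm = np.asarray(cm, dtype=float)
    usa = np.asarray(usa, dtype=float)
    if cm.shape != usa.shape:
        raise ValueError("cm and usa shapes differ")
    rho = params.rho_fraction * cm.max()
    raw = (cm - rho) / np.maximum(usa, params.epsilon) ** params.delta + rho
    return _normalize_bse(raw) if normalize else raw


def _normalize_bse(raw: np.ndarray) -> np.ndarray:
    # the inversion saturates far below 0 where transmission bottoms out in
    # deep shadow; robust percentile clipping keeps those outliers from
    # squashing the soft-tissue/shadow transition in the normalized map
    lo, hi = np.percentile(raw, (1.0, 99.0))
    return minmax_normalize(np.clip(raw, lo, hi))


def compute_shadow_set(lp: np.ndarray, params: ShadowParams | None = None) -> ShadowSet:
    """Full shadow chain: confidence map -> transmission map -> BSE."""
    if params is None:
        params = ShadowParams()
    cm = compute_confidence_map(lp, params)
    usa = estimate_transmission(cm, params)
    raw = enhance_shadow(cm, usa, params, normalize=False)
    return ShadowSet(
        cm=cm,
        usa=usa,
        bse=_normalize_bse(raw),
        bse_raw=raw,
        rho=float(params.rho_fraction * cm.max()),
    )
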