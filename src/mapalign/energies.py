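"""Energy functionals of the map-alignment models.

Total wiring energy is ``E = E_a + E_c + E_u``:

* ``E_a`` (chemoaffinity): per-connection cost built from opposing
  exponential guidance-molecule gradients along the two axes,
  ``g_a(r_s, r_l) = alpha_a (e^{x_s} - 1) e^{-x_l}
  - beta_a (e^{y_s} - 1)(e^{y_l} - 1)``, summed with multiplicity.
* ``E_c`` (competition): ``sum_l [beta_c n_A(l)^2 - alpha_c n_A(l)]
  + sum_s gamma_c n_D(s)^2`` over the cached marginals.
* ``E_u`` (activity): Hebbian reward for connecting neurons with
  correlated spontaneous activity.  In the *correlational* model the SC is
  driven by the retina alone, so the reward is a pure function of the
  V1-SC distance in Omega space.  In the *integrational* model V1 axons
  also drive SC firing: each contact additionally earns the
  synaptic-weight-normalized correlation with the other V1 axons
  converging on the same SC dendrite, and the retinal term is weighted by
  the relative retinal drive ``xi_u``.

Mutant genotypes replace the isotropic retinal kernel with a two-peak
kernel (duplicated azimuth map): peaks at azimuth ``x_l / 2`` and
``x_l / 2 + 1/2`` with amplitude ratio ``alpha_u`` and azimuthal width
stretched by ``kappa_u``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

from .omega_core import ConnectivityState, ModelParams, OmegaGrid

__all__ = [
    "EnergyBreakdown",
    "EnergyField",
    "chemoaffinity_kernel",
    "retinal_kernel",
    "axon_correlation_kernel",
    "synaptic_weight",
    "synaptic_weight_matrix",
    "chemoaffinity_energy",
    "competition_energy",
    "activity_energy",
    "total_energy",
    "delta_energy",
    "energy_field",
]


@dataclass(frozen=True)
class EnergyBreakdown:
    """Energy components (dimensionless model-energy units)."""

    E_a: float
    E_c: float
    E_u: float

    @property
    def E_total(self) -> float:
        return self.E_a + self.E_c + self.E_u


@dataclass(frozen=True)
class EnergyField:
    """Per-SC-site energy for one V1 source (supplementary heat maps)."""

    source: Tuple[float, float]
    component: str  # "chemoaffinity" | "activity"
    values: np.ndarray  # (n_sc_sites,)
    grid: OmegaGrid

    def as_matrix(self) -> np.ndarray:
        n = self.grid.n_per_axis
        return self.values.reshape(n, n)


# ---------------------------------------------------------------------------
# Per-connection kernels
# ---------------------------------------------------------------------------

def chemoaffinity_kernel(sc_coords: np.ndarray, v1_coords: np.ndarray,
                         params: ModelParams) -> np.ndarray:
    """Chemoaffinity cost ``g_a`` for every (SC site, V1 site) pair."""
    xs = sc_coords[:, 0][:, None]
    ys = sc_coords[:, 1][:, None]
    xl = v1_coords[:, 0][None, :]
    yl = v1_coords[:, 1][None, :]
    return (params.alpha_a * (np.exp(xs) - 1.0) * np.exp(-xl)
            - params.beta_a * (np.exp(ys) - 1.0) * (np.exp(yl) - 1.0))


def _two_peak_kernel(xs, ys, xl, yl, params: ModelParams) -> np.ndarray:
    """Duplicated-map activity kernel (mutant genotypes).

    Each V1 azimuth ``x_l`` correlates with two SC azimuths, ``x_l / 2``
    (anterior duplicate, amplitude ``alpha_u``) and ``x_l / 2 + 1/2``
    (posterior duplicate, amplitude 1).  With ``kernel_form ==
    "exponential"`` the exponent is the elliptical distance (azimuth scaled
    by ``kappa_u * beta_u``, elevation by ``beta_u``); the "gaussian"
    variant squares it.
    """
    kb = params.kappa_u * params.beta_u
    dy = (ys - yl) / params.beta_u
    d1 = np.sqrt(((xs - xl / 2.0) / kb) ** 2 + dy ** 2)
    d2 = np.sqrt(((xs - xl / 2.0 - 0.5) / kb) ** 2 + dy ** 2)
    if params.kernel_form == "gaussian":
        d1, d2 = d1 ** 2, d2 ** 2
    return params.alpha_u * np.exp(-d1) + np.exp(-d2)


def retinal_kernel(sc_coords: np.ndarray, v1_coords: np.ndarray,
                   params: ModelParams) -> np.ndarray:
    """Correlation between a V1 axon and retinally driven SC activity.

    Returns the (n_sc, n_v1) kernel matrix; unit peak for WT, two peaks of
    amplitude ``alpha_u`` / 1 for the duplicated-map genotypes.
    """
    sc_coords = np.atleast_2d(sc_coords)
    v1_coords = np.atleast_2d(v1_coords)
    xs = sc_coords[:, 0][:, None]
    ys = sc_coords[:, 1][:, None]
    xl = v1_coords[:, 0][None, :]
    yl = v1_coords[:, 1][None, :]
    if not params.is_mutant:
        d = np.sqrt((xs - xl) ** 2 + (ys - yl) ** 2)
        return np.exp(-d / params.beta_u)
    return _two_peak_kernel(xs, ys, xl, yl, params)


def axon_correlation_kernel(v1_coords: np.ndarray, params: ModelParams) -> np.ndarray:
    """Activity correlation between two V1 axons, ``exp(-|r_l - q_l| / beta_u)``.

    The integrational model uses the isotropic form for the axon-axon term
    under every genotype (asymmetry enters only through the retinal term).
    """
    d = np.linalg.norm(v1_coords[:, None, :] - v1_coords[None, :, :], axis=-1)
    return np.exp(-d / params.beta_u)


def synaptic_weight(r: Sequence[float], q: Sequence[float], nu_u: float) -> float:
    """Synaptic weight ``D(r, q) = exp(-(|r - q| / (2 nu_u))^2)``.

    Symmetric in its arguments and equal to 1 at zero separation.
    """
    if nu_u <= 0:
        raise ValueError("nu_u must be strictly positive")
    d = float(np.linalg.norm(np.asarray(r, float) - np.asarray(q, float)))
    return float(np.exp(-((d / (2.0 * nu_u)) ** 2)))


def synaptic_weight_matrix(sc_coords: np.ndarray, v1_coords: np.ndarray,
                           nu_u: float) -> np.ndarray:
    if nu_u <= 0:
        raise ValueError("nu_u must be strictly positive")
    d2 = ((sc_coords[:, None, :] - v1_coords[None, :, :]) ** 2).sum(axis=-1)
    return np.exp(-d2 / (4.0 * nu_u * nu_u))


# ---------------------------------------------------------------------------
# Global energies
# ---------------------------------------------------------------------------

def _check_same_grid(state: ConnectivityState, grid: Optional[OmegaGrid] = None):
    if grid is not None and grid.n_sites != state.grid.n_sites:
        raise ValueError("state and grid sizes do not match")


def chemoaffinity_energy(state: ConnectivityState, params: ModelParams) -> float:
    g = chemoaffinity_kernel(state.grid.sc_coords, state.grid.v1_coords, params)
    return float((state.counts * g).sum())


def competition_energy(state: ConnectivityState, params: ModelParams) -> float:
    n_A = state.n_A.astype(np.float64)
    n_D = state.n_D.astype(np.float64)
    return float((params.beta_c * n_A ** 2 - params.alpha_c * n_A).sum()
                 + (params.gamma_c * n_D ** 2).sum())


def _site_axon_term(counts_row: np.ndarray, D_row: np.ndarray,
                    K: np.ndarray) -> float:
    """``sum_l n(s,l) * A(s,l)`` for one SC site.

    ``A(s,l)`` is the weighted mean correlation of axon ``l`` with the
    *other* axons converging on site ``s`` (weights ``D(s,q) n(s,q)``); it
    is defined as 0 when no other axon is present (the 0/0 case).
    """
    active = np.nonzero(counts_row)[0]
    if active.size == 0:
        return 0.0
    n = counts_row[active].astype(np.float64)
    w = D_row[active] * n                      # D(s,q) n(s,q) for active q
    sw = w.sum()
    Ksub = K[np.ix_(active, active)]
    num = Ksub @ w - w                          # exclude q == l (K(l,l) = 1)
    den = sw - w
    A = np.where(den > 0.0, num / np.where(den > 0.0, den, 1.0), 0.0)
    return float((n * A).sum())


def activity_energy(state: ConnectivityState, params: ModelParams) -> float:
    """Activity-dependent energy ``E_u`` for either model."""
    grid = state.grid
    R = retinal_kernel(grid.sc_coords, grid.v1_coords, params)
    if params.model_kind == "correlational":
        return float(-params.gamma_u * (state.counts * R).sum())
    D = synaptic_weight_matrix(grid.sc_coords, grid.v1_coords, params.nu_u)
    K = axon_correlation_kernel(grid.v1_coords, params)
    retinal_part = params.xi_u * (state.counts * R).sum()
    axon_part = sum(_site_axon_term(state.counts[s], D[s], K)
                    for s in range(grid.n_sites))
    return float(-params.gamma_u * (axon_part + retinal_part))


def total_energy(state: ConnectivityState, params: ModelParams) -> EnergyBreakdown:
    return EnergyBreakdown(E_a=chemoaffinity_energy(state, params),
                           E_c=competition_energy(state, params),
                           E_u=activity_energy(state, params))


# ---------------------------------------------------------------------------
# Incremental energy differences
# ---------------------------------------------------------------------------

def _delta_single(state: ConnectivityState, pair: Tuple[int, int], sign: int,
                  params: ModelParams,
                  tables: Optional[dict] = None) -> float:
    """Energy change of adding (sign=+1) or removing (sign=-1) one contact.

    Chemoaffinity and the correlational/retinal activity terms are local to
    the contact; competition uses the closed-form marginal update
    ``(n +- 1)^2 - n^2``; the integrational axon-axon term recomputes only
    the affected SC site (its normalization couples all axons converging
    there).
    """
    s, l = pair
    grid = state.grid
    if sign < 0 and state.counts[s, l] < 1:
        raise ValueError(f"invalid move: no contact to remove at (sc={s}, v1={l})")
    sc = grid.sc_coords[s:s + 1]
    v1 = grid.v1_coords[l:l + 1]

    if tables is not None:
        g_a = tables["g_a"][s, l]
        R = tables["R"][s, l]
    else:
        g_a = float(chemoaffinity_kernel(sc, v1, params)[0, 0])
        R = float(retinal_kernel(sc, v1, params)[0, 0])

    n_A = float(state.n_A[l])
    n_D = float(state.n_D[s])
    if sign > 0:
        d_comp = (params.beta_c * (2.0 * n_A + 1.0) - params.alpha_c
                  + params.gamma_c * (2.0 * n_D + 1.0))
    else:
        d_comp = (params.beta_c * (1.0 - 2.0 * n_A) + params.alpha_c
                  + params.gamma_c * (1.0 - 2.0 * n_D))

    if params.model_kind == "correlational":
        return sign * g_a + d_comp + sign * (-params.gamma_u * R)

    # integrational: retinal term is local; axon-axon term is site-local
    if tables is not None:
        D_row = tables["D"][s]
        K = tables["K"]
    else:
        D_row = synaptic_weight_matrix(sc, grid.v1_coords, params.nu_u)[0]
        K = axon_correlation_kernel(grid.v1_coords, params)
    before = _site_axon_term(state.counts[s], D_row, K)
    state.counts[s, l] += sign
    after = _site_axon_term(state.counts[s], D_row, K)
    state.counts[s, l] -= sign
    d_axon = -params.gamma_u * (after - before)
    return sign * g_a + d_comp + sign * (-params.gamma_u * params.xi_u * R) + d_axon


def delta_energy(state: ConnectivityState, move, params: ModelParams,
                 tables: Optional[dict] = None) -> float:
    """``E_total(state after move) - E_total(state before move)``.

    ``move`` carries an optional ``add_pair`` and an optional
    ``remove_pair`` (applied in that order); the state is left unchanged.
    """
    add_pair = getattr(move, "add_pair", None)
    remove_pair = getattr(move, "remove_pair", None)
    if add_pair is None and remove_pair is None:
        return 0.0
    total = 0.0
    applied = False
    try:
        if add_pair is not None:
            total += _delta_single(state, add_pair, +1, params, tables)
            if remove_pair is not None:
                state.add_contact(*add_pair)
                applied = True
        if remove_pair is not None:
            total += _delta_single(state, remove_pair, -1, params, tables)
    finally:
        if applied:
            state.remove_contact(*add_pair)
    return total


def make_energy_tables(grid: OmegaGrid, params: ModelParams) -> dict:
    """Precompute the per-pair kernel tables used by the annealer.

    ``L`` is the fully local per-connection energy: chemoaffinity plus the
    local part of the activity energy (the whole kernel for the
    correlational model, the retinal term for the integrational model).
    Memory scales as (sites per layer)^2; a 100x100 grid needs ~0.8 GB per
    table.
    """
    g_a = chemoaffinity_kernel(grid.sc_coords, grid.v1_coords, params)
    R = retinal_kernel(grid.sc_coords, grid.v1_coords, params)
    tables = {"g_a": g_a, "R": R}
    if params.model_kind == "correlational":
        tables["L"] = g_a - params.gamma_u * R
    else:
        tables["L"] = g_a - params.gamma_u * params.xi_u * R
        tables["D"] = synaptic_weight_matrix(grid.sc_coords, grid.v1_coords,
                                             params.nu_u)
        tables["K"] = axon_correlation_kernel(grid.v1_coords, params)
    return tables


# ---------------------------------------------------------------------------
# Energy fields (supplementary heat maps)
# ---------------------------------------------------------------------------

def energy_field(params: ModelParams, v1_location: Sequence[float],
                 component: str, grid: OmegaGrid) -> EnergyField:
    """Per-SC-site per-connection energy for one V1 source location.

    ``chemoaffinity`` evaluates ``g_a``; ``activity`` evaluates the
    retinal-drive energy ``-gamma_u R`` (times ``xi_u`` for the
    integrational model, whose axon-axon term is state-dependent and has no
    single-axon field).
    """
    loc = np.asarray(v1_location, dtype=float)[None, :]
    if not ((0.0 <= loc) & (loc <= 1.0)).all():
        raise ValueError("v1_location must lie in the unit square")
    if component == "chemoaffinity":
        vals = chemoaffinity_kernel(grid.sc_coords, loc, params)[:, 0]
    elif component == "activity":
        R = retinal_kernel(grid.sc_coords, loc, params)[:, 0]
        scale = params.gamma_u * (params.xi_u if params.model_kind == "integrational" else 1.0)
        vals = -scale * R
    else:
        raise ValueError(f"unknown component {component!r}")
    return EnergyField(source=(float(loc[0, 0]), float(loc[0, 1])),
                       component=component, values=vals, grid=grid)
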