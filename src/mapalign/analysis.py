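"""Post-simulation analyses of the connectivity field.

Connection densities are Gaussian kernel-density estimates (Silverman
bandwidth) of connection endpoint coordinates, count-weighted.  A
*termination zone* is the SC density of connections made by axons from a
small V1 seed neighborhood (default radius 0.04 Omega units); its size is
quantified by the region above 20% of the zone's maximum density.  The
convergence summary of a run concatenates five SC-azimuth density
profiles sampled at five V1 azimuth bands; Euclidean distances between
consecutive summaries measure how settled the configuration is.  The
retinal-drive sweep re-anneals the duplicated-map genotype while scaling
the retinal-drive parameter (``gamma_u`` for the correlational model,
``xi_u`` for the integrational one) and tracks the azimuth profile of
central-origin projections - the single-to-duplicated transition diagram.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.signal import find_peaks
from scipy.stats import gaussian_kde

from .omega_core import (ConnectivityState, OmegaGrid, build_grid,
                         genotype_params, init_connectivity)

logger = logging.getLogger(__name__)

__all__ = [
    "DensityProfile",
    "TerminationZone",
    "SweepResult",
    "density_1d",
    "density_2d",
    "termination_zones",
    "tz_width",
    "detect_peaks",
    "peak_separation",
    "convergence_trace",
    "snapshot_profile_vector",
    "sweep_retinal_drive",
    "transition_stats",
    "DEFAULT_SEED_CENTERS",
    "SNAPSHOT_BAND_CENTERS",
]

#: 3x3 grid of default V1 seed locations for termination-zone maps
DEFAULT_SEED_CENTERS = tuple((x, y) for y in (0.25, 0.5, 0.75)
                             for x in (0.25, 0.5, 0.75))
#: V1 azimuth positions of the five sampled density profiles
SNAPSHOT_BAND_CENTERS = (0.1, 0.3, 0.5, 0.7, 0.9)
SEED_RADIUS = 0.04


@dataclass
class DensityProfile:
    """KDE-smoothed connection density along one axis or over the SC sheet.

    For 1-D profiles ``support`` is the evaluation grid and ``values`` the
    density; for 2-D profiles ``support`` is ``(xs, ys)`` and ``values``
    has shape ``(len(ys), len(xs))``.
    """

    axis: str  # "azimuth" | "elevation" | "2d"
    support: object
    values: np.ndarray
    normalized: bool = False
    bandwidth: Optional[float] = None
    is_empty: bool = False


@dataclass
class TerminationZone:
    """SC projection zone of one V1 seed neighborhood."""

    seed_center: Tuple[float, float]
    seed_radius: float
    sc_density: DensityProfile          # 2-D over the SC sheet
    azimuth_profile: DensityProfile     # 1-D marginal along the azimuth
    peak: Tuple[float, float]           # location of the 2-D density maximum
    area_fraction: float                # SC area above 20% of zone maximum
    width_at_fraction: float            # 1-D azimuth width at the threshold


# ---------------------------------------------------------------------------
# KDE helpers
# ---------------------------------------------------------------------------

def _weighted_kde_1d(x: np.ndarray, w: np.ndarray, support: np.ndarray,
                     fallback_bw: float) -> Tuple[np.ndarray, float]:
    """Gaussian KDE with Silverman bandwidth; degenerate data (all mass at
    one location, or a single point) fall back to a Gaussian bump of width
    ``fallback_bw``."""
    mu = float(np.average(x, weights=w))
    var = float(np.average((x - mu) ** 2, weights=w))
    if x.size > 1 and var > 1e-18:
        try:
            kde = gaussian_kde(x, bw_method="silverman", weights=w)
            bw = float(np.sqrt(kde.covariance[0, 0]))
            return kde(support), bw
        except (np.linalg.LinAlgError, ValueError):
            pass
    bw = fallback_bw
    vals = np.exp(-0.5 * ((support - mu) / bw) ** 2) / (bw * np.sqrt(2 * np.pi))
    return vals, bw


def _weighted_kde_2d(xy: np.ndarray, w: np.ndarray, xs: np.ndarray,
                     ys: np.ndarray, fallback_bw: float) -> Tuple[np.ndarray, float]:
    xx, yy = np.meshgrid(xs, ys)
    pts = np.vstack([xx.ravel(), yy.ravel()])
    mu = np.average(xy, axis=0, weights=w)
    var = float(np.average(((xy - mu) ** 2).sum(axis=1), weights=w))
    if xy.shape[0] > 2 and var > 1e-18:
        try:
            kde = gaussian_kde(xy.T, bw_method="silverman", weights=w)
            bw = float(np.sqrt(np.mean(np.diag(kde.covariance))))
            return kde(pts).reshape(len(ys), len(xs)), bw
        except (np.linalg.LinAlgError, ValueError):
            pass
    bw = fallback_bw
    d2 = (xx - mu[0]) ** 2 + (yy - mu[1]) ** 2
    return np.exp(-0.5 * d2 / bw ** 2) / (2 * np.pi * bw ** 2), bw


def v1_disk_mask(grid: OmegaGrid, center: Sequence[float], radius: float) -> np.ndarray:
    c = np.asarray(center, dtype=float)
    return np.linalg.norm(grid.v1_coords - c[None, :], axis=1) <= radius


def v1_azimuth_band_mask(grid: OmegaGrid, x0: float, halfwidth: float) -> np.ndarray:
    return np.abs(grid.v1_coords[:, 0] - x0) <= halfwidth


# ---------------------------------------------------------------------------
# Densities
# ---------------------------------------------------------------------------

def density_1d(state: ConnectivityState, axis: str = "azimuth",
               layer: str = "sc", v1_mask: Optional[np.ndarray] = None,
               normalize: bool = True, n_points: int = 100,
               support: Optional[np.ndarray] = None) -> DensityProfile:
    """1-D connection density along ``axis`` of ``layer``.

    ``v1_mask`` optionally restricts to connections whose V1 endpoint lies
    in a seed neighborhood (boolean array over V1 sites).  An empty
    selection returns an all-zero profile flagged ``is_empty`` rather than
    raising.
    """
    grid = state.grid
    if axis not in ("azimuth", "elevation"):
        raise ValueError(f"unknown axis {axis!r}")
    col = 0 if axis == "azimuth" else 1
    if layer == "sc":
        coords = grid.sc_coords[:, col]
        if v1_mask is None:
            weights = state.n_D.astype(float)
        else:
            weights = state.counts[:, v1_mask].sum(axis=1).astype(float)
    elif layer == "v1":
        coords = grid.v1_coords[:, col]
        weights = state.n_A.astype(float)
        if v1_mask is not None:
            weights = weights * v1_mask
    else:
        raise ValueError(f"unknown layer {layer!r}")
    if support is None:
        support = np.linspace(0.0, 1.0, n_points)
    if weights.sum() <= 0:
        return DensityProfile(axis=axis, support=support,
                              values=np.zeros_like(support),
                              normalized=normalize, bandwidth=None, is_empty=True)
    sel = weights > 0
    vals, bw = _weighted_kde_1d(coords[sel], weights[sel], support, grid.spacing)
    if normalize and vals.max() > 0:
        vals = vals / vals.max()
    return DensityProfile(axis=axis, support=support, values=vals,
                          normalized=normalize, bandwidth=bw)


def density_2d(state: ConnectivityState, v1_mask: Optional[np.ndarray] = None,
               n_points: int = 60, normalize: bool = True) -> DensityProfile:
    """2-D connection density over the SC sheet."""
    grid = state.grid
    if v1_mask is None:
        weights = state.n_D.astype(float)
    else:
        weights = state.counts[:, v1_mask].sum(axis=1).astype(float)
    xs = np.linspace(0.0, 1.0, n_points)
    ys = np.linspace(0.0, 1.0, n_points)
    if weights.sum() <= 0:
        return DensityProfile(axis="2d", support=(xs, ys),
                              values=np.zeros((n_points, n_points)),
                              normalized=normalize, is_empty=True)
    sel = weights > 0
    vals, bw = _weighted_kde_2d(grid.sc_coords[sel], weights[sel], xs, ys,
                                grid.spacing)
    if normalize and vals.max() > 0:
        vals = vals / vals.max()
    return DensityProfile(axis="2d", support=(xs, ys), values=vals,
                          normalized=normalize, bandwidth=bw)


def tz_width(profile: DensityProfile, fraction: float = 0.2) -> float:
    """Extent of the region where the density reaches ``fraction`` of max.

    1-D profiles return the total length of the super-threshold set; 2-D
    profiles return the fraction of SC area above threshold.
    """
    vals = np.asarray(profile.values, dtype=float)
    vmax = vals.max()
    if vmax <= 0:
        raise ValueError("width undefined for an all-zero profile")
    above = vals >= fraction * vmax
    if vals.ndim == 1:
        sup = np.asarray(profile.support, dtype=float)
        dx = sup[1] - sup[0]
        return float(above.sum() * dx)
    return float(above.mean())


def detect_peaks(profile: DensityProfile, threshold_frac: float = 0.2,
                 merge_within: Optional[float] = None) -> Tuple[np.ndarray, np.ndarray]:
    """Local maxima of a 1-D profile above ``threshold_frac`` of its max.

    Peaks closer than ``merge_within`` (default: the KDE bandwidth) are
    merged, keeping the higher one.  Invariant to max-normalization.
    Returns (positions, heights).
    """
    vals = np.asarray(profile.values, dtype=float)
    sup = np.asarray(profile.support, dtype=float)
    if vals.max() <= 0:
        return np.array([]), np.array([])
    if merge_within is None:
        merge_within = profile.bandwidth or (sup[1] - sup[0])
    idx, _ = find_peaks(vals, height=threshold_frac * vals.max())
    pos, height = sup[idx], vals[idx]
    order = np.argsort(height)[::-1]
    kept_pos: List[float] = []
    kept_h: List[float] = []
    for i in order:
        if all(abs(pos[i] - p) > merge_within for p in kept_pos):
            kept_pos.append(pos[i])
            kept_h.append(height[i])
    order2 = np.argsort(kept_pos)
    return np.asarray(kept_pos)[order2], np.asarray(kept_h)[order2]


def peak_separation(profile: DensityProfile, threshold_frac: float = 0.2) -> float:
    """Distance between the outermost detected peaks (0 if unimodal)."""
    pos, _ = detect_peaks(profile, threshold_frac)
    if len(pos) < 2:
        return 0.0
    return float(pos.max() - pos.min())


def termination_zones(state: ConnectivityState,
                      seed_centers: Sequence[Tuple[float, float]] = DEFAULT_SEED_CENTERS,
                      radius: float = SEED_RADIUS,
                      n_points: int = 60) -> List[TerminationZone]:
    """Termination-zone maps for a set of V1 seed neighborhoods."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    grid = state.grid
    zones: List[TerminationZone] = []
    for center in seed_centers:
        mask = v1_disk_mask(grid, center, radius)
        if not mask.any():
            raise ValueError(
                f"no V1 sites within radius {radius} of seed {tuple(center)} "
                f"on a {grid.n_per_axis}x{grid.n_per_axis} grid")
        dens2 = density_2d(state, v1_mask=mask, n_points=n_points)
        prof = density_1d(state, axis="azimuth", layer="sc", v1_mask=mask)
        if dens2.is_empty:
            zones.append(TerminationZone(seed_center=tuple(center),
                                         seed_radius=radius, sc_density=dens2,
                                         azimuth_profile=prof,
                                         peak=(np.nan, np.nan),
                                         area_fraction=0.0,
                                         width_at_fraction=0.0))
            continue
        xs, ys = dens2.support
        iy, ix = np.unravel_index(np.argmax(dens2.values), dens2.values.shape)
        zones.append(TerminationZone(
            seed_center=tuple(center), seed_radius=radius, sc_density=dens2,
            azimuth_profile=prof, peak=(float(xs[ix]), float(ys[iy])),
            area_fraction=tz_width(dens2, 0.2),
            width_at_fraction=tz_width(prof, 0.2)))
    return zones


# ---------------------------------------------------------------------------
# Convergence summaries
# ---------------------------------------------------------------------------

def snapshot_profile_vector(state: ConnectivityState,
                            band_centers: Sequence[float] = SNAPSHOT_BAND_CENTERS,
                            halfwidth: float = SEED_RADIUS,
                            n_points: int = 100) -> np.ndarray:
    """Concatenated max-normalized SC-azimuth profiles at five V1 bands.

    On coarse lattices the band half-width is widened to resolve at least
    one lattice column per band.
    """
    grid = state.grid
    hw = max(halfwidth, 0.75 * grid.spacing)
    parts = []
    for c in band_centers:
        mask = v1_azimuth_band_mask(grid, c, hw)
        prof = density_1d(state, axis="azimuth", layer="sc", v1_mask=mask,
                          normalize=True, n_points=n_points)
        parts.append(prof.values)
    return np.concatenate(parts)


def convergence_trace(trajectory) -> List[Tuple[int, float]]:
    """Euclidean distance between consecutive snapshot density summaries."""
    vecs = [np.asarray(v, dtype=float) for v in trajectory.profile_vectors]
    steps = list(trajectory.snapshot_steps)
    if len(vecs) < 2:
        raise ValueError("need at least two snapshots for a convergence trace")
    n = min(len(v) for v in vecs)
    if any(len(v) != n for v in vecs):
        logger.warning("snapshot profile lengths differ; truncating to %d", n)
        vecs = [v[:n] for v in vecs]
    return [(steps[i], float(np.linalg.norm(vecs[i] - vecs[i - 1])))
            for i in range(1, len(vecs))]


# ---------------------------------------------------------------------------
# Retinal-drive sweep
# ---------------------------------------------------------------------------

@dataclass
class SweepResult:
    """Azimuth density of central-origin projections vs retinal drive."""

    parameter_name: str                  # "gamma_u" | "xi_u"
    values: np.ndarray
    support: np.ndarray
    profiles: List[np.ndarray]           # median profile per value
    peak_stats: List[Dict]               # per value: positions, separations
    seeds: List[List[int]]
    failures: List[Dict] = field(default_factory=list)

    @property
    def separations(self) -> np.ndarray:
        return np.asarray([p["separation"] for p in self.peak_stats])


def _run_one_sweep_point(model_kind: str, value: float, grid_size: int,
                         steps_per_neuron: int, seed: int,
                         init_mean: float, n_points: int) -> np.ndarray:
    """One anneal at one retinal-drive value; returns the central-seed
    azimuth profile (max-normalized)."""
    from .annealer import AnnealSchedule, anneal  # local: avoids cycle

    name = "gamma_u" if model_kind == "correlational" else "xi_u"
    params = genotype_params(model_kind, "Isl2EphA3", **{name: float(value)})
    grid = build_grid(grid_size)
    state = init_connectivity(grid, "random", init_mean, seed=seed)
    total = steps_per_neuron * grid.n_sites
    schedule = AnnealSchedule(steps_per_neuron=steps_per_neuron,
                              snapshot_interval=total, seed=seed)
    anneal(state, params, schedule)
    hw = max(SEED_RADIUS, 0.75 * grid.spacing)
    mask = v1_azimuth_band_mask(grid, 0.5, hw)
    prof = density_1d(state, axis="azimuth", layer="sc", v1_mask=mask,
                      normalize=True, n_points=n_points)
    return prof.values


def sweep_retinal_drive(model_kind: str, values: Sequence[float],
                        grid_size: int = 30, steps_per_neuron: int = 15_000,
                        n_seeds: int = 3, base_seed: int = 0,
                        init_mean: float = 50.0, n_points: int = 100,
                        n_jobs: int = 1) -> SweepResult:
    """Bifurcation-style sweep of the retinal-drive parameter.

    For each value (ascending) the duplicated-map genotype is re-annealed
    from scratch with ``n_seeds`` independent seeds; reported profiles and
    peak separations are per-value medians over seeds.
    """
    values = np.asarray(list(values), dtype=float)
    if not (np.diff(values) > 0).all():
        raise ValueError("sweep values must be sorted ascending")
    name = "gamma_u" if model_kind == "correlational" else "xi_u"
    support = np.linspace(0.0, 1.0, n_points)
    jobs = []
    seeds_per_value: List[List[int]] = []
    for iv, v in enumerate(values):
        row = []
        for js in range(n_seeds):
            ss = np.random.SeedSequence([int(base_seed) & 0x7FFFFFFF, iv, js])
            row.append(int(ss.generate_state(1)[0] & 0x7FFFFFFF))
        seeds_per_value.append(row)
        for s in row:
            jobs.append((model_kind, float(v), grid_size, steps_per_neuron,
                         s, init_mean, n_points))

    results: Dict[int, np.ndarray] = {}
    failures: List[Dict] = []
    if n_jobs > 1:
        from concurrent.futures import ProcessPoolExecutor
        with ProcessPoolExecutor(max_workers=n_jobs) as ex:
            futs = {i: ex.submit(_run_one_sweep_point, *job)
                    for i, job in enumerate(jobs)}
            for i, fut in futs.items():
                try:
                    results[i] = fut.result()
                except Exception as err:  # pragma: no cover
                    failures.append({"job": jobs[i], "error": repr(err)})
    else:
        for i, job in enumerate(jobs):
            try:
                results[i] = _run_one_sweep_point(*job)
            except Exception as err:  # pragma: no cover
                failures.append({"job": job, "error": repr(err)})

    profiles: List[np.ndarray] = []
    peak_stats: List[Dict] = []
    for iv, v in enumerate(values):
        profs = [results[iv * n_seeds + js] for js in range(n_seeds)
                 if iv * n_seeds + js in results]
        if not profs:
            profiles.append(np.zeros(n_points))
            peak_stats.append({"value": float(v), "separation": np.nan,
                               "separations": [], "positions": []})
            continue
        med = np.median(np.asarray(profs), axis=0)
        if med.max() > 0:
            med = med / med.max()
        seps = []
        for p in profs:
            prof = DensityProfile(axis="azimuth", support=support, values=p,
                                  normalized=True, bandwidth=None)
            seps.append(peak_separation(prof))
        med_prof = DensityProfile(axis="azimuth", support=support, values=med,
                                  normalized=True, bandwidth=None)
        pos, _ = detect_peaks(med_prof)
        profiles.append(med)
        peak_stats.append({"value": float(v),
                           "separation": float(np.median(seps)),
                           "separations": [float(x) for x in seps],
                           "positions": [float(x) for x in pos]})
    return SweepResult(parameter_name=name, values=values, support=support,
                       profiles=profiles, peak_stats=peak_stats,
                       seeds=seeds_per_value, failures=failures)


def transition_stats(sweep: SweepResult, low_thr: float = 0.15,
                     high_thr: float = 0.35) -> Dict[str, float]:
    """Sharpness measures of the single-to-duplicated transition.

    ``width_decades``: log10 span between the largest value still
    essentially unimodal (separation <= ``low_thr``) and the smallest
    larger value clearly duplicated (separation >= ``high_thr``).
    ``max_jump``: largest single-step change in separation.
    """
    seps = sweep.separations
    vals = sweep.values
    jumps = np.abs(np.diff(seps))
    max_jump = float(jumps.max()) if len(jumps) else 0.0
    uni = [v for v, s in zip(vals, seps) if s <= low_thr]
    width = np.nan
    if uni:
        v_lo = max(uni)
        bi = [v for v, s in zip(vals, seps) if v > v_lo and s >= high_thr]
        if bi:
            width = float(np.log10(min(bi) / v_lo))
    return {"width_decades": width, "max_jump": max_jump}
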