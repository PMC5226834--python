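"""Omega-space geometry, connectivity state and genotype parameter presets.

The simulator places the primary visual cortex (V1) and the superior
colliculus (SC) in a shared two-dimensional coordinate system ("Omega
space"): the unit square in retinotopic coordinates.  The x component of a
coordinate is the azimuth (nasal-temporal retina, anterior-posterior SC)
and the y component is the elevation (dorsal-ventral retina,
lateral-medial SC).  Corticocollicular wiring is a nonnegative integer
field ``n(r_s, r_l)`` counting synaptic contacts between the V1 axon
arising at ``r_l`` and the SC dendrite at ``r_s``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "MODEL_KINDS",
    "GENOTYPES",
    "OmegaGrid",
    "ModelParams",
    "ConnectivityState",
    "WaveCorrelationFit",
    "build_grid",
    "genotype_params",
    "init_connectivity",
    "fit_wave_correlation",
    "scale_params",
]

MODEL_KINDS = ("correlational", "integrational")
GENOTYPES = ("WT", "Isl2EphA3", "Isl2EphA3_b2KO")

#: case-insensitive aliases accepted on the command line / in configs
_GENOTYPE_ALIASES = {
    "wt": "WT",
    "isl2": "Isl2EphA3",
    "isl2ephA3": "Isl2EphA3",
    "isl2epha3": "Isl2EphA3",
    "isl2-b2ko": "Isl2EphA3_b2KO",
    "isl2epha3_b2ko": "Isl2EphA3_b2KO",
    "isl2epha3-b2ko": "Isl2EphA3_b2KO",
    "b2ko": "Isl2EphA3_b2KO",
}


def canonical_genotype(name: str) -> str:
    """Resolve a genotype alias to its canonical name."""
    if name in GENOTYPES:
        return name
    key = name.lower()
    if key in _GENOTYPE_ALIASES:
        return _GENOTYPE_ALIASES[key]
    raise ValueError(f"unknown genotype {name!r}; expected one of {GENOTYPES}")


def canonical_model_kind(name: str) -> str:
    key = name.lower()
    if key in MODEL_KINDS:
        return key
    raise ValueError(f"unknown model kind {name!r}; expected one of {MODEL_KINDS}")


# ---------------------------------------------------------------------------
# Grid
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OmegaGrid:
    """Regular lattice of V1 and SC neuron positions in the unit square.

    Both layers use the same lattice: ``n_per_axis ** 2`` sites at cell
    centers ``((i + 0.5) / N, (j + 0.5) / N)``, which keeps every
    coordinate strictly inside ``[0, 1]`` and the spacing uniform.
    """

    n_per_axis: int
    v1_coords: np.ndarray = field(repr=False)  # (M, 2) float64
    sc_coords: np.ndarray = field(repr=False)  # (M, 2) float64

    @property
    def n_sites(self) -> int:
        return self.n_per_axis ** 2

    @property
    def spacing(self) -> float:
        return 1.0 / self.n_per_axis

    def site_index(self, coord: Sequence[float]) -> int:
        """Index of the lattice site nearest to ``coord``."""
        c = np.asarray(coord, dtype=float)
        d = np.linalg.norm(self.sc_coords - c[None, :], axis=1)
        return int(np.argmin(d))


def build_grid(n_per_axis: int) -> OmegaGrid:
    """Build the shared V1/SC lattice.

    Parameters
    ----------
    n_per_axis:
        Neurons per axis per layer; the published simulations use 100,
        desk-scale runs use 20-40.
    """
    if not isinstance(n_per_axis, (int, np.integer)) or n_per_axis < 2:
        raise ValueError(f"n_per_axis must be an integer >= 2, got {n_per_axis!r}")
    n = int(n_per_axis)
    axis = (np.arange(n) + 0.5) / n
    xx, yy = np.meshgrid(axis, axis, indexing="xy")
    coords = np.column_stack([xx.ravel(), yy.ravel()])
    coords.setflags(write=False)
    return OmegaGrid(n_per_axis=n, v1_coords=coords, sc_coords=coords)


# ---------------------------------------------------------------------------
# Model parameters (genotype presets)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelParams:
    """All scalar parameters of the energy functionals.

    ``alpha_a``/``beta_a`` weight the chemoaffinity countergradients,
    ``alpha_c``/``beta_c``/``gamma_c`` the axonal/dendritic competition,
    ``beta_u`` is the activity-correlation length (Omega units) and
    ``gamma_u`` the activity-energy scale.  ``alpha_u`` (amplitude ratio of
    the anterior vs posterior duplicated map) and ``kappa_u`` (azimuthal
    stretch of the correlation kernel) only apply to mutant genotypes;
    ``nu_u`` (synaptic-weight kernel width) and ``xi_u`` (retinal drive
    relative to V1 drive) only apply to the integrational model.
    """

    model_kind: str
    genotype: str
    alpha_a: float
    beta_a: float
    alpha_c: float
    beta_c: float
    gamma_c: float
    beta_u: float
    gamma_u: float
    alpha_u: Optional[float] = None
    kappa_u: Optional[float] = None
    nu_u: Optional[float] = None
    xi_u: Optional[float] = None
    #: "exponential" uses an elliptical-distance exponent for the duplicated
    #: activity kernel (reduces to the wild-type kernel when kappa_u == 1 and
    #: a single peak is present); "gaussian" squares the exponent instead and
    #: is kept for sensitivity checks.
    kernel_form: str = "exponential"

    def __post_init__(self) -> None:
        object.__setattr__(self, "model_kind", canonical_model_kind(self.model_kind))
        object.__setattr__(self, "genotype", canonical_genotype(self.genotype))
        for name in ("alpha_a", "beta_a", "alpha_c", "beta_c", "gamma_c",
                     "beta_u", "gamma_u"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"parameter {name} must be strictly positive, got {v}")
        if self.kernel_form not in ("exponential", "gaussian"):
            raise ValueError(f"unknown kernel_form {self.kernel_form!r}")
        if self.model_kind == "integrational":
            if self.nu_u is None or self.xi_u is None:
                raise ValueError("integrational model requires nu_u and xi_u")
            if self.nu_u <= 0 or self.xi_u <= 0:
                raise ValueError("nu_u and xi_u must be strictly positive")
        elif self.nu_u is not None or self.xi_u is not None:
            raise ValueError("nu_u / xi_u only apply to the integrational model")
        if self.genotype != "WT":
            if self.alpha_u is None or self.kappa_u is None:
                raise ValueError(f"genotype {self.genotype} requires alpha_u and kappa_u")
            if self.alpha_u <= 0 or self.kappa_u <= 0:
                raise ValueError("alpha_u and kappa_u must be strictly positive")
        elif self.alpha_u is not None or self.kappa_u is not None:
            raise ValueError("alpha_u / kappa_u only apply to mutant genotypes")

    @property
    def is_mutant(self) -> bool:
        return self.genotype != "WT"

    def replace(self, **changes) -> "ModelParams":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        d = {"model_kind": self.model_kind, "genotype": self.genotype}
        for f in dataclasses.fields(self):
            if f.name in d:
                continue
            v = getattr(self, f.name)
            if v is not None:
                d[f.name] = v
        return d


# Published parameter table.  The first block is shared between genotypes,
# the second is shared between models for mutants; WT has no asymmetry
# parameters.
_SHARED = dict(alpha_a=60.0, beta_a=90.0, alpha_c=450.0, beta_c=1.0, gamma_c=1.0)
_INTEGRATIONAL_ONLY = dict(nu_u=0.15, xi_u=3.0)
_GENOTYPE_BLOCKS = {
    "WT": dict(beta_u=0.11, gamma_u=20.0),
    "Isl2EphA3": dict(beta_u=0.11, gamma_u=20.0, alpha_u=0.625, kappa_u=1.0),
    "Isl2EphA3_b2KO": dict(beta_u=0.231, gamma_u=8.7, alpha_u=0.625, kappa_u=4.0),
}


def genotype_params(model_kind: str, genotype: str, **overrides) -> ModelParams:
    """Canonical parameter set for one (model, genotype) condition.

    Keyword overrides replace individual entries (used e.g. by the
    retinal-drive sweep, which rescales ``gamma_u`` or ``xi_u``).
    """
    model_kind = canonical_model_kind(model_kind)
    genotype = canonical_genotype(genotype)
    kwargs = dict(_SHARED)
    kwargs.update(_GENOTYPE_BLOCKS[genotype])
    if model_kind == "integrational":
        kwargs.update(_INTEGRATIONAL_ONLY)
    kwargs.update(overrides)
    return ModelParams(model_kind=model_kind, genotype=genotype, **kwargs)


# ---------------------------------------------------------------------------
# Connectivity state
# ---------------------------------------------------------------------------

class ConnectivityState:
    """The 4-D contact-count field with cached axonal/dendritic marginals.

    Counts are stored as a dense ``(n_sc_sites, n_v1_sites)`` int32 matrix
    (each 2-D layer index is a flattened lattice index).  ``n_A`` is the
    number of contacts made by each V1 axon, ``n_D`` the number received by
    each SC dendrite; both are maintained incrementally on every mutation.
    """

    __slots__ = ("grid", "counts", "n_A", "n_D", "rng_seed")

    def __init__(self, grid: OmegaGrid, counts: np.ndarray, rng_seed: int = 0):
        counts = np.ascontiguousarray(counts, dtype=np.int32)
        if counts.shape != (grid.n_sites, grid.n_sites):
            raise ValueError(
                f"counts shape {counts.shape} does not match grid with "
                f"{grid.n_sites} sites per layer")
        if (counts < 0).any():
            raise ValueError("counts must be nonnegative")
        self.grid = grid
        self.counts = counts
        self.n_A = counts.sum(axis=0, dtype=np.int64)
        self.n_D = counts.sum(axis=1, dtype=np.int64)
        self.rng_seed = int(rng_seed)

    # -- mutation -----------------------------------------------------------
    def add_contact(self, sc: int, v1: int) -> None:
        self.counts[sc, v1] += 1
        self.n_A[v1] += 1
        self.n_D[sc] += 1

    def remove_contact(self, sc: int, v1: int) -> None:
        if self.counts[sc, v1] < 1:
            raise ValueError(f"no contact to remove at (sc={sc}, v1={v1})")
        self.counts[sc, v1] -= 1
        self.n_A[v1] -= 1
        self.n_D[sc] -= 1

    # -- queries ------------------------------------------------------------
    @property
    def total_connections(self) -> int:
        return int(self.n_A.sum())

    def marginals_consistent(self) -> bool:
        """Audit the cached marginals against a full resummation."""
        return (np.array_equal(self.n_A, self.counts.sum(axis=0, dtype=np.int64))
                and np.array_equal(self.n_D, self.counts.sum(axis=1, dtype=np.int64)))

    def copy(self) -> "ConnectivityState":
        return ConnectivityState(self.grid, self.counts.copy(), self.rng_seed)

    def contact_list(self) -> Tuple[np.ndarray, np.ndarray]:
        """Expand counts into per-contact (sc, v1) index arrays."""
        sc_idx, v1_idx = np.nonzero(self.counts)
        reps = self.counts[sc_idx, v1_idx]
        return np.repeat(sc_idx, reps).astype(np.int64), np.repeat(v1_idx, reps).astype(np.int64)


def init_connectivity(grid: OmegaGrid, mode: str = "random",
                      mean_per_neuron: float = 50.0,
                      seed: int = 0) -> ConnectivityState:
    """Initial connectivity before annealing.

    ``random`` draws ``round(mean_per_neuron * n_sites)`` contacts, each at
    a uniformly random (SC site, V1 site) pair with replacement, so every
    neuron receives ``mean_per_neuron`` contacts on average (the published
    default is 50).  ``empty`` and ``full`` are the extreme initial
    conditions used to check initial-condition independence.
    """
    m = grid.n_sites
    if mode == "empty":
        return ConnectivityState(grid, np.zeros((m, m), np.int32), seed)
    if mode == "full":
        return ConnectivityState(grid, np.ones((m, m), np.int32), seed)
    if mode != "random":
        raise ValueError(f"unknown init mode {mode!r}")
    if mean_per_neuron < 0:
        raise ValueError("mean_per_neuron must be >= 0")
    rng = np.random.default_rng(seed)
    total = int(round(mean_per_neuron * m))
    counts = np.zeros((m, m), np.int32)
    # draw in blocks to bound memory on large grids
    block = 4_000_000
    for start in range(0, total, block):
        k = min(block, total - start)
        sc = rng.integers(0, m, size=k)
        v1 = rng.integers(0, m, size=k)
        np.add.at(counts, (sc, v1), 1)
    return ConnectivityState(grid, counts, seed)


# ---------------------------------------------------------------------------
# Retinal-wave correlation fit
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WaveCorrelationFit:
    """Exponential fit ``a + b * exp(-x / k)`` to a correlation-index curve.

    ``b`` is the amplitude of the distance-dependent part and ``k`` the
    decay length; between two genotypes their ratios rescale the activity
    energy scale ``gamma_u`` and correlation length ``beta_u``.
    ``k_identifiable`` is False when the data carry no distance dependence
    (b ~ 0), in which case ``k`` is meaningless.
    """

    a: float
    b: float
    k: float
    k_identifiable: bool = True


def _exp_decay(x, a, b, k):
    return a + b * np.exp(-x / k)


def fit_wave_correlation(points: Iterable[Tuple[float, float]]) -> WaveCorrelationFit:
    """Least-squares fit of ``a + b * exp(-x/k)`` to (distance, index) pairs."""
    pts = np.asarray(list(points), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 4:
        raise ValueError("need at least 4 (distance, correlation) points")
    x, y = pts[:, 0], pts[:, 1]
    if (x < 0).any():
        raise ValueError("distances must be nonnegative")
    spread = float(y.max() - y.min())
    if spread < 1e-12 * max(1.0, abs(float(y.mean()))):
        # zero-amplitude limit: constant data; k is unidentifiable
        return WaveCorrelationFit(a=float(y.mean()), b=0.0,
                                  k=float("nan"), k_identifiable=False)
    scale = float(x.max() - x.min()) or 1.0
    p0 = (float(y.min()), spread, scale / 3.0)
    try:
        popt, _ = curve_fit(_exp_decay, x, y, p0=p0,
                            bounds=([-np.inf, 0.0, 1e-12], [np.inf, np.inf, np.inf]),
                            maxfev=20000)
    except RuntimeError as err:  # pragma: no cover - diagnostics path
        raise RuntimeError(
            f"exponential fit failed to converge on {len(x)} points "
            f"(x range {x.min():g}-{x.max():g}, y range {y.min():g}-{y.max():g}): {err}"
        ) from err
    a, b, k = (float(v) for v in popt)
    return WaveCorrelationFit(a=a, b=b, k=k)


def scale_params(fit_ref: WaveCorrelationFit, fit_alt: WaveCorrelationFit,
                 params: ModelParams) -> ModelParams:
    """Rescale ``gamma_u`` and ``beta_u`` from a reference to an altered
    wave-correlation fit.

    The activity scale follows the amplitude (``gamma_u *= b_alt / b_ref``)
    and the correlation length follows the decay length
    (``beta_u *= k_alt / k_ref``), i.e. both are divided by the
    reference/altered ratio.  Applied to wild-type parameters with the
    wild-type and beta2-knockout wave fits this reproduces the knockout
    preset (gamma_u 20 -> 8.7, beta_u 0.11 -> 0.231).
    """
    if fit_ref.b <= 0 or fit_alt.b <= 0:
        raise ValueError("both fits need positive amplitude b")
    if not (fit_ref.k_identifiable and fit_alt.k_identifiable):
        raise ValueError("decay length unidentifiable in one of the fits")
    return params.replace(gamma_u=params.gamma_u * fit_alt.b / fit_ref.b,
                          beta_u=params.beta_u * fit_alt.k / fit_ref.k)
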