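"""Gradient-correlation similarity, the multi-view registration cost, and
the seeded genetic-algorithm search.

The similarity between a DRR and a fluoroscopy frame is the sum of the
normalized cross-correlations of their horizontal and vertical Sobel
gradient images (range [-2, 2]; 2 = identical up to a positive affine
intensity map). Registration minimizes the summed negative similarity over
N views sharing one 6-DOF pose.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import convolve

from .drr import RadiographImage, VoxelVolume, generate_drr, silhouette_region
from .geometry import Pose6DOF, ProjectionModel, RigidTransform, pose_to_transform

__all__ = ["SimilarityResult", "SearchSettings", "gradient_correlation",
           "multiview_cost", "ga_optimize", "biplane_register"]

_SOBEL_I = np.array([[-1.0, 0.0, 1.0], [-2.0, 0.0, 2.0], [-1.0, 0.0, 1.0]])  # d/du
_SOBEL_J = _SOBEL_I.T  # d/dv


@dataclass(frozen=True)
class SimilarityResult:
    f_gc: float
    horizontal_term: float
    vertical_term: float
    region: tuple[int, int, int, int]


@dataclass
class SearchSettings:
    """Genetic-algorithm search configuration (all runs are seeded)."""

    population: int = 60
    generations: int = 40
    tournament: int = 3
    crossover_rate: float = 0.9
    blend_alpha: float = 0.5
    mutation_rate: float = 0.1
    mutation_sigma_frac: float = 0.05  # of per-gene bound width
    elitism: int = 2
    seed: int = 0
    pose_bounds: np.ndarray = field(
        default_factory=lambda: np.array([3.0, 3.0, 3.0, 3.0, 3.0, 3.0])
    )  # +/- half-widths (mm, mm, mm, deg, deg, deg) around the initial pose
    coefficient_sd_bound: float = 3.0  # +/- SD units for shape coefficients
    absolute_bounds: tuple | None = None  # optional (lo, hi) in pose space
    drr_step: float | None = None  # ray-sampling step override (mm)
    region_dilate: int = 10  # px dilation of the silhouette similarity window
    polish: bool = False  # optional Nelder-Mead refinement after the GA


def _sobel_pair(img: np.ndarray):
    di = convolve(img.astype(float), _SOBEL_I, mode="nearest")
    dj = convolve(img.astype(float), _SOBEL_J, mode="nearest")
    return di, dj


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    na2 = np.sum(a * a)
    nb2 = np.sum(b * b)
    if na2 == 0.0 or nb2 == 0.0:
        raise ValueError("zero gradient variance in similarity region")
    # single sqrt of the product so identical operands score exactly 1
    return float(np.sum(a * b) / np.sqrt(na2 * nb2))


def gradient_correlation(
    drr: RadiographImage | np.ndarray,
    fluoro: RadiographImage | np.ndarray,
    region: tuple[int, int, int, int] | None = None,
) -> SimilarityResult:
    """Gradient correlation between two images over a pixel window.

    ``region = (u0, u1, v0, v1)`` (half-open); border pixels of the window are
    excluded from the sums so that both Sobel responses are fully supported.
    """
    A = drr.pixels if isinstance(drr, RadiographImage) else np.asarray(drr)
    B = fluoro.pixels if isinstance(fluoro, RadiographImage) else np.asarray(fluoro)
    if A.shape != B.shape:
        raise ValueError("images must share dimensions")
    nv, nu = A.shape
    u0, u1, v0, v1 = region if region is not None else (0, nu, 0, nv)
    if u1 - u0 < 3 or v1 - v0 < 3:
        raise ValueError("similarity region too small")
    wa = A[v0:v1, u0:u1]
    wb = B[v0:v1, u0:u1]
    dai, daj = _sobel_pair(wa)
    dbi, dbj = _sobel_pair(wb)
    sl = (slice(1, -1), slice(1, -1))  # exclude window border
    h = _ncc(dbi[sl], dai[sl])
    v = _ncc(dbj[sl], daj[sl])
    return SimilarityResult(h + v, h, v, (u0, u1, v0, v1))


def multiview_cost(
    volume: VoxelVolume,
    pose: Pose6DOF,
    views: list[tuple[RadiographImage, ProjectionModel, RigidTransform]],
    step: float | None = None,
    dilate: int = 10,
) -> float:
    """Summed negative gradient correlation over the views at one shared pose.

    Each view's ``RigidTransform`` maps the common frame into that view's
    acquisition frame. Lower is better; the floor is -2N.
    """
    if not views:
        raise ValueError("need at least one view")
    T_pose = pose_to_transform(pose)
    cost = 0.0
    for img, model, T_view in views:
        T = T_view @ T_pose
        region = silhouette_region(volume, T, model, dilate=dilate)
        drr = generate_drr(volume, T, model, step=step, region=region)
        cost -= gradient_correlation(drr, img, region=region).f_gc
    return cost


# ---------------------------------------------------------------------- GA

def ga_optimize(cost_fn, bounds, settings: SearchSettings, initial=None):
    """Bounded real-coded genetic algorithm (seeded, elitist).

    Tournament selection, blend (BLX-alpha) crossover, per-gene Gaussian
    mutation clipped to bounds. ``initial`` rows are injected into the first
    population. Returns ``(best_x, best_cost, history)`` where ``history``
    is the per-generation best cost; deterministic given the seed.
    """
    lo, hi = (np.asarray(b, float).ravel() for b in bounds)
    if not (np.all(np.isfinite(lo)) and np.all(np.isfinite(hi))):
        raise ValueError("bounds must be finite")
    dim = len(lo)
    width = hi - lo
    rng = np.random.default_rng(settings.seed)
    pop = lo + rng.random((settings.population, dim)) * width
    if initial is not None:
        init = np.atleast_2d(np.asarray(initial, float))
        pop[: len(init)] = np.clip(init, lo, hi)
    costs = np.array([cost_fn(x) for x in pop])

    best_i = int(np.argmin(costs))
    best_x, best_c = pop[best_i].copy(), float(costs[best_i])
    history = [best_c]

    sigma = settings.mutation_sigma_frac * width
    for _ in range(settings.generations):
        order = np.argsort(costs, kind="stable")
        elite = pop[order[: settings.elitism]]
        elite_costs = costs[order[: settings.elitism]]
        n_child = settings.population - settings.elitism
        # tournament selection
        cand = rng.integers(0, settings.population, size=(2 * n_child, settings.tournament))
        winners = cand[np.arange(2 * n_child), np.argmin(costs[cand], axis=1)]
        pa, pb = pop[winners[:n_child]], pop[winners[n_child:]]
        # BLX-alpha blend crossover
        do_x = rng.random(n_child) < settings.crossover_rate
        d = np.abs(pa - pb)
        low = np.minimum(pa, pb) - settings.blend_alpha * d
        high = np.maximum(pa, pb) + settings.blend_alpha * d
        children = low + rng.random((n_child, dim)) * (high - low)
        children = np.where(do_x[:, None], children, pa)
        # Gaussian mutation
        mut = rng.random((n_child, dim)) < settings.mutation_rate
        children = children + mut * rng.normal(0.0, 1.0, (n_child, dim)) * sigma
        children = np.clip(children, lo, hi)
        child_costs = np.array([cost_fn(x) for x in children])
        pop = np.vstack([elite, children])
        costs = np.concatenate([elite_costs, child_costs])
        gen_best = int(np.argmin(costs))
        if costs[gen_best] < best_c:
            best_c = float(costs[gen_best])
            best_x = pop[gen_best].copy()
        history.append(best_c)
    return best_x, best_c, history


def biplane_register(
    volume: VoxelVolume,
    init: Pose6DOF,
    pair: list[tuple[RadiographImage, ProjectionModel]],
    settings: SearchSettings,
    view_transforms: list[RigidTransform] | None = None,
) -> tuple[Pose6DOF, float]:
    """Register a posed volume to a (pseudo-)synchronous image pair.

    Searches the 6-DOF pose within ``settings.pose_bounds`` of ``init`` by
    the genetic algorithm (the initial pose is injected into the first
    population, so the result is never worse than the initial cost).
    """
    x0 = init.to_vector()
    if settings.absolute_bounds is not None:
        alo, ahi = (np.asarray(b, float) for b in settings.absolute_bounds)
        if np.any(x0 < alo) or np.any(x0 > ahi):
            raise ValueError("initial pose outside the absolute search bounds")
    half = np.asarray(settings.pose_bounds, float)
    lo, hi = x0 - half, x0 + half
    if view_transforms is None:
        view_transforms = [RigidTransform.identity()] * len(pair)
    views = [(img, model, T) for (img, model), T in zip(pair, view_transforms)]

    def cost(x):
        return multiview_cost(volume, Pose6DOF.from_vector(x), views,
                              step=settings.drr_step, dilate=settings.region_dilate)

    best_x, best_c, _ = ga_optimize(cost, (lo, hi), settings, initial=x0[None])
    if settings.polish:
        from scipy.optimize import minimize

        res = minimize(cost, best_x, method="Nelder-Mead",
                       options={"xatol": 1e-3, "fatol": 1e-6, "maxiter": 80})
        if res.fun < best_c:
            best_x, best_c = np.clip(res.x, lo, hi), float(res.fun)
    return Pose6DOF.from_vector(best_x), best_c
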