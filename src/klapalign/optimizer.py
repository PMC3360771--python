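"""Derivative-free search over rigid transforms minimizing F(T) at fixed k.

F(T) — the optimal cardinality-k assignment RMSD — is piecewise-smooth,
non-differentiable where the optimal assignment switches, and highly
multi-modal in the rotation angles, so the master problem is solved
derivative-free. The default engine runs four deterministic phases within
a fixed evaluation budget:

1. a seeded low-discrepancy space-filling design (Sobol), always starting
   from the zero-angle / centroid-coincidence point followed by the four
   principal-axes superposition hypotheses (rotations mapping the inertia
   axes of A onto those of B, one per proper sign combination — the
   classic registration initialization, and the antidote to the 180-degree
   flip decoys that preserve the inertia ellipsoid); with the default full
   angle box the Sobol samples are mapped to Haar-uniform rotations so the
   design covers SO(3) evenly rather than the Euler box;
2. zoom sampling: local rotation (and translation) perturbations around
   the best design points, exploiting the broad funnel around good
   superpositions;
3. Nelder-Mead polishing of the incumbent (derivative-free, fast on the
   smooth region where the assignment has locked in);
4. global continuation: further Sobol samples in chunks, re-zooming and
   re-polishing whenever the incumbent improves, until the budget is the
   normal exit.

All randomness is seeded, and the evaluation sequence at budget b is a
prefix of the sequence at any larger budget, so the returned best-so-far F
is non-increasing in the budget.

Two modes:

* ``3dof`` — both structures are pre-centered at the origin and only the
  three rotation angles are searched (centroid coincidence); the right
  choice for proteins of similar size.
* ``6dof`` — angles plus translation; the translation box is the centroid
  difference vector padded by half the larger bounding-box diagonal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize as _nelder_mead
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation
from scipy.stats import qmc

from .assignment import SubproblemResult, evaluate_F, solve_klap
from .geometry import RigidTransform, centroid, rotation_matrix

__all__ = ["SearchConfig", "centroid_coincidence_translation", "minimize_F", "write_trace_tsv"]

_FULL_CIRCLE = (-np.pi, np.pi)
_INIT_CAP = 96  # space-filling design size (capped so bigger budgets refine, not resample)
_ZOOM_TOP = 6  # design points seeding the first zoom phase
_ZOOM_LOCAL = 12  # local samples per zoomed point
_ZOOM_RADIUS = np.radians(25.0)  # rotation perturbation radius
_CHUNK = 32  # global continuation chunk


@dataclass(frozen=True)
class SearchConfig:
    """Master-search settings.

    ``budget`` is the maximum number of F evaluations per k; a few hundred
    suffices for the 3-angle search, while the 6 degree-of-freedom mode
    wants about 1000. ``angle_bounds`` restricts each angle (radians);
    with the default full circle the design is Haar-uniform over rotations.
    ``translation_pad`` (A) overrides the automatic 6dof translation
    half-box.
    """

    mode: str = "3dof"
    budget: int = 100
    seed: int = 0
    angle_bounds: tuple = _FULL_CIRCLE
    translation_pad: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("3dof", "6dof"):
            raise ValueError("mode must be '3dof' or '6dof'")
        if self.budget < 1:
            raise ValueError("budget must be >= 1")
        lo, hi = self.angle_bounds
        if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
            raise ValueError("angle bounds must be finite and ordered")


def centroid_coincidence_translation(structure_a, structure_b, theta=None) -> np.ndarray:
    """Translation landing rotated A's centroid on B's centroid.

    ``centroid(B) - R(theta) @ centroid(A)``; identity rotation if theta
    is omitted.
    """
    ca = centroid(getattr(structure_a, "coords", structure_a))
    cb = centroid(getattr(structure_b, "coords", structure_b))
    R = np.eye(3) if theta is None else rotation_matrix(theta)
    return cb - R @ ca


class _BudgetExhausted(Exception):
    pass


def _principal_axis_candidates(centered_a: np.ndarray, centered_b: np.ndarray) -> list:
    """Rotations superposing the inertia axes of A onto those of B.

    Four proper rotations, one per sign combination of the axes; with
    near-distinct eigenvalues one of them lies close to any rigid motion
    relating the two clouds, so they make powerful structured seeds for
    the search design. Returned as extrinsic-XYZ angle triples.
    """
    axes_a = np.linalg.eigh(np.cov(centered_a.T))[1][:, ::-1]
    axes_b = np.linalg.eigh(np.cov(centered_b.T))[1][:, ::-1]
    if np.linalg.det(axes_a) < 0:
        axes_a[:, 2] *= -1.0
    if np.linalg.det(axes_b) < 0:
        axes_b[:, 2] *= -1.0
    candidates = []
    for signs in ((1, 1, 1), (1, -1, -1), (-1, 1, -1), (-1, -1, 1)):
        R = axes_b @ np.diag(signs) @ axes_a.T
        candidates.append(Rotation.from_matrix(R).as_euler("xyz"))
    return candidates


def _shoemake(u: np.ndarray) -> Rotation:
    """Map unit-cube triples to Haar-uniform rotations (Shoemake quaternions)."""
    q = np.column_stack(
        [
            np.sqrt(1.0 - u[:, 0]) * np.sin(2 * np.pi * u[:, 1]),
            np.sqrt(1.0 - u[:, 0]) * np.cos(2 * np.pi * u[:, 1]),
            np.sqrt(u[:, 0]) * np.sin(2 * np.pi * u[:, 2]),
            np.sqrt(u[:, 0]) * np.cos(2 * np.pi * u[:, 2]),
        ]
    )
    return Rotation.from_quat(q)


class _Search:
    """One minimize_F run: owns the budget, the trace and the incumbent."""

    def __init__(self, objective, dim, config: SearchConfig, t_center, t_pad, seed_angles=()):
        self.objective = objective
        self.dim = dim  # 3 or 6 (angles [+ translation])
        self.config = config
        self.seed_angles = list(seed_angles)  # structured design points (angle triples)
        self.t_center = t_center  # 6dof translation box center (None in 3dof)
        self.t_pad = t_pad
        self.lo_a, self.hi_a = config.angle_bounds
        self.haar = np.allclose(config.angle_bounds, _FULL_CIRCLE)
        self.sobol = qmc.Sobol(dim, scramble=True, seed=config.seed)
        self.rng = np.random.default_rng([config.seed, 0x5EED])
        self.trace: list = []
        self.best_x = None
        self.best_f = np.inf

    # -- evaluation bookkeeping ------------------------------------------
    def _normalize(self, x):
        x = np.array(x, dtype=float)
        x[:3] = np.clip(
            (x[:3] - self.lo_a) % (self.hi_a - self.lo_a) + self.lo_a, self.lo_a, self.hi_a
        )
        if self.dim == 6:
            x[3:] = np.clip(x[3:], self.t_center - self.t_pad, self.t_center + self.t_pad)
        return x

    def evaluate(self, x) -> float:
        if len(self.trace) >= self.config.budget:
            raise _BudgetExhausted
        x = self._normalize(x)
        f = self.objective(x)
        self.trace.append((x, f))
        if f < self.best_f:
            self.best_f, self.best_x = f, x
        return f

    # -- candidate streams ------------------------------------------------
    def _stream(self, n) -> np.ndarray:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # benign balance warning, n not a power of two
            u = self.sobol.random(n)
        if self.haar:
            angles = _shoemake(u[:, :3]).as_euler("xyz")
        else:
            angles = self.lo_a + u[:, :3] * (self.hi_a - self.lo_a)
        if self.dim == 3:
            return angles
        t = self.t_center - self.t_pad + u[:, 3:] * (2.0 * self.t_pad)
        return np.hstack([angles, t])

    def _zoom(self, x0) -> None:
        """Local samples around x0: rotation ball plus translation box."""
        R0 = Rotation.from_euler("xyz", x0[:3])
        axes = self.rng.normal(size=(_ZOOM_LOCAL, 3))
        axes /= np.linalg.norm(axes, axis=1)[:, None]
        mags = _ZOOM_RADIUS * self.rng.random(_ZOOM_LOCAL) ** (1.0 / 3.0)
        shifts = (
            self.rng.uniform(-0.15, 0.15, size=(_ZOOM_LOCAL, 3)) * self.t_pad
            if self.dim == 6
            else np.zeros((_ZOOM_LOCAL, 0))
        )
        for axis, mag, shift in zip(axes, mags, shifts):
            angles = (Rotation.from_rotvec(axis * mag) * R0).as_euler("xyz")
            cand = angles if self.dim == 3 else np.concatenate([angles, x0[3:] + shift])
            self.evaluate(cand)

    def _polish(self) -> None:
        """Nelder-Mead from the incumbent until it stops improving."""
        while True:
            x0, f0 = self.best_x.copy(), self.best_f
            remaining = self.config.budget - len(self.trace)
            if remaining <= 5:
                return
            _nelder_mead(
                self.evaluate,
                x0,
                method="Nelder-Mead",
                options={"maxfev": remaining, "xatol": 1e-9, "fatol": 1e-13},
            )
            if self.best_f >= f0 - 1e-12:
                return

    def run(self, first_point) -> None:
        try:
            self.evaluate(first_point)  # zero-angle / centroid-coincidence candidate
            for angles in self.seed_angles:  # principal-axes hypotheses
                if self.dim == 3:
                    self.evaluate(angles)
                else:
                    self.evaluate(np.concatenate([angles, first_point[3:]]))
            n_init = min(self.config.budget, _INIT_CAP)
            design = self._stream(max(n_init - 1, 1))
            values = [self.evaluate(x) for x in design]
            for idx in np.argsort(values, kind="stable")[:_ZOOM_TOP]:
                self._zoom(self._normalize(design[idx]))
            self._polish()
            while True:  # global continuation until the budget is the exit
                chunk = self._stream(_CHUNK)
                values = [self.evaluate(x) for x in chunk]
                before = self.best_f
                self._zoom(self._normalize(chunk[int(np.argmin(values))]))
                if self.best_f < before - 1e-12:
                    self._polish()
        except _BudgetExhausted:
            pass


def minimize_F(structure_a, structure_b, k, config: SearchConfig):
    """Search for the transform minimizing F at cardinality k.

    Returns ``(transform, result, trace)``: the best rigid motion found
    (expressed in the original coordinate frames), its SubproblemResult
    re-evaluated through evaluate_F, and the list of ``(parameters, F)``
    evaluations in order. Deterministic for fixed inputs and seed; budget
    exhaustion is the normal exit.
    """
    coords_a = np.asarray(getattr(structure_a, "coords", structure_a), float)
    coords_b = np.asarray(getattr(structure_b, "coords", structure_b), float)

    if config.mode == "3dof":
        # pre-center once; searching angles with t = 0 is then equivalent to
        # recomputing the centroid-coincidence translation per rotation
        ac = coords_a - centroid(coords_a)
        bc = coords_b - centroid(coords_b)

        def objective(x):
            moved = ac @ rotation_matrix(x).T
            return solve_klap(cdist(moved, bc, "sqeuclidean"), k).rmsd

        search = _Search(objective, 3, config, None, None, _principal_axis_candidates(ac, bc))
        search.run(np.zeros(3))
        theta = search.best_x
        transform = RigidTransform(centroid_coincidence_translation(coords_a, coords_b, theta), theta)
    else:
        t0 = centroid(coords_b) - centroid(coords_a)
        if config.translation_pad is not None:
            pad = float(config.translation_pad)
        else:
            diag = max(
                float(np.linalg.norm(np.ptp(coords_a, axis=0))),
                float(np.linalg.norm(np.ptp(coords_b, axis=0))),
            )
            pad = max(diag / 2.0, 1.0)

        def objective(x):
            moved = coords_a @ rotation_matrix(x[:3]).T + x[3:]
            return solve_klap(cdist(moved, coords_b, "sqeuclidean"), k).rmsd

        seeds = _principal_axis_candidates(
            coords_a - centroid(coords_a), coords_b - centroid(coords_b)
        )
        search = _Search(objective, 6, config, t0, pad, seeds)
        search.run(np.concatenate([np.zeros(3), t0]))
        transform = RigidTransform(search.best_x[3:], search.best_x[:3])

    result = evaluate_F(transform, coords_a, coords_b, k)
    return transform, result, search.trace


def write_trace_tsv(path, trace) -> None:
    """Dump an evaluation trace as TSV: eval index, parameters, F."""
    with open(path, "w") as fh:
        for n, (x, f) in enumerate(trace, start=1):
            params = "\t".join(f"{v:.9g}" for v in x)
            fh.write(f"{n}\t{params}\t{f:.6f}\n")
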