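"""Hard-and-soft MCR-ALS: constrained alternating least squares with an
embedded kinetic refit.

The bilinear model is D = C S, with D the N x J data matrix (spectra by
wavenumber channels), C the N x I concentration profiles and S the I x J
pure component spectra.  Each iteration alternates exact constrained
least-squares solves for S (per channel) and C (per time point), then — when
a kinetic link is configured — refits the rate constants of the ODE system
to the soft concentration profiles by bounded nonlinear least squares and
replaces ("hardens") the linked columns of C with the ODE solution.

Non-negativity is enforced per component by active-set non-negative least
squares (Lawson-Hanson via scipy), not by clipping: clipping is not a
minimizer and would break the monotone-lack-of-fit property of the soft
algorithm.  Mixed free/non-negative problems are solved exactly by
projecting out the free block and running NNLS on the projected problem.

Convergence follows the classic rule: stop when the sum of squared residuals
changes by less than ``rel_tol`` (default 1%) for ``patience`` (default 20)
consecutive iterations, or at ``max_iter`` (default 200).

Note on the hard step: substituting the ODE solution into C can *raise* the
lack of fit relative to the purely soft solution — that is the price of the
hard model, paid for by interpretability and access to the rate constants.
Monotonicity of the lack-of-fit history is therefore only guaranteed with
the kinetic link disabled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares, nnls

from ._exceptions import (
    IdentifiabilityWarning,
    IllConditionedError,
    KineticFitWarning,
    RankCollapseWarning,
)
from .kinetics import KineticModel, KineticParams, solve_kinetics
from .preprocessing import SpectraDataset, initial_concentrations

__all__ = [
    "KineticLink",
    "ConstraintConfig",
    "MCRResult",
    "nnls_rows",
    "nnls_cols",
    "fit_kinetic_constants",
    "apply_kinetic_constraint",
    "lack_of_fit",
    "LackOfFit",
    "check_convergence",
    "run_mcr_als",
]

_COND_LIMIT = 1e12


@dataclass(frozen=True)
class KineticLink:
    """Links model states to resolved components and carries the starting k.

    ``component_indices`` (default: the model's own component map) gives the
    column of C constrained by each ODE state, in state order.  By
    convention the constrained components occupy the lowest indices so that
    reporting is unambiguous.
    """

    model: KineticModel
    k0: "KineticParams | Mapping[str, float]"
    component_indices: tuple[int, ...] = ()

    def __post_init__(self):
        idx = self.component_indices or self.model.component_map
        object.__setattr__(self, "component_indices", tuple(int(i) for i in idx))
        if len(self.component_indices) != self.model.n_states:
            raise ValueError("need one component index per model state")
        if len(set(self.component_indices)) != len(self.component_indices):
            raise ValueError("component indices must be distinct")

    def k0_dict(self) -> dict[str, float]:
        k = self.k0
        d = k.as_dict() if isinstance(k, KineticParams) else dict(k)
        return {name: float(d[name]) for name in self.model.param_names}


def _as_flags(flags, n: int) -> np.ndarray:
    if isinstance(flags, (bool, np.bool_)):
        return np.full(n, bool(flags))
    arr = np.asarray(flags, dtype=bool)
    if arr.shape != (n,):
        raise ValueError(f"expected {n} per-component flags, got shape {arr.shape}")
    return arr


@dataclass(frozen=True)
class ConstraintConfig:
    """Component count, per-component constraints, and stopping rule.

    ``nonneg_conc`` / ``nonneg_spec`` may be a single bool or one flag per
    component.  ``kinetic`` attaches the hard ODE constraint.  ``C0``
    optionally overrides the initial concentration estimate; without it the
    kinetic link provides the start (ODE at k0, unconstrained columns
    constant 1) and a purely soft run starts from the truncated SVD.
    """

    n_components: int
    nonneg_conc: bool | Sequence[bool] = True
    nonneg_spec: bool | Sequence[bool] = True
    kinetic: KineticLink | None = None
    max_iter: int = 200
    patience: int = 20
    rel_tol: float = 0.01
    C0: np.ndarray | None = None

    def __post_init__(self):
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if self.rel_tol <= 0:
            raise ValueError("rel_tol must be > 0")
        if self.max_iter < 1 or self.patience < 1:
            raise ValueError("max_iter and patience must be >= 1")
        object.__setattr__(self, "conc_flags", _as_flags(self.nonneg_conc, self.n_components))
        object.__setattr__(self, "spec_flags", _as_flags(self.nonneg_spec, self.n_components))
        if self.kinetic is not None:
            if any(i >= self.n_components for i in self.kinetic.component_indices):
                raise ValueError("kinetic component index out of range")


@dataclass
class LackOfFit:
    """Sum of squared residuals plus the conventional %LOF for logging."""

    ssr: float
    percent: float


@dataclass
class MCRResult:
    """Resolved factors, fitted constants, and the full iteration history."""

    C: np.ndarray
    S: np.ndarray
    k_final: dict[str, float] | None
    k_history: np.ndarray  # n_iter x n_params (empty if no kinetic link)
    k_param_names: tuple[str, ...]
    lof_history: np.ndarray  # SSR per iteration
    pct_lof_history: np.ndarray
    n_iter: int
    converged: bool
    stop_reason: str  # "patience" | "max_iter"


def _solve_bounded(A: np.ndarray, B: np.ndarray, nonneg: np.ndarray) -> np.ndarray:
    """Solve min ||A X - B||_F columnwise with X[i,:] >= 0 where flagged.

    Exact per-column minimizers: unconstrained columns by one shared lstsq;
    fully/partially constrained columns by Lawson-Hanson NNLS, with the free
    block projected out first (the free coefficients are then recovered by a
    final least-squares solve).  Columns whose unconstrained solution already
    satisfies the bounds are accepted as-is (it is the global minimum).
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    n, k = A.shape
    if np.linalg.matrix_rank(A) < k:
        cond = np.linalg.cond(A)
        raise IllConditionedError(
            f"design matrix is rank deficient (condition number {cond:.3g})"
        )
    X = np.linalg.lstsq(A, B, rcond=None)[0]
    if not np.any(nonneg):
        return X
    violated = np.any(X[nonneg, :] < 0, axis=0)
    if not np.any(violated):
        return X
    free = ~nonneg
    if np.any(free):
        # project B and the constrained block onto the complement of span(A_free)
        Qf, _ = np.linalg.qr(A[:, free])
        Ac = A[:, nonneg]
        Pc = Ac - Qf @ (Qf.T @ Ac)
        for j in np.where(violated)[0]:
            b = B[:, j]
            xc, _ = nnls(Pc, b - Qf @ (Qf.T @ b))
            xf = np.linalg.lstsq(A[:, free], b - Ac @ xc, rcond=None)[0]
            X[nonneg, j] = xc
            X[free, j] = xf
    else:
        for j in np.where(violated)[0]:
            X[:, j], _ = nnls(A, B[:, j])
    return X


def nnls_rows(D: np.ndarray, C: np.ndarray, nonneg_flags) -> np.ndarray:
    """Spectral step: solve D = C S for S (I x J) under per-component flags.

    Each wavenumber channel j solves min ||D[:,j] - C s||^2 with s_i >= 0 for
    flagged components; unflagged components are unconstrained (a resolved
    binding spectrum may legitimately carry negative nucleic-acid bands).
    """
    D = np.asarray(D, dtype=float)
    C = np.asarray(C, dtype=float)
    flags = _as_flags(nonneg_flags, C.shape[1])
    return _solve_bounded(C, D, flags)


def nnls_cols(D: np.ndarray, S: np.ndarray, nonneg_flags) -> np.ndarray:
    """Concentration step: solve D = C S for C (N x I), mirroring nnls_rows."""
    D = np.asarray(D, dtype=float)
    S = np.asarray(S, dtype=float)
    flags = _as_flags(nonneg_flags, S.shape[0])
    return _solve_bounded(S.T, D.T, flags).T


def fit_kinetic_constants(
    C_soft: np.ndarray,
    model: KineticModel,
    k_prev: "KineticParams | Mapping[str, float]",
    times: Sequence[float],
    component_indices: Sequence[int] | None = None,
    max_nfev: int | None = None,
) -> tuple[dict[str, float], np.ndarray]:
    """Refit the kinetic constants to the soft concentration profiles.

    Minimizes the squared mismatch between the linked columns of ``C_soft``
    and the ODE state trajectories over the free (non-fixed) parameters,
    warm-started at ``k_prev`` with bounds k >= 0 (trust-region reflective).
    Returns the updated full parameter dict and the ODE solution evaluated at
    it (time points by model states).  A failed optimizer step degrades to a
    warning and the best iterate — it must not abort the surrounding ALS
    loop.
    """
    t = np.asarray(times, dtype=float)
    idx = tuple(component_indices) if component_indices is not None else model.component_map
    target = np.asarray(C_soft, dtype=float)[:, list(idx)]
    k_full = (
        k_prev.as_dict() if isinstance(k_prev, KineticParams) else dict(k_prev)
    )
    free = model.free_param_names
    x0 = np.array([max(k_full[p], 0.0) for p in free])

    def residuals(x: np.ndarray) -> np.ndarray:
        trial = dict(k_full)
        trial.update(zip(free, x))
        prof = solve_kinetics(model, trial, t)
        return (prof.values - target).ravel()

    try:
        fit = least_squares(
            residuals,
            x0,
            bounds=(0.0, np.inf),
            method="trf",
            max_nfev=max_nfev,
        )
        if not fit.success:
            warnings.warn(
                f"kinetic refit did not converge ({fit.message}); keeping best iterate",
                KineticFitWarning,
                stacklevel=2,
            )
        x_best = fit.x
    except Exception as e:  # noqa: BLE001 - the ALS loop must survive
        warnings.warn(
            f"kinetic refit failed ({e}); keeping previous constants",
            KineticFitWarning,
            stacklevel=2,
        )
        x_best = x0
    k_new = dict(k_full)
    k_new.update(zip(free, (float(v) for v in x_best)))
    c_model = solve_kinetics(model, k_new, t).values
    return k_new, c_model


def apply_kinetic_constraint(
    C_soft: np.ndarray,
    C_model: np.ndarray,
    component_indices: Sequence[int],
) -> np.ndarray:
    """Replace the linked columns of C with the ODE solution (hard step).

    Unlinked columns pass through unchanged.
    """
    C_hard = np.array(C_soft, dtype=float, copy=True)
    for state, comp in enumerate(component_indices):
        C_hard[:, comp] = C_model[:, state]
    return C_hard


def lack_of_fit(D: np.ndarray, C: np.ndarray, S: np.ndarray) -> LackOfFit:
    """Sum of squared residuals of D - C S, with %LOF = 100 sqrt(SSR / sum D^2)."""
    D = np.asarray(D, dtype=float)
    resid = D - np.asarray(C, float) @ np.asarray(S, float)
    ssr = float(np.sum(resid**2))
    total = float(np.sum(D**2))
    pct = 100.0 * np.sqrt(ssr / total) if total > 0 else 0.0
    return LackOfFit(ssr, pct)


def check_convergence(
    lof_history: Sequence[float],
    rel_tol: float = 0.01,
    patience: int = 20,
    max_iter: int = 200,
) -> str:
    """Stopping decision from the lack-of-fit (SSR) history.

    Returns ``"stop_max_iter"`` once ``max_iter`` iterations are recorded,
    ``"stop_patience"`` once the relative change |SSR_t - SSR_{t-1}| /
    SSR_{t-1} has stayed below ``rel_tol`` for ``patience`` consecutive
    iteration pairs (a zero previous SSR counts as converged — perfect fit),
    and ``"continue"`` otherwise.
    """
    h = np.asarray(lof_history, dtype=float)
    if h.size == 0:
        raise ValueError("lof_history must be non-empty")
    if h.size >= max_iter:
        return "stop_max_iter"
    run = 0
    for i in range(h.size - 1, 0, -1):
        prev, cur = h[i - 1], h[i]
        if prev == 0.0:
            run += 1
        elif abs(cur - prev) / prev < rel_tol:
            run += 1
        else:
            break
        if run >= patience:
            return "stop_patience"
    return "continue"


def _svd_start(D: np.ndarray, n_components: int) -> np.ndarray:
    """Non-negative SVD-based initial concentration estimate for soft runs."""
    u, s, _ = np.linalg.svd(D, full_matrices=False)
    c0 = np.abs(u[:, :n_components] * s[:n_components])
    # guard against an exactly-zero column on degenerate input
    for j in range(c0.shape[1]):
        if not np.any(c0[:, j] > 0):
            c0[:, j] = 1.0
    return c0


def run_mcr_als(
    ds: SpectraDataset,
    config: ConstraintConfig,
    normalize: bool = False,
) -> MCRResult:
    """Run the hard-and-soft MCR-ALS loop on a (normalized) dataset.

    Iterates: S step -> C step -> kinetic refit -> hard substitution, with
    the lack of fit recorded once per iteration and the patience/max-iter
    stopping rule applied to its history.  Deterministic: there is no
    internal randomness, and no internal renormalization of C columns or S
    rows (capacity parameters absorb the intensity scale).

    A component whose profile collapses to all-zero is frozen at its previous
    profile with a :class:`RankCollapseWarning`; the run continues.
    """
    if normalize:
        from .preprocessing import normalize_dataset

        ds = normalize_dataset(ds)
    D = ds.intensities
    times = ds.times
    I = config.n_components

    link = config.kinetic
    if config.C0 is not None:
        C = np.array(config.C0, dtype=float, copy=True)
        if C.shape != (D.shape[0], I):
            raise ValueError("C0 has the wrong shape")
    elif link is not None:
        C = initial_concentrations(
            link.model, link.k0_dict(), times, I, link.component_indices
        )
    else:
        C = _svd_start(D, I)

    if link is not None:
        n_free = len(link.model.free_param_names)
        if ds.n_spectra < 2 * n_free:
            warnings.warn(
                f"{ds.n_spectra} time points may not identify {n_free} kinetic "
                "parameters (fewer than 2 points per parameter)",
                IdentifiabilityWarning,
                stacklevel=2,
            )
        k = link.k0_dict()
        param_names = link.model.param_names
    else:
        k = None
        param_names = ()

    ssr_hist: list[float] = []
    pct_hist: list[float] = []
    k_hist: list[list[float]] = []
    S = np.zeros((I, D.shape[1]))
    eps = np.finfo(float).tiny

    while True:
        # freeze collapsed components so the LS design stays full rank
        col_scale = np.max(np.abs(C), axis=0)
        dead = col_scale <= eps
        if np.any(dead):
            warnings.warn(
                f"component(s) {np.where(dead)[0].tolist()} collapsed to zero; frozen",
                RankCollapseWarning,
                stacklevel=2,
            )
            C[:, dead] = 1.0 if not ssr_hist else C_prev[:, dead]  # noqa: F821

        C_prev = C
        S = nnls_rows(D, C, config.spec_flags)
        C = nnls_cols(D, S, config.conc_flags)
        if link is not None:
            k, c_model = fit_kinetic_constants(
                C, link.model, k, times, link.component_indices
            )
            C = apply_kinetic_constraint(C, c_model, link.component_indices)
            k_hist.append([k[p] for p in param_names])
        lof = lack_of_fit(D, C, S)
        ssr_hist.append(lof.ssr)
        pct_hist.append(lof.percent)
        # an essentially perfect reconstruction (SSR below 1e-12 of the total
        # sum of squares) stops immediately: at that level the SSR history is
        # numerical noise and the relative-change rule is meaningless
        if lof.ssr <= 1e-12 * float(np.sum(D**2)):
            decision = "stop_patience"
            break
        decision = check_convergence(
            ssr_hist, config.rel_tol, config.patience, config.max_iter
        )
        if decision != "continue":
            break

    return MCRResult(
        C=C,
        S=S,
        k_final=dict(k) if k is not None else None,
        k_history=np.array(k_hist, dtype=float) if k_hist else np.empty((0, 0)),
        k_param_names=tuple(param_names),
        lof_history=np.array(ssr_hist),
        pct_lof_history=np.array(pct_hist),
        n_iter=len(ssr_hist),
        converged=decision == "stop_patience",
        stop_reason={"stop_patience": "patience", "stop_max_iter": "max_iter"}[decision],
    )
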