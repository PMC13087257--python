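"""Global Tikhonov inversion of dipolar traces to a distance distribution.

One or several traces of the same sample are fitted jointly with a single
shared non-negative distance distribution P(r) and independent per-trace
nuisance parameters (modulation depth, background rate, overall scale):

    min_{P >= 0, theta}  sum_i ||V_i - model_i(P, theta_i)||^2 / sigma_i^2
                         + alpha^2 ||L2 P||^2

where L2 is the second-difference operator and alpha is chosen by
(strong robust) generalised cross-validation. The optimisation is
separable: an outer bounded nonlinear search over the nuisance parameters
wraps an inner convex non-negative Tikhonov solve (variable projection).

Because the modulation depth lambda and the integral of the unnormalised P
are jointly redundant, the reported distribution is renormalised after the
fit and the per-trace depths mapped to their effective values; the data
model is unchanged by this reparameterisation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.typing import NDArray
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import least_squares, lsq_linear, nnls

from .dipolar_model import DistanceAxis, DistanceDistribution, build_kernel
from .traces import DipolarTrace, TraceSet, read_trace, truncate_end, write_trace  # noqa: F401

__all__ = [
    "InversionConfig",
    "ReliabilityRanges",
    "RegularizedFit",
    "TikhonovProblem",
    "second_difference_operator",
    "tikhonov_nnls",
    "select_alpha",
    "reliability_ranges",
    "fit_single",
    "fit_global",
    "jackknife_traces",
]


@dataclass(frozen=True)
class InversionConfig:
    """Tunable settings of the regularised inversion."""

    criterion: str = "srgcv"          # 'gcv' or 'srgcv'
    srgcv_gamma: float = 0.8          # robustness tuning of the Lukas penalty
    alpha_min: float = 1e-4
    alpha_max: float = 1e4
    n_alpha: int = 33                 # log-spaced, spans 8 decades
    background_d: float = 3.0         # stretch dimension, fixed during the fit
    lam_bounds: tuple[float, float] = (0.001, 0.7)
    k_bounds: tuple[float, float] = (0.0, 1.5)
    v0_bounds: tuple[float, float] = (0.7, 1.3)
    outer_rounds: int = 2             # alternations of alpha selection / refit
    max_sweeps: int = 30              # block-coordinate sweeps per round
    sweep_rtol: float = 1e-7          # relative objective decrease to stop
    max_nfev: int = 60                # per-trace nuisance sub-fits
    low_depth_threshold: float = 0.02

    def alpha_grid(self) -> NDArray[np.float64]:
        return np.logspace(
            np.log10(self.alpha_min), np.log10(self.alpha_max), self.n_alpha
        )


@dataclass(frozen=True)
class ReliabilityRanges:
    """Trace-length-dependent distance limits of a recovered distribution.

    Up to ``r_shape`` the full shape of P(r) is trustworthy, up to
    ``r_mean_width`` its mean and width, up to ``r_mean`` only the mean —
    the usual colour-bar convention of DEER analysis software.
    """

    r_shape: float
    r_mean_width: float
    r_mean: float

    def __post_init__(self) -> None:
        if not self.r_shape <= self.r_mean_width <= self.r_mean:
            raise ValueError("require r_shape <= r_mean_width <= r_mean")


def reliability_ranges(
    t_max_us: float,
    constants: tuple[float, float, float] = (5.0, 6.0, 7.0),
) -> ReliabilityRanges:
    """Reliability boundaries r_X = c_X * (t_max / 2 us)^(1/3) in nm."""
    if t_max_us <= 0:
        raise ValueError("t_max must be positive")
    scale = (t_max_us / 2.0) ** (1.0 / 3.0)
    c_shape, c_mw, c_mean = constants
    return ReliabilityRanges(c_shape * scale, c_mw * scale, c_mean * scale)


@dataclass
class TraceFitParams:
    """Per-trace nuisance parameters of a regularised fit."""

    lam: float
    k: float
    d: float
    v0: float
    sigma: float
    t_max: float
    label: str = ""


@dataclass
class RegularizedFit:
    """Result of a (global) regularised inversion."""

    distribution: DistanceDistribution
    trace_params: list[TraceFitParams]
    alpha: float
    alpha_grid: NDArray[np.float64]
    criterion_curve: NDArray[np.float64]
    criterion: str
    residuals: list[NDArray[np.float64]]
    reliability: list[ReliabilityRanges]
    flags: list[str] = field(default_factory=list)
    success: bool = True
    diagnostics: dict = field(default_factory=dict)

    def chi2(self) -> float:
        return float(sum(np.sum((res / p.sigma) ** 2)
                         for res, p in zip(self.residuals, self.trace_params)))


def second_difference_operator(n: int, zero_boundary: bool = True) -> NDArray[np.float64]:
    """Second-difference (discrete curvature) penalty matrix.

    With ``zero_boundary`` the distribution is treated as zero outside the
    axis, which also penalises mass at the axis edges; this resolves the
    degeneracy between a flat far-distance contribution and the background/
    modulation-depth parameters. Without it the plain (n-2) x n interior
    operator is returned.
    """
    if not zero_boundary:
        return np.diff(np.eye(n), n=2, axis=0)
    padded = np.vstack([np.zeros((2, n)), np.eye(n), np.zeros((2, n))])
    return np.diff(padded, n=2, axis=0)


def tikhonov_nnls(
    a: NDArray, b: NDArray, reg: NDArray, alpha: float
) -> NDArray[np.float64]:
    """Non-negative Tikhonov solution of min ||a x - b||^2 + alpha^2 ||reg x||^2.

    Uses the active-set NNLS solver, falling back to bounded-variable least
    squares when the active set cycles on ill-conditioned problems.
    """
    stacked = np.vstack([a, alpha * reg])
    rhs = np.concatenate([b, np.zeros(reg.shape[0])])
    try:
        x, _ = nnls(stacked, rhs, maxiter=50 * stacked.shape[1])
    except RuntimeError:
        x = lsq_linear(stacked, rhs, bounds=(0.0, np.inf), method="bvls").x
        x = np.maximum(x, 0.0)
    return x


@dataclass
class TikhonovProblem:
    """Weighted stacked design of a (global) inversion at fixed nuisance."""

    a: NDArray[np.float64]       # data rows, already divided by sigma
    b: NDArray[np.float64]
    reg: NDArray[np.float64]

    @property
    def m(self) -> int:
        return self.a.shape[0]


def select_alpha(
    problem: TikhonovProblem,
    criterion: str = "srgcv",
    alpha_grid: NDArray | None = None,
    gamma: float = 0.8,
    tie_rtol: float = 0.02,
    tie_floor: float = 1e-3,
) -> tuple[float, NDArray[np.float64]]:
    """Choose the regularisation parameter by (sr)GCV over a log-spaced grid.

    GCV(alpha) = m ||residual||^2 / (m - tr H)^2 with influence matrix
    H = A (A^T A + alpha^2 L^T L)^-1 A^T evaluated for the unconstrained
    smoother; the residual is that of the non-negative solution. The strong
    robust variant multiplies GCV by (gamma + (1-gamma) tr(H^2)/m), which
    penalises under-smoothing.

    GCV valleys are flat when the data are clean, and inside the valley the
    non-negative solution can be arbitrarily ragged; ties — and near-ties
    within ``tie_rtol`` of the minimum — are therefore broken toward the
    largest qualifying alpha (strongest smoothing). Because the residuals
    are noise-normalised, criterion values below ``tie_floor`` correspond
    to fits far beneath the noise floor and are likewise treated as tied.
    """
    if criterion not in ("gcv", "srgcv"):
        raise ValueError(f"unknown criterion {criterion!r}")
    grid = np.asarray(alpha_grid if alpha_grid is not None else
                      InversionConfig().alpha_grid(), dtype=float)
    if grid.size < 20 or np.log10(grid.max() / grid.min()) < 6:
        raise ValueError("alpha grid must have >= 20 points spanning >= 6 decades")
    a, b, reg = problem.a, problem.b, problem.reg
    m = problem.m
    ata = a.T @ a
    ltl = reg.T @ reg
    curve = np.empty(grid.size)
    n_singular = 0
    for i, alpha in enumerate(grid):
        g = ata + alpha**2 * ltl
        try:
            cf = cho_factor(g)
        except np.linalg.LinAlgError:
            # numerically singular at this alpha; exclude it from selection
            curve[i] = np.inf
            n_singular += 1
            if n_singular == grid.size:
                cond = np.linalg.cond(g)
                raise np.linalg.LinAlgError(
                    f"influence system singular over the whole alpha grid "
                    f"(cond={cond:.3g} at alpha={alpha:g})"
                ) from None
            continue
        infl = cho_solve(cf, ata)          # G^-1 A^T A, same trace as H
        tr_h = float(np.trace(infl))
        x = tikhonov_nnls(a, b, reg, alpha)
        rss = float(np.sum((a @ x - b) ** 2))
        val = m * rss / (m - tr_h) ** 2
        if criterion == "srgcv":
            tr_h2 = float(np.sum(infl * infl.T))
            val *= gamma + (1.0 - gamma) * tr_h2 / m
        curve[i] = val
    finite = np.isfinite(curve)
    cmin = float(curve[finite].min())
    threshold = max(cmin * (1.0 + tie_rtol), tie_floor)
    qualifying = np.nonzero(finite & (curve <= threshold))[0]
    best = int(qualifying[-1])
    return float(grid[best]), curve


def _init_nuisance(trace: DipolarTrace, d: float, cfg: InversionConfig) -> tuple[float, float, float]:
    """Rough (lambda, k, v0) start values from the trace tail."""
    t, v = trace.time_us, trace.signal
    tail = t > 0.6 * trace.t_max
    if tail.sum() >= 5 and np.all(v[tail] > 0):
        x = t[tail] ** (d / 3.0)
        y = np.log(v[tail])
        slope, intercept = np.polyfit(x, y, 1)
        k0 = float(np.clip(-slope, cfg.k_bounds[0] + 1e-6, cfg.k_bounds[1] - 1e-6))
        lam0 = float(np.clip(1.0 - np.exp(intercept), 0.05, 0.6))
    else:
        k0, lam0 = 0.05, 0.3
    return lam0, k0, 1.0


def _assemble(
    theta: NDArray,
    traces: list[DipolarTrace],
    kernels: list[NDArray],
    sigmas: list[float],
    d: float,
    axis: DistanceAxis | None = None,
) -> tuple[NDArray, NDArray]:
    """Weighted stacked (A, b) for the inner linear solve at given nuisance.

    When ``axis`` is given, a strongly weighted normalisation row pinning
    the trapezoidal integral of P to 1 is appended; this removes the exact
    redundancy between the modulation depths and the scale of P, without
    which the alternating optimisation crawls along a flat valley.
    """
    rows, rhs = [], []
    for i, (tr, ker) in enumerate(zip(traces, kernels)):
        lam, k, v0 = theta[3 * i : 3 * i + 3]
        bg = np.exp(-k * tr.time_us ** (d / 3.0))
        rows.append((v0 * lam) * (bg[:, None] * ker) / sigmas[i])
        rhs.append((tr.signal - v0 * (1.0 - lam) * bg) / sigmas[i])
    if axis is not None:
        w = np.full(len(axis), axis.step)
        w[0] = w[-1] = 0.5 * axis.step
        c = 100.0 / min(sigmas)
        rows.append(c * w[None, :])
        rhs.append(np.array([c]))
    return np.vstack(rows), np.concatenate(rhs)


def _refine_nuisance(
    theta: NDArray,
    lo: NDArray,
    hi: NDArray,
    traces: list[DipolarTrace],
    kernels: list[NDArray],
    sigmas: list[float],
    d: float,
    reg: NDArray,
    alpha: float,
    cfg: InversionConfig,
    axis: DistanceAxis | None = None,
) -> tuple[NDArray, float, int, bool]:
    """Block-coordinate descent on (P, theta) at fixed alpha.

    Alternates the convex shared non-negative Tikhonov solve for P with
    independent bounded 3-parameter least-squares refinements of each
    trace's (lambda, k, v0) at fixed P. Both blocks decrease the joint
    penalised objective, so the sweep objective is monotone; iteration
    stops on relative stagnation.
    """
    theta = theta.copy()
    prev_obj = np.inf
    obj = np.inf
    converged = False
    last_rel_decrease = np.inf
    n_sweeps = 0
    for sweep in range(cfg.max_sweeps):
        n_sweeps = sweep + 1
        a, b = _assemble(theta, traces, kernels, sigmas, d, axis)
        p = tikhonov_nnls(a, b, reg, alpha)
        obj = float(np.sum((a @ p - b) ** 2) + alpha**2 * np.sum((reg @ p) ** 2))
        if np.isfinite(prev_obj):
            last_rel_decrease = (prev_obj - obj) / max(prev_obj, 1.0)
            if last_rel_decrease <= cfg.sweep_rtol:
                converged = True
                break
        prev_obj = obj
        for i, (tr, ker) in enumerate(zip(traces, kernels)):
            form = ker @ p
            t_pow = tr.time_us ** (d / 3.0)

            def resid(th3):
                lam, k, v0 = th3
                model = v0 * ((1.0 - lam) + lam * form) * np.exp(-k * t_pow)
                return (tr.signal - model) / sigmas[i]

            sol = least_squares(
                resid, theta[3 * i : 3 * i + 3],
                bounds=(lo[3 * i : 3 * i + 3], hi[3 * i : 3 * i + 3]),
                method="trf", max_nfev=cfg.max_nfev,
            )
            theta[3 * i : 3 * i + 3] = sol.x
    # treat a stalled-but-stationary refinement as converged; only an
    # objective still falling markedly at the sweep cap is a real failure
    if not converged and last_rel_decrease <= 1000.0 * cfg.sweep_rtol:
        converged = True
    return theta, obj, n_sweeps, converged


def fit_global(
    traces: TraceSet,
    axis: DistanceAxis | None = None,
    config: InversionConfig | None = None,
) -> RegularizedFit:
    """Fit one shared P(r) to all traces of a set.

    Alternates data-driven alpha selection with a bounded nonlinear
    refinement of the per-trace nuisance parameters; the distribution is
    obtained by variable projection (non-negative Tikhonov solve) at every
    step. With a single trace this reduces exactly to a single-trace fit.
    """
    axis = axis or DistanceAxis()
    cfg = config or InversionConfig()
    trs = [t.with_noise_estimate() for t in traces]
    sigmas = [max(t.noise_sd, 1e-5) for t in trs]
    kernels = [build_kernel(t.time_us, axis).matrix for t in trs]
    reg = second_difference_operator(len(axis))
    d = cfg.background_d

    theta0, lo, hi = [], [], []
    for tr in trs:
        lam0, k0, v00 = _init_nuisance(tr, d, cfg)
        theta0 += [lam0, k0, v00]
        lo += [cfg.lam_bounds[0], cfg.k_bounds[0], cfg.v0_bounds[0]]
        hi += [cfg.lam_bounds[1], cfg.k_bounds[1], cfg.v0_bounds[1]]
    theta = np.asarray(theta0)

    alpha, curve = 1.0, None
    grid = cfg.alpha_grid()
    flags: list[str] = []
    diagnostics: dict = {}
    success = True

    for rnd in range(cfg.outer_rounds):
        a, b = _assemble(theta, trs, kernels, sigmas, d, axis)
        alpha, curve = select_alpha(
            TikhonovProblem(a, b, reg), cfg.criterion, grid, cfg.srgcv_gamma
        )
        # the joint (P, theta) landscape has local optima in the modulation
        # depths; on the first round try a second start at half depth and
        # keep the lower-objective solution
        if rnd == 0:
            half = theta.copy()
            half[0::3] = 0.5 * half[0::3]
            starts = [theta, half]
        else:
            starts = [theta]
        results = [
            _refine_nuisance(s0, np.array(lo), np.array(hi), trs, kernels,
                             sigmas, d, reg, alpha, cfg, axis)
            for s0 in starts
        ]
        theta, obj, sweeps, converged = min(results, key=lambda r: r[1])
        if not converged:
            success = False
            flags.append(
                f"nuisance refinement not converged in {cfg.max_sweeps} "
                f"sweeps (round {rnd + 1})"
            )
        diagnostics[f"round{rnd + 1}"] = {
            "alpha": alpha, "objective": obj, "sweeps": sweeps,
        }

    a, b = _assemble(theta, trs, kernels, sigmas, d, axis)
    p_raw = tikhonov_nnls(a, b, reg, alpha)
    z = float(np.trapezoid(p_raw, axis.values))
    if z <= 0:
        return RegularizedFit(
            DistanceDistribution(axis, np.zeros(len(axis))), [], alpha, grid,
            curve, cfg.criterion, [], [], flags + ["empty distribution recovered"],
            success=False, diagnostics=diagnostics,
        )
    dist = DistanceDistribution(axis, p_raw / z)

    params, residuals, reliab = [], [], []
    for i, tr in enumerate(trs):
        lam, k, v0 = theta[3 * i : 3 * i + 3]
        # map the (lambda, integral-of-P) redundancy to effective values
        lam_eff = lam * z / (1.0 - lam + lam * z)
        v0_eff = v0 * (1.0 - lam + lam * z)
        bg = np.exp(-k * tr.time_us ** (d / 3.0))
        model = v0 * ((1.0 - lam) + lam * (kernels[i] @ p_raw)) * bg
        residuals.append(tr.signal - model)
        params.append(TraceFitParams(lam_eff, float(k), d, v0_eff, sigmas[i],
                                     tr.t_max, tr.label))
        rel = reliability_ranges(tr.t_max)
        reliab.append(rel)
        # modulation attributable to resolvable distances: mass beyond the
        # trace's mean-and-width reliability limit has a near-flat kernel
        # over the window and is observationally equivalent to a smaller
        # depth, so it must not count toward the detected modulation
        resolvable = dist.density[axis.values <= rel.r_mean_width]
        resolvable_mass = float(
            np.trapezoid(resolvable, axis.values[: resolvable.size])
        )
        if lam_eff < cfg.low_depth_threshold or resolvable_mass < 0.5:
            flags.append(
                f"low modulation depth on trace {i} ({tr.label}): "
                f"lambda={lam_eff:.4f} with only {resolvable_mass:.2f} of P "
                f"within the {rel.r_mean_width:.1f} nm reliability limit — "
                f"the depth is degenerate with background and far-distance "
                f"mass for this evolution window"
            )
    return RegularizedFit(dist, params, alpha, grid, curve, cfg.criterion,
                          residuals, reliab, flags, success, diagnostics)


def fit_single(
    trace: DipolarTrace,
    axis: DistanceAxis | None = None,
    config: InversionConfig | None = None,
) -> RegularizedFit:
    """Regularised inversion of one trace (global fit of a singleton set)."""
    return fit_global(TraceSet([trace]), axis, config)


def distribution_l1(p1: DistanceDistribution, p2: DistanceDistribution) -> float:
    """L1 distance integral |P1 - P2| dr between distributions on one axis."""
    if p1.axis != p2.axis:
        raise ValueError("distributions live on different axes")
    return float(np.trapezoid(np.abs(p1.density - p2.density), p1.r))


def jackknife_traces(
    traces: TraceSet,
    axis: DistanceAxis | None = None,
    config: InversionConfig | None = None,
) -> tuple[list[RegularizedFit], dict]:
    """Leave-one-out global fits as a robustness check.

    Re-fits every subset with one trace omitted and summarises the spread of
    the recovered distributions by their maximum pairwise L1 distance.
    """
    if len(traces) < 3:
        raise ValueError("jackknife needs at least 3 traces")
    fits = []
    for i in range(len(traces)):
        subset = TraceSet(
            [t for j, t in enumerate(traces.traces) if j != i],
            sample_id=traces.sample_id,
        )
        fits.append(fit_global(subset, axis, config))
    dists = [f.distribution for f in fits]
    n = len(dists)
    pairwise = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pairwise[i, j] = pairwise[j, i] = distribution_l1(dists[i], dists[j])
    summary = {
        "max_pairwise_l1": float(pairwise.max()),
        "pairwise_l1": pairwise,
        "omitted": [t.label for t in traces.traces],
    }
    return fits, summary
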