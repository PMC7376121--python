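"""DEER/PELDOR distance-distribution recovery.

The chain implemented here mirrors standard pulse-dipolar practice for
oligomeric spin systems:

1. fit the intermolecular background ``B(t) = s exp(-k t^(d/3))`` to the tail
   of the raw trace (``fit_background``),
2. divide it out to obtain the form factor F(t) (``form_factor``),
3. invert F(t) to a non-negative distance distribution P(r) by Tikhonov
   regularisation with a second-derivative penalty (``tikhonov_invert``),
   selecting the regularisation weight on the L-curve (``select_alpha``),
4. assess robustness with a validation ensemble that re-runs the inversion
   while scanning the background fit start over 5–80 % of the trace and
   perturbing the data with noise, discarding trials whose fit RMSD exceeds
   1.15x the best, and reporting pointwise mean ± 2 sigma bands
   (``validate``),
5. optionally suppress multispin ghost peaks by power scaling the form
   factor, F -> F^(1/(n_spins-1)) (``power_scale``).

`DeerModel` / `DeerResults` wrap the chain in a fit-and-inspect interface.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit, nnls
from scipy.signal import savgol_filter

from .io import DistanceDistribution, PipelineError, TimeTrace
from .kernel import DipolarKernel, build_kernel

logger = logging.getLogger("pentaspin")

__all__ = [
    "BackgroundModel",
    "InversionResult",
    "ValidationEnsemble",
    "fit_background",
    "form_factor",
    "tikhonov_invert",
    "select_alpha",
    "validate",
    "power_scale",
    "reliability_ranges",
    "estimate_noise_sd",
    "default_r_grid",
    "DeerModel",
    "DeerResults",
]

#: default distance grid, nm (covers nitroxide DEER's usable range)
DEFAULT_R_MIN = 1.5
DEFAULT_R_MAX = 8.0
DEFAULT_R_STEP = 0.05

#: validation-ensemble defaults: 16 background-start steps spanning 5-80 % of
#: the trace, 50 noise trials each (800 total), noise at 50 % of the trace's
#: estimated noise sd, RMSD filter at 1.15x the best
VALIDATION_DEFAULTS = dict(
    n_steps=16, start_lo=0.05, start_hi=0.80, trials_per_step=50,
    noise_scale=0.5, rmsd_cut=1.15,
)

#: reliability rules of thumb: longest distance (nm) for which the shape /
#: width / mean of P(r) is trustworthy given a trace of length t_max (µs);
#: each boundary scales as t_max^(1/3) with the dipolar r^3 law
RELIABILITY_NM_PER_US13 = {"shape": 4.0, "width": 5.0, "mean": 6.0}


def default_r_grid() -> np.ndarray:
    n = int(round((DEFAULT_R_MAX - DEFAULT_R_MIN) / DEFAULT_R_STEP)) + 1
    return np.linspace(DEFAULT_R_MIN, DEFAULT_R_MAX, n)


# ---------------------------------------------------------------------------
# background


@dataclass
class BackgroundModel:
    """Stretched-exponential intermolecular background s exp(-k t^(d/3))."""

    rate: float
    dimension: float
    fit_start: float
    scale: float
    unphysical: bool = False

    def __call__(self, t_us: np.ndarray) -> np.ndarray:
        t = np.asarray(t_us, dtype=float)
        return self.scale * np.exp(-self.rate * np.abs(t) ** (self.dimension / 3.0))


def fit_background(
    trace: TimeTrace,
    fit_start: float = 1.0 / 3.0,
    d: float = 3.0,
    allow_unphysical: bool = False,
) -> BackgroundModel:
    """Least-squares fit of the background to the tail of a DEER trace.

    ``fit_start`` is the fraction of the trace length at which the tail
    begins. With ``allow_unphysical`` a negative decay rate (continuously
    rising background, i.e. negative intermolecular concentration) is kept
    and flagged rather than clamped; such fits can genuinely minimise the
    RMSD when the dipolar oscillation is incompletely sampled.
    """
    if not 0.0 < fit_start < 1.0:
        raise PipelineError(f"fit_start must lie in (0, 1), got {fit_start}")
    t, v = trace.axis, trace.real
    mask = t >= fit_start * t[-1]
    if mask.sum() < 5:
        raise PipelineError(
            f"background tail from fit_start={fit_start:.3g} has only "
            f"{int(mask.sum())} points (need >= 5)"
        )
    tt, vv = t[mask], v[mask]
    # linearised start: log v = log s - k t^(d/3) (positive part only)
    pos = vv > 0
    x = tt[pos] ** (d / 3.0)
    if pos.sum() >= 2:
        slope, intercept = np.polyfit(x, np.log(vv[pos]), 1)
        k0, s0 = -slope, float(np.exp(intercept))
    else:
        k0, s0 = 0.0, float(np.mean(np.abs(vv)) + 1e-12)

    def model(t_, k, s):
        return s * np.exp(-k * t_ ** (d / 3.0))

    try:
        popt, _ = curve_fit(model, tt, vv, p0=[k0, s0], maxfev=5000)
        k, s = float(popt[0]), float(popt[1])
    except RuntimeError:
        k, s = k0, s0
    unphysical = k < 0
    if unphysical and not allow_unphysical:
        logger.warning("background rate %.3g < 0 clamped to 0 (use allow_unphysical to keep)", k)
        k = 0.0
        s = float(np.mean(vv))
        unphysical = False
    if s <= 0:
        raise PipelineError("background fit produced a non-positive scale")
    return BackgroundModel(rate=k, dimension=d, fit_start=fit_start, scale=s, unphysical=unphysical)


def _zero_time_amplitude(trace: TimeTrace) -> float:
    """V(0) estimate: a quadratic fit through the first points, robust to
    single-point noise."""
    n = min(len(trace.axis), 8)
    if n < 3:
        return float(trace.real[0])
    coef = np.polyfit(trace.axis[:n], trace.real[:n], 2)
    return float(np.polyval(coef, trace.axis[0]))


def form_factor(trace: TimeTrace, bg: BackgroundModel) -> TimeTrace:
    """Divide the background out of a DEER trace: F(t) = V(t)/B(t).

    The tail fit's scale absorbs the (1 - lambda) level of the dipolar form
    factor, so the division uses the fitted decay *shape* anchored at the
    trace's zero-time amplitude: B(t) = V(0) exp(-k t^(d/3)). F therefore
    retains the modulation-depth information — it decays from 1 toward
    1 - lambda.
    """
    v0 = _zero_time_amplitude(trace)
    if v0 <= 0:
        raise PipelineError("non-positive zero-time amplitude")
    b = bg(trace.axis) / bg.scale * v0
    if np.any(b <= 0):
        raise PipelineError("background non-positive on the trace support")
    out = trace.copy(real=trace.real / b)
    out.meta["background_rate"] = bg.rate
    out.meta["background_fit_start"] = bg.fit_start
    return out


def estimate_noise_sd(trace: TimeTrace) -> float:
    """Noise sd of a trace from the residuals of a smoothness (Savitzky-
    Golay) fit; used to scale validation-ensemble noise perturbations."""
    v = trace.real
    win = min(len(v) // 4 * 2 + 1, 31)
    if win < 5:
        win = 5
    smooth = savgol_filter(v, window_length=win, polyorder=3)
    return float(np.std(v - smooth))


# ---------------------------------------------------------------------------
# Tikhonov inversion


def _second_difference(n: int) -> np.ndarray:
    """(n-2) x n second-difference operator (discrete curvature penalty)."""
    L = np.zeros((n - 2, n))
    for i in range(n - 2):
        L[i, i : i + 3] = (1.0, -2.0, 1.0)
    return L


@dataclass
class InversionResult:
    """Outcome of one regularised inversion."""

    pr: DistanceDistribution
    alpha: float
    rmsd: float
    mod_depth: float
    fit: np.ndarray | None = None  # fitted form factor on the trace grid


def tikhonov_invert(
    ff: TimeTrace,
    kernel: DipolarKernel,
    alpha: float,
) -> InversionResult:
    """Non-negative Tikhonov inversion of a form factor.

    Solves ``min || (1-lambda) + lambda K P - F ||^2 + alpha^2 ||L2 P||^2``
    with ``P >= 0``, via the unnormalised variable Q = lambda P, in which the
    problem is a single stacked non-negative least-squares solve:

        min || [(K-1) dr ; alpha L2] Q - [F-1 ; 0] ||^2,  Q >= 0.

    The modulation depth is lambda = integral(Q) and P = Q/lambda is returned
    renormalised to unit integral. The RMSD of the fit to F is reported.
    """
    if alpha <= 0:
        raise PipelineError(f"alpha must be positive, got {alpha}")
    K = kernel.matrix
    nt, nr = K.shape
    if nt != len(ff.real):
        raise PipelineError("kernel time grid does not match the form factor")
    w = np.full(nr, kernel.dr)
    w[0] = w[-1] = 0.5 * kernel.dr
    A = (K - 1.0) * w[None, :]
    b = ff.real - 1.0
    L = _second_difference(nr)
    A_stack = np.vstack([A, alpha * L])
    b_stack = np.concatenate([b, np.zeros(nr - 2)])
    try:
        q, _ = nnls(A_stack, b_stack, maxiter=50 * nr)
    except RuntimeError as exc:
        raise PipelineError(f"non-negative least squares did not converge: {exc}") from exc
    lam = float(q @ w)
    fit = 1.0 + A @ q
    rmsd = float(np.sqrt(np.mean((fit - ff.real) ** 2)))
    if lam <= 0:
        # no dipolar signal found: flat distribution, zero depth
        density = np.ones(nr) / (kernel.r_grid[-1] - kernel.r_grid[0])
    else:
        density = q / lam
    pr = DistanceDistribution(kernel.r_grid.copy(), density)
    z = pr.integral()
    if z > 0:
        pr = DistanceDistribution(pr.r, pr.density / z)
    return InversionResult(pr=pr, alpha=alpha, rmsd=rmsd, mod_depth=lam, fit=fit)


def default_alpha_grid(n: int = 24) -> np.ndarray:
    return np.logspace(-4, 1, n)


def select_alpha(
    ff: TimeTrace,
    kernel: DipolarKernel,
    alpha_grid: np.ndarray | None = None,
) -> float:
    """L-curve corner selection of the regularisation weight.

    For each alpha the residual norm rho and penalty norm eta are computed;
    the corner is the point of maximum curvature of the (log rho, log eta)
    curve. Degenerate curves (no interior curvature maximum) fall back to the
    median alpha with a warning.
    """
    if alpha_grid is None:
        alpha_grid = default_alpha_grid()
    alpha_grid = np.sort(np.asarray(alpha_grid, dtype=float))
    if alpha_grid.size == 1:
        return float(alpha_grid[0])
    if alpha_grid.size < 8:
        raise PipelineError("alpha grid needs >= 8 points (or exactly 1)")
    L = _second_difference(len(kernel.r_grid))
    rho, eta = [], []
    for a in alpha_grid:
        res = tikhonov_invert(ff, kernel, a)
        q = res.pr.density * res.mod_depth  # back to the solved variable
        rho.append(max(res.rmsd * np.sqrt(len(ff.real)), 1e-14))
        eta.append(float(np.linalg.norm(L @ q)))
    rho = np.asarray(rho)
    eta = np.asarray(eta)
    # essentially-zero solutions carry no curvature information; a curve
    # dominated by them (e.g. pure noise) has no meaningful corner
    valid = eta > 1e-12
    # a flat residual over the whole grid (pure noise: regularisation costs
    # no fit quality) leaves the L-curve a cornerless vertical line
    if (rho.max() - rho.min()) / rho.min() < 1e-2:
        warnings.warn("degenerate L-curve; falling back to median alpha", stacklevel=2)
        return float(alpha_grid[len(alpha_grid) // 2])
    if valid.sum() < alpha_grid.size // 2:
        warnings.warn("degenerate L-curve; falling back to median alpha", stacklevel=2)
        return float(alpha_grid[len(alpha_grid) // 2])
    alphas_v = alpha_grid[valid]
    x = np.log(rho[valid])
    y = np.log(eta[valid])
    # curvature via central differences in the grid parameter
    dx, dy = np.gradient(x), np.gradient(y)
    d2x, d2y = np.gradient(dx), np.gradient(dy)
    denom = (dx**2 + dy**2) ** 1.5
    with np.errstate(divide="ignore", invalid="ignore"):
        curv = (dx * d2y - dy * d2x) / denom
    curv[~np.isfinite(curv)] = -np.inf
    interior = curv[1:-1]
    if interior.size == 0 or not np.any(interior > 0):
        warnings.warn("degenerate L-curve; falling back to median alpha", stacklevel=2)
        return float(alpha_grid[len(alpha_grid) // 2])
    return float(alphas_v[1 + int(np.argmax(interior))])


# ---------------------------------------------------------------------------
# validation ensemble


@dataclass
class TrialRecord:
    fit_start: float
    seed: int
    rmsd: float
    mod_depth: float
    unphysical_bg: bool
    kept: bool = False


@dataclass
class ValidationEnsemble:
    """Ensemble of perturbed re-inversions with RMSD filtering.

    ``trials`` holds one record per planned trial; ``densities`` the matching
    P(r) rows. Kept trials (RMSD <= rmsd_cut x best) define pointwise
    mean ± 2 sigma confidence bands.
    """

    r_grid: np.ndarray
    trials: list[TrialRecord]
    densities: np.ndarray  # (n_trials, n_r)
    n_planned: int
    rmsd_cut: float
    alpha: float
    n_failures: int = 0

    @property
    def kept_mask(self) -> np.ndarray:
        return np.array([t.kept for t in self.trials], dtype=bool)

    @property
    def n_kept(self) -> int:
        return int(self.kept_mask.sum())

    def _kept_densities(self) -> np.ndarray:
        return self.densities[self.kept_mask]

    @property
    def mean_pr(self) -> DistanceDistribution:
        m = self._kept_densities().mean(axis=0)
        return DistanceDistribution(self.r_grid, m).normalized()

    def bands(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(lower, mean, upper) densities: mean ± 2 sigma, lower clipped at 0."""
        kept = self._kept_densities()
        m = kept.mean(axis=0)
        s = kept.std(axis=0)
        return np.clip(m - 2.0 * s, 0.0, None), m, m + 2.0 * s

    def to_table(self):
        """One row per trial (fit_start, seed, rmsd, mod_depth, kept)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "fit_start": [t.fit_start for t in self.trials],
                "seed": [t.seed for t in self.trials],
                "rmsd": [t.rmsd for t in self.trials],
                "mod_depth": [t.mod_depth for t in self.trials],
                "unphysical_bg": [t.unphysical_bg for t in self.trials],
                "kept": [t.kept for t in self.trials],
            }
        )


def validate(
    trace: TimeTrace,
    r_grid: np.ndarray | None = None,
    n_steps: int = VALIDATION_DEFAULTS["n_steps"],
    start_lo: float = VALIDATION_DEFAULTS["start_lo"],
    start_hi: float = VALIDATION_DEFAULTS["start_hi"],
    trials_per_step: int = VALIDATION_DEFAULTS["trials_per_step"],
    noise_scale: float = VALIDATION_DEFAULTS["noise_scale"],
    rmsd_cut: float = VALIDATION_DEFAULTS["rmsd_cut"],
    seed: int | None = None,
    alpha: float | None = None,
    bg_dimension: float = 3.0,
) -> ValidationEnsemble:
    """Validation ensemble for a DEER trace.

    For each of ``n_steps`` equally spaced background fit-start fractions in
    [start_lo, start_hi], runs ``trials_per_step`` inversions of the trace
    plus Gaussian noise of sd ``noise_scale`` x the trace's estimated noise
    sd (16 x 50 = 800 trials at the defaults). Trials whose fit RMSD exceeds
    ``rmsd_cut`` x the best RMSD are discarded (ties at the cut are kept).
    The regularisation weight is selected once on the unperturbed trace and
    held fixed across trials.
    """
    if r_grid is None:
        r_grid = default_r_grid()
    starts = np.linspace(start_lo, start_hi, n_steps)
    min_tail = 5
    nt = len(trace.axis)
    if nt * (1.0 - start_hi) < min_tail:
        raise PipelineError("trace too short for the largest background fit start")
    kernel = build_kernel(trace.axis, r_grid)
    noise_sd = estimate_noise_sd(trace) * noise_scale
    if alpha is None:
        bg0 = fit_background(trace, fit_start=float(starts[0]), d=bg_dimension, allow_unphysical=True)
        alpha = select_alpha(form_factor(trace, bg0), kernel)
    rng = np.random.default_rng(seed)
    trials: list[TrialRecord] = []
    densities = np.zeros((n_steps * trials_per_step, len(r_grid)))
    n_failures = 0
    idx = 0
    for fs in starts:
        for _ in range(trials_per_step):
            trial_seed = int(rng.integers(0, 2**31 - 1))
            noisy = trace.copy(
                real=trace.real
                + np.random.default_rng(trial_seed).normal(0.0, noise_sd, size=nt)
            )
            try:
                bg = fit_background(noisy, fit_start=float(fs), d=bg_dimension, allow_unphysical=True)
                res = tikhonov_invert(form_factor(noisy, bg), kernel, alpha)
            except PipelineError as exc:
                logger.warning("validation trial failed (fit_start=%.3g): %s", fs, exc)
                n_failures += 1
                trials.append(TrialRecord(float(fs), trial_seed, np.inf, np.nan, False))
                idx += 1
                continue
            trials.append(
                TrialRecord(float(fs), trial_seed, res.rmsd, res.mod_depth, bg.unphysical)
            )
            densities[idx] = res.pr.density
            idx += 1
    finite = [t.rmsd for t in trials if np.isfinite(t.rmsd)]
    if not finite:
        raise PipelineError("every validation trial failed")
    best = min(finite)
    for t in trials:
        t.kept = bool(np.isfinite(t.rmsd) and t.rmsd <= rmsd_cut * best)
    ens = ValidationEnsemble(
        r_grid=np.asarray(r_grid, dtype=float),
        trials=trials,
        densities=densities,
        n_planned=n_steps * trials_per_step,
        rmsd_cut=rmsd_cut,
        alpha=float(alpha),
        n_failures=n_failures,
    )
    logger.info(
        "validation: %d planned, %d kept (best rmsd %.3g), %d failures",
        ens.n_planned, ens.n_kept, best, n_failures,
    )
    return ens


# ---------------------------------------------------------------------------
# multispin suppression & reliability


def power_scale(ff: TimeTrace, n_spins: int, floor: float = 1e-3) -> TimeTrace:
    """Suppress multispin ghost peaks by power scaling the form factor.

    For n equivalent coupled spins the measured form factor is close to a
    product of the C(n,2) pair form factors; raising it to 1/(n_spins - 1)
    approximately restores pair-signal weighting. Identity for n_spins = 2.
    Non-positive values are clipped at ``floor`` with a warning.
    """
    if n_spins < 2:
        raise PipelineError("n_spins must be >= 2")
    f = ff.real
    if np.any(f <= 0):
        warnings.warn(
            f"form factor has {int((f <= 0).sum())} non-positive points; "
            f"clipped at {floor} before power scaling",
            stacklevel=2,
        )
        f = np.clip(f, floor, None)
    out = ff.copy(real=f ** (1.0 / (n_spins - 1)))
    out.meta["power_scaled_n_spins"] = n_spins
    return out


def reliability_ranges(t_max: float) -> dict[str, float]:
    """Qualitative reliability bands for a trace of length ``t_max`` (µs).

    Returns the longest distance (nm) up to which the shape, width and mean
    of P(r) are considered trustworthy, using fixed rules-of-thumb constants
    (``RELIABILITY_NM_PER_US13``); every boundary scales as t_max^(1/3),
    following the r^3 dependence of the dipolar frequency.
    """
    if t_max <= 0:
        raise PipelineError("t_max must be positive")
    return {k: c * t_max ** (1.0 / 3.0) for k, c in RELIABILITY_NM_PER_US13.items()}


# ---------------------------------------------------------------------------
# model/results interface


class DeerModel:
    """Distance-distribution model for a DEER trace.

    Parameters
    ----------
    trace : TimeTrace
        Raw DEER trace, time in µs from 0.
    r_grid : ndarray, optional
        Distance grid in nm (default 1.5–8.0 nm, 0.05 nm step).
    bg_dimension : float
        Background dimensionality d (3 = homogeneous 3-D).
    n_spins : int, optional
        If > 2, power scaling with this spin count is applied to the form
        factor before inversion.

    Examples
    --------
    >>> model = DeerModel(trace)
    >>> res = model.fit()
    >>> res.peak_distances, res.mod_depth
    """

    def __init__(
        self,
        trace: TimeTrace,
        r_grid: np.ndarray | None = None,
        bg_dimension: float = 3.0,
        n_spins: int = 2,
    ) -> None:
        self.trace = trace
        self.r_grid = default_r_grid() if r_grid is None else np.asarray(r_grid, dtype=float)
        self.bg_dimension = bg_dimension
        self.n_spins = n_spins
        self.kernel = build_kernel(trace.axis, self.r_grid)

    @classmethod
    def from_file(cls, path, **kw) -> "DeerModel":
        from .io import read_trace

        return cls(read_trace(path), **kw)

    def _invert_at(self, fit_start: float, alpha: float | None, allow_unphysical: bool):
        bg = fit_background(
            self.trace, fit_start=fit_start, d=self.bg_dimension,
            allow_unphysical=allow_unphysical,
        )
        ff = form_factor(self.trace, bg)
        if self.n_spins > 2:
            ff = power_scale(ff, self.n_spins)
        if alpha is None:
            alpha = select_alpha(ff, self.kernel)
        return bg, ff, tikhonov_invert(ff, self.kernel, alpha)

    def fit(
        self,
        fit_start: float | None = None,
        alpha: float | None = None,
        allow_unphysical: bool = True,
    ) -> "DeerResults":
        """Fit the model; with ``fit_start=None`` the background start is
        scanned over the validation grid (16 steps, 5–80 %) and the start
        minimising the fit RMSD on the full trace is used."""
        if fit_start is not None:
            bg, ff, inv = self._invert_at(fit_start, alpha, allow_unphysical)
        else:
            starts = np.linspace(
                VALIDATION_DEFAULTS["start_lo"],
                VALIDATION_DEFAULTS["start_hi"],
                VALIDATION_DEFAULTS["n_steps"],
            )
            best = None
            for fs in starts:
                try:
                    cand = self._invert_at(float(fs), alpha, allow_unphysical)
                except PipelineError:
                    continue
                if best is None or cand[2].rmsd < best[2].rmsd:
                    best = cand
            if best is None:
                raise PipelineError("background fit failed at every candidate start")
            bg, ff, inv = best
        return DeerResults(model=self, background=bg, ff=ff, inversion=inv)


class DeerResults:
    """Results of a DEER distance-distribution fit."""

    def __init__(self, model: DeerModel, background: BackgroundModel,
                 ff: TimeTrace, inversion: InversionResult) -> None:
        self.model = model
        self.background = background
        self.form_factor = ff
        self.inversion = inversion

    # -- primary estimates ---------------------------------------------------
    @property
    def distribution(self) -> DistanceDistribution:
        return self.inversion.pr

    @property
    def mod_depth(self) -> float:
        return self.inversion.mod_depth

    @property
    def alpha(self) -> float:
        return self.inversion.alpha

    @property
    def rmsd(self) -> float:
        return self.inversion.rmsd

    @property
    def peak_distances(self) -> np.ndarray:
        from .labels import detect_peaks

        return np.asarray(detect_peaks(self.distribution).modal_distances)

    def peak_report(self):
        from .labels import detect_peaks

        return detect_peaks(self.distribution)

    def reliability(self) -> dict[str, float]:
        return reliability_ranges(float(self.model.trace.axis[-1]))

    def validate(self, seed: int | None = None, **kw) -> ValidationEnsemble:
        """Run the noise/background-start validation ensemble (800 trials at
        the defaults) on the underlying trace."""
        kw.setdefault("r_grid", self.model.r_grid)
        kw.setdefault("alpha", self.alpha)
        kw.setdefault("bg_dimension", self.model.bg_dimension)
        return validate(self.model.trace, seed=seed, **kw)

    def summary(self) -> str:
        rep = self.peak_report()
        rel = self.reliability()
        lines = [
            "DEER distance-distribution fit",
            "=" * 46,
            f"trace length          {self.model.trace.axis[-1]:8.3f} µs ({len(self.model.trace.axis)} pts)",
            f"r grid                {self.model.r_grid[0]:.2f}-{self.model.r_grid[-1]:.2f} nm, "
            f"step {self.model.r_grid[1] - self.model.r_grid[0]:.3f}",
            f"background rate k     {self.background.rate:8.4f} /µs"
            + ("  [unphysical: rising]" if self.background.unphysical else ""),
            f"background fit start  {self.background.fit_start:8.3f} of trace",
            f"modulation depth      {self.mod_depth:8.4f}",
            f"regularization alpha  {self.alpha:8.4g}",
            f"fit RMSD              {self.rmsd:8.4g}",
            f"reliability (nm)      shape<{rel['shape']:.2f} width<{rel['width']:.2f} mean<{rel['mean']:.2f}",
        ]
        if len(rep.modal_distances):
            peaks = ", ".join(f"{d:.2f}" for d in rep.modal_distances)
            lines.append(f"peaks (nm)            {peaks}")
        if rep.d2_d1_ratio is not None:
            lines.append(
                f"D2/D1 ratio           {rep.d2_d1_ratio:8.3f}"
                f"  (pentamer-consistent: {rep.pentamer_consistent})"
            )
        return "\n".join(lines)

    def plot(self, ax=None, ensemble: ValidationEnsemble | None = None):
        """Plot P(r), optionally with the ensemble's ± 2 sigma band."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        pr = self.distribution
        ax.plot(pr.r, pr.density, label="P(r)")
        if ensemble is not None:
            lo, _, hi = ensemble.bands()
            ax.fill_between(ensemble.r_grid, lo, hi, alpha=0.3, label="mean ± 2σ")
        ax.set_xlabel("r (nm)")
        ax.set_ylabel("P(r) (1/nm)")
        ax.legend()
        return ax
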