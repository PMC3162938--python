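"""Stage II: dynamic-model refinement of the rough regulatory network.

Each target gene ``y`` is modelled as a multi-input single-output stochastic
dynamic system

    dy/dt = sum_i b_i * x_i(t)  -  beta * y(t)  +  k  +  noise,

where the sum runs over the target's candidate regulators, ``b_i`` is the
regulatory ability of TF ``i`` (its sign encodes activation vs. repression),
``beta`` the first-order degradation rate of the target transcript and ``k``
its basal production rate.  The regulatory input ``x_i(t)`` is a sigmoid
(logistic) function of the TF's own expression level, modelling a binding
threshold on the promoter:

    x_i(t) = 1 / (1 + exp(-r * (z_i(t) - m_i) / s_i)),

with ``m_i`` the mean and ``s_i`` the standard deviation of the TF profile
(``s_i`` standardisation makes the transition rate ``r`` scale-free; it can
be switched off for the unscaled convention).

Because the experimental design samples only a handful of non-uniform time
points, identification proceeds on an interpolation of the
replicate-averaged profiles resampled to a uniform grid (by default a
natural cubic spline in log-shifted time, matching the roughly geometric
sampling design; see :func:`interpolate_profile`).  A forward difference of
the target profile then turns the ODE into a linear regression, with the
design evaluated at interval midpoints so the discretisation error is
O(step^2); the maximum-likelihood solution (under i.i.d. Gaussian noise) is
ordinary least squares.  Model order — which regulators to keep — is selected by
minimising the Akaike information criterion, either by greedy backward
elimination (remove the regulator whose deletion lowers AIC most, stop when
no deletion improves) or by exhaustive subset search.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.special import expit
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin

from .dataset import ExpressionDataset, TimeSeriesExpression, normalize_gene_id
from .errors import (
    AlignmentError,
    GridError,
    IdentifiabilityError,
    SingularityError,
)

__all__ = [
    "SigmoidParams",
    "RegressionSystem",
    "RegulationFit",
    "AICRegulatorPruner",
    "interpolate_profile",
    "sigmoid_activity",
    "build_regression_system",
    "ml_fit",
    "aic_score",
    "prune_regulators",
    "refine_network",
]

#: variance floor guarding ln(0) in the AIC
EPS_FLOOR = 1e-12

#: largest candidate-set size for which exhaustive subset search is allowed
EXHAUSTIVE_CAP = 12


# ---------------------------------------------------------------------------
# sigmoid calibration


@dataclass(frozen=True)
class SigmoidParams:
    """Calibration of the sigmoid regulatory function per TF.

    ``means[tf]`` is the mean of that TF's expression profile and
    ``scales[tf]`` its standard deviation (all ones when ``standardize`` is
    off).  ``r`` is the transition rate of the sigmoid.
    """

    r: float
    means: Mapping[str, float]
    scales: Mapping[str, float]
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.r <= 0:
            raise ValueError("sigmoid transition rate r must be positive")
        for tf, s in self.scales.items():
            if s <= 0:
                raise ValueError(f"sigmoid scale for {tf!r} must be positive")

    @classmethod
    def from_profiles(
        cls,
        profiles: Mapping[str, np.ndarray],
        r: float = 1.0,
        standardize: bool = True,
    ) -> "SigmoidParams":
        """Calibrate from TF expression vectors (mean and sd per TF).

        A constant profile has zero sd; its scale falls back to 1 so the
        sigmoid stays defined (the resulting constant activity column is
        caught later as collinear with the intercept).
        """
        means = {}
        scales = {}
        for tf, z in profiles.items():
            z = np.asarray(z, dtype=float)
            means[tf] = float(z.mean())
            sd = float(z.std())
            scales[tf] = sd if (standardize and sd > 0) else 1.0
        return cls(r=r, means=means, scales=scales, standardize=standardize)


def sigmoid_activity(z, params: SigmoidParams, tf: str):
    """Sigmoid regulatory activity of TF ``tf`` at expression level ``z``.

    Returns values strictly inside (0, 1); saturates gracefully for extreme
    arguments.
    """
    m = params.means[tf]
    s = params.scales[tf]
    return expit(params.r * (np.asarray(z, dtype=float) - m) / s)


# ---------------------------------------------------------------------------
# interpolation to a uniform inference grid


INTERP_KINDS = ("log-cubic", "cubic", "pchip", "linear")


def interpolate_profile(
    profile: TimeSeriesExpression, step: float, kind: str = "log-cubic"
) -> TimeSeriesExpression:
    """Resample a replicate-averaged profile onto a uniform grid.

    An interpolant through the replicate-averaged design-time values is
    evaluated from the first to the last design time at spacing ``step``
    (hours).  Design-time values are reproduced exactly (interpolation,
    not smoothing).  Two-point profiles fall back to linear interpolation.

    ``kind`` selects the interpolant.  The default ``"log-cubic"`` is a
    natural cubic spline in the log-shifted time coordinate
    ``u = ln(1 + t - t0)``: sampling designs for shift-response kinetics
    are approximately geometric in time, so the knots are near-uniform in
    ``u`` and the large overshoot a plain cubic develops across the long
    late-time gap is suppressed.  ``"cubic"`` is the plain natural cubic
    spline in ``t``; ``"pchip"`` is shape-preserving; ``"linear"`` is
    piecewise linear.
    """
    if step <= 0:
        raise GridError("interpolation step must be positive")
    if kind not in INTERP_KINDS:
        raise ValueError(f"unknown interpolation kind {kind!r}; choose from {INTERP_KINDS}")
    times = profile.times
    if times.size < 2:
        raise GridError(f"{profile.gene!r}: at least two time points required")
    span = times[-1] - times[0]
    if step > span:
        raise GridError(
            f"{profile.gene!r}: step {step} exceeds the profile span {span}"
        )
    mean = profile.mean_profile()
    n = int(math.floor(span / step + 1e-9)) + 1
    grid = times[0] + step * np.arange(n)
    if times.size == 2 or kind == "linear":
        values = np.interp(grid, times, mean)
    elif kind == "log-cubic":
        u = np.log1p(times - times[0])
        values = CubicSpline(u, mean, bc_type="natural")(np.log1p(grid - times[0]))
    elif kind == "pchip":
        from scipy.interpolate import PchipInterpolator

        values = PchipInterpolator(times, mean)(grid)
    else:
        values = CubicSpline(times, mean, bc_type="natural")(grid)
    return TimeSeriesExpression(profile.gene, grid, values[:, None])


# ---------------------------------------------------------------------------
# regression system


@dataclass(frozen=True, eq=False)
class RegressionSystem:
    """Discretised linear system for one target gene.

    ``response[j] = (y[j+1] - y[j]) / step`` and the design row ``j`` is
    ``(x_1[j], ..., x_L[j], -y[j], 1)``; ``labels`` names every design
    column (TF identifiers, then ``"-y"`` and ``"const"``).
    """

    target: str
    grid: np.ndarray
    response: np.ndarray
    design: np.ndarray
    labels: tuple[str, ...]

    @property
    def n_obs(self) -> int:
        return self.response.shape[0]

    @property
    def n_params(self) -> int:
        return self.design.shape[1]

    @property
    def regulators(self) -> tuple[str, ...]:
        return self.labels[:-2]


def build_regression_system(
    target: TimeSeriesExpression,
    regulators: Mapping[str, TimeSeriesExpression],
    params: SigmoidParams,
    step: float,
    collocation: str = "midpoint",
) -> RegressionSystem:
    """Assemble the difference regression for one target.

    The response for row ``j`` is the forward difference
    ``(y[j+1] - y[j]) / step``, an O(step^2)-accurate estimate of the
    derivative at the interval midpoint; with ``collocation="midpoint"``
    (default) the design is evaluated there too (TF activities and the
    target level averaged over the interval ends), keeping the
    discretisation error at O(step^2).  ``collocation="left"`` evaluates
    the design at the left grid point (explicit-Euler convention,
    O(step) bias).  All profiles must already live on the same uniform
    grid (see :func:`interpolate_profile`).
    """
    if collocation not in ("midpoint", "left"):
        raise ValueError(f"unknown collocation {collocation!r}")
    grid = target.times
    if grid.size < 2:
        raise GridError(f"{target.gene!r}: at least two grid points required")
    y = target.mean_profile()

    def at_rows(v: np.ndarray) -> np.ndarray:
        return (v[:-1] + v[1:]) / 2 if collocation == "midpoint" else v[:-1]

    labels: list[str] = []
    columns: list[np.ndarray] = []
    for tf in sorted(regulators):
        prof = regulators[tf]
        if not np.array_equal(prof.times, grid):
            raise AlignmentError(
                f"regulator {tf!r} is not on the same grid as target {target.gene!r}"
            )
        columns.append(sigmoid_activity(at_rows(prof.mean_profile()), params, tf))
        labels.append(normalize_gene_id(tf))
    columns.append(-at_rows(y))
    labels.append("-y")
    columns.append(np.ones(grid.size - 1))
    labels.append("const")
    response = np.diff(y) / step
    design = np.column_stack(columns)
    return RegressionSystem(
        target=target.gene,
        grid=grid,
        response=response,
        design=design,
        labels=tuple(labels),
    )


# ---------------------------------------------------------------------------
# maximum-likelihood fit and AIC


@dataclass(frozen=True, eq=False)
class RegulationFit:
    """Fitted regulation model for one target gene.

    ``trace`` records the elimination path: the first entry is
    ``(None, AIC of the full candidate model)`` and each subsequent entry
    ``(removed_tf, AIC after the removal)`` is an accepted deletion.
    """

    target: str
    regulators: tuple[str, ...]
    b: Mapping[str, float]
    beta: float
    k: float
    sigma2: float
    loglik: float
    aic: float
    n_obs: int
    trace: tuple = ()
    flags: tuple[str, ...] = ()

    def with_trace(self, trace) -> "RegulationFit":
        return RegulationFit(
            target=self.target, regulators=self.regulators, b=self.b,
            beta=self.beta, k=self.k, sigma2=self.sigma2, loglik=self.loglik,
            aic=self.aic, n_obs=self.n_obs, trace=tuple(trace), flags=self.flags,
        )


def aic_score(sigma2: float, n_obs: int, n_params: int, eps_floor: float = EPS_FLOOR) -> float:
    """AIC = n * ln(max(sigma2, eps_floor)) + 2 * P.

    ``P`` counts the regression coefficients (the b_i's, beta and k); the
    noise variance is not counted, a convention that only needs to be
    internally consistent since additive constants cancel in comparisons.
    """
    if n_obs <= 0:
        raise ValueError("n_obs must be positive")
    return n_obs * math.log(max(sigma2, eps_floor)) + 2 * n_params


def ml_fit(system: RegressionSystem, eps_floor: float = EPS_FLOOR) -> RegulationFit:
    """Maximum-likelihood fit of the discretised regulation model.

    Under i.i.d. zero-mean Gaussian noise the ML coefficient estimates are
    the least-squares solution; ``sigma2 = RSS / N`` and the maximised
    log-likelihood is ``-(N/2) (ln(2 pi sigma2) + 1)``.
    """
    A = system.design
    b_vec = system.response
    n, p = A.shape
    if n < p:
        raise IdentifiabilityError(
            f"{system.target!r}: {n} observations cannot identify {p} parameters"
        )
    coef, _, rank, _ = np.linalg.lstsq(A, b_vec, rcond=None)
    if rank < p:
        bad = _collinear_columns(A, system.labels)
        raise SingularityError(
            f"{system.target!r}: rank-deficient design (collinear columns: "
            f"{', '.join(bad)})",
            columns=bad,
        )
    resid = b_vec - A @ coef
    sigma2 = float(resid @ resid) / n
    flags: list[str] = []
    sigma2_eff = sigma2
    if sigma2 < eps_floor:
        sigma2_eff = eps_floor
        flags.append("sigma2_floored")
    loglik = -0.5 * n * (math.log(2 * math.pi * sigma2_eff) + 1.0)
    aic = aic_score(sigma2, n, p, eps_floor)
    regs = system.regulators
    b = {tf: float(coef[i]) for i, tf in enumerate(regs)}
    beta = float(coef[-2])
    k = float(coef[-1])
    if beta <= 0:
        flags.append("beta_nonpositive")
    return RegulationFit(
        target=system.target,
        regulators=regs,
        b=b,
        beta=beta,
        k=k,
        sigma2=sigma2,
        loglik=loglik,
        aic=aic,
        n_obs=n,
        trace=((None, aic),),
        flags=tuple(flags),
    )


def _collinear_columns(A: np.ndarray, labels: Sequence[str]) -> list[str]:
    """Name the design columns responsible for rank deficiency (QR pivots)."""
    from scipy.linalg import qr

    _, R, piv = qr(A, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = max(A.shape) * np.finfo(float).eps * (diag.max() if diag.size else 0.0)
    rank = int((diag > tol).sum())
    return sorted(labels[i] for i in piv[rank:])


# ---------------------------------------------------------------------------
# AIC-based regulator pruning


def _fit_subset(
    target: TimeSeriesExpression,
    regulators: Mapping[str, TimeSeriesExpression],
    subset: Iterable[str],
    params: SigmoidParams,
    step: float,
    eps_floor: float,
    n_eff: int | None = None,
    collocation: str = "midpoint",
) -> RegulationFit:
    chosen = {tf: regulators[tf] for tf in subset}
    system = build_regression_system(target, chosen, params, step, collocation)
    fit = ml_fit(system, eps_floor)
    if n_eff is not None and n_eff != fit.n_obs:
        # model-selection AIC at the effective (measured) sample size: rows of
        # a spline-upsampled system are not independent observations
        aic = aic_score(fit.sigma2, n_eff, system.n_params, eps_floor)
        fit = dataclasses.replace(fit, aic=aic, trace=((None, aic),))
    return fit


def _greedy_backward(target, regulators, params, step, eps_floor, n_eff, collocation) -> RegulationFit:
    current = _fit_subset(target, regulators, sorted(regulators), params, step, eps_floor, n_eff, collocation)
    trace = [(None, current.aic)]
    active = sorted(current.regulators)
    while active:
        best_removed = None
        best_fit = None
        for tf in active:  # lexicographic order fixes ties
            subset = [t for t in active if t != tf]
            try:
                fit = _fit_subset(target, regulators, subset, params, step, eps_floor, n_eff, collocation)
            except SingularityError:
                continue
            if best_fit is None or fit.aic < best_fit.aic:
                best_fit, best_removed = fit, tf
        if best_fit is None or best_fit.aic >= current.aic:
            break
        current = best_fit
        active = [t for t in active if t != best_removed]
        trace.append((best_removed, current.aic))
    return current.with_trace(trace)


def _exhaustive(target, regulators, params, step, eps_floor, n_eff, collocation) -> RegulationFit:
    ids = sorted(regulators)
    best: RegulationFit | None = None
    # subsets ordered by (size, lexicographic): with a strict comparison the
    # first of any AIC tie wins, i.e. the smaller model, then lexicographic.
    for size in range(len(ids) + 1):
        for subset in itertools.combinations(ids, size):
            try:
                fit = _fit_subset(target, regulators, subset, params, step, eps_floor, n_eff, collocation)
            except SingularityError:
                continue
            if best is None or fit.aic < best.aic:
                best = fit
    if best is None:
        raise SingularityError(f"{target.gene!r}: every candidate subset is singular")
    return best


def prune_regulators(
    target: TimeSeriesExpression,
    candidates: Iterable[str],
    dataset: ExpressionDataset,
    *,
    mode: str = "greedy_backward",
    step: float = 0.5,
    r: float = 1.0,
    standardize: bool = True,
    exhaustive_cap: int = EXHAUSTIVE_CAP,
    eps_floor: float = EPS_FLOOR,
    n_eff: int | str | None = None,
    interp_kind: str = "log-cubic",
    collocation: str = "midpoint",
) -> RegulationFit:
    """Select a target's regulators by AIC minimisation.

    ``candidates`` is the target's rough-network regulator set; profiles are
    pulled from ``dataset``, interpolated to a uniform grid of spacing
    ``step`` and pruned in ``mode`` (``"greedy_backward"`` or
    ``"exhaustive"``).  An empty candidate set returns the regulator-free
    fit (degradation and basal terms only).

    ``n_eff`` is the sample size at which the model-selection AIC is
    evaluated.  The default ``None`` scores at the regression row count.
    Because the rows of a spline-upsampled system are strongly dependent,
    that convention is liberal (it favours retaining candidates);
    ``"design"`` scores at the number of measured design intervals
    (T - 1), a conservative alternative, and an integer overrides either.
    """
    cand = sorted({normalize_gene_id(c) for c in candidates})
    if n_eff == "design":
        n_eff = target.n_times - 1
    target_i = interpolate_profile(target, step, interp_kind)
    reg_i = {c: interpolate_profile(dataset[c], step, interp_kind) for c in cand}
    params = SigmoidParams.from_profiles(
        {c: p.mean_profile() for c, p in reg_i.items()}, r=r, standardize=standardize
    )
    return _prune_interpolated(
        target_i, reg_i, params, mode=mode, step=step,
        exhaustive_cap=exhaustive_cap, eps_floor=eps_floor, n_eff=n_eff,
        collocation=collocation,
    )


def _prune_interpolated(
    target_i, reg_i, params, *, mode, step, exhaustive_cap, eps_floor, n_eff=None,
    collocation="midpoint",
) -> RegulationFit:
    if mode not in ("greedy_backward", "exhaustive"):
        raise ValueError(f"unknown pruning mode {mode!r}")
    if not reg_i:
        return _fit_subset(target_i, {}, (), params, step, eps_floor, n_eff, collocation)
    if mode == "exhaustive" and len(reg_i) > exhaustive_cap:
        warnings.warn(
            f"{target_i.gene!r}: {len(reg_i)} candidates exceed the exhaustive "
            f"cap of {exhaustive_cap}; falling back to greedy backward elimination",
            RuntimeWarning,
            stacklevel=2,
        )
        mode = "greedy_backward"
    if mode == "exhaustive":
        return _exhaustive(target_i, reg_i, params, step, eps_floor, n_eff, collocation)
    return _greedy_backward(target_i, reg_i, params, step, eps_floor, n_eff, collocation)


# ---------------------------------------------------------------------------
# scikit-learn estimator


class AICRegulatorPruner(SelectorMixin, BaseEstimator):
    """Feature selector implementing ML + AIC regulator pruning.

    Given TF expression trajectories (columns of ``X``) and a target
    trajectory ``y`` sampled on a shared uniform time grid of spacing
    ``step`` hours, `fit` estimates the dynamic regulation model by least
    squares (the Gaussian ML solution) and selects the regulator subset
    minimising the AIC.  The estimator composes with scikit-learn
    pipelines as a feature selector: `transform` keeps the surviving
    regulator columns.

    Parameters
    ----------
    step : float, default=0.5
        Grid spacing of the supplied trajectories, in hours.
    r : float, default=1.0
        Sigmoid transition rate.
    standardize : bool, default=True
        Standardise each TF by its profile sd inside the sigmoid, making
        ``r`` scale-free.
    mode : {"greedy_backward", "exhaustive"}, default="greedy_backward"
        Subset-search strategy.
    exhaustive_cap : int, default=12
        Largest candidate count for which exhaustive search is permitted;
        beyond it greedy elimination is forced with a warning.
    eps_floor : float, default=1e-12
        Variance floor guarding ``ln(0)`` in the AIC.
    n_eff : int or None, default=None
        Sample size at which the model-selection AIC is evaluated.  Leave
        ``None`` when the rows of ``X`` are real measurements; when the
        trajectories were spline-upsampled from T design points, pass
        ``T - 1`` so the AIC reflects the measured information.

    Attributes
    ----------
    support_ : bool ndarray of shape (n_candidates,)
        Mask of surviving regulators.
    b_ : ndarray of shape (n_candidates,)
        Regulatory abilities; zero for pruned regulators.
    beta_ : float
        Degradation rate estimate (1/h).
    k_ : float
        Basal production estimate (expression units/h).
    sigma2_, loglik_, aic_ : float
        Residual variance, log-likelihood and AIC of the selected model.
    elimination_trace_ : tuple
        ``(removed_tf, AIC)`` pairs along the accepted elimination path.
    fit_result_ : RegulationFit
        The full fit record.
    """

    def __init__(
        self,
        step: float = 0.5,
        r: float = 1.0,
        standardize: bool = True,
        mode: str = "greedy_backward",
        exhaustive_cap: int = EXHAUSTIVE_CAP,
        eps_floor: float = EPS_FLOOR,
        n_eff: int | None = None,
        collocation: str = "midpoint",
    ):
        self.step = step
        self.r = r
        self.standardize = standardize
        self.mode = mode
        self.exhaustive_cap = exhaustive_cap
        self.eps_floor = eps_floor
        self.n_eff = n_eff
        self.collocation = collocation

    def fit(self, X, y):
        names = getattr(X, "columns", None)
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional (time points x candidate TFs)")
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y must have the same number of time points")
        if X.shape[0] < 2:
            raise ValueError("at least two time points are required")
        if names is not None:
            names = [normalize_gene_id(c) for c in names]
            self.feature_names_in_ = np.asarray(list(names), dtype=object)
        else:
            names = [f"TF{i + 1:03d}" for i in range(X.shape[1])]
        self.n_features_in_ = X.shape[1]

        grid = self.step * np.arange(X.shape[0])
        target_i = TimeSeriesExpression("__TARGET__", grid, y[:, None])
        reg_i = {
            name: TimeSeriesExpression(name, grid, X[:, j][:, None])
            for j, name in enumerate(names)
        }
        params = SigmoidParams.from_profiles(
            {n: p.mean_profile() for n, p in reg_i.items()},
            r=self.r,
            standardize=self.standardize,
        )
        fit = _prune_interpolated(
            target_i, reg_i, params, mode=self.mode, step=self.step,
            exhaustive_cap=self.exhaustive_cap, eps_floor=self.eps_floor,
            n_eff=self.n_eff, collocation=self.collocation,
        )
        surviving = set(fit.regulators)
        self.support_ = np.array([n in surviving for n in names], dtype=bool)
        self.b_ = np.array([fit.b.get(n, 0.0) for n in names])
        self.beta_ = fit.beta
        self.k_ = fit.k
        self.sigma2_ = fit.sigma2
        self.loglik_ = fit.loglik
        self.aic_ = fit.aic
        self.elimination_trace_ = fit.trace
        self.fit_result_ = fit
        return self

    def _get_support_mask(self):
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "support_")
        return self.support_


# ---------------------------------------------------------------------------
# network-level refinement


def refine_network(
    rough,
    dataset: ExpressionDataset,
    *,
    mode: str = "greedy_backward",
    step: float = 0.5,
    r: float = 1.0,
    standardize: bool = True,
    exhaustive_cap: int = EXHAUSTIVE_CAP,
    eps_floor: float = EPS_FLOOR,
    n_eff: int | str | None = None,
    interp_kind: str = "log-cubic",
    collocation: str = "midpoint",
    logger=None,
):
    """Prune every target of a rough network independently; assemble the result.

    Surviving edges carry weight ``b_i`` and sign (activation for positive,
    repression for negative regulatory ability).  Per-target failures
    (rank-deficient designs) are logged and that target is emitted with an
    empty regulator set rather than aborting the run.  Returns a
    :class:`~lightgrn.compare.GeneNetwork` with per-target fits attached.
    """
    from .compare import GeneNetwork

    regulator_sets = rough.regulator_sets()
    tf_ids = {e.tf for e in rough.edges}
    fits: dict[str, RegulationFit] = {}
    edges = []
    for target in sorted(rough.genes):
        candidates = sorted(regulator_sets.get(target, set()))
        try:
            fit = prune_regulators(
                dataset[target], candidates, dataset,
                mode=mode, step=step, r=r, standardize=standardize,
                exhaustive_cap=exhaustive_cap, eps_floor=eps_floor, n_eff=n_eff,
                interp_kind=interp_kind, collocation=collocation,
            )
        except (SingularityError, IdentifiabilityError) as err:
            if logger is not None:
                logger.warning("target %s: %s; emitted regulator-free", target, err)
            fit = prune_regulators(
                dataset[target], (), dataset,
                mode=mode, step=step, r=r, standardize=standardize,
                exhaustive_cap=exhaustive_cap, eps_floor=eps_floor, n_eff=n_eff,
                interp_kind=interp_kind, collocation=collocation,
            )
        fits[target] = fit
        for tf in fit.regulators:
            w = fit.b[tf]
            edges.append((tf, target, w, "activates" if w > 0 else "represses"))
    net = GeneNetwork.from_edges(
        dataset.condition, edges, nodes=sorted(rough.genes), tf_ids=tf_ids
    )
    net.fits = fits
    return net
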