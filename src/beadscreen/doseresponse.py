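"""Dose-response curve fitting with AIC model selection and ED50 extraction.

The screening assay reads out binding as rMFI while a buffer covariate (for
example the NaCl concentration, 0-1000 mM) is varied.  The dependence of
binding on the covariate is summarized by fitting a family of non-linear
dose-response models by least squares, selecting among the candidates with
the Akaike information criterion, and reporting the half-maximal dose ED50.

Model families (``x`` is the dose, parameters follow the b/c/d/e/f naming
conventional in dose-response analysis: b slope, c lower asymptote, d upper
asymptote, e location in dose units, f asymmetry):

========  ============================================  =================
name      response f(x)                                 free parameters
========  ============================================  =================
LL.2      1 / (1 + (x/e)^b)           (c=0, d=1)        b, e
LL.3      d / (1 + (x/e)^b)           (c=0)             b, d, e
LL.4      c + (d-c) / (1 + (x/e)^b)                     b, c, d, e
LL.5      c + (d-c) / (1 + (x/e)^b)^f                   b, c, d, e, f
W1.2      exp(-(x/e)^b)               (c=0, d=1)        b, e
W1.3      d exp(-(x/e)^b)             (c=0)             b, d, e
W1.4      c + (d-c) exp(-(x/e)^b)                       b, c, d, e
W2.3      d (1 - exp(-(x/e)^b))       (c=0)             b, d, e
W2.4      c + (d-c)(1 - exp(-(x/e)^b))                  b, c, d, e
EXD.2     d exp(-x/e)                                   d, e
EXD.3     c + (d-c) exp(-x/e)                           c, d, e
========  ============================================  =================

The two-parameter models with fixed asymptotes (LL.2, W1.2) are fitted on
max-normalized responses; the normalization factor is recorded and the fit
is compared with the other candidates on the original response scale, so the
AIC ranking is consistent.  The default candidate list contains exactly
these eleven families.

ED50 is the dose at which the fitted response is halfway between the lower
and upper asymptotes.  Closed forms: log-logistic families give ``e``
(general LL.5: ``e*(2**(1/f)-1)**(1/b)``), both Weibull types give
``e*ln(2)**(1/b)`` and the exponential-decay models give ``e*ln(2)``.  A
numerical bisection on the fitted curve is available as a cross-check and as
the fallback for curves without a closed form.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "DoseResponseDataset",
    "ModelSpec",
    "FittedModel",
    "MODEL_SPECS",
    "DEFAULT_CANDIDATES",
    "DegenerateDataError",
    "FitFailureError",
    "predict",
    "fit_model",
    "select_model",
    "ed50",
    "ed50_bisection",
]

_PARAM_ORDER = ("b", "c", "d", "e", "f")


class DegenerateDataError(ValueError):
    """Raised when responses carry no information to fit (all equal)."""


class FitFailureError(RuntimeError):
    """Raised when no candidate model could be fitted."""

    def __init__(self, failures: dict[str, str]):
        self.failures = failures
        lines = ", ".join(f"{k}: {v}" for k, v in failures.items())
        super().__init__(f"all candidate fits failed ({lines})")


@dataclass(frozen=True)
class ModelSpec:
    """A dose-response model family.

    ``fixed`` holds parameters constrained by the family definition (for
    example ``c=0`` for LL.3); ``free`` lists the fitted parameter names.
    ``normalized`` marks families defined on a 0-1 response scale, which are
    fitted to max-normalized responses.
    """

    name: str
    free: tuple[str, ...]
    fixed: Mapping[str, float]
    fn: Callable[[np.ndarray, Mapping[str, float]], np.ndarray]
    ed50_closed_form: Callable[[Mapping[str, float]], float] | None
    normalized: bool = False

    @property
    def n_free(self) -> int:
        return len(self.free)

    def __repr__(self) -> str:  # keep reprs short in AIC tables
        return f"ModelSpec({self.name})"


def _ll(x: np.ndarray, p: Mapping[str, float]) -> np.ndarray:
    b, c, d, e = p["b"], p["c"], p["d"], p["e"]
    f = p.get("f", 1.0)
    with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
        t = np.power(np.asarray(x, dtype=float) / e, b)
        out = c + (d - c) / np.power(1.0 + t, f)
    # x = 0 with b > 0 gives t = 0 -> d; with b < 0 gives t = inf -> c
    return np.where(np.isfinite(out), out, c)


def _w1(x: np.ndarray, p: Mapping[str, float]) -> np.ndarray:
    b, c, d, e = p["b"], p["c"], p["d"], p["e"]
    with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
        t = np.power(np.asarray(x, dtype=float) / e, b)
        out = c + (d - c) * np.exp(-t)
    return np.where(np.isfinite(out), out, c)


def _w2(x: np.ndarray, p: Mapping[str, float]) -> np.ndarray:
    b, c, d, e = p["b"], p["c"], p["d"], p["e"]
    with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
        t = np.power(np.asarray(x, dtype=float) / e, b)
        out = c + (d - c) * (1.0 - np.exp(-t))
    return np.where(np.isfinite(out), out, d)


def _exd(x: np.ndarray, p: Mapping[str, float]) -> np.ndarray:
    c, d, e = p.get("c", 0.0), p["d"], p["e"]
    return c + (d - c) * np.exp(-np.asarray(x, dtype=float) / e)


def _ed50_ll(p: Mapping[str, float]) -> float:
    f = p.get("f", 1.0)
    if f == 1.0:
        return float(p["e"])
    return float(p["e"] * (2.0 ** (1.0 / f) - 1.0) ** (1.0 / p["b"]))


def _ed50_weibull(p: Mapping[str, float]) -> float:
    return float(p["e"] * np.log(2.0) ** (1.0 / p["b"]))


def _ed50_exd(p: Mapping[str, float]) -> float:
    return float(p["e"] * np.log(2.0))


MODEL_SPECS: dict[str, ModelSpec] = {
    "LL.2": ModelSpec("LL.2", ("b", "e"), {"c": 0.0, "d": 1.0}, _ll, _ed50_ll, True),
    "LL.3": ModelSpec("LL.3", ("b", "d", "e"), {"c": 0.0}, _ll, _ed50_ll),
    "LL.4": ModelSpec("LL.4", ("b", "c", "d", "e"), {}, _ll, _ed50_ll),
    "LL.5": ModelSpec("LL.5", ("b", "c", "d", "e", "f"), {}, _ll, _ed50_ll),
    "W1.2": ModelSpec("W1.2", ("b", "e"), {"c": 0.0, "d": 1.0}, _w1, _ed50_weibull, True),
    "W1.3": ModelSpec("W1.3", ("b", "d", "e"), {"c": 0.0}, _w1, _ed50_weibull),
    "W1.4": ModelSpec("W1.4", ("b", "c", "d", "e"), {}, _w1, _ed50_weibull),
    "W2.3": ModelSpec("W2.3", ("b", "d", "e"), {"c": 0.0}, _w2, _ed50_weibull),
    "W2.4": ModelSpec("W2.4", ("b", "c", "d", "e"), {}, _w2, _ed50_weibull),
    "EXD.2": ModelSpec("EXD.2", ("d", "e"), {"c": 0.0}, _exd, _ed50_exd),
    "EXD.3": ModelSpec("EXD.3", ("c", "d", "e"), {}, _exd, _ed50_exd),
}

#: the default eleven-member candidate list for model selection; exponential
#: decay precedes the Weibull families so that exact ties between
#: observationally equivalent curves (W1 with unit slope == EXD) resolve to
#: the more parsimonious parameterization
DEFAULT_CANDIDATES: tuple[str, ...] = (
    "LL.2", "LL.3", "LL.4", "LL.5",
    "EXD.2", "EXD.3",
    "W1.2", "W1.3", "W1.4", "W2.3", "W2.4",
)


@dataclass(frozen=True)
class DoseResponseDataset:
    """Doses with replicate responses for one aptamer/population.

    ``dose`` and ``response`` are parallel arrays (replicates appear as
    repeated doses).  ``dose_unit`` is declarative only (mM, nM, ...).
    """

    dose: np.ndarray
    response: np.ndarray
    label: str = ""
    dose_unit: str = "mM"

    def __post_init__(self) -> None:
        dose = np.asarray(self.dose, dtype=float).ravel()
        resp = np.asarray(self.response, dtype=float).ravel()
        if dose.shape != resp.shape:
            raise ValueError("dose and response must have equal length")
        if dose.size < 2:
            raise ValueError("need at least two observations")
        if np.any(dose < 0):
            raise ValueError("doses must be non-negative")
        if not np.all(np.isfinite(resp)):
            raise ValueError("responses must be finite")
        object.__setattr__(self, "dose", dose)
        object.__setattr__(self, "response", resp)

    @property
    def n_distinct_doses(self) -> int:
        return int(np.unique(self.dose).size)


@dataclass(frozen=True)
class FittedModel:
    """A least-squares dose-response fit.

    ``parameters`` contains the full parameter set, with fixed parameters
    reported at their fixed values.  ``normalization`` is the max-response
    factor used for families defined on a 0-1 scale (1.0 otherwise); ``rss``
    and ``aic`` are always on the original response scale.  ``ed50`` carries
    the half-maximal dose in the dataset's dose units.
    """

    spec: ModelSpec
    parameters: dict[str, float]
    rss: float
    n: int
    aic: float
    converged: bool
    normalization: float = 1.0
    message: str = ""
    ed50: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "ed50", _closed_form_ed50(self))

    def predict(self, x: np.ndarray | float) -> np.ndarray | float:
        """Fitted response at dose ``x``, on the original response scale."""
        y = predict(self.spec, self.parameters, x)
        return y * self.normalization


def predict(
    spec: ModelSpec | str,
    parameters: Mapping[str, float],
    x: np.ndarray | float,
) -> np.ndarray | float:
    """Evaluate a model family at dose ``x``.

    Fixed parameters of the family may be omitted from ``parameters``.
    """
    if isinstance(spec, str):
        spec = MODEL_SPECS[spec]
    p = {**spec.fixed, **dict(parameters)}
    missing = [k for k in spec.free if k not in p]
    if missing:
        raise ValueError(f"{spec.name}: missing parameters {missing}")
    if p["e"] <= 0:
        raise ValueError(f"location parameter e must be positive, got {p['e']}")
    scalar = np.isscalar(x)
    xv = np.atleast_1d(np.asarray(x, dtype=float))
    if np.any(xv < 0):
        raise ValueError("doses must be non-negative")
    y = spec.fn(xv, p)
    return float(y[0]) if scalar else y


def _aic(rss: float, n: int, n_free: int, rss_floor: float) -> float:
    """AIC = n ln(RSS/n) + 2 (p+1); p free parameters plus error variance.

    RSS is floored so that near-perfect (noise-free) fits of nested models
    tie on the likelihood term and the parameter penalty decides.
    """
    rss_eff = max(float(rss), rss_floor)
    return n * np.log(rss_eff / n) + 2.0 * (n_free + 1)


def _starts(spec: ModelSpec, dose: np.ndarray, resp: np.ndarray) -> list[dict[str, float]]:
    """Self-starter heuristic grid: d near max response, c near min, e near
    the dose closest to the half-range crossing, slope b in {±0.5, ±1, ±2}."""
    d0 = float(resp.max())
    c0 = float(resp.min())
    half = 0.5 * (d0 + c0)
    pos = dose[dose > 0]
    e_half = float(pos[np.argmin(np.abs(resp[dose > 0] - half))]) if pos.size else 1.0
    e_med = float(np.median(pos)) if pos.size else 1.0
    e0 = e_half if e_half > 0 else e_med

    starts: list[dict[str, float]] = []
    if "b" in spec.free:
        for b0 in (0.5, 1.0, 2.0, -0.5, -1.0, -2.0):
            s = {"b": b0, "e": e0}
            if "c" in spec.free:
                s["c"] = c0
            if "d" in spec.free:
                s["d"] = 1.0 if spec.normalized else d0
            if spec.normalized:
                s["d"] = 1.0
            if "f" in spec.free:
                s["f"] = 1.0
            s = {k: v for k, v in s.items() if k in spec.free}
            starts.append(s)
    else:  # exponential decay: no slope parameter
        for e_start in (e0 / np.log(2.0), e_med, max(dose.max(), 1.0)):
            if e_start <= 0:
                continue
            s = {"d": d0, "e": float(e_start)}
            if "c" in spec.free:
                s["c"] = c0
            s = {k: v for k, v in s.items() if k in spec.free}
            starts.append(s)
    return starts


_BOUNDS = {
    "b": (-50.0, 50.0),
    "c": (-np.inf, np.inf),
    "d": (-np.inf, np.inf),
    "e": (1e-9, np.inf),
    "f": (1e-3, 1e3),
}


def fit_model(
    data: DoseResponseDataset,
    spec: ModelSpec | str,
    rss_floor_rel: float = 1e-10,
    xtol: float = 1e-12,
    ftol: float = 1e-10,
) -> FittedModel:
    """Fit one model family by multi-start non-linear least squares.

    The start grid is deterministic (no stochastic restarts); the best local
    optimum over the grid is returned.  ``rss_floor_rel`` scales the RSS
    floor used in the AIC (relative to the total response sum of squares) so
    interpolating fits of nested families tie on fit quality and are ranked
    by parameter count.

    Raises
    ------
    DegenerateDataError
        if all responses are identical (no curve to fit).
    ValueError
        if there are fewer distinct doses than free parameters + 1.
    """
    if isinstance(spec, str):
        spec = MODEL_SPECS[spec]
    dose = data.dose
    resp_orig = data.response
    if np.ptp(resp_orig) == 0.0:
        raise DegenerateDataError(
            f"{spec.name}: all responses equal ({resp_orig[0]}); degenerate fit"
        )
    if data.n_distinct_doses < spec.n_free + 1:
        raise ValueError(
            f"{spec.name} needs at least {spec.n_free + 1} distinct doses, "
            f"got {data.n_distinct_doses}"
        )

    if spec.normalized:
        norm = float(resp_orig.max())
        if norm <= 0:
            raise DegenerateDataError(
                f"{spec.name}: max response {norm} <= 0, cannot max-normalize"
            )
    else:
        norm = 1.0
    resp = resp_orig / norm

    free = spec.free

    def residuals(theta: np.ndarray) -> np.ndarray:
        p = {**spec.fixed, **dict(zip(free, theta))}
        return spec.fn(dose, p) - resp

    lb = np.array([_BOUNDS[k][0] for k in free])
    ub = np.array([_BOUNDS[k][1] for k in free])

    best_theta: np.ndarray | None = None
    best_cost = np.inf
    message = ""
    for start in _starts(spec, dose, resp):
        theta0 = np.clip(
            np.array([start[k] for k in free], dtype=float), lb + 1e-12, ub - 1e-12
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = least_squares(
                    residuals, theta0, bounds=(lb, ub),
                    xtol=xtol, ftol=ftol, gtol=1e-12, max_nfev=2000,
                )
            except Exception as exc:  # singular Jacobian, overflow, ...
                message = str(exc)
                continue
        if not np.all(np.isfinite(res.x)):
            continue
        cost = float(np.sum(res.fun**2))
        if cost < best_cost:
            best_cost, best_theta = cost, res.x.copy()

    if best_theta is None:
        return FittedModel(
            spec=spec, parameters=dict(spec.fixed), rss=np.inf, n=dose.size,
            aic=np.inf, converged=False, normalization=norm,
            message=message or "no start converged",
        )

    params = {**spec.fixed, **dict(zip(free, best_theta))}
    params = {k: float(params[k]) for k in _PARAM_ORDER if k in params}
    if spec.name == "LL.4" and params["b"] < 0:
        # exact reparameterization symmetry: (b, c, d) -> (-b, d, c) leaves
        # the curve unchanged; canonicalize so d is the zero-dose asymptote
        params["b"] = -params["b"]
        params["c"], params["d"] = params["d"], params["c"]
    # RSS on the original response scale for cross-family comparability
    rss = best_cost * norm**2
    n = int(dose.size)
    floor = rss_floor_rel * float(np.sum(resp_orig**2))
    # the max-normalization of fixed-asymptote families is a data-derived
    # scale, so it counts as one effective parameter in the AIC
    n_eff = spec.n_free + (1 if spec.normalized else 0)
    aic = _aic(rss, n, n_eff, max(floor, 1e-300))
    return FittedModel(
        spec=spec, parameters=params, rss=float(rss), n=n, aic=float(aic),
        converged=True, normalization=norm,
    )


def select_model(
    data: DoseResponseDataset,
    candidates: Sequence[ModelSpec | str] = DEFAULT_CANDIDATES,
    return_table: bool = False,
):
    """Fit every candidate family and return the lowest-AIC fit.

    Non-converged candidates are discarded.  Exact AIC ties are broken by
    fewest free parameters, then by candidate order.  With
    ``return_table=True`` the full list of fits (in candidate order,
    including failures) is returned alongside the winner for reporting.
    """
    if len(candidates) == 0:
        raise ValueError("candidate list must be non-empty")
    fits: list[FittedModel] = []
    failures: dict[str, str] = {}
    for cand in candidates:
        spec = MODEL_SPECS[cand] if isinstance(cand, str) else cand
        try:
            fit = fit_model(data, spec)
        except (DegenerateDataError, ValueError) as exc:
            failures[spec.name] = str(exc)
            fit = FittedModel(
                spec=spec, parameters=dict(spec.fixed), rss=np.inf,
                n=data.dose.size, aic=np.inf, converged=False, message=str(exc),
            )
        fits.append(fit)
        if not fit.converged:
            failures[spec.name] = fit.message

    converged = [f for f in fits if f.converged]
    if not converged:
        raise FitFailureError(failures)
    best = min(
        enumerate(converged),
        key=lambda item: (item[1].aic, item[1].spec.n_free, item[0]),
    )[1]
    if return_table:
        return best, fits
    return best


def ed50_bisection(
    fit: FittedModel,
    rel_tol: float = 1e-12,
    grid_size: int = 4096,
) -> tuple[float, bool]:
    """ED50 by bisection on the fitted curve; returns (dose, ambiguous).

    The midpoint between the fitted asymptotes is bracketed on a geometric
    dose grid spanning several decades around the location parameter; the
    smallest crossing is refined by bisection.  ``ambiguous`` is True when
    the fitted curve is non-monotone over the grid (several crossings can
    exist; the smallest is reported).
    """
    p = {**fit.spec.fixed, **fit.parameters}
    c = p.get("c", 0.0)
    d = p["d"]
    if d == c:
        raise ValueError("response range d - c is zero; ED50 undefined")
    target = 0.5 * (c + d)
    e = p["e"]
    grid = np.concatenate([[0.0], np.geomspace(e * 1e-6, e * 1e6, grid_size)])
    y = np.asarray(predict(fit.spec, fit.parameters, grid))
    diffs = np.diff(y)
    monotone = bool(np.all(diffs <= 1e-12 * abs(d - c)) or np.all(diffs >= -1e-12 * abs(d - c)))
    sign = np.sign(y - target)
    crossings = np.nonzero(sign[:-1] * sign[1:] <= 0)[0]
    if crossings.size == 0:
        raise ValueError("fitted curve does not cross its midpoint on the grid")
    i = int(crossings[0])
    lo, hi = grid[i], grid[i + 1]
    f_lo = y[i] - target
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        f_mid = float(predict(fit.spec, fit.parameters, mid)) - target
        if f_mid == 0.0 or (hi - lo) <= rel_tol * max(hi, 1e-30):
            return mid, not monotone
        if (f_lo > 0) == (f_mid > 0):
            lo, f_lo = mid, f_mid
        else:
            hi = mid
    return 0.5 * (lo + hi), not monotone


def _closed_form_ed50(fit: FittedModel) -> float:
    p = {**fit.spec.fixed, **fit.parameters}
    if not fit.converged or not np.isfinite(p.get("e", np.nan)):
        return float("nan")
    if fit.spec.ed50_closed_form is not None:
        return fit.spec.ed50_closed_form(p)
    return ed50_bisection(fit)[0]


def ed50(fit: FittedModel) -> float:
    """Half-maximal dose of a converged fit, in the dataset's dose units.

    Uses the family's closed form where one exists (all eleven default
    families have one), numeric bisection otherwise.
    """
    if not fit.converged:
        raise ValueError("cannot compute ED50 of a non-converged fit")
    return _closed_form_ed50(fit)
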