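"""Inverse engine: parametric sweep, quadratic response surface, cost
minimization, acquisition-time (delta-t) ambiguity scan.

The volumetric metamodel is the full quadratic in the wall constants,

    dV_num(a, b) = alpha1 a^2 + alpha2 b^2 + alpha3 a + alpha4 b
                   + alpha5 a b + alpha6,

fitted by ordinary least squares over a sweep of (a, b) couples, and the
cost function FC(a, b) = |dV_num(a, b) - dV_exp| is minimized over the
sampled parameter box.  Because matching a single scalar generically
admits a zero-level curve, per-load minimization breaks ties toward the
literature anchor for unruptured aneurysm walls (a = 353.6 kPa, b = 16.7);
the statistically identifiable default is the joint mode, which minimizes
the sum of squared costs across the three stimulus flow rates and then
polishes the surface minimizer against the forward model itself
(Gauss-Newton on the true residuals), removing the metamodel's
approximation bias from the point estimate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, minimize

from .exceptions import ExtrapolationError, ValidationError

__all__ = [
    "DEFAULT_A_RANGE",
    "DEFAULT_B_RANGE",
    "LITERATURE_ANCHOR",
    "DEFAULT_DT_GRID",
    "ParameterGrid",
    "ResponseSurface",
    "IdentificationResult",
    "ScanResult",
    "design_grid",
    "fit_response_surface",
    "cost",
    "minimize_cost",
    "identify",
    "scan_delta_t",
]

log = logging.getLogger(__name__)

DEFAULT_A_RANGE = (85.0, 645.0)  # kPa
DEFAULT_B_RANGE = (14.4, 17.6)
#: literature wall constants for unruptured aneurysms, used as tie-break anchor
LITERATURE_ANCHOR = (353.6, 16.7)
DEFAULT_DT_GRID = tuple(np.round(np.arange(0.01, 0.0701, 0.01), 4))


@dataclass(frozen=True)
class ParameterGrid:
    """Sweep design over the (a, b) box."""

    couples: np.ndarray  # (n, 2)
    a_range: tuple[float, float] = DEFAULT_A_RANGE
    b_range: tuple[float, float] = DEFAULT_B_RANGE
    layout: str = "grid"
    seed: int | None = None

    def __post_init__(self) -> None:
        c = np.asarray(self.couples, dtype=float).reshape(-1, 2)
        object.__setattr__(self, "couples", c)
        if len(c) < 6:
            raise ValidationError("need at least 6 couples to identify six coefficients")
        a, b = c[:, 0], c[:, 1]
        eps = 1e-9
        if a.min() < self.a_range[0] - eps or a.max() > self.a_range[1] + eps:
            raise ValidationError("a couples outside the declared range")
        if b.min() < self.b_range[0] - eps or b.max() > self.b_range[1] + eps:
            raise ValidationError("b couples outside the declared range")

    @property
    def n(self) -> int:
        return len(self.couples)


def _scaling(a_range, b_range) -> tuple[float, float, float, float]:
    """Affine normalization (center, half-width) per axis, mapping to [-1, 1]."""
    a0 = 0.5 * (a_range[0] + a_range[1])
    sa = 0.5 * (a_range[1] - a_range[0])
    b0 = 0.5 * (b_range[0] + b_range[1])
    sb = 0.5 * (b_range[1] - b_range[0])
    return a0, sa, b0, sb


def _basis(xa: np.ndarray, xb: np.ndarray) -> np.ndarray:
    """Quadratic basis [x_a^2, x_b^2, x_a, x_b, x_a x_b, 1]."""
    one = np.ones_like(xa)
    return np.stack([xa**2, xb**2, xa, xb, xa * xb, one], axis=-1)


def _lattice_selection(n: int, a_range, b_range) -> np.ndarray:
    """Deterministic 'grid' layout of n couples including the four corners.

    Uses an exact na x nb tensor lattice (>= 3 levels per axis) when n
    factors that way; otherwise selects n points from the smallest such
    lattice, corners first, then center and edge midpoints, then row-major
    interior fill.
    """
    pairs = [(na, n // na) for na in range(3, n + 1) if n % na == 0 and n // na >= 3]
    if pairs:
        na, nb = max(pairs, key=lambda p: (min(p), -abs(p[0] - p[1])))
        if na < nb:
            na, nb = nb, na
        av = np.linspace(*a_range, na)
        bv = np.linspace(*b_range, nb)
        return np.array([(a, b) for a in av for b in bv])
    # fallback: subset of the smallest >=3x3 lattice holding n points
    nb = 3
    na = max(3, int(np.ceil(n / nb)))
    av = np.linspace(*a_range, na)
    bv = np.linspace(*b_range, nb)
    ia, ib = na - 1, nb - 1
    priority = [
        (0, 0), (ia, 0), (0, ib), (ia, ib),  # corners
        (ia // 2, ib // 2),  # center
        (ia // 2, 0), (ia // 2, ib), (0, ib // 2), (ia, ib // 2),  # edge midpoints
    ]
    seen = set()
    order = []
    for ij in priority + [(i, j) for i in range(na) for j in range(nb)]:
        if ij not in seen:
            seen.add(ij)
            order.append(ij)
    chosen = order[:n]
    return np.array([(av[i], bv[j]) for i, j in chosen])


def design_grid(
    n: int = 51,
    a_range: tuple[float, float] = DEFAULT_A_RANGE,
    b_range: tuple[float, float] = DEFAULT_B_RANGE,
    layout: str = "grid",
    seed: int | None = None,
) -> ParameterGrid:
    """Design the (a, b) sweep: 51 couples over [85, 645] x [14.4, 17.6] by default."""
    if n < 6:
        raise ValidationError("rank-deficient design: need n >= 6")
    if a_range[0] >= a_range[1] or b_range[0] >= b_range[1]:
        raise ValidationError("parameter ranges must be increasing")
    if layout == "grid":
        couples = _lattice_selection(n, a_range, b_range)
    elif layout == "latin-hypercube":
        from scipy.stats import qmc

        sampler = qmc.LatinHypercube(d=2, seed=seed)
        u = sampler.random(n)
        couples = np.column_stack(
            [a_range[0] + u[:, 0] * (a_range[1] - a_range[0]), b_range[0] + u[:, 1] * (b_range[1] - b_range[0])]
        )
    else:
        raise ValidationError(f"unknown layout {layout!r}")
    grid = ParameterGrid(couples=couples, a_range=a_range, b_range=b_range, layout=layout, seed=seed)
    a0, sa, b0, sb = _scaling(a_range, b_range)
    X = _basis((grid.couples[:, 0] - a0) / sa, (grid.couples[:, 1] - b0) / sb)
    if np.linalg.matrix_rank(X) < 6:
        raise ValidationError("rank-deficient design: quadratic basis not identifiable")
    return grid


@dataclass(frozen=True)
class ResponseSurface:
    """Quadratic metamodel of dV_num over (a, b).

    ``alpha`` holds the six raw-coordinate coefficients (a^2, b^2, a, b,
    ab, 1); evaluation goes through the stored affine normalization so
    training predictions are reproduced bit-identically.
    """

    alpha: np.ndarray  # raw-coordinate coefficients
    coef_normalized: np.ndarray
    scaling: tuple[float, float, float, float]  # (a0, sa, b0, sb)
    a_range: tuple[float, float]
    b_range: tuple[float, float]
    fit_r2: float
    max_residual: float
    rms_residual: float

    def _check_range(self, a, b, allow_extrapolation: bool) -> None:
        if allow_extrapolation:
            return
        eps = 1e-9
        if np.any(np.asarray(a) < self.a_range[0] - eps) or np.any(np.asarray(a) > self.a_range[1] + eps) or np.any(
            np.asarray(b) < self.b_range[0] - eps
        ) or np.any(np.asarray(b) > self.b_range[1] + eps):
            raise ExtrapolationError(
                f"(a, b) outside the fitted box {self.a_range} x {self.b_range}; "
                "the surface is only trusted where sampled"
            )

    def predict(self, a, b, allow_extrapolation: bool = False):
        self._check_range(a, b, allow_extrapolation)
        a0, sa, b0, sb = self.scaling
        xa = (np.asarray(a, dtype=float) - a0) / sa
        xb = (np.asarray(b, dtype=float) - b0) / sb
        return _basis(xa, xb) @ self.coef_normalized

    __call__ = predict


def _raw_alpha(c: np.ndarray, scaling) -> np.ndarray:
    """Expand normalized-basis coefficients into raw (a, b) coefficients."""
    a0, sa, b0, sb = scaling
    A1, A0 = 1.0 / sa, -a0 / sa
    B1, B0 = 1.0 / sb, -b0 / sb
    c1, c2, c3, c4, c5, c6 = c
    return np.array(
        [
            c1 * A1**2,
            c2 * B1**2,
            2 * c1 * A1 * A0 + c3 * A1 + c5 * A1 * B0,
            2 * c2 * B1 * B0 + c4 * B1 + c5 * A0 * B1,
            c5 * A1 * B1,
            c1 * A0**2 + c2 * B0**2 + c3 * A0 + c4 * B0 + c5 * A0 * B0 + c6,
        ]
    )


def fit_response_surface(
    samples: Sequence[tuple[tuple[float, float], float]] | tuple[np.ndarray, np.ndarray],
    a_range: tuple[float, float] | None = None,
    b_range: tuple[float, float] | None = None,
) -> ResponseSurface:
    """Least-squares fit of the quadratic metamodel.

    ``samples`` is either a sequence of ((a, b), dv) pairs or a tuple of
    (couples, dv) arrays.  Fitting happens in affine-normalized coordinates
    (a and b differ by ~20x in scale) and the normalization is stored.
    """
    if isinstance(samples, tuple) and len(samples) == 2 and not np.isscalar(samples[1]):
        couples = np.asarray(samples[0], dtype=float).reshape(-1, 2)
        dv = np.asarray(samples[1], dtype=float).reshape(-1)
    else:
        couples = np.array([list(ab) for ab, _ in samples], dtype=float)
        dv = np.array([v for _, v in samples], dtype=float)
    if len(couples) < 6:
        raise ValidationError("need at least 6 samples")
    if len(couples) != len(dv):
        raise ValidationError("couples and values length mismatch")
    a_range = a_range or (couples[:, 0].min(), couples[:, 0].max())
    b_range = b_range or (couples[:, 1].min(), couples[:, 1].max())
    if a_range[0] >= a_range[1] or b_range[0] >= b_range[1]:
        raise ValidationError("rank-deficient design: a degenerate parameter range")
    scaling = _scaling(a_range, b_range)
    a0, sa, b0, sb = scaling
    X = _basis((couples[:, 0] - a0) / sa, (couples[:, 1] - b0) / sb)
    if np.linalg.matrix_rank(X) < 6:
        raise ValidationError("rank-deficient design: quadratic basis not identifiable")
    c, *_ = np.linalg.lstsq(X, dv, rcond=None)
    pred = X @ c
    resid = pred - dv
    ss_tot = float(((dv - dv.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else 1.0
    return ResponseSurface(
        alpha=_raw_alpha(c, scaling),
        coef_normalized=c,
        scaling=scaling,
        a_range=(float(a_range[0]), float(a_range[1])),
        b_range=(float(b_range[0]), float(b_range[1])),
        fit_r2=r2,
        max_residual=float(np.max(np.abs(resid))),
        rms_residual=float(np.sqrt(np.mean(resid**2))),
    )


def cost(a: float, b: float, surface: ResponseSurface, dv_exp: float, allow_extrapolation: bool = False) -> float:
    """FC(a, b) = |dV_num(a, b) - dV_exp| in mm^3."""
    return float(np.abs(surface.predict(a, b, allow_extrapolation) - dv_exp))


@dataclass(frozen=True)
class IdentificationResult:
    """Identified wall constants and their provenance."""

    a_hat: float  # kPa
    b_hat: float
    delta_t: float | None  # s (None when no scan was run)
    fc_min: float  # mm^3 (joint mode: sqrt of the summed squared costs)
    delta_v_num_mat: dict[float, float]  # flow -> forward-model dV at (a_hat, b_hat)
    e: dict[float, float]  # flow -> relative error vs dV_exp, percent
    dv_exp: dict[float, float]
    mode: str  # "per-load" | "joint"
    flow_rate: float | None = None  # set in per-load mode
    surface_max_residual: float = float("nan")
    refined: bool = False

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items()}
        for key in ("delta_v_num_mat", "e", "dv_exp"):
            d[key] = {str(k): v for k, v in d[key].items()}
        return d


@dataclass(frozen=True)
class ScanResult:
    """Outcome of the acquisition-time ambiguity scan."""

    best: IdentificationResult
    table: pd.DataFrame  # per delta-t: dt, a, b, fc_min
    ties: tuple[float, ...] = ()


def _box_minimize(residuals, n_starts: int = 5):
    """Multi-start minimization of a sum of squared residuals over the
    normalized [-1, 1]^2 box, polished by bounded Levenberg-Marquardt
    (which stays accurate on the flat quartic minima the squared cost
    develops near a zero level set).  Returns (x, sum of squares)."""

    def fun(x):
        return float(np.sum(np.asarray(residuals(x)) ** 2))

    best = None
    for xa in np.linspace(-0.9, 0.9, n_starts):
        for xb in np.linspace(-0.9, 0.9, n_starts):
            r = minimize(fun, np.array([xa, xb]), bounds=[(-1, 1), (-1, 1)], method="L-BFGS-B")
            if best is None or r.fun < best.fun:
                best = r
    polish = least_squares(
        residuals, best.x, bounds=([-1, -1], [1, 1]), xtol=3e-16, ftol=3e-16, gtol=3e-16, max_nfev=2000
    )
    x = polish.x if fun(polish.x) <= best.fun else best.x
    return x, fun(x)


def minimize_cost(
    surface: ResponseSurface | Sequence[ResponseSurface],
    dv_exp: float | Sequence[float],
    ranges: tuple[tuple[float, float], tuple[float, float]] | None = None,
    mode: str = "per-load",
    anchor: tuple[float, float] = LITERATURE_ANCHOR,
    tie_tol: float = 1e-9,
    n_starts: int = 5,
) -> tuple[float, float, float]:
    """Minimize the cost over the parameter box; returns (a, b, fc_min).

    per-load: minimizes FC for a single surface; when the minimum is a
    zero-level set (fc below ``tie_tol``), the tie is broken by the point
    of that level set closest to ``anchor`` in normalized coordinates.

    joint: minimizes sum_k FC_k^2 over several surfaces sharing one
    (a, b); returns fc_min = sqrt(sum of squared costs).
    """
    surfaces = [surface] if isinstance(surface, ResponseSurface) else list(surface)
    dvs = np.atleast_1d(np.asarray(dv_exp, dtype=float))
    if mode == "per-load" and (len(surfaces) != 1 or dvs.size != 1):
        raise ValidationError("per-load mode takes one surface and one dv_exp")
    if mode == "joint" and len(surfaces) != dvs.size:
        raise ValidationError("joint mode needs one dv_exp per surface")
    s0 = surfaces[0]
    if ranges is None:
        ranges = (s0.a_range, s0.b_range)
    (a_lo, a_hi), (b_lo, b_hi) = ranges
    a0, sa = 0.5 * (a_lo + a_hi), 0.5 * (a_hi - a_lo)
    b0, sb = 0.5 * (b_lo + b_hi), 0.5 * (b_hi - b_lo)

    def unpack(x):
        return a0 + sa * x[0], b0 + sb * x[1]

    preds = [
        (lambda x, s=s: float(s.predict(*unpack(x), allow_extrapolation=True))) for s in surfaces
    ]
    for s in surfaces:
        if not np.all(np.isfinite(s.coef_normalized)):
            raise ValidationError("non-finite surface coefficients")

    if mode == "joint":
        def residuals(x):
            return np.array([p(x) - d for p, d in zip(preds, dvs)])

        x, f = _box_minimize(residuals, n_starts)
        a, b = unpack(x)
        return float(a), float(b), float(np.sqrt(max(f, 0.0)))

    # per-load
    p = preds[0]
    d = float(dvs[0])

    def residuals(x):
        return np.array([p(x) - d])

    x, f = _box_minimize(residuals, n_starts)
    fc = float(np.sqrt(max(f, 0.0)))
    if fc < tie_tol:
        # tie-break along the zero-level curve: closest point to the anchor
        xa_anchor = (anchor[0] - a0) / sa
        xb_anchor = (anchor[1] - b0) / sb

        def dist2(x):
            return (x[0] - xa_anchor) ** 2 + (x[1] - xb_anchor) ** 2

        res = minimize(
            dist2,
            x,
            method="SLSQP",
            bounds=[(-1, 1), (-1, 1)],
            constraints=[{"type": "eq", "fun": lambda x: p(x) - d}],
            options={"maxiter": 200, "ftol": 1e-14},
        )
        if res.success:
            # project back onto the level set (SLSQP meets the constraint
            # only to its own tolerance)
            proj = least_squares(
                residuals, res.x, bounds=([-1, -1], [1, 1]), xtol=3e-16, ftol=3e-16, gtol=3e-16
            )
            if abs(p(proj.x) - d) < tie_tol:
                x = proj.x
                fc = float(abs(p(x) - d))
                log.info("per-load zero-level tie broken toward anchor (%.1f, %.2f)", *anchor)
    a, b = unpack(x)
    return float(a), float(b), fc


def _refine_forward(
    fwd: Callable[[float, float, float], float],
    flows: Sequence[float],
    dv_exp: np.ndarray,
    x0_ab: tuple[float, float],
    ranges,
) -> tuple[float, float]:
    """Gauss-Newton polish of (a, b) against the forward model itself."""
    (a_lo, a_hi), (b_lo, b_hi) = ranges
    a0, sa = 0.5 * (a_lo + a_hi), 0.5 * (a_hi - a_lo)
    b0, sb = 0.5 * (b_lo + b_hi), 0.5 * (b_hi - b_lo)
    scale = np.maximum(np.abs(dv_exp), 1e-6)

    def resid(x):
        a, b = a0 + sa * x[0], b0 + sb * x[1]
        return np.array([(fwd(a, b, fl) - d) for fl, d in zip(flows, dv_exp)]) / scale

    x0 = np.array([(x0_ab[0] - a0) / sa, (x0_ab[1] - b0) / sb])
    res = least_squares(
        resid, np.clip(x0, -1, 1), bounds=([-1, -1], [1, 1]), xtol=1e-14, ftol=1e-14, gtol=1e-14
    )
    return float(a0 + sa * res.x[0]), float(b0 + sb * res.x[1])


def identify(
    runner,
    dv_exp: dict[float, float],
    grid: ParameterGrid,
    t1: float,
    t2: float,
    mode: str = "joint",
    refine: bool = True,
    delta_t: float | None = None,
    flow_rate: float | None = None,
) -> IdentificationResult:
    """Fit surfaces from forward-model sweeps and identify (a, b).

    ``runner`` follows the SacForwardRunner protocol (``flows``,
    ``sample``, ``delta_v``).  In joint mode all flows in ``dv_exp`` are
    matched simultaneously; ``refine=True`` (default) polishes the surface
    minimizer with the forward model, eliminating metamodel bias.  In
    per-load mode a single ``flow_rate`` is used and the documented anchor
    tie-break applies; per-load estimates are never refined (they are the
    metamodel's own point estimate).
    """
    flows = [flow_rate] if mode == "per-load" else sorted(dv_exp)
    if mode == "per-load" and flow_rate is None:
        raise ValidationError("per-load mode needs flow_rate")
    surfaces = []
    for fl in flows:
        dv = runner.sample(fl, grid.couples, t1, t2)
        surfaces.append(fit_response_surface((grid.couples, dv), grid.a_range, grid.b_range))
    dvs = [dv_exp[fl] for fl in flows]
    if mode == "joint":
        a_hat, b_hat, fc = minimize_cost(surfaces, dvs, (grid.a_range, grid.b_range), mode="joint")
        refined = False
        if refine:
            a_hat, b_hat = _refine_forward(
                lambda a, b, fl: runner.delta_v(fl, a, b, t1, t2),
                flows,
                np.asarray(dvs),
                (a_hat, b_hat),
                (grid.a_range, grid.b_range),
            )
            fc = float(
                np.sqrt(sum((runner.delta_v(fl, a_hat, b_hat, t1, t2) - d) ** 2 for fl, d in zip(flows, dvs)))
            )
            refined = True
    else:
        a_hat, b_hat, fc = minimize_cost(surfaces[0], dvs[0], (grid.a_range, grid.b_range), mode="per-load")
        refined = False
    dv_mat = {fl: runner.delta_v(fl, a_hat, b_hat, t1, t2) for fl in flows}
    e = {
        fl: abs(dv_mat[fl] - dv_exp[fl]) / abs(dv_exp[fl]) * 100.0 if dv_exp[fl] != 0 else float("nan")
        for fl in flows
    }
    return IdentificationResult(
        a_hat=a_hat,
        b_hat=b_hat,
        delta_t=delta_t,
        fc_min=fc,
        delta_v_num_mat=dv_mat,
        e=e,
        dv_exp={fl: dv_exp[fl] for fl in flows},
        mode=mode,
        flow_rate=flow_rate,
        surface_max_residual=max(s.max_residual for s in surfaces),
        refined=refined,
    )


def scan_delta_t(
    dv_exp: dict[float, float],
    runner,
    grid: ParameterGrid,
    t2: float,
    period: float,
    dt_grid: Sequence[float] = DEFAULT_DT_GRID,
    mode: str = "joint",
    refine: bool = True,
    flow_rate: float | None = None,
    tie_tol: float = 1e-12,
) -> ScanResult:
    """Scan candidate acquisition offsets delta-t and keep the lowest minimum.

    For each delta-t the baseline instant is the cardiac phase
    ``t2 - delta_t`` folded into one cycle; surfaces are fitted and the
    cost minimized, and the delta-t whose minimized cost is lowest wins
    (ties logged and reported).  The forward model is re-run at the winning
    (a, b) to produce dV_num/mat and the relative errors e.
    """
    if len(dt_grid) == 0:
        raise ValidationError("empty delta-t grid")
    rows = []
    results = []
    for dt in dt_grid:
        t1 = float(np.mod(t2 - dt, period))
        res = identify(
            runner, dv_exp, grid, t1, t2, mode=mode, refine=refine, delta_t=float(dt), flow_rate=flow_rate
        )
        results.append(res)
        rows.append({"delta_t": float(dt), "a_hat": res.a_hat, "b_hat": res.b_hat, "fc_min": res.fc_min})
    table = pd.DataFrame(rows)
    fc = table["fc_min"].to_numpy()
    i_best = int(np.argmin(fc))
    ties = tuple(table["delta_t"][np.abs(fc - fc[i_best]) <= tie_tol].tolist())
    if len(ties) > 1:
        log.warning("delta-t scan tie between %s (fc_min within %g)", ties, tie_tol)
    return ScanResult(best=results[i_best], table=table, ties=ties if len(ties) > 1 else ())
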