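"""The 1-D structural non-identifiability manifold.

A structurally non-identifiable model admits a functional relationship ρ
mapping one free parameter to the remaining ones such that the
deterministic (ODE) observable trajectories are identical along the
resulting 1-D parameter subset Θ.  :class:`ManifoldRho` represents ρ either
in closed form (known a priori) or as a monotone interpolant through
per-point deterministic fits (:func:`estimate_rho_by_scan`).
"""

from __future__ import annotations

import json
from typing import Callable, Sequence

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.optimize import least_squares

from .meanfield import MeanFieldTrajectory, integrate_ode
from .networks import ObservableMap, ReactionNetwork
from .simulate import TimeGrid

__all__ = [
    "ManifoldRho",
    "rho_immigration_death",
    "rho_gene_expression",
    "rho_epo_scaling",
    "estimate_rho_by_scan",
]

ParameterPoint = dict  # name -> value


class ManifoldRho:
    """Map from the free parameter to a full parameter point on Θ.

    ``kind='closed_form'`` wraps an analytic relation; ``kind='interpolated'``
    evaluates monotone piecewise-cubic interpolants (linear for two-point
    grids) through fitted dependent-parameter values, valid only inside the
    scanned grid hull.
    """

    def __init__(
        self,
        free_param: str,
        kind: str,
        *,
        fn: Callable[[float], ParameterPoint] | None = None,
        domain: tuple[float, float] = (0.0, np.inf),
        tag: str | None = None,
        constants: dict | None = None,
        scan_grid: np.ndarray | None = None,
        dependent_names: Sequence[str] | None = None,
        fitted_points: np.ndarray | None = None,
        fixed_params: dict | None = None,
        off_manifold: np.ndarray | None = None,
    ):
        if kind not in ("closed_form", "interpolated"):
            raise ValueError(f"unknown manifold kind {kind!r}")
        self.free_param = free_param
        self.kind = kind
        self.tag = tag
        self.constants = dict(constants or {})
        if kind == "closed_form":
            if fn is None:
                raise ValueError("closed_form manifold requires fn")
            self._fn = fn
            self.domain = domain
        else:
            grid = np.asarray(scan_grid, dtype=float)
            if grid.ndim != 1 or np.any(np.diff(grid) <= 0):
                raise ValueError("scan_grid must be strictly increasing")
            pts = np.asarray(fitted_points, dtype=float)
            if pts.shape[0] != grid.size:
                raise ValueError("fitted_points row count must equal grid length")
            self.scan_grid = grid
            self.dependent_names = list(dependent_names)
            self.fitted_points = pts
            self.fixed_params = dict(fixed_params or {})
            self.off_manifold = (
                np.zeros(grid.size, dtype=bool) if off_manifold is None else np.asarray(off_manifold, dtype=bool)
            )
            self.domain = (float(grid[0]), float(grid[-1]))
            if grid.size >= 3:
                self._interp = [PchipInterpolator(grid, pts[:, j]) for j in range(pts.shape[1])]
            else:
                self._interp = [
                    lambda v, j=j: np.interp(v, grid, pts[:, j]) for j in range(pts.shape[1])
                ]

    def __call__(self, theta_free: float) -> ParameterPoint:
        """Full parameter point at the given free-parameter value."""
        lo, hi = self.domain
        if not lo <= theta_free <= hi:
            raise ValueError(
                f"{self.free_param}={theta_free} outside the manifold domain [{lo}, {hi}]"
            )
        if self.kind == "closed_form":
            point = dict(self._fn(theta_free))
        else:
            point = dict(self.fixed_params)
            for name, f in zip(self.dependent_names, self._interp):
                point[name] = float(f(theta_free))
        point[self.free_param] = float(theta_free)
        return point

    # -- serialisation (interpolated and tagged closed forms) ----------

    def to_dict(self) -> dict:
        d = {"free_param": self.free_param, "kind": self.kind, "tag": self.tag, "constants": self.constants}
        if self.kind == "interpolated":
            d.update(
                scan_grid=self.scan_grid.tolist(),
                dependent_names=self.dependent_names,
                fitted_points=self.fitted_points.tolist(),
                fixed_params=self.fixed_params,
                off_manifold=self.off_manifold.astype(int).tolist(),
            )
        return d

    def to_json(self, path=None) -> str:
        s = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    @classmethod
    def from_dict(cls, d: dict) -> "ManifoldRho":
        if d["kind"] == "interpolated":
            return cls(
                d["free_param"],
                "interpolated",
                tag=d.get("tag"),
                constants=d.get("constants"),
                scan_grid=np.asarray(d["scan_grid"]),
                dependent_names=d["dependent_names"],
                fitted_points=np.asarray(d["fitted_points"]),
                fixed_params=d.get("fixed_params"),
                off_manifold=np.asarray(d.get("off_manifold", []), dtype=bool) if d.get("off_manifold") else None,
            )
        factories = {
            "immigration_death": rho_immigration_death,
            "gene_expression": rho_gene_expression,
            "epo_scaling": rho_epo_scaling,
        }
        if d.get("tag") not in factories:
            raise ValueError(f"cannot deserialise closed-form manifold with tag {d.get('tag')!r}")
        return factories[d["tag"]](**d.get("constants", {}))

    @classmethod
    def from_json(cls, source: str) -> "ManifoldRho":
        try:
            d = json.loads(source)
        except json.JSONDecodeError:
            with open(source) as fh:
                d = json.load(fh)
        return cls.from_dict(d)


# ----------------------------------------------------------------------
# Closed-form relations for the built-in models
# ----------------------------------------------------------------------

def rho_immigration_death(xs: float, free_param: str = "theta2") -> ManifoldRho:
    """Quotient relation θ1 = θ2·x^s of the immigration-death model.

    ``xs`` is the (known or ν̄-estimated) steady state; the free parameter
    may be either rate.
    """
    if xs <= 0:
        raise ValueError("steady state xs must be positive")
    if free_param == "theta2":
        fn = lambda th2: {"theta1": th2 * xs, "theta2": th2}
    elif free_param == "theta1":
        fn = lambda th1: {"theta1": th1, "theta2": th1 / xs}
    else:
        raise ValueError("free_param must be 'theta1' or 'theta2'")
    return ManifoldRho(
        free_param, "closed_form", fn=fn, domain=(0.0, np.inf),
        tag="immigration_death", constants={"xs": xs, "free_param": free_param},
    )


def rho_gene_expression(
    pro_ss: float,
    gamma_r: float = 1.2,
    gamma_p: float = 0.7,
    free_param: str = "kr",
) -> ManifoldRho:
    """Transcription/translation trade-off of the gene-expression model.

    With only protein observed, the steady state Pro^s = kp·kr/(γr·γp) pins
    the product kr·kp; given the free transcription rate kr the translation
    rate is kp = γr·γp·Pro^s / kr (degradation rates fixed and known).
    """
    if pro_ss <= 0:
        raise ValueError("protein steady state must be positive")
    if free_param != "kr":
        raise ValueError("only kr is supported as the free parameter")

    def fn(kr: float) -> ParameterPoint:
        if kr <= 0:
            raise ValueError("kr must be positive")
        return {"kr": kr, "kp": gamma_r * gamma_p * pro_ss / kr, "gamma_r": gamma_r, "gamma_p": gamma_p}

    return ManifoldRho(
        "kr", "closed_form", fn=fn, domain=(np.finfo(float).tiny, np.inf),
        tag="gene_expression",
        constants={"pro_ss": pro_ss, "gamma_r": gamma_r, "gamma_p": gamma_p},
    )


def rho_epo_scaling(anchor: dict | None = None, free_param: str = "Bmax") -> ManifoldRho:
    """Exact scaling family of the Epo-receptor model.

    Scaling every concentration by c = Bmax/Bmax₀ while dividing the
    measurement scale and the binding constant by c (kon → kon/c,
    kD → c·kD, Epo(0) → c·Epo(0), scale → scale/c) leaves both read-outs
    y1, y2 unchanged — the model's non-identifiability in closed form.
    Used mainly as an independent cross-check of the scan-based estimate.
    """
    from .networks import EPO_TRUE_PARAMS

    a = dict(EPO_TRUE_PARAMS)
    if anchor:
        a.update(anchor)
    if free_param != "Bmax":
        raise ValueError("only Bmax is supported as the free parameter")

    def fn(bmax: float) -> ParameterPoint:
        c = bmax / a["Bmax"]
        if c <= 0:
            raise ValueError("Bmax must be positive")
        p = dict(a)
        p.update(Bmax=bmax, kon=a["kon"] / c, kD=a["kD"] * c, scale=a["scale"] / c, Epo0=a["Epo0"] * c)
        return p

    return ManifoldRho(
        "Bmax", "closed_form", fn=fn, domain=(np.finfo(float).tiny, np.inf),
        tag="epo_scaling", constants={"anchor": a},
    )


# ----------------------------------------------------------------------
# Scan-based estimation
# ----------------------------------------------------------------------

def _ode_observables(
    make_model: Callable[[dict], tuple[ReactionNetwork, ObservableMap | None]],
    params: dict,
    grid: TimeGrid,
) -> np.ndarray:
    net, obs = make_model(params)
    phi = integrate_ode(net, None, grid, observables=obs)
    return phi.values


def estimate_rho_by_scan(
    make_model: Callable[[dict], tuple[ReactionNetwork, ObservableMap | None]],
    nominal: dict,
    free_param: str,
    scan_grid: Sequence[float],
    dependent: Sequence[str],
    grid: TimeGrid,
    reference: MeanFieldTrajectory | np.ndarray | None = None,
    residual_tol: float = 1e-4,
    n_restarts: int = 4,
    seed: int = 0,
) -> ManifoldRho:
    """Estimate ρ by scanning the free parameter and refitting the rest.

    For each grid value of the free parameter the dependent parameters are
    optimised (in log space, Levenberg–Marquardt style trust region) so the
    deterministic observable trajectories match a reference computed at the
    nominal parameter point; fits continue from the previous grid point's
    solution, with randomised restarts as a fallback.  Grid points whose
    scaled residual exceeds ``residual_tol`` are flagged off-manifold.
    """
    scan_grid = np.asarray(scan_grid, dtype=float)
    if np.any(np.diff(scan_grid) <= 0):
        raise ValueError("scan_grid must be strictly increasing")
    if reference is None:
        ref = _ode_observables(make_model, nominal, grid)
    else:
        ref = reference.values if isinstance(reference, MeanFieldTrajectory) else np.asarray(reference)
    col_scale = np.maximum(np.abs(ref).max(axis=0), 1e-12)
    fixed = {k: v for k, v in nominal.items() if k != free_param and k not in dependent}
    rng = np.random.Generator(np.random.PCG64(seed))

    def residuals(log_dep: np.ndarray, free_value: float) -> np.ndarray:
        params = dict(fixed)
        params[free_param] = free_value
        for name, lv in zip(dependent, log_dep):
            params[name] = float(np.exp(lv))
        try:
            model = _ode_observables(make_model, params, grid)
        except (RuntimeError, ValueError):
            return np.full(ref.size, 1e6)
        return ((model - ref) / col_scale).ravel()

    start = np.log([nominal[name] for name in dependent])
    fitted = np.empty((scan_grid.size, len(dependent)))
    off = np.zeros(scan_grid.size, dtype=bool)
    for g, free_value in enumerate(scan_grid):
        best = None
        x0 = start
        for attempt in range(n_restarts + 1):
            res = least_squares(residuals, x0, args=(free_value,), method="lm", xtol=1e-14, ftol=1e-14)
            if best is None or res.cost < best.cost:
                best = res
            rms = np.sqrt(2 * best.cost / ref.size)
            if rms <= residual_tol:
                break
            x0 = start + rng.normal(scale=0.5, size=start.size)
        fitted[g] = np.exp(best.x)
        rms = np.sqrt(2 * best.cost / ref.size)
        off[g] = rms > residual_tol
        start = best.x  # continuation
    return ManifoldRho(
        free_param,
        "interpolated",
        scan_grid=scan_grid,
        dependent_names=dependent,
        fitted_points=fitted,
        fixed_params=fixed,
        off_manifold=off,
        tag="scan",
        constants={"residual_tol": residual_tol},
    )
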