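"""Fitting the kinetic model to experimental PEGylation progress curves.

:class:`PEGylationKinetics` is the model object: it binds a set of
progress curves (time courses of native protein, PEGmers, and reagent)
to the site geometry and per-site reactivities, and ``fit()`` estimates
the three free parameters — the diffusional parameter κ, the reaction
prefactor ε, and the shielding radius R — by minimizing the pooled
root-mean-square error between simulated and experimental
concentrations:

    RMSE = sqrt( Σ (C_ex − C_calc)² / n )

κ and ε are searched in log space with a derivative-free simplex from
multiple seeded restarts; the radius, which acts through a discrete
site-blocking rule and therefore makes the objective piecewise
constant in R, is scanned on an integer-Å grid.

:class:`PEGylationKineticsResults` carries the estimates, the RMSE,
and F-test 95% confidence intervals: a parameter set p is accepted
when

    D(p)² ≤ D(p*)²·(1 + n_p/(n−n_p)·F_{1−q}(n_p, n−n_p))

and per-parameter bounds are taken over seeded random perturbations of
p* that pass this criterion.
"""

from __future__ import annotations

import io
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .reactivity import ReactivityModel
from .simulation import (KineticParameters, SimulationResult,
                         reaction_sequence, simulate)
from .structure import AmineSite

__all__ = [
    "ProgressCurve",
    "KineticFit",
    "PEGylationKinetics",
    "PEGylationKineticsResults",
    "fit_kinetics",
    "confidence_interval",
    "read_progress_curves",
    "rmse",
]

logger = logging.getLogger(__name__)


@dataclass
class ProgressCurve:
    """One measured species time course.

    ``species`` is ``"native"``, ``"PEG-1"`` … ``"PEG-N"``, or
    ``"reagent"``; ``basis`` is ``"relative"`` (normalized by initial
    native-protein concentration) or ``"molar"``.
    """

    times: np.ndarray
    species: str
    concentrations: np.ndarray
    basis: str = "relative"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.times.shape != self.concentrations.shape:
            raise ValueError("times and concentrations must have equal length")
        if np.any(np.diff(self.times) < 0):
            raise ValueError("times must be non-decreasing")
        if np.any(self.concentrations < 0):
            raise ValueError("concentrations must be >= 0")
        if self.basis not in ("relative", "molar"):
            raise ValueError("basis must be 'relative' or 'molar'")


def read_progress_curves(text: str, basis: str = "relative") -> list[ProgressCurve]:
    """Parse delimited text with header ``time_min`` plus species columns."""
    df = pd.read_csv(io.StringIO(text), sep=None, engine="python")
    df.columns = [c.strip() for c in df.columns]
    if "time_min" not in df.columns:
        raise ValueError("curve file needs a time_min column")
    curves = []
    for col in df.columns:
        if col == "time_min":
            continue
        curves.append(ProgressCurve(times=df["time_min"].to_numpy(),
                                    species=col,
                                    concentrations=df[col].to_numpy(),
                                    basis=basis))
    return curves


def rmse(experimental: np.ndarray, simulated: np.ndarray) -> float:
    """Pooled root-mean-square error over all points."""
    experimental = np.asarray(experimental, dtype=float)
    simulated = np.asarray(simulated, dtype=float)
    if experimental.shape != simulated.shape:
        raise ValueError("shape mismatch")
    return float(np.sqrt(np.mean((experimental - simulated) ** 2)))


_SPECIES_ALIASES = {"native": "P_0", "reagent": "PEG"}


def _species_column(species: str) -> str:
    if species in _SPECIES_ALIASES:
        return _SPECIES_ALIASES[species]
    if species.upper().startswith("PEG-"):
        return f"P_{int(species.split('-')[1])}"
    if species.startswith("P_"):
        return species
    raise ValueError(f"unknown species label {species!r}")


def _simulated_values(result: SimulationResult, curve: ProgressCurve) -> np.ndarray:
    col = _species_column(curve.species)
    n = result.pegmer_conc.shape[0] - 1
    dense = result._dense

    def value_at(t: float) -> float:
        y = dense(min(max(t, result.times[0]), result.times[-1]))
        if col == "PEG":
            v = y[n + 1]
        elif col == "PEG_d":
            v = y[n + 2]
        else:
            j = int(col.split("_")[1])
            v = y[j] if j <= n else 0.0
        return float(v)

    vals = np.array([value_at(t) for t in curve.times])
    if curve.basis == "relative":
        if col == "PEG":
            vals = vals / result.params.peg0
        else:
            vals = vals / result.params.protein0
    return vals


@dataclass
class KineticFit:
    """Container for the fitted parameters and their uncertainty."""

    best_params: dict[str, float]  # kappa, epsilon, shield_radius
    rmse: float
    restarts: int
    n: int
    n_p: int = 3
    ci_95: dict[str, tuple[float, float]] | None = None


class PEGylationKinetics:
    """Kinetic model of a PEGylation reaction, bound to observed curves.

    Parameters
    ----------
    curves : list of ProgressCurve
        Experimental time courses (any subset of species).
    sites, reactivity_model :
        Amine sites with descriptors and the per-site reactivity model;
        together they define the modification sequence and the averaged
        per-step rate constants at a given shielding radius.
    base_params : KineticParameters
        Reaction conditions (k_d, concentrations, PEG MW); κ, ε and the
        radius inside it are ignored during fitting.
    bounds : dict
        ``{"kappa": (lo, hi), "epsilon": (lo, hi)}``, both positive.
    radius_grid : sequence of float
        Candidate shielding radii (Å); include the 11 Å floor.
    sequence_seed : int
        Seed for the stochastic site-selection sequence; fixed so the
        objective is deterministic during optimization.
    share_epsilon_with : optional list of PEGylationKinetics
        Reserved hook for joint fits sharing ε across datasets.
    """

    def __init__(self, curves: list[ProgressCurve], sites: list[AmineSite],
                 reactivity_model: ReactivityModel,
                 base_params: KineticParameters,
                 bounds: dict[str, tuple[float, float]] | None = None,
                 radius_grid: list[float] | None = None,
                 sequence_seed: int = 0):
        if not curves:
            raise ValueError("at least one progress curve is required")
        self.curves = curves
        self.sites = sites
        self.reactivity_model = reactivity_model
        self.base_params = base_params
        self.bounds = bounds or {"kappa": (1e-5, 1e-1), "epsilon": (1e-1, 1e3)}
        for name, (lo, hi) in self.bounds.items():
            if not (0 < lo < hi < np.inf):
                raise ValueError(f"bounds for {name} must be finite and positive")
        self.radius_grid = list(radius_grid) if radius_grid is not None else [11.0, 13.0, 15.0, 17.0]
        self.sequence_seed = sequence_seed
        self._t_end = max(float(c.times.max()) for c in curves)
        self._sequences: dict[float, tuple[list[str], list[float]]] = {}
        self.nobs = int(sum(len(c.times) for c in curves))

    # -- objective -------------------------------------------------------
    def _sequence_for(self, radius: float) -> tuple[list[str], list[float]]:
        if radius not in self._sequences:
            self._sequences[radius] = reaction_sequence(
                self.sites, self.reactivity_model, radius,
                seed=self.sequence_seed)
        return self._sequences[radius]

    def _simulate(self, kappa: float, epsilon: float, radius: float,
                  ) -> SimulationResult:
        _seq, k_avg = self._sequence_for(radius)
        params = KineticParameters(
            k_d=self.base_params.k_d, kappa=kappa, epsilon=epsilon,
            shield_radius=radius, peg_mw=self.base_params.peg_mw,
            protein0=self.base_params.protein0, peg0=self.base_params.peg0,
            cutoff_rate=self.base_params.cutoff_rate)
        t_grid = np.linspace(0.0, self._t_end, 50)
        return simulate(params, k_avg, t_grid)

    def objective(self, kappa: float, epsilon: float, shield_radius: float) -> float:
        """Pooled RMSE between simulation and every experimental point."""
        result = self._simulate(kappa, epsilon, shield_radius)
        ex, calc = [], []
        for curve in self.curves:
            ex.append(curve.concentrations)
            calc.append(_simulated_values(result, curve))
        return rmse(np.concatenate(ex), np.concatenate(calc))

    # -- fitting ---------------------------------------------------------
    def fit(self, restarts: int = 50, seed: int | None = None,
            maxiter: int = 200) -> "PEGylationKineticsResults":
        """Best-of-restarts simplex minimization of the pooled RMSE.

        Each restart draws a log-uniform start for (κ, ε) inside the
        bounds; the radius is scanned over ``radius_grid``.  Trial
        points where the simulation fails are discarded with a log
        entry; if every trial fails an error is raised.
        """
        rng = np.random.default_rng(seed)
        lk = np.log(self.bounds["kappa"])
        le = np.log(self.bounds["epsilon"])

        best: tuple[float, float, float, float] | None = None  # rmse, κ, ε, R
        n_failed = 0
        for radius in self.radius_grid:

            def obj_log(x: np.ndarray, radius=radius) -> float:
                kappa = float(np.exp(np.clip(x[0], lk[0], lk[1])))
                epsilon = float(np.exp(np.clip(x[1], le[0], le[1])))
                return self.objective(kappa, epsilon, radius)

            for _ in range(max(1, restarts)):
                x0 = np.array([rng.uniform(*lk), rng.uniform(*le)])
                try:
                    res = optimize.minimize(obj_log, x0, method="Nelder-Mead",
                                            options={"maxiter": maxiter,
                                                     "xatol": 1e-4, "fatol": 1e-10})
                except (RuntimeError, ValueError) as exc:
                    n_failed += 1
                    logger.warning("trial discarded (radius %.1f): %s", radius, exc)
                    continue
                if best is None or res.fun < best[0]:
                    best = (float(res.fun), float(res.x[0]), float(res.x[1]),
                            float(radius))
        if best is None:
            raise RuntimeError(f"all {n_failed} fitting trials failed")
        # polish the winner with a longer simplex run from its own optimum
        def obj_best(x: np.ndarray) -> float:
            kappa = float(np.exp(np.clip(x[0], lk[0], lk[1])))
            epsilon = float(np.exp(np.clip(x[1], le[0], le[1])))
            return self.objective(kappa, epsilon, best[3])

        res = optimize.minimize(obj_best, np.array([best[1], best[2]]),
                                method="Nelder-Mead",
                                options={"maxiter": 2 * maxiter,
                                         "xatol": 1e-6, "fatol": 1e-12})
        if res.fun <= best[0]:
            best = (float(res.fun), float(res.x[0]), float(res.x[1]), best[3])
        best = (best[0],
                float(np.exp(np.clip(best[1], lk[0], lk[1]))),
                float(np.exp(np.clip(best[2], le[0], le[1]))),
                best[3])
        fit = KineticFit(
            best_params={"kappa": best[1], "epsilon": best[2],
                         "shield_radius": best[3]},
            rmse=best[0], restarts=restarts, n=self.nobs)
        return PEGylationKineticsResults(model=self, fit=fit, seed=seed)


@dataclass
class PEGylationKineticsResults:
    """Results of a kinetic fit: estimates, RMSE, and F-test intervals."""

    model: PEGylationKinetics
    fit: KineticFit
    seed: int | None = None
    _accepted: list[dict[str, float]] = field(default_factory=list, repr=False)

    @property
    def params(self) -> dict[str, float]:
        return dict(self.fit.best_params)

    @property
    def rmse(self) -> float:
        return self.fit.rmse

    def f_threshold(self, q: float = 0.05, n: int | None = None) -> float:
        """Maximum accepted RMSE under the F criterion (D_max)."""
        n = self.fit.n if n is None else n
        n_p = self.fit.n_p
        if n <= n_p:
            raise ValueError("need more data points than parameters")
        f_crit = stats.f.ppf(1 - q, n_p, n - n_p)
        return float(self.fit.rmse * np.sqrt(1.0 + n_p / (n - n_p) * f_crit))

    def conf_int(self, q: float = 0.05, n_perturbations: int = 300,
                 seed: int | None = None, spread: float = 3.0,
                 n: int | None = None) -> dict[str, tuple[float, float]]:
        """F-test confidence intervals by seeded random perturbation.

        κ and ε are perturbed multiplicatively with log-scales drawn
        from fine (×1.001) to coarse (×``spread``), so the acceptance
        region is mapped near its boundary as well as near p*; the
        radius is drawn from the model's radius grid (mostly the fitted
        value).  Parameter sets whose RMSE stays below D_max are
        accepted; per-parameter min/max over the accepted set (which
        always includes the best fit) form the intervals.
        """
        d_max = self.f_threshold(q=q, n=n)
        rng = np.random.default_rng(seed)
        p_star = self.fit.best_params

        def factor() -> float:
            # log-uniform scale between 0.1% and the full spread
            s = np.exp(rng.uniform(np.log(1e-3), np.log(np.log(spread))))
            return float(np.exp(rng.uniform(-s, s)))

        def evaluate(trial: dict[str, float]) -> None:
            try:
                d = self.model.objective(trial["kappa"], trial["epsilon"],
                                         trial["shield_radius"])
            except (RuntimeError, ValueError):
                return
            if d <= d_max:
                accepted.append(trial)

        accepted = [dict(p_star)]
        n_scan = n_perturbations // 2
        for _ in range(n_scan):
            radius = (p_star["shield_radius"] if rng.random() < 0.7
                      else float(rng.choice(self.model.radius_grid)))
            evaluate({"kappa": p_star["kappa"] * factor(),
                      "epsilon": p_star["epsilon"] * factor(),
                      "shield_radius": radius})
        # second phase: walk along the accepted set's correlation structure so
        # the extremes of an elongated acceptance region are reached
        for _ in range(n_perturbations - n_scan):
            if len(accepted) >= 3:
                logs = np.log([[a["kappa"], a["epsilon"]] for a in accepted])
                center = logs.mean(axis=0)
                cov = np.cov(logs.T) + 1e-12 * np.eye(2)
                draw = rng.multivariate_normal(center, 4.0 * cov)
            else:
                draw = np.log([p_star["kappa"] * factor(),
                               p_star["epsilon"] * factor()])
            radius = (p_star["shield_radius"] if rng.random() < 0.7
                      else float(rng.choice(self.model.radius_grid)))
            evaluate({"kappa": float(np.exp(draw[0])),
                      "epsilon": float(np.exp(draw[1])),
                      "shield_radius": radius})
        self._accepted = accepted
        ci = {}
        for name in ("kappa", "epsilon", "shield_radius"):
            vals = [a[name] for a in accepted]
            ci[name] = (min(vals), max(vals))
        self.fit.ci_95 = ci
        return ci

    def summary(self) -> str:
        p = self.fit.best_params
        lines = [
            "PEGylation kinetic fit",
            "======================",
            f"  observations:        {self.fit.n}",
            f"  fitted parameters:   {self.fit.n_p} (κ, ε, shield radius)",
            f"  restarts:            {self.fit.restarts}",
            f"  RMSE:                {self.fit.rmse:.6g}",
            f"  κ (diffusion):       {p['kappa']:.4g} Å⁻²",
            f"  ε (prefactor):       {p['epsilon']:.4g}",
            f"  shield radius:       {p['shield_radius']:.1f} Å",
        ]
        if self.fit.ci_95:
            lines.append("  95% CI (F-test):")
            for name, (lo, hi) in self.fit.ci_95.items():
                lines.append(f"    {name:14s} [{lo:.4g}, {hi:.4g}]")
        return "\n".join(lines)

    def to_json(self) -> str:
        doc = {"best_params": self.fit.best_params, "rmse": self.fit.rmse,
               "restarts": self.fit.restarts, "n": self.fit.n,
               "n_p": self.fit.n_p, "seed": self.seed,
               "ci_95": self.fit.ci_95}
        return json.dumps(doc, indent=2)


def fit_kinetics(curves: list[ProgressCurve], sites: list[AmineSite],
                 reactivity_model: ReactivityModel,
                 base_params: KineticParameters,
                 bounds: dict[str, tuple[float, float]] | None = None,
                 radius_grid: list[float] | None = None,
                 restarts: int = 50, seed: int | None = None,
                 sequence_seed: int = 0) -> PEGylationKineticsResults:
    """Functional wrapper over :class:`PEGylationKinetics`."""
    model = PEGylationKinetics(curves, sites, reactivity_model, base_params,
                               bounds=bounds, radius_grid=radius_grid,
                               sequence_seed=sequence_seed)
    return model.fit(restarts=restarts, seed=seed)


def confidence_interval(results: PEGylationKineticsResults, q: float = 0.05,
                        n_perturbations: int = 300, seed: int | None = None,
                        ) -> dict[str, tuple[float, float]]:
    """Functional wrapper over :meth:`PEGylationKineticsResults.conf_int`."""
    return results.conf_int(q=q, n_perturbations=n_perturbations, seed=seed)
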