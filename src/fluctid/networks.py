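"""Declarative mass-action reaction networks.

A :class:`ReactionNetwork` carries both semantics used throughout the
package: stochastic mass-action propensities for the Gillespie simulator
and deterministic rate equations for the mean-field (ODE) solver.  Three
models of increasing complexity are provided as factories:

* an immigration-death process ``∅ →θ1 X``, ``X →θ2·x ∅`` — the canonical
  birth-death system whose deterministic behaviour depends only on the
  quotient θ1/θ2;
* a two-stage gene-expression model (transcription, translation, mRNA and
  protein degradation);
* an erythropoietin (Epo) / Epo-receptor interaction model with ligand
  binding, receptor turnover, complex internalisation and Epo degradation,
  observed through two scaled read-outs y1 and y2.

All species are interpreted directly as molecule counts; rate constants are
per-time (zeroth/first order) or per-time-per-molecule (second order).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Reaction",
    "ReactionNetwork",
    "ObservableMap",
    "build_immigration_death",
    "build_gene_expression",
    "build_epo_receptor",
    "propensities",
]


@dataclass(frozen=True)
class Reaction:
    """One mass-action reaction: substrate/product stoichiometries and a rate name."""

    substrates: tuple[int, ...]
    products: tuple[int, ...]
    rate_param: str


class ReactionNetwork:
    """A mass-action reaction network over integer copy numbers.

    Parameters
    ----------
    species_names
        Ordered species identifiers.
    reactions
        Sequence of :class:`Reaction` (or ``(sub, prod, rate_name)`` triples);
        stoichiometry vectors have one nonnegative integer entry per species.
    parameters
        Map rate-parameter name -> nonnegative value.
    initial_state
        Nonnegative integer copy number per species.
    """

    def __init__(
        self,
        species_names: Sequence[str],
        reactions: Sequence[Reaction | tuple],
        parameters: dict[str, float],
        initial_state: Sequence[int],
    ):
        self.species_names = list(species_names)
        n_sp = len(self.species_names)
        self.reactions = []
        for r in reactions:
            if not isinstance(r, Reaction):
                r = Reaction(tuple(r[0]), tuple(r[1]), r[2])
            if len(r.substrates) != n_sp or len(r.products) != n_sp:
                raise ValueError(
                    f"stoichiometry length mismatch in reaction {r!r}: "
                    f"expected {n_sp} species"
                )
            for v in (*r.substrates, *r.products):
                if v < 0 or int(v) != v:
                    raise ValueError("stoichiometric coefficients must be nonnegative integers")
            if r.rate_param not in parameters:
                raise ValueError(f"reaction references unknown parameter {r.rate_param!r}")
            self.reactions.append(
                Reaction(tuple(int(v) for v in r.substrates), tuple(int(v) for v in r.products), r.rate_param)
            )
        for name, val in parameters.items():
            if val < 0:
                raise ValueError(f"parameter {name!r} is negative: {val}")
        self.parameters = dict(parameters)
        init = np.asarray(initial_state, dtype=float)
        if init.shape != (n_sp,):
            raise ValueError("initial_state length must equal number of species")
        if np.any(init < 0):
            raise ValueError("initial copy numbers must be nonnegative")
        # the jump process lives on integer counts; the rate equations keep
        # the exact real-valued initial condition
        self.initial_state_real = init
        if not np.allclose(init, np.round(init)):
            warnings.warn("non-integer initial copy numbers rounded to nearest integer for stochastic simulation")
        self.initial_state = np.round(init).astype(np.int64)
        self._arrays: tuple | None = None

    # -- derived views -------------------------------------------------

    @property
    def n_species(self) -> int:
        return len(self.species_names)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    def species_index(self, name: str) -> int:
        try:
            return self.species_names.index(name)
        except ValueError:
            raise KeyError(f"unknown species {name!r}") from None

    def stoich_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """``(substrates, products, rates)`` arrays for the simulator core."""
        if self._arrays is None:
            sub = np.array([r.substrates for r in self.reactions], dtype=np.int64)
            prod = np.array([r.products for r in self.reactions], dtype=np.int64)
            rates = np.array([self.parameters[r.rate_param] for r in self.reactions])
            self._arrays = (sub, prod, rates)
        return self._arrays

    # -- kinetics ------------------------------------------------------

    def propensities(self, state: Sequence[int]) -> np.ndarray:
        """Stochastic mass-action propensities a_j(x).

        Zeroth order: k; first order: k·x; bimolecular A+B: k·x_A·x_B;
        homodimerisation 2A: k·x_A(x_A−1)/2 (general falling factorial /s!).
        """
        x = np.asarray(state, dtype=float)
        if np.any(x < 0):
            raise ValueError("state must be nonnegative")
        sub, _, rates = self.stoich_arrays()
        a = np.empty(self.n_reactions)
        for j in range(self.n_reactions):
            h = rates[j]
            for i in range(self.n_species):
                s = sub[j, i]
                if s == 0:
                    continue
                for m in range(s):
                    h *= max(x[i] - m, 0.0)
                h /= math.factorial(s)
            a[j] = h
        return a

    def ode_rhs(self, t: float, x: np.ndarray) -> np.ndarray:
        """Deterministic mass-action rate equations dx/dt (continuous x)."""
        sub, prod, rates = self.stoich_arrays()
        xc = np.asarray(x, dtype=float)
        dx = np.zeros(self.n_species)
        for j in range(self.n_reactions):
            v = rates[j]
            for i in range(self.n_species):
                s = sub[j, i]
                if s == 1:
                    v *= xc[i]
                elif s > 1:
                    v *= xc[i] ** s / math.factorial(s)
            dx += v * (prod[j] - sub[j])
        return dx

    # -- copies --------------------------------------------------------

    def with_parameters(self, **updates: float) -> "ReactionNetwork":
        params = dict(self.parameters)
        for k, v in updates.items():
            if k not in params:
                raise KeyError(f"unknown parameter {k!r}")
            params[k] = v
        return ReactionNetwork(self.species_names, self.reactions, params, self.initial_state_real)

    def with_initial_state(self, initial_state: Sequence[int]) -> "ReactionNetwork":
        return ReactionNetwork(self.species_names, self.reactions, self.parameters, initial_state)

    # -- serialisation -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "species": self.species_names,
            "reactions": [
                {
                    "substrates": {s: int(c) for s, c in zip(self.species_names, r.substrates) if c},
                    "products": {s: int(c) for s, c in zip(self.species_names, r.products) if c},
                    "rate_param": r.rate_param,
                }
                for r in self.reactions
            ],
            "parameters": self.parameters,
            "initial_state": {
                s: (int(c) if float(c).is_integer() else float(c))
                for s, c in zip(self.species_names, self.initial_state_real)
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ReactionNetwork":
        species = list(d["species"])
        idx = {s: i for i, s in enumerate(species)}
        reactions = []
        for r in d["reactions"]:
            sub = [0] * len(species)
            prod = [0] * len(species)
            for s, c in r["substrates"].items():
                sub[idx[s]] = c
            for s, c in r["products"].items():
                prod[idx[s]] = c
            reactions.append(Reaction(tuple(sub), tuple(prod), r["rate_param"]))
        init = [d["initial_state"].get(s, 0) for s in species]
        return cls(species, reactions, dict(d["parameters"]), init)

    def to_json(self, path=None) -> str:
        s = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    @classmethod
    def from_json(cls, source: str) -> "ReactionNetwork":
        try:
            d = json.loads(source)
        except json.JSONDecodeError:
            with open(source) as fh:
                d = json.load(fh)
        return cls.from_dict(d)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"ReactionNetwork({self.n_species} species, {self.n_reactions} reactions, "
            f"params={self.parameters})"
        )


class ObservableMap:
    """Linear, scaled read-outs of species counts.

    Each observable is ``scale · (coefficients · counts)``; e.g. a measured
    concentration proxy y = scale·(Epo + Epo_e).
    """

    def __init__(self, species_names: Sequence[str], observables: Sequence[tuple[str, dict | Sequence[float], float]]):
        if not observables:
            raise ValueError("at least one observable required")
        self.species_names = list(species_names)
        n_sp = len(self.species_names)
        self.names: list[str] = []
        coeffs = []
        self.scales: list[float] = []
        for name, coef, scale in observables:
            if isinstance(coef, dict):
                vec = np.zeros(n_sp)
                for s, c in coef.items():
                    if s not in self.species_names:
                        raise KeyError(f"unknown species {s!r} in observable {name!r}")
                    vec[self.species_names.index(s)] = c
            else:
                vec = np.asarray(coef, dtype=float)
                if vec.shape != (n_sp,):
                    raise ValueError("coefficient vector length must equal species count")
            self.names.append(name)
            coeffs.append(vec)
            self.scales.append(float(scale))
        self.coefficients = np.array(coeffs)

    @property
    def n_observables(self) -> int:
        return len(self.names)

    def apply(self, counts: np.ndarray) -> np.ndarray:
        """Map an (n_samples × n_species) count matrix to observables."""
        return (np.asarray(counts, dtype=float) @ self.coefficients.T) * np.asarray(self.scales)

    def subset(self, names: Sequence[str]) -> "ObservableMap":
        keep = [
            (n, self.coefficients[self.names.index(n)], self.scales[self.names.index(n)])
            for n in names
        ]
        return ObservableMap(self.species_names, keep)


def propensities(net: ReactionNetwork, state: Sequence[int]) -> np.ndarray:
    """Functional alias for :meth:`ReactionNetwork.propensities`."""
    return net.propensities(state)


# ----------------------------------------------------------------------
# Built-in model factories
# ----------------------------------------------------------------------

def _check_nonnegative(**kwargs: float) -> None:
    for k, v in kwargs.items():
        if v < 0:
            raise ValueError(f"{k} must be nonnegative, got {v}")


def build_immigration_death(theta1: float = 1.0, theta2: float = 0.1, x0: int = 10) -> ReactionNetwork:
    """Immigration-death process: ∅ → X at rate θ1, X → ∅ at per-capita rate θ2.

    Its deterministic steady state is θ1/θ2, so (θ1, θ2) are structurally
    non-identifiable from steady-state ODE output; only the quotient is.
    """
    _check_nonnegative(theta1=theta1, theta2=theta2, x0=x0)
    return ReactionNetwork(
        ["X"],
        [((0,), (1,), "theta1"), ((1,), (0,), "theta2")],
        {"theta1": theta1, "theta2": theta2},
        [x0],
    )


def build_gene_expression(
    kr: float = 20.0,
    kp: float = 10.0,
    gamma_r: float = 1.2,
    gamma_p: float = 0.7,
    mrna0: int | None = None,
    pro0: int | None = None,
) -> ReactionNetwork:
    """Two-stage gene expression: ∅→mRNA (kr), mRNA→mRNA+Pro (kp·mRNA),
    mRNA→∅ (γr·mRNA), Pro→∅ (γp·Pro).

    Defaults start the system at the (rounded) deterministic steady state
    (kr/γr, kp·kr/(γr·γp)); pass ``mrna0``/``pro0`` to start elsewhere.
    """
    _check_nonnegative(kr=kr, kp=kp, gamma_r=gamma_r, gamma_p=gamma_p)
    if mrna0 is None:
        mrna0 = int(round(kr / gamma_r)) if gamma_r > 0 else 0
    if pro0 is None:
        pro0 = int(round(kp * kr / (gamma_r * gamma_p))) if gamma_r > 0 and gamma_p > 0 else 0
    _check_nonnegative(mrna0=mrna0, pro0=pro0)
    return ReactionNetwork(
        ["mRNA", "Pro"],
        [
            ((0, 0), (1, 0), "kr"),
            ((1, 0), (1, 1), "kp"),
            ((1, 0), (0, 0), "gamma_r"),
            ((0, 1), (0, 0), "gamma_p"),
        ],
        {"kr": kr, "kp": kp, "gamma_r": gamma_r, "gamma_p": gamma_p},
        [mrna0, pro0],
    )


EPO_TRUE_PARAMS: dict[str, float] = {
    "Bmax": 170.0,
    "kon": 0.017,
    "kD": 13.2,
    "scale": 9.12,
    "Epo0": 300.0,
    "kt": 0.17,
    "ke": 0.3,
    "kex": 0.087,
    "kdi": 0.065,
    "kde": 0.15,
}
"""Nominal parameter set of the Epo/EpoR model used throughout the studies."""


def build_epo_receptor(**params: float) -> tuple[ReactionNetwork, ObservableMap]:
    """Epo / Epo-receptor interaction model.

    Species: extracellular Epo, free receptor EpoR, surface complex EpoEpoR,
    internalised complex EpoEpoR_i, intracellularly degraded Epo_i and
    extracellularly degraded Epo_e.  Reactions: reversible binding
    (kon, with dissociation rate kon·kD), receptor turnover (synthesis at
    kt·Bmax, degradation kt), internalisation (ke), recycling (kex) and the
    two degradation routes (kdi, kde).  Initial state: Epo(0)=Epo0,
    EpoR(0)=Bmax, all other species 0.

    Returns the network together with the measured read-outs
    y1 = scale·(Epo + Epo_e) and y2 = scale·EpoEpoR.
    """
    p = dict(EPO_TRUE_PARAMS)
    for k, v in params.items():
        if k not in p:
            raise KeyError(f"unknown Epo-model parameter {k!r}")
        p[k] = v
    _check_nonnegative(**p)
    species = ["Epo", "EpoR", "EpoEpoR", "EpoEpoR_i", "Epo_i", "Epo_e"]

    def stoich(**counts: int) -> tuple[int, ...]:
        return tuple(counts.get(s, 0) for s in species)

    reactions = [
        (stoich(Epo=1, EpoR=1), stoich(EpoEpoR=1), "kon"),
        (stoich(EpoEpoR=1), stoich(Epo=1, EpoR=1), "koff"),
        (stoich(), stoich(EpoR=1), "kt_Bmax"),
        (stoich(EpoR=1), stoich(), "kt"),
        (stoich(EpoEpoR=1), stoich(EpoEpoR_i=1), "ke"),
        (stoich(EpoEpoR_i=1), stoich(Epo=1, EpoR=1), "kex"),
        (stoich(EpoEpoR_i=1), stoich(Epo_i=1), "kdi"),
        (stoich(EpoEpoR_i=1), stoich(Epo_e=1), "kde"),
    ]
    rates = {
        "kon": p["kon"],
        "koff": p["kon"] * p["kD"],
        "kt_Bmax": p["kt"] * p["Bmax"],
        "kt": p["kt"],
        "ke": p["ke"],
        "kex": p["kex"],
        "kdi": p["kdi"],
        "kde": p["kde"],
    }
    init = stoich(Epo=p["Epo0"], EpoR=p["Bmax"])
    net = ReactionNetwork(species, reactions, rates, init)
    obs = ObservableMap(
        species,
        [
            ("y1", {"Epo": 1.0, "Epo_e": 1.0}, p["scale"]),
            ("y2", {"EpoEpoR": 1.0}, p["scale"]),
        ],
    )
    return net, obs


BUILTIN_MODELS: dict[str, Callable] = {
    "immigration-death": build_immigration_death,
    "gene-expression": build_gene_expression,
    "epo": build_epo_receptor,
}
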