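"""Candidate Robust Design model structures.

The candidate set is the full factorial of

* apparent survival: constant ``S(.)`` or seasonal ``S(season)``;
* temporary emigration: ``none`` (gamma' = gamma'' = 0), ``random``
  (gamma' = gamma''), or ``markovian`` (gamma' and gamma'' free);
* within-primary detection: constant ``p(.)``, seasonal ``p(season)``,
  per-occasion ``p(session)``, calendar-month-within-season
  ``p(season.month)``, or a two-class finite mixture ``p(mixture)``,

which yields 2 x 3 x 5 = 30 model structures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Optional

import numpy as np
from scipy.special import expit, logit

from .design import StudyDesign

SURVIVAL_STRUCTURES = ("constant", "seasonal")
EMIGRATION_STRUCTURES = ("none", "random", "markovian")
DETECTION_STRUCTURES = ("constant", "seasonal", "monthly",
                        "seasonal_by_month", "mixture2")

_SURVIVAL_LABEL = {"constant": "S(.)", "seasonal": "S(season)"}
_EMIGRATION_LABEL = {"none": "gamma(none)", "random": "gamma(random)",
                     "markovian": "gamma(markovian)"}
_DETECTION_LABEL = {"constant": "p(.)", "seasonal": "p(season)",
                    "monthly": "p(session)",
                    "seasonal_by_month": "p(season.month)",
                    "mixture2": "p(mixture)"}


@dataclass(frozen=True)
class RDModelSpec:
    """One candidate structure: survival x emigration x detection."""

    survival: str = "constant"
    emigration: str = "none"
    detection: str = "constant"

    def __post_init__(self):
        if self.survival not in SURVIVAL_STRUCTURES:
            raise ValueError(f"unknown survival structure {self.survival!r}")
        if self.emigration not in EMIGRATION_STRUCTURES:
            raise ValueError(f"unknown emigration structure {self.emigration!r}")
        if self.detection not in DETECTION_STRUCTURES:
            raise ValueError(f"unknown detection structure {self.detection!r}")

    @property
    def name(self) -> str:
        return ",".join([_SURVIVAL_LABEL[self.survival],
                         _EMIGRATION_LABEL[self.emigration],
                         _DETECTION_LABEL[self.detection]])

    @property
    def n_classes(self) -> int:
        return 2 if self.detection == "mixture2" else 1

    @classmethod
    def from_name(cls, name: str) -> "RDModelSpec":
        """Parse ``"S(.),gamma(random),p(mixture)"``-style model names."""
        rev_s = {v: k for k, v in _SURVIVAL_LABEL.items()}
        rev_g = {v: k for k, v in _EMIGRATION_LABEL.items()}
        rev_p = {v: k for k, v in _DETECTION_LABEL.items()}
        parts = [p.strip() for p in name.split(",")]
        if len(parts) != 3 or parts[0] not in rev_s or parts[1] not in rev_g \
                or parts[2] not in rev_p:
            raise ValueError(
                f"cannot parse model name {name!r}; expected e.g. "
                "'S(.),gamma(random),p(mixture)'"
            )
        return cls(rev_s[parts[0]], rev_g[parts[1]], rev_p[parts[2]])


def enumerate_model_suite(design: Optional[StudyDesign] = None) -> list[RDModelSpec]:
    """The full 30-member candidate suite, in a fixed deterministic order."""
    return [RDModelSpec(s, g, p)
            for s, g, p in product(SURVIVAL_STRUCTURES, EMIGRATION_STRUCTURES,
                                   DETECTION_STRUCTURES)]


@dataclass
class RDParameters:
    """Expanded natural-scale parameters of a Robust Design model.

    Arrays are fully expanded over intervals / occasions / mixture classes
    regardless of the generating structure, so the likelihood code is
    structure-agnostic.
    """

    S: np.ndarray             # (n_intervals,) apparent survival per interval
    gamma_prime: np.ndarray   # (n_intervals,) P(unavailable stays unavailable)
    gamma_dprime: np.ndarray  # (n_intervals,) P(available becomes unavailable)
    p: np.ndarray             # (n_occasions, n_classes) detection per occasion
    pi: np.ndarray            # (n_classes,) mixture weights, sum to 1

    def __post_init__(self):
        self.S = np.atleast_1d(np.asarray(self.S, dtype=float))
        self.gamma_prime = np.atleast_1d(np.asarray(self.gamma_prime, dtype=float))
        self.gamma_dprime = np.atleast_1d(np.asarray(self.gamma_dprime, dtype=float))
        self.p = np.asarray(self.p, dtype=float)
        if self.p.ndim == 1:
            self.p = self.p[:, None]
        self.pi = np.atleast_1d(np.asarray(self.pi, dtype=float))

    def validate(self):
        for name in ("S", "gamma_prime", "gamma_dprime", "p", "pi"):
            a = getattr(self, name)
            if np.any(a < 0) or np.any(a > 1) or np.any(~np.isfinite(a)):
                raise ValueError(f"{name} outside [0, 1]")
        if abs(self.pi.sum() - 1.0) > 1e-8:
            raise ValueError("mixture weights must sum to 1")
        if self.p.shape[1] != len(self.pi):
            raise ValueError("p classes inconsistent with pi")
        return self

    @property
    def n_classes(self) -> int:
        return len(self.pi)


class ParameterLayout:
    """Mapping between a free parameter vector (logit scale) and RDParameters.

    The free vector concatenates [survival | emigration | detection | pi],
    every entry on the logit scale, so quasi-Newton optimization is
    unconstrained.  The layout depends on both the model structure and the
    study design (a single-primary design has no survival or emigration
    parameters; seasonal structures use only the seasons actually present).
    """

    def __init__(self, spec: RDModelSpec, design: StudyDesign):
        self.spec = spec
        self.design = design
        T = design.n_primary
        n_int = design.n_intervals
        names: list[str] = []

        # survival: index per interval into the survival block
        if n_int == 0:
            self._s_idx = np.zeros(0, dtype=int)
            self._n_s = 0
        elif spec.survival == "constant":
            self._s_idx = np.zeros(n_int, dtype=int)
            self._n_s = 1
            names.append("S")
        else:
            seasons = [design.interval_season(i + 1) for i in range(n_int)]
            levels = sorted(set(seasons))
            self._s_idx = np.array([levels.index(s) for s in seasons])
            self._n_s = len(levels)
            names += [f"S[{s}]" for s in levels]

        # emigration
        if n_int == 0 or spec.emigration == "none":
            self._n_g = 0
        elif spec.emigration == "random":
            self._n_g = 1
            names.append("gamma")
        else:
            self._n_g = 2
            names += ["gamma_dprime", "gamma_prime"]

        # detection: index per occasion (class handled separately for mixture)
        occ = design.occasions
        if spec.detection == "constant":
            self._p_idx = np.zeros(len(occ), dtype=int)
            self._n_p = 1
            names.append("p")
        elif spec.detection == "seasonal":
            seasons = [o.season for o in occ]
            levels = sorted(set(seasons))
            self._p_idx = np.array([levels.index(s) for s in seasons])
            self._n_p = len(levels)
            names += [f"p[{s}]" for s in levels]
        elif spec.detection == "monthly":
            self._p_idx = np.arange(len(occ))
            self._n_p = len(occ)
            names += [f"p[{o.label}]" for o in occ]
        elif spec.detection == "seasonal_by_month":
            months = [o.month for o in occ]
            levels = sorted(set(months))
            self._p_idx = np.array([levels.index(m) for m in months])
            self._n_p = len(levels)
            names += [f"p[month={m}]" for m in levels]
        else:  # mixture2: one constant p per latent class, plus the weight
            self._p_idx = np.zeros(len(occ), dtype=int)
            self._n_p = 2
            names += ["p[class1]", "p[class2]", "pi"]

        self.names = names

    @property
    def n_par(self) -> int:
        extra = 1 if self.spec.detection == "mixture2" else 0
        return self._n_s + self._n_g + self._n_p + extra

    def default_start(self) -> np.ndarray:
        """All probabilities 0.5 on the natural scale (0 on logit scale)."""
        return np.zeros(self.n_par)

    def expand(self, theta: np.ndarray) -> RDParameters:
        """Free logit-scale vector -> fully expanded natural-scale parameters."""
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (self.n_par,):
            raise ValueError(f"expected {self.n_par} free parameters")
        x = expit(theta)
        n_int = self.design.n_intervals
        i = 0
        S = x[i + self._s_idx] if self._n_s else np.ones(n_int)
        i += self._n_s
        if self._n_g == 0:
            gp = gdp = np.zeros(n_int)
        elif self._n_g == 1:
            gp = gdp = np.full(n_int, x[i])
        else:
            gdp = np.full(n_int, x[i])
            gp = np.full(n_int, x[i + 1])
        i += self._n_g
        if self.spec.detection == "mixture2":
            p = np.column_stack([x[i + self._p_idx], x[i + 1 + self._p_idx]])
            pi1 = x[i + 2]
            pi = np.array([pi1, 1.0 - pi1])
        else:
            p = x[i + self._p_idx][:, None]
            pi = np.array([1.0])
        return RDParameters(S=S, gamma_prime=gp, gamma_dprime=gdp, p=p, pi=pi)

    def pack(self, params: RDParameters) -> np.ndarray:
        """Natural-scale RDParameters -> free logit vector (inverse of expand).

        Assumes the parameters are consistent with the structure (values tied
        by the layout must be equal); used for warm starts and testing.
        """
        def _first(vals, idx, k):
            out = np.empty(k)
            for j in range(k):
                out[j] = vals[np.nonzero(idx == j)[0][0]]
            return out

        parts = []
        if self._n_s:
            parts.append(_first(params.S, self._s_idx, self._n_s))
        if self._n_g == 1:
            parts.append([params.gamma_prime[0]])
        elif self._n_g == 2:
            parts.append([params.gamma_dprime[0], params.gamma_prime[0]])
        if self.spec.detection == "mixture2":
            parts.append(_first(params.p[:, 0], self._p_idx, 1))
            parts.append(_first(params.p[:, 1], self._p_idx, 1))
            parts.append([params.pi[0]])
        else:
            parts.append(_first(params.p[:, 0], self._p_idx, self._n_p))
        flat = np.concatenate([np.asarray(p, dtype=float) for p in parts])
        return logit(np.clip(flat, 1e-12, 1 - 1e-12))


def count_parameters(spec: RDModelSpec, design: StudyDesign) -> int:
    """Number of free parameters of a structure under a design."""
    return ParameterLayout(spec, design).n_par
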