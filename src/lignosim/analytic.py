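"""Closed-form characteristic-time framework for a single cellulose chain.

A chain of DP ``2N`` digested by EG, CBH and BGL admits first-order
characteristic times (hours):

* ``tau_EG   = F / ((2N - 4) K_EG n_EG)``
* ``tau_CBHA = 1 / (4 K_CBHA n_CBH)``   (attachment, crystallinity-blind)
* ``tau_CBHD = F * N / K_CBHD``
* ``tau_CBH  = tau_CBHA + tau_CBHD``
* ``tau_BGL  = F / (K_BGL n_BGL)``

where ``F = 1 + X (1/r - 1)`` is the crystallinity weighting.  Glucose
inhibition divides the enzyme counts by ``1 - omega n_glc / (S + n_glc)``
(cellobiose inhibition is negligible and dropped here, though the
simulator retains it).

The enzyme with the largest time is the time-limiting step.  In the most
constrained case the CBH-vs-EG comparison reduces to a quadratic in ``N``.
Two forms of that quadratic are provided:

* ``printed``:  P(N)  = 6N^2 - N (12 + 2 K_R) - 3 K_R
* ``derived``:  P~(N) = 6N^2 - N (12 + 2/K_R) - 3/K_R

The two differ by inversion of ``K_R = K_EG / K_CBHD``; the printed form
reproduces the reported roots at ``K_R = 1`` but its large-``K_R`` limit
contradicts the reported asymptotics, which match the derived form.  Both
are exposed and the discrepancy is surfaced in the regime report rather
than silently fixed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .kinetics import ParameterSet

__all__ = [
    "CharacteristicTimes",
    "RegimeReport",
    "crystallinity_factor",
    "characteristic_times",
    "limiting_step",
    "eg_regime_roots",
    "eg_validity",
    "bgl_threshold",
    "tau_sensitivity_report",
    "regime_report",
    "trunc_round",
]


def trunc_round(x: float, ndigits: int = 2) -> float:
    """Round toward zero at ``ndigits`` decimals (matches reported roots)."""
    scale = 10 ** ndigits
    return math.trunc(x * scale) / scale


def crystallinity_factor(X: float, r: float) -> float:
    """Crystallinity weighting ``1 + X (1/r - 1)``; >= 1, never < 1."""
    if not 0.0 <= X <= 1.0:
        raise ValueError("X must lie in [0, 1]")
    if not 0.0 < r <= 1.0:
        raise ValueError("r must lie in (0, 1]")
    return 1.0 + X * (1.0 / r - 1.0)


@dataclass(frozen=True)
class CharacteristicTimes:
    tau_EG: float
    tau_CBHA: float
    tau_CBHD: float
    tau_BGL: float
    inputs: dict = field(default_factory=dict)

    @property
    def tau_CBH(self) -> float:
        return self.tau_CBHA + self.tau_CBHD

    def as_dict(self) -> dict:
        return {"tau_EG": self.tau_EG, "tau_CBHA": self.tau_CBHA,
                "tau_CBHD": self.tau_CBHD, "tau_CBH": self.tau_CBH,
                "tau_BGL": self.tau_BGL}


def _inhibition_factor(omega: float, n_glc: float, s0: float) -> float:
    if n_glc <= 0:
        return 1.0
    return 1.0 - omega * n_glc / (s0 + n_glc)


def characteristic_times(N: float, K_EG: float, K_CBHA: float, K_CBHD: float,
                         K_BGL: float, n_EG0: float = 1.0, n_CBH0: float = 1.0,
                         n_BGL0: float = 1.0, X: float = 0.0, r: float = 1.0,
                         n_glc: float = 0.0, omega_EG_glc: float = 0.0,
                         omega_CBH_glc: float = 0.0, omega_BGL_glc: float = 0.0,
                         ) -> CharacteristicTimes:
    """Characteristic times for a chain of DP ``2N`` (requires ``N >= 3``).

    With all omegas zero this reduces to the uninhibited forms; with
    ``X = 0`` additionally to the bare amorphous-chain times.
    """
    if N < 3:
        raise ValueError("N must be >= 3 (EG needs at least one attack point)")
    for name, v in (("K_EG", K_EG), ("K_CBHA", K_CBHA), ("K_CBHD", K_CBHD),
                    ("K_BGL", K_BGL), ("n_EG0", n_EG0), ("n_CBH0", n_CBH0),
                    ("n_BGL0", n_BGL0)):
        if v <= 0:
            raise ValueError(f"{name} must be positive")
    F = crystallinity_factor(X, r)
    s0 = n_EG0 + n_CBH0 + n_BGL0
    inh_EG = _inhibition_factor(omega_EG_glc, n_glc, s0)
    inh_CBH = _inhibition_factor(omega_CBH_glc, n_glc, s0)
    inh_BGL = _inhibition_factor(omega_BGL_glc, n_glc, s0)

    def inv(x: float) -> float:
        return 1.0 / x if x > 0 else math.inf

    tau_EG = F * inv((2 * N - 4) * K_EG * n_EG0 * inh_EG)
    tau_CBHA = inv(4.0 * K_CBHA * n_CBH0 * inh_CBH)
    tau_CBHD = F * N / K_CBHD
    tau_BGL = F * inv(K_BGL * n_BGL0 * inh_BGL)
    return CharacteristicTimes(
        tau_EG=tau_EG, tau_CBHA=tau_CBHA, tau_CBHD=tau_CBHD, tau_BGL=tau_BGL,
        inputs={"N": N, "X": X, "r": r, "n_glc": n_glc,
                "K_EG": K_EG, "K_CBHA": K_CBHA, "K_CBHD": K_CBHD,
                "K_BGL": K_BGL, "n_EG0": n_EG0, "n_CBH0": n_CBH0,
                "n_BGL0": n_BGL0, "omega_EG_glc": omega_EG_glc,
                "omega_CBH_glc": omega_CBH_glc, "omega_BGL_glc": omega_BGL_glc})


def limiting_step(times: CharacteristicTimes):
    """Time-limiting enzyme (largest characteristic time) plus margins.

    Returns ``(enzyme, margins)`` where margins maps enzyme pairs to
    ratios; exact ties are reported as ``"tie"``.
    """
    taus = {"EG": times.tau_EG, "CBH": times.tau_CBH, "BGL": times.tau_BGL}
    best = max(taus, key=taus.get)
    ties = [k for k, v in taus.items() if v == taus[best]]
    margins = {f"{best}/{k}": (taus[best] / taus[k] if taus[k] > 0 else math.inf)
               for k in taus if k != best}
    return ("tie" if len(ties) > 1 else best), margins


def _quadratic_coeffs(K_R: float, form: str):
    if form == "printed":
        return 6.0, -(12.0 + 2.0 * K_R), -3.0 * K_R
    if form == "derived":
        return 6.0, -(12.0 + 2.0 / K_R), -3.0 / K_R
    raise ValueError(f"unknown form {form!r}")


def eg_regime_roots(K_R: float, form: str = "printed"):
    """Real roots (N1 >= N2) of the CBH-vs-EG regime quadratic.

    The discriminant is positive for every ``K_R > 0``, so both roots are
    always real, and their product is negative (they straddle zero).
    """
    if K_R <= 0:
        raise ValueError("K_R must be positive")
    a, b, c = _quadratic_coeffs(K_R, form)
    disc = b * b - 4 * a * c
    sq = math.sqrt(disc)
    n1 = (-b + sq) / (2 * a)
    n2 = (-b - sq) / (2 * a)
    return n1, n2


def eg_validity(K_R: float, N: float, form: str = "printed") -> bool:
    """True iff the regime quadratic is positive at ``N`` (CBH slower than
    EG in the most constrained case).

    The regime statement concerns ``N >= 3`` but the polynomial may be
    probed at any positive ``N`` (e.g. to verify root positions).
    """
    if N <= 0:
        raise ValueError("N must be positive")
    a, b, c = _quadratic_coeffs(K_R, form)
    return a * N * N + b * N + c > 0


@dataclass(frozen=True)
class BGLThreshold:
    """CBH-vs-BGL validity rule: kind in {all, none, above_threshold}."""

    kind: str
    threshold: float | None = None

    def valid(self, N: float) -> bool:
        if N < 3:
            raise ValueError("N must be >= 3")
        if self.kind == "all":
            return True
        if self.kind == "none":
            return False
        return N > self.threshold


def bgl_threshold(K_R_prime: float) -> BGLThreshold:
    """Validity rule for the CBH-vs-BGL comparison.

    ``K_R' < 2/3`` -> valid for all ``N >= 3``; ``K_R' = 2/3`` -> never;
    otherwise valid iff ``N > 3 / (3 K_R' - 2)``.
    """
    if K_R_prime <= 0:
        raise ValueError("K_R_prime must be positive")
    denom = 3.0 * K_R_prime - 2.0
    if denom < 0:
        return BGLThreshold("all")
    if denom == 0:
        return BGLThreshold("none")
    return BGLThreshold("above_threshold", threshold=3.0 / denom)


def tau_sensitivity_report(ranges: dict | None = None) -> dict:
    """Max relative change of ``tau_CBHA`` per unit parameter deviation.

    ``tau_CBHA`` is proportional to ``1/(n_CBH0 K_CBHA)``, so a unit
    deviation changes it by at most ``1/p`` evaluated at the range
    minimum.  Values are returned in percent.
    """
    if ranges is None:
        ranges = {"n_CBH0": (10.0, 100.0), "K_CBHA": (100.0, 1000.0)}
    out = {}
    for name, (lo, hi) in ranges.items():
        if lo <= 0 or hi < lo:
            raise ValueError(f"bad range for {name}")
        out[name] = {"range": (lo, hi),
                     "max_relative_change_pct": 100.0 / lo,
                     "at_value": lo}
    return out


@dataclass(frozen=True)
class RegimeReport:
    K_R: float
    K_R_prime: float
    N: float
    roots_printed: tuple
    roots_derived: tuple
    eg_valid_printed: bool
    eg_valid_derived: bool
    bgl_rule: BGLThreshold
    bgl_valid: bool
    limiting_enzyme: str
    margins: dict
    taus: dict

    def as_dict(self) -> dict:
        return {
            "K_R": self.K_R,
            "K_R_prime": self.K_R_prime,
            "N": self.N,
            "roots_printed": [trunc_round(x) for x in self.roots_printed],
            "roots_derived": [trunc_round(x) for x in self.roots_derived],
            "roots_printed_exact": list(self.roots_printed),
            "roots_derived_exact": list(self.roots_derived),
            "eg_valid_printed": self.eg_valid_printed,
            "eg_valid_derived": self.eg_valid_derived,
            "eg_forms_agree": self.eg_valid_printed == self.eg_valid_derived,
            "bgl_rule": {"kind": self.bgl_rule.kind,
                         "threshold": self.bgl_rule.threshold},
            "bgl_valid": self.bgl_valid,
            "limiting_enzyme": self.limiting_enzyme,
            "margins": self.margins,
            "taus": self.taus,
        }


def regime_report(params: ParameterSet, N: float, n_glc: float = 0.0) -> RegimeReport:
    """Full regime classification for one parameter set at half-DP ``N``."""
    K_R = params.K_EG / params.K_CBHD
    K_Rp = params.K_BGL / params.K_CBHD
    times = characteristic_times(
        N, K_EG=params.K_EG, K_CBHA=params.K_CBHA, K_CBHD=params.K_CBHD,
        K_BGL=params.K_BGL, n_EG0=params.n_EG0, n_CBH0=params.n_CBH0,
        n_BGL0=params.n_BGL0, X=params.X_cellulose, r=params.r_cellulose,
        n_glc=n_glc, omega_EG_glc=params.omega_EG_glc,
        omega_CBH_glc=params.omega_CBH_glc, omega_BGL_glc=params.omega_BGL_glc)
    enzyme, margins = limiting_step(times)
    rule = bgl_threshold(K_Rp)
    return RegimeReport(
        K_R=K_R, K_R_prime=K_Rp, N=N,
        roots_printed=eg_regime_roots(K_R, "printed"),
        roots_derived=eg_regime_roots(K_R, "derived"),
        eg_valid_printed=eg_validity(K_R, N, "printed"),
        eg_valid_derived=eg_validity(K_R, N, "derived"),
        bgl_rule=rule, bgl_valid=rule.valid(N),
        limiting_enzyme=enzyme, margins=margins, taus=times.as_dict())
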