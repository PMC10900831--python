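"""Enzyme cocktail: parameter registry, propensities, inhibition, lignin.

Four enzyme species act on the substrate:

* EG cuts any exposed intact cellulose bond except the two outermost bonds
  at each fragment end (so a bare fragment of DP ``m`` offers ``m - 5``
  attack points).
* CBH attaches to exposed free ends of cellulose fragments (rate
  ``K_CBHA`` per end per free enzyme) and processively cleaves cellobiose
  (rate ``K_CBHD`` per attached enzyme, scaled by ``r`` across crystalline
  bonds).
* BGL splits free cellobiose into two glucoses.
* XYL cuts any exposed intact hemicellulose bond.

End-product inhibition reduces the *effective* (possibly fractional)
number of cellulases:

    n_y = n_y0 * (1 - sum_x omega_y^x * n_x / (sum_y n_y0 + n_x))

with x in {glucose, cellobiose} and y in {EG, CBH, BGL}; the
BGL/cellobiose affinity is excluded (cellobiose is BGL's substrate),
leaving a registry of exactly 19 named parameters.  Lignin sequesters
enzymes non-productively: one enzyme per ``L_adh`` exposed monolignols,
statically bound.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Iterable

import numpy as np

from .substrate import Fragment, MicrofibrilState, PolymerKind

__all__ = [
    "PARAM_NAMES",
    "ParameterSet",
    "EnzymePool",
    "EventChannel",
    "effective_enzymes",
    "lignin_adsorb",
    "enumerate_channels",
    "total_propensity",
    "severing_bond",
]

#: The 19 sensitivity parameters, in registry order.
PARAM_NAMES = (
    "K_EG", "K_CBHA", "K_CBHD", "K_BGL", "K_XYL",
    "n_EG0", "n_CBH0", "n_BGL0", "n_XYL0",
    "X_cellulose", "X_hemicellulose", "r_cellulose", "r_hemicellulose",
    "L_adh",
    "omega_EG_glc", "omega_CBH_glc", "omega_BGL_glc",
    "omega_EG_cbs", "omega_CBH_cbs",
)

CELLULASES = ("EG", "CBH", "BGL")
SPECIES = ("EG", "CBH", "BGL", "XYL")


@dataclass(frozen=True)
class ParameterSet:
    """The 19 named scalar parameters (rates in events/h)."""

    K_EG: float = 500.0
    K_CBHA: float = 300.0
    K_CBHD: float = 50.0
    K_BGL: float = 500.0
    K_XYL: float = 500.0
    n_EG0: float = 5.0
    n_CBH0: float = 5.0
    n_BGL0: float = 5.0
    n_XYL0: float = 5.0
    X_cellulose: float = 0.3
    X_hemicellulose: float = 0.3
    r_cellulose: float = 5e-3
    r_hemicellulose: float = 5e-3
    L_adh: float = 0.0
    omega_EG_glc: float = 0.3
    omega_CBH_glc: float = 0.3
    omega_BGL_glc: float = 0.3
    omega_EG_cbs: float = 0.3
    omega_CBH_cbs: float = 0.3

    def __post_init__(self) -> None:
        for name in ("K_EG", "K_CBHA", "K_CBHD", "K_BGL", "K_XYL",
                     "n_EG0", "n_CBH0", "n_BGL0", "n_XYL0", "L_adh"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("X_cellulose", "X_hemicellulose"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} outside [0, 1]")
        for name in ("r_cellulose", "r_hemicellulose"):
            if not 0.0 < getattr(self, name) <= 1.0:
                raise ValueError(f"{name} outside (0, 1]")
        for name in PARAM_NAMES:
            if name.startswith("omega") and not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} outside [0, 1]")

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in PARAM_NAMES}

    @classmethod
    def from_dict(cls, d: dict) -> "ParameterSet":
        unknown = set(d) - set(PARAM_NAMES)
        if unknown:
            raise ValueError(f"unknown parameters: {sorted(unknown)}")
        return cls(**d)

    def replace(self, **kw) -> "ParameterSet":
        return replace(self, **kw)

    def omega(self, enzyme: str, inhibitor: str) -> float:
        if enzyme == "BGL" and inhibitor == "cbs":
            return 0.0  # excluded from the registry
        return getattr(self, f"omega_{enzyme}_{inhibitor}", 0.0)


assert len(PARAM_NAMES) == 19
assert len(PARAM_NAMES) == len(set(PARAM_NAMES))
assert set(PARAM_NAMES) == {f.name for f in fields(ParameterSet)}


@dataclass
class EnzymePool:
    """Per-species availability bookkeeping.

    ``n_effective`` is fractional: inhibition scales availability
    continuously rather than removing whole enzymes.  CBH attachments are
    stored on the substrate fragments; ``n_cbh_attached`` mirrors their
    count.
    """

    n0: dict = field(default_factory=dict)
    n_effective: dict = field(default_factory=dict)
    n_lignin_bound: dict = field(default_factory=dict)
    n_cbh_attached: int = 0

    @classmethod
    def from_params(cls, params: ParameterSet) -> "EnzymePool":
        n0 = {"EG": params.n_EG0, "CBH": params.n_CBH0,
              "BGL": params.n_BGL0, "XYL": params.n_XYL0}
        return cls(n0=n0, n_effective=dict(n0),
                   n_lignin_bound={s: 0 for s in SPECIES})

    @property
    def n_cbh_free(self) -> float:
        return max(0.0, self.n_effective["CBH"] - self.n_cbh_attached)

    def attachments(self, state: MicrofibrilState) -> list:
        """Stable-ordered list of (chain, end, position) CBH attachments."""
        out = []
        for ci, _ in state.iter_cellulose():
            for frag in state.fragments[ci]:
                if frag.cbh_left:
                    out.append((ci, "left", frag.start))
                if frag.cbh_right:
                    out.append((ci, "right", frag.end))
        return out


def effective_enzymes(pool: EnzymePool, free_glucose: int, free_cellobiose: int,
                      params: ParameterSet) -> EnzymePool:
    """Recompute fractional availability under end-product inhibition.

    The inhibition denominator sums the initial counts of the three
    cellulases (XYL is not inhibited).  Lignin-bound enzymes are removed
    before the inhibition factor is applied.
    """
    s0 = params.n_EG0 + params.n_CBH0 + params.n_BGL0
    for y in SPECIES:
        avail = max(0.0, pool.n0[y] - pool.n_lignin_bound[y])
        if y == "XYL":
            pool.n_effective[y] = avail
            continue
        inh = 0.0
        for x, n_x in (("glc", free_glucose), ("cbs", free_cellobiose)):
            if n_x > 0:
                inh += params.omega(y, x) * n_x / (s0 + n_x)
        pool.n_effective[y] = max(0.0, avail * (1.0 - inh))
    return pool


def lignin_adsorb(pool: EnzymePool, state: MicrofibrilState,
                  params: ParameterSet) -> EnzymePool:
    """Statically sequester enzymes on exposed lignin.

    One enzyme per ``L_adh`` exposed monolignols, allocated round-robin
    over EG, CBH, BGL, XYL.  ``L_adh = 0`` disables adsorption.  Bound
    enzymes are released only if the shielding lignin disappears (never,
    in the current cocktail, which contains no ligninase).
    """
    if params.L_adh <= 0:
        pool.n_lignin_bound = {s: 0 for s in SPECIES}
        return pool
    n_sites = math.floor(state.exposed_monolignols / params.L_adh)
    bound = {s: 0 for s in SPECIES}
    remaining = n_sites
    while remaining > 0:
        progressed = False
        for s in SPECIES:
            if remaining == 0:
                break
            if bound[s] < pool.n0[s]:
                bound[s] += 1
                remaining -= 1
                progressed = True
        if not progressed:
            break
    pool.n_lignin_bound = bound
    return pool


@dataclass(frozen=True)
class EventChannel:
    kind: str  # EG_cut | CBH_attach | CBH_cleave | BGL_split | XYL_cut
    target: tuple
    propensity: float

    def __post_init__(self) -> None:
        if self.propensity < 0:
            raise ValueError("negative propensity")


def severing_bond(frag: Fragment, side: str) -> int:
    """Bond hydrolysed when a CBH at ``side`` cleaves off a cellobiose."""
    if frag.dp == 2:
        return frag.start
    return frag.start + 1 if side == "left" else frag.end - 2


def eg_bond_range(frag: Fragment) -> tuple:
    """Inclusive bond-index range attackable by EG (two bonds excluded at
    each fragment end); empty if hi < lo."""
    return frag.start + 2, frag.end - 3


def enumerate_channels(state: MicrofibrilState, pool: EnzymePool,
                       params: ParameterSet) -> list:
    """Explicit per-site event channels in stable order.

    This is the reference enumeration used by tests and small runs; the
    engine uses an aggregated two-level draw with identical distribution
    and site ordering.
    """
    channels: list[EventChannel] = []
    r = params.r_cellulose
    k_eg = params.K_EG * pool.n_effective["EG"]
    for ci, chain in state.iter_cellulose():
        for frag in state.fragments[ci]:
            lo, hi = eg_bond_range(frag)
            for b in range(lo, hi + 1):
                if not state.bond_exposed(ci, b):
                    continue
                w = r if chain.bond_crystalline[b] else 1.0
                channels.append(EventChannel("EG_cut", (ci, b), k_eg * w))
    k_att = params.K_CBHA * pool.n_cbh_free
    for ci, _ in state.iter_cellulose():
        for frag in state.fragments[ci]:
            if frag.dp < 2:
                continue
            if not frag.cbh_left and state.monomer_exposed(ci, frag.start):
                channels.append(EventChannel(
                    "CBH_attach", (ci, frag.start, "left"), k_att))
            if not frag.cbh_right and state.monomer_exposed(ci, frag.end):
                channels.append(EventChannel(
                    "CBH_attach", (ci, frag.end, "right"), k_att))
    for ci, chain in state.iter_cellulose():
        for frag in state.fragments[ci]:
            for side, attached in (("left", frag.cbh_left),
                                   ("right", frag.cbh_right)):
                if not attached:
                    continue
                b = severing_bond(frag, side)
                w = r if chain.bond_crystalline[b] else 1.0
                channels.append(EventChannel(
                    "CBH_cleave", (ci, frag.start, side), params.K_CBHD * w))
    k_bgl = params.K_BGL * pool.n_effective["BGL"]
    for i in range(state.free_cellobiose):
        channels.append(EventChannel("BGL_split", (i,), k_bgl))
    r_h = params.r_hemicellulose
    k_xyl = params.K_XYL * pool.n_effective["XYL"]
    for ci, chain in enumerate(state.chains):
        if chain.kind is not PolymerKind.HEMICELLULOSE:
            continue
        for b in np.flatnonzero(chain.bond_intact):
            b = int(b)
            if not (chain.present[b] and chain.present[b + 1]):
                continue
            if not state.bond_exposed(ci, b):
                continue
            w = r_h if chain.bond_crystalline[b] else 1.0
            channels.append(EventChannel("XYL_cut", (ci, b), k_xyl * w))
    return channels


def total_propensity(channels: Iterable[EventChannel]) -> float:
    return float(sum(ch.propensity for ch in channels))
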