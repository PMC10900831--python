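"""Coarse-grained microfibril substrate.

The substrate is a single microfibril resolved at monomer level: cellulose
chains at the core (glucose monomers), an optional hemicellulose sheath
(xylose monomers) and an optional outer lignin layer (monolignols).  Chains
are laid out on a concentric-ring lattice; a monomer in layer ``l`` is
shielded by the monomer directly above it in layer ``l + 1`` (same axial
index, ring sector mapped by modular wrap).  The outermost layer is always
exposed.

Bonds carry a crystalline/amorphous label; crystalline bonds are digested
at a reduced propensity (the digestibility ratio ``r``).  Cleaving a bond
never changes its label.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "PolymerKind",
    "PolymerChain",
    "Fragment",
    "CrystallinitySpec",
    "StructureConfig",
    "MicrofibrilState",
    "build_microfibril",
    "assign_crystallinity",
    "expose_update",
]


class PolymerKind(str, Enum):
    CELLULOSE = "cellulose"
    HEMICELLULOSE = "hemicellulose"
    LIGNIN = "lignin"


@dataclass
class PolymerChain:
    """One polymer chain on the lattice.

    ``bond_intact[i]`` / ``bond_crystalline[i]`` refer to the bond between
    monomers ``i`` and ``i + 1``; a chain of ``n`` monomers has ``n - 1``
    bonds.  ``present[m]`` is False once monomer ``m`` has been released
    from the lattice.
    """

    kind: PolymerKind
    monomer_count: int
    layer_index: int
    ring_pos: int
    axial_offset: int = 0
    bond_intact: np.ndarray = field(default=None, repr=False)
    bond_crystalline: np.ndarray = field(default=None, repr=False)
    present: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        n_bonds = max(self.monomer_count - 1, 0)
        if self.bond_intact is None:
            self.bond_intact = np.ones(n_bonds, dtype=bool)
        if self.bond_crystalline is None:
            self.bond_crystalline = np.zeros(n_bonds, dtype=bool)
        if self.present is None:
            self.present = np.ones(self.monomer_count, dtype=bool)
        if self.kind is PolymerKind.LIGNIN and self.bond_crystalline.any():
            raise ValueError("lignin bonds are always amorphous")

    @property
    def n_bonds(self) -> int:
        return max(self.monomer_count - 1, 0)


@dataclass
class Fragment:
    """Maximal run of connected cellulose monomers (inclusive indices).

    All bonds strictly inside a fragment are intact by construction.  A CBH
    enzyme may occupy either end; at most one per end.
    """

    start: int
    end: int
    cbh_left: bool = False
    cbh_right: bool = False

    @property
    def dp(self) -> int:
        return self.end - self.start + 1


def _round_half_away(x: float) -> int:
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


@dataclass(frozen=True)
class CrystallinitySpec:
    """Requested crystalline-bond fractions and digestibility ratios.

    The realised crystalline count per polymer type is exactly
    ``round(X * total_bonds)`` with half-away-from-zero rounding, pooled
    over all chains of that type and then distributed by ``layout``.
    """

    X_cellulose: float = 0.0
    X_hemicellulose: float = 0.0
    r_cellulose: float = 1.0
    r_hemicellulose: float = 1.0
    layout: str = "contiguous_blocks"

    def __post_init__(self) -> None:
        for name in ("X_cellulose", "X_hemicellulose"):
            x = getattr(self, name)
            if not 0.0 <= x <= 1.0:
                raise ValueError(f"{name}={x} outside [0, 1]")
        for name in ("r_cellulose", "r_hemicellulose"):
            r = getattr(self, name)
            if not 0.0 < r <= 1.0:
                raise ValueError(f"{name}={r} outside (0, 1]")
        if self.layout not in ("random", "contiguous_blocks"):
            raise ValueError(f"unknown layout {self.layout!r}")


@dataclass(frozen=True)
class StructureConfig:
    """Microfibril geometry.

    ``cellulose_rings`` lists the number of cellulose chains per concentric
    ring, innermost first.  The hemicellulose sheath (if any) sits in the
    layer above the outermost cellulose ring, and the lignin layer above
    that.  ``lignin_monomers`` are distributed over the lignin-layer
    columns starting from axial index 0.

    The default desk-scale fibril (12 chains of DP 100) is a project
    choice, small enough for seconds-scale runs while preserving layered
    shielding; it is not a measured geometry.
    """

    cellulose_rings: tuple = (12,)
    cellulose_dp: int = 100
    hemicellulose_chains: int = 0
    hemicellulose_dp: int = 100
    lignin_monomers: int = 0
    pretreated: bool = False

    def __post_init__(self) -> None:
        if len(self.cellulose_rings) < 1 or any(c < 1 for c in self.cellulose_rings):
            raise ValueError("need at least one cellulose chain per ring")
        if self.cellulose_dp < 4:
            raise ValueError("cellulose DP must be >= 4")
        if self.hemicellulose_chains < 0 or self.lignin_monomers < 0:
            raise ValueError("layer content must be >= 0")
        if self.hemicellulose_chains > 0 and self.hemicellulose_dp < 2:
            raise ValueError("hemicellulose DP must be >= 2")

    @property
    def effective(self) -> "StructureConfig":
        """Config with pre-treatment applied (strips hemicellulose/lignin)."""
        if self.pretreated:
            return replace(self, hemicellulose_chains=0, lignin_monomers=0,
                           pretreated=False)
        return self

    def to_dict(self) -> dict:
        return {
            "cellulose_rings": list(self.cellulose_rings),
            "cellulose_dp": self.cellulose_dp,
            "hemicellulose_chains": self.hemicellulose_chains,
            "hemicellulose_dp": self.hemicellulose_dp,
            "lignin_monomers": self.lignin_monomers,
            "pretreated": self.pretreated,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StructureConfig":
        d = dict(d)
        if "cellulose_rings" in d:
            d["cellulose_rings"] = tuple(d["cellulose_rings"])
        return cls(**d)


@dataclass
class MicrofibrilState:
    """Full mutable substrate state plus free-sugar pools."""

    chains: list
    fragments: list  # per-chain list[Fragment]; empty for non-cellulose
    layers: dict  # layer index -> ordered chain indices
    cover: list  # per-chain covering chain index (or None if outermost)
    initial_glucose: int = 0
    initial_xylose: int = 0
    free_cellobiose: int = 0
    free_glucose: int = 0
    free_xylose: int = 0
    crystallinity: CrystallinitySpec | None = None
    _crys_prefix: list = field(default=None, repr=False)

    # -- exposure ---------------------------------------------------------

    def monomer_exposed(self, ci: int, m: int) -> bool:
        cov = self.cover[ci]
        if cov is None:
            return True
        cov_chain = self.chains[cov]
        if m >= cov_chain.monomer_count:
            return True
        return not cov_chain.present[m]

    def bond_exposed(self, ci: int, b: int) -> bool:
        return self.monomer_exposed(ci, b) and self.monomer_exposed(ci, b + 1)

    def bond_exposure_array(self, ci: int):
        """Boolean exposure per bond of chain ``ci``; None if all exposed."""
        cov = self.cover[ci]
        if cov is None:
            return None
        chain = self.chains[ci]
        cov_chain = self.chains[cov]
        covp = np.zeros(chain.monomer_count, dtype=bool)
        n = min(cov_chain.monomer_count, chain.monomer_count)
        covp[:n] = cov_chain.present[:n]
        return ~covp[:-1] & ~covp[1:]

    @property
    def exposed_bond_index(self) -> set:
        """Set of (chain, bond) pairs that are intact and attackable."""
        out = set()
        for ci, chain in enumerate(self.chains):
            if chain.kind is PolymerKind.LIGNIN:
                continue
            for b in np.flatnonzero(chain.bond_intact):
                b = int(b)
                if (chain.present[b] and chain.present[b + 1]
                        and self.bond_exposed(ci, b)):
                    out.add((ci, b))
        return out

    @property
    def exposed_monolignols(self) -> int:
        n = 0
        for ci, chain in enumerate(self.chains):
            if chain.kind is not PolymerKind.LIGNIN:
                continue
            for m in range(chain.monomer_count):
                if chain.present[m] and self.monomer_exposed(ci, m):
                    n += 1
        return n

    # -- bookkeeping ------------------------------------------------------

    def iter_cellulose(self) -> Iterator[tuple]:
        for ci, chain in enumerate(self.chains):
            if chain.kind is PolymerKind.CELLULOSE:
                yield ci, chain

    def glucose_in_chains(self) -> int:
        return sum(f.dp for ci, _ in self.iter_cellulose()
                   for f in self.fragments[ci])

    def xylose_in_chains(self) -> int:
        return int(sum(chain.present.sum() for chain in self.chains
                       if chain.kind is PolymerKind.HEMICELLULOSE))

    def check_conservation(self) -> None:
        glc = self.glucose_in_chains() + 2 * self.free_cellobiose + self.free_glucose
        if glc != self.initial_glucose:
            raise AssertionError(
                f"glucose balance broken: {glc} != {self.initial_glucose}")
        xyl = self.xylose_in_chains() + self.free_xylose
        if xyl != self.initial_xylose:
            raise AssertionError(
                f"xylose balance broken: {xyl} != {self.initial_xylose}")

    def conversion(self) -> float:
        """Percent glucose released from cellulose."""
        if self.initial_glucose == 0:
            return 0.0
        return 100.0 * self.free_glucose / self.initial_glucose

    def crys_prefix(self, ci: int) -> np.ndarray:
        """Prefix sums of crystalline bond labels for chain ``ci``."""
        if self._crys_prefix is None:
            self._crys_prefix = [None] * len(self.chains)
        if self._crys_prefix[ci] is None:
            chain = self.chains[ci]
            self._crys_prefix[ci] = np.concatenate(
                ([0], np.cumsum(chain.bond_crystalline, dtype=np.int64)))
        return self._crys_prefix[ci]

    def invalidate_crys_cache(self) -> None:
        self._crys_prefix = None

    def snapshot(self) -> dict:
        """JSON-serialisable snapshot (debugging / fixtures)."""
        return {
            "free_glucose": self.free_glucose,
            "free_cellobiose": self.free_cellobiose,
            "free_xylose": self.free_xylose,
            "initial_glucose": self.initial_glucose,
            "initial_xylose": self.initial_xylose,
            "chains": [
                {
                    "kind": c.kind.value,
                    "layer": c.layer_index,
                    "ring_pos": c.ring_pos,
                    "monomer_count": c.monomer_count,
                    "bond_intact": c.bond_intact.astype(int).tolist(),
                    "bond_crystalline": c.bond_crystalline.astype(int).tolist(),
                    "present": c.present.astype(int).tolist(),
                }
                for c in self.chains
            ],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.snapshot(), fh)


def build_microfibril(config: StructureConfig, seed: int = 0) -> MicrofibrilState:
    """Construct a fresh (fully intact, all-amorphous) microfibril.

    Deterministic for a fixed ``(config, seed)``; the seed is reserved for
    future randomised placements and is currently unused because the
    lattice layout is fully deterministic.
    """
    cfg = config.effective
    chains: list[PolymerChain] = []
    layers: dict[int, list[int]] = {}

    def add_chain(chain: PolymerChain) -> int:
        idx = len(chains)
        chains.append(chain)
        layers.setdefault(chain.layer_index, []).append(idx)
        return idx

    for ring, n_chains in enumerate(cfg.cellulose_rings):
        for pos in range(n_chains):
            add_chain(PolymerChain(PolymerKind.CELLULOSE, cfg.cellulose_dp,
                                   layer_index=ring, ring_pos=pos))
    layer = len(cfg.cellulose_rings)
    if cfg.hemicellulose_chains > 0:
        for pos in range(cfg.hemicellulose_chains):
            add_chain(PolymerChain(PolymerKind.HEMICELLULOSE,
                                   cfg.hemicellulose_dp,
                                   layer_index=layer, ring_pos=pos))
        layer += 1
    if cfg.lignin_monomers > 0:
        n_cols = cfg.hemicellulose_chains or cfg.cellulose_rings[-1]
        base, rem = divmod(cfg.lignin_monomers, n_cols)
        pos = 0
        for col in range(n_cols):
            n_mono = base + (1 if col < rem else 0)
            if n_mono == 0:
                continue
            add_chain(PolymerChain(PolymerKind.LIGNIN, n_mono,
                                   layer_index=layer, ring_pos=pos))
            pos += 1

    top = max(layers)
    cover: list[int | None] = []
    for chain in chains:
        if chain.layer_index == top:
            cover.append(None)
        else:
            above = layers.get(chain.layer_index + 1)
            if not above:
                cover.append(None)
            else:
                cover.append(above[chain.ring_pos % len(above)])

    fragments = [
        [Fragment(0, c.monomer_count - 1)] if c.kind is PolymerKind.CELLULOSE else []
        for c in chains
    ]
    state = MicrofibrilState(
        chains=chains,
        fragments=fragments,
        layers=layers,
        cover=cover,
        initial_glucose=sum(c.monomer_count for c in chains
                            if c.kind is PolymerKind.CELLULOSE),
        initial_xylose=sum(c.monomer_count for c in chains
                           if c.kind is PolymerKind.HEMICELLULOSE),
    )
    return state


def _distribute_counts(total: int, sizes: Sequence[int]) -> list:
    """Largest-remainder split of ``total`` over buckets with capacities."""
    cap = sum(sizes)
    if total > cap:
        raise ValueError("crystalline bond count exceeds available bonds")
    if cap == 0:
        return [0] * len(sizes)
    quotas = [total * s / cap for s in sizes]
    counts = [min(int(q), s) for q, s in zip(quotas, sizes)]
    remainders = sorted(range(len(sizes)),
                        key=lambda i: quotas[i] - int(quotas[i]), reverse=True)
    short = total - sum(counts)
    for i in remainders:
        if short == 0:
            break
        if counts[i] < sizes[i]:
            counts[i] += 1
            short -= 1
    # spill over if some buckets were capped
    i = 0
    while short > 0 and i < len(sizes):
        room = sizes[i] - counts[i]
        take = min(room, short)
        counts[i] += take
        short -= take
        i += 1
    return counts


def assign_crystallinity(state: MicrofibrilState, spec: CrystallinitySpec,
                         seed=0) -> MicrofibrilState:
    """Label bonds crystalline in place, matching round(X * bonds) exactly.

    ``seed`` may be an int or a ``numpy.random.Generator``.  Requires a
    freshly built state (no cleaved bonds, nothing released).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    for chain in state.chains:
        if chain.kind is PolymerKind.LIGNIN:
            continue
        if not chain.bond_intact.all() or not chain.present.all():
            raise ValueError("crystallinity must be assigned before digestion")

    for kind, x_frac in ((PolymerKind.CELLULOSE, spec.X_cellulose),
                         (PolymerKind.HEMICELLULOSE, spec.X_hemicellulose)):
        targets = [c for c in state.chains if c.kind is kind]
        if not targets:
            continue
        total_bonds = sum(c.n_bonds for c in targets)
        n_crys = _round_half_away(x_frac * total_bonds)
        if spec.layout == "random":
            flat = rng.choice(total_bonds, size=n_crys, replace=False)
            mask = np.zeros(total_bonds, dtype=bool)
            mask[flat] = True
            off = 0
            for c in targets:
                c.bond_crystalline[:] = mask[off:off + c.n_bonds]
                off += c.n_bonds
        else:  # contiguous_blocks: one block per chain, seeded start
            per_chain = _distribute_counts(n_crys, [c.n_bonds for c in targets])
            for c, k in zip(targets, per_chain):
                c.bond_crystalline[:] = False
                if k > 0:
                    start = int(rng.integers(0, c.n_bonds - k + 1))
                    c.bond_crystalline[start:start + k] = True
    state.crystallinity = spec
    state.invalidate_crys_cache()
    return state


def expose_update(state: MicrofibrilState, event=None) -> MicrofibrilState:
    """Refresh exposure bookkeeping after an applied event.

    Exposure is derived on demand from the ``present`` arrays of covering
    chains, so there is no cached index to rebuild; this hook exists for
    API symmetry and returns the state unchanged.
    """
    return state
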