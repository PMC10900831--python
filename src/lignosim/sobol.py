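"""Variance-based global sensitivity analysis (total-order indices only).

The sampling design is the first/total-order cross-sampling construction:
a scrambled Sobol' sequence of dimension ``2p`` provides matrices A and B
(``N_base`` rows each); the AB_i matrices copy A with column ``i`` taken
from B.  The design emits ``N_base * (p + 2)`` parameter sets, laid out as
``[A; B; AB_0; ...; AB_{p-1}]``.  Total-order indices use the Jansen
estimator

    S_T,i = mean((f(A_j) - f(AB_j^i))^2) / (2 Var(f))

with bootstrap percentile confidence intervals over the base-sample rows.
Indices are reported raw and normalised by the index of a reference
parameter (default ``K_CBHD``).
"""

from __future__ import annotations

import hashlib
import json
import math
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import qmc

from . import __version__
from .engine import TimeCourse

__all__ = [
    "SSAProblem",
    "ObjectiveValue",
    "SobolResult",
    "CampaignManifest",
    "saltelli_sample",
    "objective",
    "total_indices",
    "normalise",
    "build_manifest",
    "run_campaign",
]


@dataclass(frozen=True)
class SSAProblem:
    """Sensitivity-problem definition.

    ``bounds`` maps each parameter name to ``(low, high)`` and ``scales``
    to ``"linear"`` or ``"log10"``.  ``n_base`` must be a power of two
    (balance of the low-discrepancy sequence).
    """

    names: tuple
    bounds: dict
    scales: dict
    n_base: int = 1024
    replicates: int = 10
    reference: TimeCourse | None = None
    threshold_close: float = 150.0
    threshold_spread: float = 75.0

    def __post_init__(self) -> None:
        if len(self.names) != len(set(self.names)):
            raise ValueError("parameter names must be unique")
        if self.n_base < 2 or self.n_base & (self.n_base - 1):
            raise ValueError("n_base must be a power of 2")
        for name in self.names:
            lo, hi = self.bounds[name]
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError(f"bad bounds for {name}: ({lo}, {hi})")
            scale = self.scales.get(name, "linear")
            if scale not in ("linear", "log10"):
                raise ValueError(f"bad scale for {name}: {scale}")
            if scale == "log10" and lo <= 0:
                raise ValueError(f"log10 scale needs positive bounds ({name})")

    @property
    def p(self) -> int:
        return len(self.names)

    @property
    def n_samples(self) -> int:
        return self.n_base * (self.p + 2)


def _transform(u: np.ndarray, problem: SSAProblem) -> np.ndarray:
    out = np.empty_like(u)
    for j, name in enumerate(problem.names):
        lo, hi = problem.bounds[name]
        if problem.scales.get(name, "linear") == "log10":
            out[:, j] = 10 ** (math.log10(lo)
                               + u[:, j] * (math.log10(hi) - math.log10(lo)))
        else:
            out[:, j] = lo + u[:, j] * (hi - lo)
    return out


def saltelli_sample(problem: SSAProblem, seed: int = 0) -> np.ndarray:
    """Emit the ``N_base * (p + 2)`` design matrix (rows = parameter sets).

    Layout: rows ``[0, N)`` are A, ``[N, 2N)`` are B, then one AB_i block
    of ``N`` rows per parameter, in registry order.
    """
    p = problem.p
    n = problem.n_base
    sampler = qmc.Sobol(d=2 * p, scramble=True, seed=seed)
    base = sampler.random_base2(int(math.log2(n)))
    a, b = base[:, :p], base[:, p:]
    blocks = [a, b]
    for i in range(p):
        ab = a.copy()
        ab[:, i] = b[:, i]
        blocks.append(ab)
    return _transform(np.vstack(blocks), problem)


@dataclass(frozen=True)
class ObjectiveValue:
    Y: float
    sign_class: str  # close | above | below
    signed: float


def objective(sim: TimeCourse, ref: TimeCourse, threshold_close: float = 150.0,
              interpolate: bool = False) -> ObjectiveValue:
    """Grid-point sum of absolute curve differences (percent units).

    ``Y = sum_i |sim(t_i) - ref(t_i)|`` over the reference grid; the
    close/above/below class follows the sign of the summed difference when
    ``Y`` exceeds the threshold.
    """
    if sim.times.shape != ref.times.shape or not np.allclose(sim.times, ref.times):
        if not interpolate:
            raise ValueError("time grids differ; pass interpolate=True")
        sim_vals = np.interp(ref.times, sim.times, sim.conversion)
    else:
        sim_vals = sim.conversion
    diff = sim_vals - ref.conversion
    y = float(np.abs(diff).sum())
    signed = float(diff.sum())
    if y < threshold_close:
        cls = "close"
    else:
        cls = "above" if signed > 0 else "below"
    return ObjectiveValue(Y=y, sign_class=cls, signed=signed)


@dataclass
class SobolResult:
    names: tuple
    S_T: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_base: int
    estimator: str = "jansen"
    normalised: np.ndarray | None = None
    reference_param: str | None = None

    def as_dict(self) -> dict:
        d = {
            "names": list(self.names),
            "S_T": [float(x) for x in self.S_T],
            "ci_low": [float(x) for x in self.ci_low],
            "ci_high": [float(x) for x in self.ci_high],
            "n_base": self.n_base,
            "estimator": self.estimator,
        }
        if self.normalised is not None:
            d["normalised"] = [float(x) for x in self.normalised]
            d["reference_param"] = self.reference_param
        return d

    def ranks(self, normalised: bool = True) -> dict:
        """Map name -> rank (1 = largest index)."""
        vals = self.normalised if (normalised and self.normalised is not None) \
            else self.S_T
        order = np.argsort(vals)[::-1]
        return {self.names[i]: rank + 1 for rank, i in enumerate(order)}


def _jansen(f_a: np.ndarray, f_b: np.ndarray, f_ab: np.ndarray) -> np.ndarray:
    var = np.var(np.concatenate([f_a, f_b]))
    if var == 0:
        raise ValueError("zero output variance: Sobol indices undefined")
    return 0.5 * np.mean((f_a[None, :] - f_ab) ** 2, axis=1) / var


def total_indices(Y: np.ndarray, problem: SSAProblem, n_boot: int = 100,
                  seed: int = 0) -> SobolResult:
    """Jansen total-order estimates from objective values in design layout."""
    Y = np.asarray(Y, dtype=float)
    p, n = problem.p, problem.n_base
    if Y.shape != (n * (p + 2),):
        raise ValueError("Y length does not match the design layout")
    f_a = Y[:n]
    f_b = Y[n:2 * n]
    f_ab = Y[2 * n:].reshape(p, n)
    s_t = _jansen(f_a, f_b, f_ab)
    rng = np.random.default_rng(seed)
    boots = np.empty((n_boot, p))
    for k in range(n_boot):
        idx = rng.integers(0, n, size=n)
        boots[k] = _jansen(f_a[idx], f_b[idx], f_ab[:, idx])
    ci_low = np.percentile(boots, 2.5, axis=0)
    ci_high = np.percentile(boots, 97.5, axis=0)
    return SobolResult(names=tuple(problem.names), S_T=s_t,
                       ci_low=ci_low, ci_high=ci_high, n_base=n)


def normalise(result: SobolResult, reference_param: str = "K_CBHD") -> SobolResult:
    """Scale indices by the reference parameter's total index."""
    if reference_param not in result.names:
        raise ValueError(f"{reference_param} not in result")
    base = result.normalised if result.normalised is not None else result.S_T
    ref = base[result.names.index(reference_param)]
    if ref == 0:
        raise ValueError("reference parameter has zero total index")
    result.normalised = np.asarray(base) / ref
    result.reference_param = reference_param
    return result


@dataclass
class CampaignManifest:
    """Reproducibility record for a (multi-condition) campaign."""

    version: str
    seed: int
    n_base: int
    n_parameters: int
    sets_per_condition: int
    replicates: int
    conditions: int
    planned_runs: int
    config_hash: str = ""
    paths: dict = field(default_factory=dict)
    timestamp: float = 0.0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def build_manifest(problem: SSAProblem, conditions: int = 1, seed: int = 0,
                   paths: dict | None = None) -> CampaignManifest:
    payload = json.dumps({"names": list(problem.names),
                          "bounds": {k: list(v) for k, v in problem.bounds.items()},
                          "n_base": problem.n_base,
                          "replicates": problem.replicates,
                          "seed": seed}, sort_keys=True)
    sets = problem.n_samples
    return CampaignManifest(
        version=__version__, seed=seed, n_base=problem.n_base,
        n_parameters=problem.p, sets_per_condition=sets,
        replicates=problem.replicates, conditions=conditions,
        planned_runs=sets * problem.replicates * conditions,
        config_hash=hashlib.sha256(payload.encode()).hexdigest()[:16],
        paths=paths or {}, timestamp=time.time())


def _row_seed(row: int, n_base: int, base_seed: int) -> int:
    """Common random numbers: every block reuses the seed of its base row."""
    if row < 2 * n_base:
        j = row % n_base
    else:
        j = (row - 2 * n_base) % n_base
    return base_seed + 7919 * (j + 1)


def run_campaign(problem: SSAProblem, simulator, out_dir, seed: int = 0,
                 reference_param: str = "K_CBHD", resume: bool = True,
                 flush_every: int = 256):
    """Full pipeline: sample -> simulate -> objective -> analyse.

    ``simulator(params: dict, seed: int) -> TimeCourse`` must perform its
    own replicate averaging.  The per-sample table is persisted
    incrementally so an interrupted campaign can resume.  Returns
    ``(SobolResult, objectives DataFrame)``.
    """
    if problem.reference is None:
        raise ValueError("problem.reference required for a campaign")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    samples = saltelli_sample(problem, seed=seed)
    sample_df = pd.DataFrame(samples, columns=list(problem.names))
    sample_df.to_csv(out_dir / "samples.csv", index=False)

    obj_path = out_dir / "objectives.csv"
    done: dict[int, tuple] = {}
    if resume and obj_path.exists():
        try:
            prev = pd.read_csv(obj_path)
            for _, row in prev.iterrows():
                done[int(row["row"])] = (row["Y"], row["signed"], row["sign_class"])
        except Exception:
            done = {}

    rows = []
    mode = "w"
    header = True
    buffer = []

    def flush():
        nonlocal mode, header, buffer
        if buffer:
            pd.DataFrame(buffer).to_csv(obj_path, mode=mode, header=header,
                                        index=False)
            mode, header, buffer = "a", False, []

    for row_i in range(len(samples)):
        if row_i in done:
            y, signed, cls = done[row_i]
        else:
            params = dict(zip(problem.names, samples[row_i]))
            sim = simulator(params, _row_seed(row_i, problem.n_base, seed))
            obj = objective(sim, problem.reference,
                            threshold_close=problem.threshold_close,
                            interpolate=True)
            y, signed, cls = obj.Y, obj.signed, obj.sign_class
        rec = {"row": row_i, "Y": y, "signed": signed, "sign_class": cls}
        rows.append(rec)
        buffer.append(rec)
        if len(buffer) >= flush_every:
            flush()
    flush()

    obj_df = pd.DataFrame(rows)
    result = total_indices(obj_df["Y"].to_numpy(), problem, seed=seed)
    result = normalise(result, reference_param)
    with open(out_dir / "sobol_indices.json", "w") as fh:
        json.dump(result.as_dict(), fh, indent=2)
    manifest = build_manifest(problem, conditions=1, seed=seed,
                              paths={"samples": "samples.csv",
                                     "objectives": "objectives.csv",
                                     "indices": "sobol_indices.json"})
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest.as_dict(), fh, indent=2)
    return result, obj_df
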