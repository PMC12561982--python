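"""Foreperiod probability distributions and normalized hazard functions.

The hazard function HF(t) = f(t) / (1 - C(t)) gives the probability that the
target occurs at time t given that it has not occurred yet, where f is the
discrete foreperiod distribution on the 0.4-2.0 s grid and C(t) is the
cumulative mass strictly before t.  Where the denominator vanishes the value
is capped at the running maximum of the preceding hazard values, and the
final series is normalized to [0, 1] by its maximum.

Two hazards drive the analyses: HF_U from the unconditional (pooled)
foreperiod distribution, and HF_C from the distribution of FP2 conditioned on
the preceding FP1.  Utilities cover cubic-spline upsampling to the neural
sampling rate, temporally/probabilistically blurred variants, and the
5-segment shuffle used as an encoding-model control.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from . import paradigm

#: Native hazard grid: 0.4..2.0 s at 0.1-s steps (17 points, 10 Hz).
NATIVE_TIMES: np.ndarray = np.round(np.arange(40, 201, 10) / 100.0, 2)
NATIVE_RATE_HZ = 10

_SHORT_MASK = NATIVE_TIMES <= 1.15
_LONG_MASK = NATIVE_TIMES >= 1.25


@dataclass(frozen=True)
class Pmf:
    """Discrete probability mass over foreperiod durations (seconds)."""

    times: np.ndarray
    mass: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        m = np.asarray(self.mass, dtype=float)
        if t.shape != m.shape or t.ndim != 1:
            raise ValueError("times and mass must be 1-D arrays of equal length")
        if np.any(m < -1e-12):
            raise ValueError("probability mass must be nonnegative")
        if abs(m.sum() - 1.0) > 1e-9:
            raise ValueError(f"probability mass sums to {m.sum()}, not 1")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "mass", m)

    def mass_in(self, lo: float, hi: float) -> float:
        """Total mass on durations in the closed interval [lo, hi]."""
        sel = (self.times >= lo - 1e-9) & (self.times <= hi + 1e-9)
        return float(self.mass[sel].sum())

    @property
    def short_mass(self) -> float:
        return self.mass_in(0.4, 1.1)

    @property
    def long_mass(self) -> float:
        return self.mass_in(1.3, 2.0)


@dataclass(frozen=True)
class ConditionalPmfSet:
    """FP2 distributions keyed by FP1 duration or category ('S'/'L')."""

    mapping: Mapping[object, Pmf]
    conditioning_mode: str


@dataclass(frozen=True)
class HazardSeries:
    """A (normalized) hazard sampled on a regular time grid."""

    times: np.ndarray
    values: np.ndarray
    rate_hz: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.shape != v.shape or t.ndim != 1:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    def value_at(self, time_s) -> np.ndarray | float:
        """Value(s) at grid time(s); raises if a time is off the grid."""
        idx = np.round((np.asarray(time_s, dtype=float) - self.times[0]) * self.rate_hz)
        idx = idx.astype(int)
        on_grid = np.isclose(
            self.times[np.clip(idx, 0, len(self.times) - 1)], time_s, atol=1e-6
        )
        if np.any(idx < 0) or np.any(idx >= len(self.times)) or not np.all(on_grid):
            bad = np.atleast_1d(np.asarray(time_s))[~np.atleast_1d(on_grid)]
            raise KeyError(f"time(s) {bad} not on the hazard grid")
        out = self.values[idx]
        return float(out) if np.isscalar(time_s) else out

    def slice_until(self, t_end: float) -> "HazardSeries":
        """Restrict the series to times <= t_end."""
        sel = self.times <= t_end + 1e-9
        return HazardSeries(self.times[sel], self.values[sel], self.rate_hz, dict(self.provenance))


def _counts_on_grid(fp_s: np.ndarray) -> np.ndarray:
    idx = np.round(fp_s * 10).astype(int) - 4  # 0.4 s -> index 0
    if np.any(idx < 0) or np.any(idx >= len(NATIVE_TIMES)):
        raise ValueError("foreperiod off the 0.4-2.0 s grid")
    return np.bincount(idx, minlength=len(NATIVE_TIMES)).astype(float)


def empirical_pmf(trials: pd.DataFrame, position: str = "pooled") -> Pmf:
    """Empirical foreperiod distribution from a trial table.

    ``position`` selects FP1 rows, FP2 rows, or both ('pooled').
    """
    if position == "pooled":
        sel = trials
    elif position in ("FP1", "FP2"):
        sel = trials[trials["position"] == position]
    else:
        raise ValueError(f"unknown position {position!r}")
    if len(sel) == 0:
        raise ValueError(f"no trials for position {position!r}")
    counts = _counts_on_grid(sel["foreperiod_s"].to_numpy())
    return Pmf(NATIVE_TIMES.copy(), counts / counts.sum())


def conditional_pmf(trials: pd.DataFrame, conditioning_mode: str = "per_category") -> ConditionalPmfSet:
    """FP2 distributions conditioned on the preceding FP1.

    Keys are FP1 categories ('S'/'L') or exact FP1 durations depending on
    ``conditioning_mode``; FP1 contexts with no sequences are omitted.
    """
    fp2 = trials[trials["position"] == "FP2"]
    if fp2["fp1_context_s"].isna().any():
        raise ValueError("FP2 rows with missing fp1_context")
    if conditioning_mode == "per_category":
        keys = fp2["fp1_context_s"].map(paradigm.duration_category)
    elif conditioning_mode == "per_duration":
        keys = fp2["fp1_context_s"].round(2)
    else:
        raise ValueError(f"unknown conditioning_mode {conditioning_mode!r}")
    mapping = {}
    for key, grp in fp2.groupby(keys):
        counts = _counts_on_grid(grp["foreperiod_s"].to_numpy())
        mapping[key] = Pmf(NATIVE_TIMES.copy(), counts / counts.sum())
    return ConditionalPmfSet(mapping, conditioning_mode)


def hazard_from_pmf(pmf: Pmf, eps: float = 1e-9) -> HazardSeries:
    """Normalized hazard HF(t) = f(t) / (1 - C(t)), C exclusive-cumulative.

    Grid points where the survival 1 - C(t) falls below ``eps`` take the
    maximum of the preceding raw hazard values; the series is then divided by
    its maximum so values lie in [0, 1].
    """
    f = pmf.mass
    if f.sum() <= 0:
        raise ValueError("all-zero probability mass")
    survival = 1.0 - (np.cumsum(f) - f)  # excludes mass at t itself
    raw = np.zeros_like(f)
    running_max = 0.0
    for i in range(len(f)):
        if survival[i] < eps:
            raw[i] = running_max
        else:
            raw[i] = f[i] / survival[i]
        running_max = max(running_max, raw[i])
    peak = raw.max()
    if peak <= 0:
        raise ValueError("degenerate hazard: no positive values")
    dt = np.diff(pmf.times)
    rate = 1.0 / dt[0] if len(dt) and np.allclose(dt, dt[0]) else np.nan
    return HazardSeries(pmf.times.copy(), raw / peak, rate, {"kind": "hazard"})


def interpolate_hazard(hz: HazardSeries, target_rate_hz: int = 250) -> HazardSeries:
    """Cubic-spline upsampling of a native 10-Hz hazard to ``target_rate_hz``.

    Original knots are reproduced exactly; the result is clipped to [0, 1].
    """
    ratio = target_rate_hz / hz.rate_hz
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError(
            f"target rate {target_rate_hz} Hz is not a multiple of the native "
            f"{hz.rate_hz} Hz grid"
        )
    spline = CubicSpline(hz.times, hz.values)  # not-a-knot ends
    n = int(round((hz.times[-1] - hz.times[0]) * target_rate_hz)) + 1
    t = hz.times[0] + np.arange(n) / target_rate_hz
    v = np.clip(spline(t), 0.0, 1.0)
    # exact knot reproduction despite float rounding of the fine grid
    knot_idx = np.round((hz.times - hz.times[0]) * target_rate_hz).astype(int)
    v[knot_idx] = np.clip(hz.values, 0.0, 1.0)
    prov = dict(hz.provenance)
    prov["interpolated_from_hz"] = hz.rate_hz
    return HazardSeries(t, v, target_rate_hz, prov)


def _time_scaled_kernel(times: np.ndarray, centers: np.ndarray, sigmas: np.ndarray) -> np.ndarray:
    """K[i, j] = normal density at times[i] for center j, truncated at 4 SD."""
    d = times[:, None] - centers[None, :]
    s = np.maximum(sigmas, 1e-12)[None, :]
    k = np.exp(-0.5 * (d / s) ** 2)
    k[np.abs(d) > 4.0 * s] = 0.0
    return k


def blur_hazard(source, mode: str, phi: float) -> HazardSeries:
    """Blurred hazard variant with time-scaled Gaussian uncertainty.

    ``temporal`` convolves an existing hazard series with a Gaussian kernel
    whose SD grows as phi*t (scalar timing uncertainty); ``probabilistic``
    blurs the probability mass the same way before the hazard transform.
    The output is renormalized to [0, 1].
    """
    if phi <= 0:
        raise ValueError("blur coefficient phi must be positive")
    if mode == "temporal":
        if not isinstance(source, HazardSeries):
            raise TypeError("temporal blur operates on a HazardSeries")
        t, v = source.times, source.values
        d = t[:, None] - t[None, :]
        s = phi * t[:, None]  # SD tied to the output time
        k = np.exp(-0.5 * (d / s) ** 2)
        k[np.abs(d) > 4.0 * s] = 0.0
        out = (k * v[None, :]).sum(axis=1) / k.sum(axis=1)
        out = out / out.max()
        return HazardSeries(t.copy(), out, source.rate_hz,
                            {**source.provenance, "blur": ("temporal", phi)})
    if mode == "probabilistic":
        if not isinstance(source, Pmf):
            raise TypeError("probabilistic blur operates on a Pmf")
        t, m = source.times, source.mass
        k = _time_scaled_kernel(t, t, phi * t)  # each mass point spreads with SD phi*t_j
        col = k.sum(axis=0)
        col[col == 0] = 1.0
        blurred = (k / col[None, :]) @ m  # mass-conserving on the grid
        blurred = blurred / blurred.sum()
        hz = hazard_from_pmf(Pmf(t.copy(), blurred))
        prov = {**hz.provenance, "blur": ("probabilistic", phi)}
        return HazardSeries(hz.times, hz.values, hz.rate_hz, prov)
    raise ValueError(f"unknown blur mode {mode!r}")


def apply_segment_order(values: np.ndarray, order) -> np.ndarray:
    """Rearrange contiguous segments of `values` into the given 1-based order."""
    segments = np.array_split(np.asarray(values), len(order))
    return np.concatenate([segments[i - 1] for i in order])


def draw_segment_order(n_segments: int, rng: np.random.Generator) -> tuple[int, ...]:
    """Uniform non-identity permutation of 1..n_segments."""
    identity = tuple(range(1, n_segments + 1))
    while True:
        order = tuple(int(i) + 1 for i in rng.permutation(n_segments))
        if order != identity:
            return order


def segment_shuffle(
    hz: HazardSeries,
    n_segments: int = 5,
    seed: int | np.random.Generator | None = None,
) -> HazardSeries:
    """Shuffle the hazard by permuting five contiguous segments.

    Preserves local hazard structure while breaking its global alignment;
    used as the benchmark control regressor for the encoding model.
    """
    if len(hz.values) < n_segments:
        raise ValueError(f"series of length {len(hz.values)} cannot form {n_segments} segments")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    order = draw_segment_order(n_segments, rng)
    values = apply_segment_order(hz.values, order)
    prov = dict(hz.provenance)
    prov["shuffled_order"] = order
    return HazardSeries(hz.times.copy(), values, hz.rate_hz, prov)


# ---------------------------------------------------------------------------
# Study hazard sets


def _category_profile(category: str) -> np.ndarray:
    """Idealized within-category mass profile on the native grid (sums to 1)."""
    mass = np.zeros_like(NATIVE_TIMES)
    for cs, c in paradigm.IDEALIZED_COUNTS[category].items():
        mass[int(round(cs / 10)) - 4] = c
    return mass / mass.sum()


def idealized_hazards() -> tuple[HazardSeries, dict[tuple[int, str], HazardSeries]]:
    """Design-level HF_U and per-block, per-context HF_C.

    The unconditional distribution is the 50-50 mixture of the short and long
    triangular profiles (identical in every block); each conditional
    distribution mixes the two profiles with the block's sequence-type
    proportions given the FP1 category.
    """
    prof = {c: _category_profile(c) for c in ("S", "L")}
    hz_u = hazard_from_pmf(Pmf(NATIVE_TIMES.copy(), 0.5 * prof["S"] + 0.5 * prof["L"]))
    hz_u = HazardSeries(hz_u.times, hz_u.values, hz_u.rate_hz, {"kind": "HF_U", "mode": "idealized"})
    hz_c: dict[tuple[int, str], HazardSeries] = {}
    for block, counts in paradigm.BLOCK_COUNTS.items():
        for ctx in ("S", "L"):
            pairs = {st: n for st, n in counts.items() if st[0] == ctx}
            total = sum(pairs.values())
            if total == 0:
                continue
            w_s = sum(n for st, n in pairs.items() if st[1] == "S") / total
            pmf = Pmf(NATIVE_TIMES.copy(), w_s * prof["S"] + (1 - w_s) * prof["L"])
            hz = hazard_from_pmf(pmf)
            hz_c[(block, ctx)] = HazardSeries(
                hz.times, hz.values, hz.rate_hz,
                {"kind": "HF_C", "block": block, "context": ctx, "mode": "idealized"},
            )
    return hz_u, hz_c


def empirical_hazards(trials: pd.DataFrame) -> tuple[HazardSeries, dict[tuple[int, str], HazardSeries]]:
    """HF_U (pooled over all rows) and HF_C per (block, FP1 category) from data."""
    hz_u = hazard_from_pmf(empirical_pmf(trials, "pooled"))
    hz_u = HazardSeries(hz_u.times, hz_u.values, hz_u.rate_hz, {"kind": "HF_U", "mode": "empirical"})
    hz_c: dict[tuple[int, str], HazardSeries] = {}
    for block, sub in trials.groupby("block"):
        cps = conditional_pmf(sub, "per_category")
        for ctx, pmf in cps.mapping.items():
            hz = hazard_from_pmf(pmf)
            hz_c[(int(block), ctx)] = HazardSeries(
                hz.times, hz.values, hz.rate_hz,
                {"kind": "HF_C", "block": int(block), "context": ctx, "mode": "empirical"},
            )
    return hz_u, hz_c


# ---------------------------------------------------------------------------
# Serialization


def write_hazard(hz: HazardSeries, path) -> None:
    """Tab-delimited (time_s, value) with a JSON provenance sidecar."""
    pd.DataFrame({"time_s": hz.times, "value": hz.values}).to_csv(
        path, sep="\t", index=False, float_format="%.12g"
    )
    sidecar = {"rate_hz": hz.rate_hz, "provenance": _jsonable(hz.provenance)}
    with open(str(path) + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=1)


def read_hazard(path) -> HazardSeries:
    df = pd.read_csv(path, sep="\t")
    with open(str(path) + ".json") as fh:
        sidecar = json.load(fh)
    return HazardSeries(
        df["time_s"].to_numpy(), df["value"].to_numpy(),
        sidecar["rate_hz"], sidecar["provenance"],
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj
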