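"""Synthetic behavior and source-like neural data with planted ground truth.

Reaction times are generated from the same linear mixed model the analysis
fits — fixed effects of the unconditional hazard HF_U, the conditional hazard
HF_C and their product, plus participant and FP1-category random intercepts
and Gaussian residual noise — so that parameter recovery can be tested
against known coefficients.  Multichannel "source-like" series at 250 Hz are
produced by convolving hazard regressors with planted temporal response
functions on a small spatial lattice, with pure-noise (null) channels for
calibration of the downstream cluster statistics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import paradigm
from .encoding import EncodingTrial, LagSpec, build_lagged_design
from .hazard import HazardSeries, interpolate_hazard

#: Default fixed effects: the estimated coefficients of the full
#: reaction-time model (seconds per normalized-hazard unit).
DEFAULT_BETA0 = 0.243
DEFAULT_BETA_U = -0.049
DEFAULT_BETA_C = -0.008
DEFAULT_BETA_UC = 0.042
#: HF_U effect on reaction times following FP1 (participant intercept only).
FP1_BETA_U = -0.021

RT_FLOOR_S = 0.1


@dataclass(frozen=True)
class BehaviorGenParams:
    """Generative parameters of the reaction-time model.

    The default standard deviations give a high-signal-to-noise regime:
    between-participant spread of ~40 ms (consistent with the intercept
    standard error at 31 participants), a weak FP1-category intercept
    (~10 ms) carrying the asymmetric sequential effect, and ~50 ms of
    trial-to-trial residual noise.
    """

    beta0: float = DEFAULT_BETA0
    beta_u: float = DEFAULT_BETA_U
    beta_c: float = DEFAULT_BETA_C
    beta_uc: float = DEFAULT_BETA_UC
    sd_participant: float = 0.04
    sd_fp1context: float = 0.01
    sd_resid: float = 0.05
    false_alarm_rate: float = 0.02
    n_participants: int = 31
    response_scale: str = "raw"  # 'raw' seconds or 'log' (log-normal residuals)

    def __post_init__(self):
        if min(self.sd_participant, self.sd_fp1context, self.sd_resid) < 0:
            raise ValueError("standard deviations must be nonnegative")
        if not 0 <= self.false_alarm_rate <= 0.1:
            raise ValueError("false_alarm_rate must lie in [0, 0.1]")


def _hazard_lookup(hz: HazardSeries, fp_s: np.ndarray) -> np.ndarray:
    return np.asarray(hz.value_at(np.round(fp_s, 2)))


def simulate_reaction_times(
    session: pd.DataFrame,
    hz_u: HazardSeries,
    hz_c: dict[tuple[int, str], HazardSeries],
    params: BehaviorGenParams,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Fill the rt column of a trial table from the generative mixed model.

    FP1 rows:  rt = beta0 + beta_u * HF_U(fp) + b_participant + eps.
    FP2 rows additionally receive beta_c * HF_C(fp) + beta_uc * HF_U * HF_C
    and the FP1-category intercept, where HF_C is the conditional hazard of
    the row's block given its FP1 category.  Reaction times are floored at
    0.1 s.  Hazards are evaluated on the native 10-Hz grid.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    table = session.copy()
    fp = table["foreperiod_s"].to_numpy()
    is_fp2 = (table["position"] == "FP2").to_numpy()

    try:
        hf_u = _hazard_lookup(hz_u, fp)
    except KeyError as exc:
        raise ValueError(f"missing HF_U value: {exc}") from exc

    hf_c = np.zeros(len(table))
    if is_fp2.any():
        blocks = table["block"].to_numpy()
        ctx = np.array([
            paradigm.duration_category(c) if is_fp2[i] else ""
            for i, c in enumerate(table["fp1_context_s"].to_numpy())
        ])
        for (block, category), hz in hz_c.items():
            sel = is_fp2 & (blocks == block) & (ctx == category)
            if sel.any():
                hf_c[sel] = _hazard_lookup(hz, fp[sel])
        unresolved = is_fp2 & (hf_c == 0) & np.array(
            [(int(b), c) not in hz_c for b, c in zip(blocks, ctx)]
        )
        if unresolved.any():
            rows = table.index[unresolved][:5].tolist()
            raise ValueError(f"no conditional hazard for trial rows {rows}")

    participants = table["participant_id"].to_numpy()
    pid_levels, pid_idx = np.unique(participants, return_inverse=True)
    b_part = rng.normal(0.0, params.sd_participant, len(pid_levels))
    b_ctx = {"S": rng.normal(0.0, params.sd_fp1context),
             "L": rng.normal(0.0, params.sd_fp1context)}

    b_ctx_row = np.array([b_ctx.get(c, 0.0) for c in ctx]) if is_fp2.any() else 0.0
    mu = params.beta0 + params.beta_u * hf_u + b_part[pid_idx]
    mu = mu + np.where(
        is_fp2,
        params.beta_c * hf_c + params.beta_uc * hf_u * hf_c + b_ctx_row,
        0.0,
    )
    eps = rng.normal(0.0, params.sd_resid, len(table))
    if params.response_scale == "log":
        rt = np.exp(np.log(np.maximum(mu, RT_FLOOR_S)) + eps)
    else:
        rt = mu + eps
    table["rt_s"] = np.maximum(rt, RT_FLOOR_S)
    return table


def inject_false_alarms(
    table: pd.DataFrame,
    rate: float,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Flag an independent Bernoulli(rate) subset of trials as false alarms.

    Flagged rows (responses before target onset) lose their reaction time and
    are excluded by all downstream analyses.
    """
    if not 0 <= rate <= 0.1:
        raise ValueError("false-alarm rate must lie in [0, 0.1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = table.copy()
    flags = rng.random(len(out)) < rate
    out["false_alarm"] = flags
    out.loc[flags, "rt_s"] = np.nan
    return out


# ---------------------------------------------------------------------------
# Neural generator


@dataclass(frozen=True)
class NeuralGenParams:
    """Planted-TRF source-signal generator parameters.

    ``true_trf`` maps regressor name -> (n_lags x n_channels) weights on the
    encoder's lag axis; channels whose weights are all zero are null channels.
    The default 8x8 lattice with 4-neighbor adjacency is the desk-scale stand
    -in for a source grid.
    """

    grid_shape: tuple[int, ...] = (8, 8)
    true_trf: dict = field(default_factory=dict)
    noise_sd: float = 1.0
    rate_hz: float = 250.0
    lagspec: LagSpec = field(default_factory=LagSpec)

    @property
    def n_channels(self) -> int:
        return int(np.prod(self.grid_shape))

    def __post_init__(self):
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        for name, w in self.true_trf.items():
            w = np.asarray(w)
            if w.shape != (self.lagspec.n_lags, self.n_channels):
                raise ValueError(
                    f"true_trf[{name!r}] must be (n_lags x n_channels) "
                    f"= ({self.lagspec.n_lags}, {self.n_channels}), got {w.shape}"
                )


def _lag_bump(lagspec: LagSpec, center_s: float = 0.0, width_s: float = 0.02) -> np.ndarray:
    """Unit-peak Gaussian lag profile used as the planted TRF shape."""
    lags = lagspec.lags_s
    return np.exp(-0.5 * ((lags - center_s) / width_s) ** 2)


def channel_patch(grid_shape: tuple[int, int], rows: slice, cols: slice) -> np.ndarray:
    """Flat channel indices of a rectangular patch on a 2-D lattice."""
    mask = np.zeros(grid_shape, dtype=bool)
    mask[rows, cols] = True
    return np.flatnonzero(mask.ravel())


def default_neural_params(
    noise_sd: float = 1.0,
    amplitude: float = 1.0,
    grid_shape: tuple[int, int] = (8, 8),
    lagspec: LagSpec | None = None,
) -> NeuralGenParams:
    """Planted layout mirroring the study's topography at desk scale.

    HF_U carries a negative TRF on a "posterior" patch, HF_C a negative TRF
    on an "anterior" patch, and the interaction a positive TRF on a middle
    patch; all other channels are pure noise.
    """
    spec = lagspec or LagSpec()
    n_ch = int(np.prod(grid_shape))
    bump = _lag_bump(spec)
    trf = {name: np.zeros((spec.n_lags, n_ch)) for name in ("HF_U", "HF_C", "HF_UxC")}
    trf["HF_U"][:, channel_patch(grid_shape, slice(0, 3), slice(0, 3))] = \
        -amplitude * bump[:, None]
    trf["HF_C"][:, channel_patch(grid_shape, slice(5, 8), slice(5, 8))] = \
        -amplitude * bump[:, None]
    trf["HF_UxC"][:, channel_patch(grid_shape, slice(3, 5), slice(2, 6))] = \
        amplitude * bump[:, None]
    return NeuralGenParams(grid_shape, trf, noise_sd, spec.rate_hz, spec)


def trial_regressors(
    fp_s: float,
    hz_u_250: HazardSeries,
    hz_c_250: HazardSeries | None,
) -> dict[str, np.ndarray]:
    """Regressor segment(s) for one trial: 0.4 s post-warning to target onset."""
    u = hz_u_250.slice_until(fp_s).values
    regs = {"HF_U": u}
    if hz_c_250 is not None:
        c = hz_c_250.slice_until(fp_s).values
        regs["HF_C"] = c
        regs["HF_UxC"] = u * c
    return regs


def simulate_source_signals(
    session: pd.DataFrame,
    hz_u: HazardSeries,
    hz_c: dict[tuple[int, str], HazardSeries],
    params: NeuralGenParams,
    seed: int | np.random.Generator | None = None,
    position: str = "FP2",
    min_foreperiod_s: float = 0.7,
) -> list[EncodingTrial]:
    """Planted-TRF multichannel series for each eligible trial.

    Only trials with foreperiod > ``min_foreperiod_s`` and no false alarm are
    emitted (short segments leave too little data for the lagged model).
    Each segment spans 0.4 s after warning onset up to the target onset at
    250 Hz; every channel is the sum over regressors of the lag-convolution
    with its planted TRF, plus Gaussian noise.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    hz_u_250 = hz_u if hz_u.rate_hz == params.rate_hz else interpolate_hazard(hz_u, int(params.rate_hz))
    hz_c_250 = {
        k: (v if v.rate_hz == params.rate_hz else interpolate_hazard(v, int(params.rate_hz)))
        for k, v in hz_c.items()
    }

    sel = session[
        (session["position"] == position)
        & (session["foreperiod_s"] > min_foreperiod_s + 1e-9)
        & (~session["false_alarm"])
    ]
    trials: list[EncodingTrial] = []
    for row in sel.itertuples():
        fp = round(float(row.foreperiod_s), 2)
        if position == "FP2":
            key = (int(row.block), paradigm.duration_category(row.fp1_context_s))
            if key not in hz_c_250:
                raise ValueError(f"no conditional hazard for block/context {key}")
            regs = trial_regressors(fp, hz_u_250, hz_c_250[key])
        else:
            regs = trial_regressors(fp, hz_u_250, None)
        n_t = len(regs["HF_U"])
        signal = np.zeros((n_t, params.n_channels))
        for name, w in params.true_trf.items():
            if name not in regs:
                continue
            design = build_lagged_design(regs[name], params.lagspec)
            signal += design @ np.asarray(w)
        signal += rng.normal(0.0, params.noise_sd, signal.shape)
        trial_id = (int(row.participant_id), int(row.run), int(row.sequence), position)
        trials.append(EncodingTrial(trial_id, regs, signal))
    return trials


# ---------------------------------------------------------------------------
# Serialization: one delimited file per trial plus a JSON manifest


def write_source_trials(trials: list[EncodingTrial], out_dir) -> None:
    """Write each trial as a TSV (regressor + channel columns) with a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = []
    for i, t in enumerate(trials):
        fname = f"trial_{i:05d}.tsv"
        cols = {f"reg:{name}": np.asarray(v) for name, v in t.regressors.items()}
        for ch in range(t.response.shape[1]):
            cols[f"ch:{ch}"] = t.response[:, ch]
        pd.DataFrame(cols).to_csv(out / fname, sep="\t", index=False,
                                  float_format="%.10g")
        manifest.append({
            "file": fname,
            "trial_id": list(t.trial_id) if isinstance(t.trial_id, tuple) else t.trial_id,
            "n_samples": int(t.response.shape[0]),
            "n_channels": int(t.response.shape[1]),
            "regressors": sorted(t.regressors),
        })
    (out / "manifest.json").write_text(json.dumps(
        {"rate_hz": 250, "segment_start_s": 0.4, "trials": manifest}, indent=1
    ))


def read_source_trials(in_dir) -> list[EncodingTrial]:
    src = Path(in_dir)
    manifest = json.loads((src / "manifest.json").read_text())
    trials = []
    for entry in manifest["trials"]:
        df = pd.read_csv(src / entry["file"], sep="\t")
        regs = {
            c[len("reg:"):]: df[c].to_numpy() for c in df.columns if c.startswith("reg:")
        }
        chans = [c for c in df.columns if c.startswith("ch:")]
        response = df[chans].to_numpy()
        tid = entry["trial_id"]
        trials.append(EncodingTrial(tuple(tid) if isinstance(tid, list) else tid,
                                    regs, response))
    return trials
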