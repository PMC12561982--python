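"""Forward encoding model: lagged ridge temporal response functions (TRFs).

A TRF is a set of linear weights w(tau, channel) mapping a stimulus regressor
(here: hazard values upsampled to the neural rate) onto a neural time series:

    r(t, n) = sum_tau w(tau, n) s(t - tau) + eps(t, n)

estimated per channel by ridge regression, w = (S'S + lambda*I)^-1 S'r, over
a lagged design matrix S.  Model performance is scored by leave-one-trial-out
reconstruction: the TRF trained on n-1 trials reconstructs the held-out trial
from its lag-0 weight slice, and the Pearson correlation with the actual
signal is averaged over folds per channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

FULL_MODEL = ("HF_U", "HF_C", "HF_UxC")
MODEL_SETS: dict[str, tuple[str, ...]] = {
    "U": ("HF_U",),
    "C": ("HF_C",),
    "U+C": ("HF_U", "HF_C"),
    "U+C+UxC": FULL_MODEL,
}

#: Ridge-parameter search grid, 10^-3 .. 10^3 (7 log-spaced values).
LAMBDA_GRID: tuple[float, ...] = tuple(10.0 ** k for k in range(-3, 4))


@dataclass(frozen=True)
class LagSpec:
    """Lag axis of the TRF: defaults give 76 lags, -0.1..+0.2 s at 4 ms."""

    tmin: float = -0.1
    tmax: float = 0.2
    step: float = 0.004
    rate_hz: float = 250.0

    @property
    def n_lags(self) -> int:
        return int(round((self.tmax - self.tmin) / self.step)) + 1

    @property
    def lags_s(self) -> np.ndarray:
        return self.tmin + self.step * np.arange(self.n_lags)

    @property
    def lags_samples(self) -> np.ndarray:
        return np.round(self.lags_s * self.rate_hz).astype(int)

    @property
    def lag0_index(self) -> int:
        idx = int(round(-self.tmin / self.step))
        if not 0 <= idx < self.n_lags:
            raise ValueError("lag 0 outside the lag window")
        return idx


#: Standard candidate lag windows for the hyperparameter search.
LAG_CANDIDATES: tuple[LagSpec, ...] = tuple(
    LagSpec(tmin=a, tmax=b) for a in (-0.2, -0.1) for b in (0.2, 0.3)
)


@dataclass(frozen=True)
class EncodingTrial:
    """One trial's regressors (name -> 1-D array) and response (time x channels)."""

    trial_id: object
    regressors: Mapping[str, np.ndarray]
    response: np.ndarray

    def __post_init__(self):
        r = np.asarray(self.response, dtype=float)
        if r.ndim != 2:
            raise ValueError("response must be 2-D (time x channels)")
        object.__setattr__(self, "response", r)
        for name, s in self.regressors.items():
            if len(np.asarray(s)) != r.shape[0]:
                raise ValueError(f"regressor {name!r} length mismatches the response")


@dataclass(frozen=True)
class TRF:
    weights: np.ndarray  # predictors x lags x channels
    lam: float
    lagspec: LagSpec
    predictors: tuple[str, ...]


@dataclass(frozen=True)
class EncodingScore:
    """Per-channel mean held-out reconstruction correlation."""

    channel_means: np.ndarray
    per_trial: np.ndarray  # folds x channels, NaN where undefined
    predictors: tuple[str, ...]
    lam: float
    lagspec: LagSpec
    provenance: dict = field(default_factory=dict)


def build_lagged_design(stimulus, lagspec: LagSpec) -> np.ndarray:
    """Time x (predictors * lags) design matrix of shifted stimulus copies.

    ``stimulus`` is a 1-D array (one predictor) or a time x predictors array;
    column (k, tau) holds predictor k delayed by tau (s(t - tau)), zero-padded
    at the segment edges.  Columns are ordered predictors-outer, lags
    ascending from ``tmin``.
    """
    s = np.asarray(stimulus, dtype=float)
    if s.ndim == 1:
        s = s[:, None]
    n_t, n_pred = s.shape
    lags = lagspec.lags_samples
    if n_t < lagspec.n_lags:
        raise ValueError(
            f"segment of {n_t} samples is shorter than the {lagspec.n_lags}-lag span"
        )
    design = np.zeros((n_t, n_pred * lagspec.n_lags))
    for k in range(n_pred):
        for j, lag in enumerate(lags):
            col = k * lagspec.n_lags + j
            if lag >= 0:
                design[lag:, col] = s[: n_t - lag, k]
            else:
                design[:lag, col] = s[-lag:, k]
    return design


def ridge_trf(design, response, lam: float,
              lagspec: LagSpec | None = None,
              predictors: Sequence[str] | None = None) -> TRF:
    """Solve (S'S + lambda*I) w = S'r, stacking multiple trials if given.

    ``design``/``response`` are single arrays or equal-length lists of
    per-trial arrays; multi-trial fits sum the cross-products, which equals
    concatenation with per-trial zero padding but avoids edge artifacts.
    """
    if lam < 0:
        raise ValueError("ridge parameter must be nonnegative")
    designs = design if isinstance(design, (list, tuple)) else [design]
    responses = response if isinstance(response, (list, tuple)) else [response]
    if len(designs) != len(responses):
        raise ValueError("design and response lists differ in length")
    p = designs[0].shape[1]
    sts = np.zeros((p, p))
    str_ = None
    for d, r in zip(designs, responses):
        r = np.atleast_2d(np.asarray(r, dtype=float))
        if r.shape[0] != d.shape[0]:
            r = r.T
        sts += d.T @ d
        str_ = d.T @ r if str_ is None else str_ + d.T @ r
    a = sts + lam * np.eye(p)
    try:
        w = np.linalg.solve(a, str_)
        if not np.all(np.isfinite(w)):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        if lam == 0:
            raise np.linalg.LinAlgError(
                "rank-deficient design with lambda = 0; use a positive ridge parameter"
            )
        raise
    spec = lagspec or LagSpec()
    names = tuple(predictors) if predictors is not None else tuple(
        f"p{k}" for k in range(p // spec.n_lags or 1)
    )
    n_pred = max(1, p // spec.n_lags) if p % spec.n_lags == 0 else 1
    shape = (n_pred, p // n_pred, w.shape[1])
    return TRF(w.reshape(shape), lam, spec, names)


def _center(x: np.ndarray) -> np.ndarray:
    return x - x.mean(axis=0, keepdims=True)


def _pearson_columns(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Column-wise Pearson correlation; NaN where either column is constant."""
    a = _center(a)
    b = _center(b)
    sa = np.sqrt((a ** 2).sum(axis=0))
    sb = np.sqrt((b ** 2).sum(axis=0))
    denom = sa * sb
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (a * b).sum(axis=0) / denom
    r[denom == 0] = np.nan
    return r


def _prepare_trial(trial: EncodingTrial, predictors: Sequence[str], lagspec: LagSpec):
    # centering is applied to the lagged columns (not the stimulus before
    # lagging), so the zero-padded segment edges introduce no DC mismatch
    stim = np.column_stack([np.asarray(trial.regressors[p], dtype=float) for p in predictors])
    design = _center(build_lagged_design(stim, lagspec))
    resp = _center(trial.response)
    return stim, design, resp


def loo_encode(
    trials: Sequence[EncodingTrial],
    lam: float = 1.0,
    lagspec: LagSpec | None = None,
    predictors: Sequence[str] = FULL_MODEL,
) -> tuple[EncodingScore, TRF]:
    """Leave-one-out encoding-model evaluation.

    For each fold the TRF is fit on the remaining trials (regressors and
    responses per-trial mean-centered, cross-products summed), and the
    held-out trial is reconstructed channel-by-channel from the lag-0 weight
    slice alone; per-channel correlations are averaged over folds.  Returns
    the score and the fold-averaged TRF.
    """
    if len(trials) < 3:
        raise ValueError("leave-one-out evaluation needs at least 3 trials")
    spec = lagspec or LagSpec()
    predictors = tuple(predictors)
    n_ch = trials[0].response.shape[1]
    p = len(predictors) * spec.n_lags

    per = [_prepare_trial(t, predictors, spec) for t in trials]
    xtx = [d.T @ d for _, d, _ in per]
    xtr = [d.T @ r for _, d, r in per]
    tot_xtx = np.sum(xtx, axis=0)
    tot_xtr = np.sum(xtr, axis=0)

    scores = np.full((len(trials), n_ch), np.nan)
    w_sum = np.zeros((p, n_ch))
    eye = np.eye(p)
    lag0 = spec.lag0_index
    for i, (stim, _d, resp) in enumerate(per):
        w = np.linalg.solve(tot_xtx - xtx[i] + lam * eye, tot_xtr - xtr[i])
        w_sum += w
        w3 = w.reshape(len(predictors), spec.n_lags, n_ch)
        pred = _center(stim) @ w3[:, lag0, :]  # lag-0 slice reconstruction
        scores[i] = _pearson_columns(pred, resp)

    with np.errstate(invalid="ignore"):
        channel_means = np.nanmean(scores, axis=0)
    trf = TRF(w_sum.reshape(len(predictors), spec.n_lags, n_ch) / len(trials),
              lam, spec, predictors)
    score = EncodingScore(channel_means, scores, predictors, lam, spec,
                          {"n_trials": len(trials)})
    return score, trf


def tune_hyperparams(
    trials: Sequence[EncodingTrial],
    lambda_grid: Sequence[float] = LAMBDA_GRID,
    lag_candidates: Sequence[LagSpec] = LAG_CANDIDATES,
    predictors: Sequence[str] = FULL_MODEL,
) -> tuple[float, LagSpec, dict]:
    """Grid search over ridge parameters and lag windows.

    Every (lambda, lag window) pair is evaluated by the same leave-one-out
    procedure as :func:`loo_encode`; the pair with the highest grand-mean
    held-out correlation wins.
    """
    if not lambda_grid or not lag_candidates:
        raise ValueError("empty hyperparameter grid")
    results = {}
    best, best_score = None, -np.inf
    for spec in lag_candidates:
        for lam in lambda_grid:
            score, _ = loo_encode(trials, lam, spec, predictors)
            mean = float(np.nanmean(score.channel_means))
            results[(lam, (spec.tmin, spec.tmax))] = mean
            if mean > best_score:
                best, best_score = (lam, spec), mean
    return best[0], best[1], results


def shuffled_control(
    trials: Sequence[EncodingTrial],
    lam: float = 1.0,
    lagspec: LagSpec | None = None,
    predictors: Sequence[str] = FULL_MODEL,
    n_segments: int = 5,
    seed: int | np.random.Generator | None = None,
) -> tuple[EncodingScore, TRF]:
    """Benchmark control: the same pipeline on 5-segment-shuffled regressors.

    Each regressor of each trial is independently segment-shuffled (uniform
    non-identity order), preserving local hazard structure while destroying
    its alignment to the neural signal.
    """
    from . import hazard as _hazard

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    shuffled = []
    orders = []
    for t in trials:
        regs = {}
        for name in predictors:
            order = _hazard.draw_segment_order(n_segments, rng)
            orders.append(order)
            regs[name] = _hazard.apply_segment_order(np.asarray(t.regressors[name]), order)
        shuffled.append(EncodingTrial(t.trial_id, regs, t.response))
    score, trf = loo_encode(shuffled, lam, lagspec, predictors)
    prov = dict(score.provenance)
    prov.update({"control": "segment_shuffle", "n_segments": n_segments,
                 "orders": [list(o) for o in orders]})
    return EncodingScore(score.channel_means, score.per_trial, score.predictors,
                         score.lam, score.lagspec, prov), trf
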