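"""Single-trial topographical analysis (STTA).

Each condition's GFP-normalised voltage topographies — pooled over all trials
and latencies — are modelled by a mixture of Gaussians whose component means
act as *template maps*. A held-out trial is scored by the cumulative
log-likelihood ratio of its instantaneous topographies under the deviant
versus the standard mixture, summed over a *discriminative window*. The
number of Gaussians per condition and the window are selected by stratified
cross-validation to maximise the AUC of these scores; test performance is
then measured once on an independent partition.

The expectation-maximisation fit uses diagonal covariances (stable in the
channels >> trials regime at 63 electrodes), multiple random restarts, and a
variance floor; the log-likelihood trace is recorded and is non-decreasing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from ._utils import child_seed
from .epochs import NormalizedEpochSet
from .inference import auc_many, compute_auc

_LOG2PI = float(np.log(2 * np.pi))


@dataclass
class GmmConditionModel:
    """Mixture of diagonal Gaussians over one condition's topographies.

    ``means`` (k, n_channels) are the template maps; ``weights`` sum to one;
    ``variances`` are per-component, per-channel. ``ll_trace`` holds the
    total log-likelihood at each EM iteration of the winning restart.
    """

    weights: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    log_likelihood: float = np.nan
    n_iter: int = 0
    ll_trace: list[float] = field(default_factory=list)

    @property
    def k(self) -> int:
        return len(self.weights)

    def log_density(self, x: np.ndarray) -> np.ndarray:
        """Log mixture density of points ``x`` with shape (n_points, n_channels)."""
        x = np.atleast_2d(x)
        lp = _component_log_density(x, self.means, self.variances)
        lp = lp + np.log(self.weights)[None, :]
        m = lp.max(axis=1, keepdims=True)
        return (m + np.log(np.exp(lp - m).sum(axis=1, keepdims=True)))[:, 0]


def _component_log_density(x: np.ndarray, means: np.ndarray, variances: np.ndarray
                           ) -> np.ndarray:
    """(n_points, k) log density of each point under each diagonal Gaussian."""
    # sum_d [ (x_d - mu_d)^2 / var_d ] expanded to avoid an (n, k, d) temporary
    inv = 1.0 / variances                               # (k, d)
    quad = (x**2) @ inv.T - 2.0 * x @ (means * inv).T \
        + np.sum(means**2 * inv, axis=1)[None, :]
    logdet = np.sum(np.log(variances), axis=1)[None, :]
    d = x.shape[1]
    return -0.5 * (quad + logdet + d * _LOG2PI)


def fit_gmm(x: np.ndarray, k: int, seed: int = 0, n_restarts: int = 3,
            max_iter: int = 200, tol: float = 1e-5, var_floor: float = 1e-6
            ) -> GmmConditionModel:
    """Fit a k-component diagonal-covariance Gaussian mixture by EM.

    Best of ``n_restarts`` random initialisations (means drawn from the data
    points, shared data variances, uniform weights). Converged when the total
    log-likelihood improves by less than ``tol`` (relative to its magnitude).
    A restart whose components collapse (vanishing weight) is discarded;
    raises if every restart fails. Deterministic given ``seed``.
    """
    x = np.asarray(x, dtype=float)
    n, d = x.shape
    if n < 10 * k:
        raise ValueError(f"need at least {10 * k} points to fit k={k} (got {n})")
    rng = np.random.default_rng(seed)
    base_var = np.maximum(x.var(axis=0), var_floor)

    best: GmmConditionModel | None = None
    for _ in range(n_restarts):
        idx = rng.choice(n, size=k, replace=False)
        means = x[idx].copy()
        variances = np.tile(base_var, (k, 1))
        weights = np.full(k, 1.0 / k)
        trace: list[float] = []
        failed = False
        for it in range(max_iter):
            lp = _component_log_density(x, means, variances) + np.log(weights)[None, :]
            m = lp.max(axis=1, keepdims=True)
            log_norm = m + np.log(np.exp(lp - m).sum(axis=1, keepdims=True))
            ll = float(log_norm.sum())
            trace.append(ll)
            resp = np.exp(lp - log_norm)                # (n, k)
            nk = resp.sum(axis=0)
            if np.any(nk < 1e-8):
                failed = True
                break
            weights = nk / n
            means = (resp.T @ x) / nk[:, None]
            variances = (resp.T @ (x**2)) / nk[:, None] - means**2
            variances = np.maximum(variances, var_floor)
            if len(trace) > 1 and trace[-1] - trace[-2] < tol * max(1.0, abs(trace[-1])):
                break
        if failed or not np.isfinite(trace[-1]):
            continue
        if best is None or trace[-1] > best.log_likelihood:
            best = GmmConditionModel(weights=weights, means=means, variances=variances,
                                     log_likelihood=trace[-1], n_iter=len(trace),
                                     ll_trace=trace)
    if best is None:
        raise RuntimeError(f"all {n_restarts} EM restarts failed for k={k}")
    return best


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def per_timepoint_llr(data: np.ndarray, mask: np.ndarray,
                      model_dev: GmmConditionModel, model_std: GmmConditionModel
                      ) -> np.ndarray:
    """(n_trials, n_samples) log-likelihood ratio (deviant vs standard) of
    every topography; masked time-points contribute 0."""
    n_tr, n_ch, n_s = data.shape
    pts = data.transpose(0, 2, 1).reshape(-1, n_ch)
    llr = model_dev.log_density(pts) - model_std.log_density(pts)
    llr = llr.reshape(n_tr, n_s)
    return np.where(mask, llr, 0.0)


def trial_llr(trial: np.ndarray, mask: np.ndarray, model_dev: GmmConditionModel,
              model_std: GmmConditionModel, window_sel: np.ndarray) -> float:
    """Decision score of one trial: summed log-likelihood ratio over the
    unmasked time-points of the window. Higher = more deviant-like."""
    use = window_sel & mask
    if not np.any(use):
        raise ValueError("window is empty after masking")
    pts = trial[:, use].T
    return float(np.sum(model_dev.log_density(pts) - model_std.log_density(pts)))


# ---------------------------------------------------------------------------
# cross-validated selection
# ---------------------------------------------------------------------------

@dataclass
class SttaConfig:
    """Candidate grid and EM settings for STTA model selection.

    Candidate windows are contiguous intervals [start, end) on a millisecond
    grid within the post-onset range; candidate component counts apply to
    each condition independently.
    """

    k_values: Sequence[int] = (1, 2, 3, 4, 5, 6)
    window_range_ms: tuple[float, float] = (0.0, 500.0)
    window_start_step_ms: float = 10.0
    window_min_length_ms: float = 20.0
    n_folds: int = 5
    em_tol: float = 1e-5
    em_max_iter: int = 200
    n_restarts: int = 3
    max_fit_points: int = 20_000   # subsample cap for the pooled EM fit
    seed: int = 0


@dataclass
class SttaResult:
    """Outcome of STTA selection and test-set evaluation."""

    contrast: str
    k_deviant: int
    k_standard: int
    window_ms: tuple[float, float]
    cv_auc: float
    test_auc: float = np.nan
    scores: np.ndarray | None = None

    def to_dict(self) -> dict:
        return {
            "decoder": "stta", "contrast": self.contrast,
            "k_deviant": int(self.k_deviant), "k_standard": int(self.k_standard),
            "window_ms": [float(w) for w in self.window_ms],
            "cv_auc": float(self.cv_auc), "test_auc": float(self.test_auc),
            "scores": None if self.scores is None else [float(s) for s in self.scores],
        }


def candidate_windows(times: np.ndarray, config: SttaConfig
                      ) -> list[tuple[float, float, int, int]]:
    """Enumerate candidate windows as (start_ms, end_ms, i0, i1) where i0/i1
    index the post-onset sample axis. Windows that collapse onto the same
    sample range at the given sampling rate are de-duplicated keeping the
    earliest/shortest, preserving the tie-break order (earliest start, then
    shortest)."""
    lo, hi = config.window_range_ms
    post = post_onset_selector(times, config)
    post_times_ms = times[post] * 1000.0
    out, seen = [], set()
    starts = np.arange(lo, hi - config.window_min_length_ms + 1e-9,
                       config.window_start_step_ms)
    for s in starts:
        ends = np.arange(s + config.window_min_length_ms, hi + 1e-9,
                         config.window_start_step_ms)
        for e in ends:
            i0 = int(np.searchsorted(post_times_ms, s - 1e-9))
            i1 = int(np.searchsorted(post_times_ms, e - 1e-9))
            if i1 <= i0 or (i0, i1) in seen:
                continue
            seen.add((i0, i1))
            out.append((float(s), float(e), i0, i1))
    if not out:
        raise ValueError("no valid candidate windows at this sampling rate")
    # sorted for deterministic tie-breaking: earliest start, then shortest
    out.sort(key=lambda w: (w[0], w[1] - w[0]))
    return out


def post_onset_selector(times: np.ndarray, config: SttaConfig) -> np.ndarray:
    lo, hi = config.window_range_ms
    return (times >= lo / 1000.0 - 1e-12) & (times < hi / 1000.0 - 1e-12)


def _pooled_points(norm: NormalizedEpochSet, trial_idx: np.ndarray,
                   post: np.ndarray, rng: np.random.Generator | None,
                   cap: int) -> np.ndarray:
    data = norm.data[trial_idx][:, :, post]
    mask = norm.mask[trial_idx][:, post]
    pts = data.transpose(0, 2, 1)[mask]
    if rng is not None and cap and len(pts) > cap:
        pts = pts[rng.choice(len(pts), size=cap, replace=False)]
    return pts


def _fit_condition_models(norm: NormalizedEpochSet, contrast: str,
                          trial_idx: np.ndarray, post: np.ndarray,
                          config: SttaConfig, seed: int
                          ) -> dict[str, dict[int, GmmConditionModel]]:
    """Fit one GMM per condition per candidate k on the pooled unmasked
    post-onset topographies of the given trials."""
    dev_mask = norm.deviant_mask(contrast)[trial_idx]
    models: dict[str, dict[int, GmmConditionModel]] = {"dev": {}, "std": {}}
    for name, sel in (("dev", dev_mask), ("std", ~dev_mask)):
        rng = np.random.default_rng(child_seed(seed, "subsample", name))
        pts = _pooled_points(norm, trial_idx[sel], post, rng, config.max_fit_points)
        for k in config.k_values:
            if len(pts) < 10 * k:
                continue
            models[name][k] = fit_gmm(
                pts, k, seed=child_seed(seed, "gmm", name, k),
                n_restarts=config.n_restarts, max_iter=config.em_max_iter,
                tol=config.em_tol)
    if not models["dev"] or not models["std"]:
        raise ValueError("too few topographies to fit any candidate model")
    return models


def _window_scores(logd_dev: np.ndarray, logd_std: np.ndarray,
                   windows: Sequence[tuple[float, float, int, int]]
                   ) -> np.ndarray:
    """(n_windows, n_trials) summed LLR scores from per-timepoint log
    densities (already zeroed at masked points)."""
    llr = logd_dev - logd_std
    c = np.concatenate([np.zeros((llr.shape[0], 1)), np.cumsum(llr, axis=1)], axis=1)
    return np.stack([c[:, i1] - c[:, i0] for (_, _, i0, i1) in windows])


def _masked_log_densities(norm: NormalizedEpochSet, trial_idx: np.ndarray,
                          post: np.ndarray,
                          models: dict[int, GmmConditionModel]
                          ) -> dict[int, np.ndarray]:
    data = norm.data[trial_idx][:, :, post]
    mask = norm.mask[trial_idx][:, post]
    n_tr, n_ch, n_s = data.shape
    pts = data.transpose(0, 2, 1).reshape(-1, n_ch)
    out = {}
    for k, model in models.items():
        ld = model.log_density(pts).reshape(n_tr, n_s)
        out[k] = np.where(mask, ld, 0.0)
    return out


def cross_validate_stta(cv_norm: NormalizedEpochSet, contrast: str = "global",
                        config: SttaConfig | None = None) -> SttaResult:
    """Stratified k-fold selection of (k_deviant, k_standard, window).

    For every fold, mixtures are fitted on the training trials only and all
    candidate (k-pair, window) combinations are scored on the held-out fold;
    the candidate with the highest mean held-out AUC is selected. Ties break
    to the earliest window start, then the shortest window, then the smallest
    component counts.
    """
    config = config or SttaConfig()
    post = post_onset_selector(cv_norm.times, config)
    windows = candidate_windows(cv_norm.times, config)
    y = cv_norm.deviant_mask(contrast)
    skf = StratifiedKFold(n_splits=config.n_folds, shuffle=True,
                          random_state=config.seed % (2**32 - 1))
    idx = np.arange(cv_norm.n_trials)

    pair_list: list[tuple[int, int]] | None = None
    auc_sum: np.ndarray | None = None
    n_folds_done = 0
    for fold, (tr, va) in enumerate(skf.split(idx, y)):
        models = _fit_condition_models(cv_norm, contrast, idx[tr], post, config,
                                       seed=child_seed(config.seed, "fold", fold))
        if pair_list is None:
            ks_dev = sorted(models["dev"])
            ks_std = sorted(models["std"])
            # smallest-k tie-break: ordered by total components, then k_dev
            pair_list = sorted(((kd, ks) for kd in ks_dev for ks in ks_std),
                               key=lambda p: (p[0] + p[1], p[0]))
            auc_sum = np.zeros((len(pair_list), len(windows)))
        logd_dev = _masked_log_densities(cv_norm, idx[va], post, models["dev"])
        logd_std = _masked_log_densities(cv_norm, idx[va], post, models["std"])
        y_va = y[va]
        for pi, (kd, ks) in enumerate(pair_list):
            scores = _window_scores(logd_dev[kd], logd_std[ks], windows)
            auc_sum[pi] += auc_many(scores, y_va)
        n_folds_done += 1

    mean_auc = auc_sum / n_folds_done
    # candidate order implements the tie-break: windows already sorted by
    # (start, length); iterate windows outer so earlier windows win ties
    best = (-np.inf, 0, 0)
    for wi in range(len(windows)):
        for pi in range(len(pair_list)):
            if mean_auc[pi, wi] > best[0] + 1e-12:
                best = (mean_auc[pi, wi], pi, wi)
    cv_auc, pi, wi = best
    kd, ks = pair_list[pi]
    s, e, _, _ = windows[wi]
    return SttaResult(contrast=contrast, k_deviant=kd, k_standard=ks,
                      window_ms=(s, e), cv_auc=float(cv_auc))


def decode_test_stta(cv_norm: NormalizedEpochSet, test_norm: NormalizedEpochSet,
                     contrast: str = "global", config: SttaConfig | None = None
                     ) -> SttaResult:
    """Full STTA decoding: select (k, window) on the CV partition, refit the
    condition mixtures on the entire CV partition, and report the AUC of the
    summed LLR scores on the disjoint test partition."""
    config = config or SttaConfig()
    sel = cross_validate_stta(cv_norm, contrast, config)
    post = post_onset_selector(cv_norm.times, config)
    idx = np.arange(cv_norm.n_trials)
    config_refit = config
    models = _fit_condition_models(cv_norm, contrast, idx, post, config_refit,
                                   seed=child_seed(config.seed, "refit"))
    kd = sel.k_deviant if sel.k_deviant in models["dev"] else max(models["dev"])
    ks = sel.k_standard if sel.k_standard in models["std"] else max(models["std"])
    windows = candidate_windows(cv_norm.times, config)
    i0, i1 = next((w[2], w[3]) for w in windows
                  if (w[0], w[1]) == tuple(sel.window_ms))
    logd_dev = _masked_log_densities(test_norm, np.arange(test_norm.n_trials), post,
                                     {kd: models["dev"][kd]})
    logd_std = _masked_log_densities(test_norm, np.arange(test_norm.n_trials), post,
                                     {ks: models["std"][ks]})
    scores = _window_scores(logd_dev[kd], logd_std[ks],
                            [(sel.window_ms[0], sel.window_ms[1], i0, i1)])[0]
    test_auc = compute_auc(scores, test_norm.deviant_mask(contrast))
    return SttaResult(contrast=contrast, k_deviant=kd, k_standard=ks,
                      window_ms=sel.window_ms, cv_auc=sel.cv_auc,
                      test_auc=float(test_auc), scores=scores)
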