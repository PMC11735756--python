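"""AUC computation and recording-level significance via permutation testing.

A recording's decoding performance is the AUC of per-trial decision scores on
the held-out test partition. Its significance is assessed against a null
distribution obtained by re-running the *entire* pipeline — split,
cross-validated selection, refit, test — on label-permuted copies of the data
(labels are shuffled before the CV/test split so that selection bias is part
of the null). Two p-values are reported: the standard add-one empirical
permutation p, and a one-sided Wilcoxon signed-rank test of the permutation
AUCs against the observed AUC. The default significance rule is their
conjunction at alpha = 0.05; either criterion alone can be configured.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import stats

from ._utils import child_seed
from .epochs import EpochSet

MIN_PERMUTATIONS = 100


def compute_auc(scores: np.ndarray, labels) -> float:
    """Area under the ROC curve of decision scores for a binary contrast.

    ``labels`` may be boolean (True = deviant) or the string labels
    "standard"/"deviant". Equals the probability that a randomly drawn
    deviant outscores a randomly drawn standard, ties counted one half
    (Mann-Whitney U / (n1 * n2)).
    """
    scores = np.asarray(scores, dtype=float)
    labels = _as_bool_labels(labels)
    return float(auc_many(scores[None, :], labels)[0])


def _as_bool_labels(labels) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.dtype.kind in "US":
        labels = labels == "deviant"
    labels = labels.astype(bool)
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present to compute an AUC")
    return labels


def auc_many(scores: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Midrank AUC of each row of ``scores`` (shape (m, n_trials)) against a
    common boolean label vector: U / (n1 * n0) with tied scores counted one
    half via average ranks."""
    labels = _as_bool_labels(labels)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    ranks = stats.rankdata(scores, axis=-1)
    u = ranks[..., labels].sum(axis=-1) - n1 * (n1 + 1) / 2.0
    return u / (n1 * n0)


@dataclass
class SignificanceResult:
    empirical_p: float
    wilcoxon_p: float
    significant: bool
    alpha: float = 0.05
    rule: str = "conjunction"


def significance(observed_auc: float, perm_aucs: np.ndarray, alpha: float = 0.05,
                 rule: str = "conjunction", min_perm: int = MIN_PERMUTATIONS
                 ) -> SignificanceResult:
    """Significance of an observed AUC against its permutation null.

    empirical p = (1 + #{perm >= observed}) / (n_perm + 1)   (never zero)

    wilcoxon p: one-sided signed-rank test that the permutation AUCs sit
    below the observed value (exact when sample size permits, otherwise a
    normal approximation with continuity correction; zero differences are
    discarded, all-zero differences give p = 1).

    ``rule`` gates the ``significant`` flag: "conjunction" (default, both
    p < alpha), "empirical" or "wilcoxon".
    """
    perm_aucs = np.asarray(perm_aucs, dtype=float)
    n = len(perm_aucs)
    if n < min_perm:
        raise ValueError(f"need at least {min_perm} permutations (got {n})")
    emp_p = (1.0 + np.sum(perm_aucs >= observed_auc)) / (n + 1.0)

    diffs = perm_aucs - observed_auc
    if np.all(diffs == 0):
        wil_p = 1.0
    else:
        wil_p = float(stats.wilcoxon(diffs, alternative="less",
                                     zero_method="wilcox", correction=True,
                                     method="auto").pvalue)
    if rule == "conjunction":
        sig = (emp_p < alpha) and (wil_p < alpha)
    elif rule == "empirical":
        sig = emp_p < alpha
    elif rule == "wilcoxon":
        sig = wil_p < alpha
    else:
        raise ValueError(f"unknown significance rule {rule!r}")
    return SignificanceResult(empirical_p=float(emp_p), wilcoxon_p=wil_p,
                              significant=bool(sig), alpha=alpha, rule=rule)


def permutation_null(epochs: EpochSet, decode_fn: Callable[[EpochSet, int], float],
                     contrast: str = "global", n_perm: int = MIN_PERMUTATIONS,
                     seed: int = 0, min_perm: int = MIN_PERMUTATIONS) -> np.ndarray:
    """Null AUC distribution from full pipeline re-runs on shuffled labels.

    ``decode_fn(epochs, seed) -> auc`` must perform the complete analysis
    (CV/test split, selection, refit, test AUC). Labels of the requested
    contrast are permuted across trials *before* the split. Deterministic
    given ``seed``.
    """
    if n_perm < min_perm:
        raise ValueError(f"need at least {min_perm} permutations (got {n_perm})")
    labels = epochs.labels(contrast)
    aucs = np.empty(n_perm)
    for i in range(n_perm):
        rng = np.random.default_rng(child_seed(seed, "perm", i))
        shuffled = labels[rng.permutation(len(labels))]
        perm_epochs = epochs.with_labels(contrast, shuffled)
        aucs[i] = decode_fn(perm_epochs, child_seed(seed, "perm-decode", i))
    return aucs


@dataclass
class DecodingResult:
    """Complete per-recording, per-contrast decoding outcome."""

    decoder: str                  # "stta" | "svm_concat" | "svm_timepoint"
    contrast: str                 # "global" | "local"
    test_auc: float
    scores: np.ndarray | None = None
    selected: dict = field(default_factory=dict)
    perm_aucs: np.ndarray | None = None
    empirical_p: float = np.nan
    wilcoxon_p: float = np.nan
    significant: bool | None = None
    n_perm: int = 0

    def to_dict(self) -> dict:
        return {
            "decoder": self.decoder, "contrast": self.contrast,
            "test_auc": float(self.test_auc),
            "scores": None if self.scores is None else [float(s) for s in self.scores],
            "selected": self.selected,
            "perm_aucs": None if self.perm_aucs is None
            else [float(a) for a in self.perm_aucs],
            "empirical_p": float(self.empirical_p),
            "wilcoxon_p": float(self.wilcoxon_p),
            "significant": self.significant,
            "n_perm": int(self.n_perm),
        }
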