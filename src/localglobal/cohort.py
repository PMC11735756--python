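"""Cohort-level statistics: sampling-plan power simulation, outcome tests,
consciousness-level correlations, and sedation model selection.

The sampling plan treats each recording as an independent Bernoulli trial
(success = significant single-recording decoding) with an a-priori success
probability estimated from earlier work (5 of 24 first-day coma recordings,
p = 0.21). For each candidate sample size N the number of successes K' is
drawn repeatedly from Binomial(N, p); a draw counts as significant when its
success count could not arise under the null of a zero success probability,
i.e. whenever K' >= 1, so

    Power(N) = sum_i 1[P_H0,i < alpha] / n  ->  1 - (1 - p)^N,

which is also the closed-form oracle against which the Monte-Carlo estimate
is checked.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats


def prior_success_probability(successes: int, total: int) -> float:
    """A-priori per-recording success probability, rounded to two decimals
    as used to parametrise the power simulation (5/24 -> 0.21, 2/10 -> 0.20).
    """
    if not 0 <= successes <= total or total <= 0:
        raise ValueError("need 0 <= successes <= total, total > 0")
    return round(successes / total, 2)


@dataclass
class PowerCurve:
    """Per-N power estimates from the binomial success-count simulation."""

    table: pd.DataFrame     # columns: n, power, mean_k, mc_se, power_closed_form
    p: float
    alpha: float
    n_sims: int

    def power_at(self, n: int) -> float:
        return float(self.table.set_index("n").loc[n, "power"])

    def mean_k_at(self, n: int) -> float:
        return float(self.table.set_index("n").loc[n, "mean_k"])


def power_simulation(p: float, n_range=range(4, 31), n_sims: int = 5000,
                     alpha: float = 0.05, seed: int = 0) -> PowerCurve:
    """Monte-Carlo power of the count-of-successes design.

    For each N in ``n_range``, draws ``n_sims`` success counts
    K' ~ Binomial(N, p). Under H0 (success probability zero) the probability
    of at least K' successes is 1 for K' = 0 and 0 otherwise, so a draw is
    significant iff K' >= 1 (for any alpha in (0, 1)). Reports the estimated
    power, the mean success count <K'>, the Monte-Carlo standard error and
    the closed form 1 - (1-p)^N. Deterministic given ``seed``.
    """
    if not 0 <= p <= 1:
        raise ValueError("p must be in [0, 1]")
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    if n_sims < 1000:
        warnings.warn("n_sims < 1000 gives noisy power estimates")
    rng = np.random.default_rng(seed)
    rows = []
    for n in n_range:
        k = rng.binomial(n, p, size=n_sims)
        p_h0 = np.where(k == 0, 1.0, 0.0)   # P(>= K' successes | p = 0)
        power = float(np.mean(p_h0 < alpha))
        rows.append({
            "n": int(n),
            "power": power,
            "mean_k": float(k.mean()),
            "mc_se": float(np.sqrt(power * (1 - power) / n_sims)),
            "power_closed_form": 1.0 - (1.0 - p) ** n,
        })
    return PowerCurve(table=pd.DataFrame(rows), p=p, alpha=alpha, n_sims=n_sims)


def minimal_sample_size(curve: PowerCurve, target: float = 0.95) -> int:
    """Smallest N in the simulated range whose estimated power reaches the
    target. Raises if the target is never reached."""
    ok = curve.table[curve.table["power"] >= target]
    if ok.empty:
        raise ValueError(
            f"power never reaches {target} in the simulated range "
            f"(max {curve.table['power'].max():.3f})")
    return int(ok["n"].min())


# ---------------------------------------------------------------------------
# outcome / consciousness-level tests
# ---------------------------------------------------------------------------

def outcome_fisher(significant: np.ndarray, favourable: np.ndarray
                   ) -> tuple[float, np.ndarray]:
    """Two-sided Fisher exact test of significant decoding x dichotomised
    outcome. Returns (p, 2x2 counts) with rows = decoding {yes, no} and
    columns = outcome {favourable, unfavourable}."""
    significant = np.asarray(significant, dtype=bool)
    favourable = np.asarray(favourable, dtype=bool)
    if favourable.all() or not favourable.any():
        raise ValueError("both outcome groups must be non-empty")
    counts = np.array([
        [np.sum(significant & favourable), np.sum(significant & ~favourable)],
        [np.sum(~significant & favourable), np.sum(~significant & ~favourable)],
    ])
    p = float(stats.fisher_exact(counts, alternative="two-sided")[1])
    return p, counts


def correlate(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson correlation with a two-sided t-distributed p-value (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need matched samples with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def kruskal_wallis(*groups: np.ndarray) -> tuple[float, float]:
    """Rank-based Kruskal-Wallis H with tie correction; p from the chi-square
    distribution with (n_groups - 1) degrees of freedom. Degenerate input
    (all values identical) returns (0, 1)."""
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    flat = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.all(flat == flat[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


# ---------------------------------------------------------------------------
# sedation model selection
# ---------------------------------------------------------------------------

@dataclass
class ModelSelectionResult:
    selected_terms: list[str]
    coefficients: dict[str, float]
    adj_r2: float
    aic: float
    ledger: list[dict] = field(default_factory=list)
    dropped: list[str] = field(default_factory=list)


def _design(table: pd.DataFrame, terms: list[str]) -> np.ndarray:
    cols = []
    for t in terms:
        if ":" in t:
            a, b = t.split(":")
            cols.append(table[a].to_numpy(float) * table[b].to_numpy(float))
        else:
            cols.append(table[t].to_numpy(float))
    x = np.column_stack(cols) if cols else np.empty((len(table), 0))
    return sm.add_constant(x, has_constant="add")


def sedation_model_selection(table: pd.DataFrame, response: str = "auc",
                             terms: tuple[str, ...] = ("propofol", "fentanyl",
                                                       "midazolam"),
                             include_interactions: bool = True,
                             logit_response: bool = False) -> ModelSelectionResult:
    """Forward selection of sedative infusion-rate terms explaining AUC.

    Ordinary least squares (Gaussian identity link; set ``logit_response`` to
    model logit(AUC) instead). At each step the candidate term with the
    largest adjusted-R2 gain is added, provided the AIC decreases; otherwise
    selection stops. Pairwise interactions become eligible only once both
    main effects are in the model. Zero-variance covariates are dropped with
    a warning. The full candidate ledger (every model evaluated, with
    adjusted R2 and AIC) is returned.
    """
    if len(table) < 10:
        raise ValueError("need at least 10 recordings for model selection")
    y = table[response].to_numpy(float)
    if logit_response:
        eps = 1e-6
        y = np.log(np.clip(y, eps, 1 - eps) / (1 - np.clip(y, eps, 1 - eps)))

    usable, dropped = [], []
    for t in terms:
        if np.std(table[t].to_numpy(float)) == 0:
            warnings.warn(f"covariate {t!r} has zero variance; dropped")
            dropped.append(t)
        else:
            usable.append(t)

    def fit(model_terms: list[str]):
        res = sm.OLS(y, _design(table, model_terms)).fit()
        adj = res.rsquared_adj if model_terms else 0.0
        return res, float(adj), float(res.aic)

    current: list[str] = []
    res, cur_adj, cur_aic = fit(current)
    ledger = [{"terms": [], "adj_r2": cur_adj, "aic": cur_aic, "step": 0,
               "added": None}]
    step = 0
    while True:
        step += 1
        eligible = [t for t in usable if t not in current]
        if include_interactions:
            for a in usable:
                for b in usable:
                    if a < b and a in current and b in current:
                        inter = f"{a}:{b}"
                        if inter not in current:
                            eligible.append(inter)
        if not eligible:
            break
        candidates = []
        for t in eligible:
            _, adj, aic = fit(current + [t])
            candidates.append((t, adj, aic))
            ledger.append({"terms": current + [t], "adj_r2": adj, "aic": aic,
                           "step": step, "added": t})
        best_t, best_adj, best_aic = max(candidates, key=lambda c: c[1])
        if best_aic < cur_aic:
            current = current + [best_t]
            res, cur_adj, cur_aic = fit(current)
        else:
            break
    names = ["intercept"] + current
    coefs = {n: float(b) for n, b in zip(names, res.params)}
    return ModelSelectionResult(selected_terms=current, coefficients=coefs,
                                adj_r2=cur_adj, aic=cur_aic, ledger=ledger,
                                dropped=dropped)


# ---------------------------------------------------------------------------
# cohort-wide summary
# ---------------------------------------------------------------------------

def cohort_statistics(table: pd.DataFrame, alpha: float = 0.05,
                      clinical_features: tuple[str, ...] = ("propofol", "fentanyl",
                                                            "midazolam",
                                                            "temperature", "age")
                      ) -> dict:
    """All protocol statistics for one cohort table, computed per day.

    Requires columns ``auc`` and (for the Fisher and Kruskal-Wallis tests)
    ``significant``; tests whose preconditions fail (empty margins, missing
    flags) are skipped with the reason recorded.
    """
    out: dict = {}
    for day, sub in table.groupby("day"):
        day_stats: dict = {"n": int(len(sub))}
        sub = sub.dropna(subset=["auc"])
        if len(sub) >= 3 and sub["four"].std() > 0 and sub["auc"].std() > 0:
            r, p = correlate(sub["auc"], sub["four"])
            day_stats["pearson_auc_four"] = {"r": r, "p": p}
        if len(sub) >= 3 and sub["cpc"].std() > 0 and sub["auc"].std() > 0:
            r, p = correlate(sub["auc"], sub["cpc"])
            day_stats["pearson_auc_cpc"] = {"r": r, "p": p}
        sig = sub["significant"]
        if sig.notna().all() and len(sub):
            sig = sig.astype(bool).to_numpy()
            fav = (sub["outcome"] == "favourable").to_numpy()
            if 0 < fav.sum() < len(fav):
                p, counts = outcome_fisher(sig, fav)
                day_stats["fisher_outcome"] = {"p": p, "counts": counts.tolist()}
            else:
                day_stats["fisher_outcome"] = {"skipped": "one outcome group empty"}
            kw = {}
            if 0 < sig.sum() < len(sig):
                for feat in clinical_features:
                    if feat in sub:
                        h, p = kruskal_wallis(sub[feat].to_numpy(float)[sig],
                                              sub[feat].to_numpy(float)[~sig])
                        kw[feat] = {"H": h, "p": p}
            day_stats["kruskal_wallis"] = kw or {"skipped": "one decoding group empty"}
        else:
            day_stats["fisher_outcome"] = {"skipped": "significance flags missing"}
        if len(sub) >= 10:
            msel = sedation_model_selection(sub)
            day_stats["sedation_model"] = {
                "selected_terms": msel.selected_terms,
                "coefficients": msel.coefficients,
                "adj_r2": msel.adj_r2, "aic": msel.aic,
            }
        out[int(day)] = day_stats
    return out
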