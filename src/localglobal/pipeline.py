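"""End-to-end orchestration: configuration, seed fan-out, recording-level and
cohort-level runs.

Every run is driven by a single :class:`RunConfig` whose global seed
deterministically derives all stage seeds (SHA-256 fan-out), so reruns with
the same configuration produce identical results. Two profiles are provided:
``RunConfig.default()`` matches the acquisition geometry of the protocol
(63 channels, 1200 Hz, 8 blocks, >= 100 permutations) and
``RunConfig.reduced()`` is a scaled-down profile (16 channels, 120 + 24
trials of a single block, coarser window grid, 50 permutations) for
simulation studies and continuous testing.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd
import yaml

from ._utils import child_seed, config_hash
from .epochs import EpochSet
from .inference import DecodingResult, permutation_null, significance
from .preprocessing import baseline_correct, gfp_normalize, split_cv_test
from .stta import SttaConfig, decode_test_stta
from .svm import SvmConfig, build_features_concat, cv_select_svm, decode_test_svm
from .synthetic import (CohortSimParams, HeadModel, RecordingSimParams,
                        default_effects, simulate_cohort, simulate_recording)
from .paradigm import build_session


@dataclass
class RunConfig:
    """Complete configuration of a decoding run."""

    seed: int = 0
    decoder: str = "stta"                    # "stta" | "svm_concat"
    contrasts: tuple[str, ...] = ("global", "local")
    cv_frac: float = 0.8
    n_perm: int = 100
    min_perm: int = 100
    alpha: float = 0.05
    significance_rule: str = "conjunction"
    baseline: bool = True
    stta: SttaConfig = field(default_factory=SttaConfig)
    svm: SvmConfig = field(default_factory=SvmConfig)
    # simulation geometry (used when the run simulates its own recordings)
    n_channels: int = 63
    sfreq: float = 1200.0
    n_standard: int = 100
    n_deviant: int = 20
    n_reps: int = 2
    single_block: bool = False   # simulate one block only (reduced profile)
    noise_sd: float = 5.0
    global_amplitude_uv: float = 2.0
    local_amplitude_uv: float = 2.0

    @classmethod
    def default(cls, seed: int = 0) -> "RunConfig":
        return cls(seed=seed)

    @classmethod
    def reduced(cls, seed: int = 0) -> "RunConfig":
        """Scaled-down profile for simulation studies: 16 channels, one block
        of 120 standards + 24 deviants at 120 Hz, coarse STTA grid, 50
        permutations."""
        return cls(
            seed=seed,
            n_perm=50, min_perm=50,
            stta=SttaConfig(k_values=(1, 2), window_start_step_ms=50.0,
                            window_min_length_ms=100.0, n_folds=3, n_restarts=1,
                            em_max_iter=100, max_fit_points=8000),
            svm=SvmConfig(kernels=("linear",), c_grid=(0.01, 1.0), n_folds=3),
            n_channels=16, sfreq=120.0, n_standard=120, n_deviant=24, n_reps=1,
            single_block=True,
        )

    # -- (de)serialisation ---------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stta"] = dataclasses.asdict(self.stta)
        d["svm"] = {k: v for k, v in dataclasses.asdict(self.svm).items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "stta" in d:
            s = dict(d["stta"])
            s["k_values"] = tuple(s.get("k_values", (1, 2, 3, 4, 5, 6)))
            if "window_range_ms" in s:
                s["window_range_ms"] = tuple(s["window_range_ms"])
            d["stta"] = SttaConfig(**s)
        if "svm" in d:
            s = {k: v for k, v in d["svm"].items() if k != "grid"}
            for key in ("kernels", "c_grid", "gamma_grid"):
                if key in s:
                    s[key] = tuple(s[key])
            d["svm"] = SvmConfig(**s)
        for key in ("contrasts",):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    @property
    def hash(self) -> str:
        return config_hash(self.to_dict())


def simulate_session_epochs(config: RunConfig, seed: int | None = None,
                            global_amplitude_uv: float | None = None,
                            local_amplitude_uv: float | None = None) -> EpochSet:
    """Simulate one recording's epochs under the configuration's geometry."""
    seed = config.seed if seed is None else seed
    if config.single_block:
        from .synthetic import single_block_schedule
        sched = single_block_schedule(child_seed(seed, "schedule"),
                                      config.n_standard, config.n_deviant)
    else:
        sched = build_session(child_seed(seed, "schedule"),
                              n_standard=config.n_standard,
                              n_deviant=config.n_deviant, n_reps=config.n_reps)
    head = HeadModel.random(config.n_channels, n_components=2,
                            seed=child_seed(seed, "head"))
    ga = config.global_amplitude_uv if global_amplitude_uv is None else global_amplitude_uv
    la = config.local_amplitude_uv if local_amplitude_uv is None else local_amplitude_uv
    params = RecordingSimParams(
        schedule=sched, head=head, effects=default_effects(ga, la),
        noise_sd=config.noise_sd, sfreq=config.sfreq,
        seed=child_seed(seed, "recording"))
    return simulate_recording(params)


def decode_once(epochs: EpochSet, contrast: str, config: RunConfig, seed: int
                ) -> tuple[float, dict]:
    """One full decode: split -> CV selection -> refit -> test AUC."""
    data = baseline_correct(epochs) if config.baseline else epochs
    cv, test = split_cv_test(data, contrast, config.cv_frac,
                             seed=child_seed(seed, "split"))
    if config.decoder == "stta":
        scfg = replace(config.stta, seed=child_seed(seed, "stta"))
        res = decode_test_stta(gfp_normalize(cv), gfp_normalize(test),
                               contrast, scfg)
        return res.test_auc, {
            "selected": {"k_deviant": res.k_deviant, "k_standard": res.k_standard,
                         "window_ms": list(res.window_ms), "cv_auc": res.cv_auc},
            "scores": res.scores}
    if config.decoder == "svm_concat":
        scfg = replace(config.svm, seed=child_seed(seed, "svm"))
        x_cv, x_te = build_features_concat(cv), build_features_concat(test)
        y_cv, y_te = cv.deviant_mask(contrast), test.deviant_mask(contrast)
        params, cv_auc, _ = cv_select_svm(x_cv, y_cv, scfg)
        auc, margins = decode_test_svm(x_cv, y_cv, x_te, y_te, params, scfg)
        return auc, {"selected": {**params, "cv_auc": cv_auc}, "scores": margins}
    raise ValueError(f"unknown decoder {config.decoder!r}")


def run_recording(epochs: EpochSet, config: RunConfig,
                  recording_id: str = "rec000", out_dir: str | Path | None = None
                  ) -> dict[str, DecodingResult]:
    """Decode one recording on every requested contrast, with permutation
    significance, optionally writing one JSON result file per contrast."""
    results: dict[str, DecodingResult] = {}
    for contrast in config.contrasts:
        seed = child_seed(config.seed, "recording", recording_id, contrast)
        try:
            auc, details = decode_once(epochs, contrast, config, seed)
        except Exception as exc:
            raise RuntimeError(f"[decode:{contrast}] {exc}") from exc
        perm = permutation_null(
            epochs, lambda ep, s: decode_once(ep, contrast, config, s)[0],
            contrast=contrast, n_perm=config.n_perm,
            seed=child_seed(seed, "null"), min_perm=config.min_perm)
        sig = significance(auc, perm, alpha=config.alpha,
                           rule=config.significance_rule, min_perm=config.min_perm)
        results[contrast] = DecodingResult(
            decoder=config.decoder, contrast=contrast, test_auc=auc,
            scores=details.get("scores"), selected=details.get("selected", {}),
            perm_aucs=perm, empirical_p=sig.empirical_p, wilcoxon_p=sig.wilcoxon_p,
            significant=sig.significant, n_perm=config.n_perm)
        if out_dir is not None:
            out_dir = Path(out_dir)
            out_dir.mkdir(parents=True, exist_ok=True)
            payload = results[contrast].to_dict()
            payload["config_hash"] = config.hash
            payload["recording_id"] = recording_id
            (out_dir / f"{recording_id}_{contrast}_{config.decoder}.json"
             ).write_text(json.dumps(payload, indent=1))
    return results


def decode_cohort(table: pd.DataFrame, recordings: list[EpochSet],
                  config: RunConfig, with_significance: bool = False
                  ) -> pd.DataFrame:
    """Fill the ``auc`` (and optionally ``significant``) columns of a cohort
    table by decoding each recording's global contrast."""
    table = table.copy()
    for i, rec in enumerate(recordings):
        seed = child_seed(config.seed, "cohort-rec", i)
        auc, _ = decode_once(rec, "global", config, seed)
        table.loc[table.index[i], "auc"] = auc
        if with_significance:
            perm = permutation_null(
                rec, lambda ep, s: decode_once(ep, "global", config, s)[0],
                contrast="global", n_perm=config.n_perm,
                seed=child_seed(seed, "null"), min_perm=config.min_perm)
            sig = significance(auc, perm, alpha=config.alpha,
                               rule=config.significance_rule,
                               min_perm=config.min_perm)
            table.loc[table.index[i], "significant"] = sig.significant
    return table


def run_cohort(cohort_params: CohortSimParams, config: RunConfig,
               with_significance: bool = False,
               out_dir: str | Path | None = None) -> tuple[pd.DataFrame, dict]:
    """Simulate a cohort, decode every recording, and compute all cohort
    statistics. Returns the filled table and the statistics mapping."""
    from .cohort import cohort_statistics

    table, recordings = simulate_cohort(cohort_params)
    table = decode_cohort(table, recordings, config,
                          with_significance=with_significance)
    stats = cohort_statistics(table, alpha=config.alpha)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        table.to_csv(out_dir / "cohort_table.csv", index=False)
        (out_dir / "cohort_stats.json").write_text(
            json.dumps({"config_hash": config.hash, "stats": stats}, indent=1,
                       default=float))
    return table, stats
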