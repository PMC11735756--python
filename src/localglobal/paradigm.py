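"""Local-global auditory paradigm: stimulus schedule construction and labels.

The paradigm presents series of five pure tones (A = 100 ms, B = 150 ms) with a
fixed 490 ms stimulus onset asynchrony. Within a block one series type is
frequent (the *global standard*, 100 of 120 series) and one is rare (the
*global deviant*, 20 of 120). Independently, a series whose fifth tone differs
from the first four (AAAAB, BBBBA) is a *local deviant*. Four block types cross
the two regularity dimensions:

====== =============== ==============
block  global standard global deviant
====== =============== ==============
1      AAAAB           AAAAA
2      AAAAA           AAAAB
3      BBBBB           BBBBA
4      BBBBA           BBBBB
====== =============== ==============

A session consists of two repetitions of each block type in a semi-randomised
order (no immediate repetition of the same block type). Inter-trial intervals
between series are drawn uniformly from [1450, 1800] ms, measured from the
fifth-tone onset to the next series' first-tone onset.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .epochs import DEVIANT, STANDARD
from ._utils import child_seed

#: tone identities and durations (ms); A and B differ only in duration
TONE_DURATION_MS = {"A": 100.0, "B": 150.0}
#: default carrier frequency (Hz) of the binaural synchronous pure tones
TONE_CARRIER_HZ = 1000.0

SERIES_KINDS = ("AAAAA", "AAAAB", "BBBBB", "BBBBA")

#: (global standard, global deviant) per block type; block 2 reverses block 1,
#: blocks 3/4 repeat the structure with tones A and B swapped
BLOCK_ASSIGNMENTS = {
    1: ("AAAAB", "AAAAA"),
    2: ("AAAAA", "AAAAB"),
    3: ("BBBBB", "BBBBA"),
    4: ("BBBBA", "BBBBB"),
}

SOA_MS = 490.0
ITI_RANGE_MS = (1450.0, 1800.0)
N_STANDARD = 100
N_DEVIANT = 20
N_BLOCKS = 8
#: series per block before which no global deviant may occur (the regularity
#: must be establishable) and minimum spacing: no two consecutive deviants
DEVIANT_LEAD_IN = 10


@dataclass(frozen=True)
class ToneSpec:
    """A single pure tone: identity, duration, carrier frequency."""

    identity: str
    duration_ms: float
    carrier_hz: float = TONE_CARRIER_HZ

    @classmethod
    def from_identity(cls, identity: str) -> "ToneSpec":
        if identity not in TONE_DURATION_MS:
            raise ValueError(f"unknown tone identity {identity!r}; expected 'A' or 'B'")
        return cls(identity=identity, duration_ms=TONE_DURATION_MS[identity])


def is_local_deviant(kind: str) -> bool:
    """A series is a local deviant iff its fifth tone differs from the first four."""
    if kind not in SERIES_KINDS:
        raise ValueError(f"unknown series kind {kind!r}; expected one of {SERIES_KINDS}")
    return kind[4] != kind[0]


@dataclass(frozen=True)
class BlockSpec:
    """One block: the standard/deviant series assignment and the counts."""

    block_type: int
    global_standard: str
    global_deviant: str
    n_standard: int = N_STANDARD
    n_deviant: int = N_DEVIANT

    @property
    def n_series(self) -> int:
        return self.n_standard + self.n_deviant


def _deviant_positions(n_series: int, n_deviant: int, lead_in: int,
                       rng: np.random.Generator) -> np.ndarray:
    """Uniform draw of deviant positions with no deviant in the first
    ``lead_in`` series and no two consecutive deviants."""
    n_allowed = n_series - lead_in
    # stars-and-bars: non-consecutive k-subsets of n_allowed slots correspond
    # to plain k-subsets of n_allowed - (k - 1) slots
    n_compressed = n_allowed - (n_deviant - 1)
    if n_compressed < n_deviant:
        raise ValueError("deviant placement constraints are infeasible for these counts")
    base = np.sort(rng.choice(n_compressed, size=n_deviant, replace=False))
    return lead_in + base + np.arange(n_deviant)


def build_block(block_type: int, seed: int, n_standard: int = N_STANDARD,
                n_deviant: int = N_DEVIANT, lead_in: int = DEVIANT_LEAD_IN
                ) -> tuple[BlockSpec, list[str]]:
    """Build one block: its spec and the ordered list of series kinds.

    Deviants are placed pseudo-randomly: never within the first ``lead_in``
    series, never on consecutive series, uniform otherwise. Deterministic
    given ``seed``.
    """
    if block_type not in BLOCK_ASSIGNMENTS:
        raise ValueError(
            f"unknown block_type {block_type!r}; valid block types are 1-4")
    std, dev = BLOCK_ASSIGNMENTS[block_type]
    spec = BlockSpec(block_type, std, dev, n_standard, n_deviant)
    rng = np.random.default_rng(seed)
    pos = _deviant_positions(spec.n_series, n_deviant, lead_in, rng)
    kinds = [std] * spec.n_series
    for p in pos:
        kinds[int(p)] = dev
    return spec, kinds


def _block_order(rng: np.random.Generator, n_reps: int = 2) -> list[int]:
    """Semi-randomised order: permutation of each block type repeated
    ``n_reps`` times, with no two identical types adjacent."""
    types = np.repeat(np.arange(1, 5), n_reps)
    for _ in range(10_000):
        order = rng.permutation(types)
        if not np.any(order[1:] == order[:-1]):
            return [int(t) for t in order]
    raise RuntimeError("could not find a valid semi-randomised block order")


@dataclass
class StimulusSchedule:
    """Ordered series of tone quintets with onsets and condition labels.

    ``series`` is a DataFrame with one row per series:
    ``block`` (1-based position in session), ``block_type``, ``series_index``
    (within block), ``series_kind``, ``onset`` (s, first-tone onset),
    ``global_label``, ``local_label``.
    """

    series: pd.DataFrame
    soa_ms: float = SOA_MS
    iti_range_ms: tuple[float, float] = ITI_RANGE_MS
    seed: int | None = None
    blocks: list[BlockSpec] = field(default_factory=list)

    @property
    def n_series(self) -> int:
        return len(self.series)

    def tone_onsets(self) -> np.ndarray:
        """(n_series, 5) tone onsets in seconds."""
        onsets = self.series["onset"].to_numpy()
        return onsets[:, None] + np.arange(5)[None, :] * self.soa_ms / 1000.0

    def fifth_tone_onsets(self) -> np.ndarray:
        return self.series["onset"].to_numpy() + 4 * self.soa_ms / 1000.0

    # -- BIDS-style events export --------------------------------------
    def to_events(self) -> pd.DataFrame:
        dur = [4 * self.soa_ms / 1000.0 + TONE_DURATION_MS[k[4]] / 1000.0
               for k in self.series["series_kind"]]
        ev = self.series[["onset", "block", "series_index", "series_kind",
                          "global_label", "local_label"]].copy()
        ev.insert(1, "duration", dur)
        return ev

    def save_events(self, path: str | Path) -> None:
        """Write a tab-separated events table plus a JSON sidecar."""
        path = Path(path)
        self.to_events().to_csv(path, sep="\t", index=False)
        sidecar = {"soa_ms": self.soa_ms, "iti_range_ms": list(self.iti_range_ms),
                   "seed": self.seed}
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load_events(cls, path: str | Path) -> "StimulusSchedule":
        path = Path(path)
        ev = pd.read_csv(path, sep="\t")
        meta = {}
        sidecar = path.with_suffix(".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
        series = ev.drop(columns=["duration"])
        return cls(series=series,
                   soa_ms=meta.get("soa_ms", SOA_MS),
                   iti_range_ms=tuple(meta.get("iti_range_ms", ITI_RANGE_MS)),
                   seed=meta.get("seed"))


def build_session(seed: int, n_standard: int = N_STANDARD, n_deviant: int = N_DEVIANT,
                  n_reps: int = 2, soa_ms: float = SOA_MS,
                  iti_range_ms: tuple[float, float] = ITI_RANGE_MS) -> StimulusSchedule:
    """Build a full session schedule: two repetitions of each of the four
    block types in semi-randomised order, with all tone/series timings.

    Deterministic given ``seed``: block order, deviant placement and the
    uniform inter-trial intervals are all derived from it.
    """
    rng = np.random.default_rng(child_seed(seed, "session"))
    order = _block_order(rng, n_reps=n_reps)
    lo, hi = iti_range_ms
    rows = []
    blocks: list[BlockSpec] = []
    t = 0.0
    for b_idx, b_type in enumerate(order, start=1):
        spec, kinds = build_block(b_type, child_seed(seed, "block", b_idx),
                                  n_standard=n_standard, n_deviant=n_deviant)
        blocks.append(spec)
        for s_idx, kind in enumerate(kinds):
            glabel = STANDARD if kind == spec.global_standard else DEVIANT
            llabel = DEVIANT if is_local_deviant(kind) else STANDARD
            rows.append({"block": b_idx, "block_type": b_type, "series_index": s_idx,
                         "series_kind": kind, "onset": t, "global_label": glabel,
                         "local_label": llabel})
            iti = rng.uniform(lo, hi) / 1000.0
            t = t + 4 * soa_ms / 1000.0 + iti
    series = pd.DataFrame(rows)
    return StimulusSchedule(series=series, soa_ms=soa_ms, iti_range_ms=iti_range_ms,
                            seed=seed, blocks=blocks)


def label_series(schedule: StimulusSchedule) -> pd.DataFrame:
    """Recompute (global_label, local_label) for every series from its kind
    and block-type assignment. Labels are independent dimensions: in block
    type 1 the global standard AAAAB is a local deviant."""
    glabels, llabels = [], []
    for _, row in schedule.series.iterrows():
        std, dev = BLOCK_ASSIGNMENTS[int(row["block_type"])]
        kind = row["series_kind"]
        if kind not in (std, dev):
            raise ValueError(f"series kind {kind!r} not valid in block type "
                             f"{row['block_type']}")
        glabels.append(STANDARD if kind == std else DEVIANT)
        llabels.append(DEVIANT if is_local_deviant(kind) else STANDARD)
    return pd.DataFrame({"global_label": glabels, "local_label": llabels},
                        index=schedule.series.index)
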