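"""Synthetic behavioral experiment generator.

Emulates a masked-Gabor two-interval confidence experiment: on each trial one
interval contains a tilted target at one of thirteen contrast levels (15-90%
stimulus contrast) and the other is blank; the participant discriminates the
tilt of *both* intervals and bets on the discrimination they are more
confident in. The simulated participant is a Bayesian observer from
:mod:`metabet.observer`. "Discrimination" responses to the blank interval have
no correct answer, so their correctness is coded as an independent Bernoulli
with probability 0.5, exactly as in the task's scoring rule.

Defaults reproduce the reference design: 13 contrasts x 2 tilts x 2 interval
orders x 10 trials per cell x 5 sessions = 2600 trials, 200 per contrast.
"""

from __future__ import annotations

import hashlib
import io
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .observer import ObserverConfig, simulate_trials

#: CSV schema, in column order. Orientations are "left"/"right", intervals
#: "TP"/"TA" (target-present / target-absent).
CSV_COLUMNS = [
    "experiment_id",
    "subject_id",
    "session",
    "trial_index",
    "contrast_pct",
    "evidence",
    "true_orientation",
    "interval_order",
    "response_tp",
    "response_ta",
    "bet_interval",
    "correct_tp",
    "correct_ta_coded",
]

ORIENTATIONS = ("left", "right")
INTERVAL_ORDERS = ("TP-first", "TP-second")

#: Default mapping of the 15-90% stimulus contrast range onto evidence units
#: (multiples of the baseline noise SD). The linear map below makes the ideal
#: observer's discrimination accuracy span roughly evenly from chance to ~100%
#: across the grid, matching the titration goal of the reference design.
DEFAULT_EVIDENCE_RANGE = (0.2, 4.2)
DEFAULT_CONTRAST_RANGE_PCT = (15.0, 90.0)


def contrast_to_evidence(
    contrast_pct: np.ndarray,
    contrast_range: tuple[float, float] = DEFAULT_CONTRAST_RANGE_PCT,
    evidence_range: tuple[float, float] = DEFAULT_EVIDENCE_RANGE,
) -> np.ndarray:
    """Linear map from stimulus contrast (%) to evidence units."""
    c = np.asarray(contrast_pct, dtype=float)
    lo, hi = contrast_range
    e_lo, e_hi = evidence_range
    return e_lo + (c - lo) * (e_hi - e_lo) / (hi - lo)


@dataclass(frozen=True)
class ExperimentDesign:
    """Full-factorial two-interval confidence task design."""

    contrast_values_pct: tuple[float, ...] = tuple(
        np.round(np.linspace(*DEFAULT_CONTRAST_RANGE_PCT, 13), 3)
    )
    trials_per_cell: int = 10
    n_sessions: int = 5
    evidence_range: tuple[float, float] = DEFAULT_EVIDENCE_RANGE
    feedback_mode: str = "none"  # "none" (Expt-1 style) or "type2-hit" (Expt-2)
    question_order: str = "bet-first"  # or "discriminate-first"

    def __post_init__(self) -> None:
        if len(self.contrast_values_pct) < 1:
            raise ValueError("need at least one contrast level")
        if self.trials_per_cell < 1 or self.n_sessions < 1:
            raise ValueError("counts must be positive")
        if self.feedback_mode not in ("none", "type2-hit"):
            raise ValueError("feedback_mode must be 'none' or 'type2-hit'")
        if self.question_order not in ("bet-first", "discriminate-first"):
            raise ValueError("question_order must be 'bet-first' or 'discriminate-first'")

    @property
    def n_contrasts(self) -> int:
        return len(self.contrast_values_pct)

    @property
    def n_trials(self) -> int:
        return self.n_contrasts * 2 * 2 * self.trials_per_cell * self.n_sessions

    @property
    def trials_per_contrast(self) -> int:
        return 2 * 2 * self.trials_per_cell * self.n_sessions

    def evidence_levels(self) -> np.ndarray:
        lo, hi = min(self.contrast_values_pct), max(self.contrast_values_pct)
        rng_pct = (lo, hi) if lo < hi else DEFAULT_CONTRAST_RANGE_PCT
        return contrast_to_evidence(
            np.asarray(self.contrast_values_pct), rng_pct, self.evidence_range
        )


def build_design(**params) -> ExperimentDesign:
    """Construct a design; defaults give 2600 trials, 200 per contrast."""
    return ExperimentDesign(**params)


def enumerate_trials(design: ExperimentDesign, rng: np.random.Generator) -> pd.DataFrame:
    """Counterbalanced trial list, shuffled within each session.

    Every (contrast x tilt x interval-order) cell appears exactly
    ``trials_per_cell`` times per session.
    """
    evidence = design.evidence_levels()
    cells = [
        (s, pct, ev, ori, order)
        for s in range(1, design.n_sessions + 1)
        for pct, ev in zip(design.contrast_values_pct, evidence)
        for ori in ORIENTATIONS
        for order in INTERVAL_ORDERS
        for _ in range(design.trials_per_cell)
    ]
    df = pd.DataFrame(
        cells,
        columns=["session", "contrast_pct", "evidence", "true_orientation", "interval_order"],
    )
    # shuffle within session, preserving session order
    parts = []
    for s, grp in df.groupby("session", sort=True):
        parts.append(grp.iloc[rng.permutation(len(grp))])
    out = pd.concat(parts, ignore_index=True)
    out["trial_index"] = np.arange(1, len(out) + 1)
    return out


@dataclass
class BehavioralDataset:
    """Trial records plus (for simulated data) generating provenance."""

    design: ExperimentDesign | None
    records: pd.DataFrame
    provenance: dict | None = None  # generating ObserverConfig + seed; None if imported

    @property
    def imported(self) -> bool:
        return self.provenance is None

    def __post_init__(self) -> None:
        missing = [c for c in CSV_COLUMNS if c not in self.records.columns]
        if missing:
            raise ValueError(f"dataset missing columns: {missing}")


def simulate_dataset(
    design: ExperimentDesign,
    agent: ObserverConfig,
    seed: int,
    subject_id: str = "sim01",
    experiment_id: str = "1",
) -> BehavioralDataset:
    """Run one simulated participant through the full design.

    The agent's contrast grid is ignored in favour of the design's evidence
    levels only for stimulus generation; the observer still marginalises over
    its own configured grid. Reproducible: the same seed yields an identical
    dataset.
    """
    rng = np.random.default_rng(seed)
    trials = enumerate_trials(design, rng)
    sim = simulate_trials(
        agent,
        trials["true_orientation"].to_numpy(),
        trials["evidence"].to_numpy(),
        rng,
    )
    code = {1: "left", -1: "right"}
    trials = trials.copy()
    trials["experiment_id"] = experiment_id
    trials["subject_id"] = subject_id
    trials["response_tp"] = [code[v] for v in sim["choice_tp"]]
    trials["response_ta"] = [code[v] for v in sim["choice_ta"]]
    trials["bet_interval"] = np.where(sim["bet_tp"], "TP", "TA")
    trials["correct_tp"] = sim["correct_tp"]
    # blank-interval "discrimination" has no right answer: coded correct at 50%
    trials["correct_ta_coded"] = rng.random(len(trials)) < 0.5
    records = trials[CSV_COLUMNS].reset_index(drop=True)
    # JSON-normalised (tuples become lists) so it round-trips the CSV header
    prov = json.loads(json.dumps({"agent": asdict(agent), "seed": int(seed)}))
    return BehavioralDataset(design=design, records=records, provenance=prov)


def default_observer_config(design: ExperimentDesign | None = None, **overrides) -> ObserverConfig:
    """Observer whose marginalisation grid is the design's evidence levels."""
    design = design or ExperimentDesign()
    kw = dict(contrast_grid=tuple(design.evidence_levels()))
    kw.update(overrides)
    return ObserverConfig(**kw)


# ---------------------------------------------------------------------------
# CSV round-trip
# ---------------------------------------------------------------------------

def _provenance_hash(provenance: dict) -> str:
    return hashlib.sha256(
        json.dumps(provenance, sort_keys=True).encode()
    ).hexdigest()[:12]


def write_csv(dataset: BehavioralDataset, path: str | Path) -> None:
    """Write a dataset as UTF-8 CSV with a provenance comment header."""
    path = Path(path)
    buf = io.StringIO()
    if dataset.provenance is not None:
        prov_json = json.dumps(dataset.provenance, sort_keys=True)
        buf.write(f"# metabet-provenance hash={_provenance_hash(dataset.provenance)} {prov_json}\n")
    dataset.records.to_csv(buf, index=False)
    path.write_text(buf.getvalue(), encoding="utf-8")


def read_csv(path: str | Path) -> BehavioralDataset:
    """Read a trial CSV; third-party files without provenance are accepted
    and flagged as imported."""
    path = Path(path)
    provenance = None
    with path.open(encoding="utf-8") as fh:
        first = fh.readline()
    if first.startswith("# metabet-provenance"):
        provenance = json.loads(first.split(None, 3)[3])
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:  # malformed CSV
        raise ValueError(f"could not parse {path}: {exc}") from exc
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    bad_ori = set(df["true_orientation"]) | set(df["response_tp"]) | set(df["response_ta"])
    unknown = bad_ori - set(ORIENTATIONS)
    if unknown:
        rows = df.index[
            ~df["true_orientation"].isin(ORIENTATIONS)
            | ~df["response_tp"].isin(ORIENTATIONS)
            | ~df["response_ta"].isin(ORIENTATIONS)
        ]
        line = int(rows[0]) + 2  # +1 header, +1 one-based
        raise ValueError(f"{path}: unknown orientation label(s) {sorted(unknown)} at line {line}")
    if not set(df["bet_interval"]) <= {"TP", "TA"}:
        raise ValueError(f"{path}: bet_interval must be 'TP' or 'TA'")
    for col in ("correct_tp", "correct_ta_coded"):
        df[col] = df[col].astype(bool)
    for col in ("experiment_id", "subject_id"):
        df[col] = df[col].astype(str)
    return BehavioralDataset(design=None, records=df[CSV_COLUMNS], provenance=provenance)
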