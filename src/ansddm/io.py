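"""Trial-level data model for the dot-comparison task.

A session is 12 blocks of 64 two-alternative trials: two dot arrays
(numerosities 9-21, ratio 4:3, 7:6, 9:8 or 10:9) are flashed and the
participant presses the side with more dots within a 3 s response window.
This module parses/writes the trial CSV, collapses left/right-mirrored
trials into the four ratio conditions, and applies the cohort exclusion
rules (overall accuracy and fast-guess screening).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The four design ratios, as (larger, smaller) integer pairs.
RATIOS: tuple[tuple[int, int], ...] = ((4, 3), (7, 6), (9, 8), (10, 9))

_RATIO_BY_FRACTION = {Fraction(a, b): (a, b) for a, b in RATIOS}

#: Response window in seconds; later responses were not recorded.
RESPONSE_WINDOW = 3.0

#: Admissible numerosity range for either array.
NUMEROSITY_RANGE = (9, 21)

#: Columns of the trial CSV, in canonical order.
TRIAL_COLUMNS = (
    "participant_id",
    "block",
    "trial",
    "n_left",
    "n_right",
    "response",
    "rt",
    "area_control",
    "field_control",
)


class TrialFormatError(ValueError):
    """The file does not have the expected columns/types."""


class TrialValidationError(ValueError):
    """One or more rows violate the trial invariants."""


@dataclass(frozen=True)
class TrialRecord:
    """A single comparison trial.

    ``area_control`` is 1 when total surface area was equated between the
    two arrays (0: individual item area equated); ``field_control`` is 1
    when density was equated (0: convex-field area equated).
    """

    participant_id: str
    block: int
    trial: int
    n_left: int
    n_right: int
    response: str  # "left" or "right"
    rt: float  # seconds
    area_control: int = 0
    field_control: int = 0

    def __post_init__(self) -> None:
        if self.n_left == self.n_right:
            raise TrialValidationError(
                f"n_left == n_right == {self.n_left}; the design has no equal pairs"
            )
        if self.response not in ("left", "right"):
            raise TrialValidationError(f"response must be left/right, got {self.response!r}")
        hi, lo = max(self.n_left, self.n_right), min(self.n_left, self.n_right)
        frac = Fraction(hi, lo)
        if frac not in _RATIO_BY_FRACTION:
            raise TrialValidationError(
                f"numerosity pair {self.n_left}:{self.n_right} is not in the "
                f"design ratio set {{4:3, 7:6, 9:8, 10:9}}"
            )
        if not (0.0 < self.rt <= RESPONSE_WINDOW):
            raise TrialValidationError(
                f"rt={self.rt} outside (0, {RESPONSE_WINDOW}] s response window"
            )

    @property
    def ratio(self) -> tuple[int, int]:
        hi, lo = max(self.n_left, self.n_right), min(self.n_left, self.n_right)
        return _RATIO_BY_FRACTION[Fraction(hi, lo)]

    @property
    def larger_side(self) -> str:
        return "left" if self.n_left > self.n_right else "right"

    @property
    def correct(self) -> bool:
        """A response is correct iff it points at the larger array."""
        return self.response == self.larger_side


@dataclass
class ConditionData:
    """Per-ratio correct/error RT samples after side-collapsing."""

    ratio: tuple[int, int]
    correct_rts: np.ndarray
    error_rts: np.ndarray

    def __post_init__(self) -> None:
        self.correct_rts = np.asarray(self.correct_rts, dtype=float)
        self.error_rts = np.asarray(self.error_rts, dtype=float)

    @property
    def n_correct(self) -> int:
        return int(self.correct_rts.size)

    @property
    def n_error(self) -> int:
        return int(self.error_rts.size)

    @property
    def n_total(self) -> int:
        return self.n_correct + self.n_error

    @property
    def accuracy(self) -> float:
        return self.n_correct / self.n_total if self.n_total else float("nan")


def read_trials(path, rt_unit: str = "s") -> dict[str, list[TrialRecord]]:
    """Read a trial CSV into validated records grouped by participant.

    Rows with an empty response (omitted trials) are dropped with a logged
    count.  Malformed rows raise :class:`TrialValidationError` listing the
    offending file line numbers (header = line 1).

    Parameters
    ----------
    path : str or file-like
        Delimited text with the columns in :data:`TRIAL_COLUMNS`.
    rt_unit : {"s", "ms"}
        Unit of the ``rt`` column.  All in-memory RTs are seconds.
    """
    if rt_unit not in ("s", "ms"):
        raise ValueError(f"rt_unit must be 's' or 'ms', got {rt_unit!r}")
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise TrialFormatError(f"missing column(s): {sorted(missing)}")

    omitted = df["response"].isna() | (df["response"].astype(str).str.strip() == "")
    if omitted.any():
        logger.warning("dropping %d omitted (no-response) trial(s)", int(omitted.sum()))
    df = df[~omitted]

    groups: dict[str, list[TrialRecord]] = {}
    errors: list[str] = []
    for idx, row in df.iterrows():
        line = idx + 2  # header occupies line 1
        try:
            rt = float(row["rt"])
            if rt_unit == "ms":
                rt /= 1000.0
            rec = TrialRecord(
                participant_id=str(row["participant_id"]),
                block=int(row["block"]),
                trial=int(row["trial"]),
                n_left=int(row["n_left"]),
                n_right=int(row["n_right"]),
                response=str(row["response"]).strip(),
                rt=rt,
                area_control=int(row["area_control"]),
                field_control=int(row["field_control"]),
            )
        except (TrialValidationError, ValueError) as exc:
            errors.append(f"line {line}: {exc}")
            continue
        groups.setdefault(rec.participant_id, []).append(rec)
    if errors:
        raise TrialValidationError(
            f"{len(errors)} malformed row(s):\n" + "\n".join(errors)
        )
    return groups


def trials_to_frame(groups: dict[str, list[TrialRecord]]) -> pd.DataFrame:
    rows = [
        {c: getattr(t, c) for c in TRIAL_COLUMNS}
        for trials in groups.values()
        for t in trials
    ]
    return pd.DataFrame(rows, columns=list(TRIAL_COLUMNS))


def write_trials(groups: dict[str, list[TrialRecord]] | pd.DataFrame, path) -> None:
    """Write trials back to the canonical CSV format (RT in seconds)."""
    df = groups if isinstance(groups, pd.DataFrame) else trials_to_frame(groups)
    df.to_csv(path, index=False)


def frame_to_groups(df: pd.DataFrame) -> dict[str, list[TrialRecord]]:
    """Build validated records from an in-memory trial table."""
    groups: dict[str, list[TrialRecord]] = {}
    for row in df.itertuples(index=False):
        rec = TrialRecord(
            participant_id=str(row.participant_id),
            block=int(row.block),
            trial=int(row.trial),
            n_left=int(row.n_left),
            n_right=int(row.n_right),
            response=str(row.response),
            rt=float(row.rt),
            area_control=int(row.area_control),
            field_control=int(row.field_control),
        )
        groups.setdefault(rec.participant_id, []).append(rec)
    return groups


def collapse_conditions(trials: list[TrialRecord]) -> dict[tuple[int, int], ConditionData]:
    """Collapse one participant's trials into the four ratio conditions.

    Trials with the larger array on the left are combined with mirrored
    trials (larger on the right, response switched), so only the ratio and
    the correct/error status survive.  Always returns all four ratios; with
    empty input every condition has zero counts.
    """
    pids = {t.participant_id for t in trials}
    if len(pids) > 1:
        raise ValueError(f"trials span multiple participants: {sorted(pids)}")
    rts: dict[tuple[int, int], tuple[list[float], list[float]]] = {
        r: ([], []) for r in RATIOS
    }
    for t in trials:
        correct, error = rts[t.ratio]
        (correct if t.correct else error).append(t.rt)
    return {
        r: ConditionData(ratio=r, correct_rts=np.array(c), error_rts=np.array(e))
        for r, (c, e) in rts.items()
    }


@dataclass
class ExclusionReport:
    kept: dict[str, list[TrialRecord]]
    excluded: dict[str, list[str]] = field(default_factory=dict)


def apply_exclusions(
    cohort: dict[str, list[TrialRecord]],
    min_accuracy: float = 0.60,
    fast_rt_cut: float = 0.250,
    max_fast_fraction: float = 0.10,
) -> ExclusionReport:
    """Screen participants who were likely guessing or fast-responding.

    A participant is excluded iff overall accuracy < ``min_accuracy`` or the
    fraction of trials with rt < ``fast_rt_cut`` exceeds
    ``max_fast_fraction``; both reasons are recorded when both apply.
    """
    kept: dict[str, list[TrialRecord]] = {}
    excluded: dict[str, list[str]] = {}
    for pid, trials in cohort.items():
        if not trials:
            raise ValueError(f"participant {pid} has no trials")
        acc = float(np.mean([t.correct for t in trials]))
        fast = float(np.mean([t.rt < fast_rt_cut for t in trials]))
        reasons = []
        if acc < min_accuracy:
            reasons.append("accuracy")
        if fast > max_fast_fraction:
            reasons.append("fast responses")
        if reasons:
            excluded[pid] = reasons
        else:
            kept[pid] = trials
    return ExclusionReport(kept=kept, excluded=excluded)
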