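"""Courtship ethogram I/O and courtship-index computation.

An ethogram records, for one male fly, the time intervals ("bouts") during
which the male courted a target female within a fixed observation window
(300 s in the conditioned courtship suppression paradigm).  The courtship
index (CI) of a male is the percentage of the window covered by courtship:

    CI = 100 * (union length of bouts, clipped to the window) / window

Bouts are normalized before any CI is computed: sorted, clipped to
``[0, window]``, and overlapping or touching intervals merged into their
union.  Merging (rather than summing raw durations) guarantees CI <= 100
even for sloppy or redundant scoring.

Input format: a UTF-8 CSV with header

    male_id,strain,condition,timepoint,timepoint_unit,window_s,bout_start_s,bout_end_s

one row per bout; a male observed with zero courtship appears as a single
row with both bout columns empty (CI = 0 is an observation, distinct from
the male being absent from the file).
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field

logger = logging.getLogger(__name__)

CONDITIONS = ("naive", "trained")
TIME_UNITS = ("minutes", "days")
DEFAULT_WINDOW_S = 300.0

#: comparison tolerance for interval arithmetic (seconds)
TIME_TOL = 1e-9

ETHOGRAM_COLUMNS = [
    "male_id",
    "strain",
    "condition",
    "timepoint",
    "timepoint_unit",
    "window_s",
    "bout_start_s",
    "bout_end_s",
]


class EthogramError(ValueError):
    """Raised for invalid bouts, malformed files, or violated grouping rules."""


@dataclass(frozen=True)
class Bout:
    """A single courtship interval, in seconds from the start of observation."""

    start: float
    end: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.start) and math.isfinite(self.end)):
            raise EthogramError(f"non-finite bout times ({self.start}, {self.end})")
        if self.start < 0:
            raise EthogramError(f"negative bout start {self.start}")
        if self.end <= self.start:
            raise EthogramError(
                f"bout end {self.end} not after start {self.start}"
            )

    @property
    def duration(self) -> float:
        return self.end - self.start


def normalize_bouts(
    bouts: list[Bout], window: float = DEFAULT_WINDOW_S, *, label: str = ""
) -> list[Bout]:
    """Sort, clip to ``[0, window]`` and merge overlapping bouts.

    The returned list covers the interval union of the input, so total bout
    time is invariant under input ordering and under splitting a bout into
    contiguous pieces.  Bouts extending past the window are clipped with a
    warning; bouts entirely outside are dropped.
    """
    if window <= 0:
        raise EthogramError(f"window must be positive, got {window}")
    clipped: list[tuple[float, float]] = []
    n_clipped = 0
    for b in bouts:
        if not isinstance(b, Bout):
            b = Bout(*b)
        start, end = b.start, b.end
        if start >= window:
            n_clipped += 1
            continue
        if end > window:
            end = window
            n_clipped += 1
        clipped.append((start, end))
    if n_clipped:
        who = f" for {label}" if label else ""
        logger.warning("clipped %d bout(s) to the %gs window%s", n_clipped, window, who)
    clipped.sort()
    merged: list[Bout] = []
    for start, end in clipped:
        if merged and start <= merged[-1].end + TIME_TOL:
            if end > merged[-1].end:
                merged[-1] = Bout(merged[-1].start, end)
        else:
            merged.append(Bout(start, end))
    return merged


@dataclass
class MaleObservation:
    """One male's normalized courtship record within an observation window."""

    male_id: str
    strain: str
    condition: str
    timepoint: str
    timepoint_unit: str = "minutes"
    window: float = DEFAULT_WINDOW_S
    bouts: list[Bout] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise EthogramError(
                f"unknown condition {self.condition!r} for male {self.male_id!r} "
                f"(expected one of {CONDITIONS})"
            )
        if self.timepoint_unit not in TIME_UNITS:
            raise EthogramError(
                f"unknown timepoint unit {self.timepoint_unit!r} for male "
                f"{self.male_id!r} (expected one of {TIME_UNITS})"
            )
        self.bouts = normalize_bouts(self.bouts, self.window, label=self.male_id)

    @property
    def total_courtship_s(self) -> float:
        return sum(b.duration for b in self.bouts)


def compute_ci(obs: MaleObservation) -> float:
    """Courtship index: percentage of the window spent courting, in [0, 100]."""
    if obs.window <= 0:
        raise EthogramError(f"window must be positive, got {obs.window}")
    return 100.0 * obs.total_courtship_s / obs.window


@dataclass
class GroupSample:
    """Per-male CIs for one strain x condition x timepoint cell.

    Houses the CI_na (condition="naive") and CI_tr (condition="trained")
    samples entering the learning index; one CI per independent male.
    """

    strain: str
    condition: str
    timepoint: str
    timepoint_unit: str
    male_ids: tuple[str, ...]
    cis: tuple[float, ...]

    def __post_init__(self) -> None:
        for ci in self.cis:
            if not (0.0 <= ci <= 100.0 + 1e-9):
                raise EthogramError(f"CI {ci} outside [0, 100] in group {self.key}")

    @property
    def key(self) -> tuple[str, str, str, str]:
        return (self.strain, self.condition, self.timepoint, self.timepoint_unit)

    @property
    def n(self) -> int:
        return len(self.cis)


def _parse_time(value: str, column: str, line_no: int) -> float:
    try:
        t = float(value)
    except ValueError:
        raise EthogramError(f"line {line_no}: cannot parse {column}={value!r}") from None
    if not math.isfinite(t):
        raise EthogramError(f"line {line_no}: non-finite {column}={value!r}")
    if t < 0:
        raise EthogramError(f"line {line_no}: negative {column}={value!r}")
    return t


def read_ethograms(path) -> list[MaleObservation]:
    """Read an ethogram CSV into normalized :class:`MaleObservation` records.

    Rows are grouped by ``male_id``; per-male metadata (strain, condition,
    timepoint, window) must be consistent across that male's rows.  Raises
    :class:`EthogramError` with the offending line number on any violation.
    """
    males: dict[str, dict] = {}
    n_rows = 0
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or [
            c for c in ETHOGRAM_COLUMNS if c not in reader.fieldnames
        ]:
            raise EthogramError(
                f"{path}: missing or malformed header; expected columns "
                f"{','.join(ETHOGRAM_COLUMNS)}"
            )
        for line_no, row in enumerate(reader, start=2):
            n_rows += 1
            male_id = (row["male_id"] or "").strip()
            if not male_id:
                raise EthogramError(f"line {line_no}: empty male_id")
            meta = (
                row["strain"].strip(),
                row["condition"].strip(),
                row["timepoint"].strip(),
                row["timepoint_unit"].strip(),
                row["window_s"].strip(),
            )
            entry = males.setdefault(male_id, {"meta": meta, "line": line_no, "bouts": []})
            if entry["meta"] != meta:
                raise EthogramError(
                    f"line {line_no}: male {male_id!r} metadata conflicts with "
                    f"line {entry['line']}"
                )
            raw_start = (row["bout_start_s"] or "").strip()
            raw_end = (row["bout_end_s"] or "").strip()
            if raw_start == "" and raw_end == "":
                continue  # observed male, no courtship this row
            if raw_start == "" or raw_end == "":
                raise EthogramError(
                    f"line {line_no}: bout_start_s/bout_end_s must be both set or both empty"
                )
            start = _parse_time(raw_start, "bout_start_s", line_no)
            end = _parse_time(raw_end, "bout_end_s", line_no)
            if end <= start:
                raise EthogramError(
                    f"line {line_no}: male {male_id!r} bout end {end} <= start {start}"
                )
            entry["bouts"].append(Bout(start, end))

    observations = []
    for male_id, entry in males.items():
        strain, condition, timepoint, unit, window_s = entry["meta"]
        try:
            window = float(window_s)
        except ValueError:
            raise EthogramError(
                f"line {entry['line']}: cannot parse window_s={window_s!r}"
            ) from None
        observations.append(
            MaleObservation(
                male_id=male_id,
                strain=strain,
                condition=condition,
                timepoint=timepoint,
                timepoint_unit=unit,
                window=window,
                bouts=entry["bouts"],
            )
        )
    logger.info("read %d bout rows -> %d observations from %s", n_rows, len(observations), path)
    return observations


def write_ethograms(observations: list[MaleObservation], path) -> None:
    """Write observations to the ethogram CSV dialect (millisecond resolution)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(ETHOGRAM_COLUMNS)
        for obs in observations:
            meta = [
                obs.male_id,
                obs.strain,
                obs.condition,
                obs.timepoint,
                obs.timepoint_unit,
                f"{obs.window:g}",
            ]
            if not obs.bouts:
                writer.writerow(meta + ["", ""])
            for b in obs.bouts:
                writer.writerow(meta + [f"{b.start:.3f}", f"{b.end:.3f}"])


def aggregate_groups(observations: list[MaleObservation]) -> list[GroupSample]:
    """Collect per-male CIs into (strain, condition, timepoint) groups.

    Each male contributes exactly one CI; a duplicated male_id within a group
    violates the independence assumption of the randomization tests and is an
    error.  Groups are returned in order of first appearance.
    """
    groups: dict[tuple, dict] = {}
    for obs in observations:
        key = (obs.strain, obs.condition, obs.timepoint, obs.timepoint_unit)
        entry = groups.setdefault(key, {"ids": [], "cis": []})
        if obs.male_id in entry["ids"]:
            raise EthogramError(
                f"duplicate male_id {obs.male_id!r} in group {key} "
                "(males must be independent)"
            )
        entry["ids"].append(obs.male_id)
        entry["cis"].append(compute_ci(obs))
    return [
        GroupSample(
            strain=key[0],
            condition=key[1],
            timepoint=key[2],
            timepoint_unit=key[3],
            male_ids=tuple(entry["ids"]),
            cis=tuple(entry["cis"]),
        )
        for key, entry in groups.items()
    ]
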