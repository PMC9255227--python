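"""Readers and writers for every on-disk artifact.

All formats are plain delimited text (comma by default, tab auto-detected;
decimal points only), with times in milliseconds everywhere. Floats are
written with 17 significant digits so every reader/writer pair round-trips
exactly.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import CoverageError, InvalidCurveError, OjipError, SampleSheetError
from .mr820 import MR820Curve
from .transient import DEFAULT_CARDINAL_TIMES, FluorescenceTransient

logger = logging.getLogger("ojipkit")

FLOAT_FORMAT = "%.17g"
MIN_CURVE_ROWS = 20

TIDY_COLUMNS = ["sample_id", "group", "replicate", "parameter", "value"]
SHEET_REQUIRED = ["sample_id", "group", "replicate", "curve_path"]
SHEET_OPTIONAL = ["mr820_path"]


def setup_logging(log_file=None, level=logging.INFO) -> logging.Logger:
    """Route pipeline logs to stderr and, optionally, a run log file."""
    lg = logging.getLogger("ojipkit")
    lg.setLevel(level)
    if not any(isinstance(h, logging.StreamHandler) and h.stream is sys.stderr
               for h in lg.handlers):
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
        lg.addHandler(handler)
    if log_file is not None:
        for handler in [h for h in lg.handlers if isinstance(h, logging.FileHandler)]:
            handler.close()
            lg.removeHandler(handler)
        fh = logging.FileHandler(log_file, mode="w")
        # no wall-clock stamps: seeded reruns must reproduce the log exactly
        fh.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
        lg.addHandler(fh)
    return lg


# ---------------------------------------------------------------------------
# two-column curve files

def _sniff_delimiter(path: Path, dialect: str | None) -> str:
    if dialect:
        return dialect
    with open(path) as fh:
        first = fh.readline()
    return "\t" if "\t" in first else ","


def _read_two_column(path, dialect: str | None, what: str) -> tuple[np.ndarray, np.ndarray]:
    path = Path(path)
    sep = _sniff_delimiter(path, dialect)
    frame = pd.read_csv(path, sep=sep, header=None, comment="#",
                        skip_blank_lines=True)
    # tolerate a single header line
    try:
        float(frame.iloc[0, 0])
    except (TypeError, ValueError):
        frame = frame.iloc[1:].reset_index(drop=True)
    if frame.shape[1] < 2:
        raise InvalidCurveError(f"{path}: expected >= 2 numeric columns")
    try:
        t = frame.iloc[:, 0].astype(float).to_numpy()
        y = frame.iloc[:, 1].astype(float).to_numpy()
    except (TypeError, ValueError) as exc:
        raise InvalidCurveError(f"{path}: non-numeric {what} data: {exc}") from exc
    if t.size < MIN_CURVE_ROWS:
        raise InvalidCurveError(
            f"{path}: only {t.size} rows; need >= {MIN_CURVE_ROWS}")
    bad = np.nonzero(np.diff(t) <= 0)[0]
    if bad.size:
        raise InvalidCurveError(
            f"{path}: time not strictly increasing at row {int(bad[0]) + 1}")
    if not np.all(np.isfinite(y)) or np.any(y <= 0):
        raise InvalidCurveError(f"{path}: {what} must be finite and positive")
    return t, y


def read_transient(path, dialect: str | None = None) -> FluorescenceTransient:
    """Read one transient (time_ms, signal) and validate its coverage.

    The sampled range must span the O and P times (0.01 and 1000 ms by
    default); metadata is seeded from the filename stem and refined by the
    sample sheet during pipeline runs.
    """
    path = Path(path)
    t, y = _read_two_column(path, dialect, "signal")
    for name in ("O", "P"):
        t_c = DEFAULT_CARDINAL_TIMES[name]
        if not t[0] <= t_c <= t[-1]:
            raise CoverageError(
                f"{path}: time range does not cover {name} time ({t_c:g} ms)")
    return FluorescenceTransient(t, y, sample_id=path.stem)


def write_transient(transient: FluorescenceTransient, path) -> Path:
    path = Path(path)
    _write_two_column(path, "time_ms,signal", transient.time_ms, transient.signal)
    return path


def read_mr820(path, dialect: str | None = None) -> MR820Curve:
    path = Path(path)
    t, y = _read_two_column(path, dialect, "reflection")
    return MR820Curve(t, y, sample_id=path.stem)


def write_mr820(curve: MR820Curve, path) -> Path:
    path = Path(path)
    _write_two_column(path, "time_ms,reflection", curve.time_ms, curve.reflection)
    return path


def _write_two_column(path: Path, header: str, t: np.ndarray, y: np.ndarray) -> None:
    with open(path, "w") as fh:
        fh.write(header + "\n")
        for ti, yi in zip(t, y):
            fh.write(f"{ti:.17g},{yi:.17g}\n")


# ---------------------------------------------------------------------------
# sample sheet

@dataclass
class SampleSheet:
    """Validated mapping of samples to groups, replicates and curve files."""

    frame: pd.DataFrame
    base_dir: Path = field(default_factory=Path)
    no_statistics_groups: tuple[str, ...] = ()

    @property
    def groups(self) -> list[str]:
        return list(dict.fromkeys(self.frame["group"]))

    def __len__(self) -> int:
        return len(self.frame)

    def rows(self):
        for row in self.frame.itertuples(index=False):
            yield row

    def curve_path(self, row) -> Path:
        return self.base_dir / str(row.curve_path)

    def mr820_path(self, row) -> Path | None:
        value = getattr(row, "mr820_path", None)
        if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
            return None
        return self.base_dir / str(value)


def read_sample_sheet(path) -> SampleSheet:
    """Load and validate a sample sheet.

    Relative curve paths resolve against the sheet's directory. Duplicate
    sample ids and missing files are rejected; groups with a single
    replicate load but are flagged for exclusion from statistics.
    """
    path = Path(path)
    sep = _sniff_delimiter(path, None)
    frame = pd.read_csv(path, sep=sep, dtype={"sample_id": str, "group": str})
    missing = [c for c in SHEET_REQUIRED if c not in frame.columns]
    if missing:
        raise SampleSheetError(f"{path}: missing required column(s) {missing}")
    unknown = [c for c in frame.columns if c not in SHEET_REQUIRED + SHEET_OPTIONAL]
    if unknown:
        logger.warning("%s: ignoring unknown column(s) %s", path, unknown)
        frame = frame.drop(columns=unknown)
    dup = frame["sample_id"][frame["sample_id"].duplicated()]
    if not dup.empty:
        raise SampleSheetError(f"{path}: duplicated sample_id {dup.iloc[0]!r}")
    if (frame["replicate"].astype(int) < 1).any():
        raise SampleSheetError(f"{path}: replicate numbers must be positive")
    frame["replicate"] = frame["replicate"].astype(int)

    base = path.parent
    for row in frame.itertuples(index=False):
        curve = base / str(row.curve_path)
        if not curve.exists():
            raise SampleSheetError(f"{path}: curve file not found: {curve}")
        mr = getattr(row, "mr820_path", None)
        if isinstance(mr, str) and mr and not (base / mr).exists():
            raise SampleSheetError(f"{path}: MR820 file not found: {base / mr}")

    sizes = frame.groupby("group")["sample_id"].count()
    small = tuple(sizes.index[sizes < 2])
    if small:
        logger.warning("%s: group(s) %s have < 2 replicates: no statistics",
                       path, list(small))
    return SampleSheet(frame=frame, base_dir=base, no_statistics_groups=small)


def write_sample_sheet(rows: Sequence[Mapping], path) -> Path:
    path = Path(path)
    frame = pd.DataFrame(list(rows))
    cols = [c for c in SHEET_REQUIRED + SHEET_OPTIONAL if c in frame.columns]
    frame[cols].to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# tidy tables and generic records

def write_tidy_table(table: pd.DataFrame, path) -> Path:
    """Write a long-format parameter table with a stable column order."""
    if table is None or len(table) == 0:
        raise OjipError("nothing to write: tidy table is empty")
    missing = [c for c in TIDY_COLUMNS if c not in table.columns]
    if missing:
        raise OjipError(f"tidy table missing column(s) {missing}")
    path = Path(path)
    table[TIDY_COLUMNS].to_csv(path, index=False, float_format=FLOAT_FORMAT)
    return path


def read_tidy_table(path) -> pd.DataFrame:
    path = Path(path)
    frame = pd.read_csv(path, dtype={"sample_id": str, "group": str,
                                     "parameter": str})
    missing = [c for c in TIDY_COLUMNS if c not in frame.columns]
    if missing:
        raise OjipError(f"{path}: not a tidy table, missing {missing}")
    frame["replicate"] = frame["replicate"].astype(int)
    frame["value"] = frame["value"].astype(float)
    return frame


def write_records(rows: Sequence[Mapping], path) -> Path:
    """Write generic record rows (pigments, gas exchange, ground truth)."""
    if not rows:
        raise OjipError("nothing to write: no records")
    path = Path(path)
    pd.DataFrame(list(rows)).to_csv(path, index=False, float_format=FLOAT_FORMAT)
    return path


def read_records(path, required: Iterable[str] = ()) -> pd.DataFrame:
    path = Path(path)
    frame = pd.read_csv(path)
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise OjipError(f"{path}: missing required column(s) {missing}")
    return frame


# ---------------------------------------------------------------------------
# run configuration

@dataclass
class RunConfig:
    """Flat run configuration; an empty config file is fully valid."""

    cardinal_times_ms: dict = field(
        default_factory=lambda: dict(DEFAULT_CARDINAL_TIMES))
    fm_rule: str = "at_P_time"
    interpolation: str = "linear_log_time"
    alpha: float = 0.05
    seed: int = 0
    output_dir: str = "."
    control: str = "CK"
    points_per_decade: int = 100
    median_filter: bool = False

    def __post_init__(self) -> None:
        order = [self.cardinal_times_ms[c] for c in ("O", "L", "K", "J", "I", "P")]
        if not all(a < b for a, b in zip(order, order[1:])):
            raise OjipError("cardinal times must be strictly increasing O<L<K<J<I<P")
        if not 0.0 < self.alpha < 1.0:
            raise OjipError("alpha must lie in (0, 1)")
        if self.fm_rule not in ("at_P_time", "curve_max"):
            raise OjipError(f"unknown fm_rule {self.fm_rule!r}")
        if self.interpolation != "linear_log_time":
            raise OjipError("only linear_log_time interpolation is supported")

    def to_mapping(self) -> dict:
        out = {f"time_{c}": float(t) for c, t in self.cardinal_times_ms.items()}
        for f in fields(self):
            if f.name != "cardinal_times_ms":
                out[f.name] = getattr(self, f.name)
        return out


def load_config(path=None) -> RunConfig:
    """Read a flat YAML mapping; unknown keys are rejected by name."""
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise OjipError(f"{path}: config must be a flat key: value mapping")
    times = dict(DEFAULT_CARDINAL_TIMES)
    kwargs: dict = {}
    valid = {f.name for f in fields(RunConfig)} - {"cardinal_times_ms"}
    for key, value in raw.items():
        if key.startswith("time_") and key[5:] in times:
            times[key[5:]] = float(value)
        elif key in valid:
            kwargs[key] = value
        else:
            raise OjipError(f"{path}: unknown config key {key!r}")
    return RunConfig(cardinal_times_ms=times, **kwargs)


def save_config(config: RunConfig, path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(config.to_mapping(), sort_keys=True))
    return path
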