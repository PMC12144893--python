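"""PLUMED-dialect plain-text I/O: HILLS and COLVAR files.

Both formats are whitespace-separated numeric tables preceded by a comment
header declaring the column names::

    #! FIELDS time s sigma_s height biasf

Columns are mapped by name, never by position.  Numbers are printed with
``repr`` (shortest exact decimal), so a write→read→write round trip is
bit-exact.  Unknown columns are preserved verbatim.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np


class FormatError(ValueError):
    """Malformed HILLS/COLVAR file; message carries line (and column) info."""


@dataclass
class HillsLog:
    """Deposited metadynamics Gaussians, time-ordered per walker."""

    time: np.ndarray
    center: np.ndarray
    sigma: np.ndarray
    height: np.ndarray
    biasf: np.ndarray
    walker_id: np.ndarray | None = None
    cv_name: str = "s"
    extras: dict = field(default_factory=dict)  # name -> list of verbatim strings

    def __post_init__(self):
        for name in ("time", "center", "sigma", "height", "biasf"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.walker_id is not None:
            self.walker_id = np.asarray(self.walker_id, dtype=int)
        if self.n and np.any(self.height <= 0):
            raise FormatError("hill heights must be positive")

    @property
    def n(self) -> int:
        return self.time.shape[0]

    def validate(self) -> None:
        """Well-tempered sanity: positive heights, per-walker non-decreasing times."""
        walkers = self.walker_id if self.walker_id is not None else np.zeros(self.n, dtype=int)
        for w in np.unique(walkers):
            t = self.time[walkers == w]
            if np.any(np.diff(t) < 0):
                raise FormatError(f"hill times decrease for walker {w}")


def _parse_header(line: str, lineno: int) -> list[str]:
    toks = line.split()
    if len(toks) < 3 or toks[0] != "#!" or toks[1] != "FIELDS":
        raise FormatError(f"line {lineno}: expected '#! FIELDS <names...>' header")
    return toks[2:]


def _read_table(path):
    names = None
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                if names is None:
                    names = _parse_header(line, lineno)
                continue
            if names is None:
                raise FormatError(f"line {lineno}: data before '#! FIELDS' header")
            toks = line.split()
            if len(toks) != len(names):
                raise FormatError(
                    f"line {lineno}: expected {len(names)} columns, got {len(toks)}"
                )
            rows.append((lineno, toks))
    if names is None:
        raise FormatError("missing '#! FIELDS' header")
    return names, rows


def _numeric_column(names, rows, col: str) -> np.ndarray:
    j = names.index(col)
    out = np.empty(len(rows))
    for i, (lineno, toks) in enumerate(rows):
        try:
            out[i] = float(toks[j])
        except ValueError:
            raise FormatError(
                f"line {lineno}, column {j + 1} ({col}): non-numeric value {toks[j]!r}"
            ) from None
    return out


def read_hills(path) -> HillsLog:
    """Parse a HILLS file; fields mapped by name (reordering is harmless)."""
    names, rows = _read_table(path)
    sigma_cols = [n for n in names if n.startswith("sigma_")]
    if "time" not in names or not sigma_cols:
        raise FormatError(f"HILLS header must contain 'time' and a 'sigma_<cv>' field: {names}")
    cv = sigma_cols[0][len("sigma_"):]
    if cv not in names:
        raise FormatError(f"HILLS header declares sigma_{cv} but no {cv} column")
    known = {"time", cv, f"sigma_{cv}", "height", "biasf", "walker"}
    if "height" not in names:
        raise FormatError("HILLS header must contain 'height'")
    biasf = (
        _numeric_column(names, rows, "biasf")
        if "biasf" in names
        else np.full(len(rows), np.inf)
    )
    walker = None
    if "walker" in names:
        walker = _numeric_column(names, rows, "walker").astype(int)
    extras = {}
    for name in names:
        if name not in known:
            j = names.index(name)
            extras[name] = [toks[j] for _, toks in rows]
    return HillsLog(
        time=_numeric_column(names, rows, "time"),
        center=_numeric_column(names, rows, cv),
        sigma=_numeric_column(names, rows, f"sigma_{cv}"),
        height=_numeric_column(names, rows, "height"),
        biasf=biasf,
        walker_id=walker,
        cv_name=cv,
        extras=extras,
    )


def write_hills(log: HillsLog, path) -> None:
    cv = log.cv_name
    names = ["time", cv, f"sigma_{cv}", "height", "biasf"]
    if log.walker_id is not None:
        names.append("walker")
    names += list(log.extras)
    with open(path, "w") as fh:
        fh.write("#! FIELDS " + " ".join(names) + "\n")
        for i in range(log.n):
            toks = [
                repr(float(log.time[i])),
                repr(float(log.center[i])),
                repr(float(log.sigma[i])),
                repr(float(log.height[i])),
                repr(float(log.biasf[i])),
            ]
            if log.walker_id is not None:
                toks.append(str(int(log.walker_id[i])))
            for name in log.extras:
                toks.append(log.extras[name][i])
            fh.write(" ".join(toks) + "\n")


def read_colvar(path):
    """Parse a COLVAR file into a CV-only Trajectory.

    Expected fields: time, one or more CV columns, optionally a bias column
    (any name containing 'bias').  Non-monotone times trigger a warning;
    frames are kept in file order.
    """
    from .dynamics import Trajectory  # local import to avoid a cycle

    names, rows = _read_table(path)
    if "time" not in names:
        raise FormatError(f"COLVAR header must contain 'time': {names}")
    time = _numeric_column(names, rows, "time")
    bias_cols = [n for n in names if "bias" in n.lower()]
    cv_cols = [n for n in names if n != "time" and n not in bias_cols]
    if not cv_cols:
        raise FormatError("COLVAR file declares no CV column")
    if np.any(np.diff(time) <= 0):
        warnings.warn(f"{path}: non-monotone time column; keeping frames in file order")
    cv = _numeric_column(names, rows, cv_cols[0])
    bias = _numeric_column(names, rows, bias_cols[0]) if bias_cols else None
    return Trajectory(
        times=time,
        positions=cv[:, None],
        cv_values=cv,
        surface_label=[""] * len(cv),
        bias_at_frame=bias,
    )


def write_colvar(traj, path, cv_name: str = "s") -> None:
    names = ["time", cv_name]
    has_bias = traj.bias_at_frame is not None
    if has_bias:
        names.append("metad_bias")
    with open(path, "w") as fh:
        fh.write("#! FIELDS " + " ".join(names) + "\n")
        for i in range(traj.n_frames):
            toks = [repr(float(traj.times[i])), repr(float(traj.cv_values[i]))]
            if has_bias:
                toks.append(repr(float(traj.bias_at_frame[i])))
            fh.write(" ".join(toks) + "\n")
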