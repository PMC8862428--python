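"""CSV input/output with provenance headers.

All tables are plain comma-separated UTF-8 with a header row and dot
decimals.  Every file written by the package starts with '#'-prefixed
comment lines recording the package version, a hash of the run
configuration, and the seed, so a dataset or report can always be traced to
the exact run that produced it.  Rates are min^-1 per transporter homodimer
(135 kDa); this convention is stamped into the header of every rate table.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ParseError
from .simulate import RateObservation, TimeCourse

RATE_COLUMNS = ["condition", "atp_mM", "gssg_mM", "replicate", "rate_per_min"]
TIMECOURSE_COLUMNS = ["condition", "atp_mM", "gssg_mM", "replicate", "time_min", "pi_uM"]

_UNITS_NOTE = "rates are min^-1 per transporter homodimer (135 kDa)"


def _version() -> str:
    from . import __version__

    return __version__


def config_hash(config: Mapping) -> str:
    """Short stable hash of a flat configuration mapping."""
    canon = json.dumps({str(k): str(v) for k, v in sorted(config.items())})
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def provenance_lines(config: Mapping, seed: int | None) -> list[str]:
    lines = [
        f"# actikin v{_version()}",
        f"# config_hash: {config_hash(config)}",
        f"# seed: {seed if seed is not None else 'none'}",
        f"# {_UNITS_NOTE}",
    ]
    for key, value in sorted(config.items()):
        lines.append(f"# cfg {key} = {value}")
    return lines


def write_table(
    df: pd.DataFrame, path: Path | str, config: Mapping, seed: int | None
) -> Path:
    """Write a DataFrame as CSV beneath a provenance comment header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header = "\n".join(provenance_lines(config, seed))
    body = df.to_csv(index=False, lineterminator="\n")
    path.write_text(header + "\n" + body, encoding="utf-8")
    return path


def rates_frame(observations: Iterable[RateObservation]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "condition": [o.condition_name for o in observations],
            "atp_mM": [o.atp for o in observations],
            "gssg_mM": [o.gssg for o in observations],
            "replicate": [o.replicate for o in observations],
            "rate_per_min": [o.rate for o in observations],
        }
    )


def timecourses_frame(courses: Iterable[TimeCourse]) -> pd.DataFrame:
    rows = []
    for tc in courses:
        for t, pi in zip(tc.times, tc.pi_conc):
            rows.append(
                {
                    "condition": tc.condition_name,
                    "atp_mM": tc.atp,
                    "gssg_mM": tc.gssg,
                    "replicate": tc.replicate,
                    "time_min": t,
                    "pi_uM": pi,
                }
            )
    return pd.DataFrame(rows, columns=TIMECOURSE_COLUMNS)


def read_rates(path: Path | str) -> pd.DataFrame:
    """Read a rate-observation CSV, skipping provenance comments.

    Raises ParseError with the offending detail on malformed input.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#")
    except FileNotFoundError:
        raise
    except Exception as exc:  # pandas raises several parse error types
        raise ParseError(f"could not parse {path}: {exc}") from exc
    if df.empty:
        raise ParseError(f"{path} contains no data rows")
    missing = set(RATE_COLUMNS[1:]) - set(df.columns)
    if missing:
        raise ParseError(f"{path} lacks required columns {sorted(missing)}")
    bad = df[~df[["atp_mM", "gssg_mM", "rate_per_min"]].map(
        lambda v: isinstance(v, (int, float))
    ).all(axis=1)]
    if len(bad):
        raise ParseError(
            f"{path}: non-numeric values in rows {bad.index.tolist()[:5]}"
        )
    return df


def read_timecourses(path: Path | str) -> list[TimeCourse]:
    """Read a time-course CSV back into TimeCourse objects."""
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#")
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise ParseError(f"could not parse {path}: {exc}") from exc
    missing = set(TIMECOURSE_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path} lacks required columns {sorted(missing)}")
    courses = []
    keys = ["condition", "atp_mM", "gssg_mM", "replicate"]
    for (condition, atp, gssg, rep), g in df.groupby(keys, sort=True):
        g = g.sort_values("time_min")
        courses.append(
            TimeCourse(
                condition_name=str(condition),
                atp=float(atp),
                gssg=float(gssg),
                replicate=int(rep),
                times=tuple(g["time_min"].astype(float)),
                pi_conc=tuple(g["pi_uM"].astype(float)),
            )
        )
    return courses


def read_config(path: Path | str) -> dict[str, str]:
    """Read a flat key=value config file ('#' comments, blank lines ignored)."""
    path = Path(path)
    out: dict[str, str] = {}
    for lineno, raw in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#") or line.startswith("["):
            continue
        if "=" not in line:
            raise ParseError(f"{path}:{lineno}: expected key = value, got {raw!r}")
        key, _, value = line.partition("=")
        out[key.strip().replace("-", "_")] = value.strip()
    return out
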