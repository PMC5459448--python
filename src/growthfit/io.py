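"""CSV/JSON readers and writers.

Data files are plain two-column CSV (header with ``time`` and ``value``
columns in any order, ``#`` comment lines skipped); results serialize to
JSON (full structure) or CSV (one row per parameter).  Numbers are written
with 12 significant digits so conversions survive a round trip through
files.
"""

from __future__ import annotations

import csv
import json
import logging
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .errors import MalformedFileError
from .fitting import FitResult
from .forms import PARAM_NAMES, GrowthForm, ParamVector, TimeSeries
from .reparam import CurveSummary

logger = logging.getLogger("growthfit")

__all__ = ["read_series", "write_series", "write_result", "read_result"]


def _sig12(x: Any) -> Any:
    """Round floats to 12 significant digits for stable serialization."""
    if isinstance(x, float):
        if not np.isfinite(x):
            return x
        return float(f"{x:.12g}")
    if isinstance(x, dict):
        return {k: _sig12(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_sig12(v) for v in x]
    return x


def read_series(path: str | Path) -> TimeSeries:
    """Read a two-column time/value CSV into a validated TimeSeries.

    Extra columns are ignored, rows with missing entries dropped (logged),
    and out-of-order rows sorted by time (logged).  Tied times raise.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, comment="#", skip_blank_lines=True)
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise MalformedFileError(f"{path}: cannot parse CSV ({exc})") from exc
    cols = {c.strip().lower(): c for c in frame.columns}
    if "time" not in cols or "value" not in cols:
        raise MalformedFileError(
            f"{path}: header must contain 'time' and 'value' columns; "
            f"found {list(frame.columns)}"
        )
    sub = frame[[cols["time"], cols["value"]]].apply(pd.to_numeric, errors="coerce")
    n_bad = int(sub.isna().any(axis=1).sum())
    if n_bad:
        bad_lines = [int(i) + 2 for i in sub.index[sub.isna().any(axis=1)][:5]]
        logger.warning(
            "%s: dropped %d row(s) with missing/non-numeric entries (near lines %s)",
            path, n_bad, bad_lines,
        )
        sub = sub.dropna()
    if len(sub) < 2:
        raise MalformedFileError(f"{path}: fewer than 2 usable rows")
    t = sub[cols["time"]].to_numpy(dtype=float)
    w = sub[cols["value"]].to_numpy(dtype=float)
    if np.any(np.diff(t) < 0):
        logger.info("%s: rows were not time-ordered; sorting by time", path)
        order = np.argsort(t, kind="stable")
        t, w = t[order], w[order]
    return TimeSeries(times=t, values=w)


def write_series(series: TimeSeries, path: str | Path) -> None:
    """Write a TimeSeries as a `time,value` CSV."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["time", "value"])
        for t, w in series:
            writer.writerow([f"{t:.12g}", f"{w:.12g}"])


def _summary_dict(s: CurveSummary) -> dict:
    return {
        "A": s.A, "W_0": s.W_0, "T_i": s.T_i, "W_i": s.W_i,
        "k_G": s.k_G, "k_U": s.k_U, "K_U": s.K_U, "d": s.d, "B": s.B,
    }


def result_to_dict(r: "FitResult | CurveSummary | ParamVector | dict") -> dict:
    """JSON-ready dict for any writable result object."""
    if isinstance(r, dict):
        return _sig12(r)
    if isinstance(r, ParamVector):
        return _sig12({"kind": "params", "form": r.form.value, "params": dict(r.params)})
    if isinstance(r, CurveSummary):
        return _sig12({"kind": "summary", **_summary_dict(r)})
    if isinstance(r, FitResult):
        return _sig12(
            {
                "kind": "fit",
                "form": r.params.form.value,
                "params": dict(r.params.params),
                "summary": _summary_dict(r.summary) if r.summary else None,
                "rss": r.rss,
                "sigma2": r.sigma2,
                "converged": r.converged,
                "singular": r.singular,
                "n_iter": r.n_iter,
                "n_obs": r.n_obs,
                "ci_level": r.ci_level,
                "se": r.se,
                "ci": {k: list(v) for k, v in r.ci.items()},
                "covariance": r.covariance.tolist(),
                "message": r.message,
            }
        )
    raise TypeError(f"cannot serialize {type(r).__name__}")


def write_result(r, path: str | Path | None, fmt: str = "json") -> str:
    """Serialize a FitResult, CurveSummary, ParamVector or report dict.

    ``fmt='json'`` writes the full structure; ``fmt='csv'`` writes one row
    per parameter (estimate, SE, CI bounds — FitResult only).  Returns the
    serialized text; ``path=None`` writes nowhere (caller prints it).
    """
    if fmt == "json":
        text = json.dumps(result_to_dict(r), indent=2)
    elif fmt == "csv":
        if not isinstance(r, FitResult):
            raise ValueError("csv output is defined for fit results only")
        lines = ["parameter,estimate,se,ci_lower,ci_upper"]
        se = r.se
        for name in PARAM_NAMES[r.params.form]:
            lo, hi = r.ci.get(name, (float("nan"), float("nan")))
            lines.append(
                f"{name},{r.params[name]:.12g},{se[name]:.12g},{lo:.12g},{hi:.12g}"
            )
        text = "\n".join(lines) + "\n"
    else:
        raise ValueError(f"unsupported output format {fmt!r} (use 'json' or 'csv')")
    if path is not None:
        Path(path).write_text(text if text.endswith("\n") else text + "\n")
    return text


def read_result(path: str | Path) -> dict:
    """Read back a JSON result written by :func:`write_result`."""
    with Path(path).open() as fh:
        return json.load(fh)
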