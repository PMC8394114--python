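"""CSV readers/writers, flat parameter configs, and fixture generation.

Series travel as plain CSV: one column per signal, an optional single
header line, decimal points, no thousands separators.  Values round-trip
losslessly at double precision (written with ``repr`` precision).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .simulators import SimConfig, simulate

__all__ = [
    "read_series_csv",
    "write_series_csv",
    "params_to_config",
    "params_from_config",
    "FIXTURES",
    "make_fixture",
]


def read_series_csv(path) -> pd.DataFrame:
    """Read one or two series from a CSV file.

    The file must hold one or two numeric columns with an optional single
    header line.  Returns a DataFrame (column names preserved when a header
    is present, else ``x`` / ``y``).  Non-numeric or missing cells raise a
    ``ValueError`` naming the offending row and column.
    """
    path = Path(path)
    text = path.read_text().strip()
    if not text:
        raise ValueError(f"{path}: empty file")
    first = text.splitlines()[0]
    has_header = False
    for token in first.split(","):
        try:
            float(token)
        except ValueError:
            has_header = True
            break
    df = pd.read_csv(path, header=0 if has_header else None,
                     skip_blank_lines=True, float_precision="round_trip")
    if not has_header:
        df.columns = ["x", "y"][: df.shape[1]] if df.shape[1] <= 2 else df.columns
    if df.shape[1] not in (1, 2):
        raise ValueError(f"{path}: expected 1 or 2 columns, found {df.shape[1]}")
    for col in df.columns:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.index[numeric.isna()]
        if len(bad) > 0:
            row = int(bad[0]) + (2 if has_header else 1)  # 1-based file line
            raise ValueError(
                f"{path}: non-numeric or missing value in column {col!r}, line {row}"
            )
        df[col] = numeric.astype(float)
    if df.shape[0] == 0:
        raise ValueError(f"{path}: no data rows")
    return df


def write_series_csv(path, *series, names: Optional[Sequence[str]] = None) -> None:
    """Write one or two series to CSV with full double precision."""
    if not 1 <= len(series) <= 2:
        raise ValueError("write_series_csv takes one or two series")
    names = list(names) if names is not None else ["x", "y"][: len(series)]
    df = pd.DataFrame({nm: np.asarray(s, dtype=float) for nm, s in zip(names, series)})
    df.to_csv(path, index=False, float_format=lambda v: repr(float(v)))


# ---------------------------------------------------------------------------
# flat key=value parameter configs
# ---------------------------------------------------------------------------

def params_to_config(params: Dict) -> str:
    """Serialize a flat parameter record to ``key=value`` lines."""
    lines = []
    for key, value in params.items():
        lines.append(f"{key}={value}")
    return "\n".join(lines) + ("\n" if lines else "")


def params_from_config(text: str) -> Dict:
    """Parse ``key=value`` lines back into a parameter record.

    Values are coerced to int when possible, else float, else kept as
    strings -- covering the estimator/embedding keys (estimator, k, Q,
    alpha, tau, m, n).
    """
    params: Dict = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"malformed config line: {line!r}")
        key, _, raw = line.partition("=")
        raw = raw.strip()
        value: object
        try:
            value = int(raw)
        except ValueError:
            try:
                value = float(raw)
            except ValueError:
                value = raw
        params[key.strip()] = value
    return params


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

#: Named fixture configurations; ``independent`` is the linear model with
#: the coupling switched off.
FIXTURES: Dict[str, SimConfig] = {
    "linear": SimConfig(model="linear", a=0.5),
    "nonlinear": SimConfig(model="nonlinear", b=0.4),
    "linnonlin": SimConfig(model="linnonlin", c=0.4, d=0.6),
    "independent": SimConfig(model="linear", a=0.0),
}


def make_fixture(name: str, seed: int, outdir=".") -> Tuple[Path, Path]:
    """Write a reproducible two-column trial CSV plus a JSON sidecar.

    The sidecar records the generating model and parameters.  Running the
    same (name, seed) twice produces byte-identical files.
    """
    if name not in FIXTURES:
        raise ValueError(f"unknown fixture {name!r}; expected one of {sorted(FIXTURES)}")
    cfg = FIXTURES[name]
    from dataclasses import replace, asdict

    cfg = replace(cfg, seed=int(seed))
    x, y = simulate(cfg)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    csv_path = outdir / f"{name}_{seed}.csv"
    json_path = outdir / f"{name}_{seed}.json"
    write_series_csv(csv_path, x, y)
    meta = {"name": name, **asdict(cfg)}
    json_path.write_text(json.dumps(meta, sort_keys=True, indent=2) + "\n")
    return csv_path, json_path
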