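"""Reading and writing landmark data.

Two plain-text formats are supported:

* the tpsDig dialect of the TPS format: per record a ``LM=k`` line, ``k``
  coordinate lines (``x y``, y axis up), then optional ``ID=``, ``IMAGE=``
  and ``SCALE=`` keys.  ``SCALE`` multiplies the coordinates on read.
* a long CSV with columns ``cell_id, replicate, landmark_index, x, y``.
"""

from __future__ import annotations

import re
from pathlib import Path

import pandas as pd

from .geometry import LandmarkConfiguration

__all__ = ["read_tps", "write_tps", "read_landmarks_csv", "write_landmarks_csv", "TPSParseError"]


class TPSParseError(ValueError):
    """Raised for a malformed TPS file, naming the offending record/line."""


_KEY_RE = re.compile(r"^\s*([A-Za-z]+)\s*=\s*(.*?)\s*$")


def read_tps(path) -> list[LandmarkConfiguration]:
    """Parse a TPS file into a list of :class:`LandmarkConfiguration`.

    Record order is preserved.  Replicate identity is recovered from IDs of
    the form ``<cell>_rep<j>`` when present.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    records: list[LandmarkConfiguration] = []
    i = 0
    n_record = 0
    while i < len(lines):
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        m = _KEY_RE.match(line)
        if not m or m.group(1).upper() != "LM":
            raise TPSParseError(f"{path.name}:{i + 1}: expected LM=, got {line!r}")
        n_record += 1
        try:
            k = int(m.group(2))
        except ValueError:
            raise TPSParseError(f"{path.name}:{i + 1}: non-integer landmark count") from None
        i += 1
        points = []
        for j in range(k):
            if i >= len(lines):
                raise TPSParseError(
                    f"{path.name}: record {n_record}: LM={k} but only {j} coordinate lines present"
                )
            parts = lines[i].split()
            if len(parts) != 2 or _KEY_RE.match(lines[i].strip()):
                raise TPSParseError(
                    f"{path.name}: record {n_record}: LM={k} but only {j} coordinate lines present"
                )
            try:
                points.append((float(parts[0]), float(parts[1])))
            except ValueError:
                raise TPSParseError(
                    f"{path.name}:{i + 1}: non-numeric coordinate {lines[i]!r}"
                ) from None
            i += 1
        cell_id = ""
        scale = None
        while i < len(lines):
            stripped = lines[i].strip()
            if not stripped:
                i += 1
                continue
            m = _KEY_RE.match(stripped)
            if not m or m.group(1).upper() == "LM":
                break
            key, value = m.group(1).upper(), m.group(2)
            if key == "ID":
                cell_id = value
            elif key == "SCALE":
                try:
                    scale = float(value)
                except ValueError:
                    raise TPSParseError(f"{path.name}:{i + 1}: non-numeric SCALE") from None
            # IMAGE and other keys are accepted and ignored
            i += 1
        pts = [(x * scale, y * scale) for x, y in points] if scale is not None else points
        replicate = 1
        rep_match = re.search(r"_rep(\d+)$", cell_id)
        if rep_match:
            replicate = int(rep_match.group(1))
            cell_id = cell_id[: rep_match.start()]
        records.append(
            LandmarkConfiguration(pts, cell_id=cell_id or f"record{n_record}", replicate_id=replicate)
        )
    return records


def write_tps(path, configs) -> None:
    """Write configurations to a TPS file (full float precision, no SCALE)."""
    path = Path(path)
    out = []
    for cfg in configs:
        out.append(f"LM={cfg.k}")
        for x, y in cfg.points:
            out.append(f"{x:.17g} {y:.17g}")
        out.append(f"ID={cfg.cell_id}_rep{cfg.replicate_id}")
    path.write_text("\n".join(out) + "\n")


def write_landmarks_csv(path, configs) -> None:
    rows = []
    for cfg in configs:
        for j, (x, y) in enumerate(cfg.points):
            rows.append((cfg.cell_id, cfg.replicate_id, j, x, y))
    pd.DataFrame(rows, columns=["cell_id", "replicate", "landmark_index", "x", "y"]).to_csv(
        path, index=False
    )


def read_landmarks_csv(path) -> list[LandmarkConfiguration]:
    df = pd.read_csv(path)
    required = {"cell_id", "replicate", "landmark_index", "x", "y"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"CSV is missing columns: {sorted(missing)}")
    configs = []
    for (cell, rep), grp in df.groupby(["cell_id", "replicate"], sort=False):
        grp = grp.sort_values("landmark_index")
        configs.append(
            LandmarkConfiguration(grp[["x", "y"]].to_numpy(), cell_id=str(cell), replicate_id=int(rep))
        )
    return configs
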