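"""File formats: TPS landmark files, labeled-coordinate CSV, measurement CSV.

Outline interchange uses two plain-text dialects:

* **TPS** — the classic geometric-morphometrics landmark format.  One
  record per specimen::

      LM=2
      <tip x> <tip y>
      <base x> <base y>
      CURVES=3
      POINTS=<n inner>
      x y          (inner edge, tip -> base)
      ...
      POINTS=<n outer>
      ...          (outer edge, tip -> base)
      POINTS=2
      x y          (handle tip, handle base)
      ID=<specimen id>
      SCALE=<um per coordinate unit>

  Curves are written in fixed order inner, outer, handle (handle
  optional).  On read, coordinates are multiplied by SCALE to yield
  micrometres; the straight shaft section defaults to the proximal 40%
  of the inner edge (TPS has no place to carry the flag).

* **Labeled CSV** — columns ``specimen_id, edge_label, vertex_index, x, y``
  with ``edge_label`` in {tip, base, inner, outer, handle}; the handle rows
  are (tip, base) in vertex order.  This dialect carries the straight-flag
  range in optional ``straight_start``/``straight_stop`` columns.

Measurement tables are plain CSV: ``specimen_id, species`` then the 14
variables in canonical order.  All CSV output is comma-separated,
"."-decimal, UTF-8, with leading ``#`` comment lines for provenance
(seed, configuration hash) that readers skip.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError
from .geometry import HookOutline, MeasurementSet
from .variables import VARIABLE_NAMES

__all__ = [
    "read_landmarks",
    "write_landmarks",
    "read_measurements",
    "write_measurements",
    "write_table",
]


# ---------------------------------------------------------------------------
# TPS


def _write_tps_record(buf, outline: HookOutline) -> None:
    def pts(arr):
        for x, y in np.atleast_2d(arr):
            buf.write(f"{x:.6f} {y:.6f}\n")

    buf.write("LM=2\n")
    pts(outline.tip)
    pts(outline.articulation_base)
    n_curves = 3 if outline.handle is not None else 2
    buf.write(f"CURVES={n_curves}\n")
    buf.write(f"POINTS={len(outline.inner_edge)}\n")
    pts(outline.inner_edge)
    buf.write(f"POINTS={len(outline.outer_edge)}\n")
    pts(outline.outer_edge)
    if outline.handle is not None:
        buf.write("POINTS=2\n")
        pts(outline.handle[0])
        pts(outline.handle[1])
    buf.write(f"ID={outline.specimen_id}\n")
    buf.write(f"SCALE={outline.units_scale:g}\n")


def _parse_tps(text: str) -> list[HookOutline]:
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    outlines: list[HookOutline] = []
    i = 0

    def err(msg):
        return ParseError(f"TPS record {len(outlines) + 1}: {msg}")

    while i < len(lines):
        if not lines[i].upper().startswith("LM="):
            raise err(f"expected LM=, got {lines[i]!r}")
        try:
            n_lm = int(lines[i].split("=", 1)[1])
        except ValueError as exc:
            raise err("bad LM count") from exc
        if n_lm != 2:
            raise err(f"need exactly 2 landmarks (tip, base), got {n_lm}")
        i += 1

        def read_points(n, i):
            pts = []
            for _ in range(n):
                if i >= len(lines):
                    raise err("truncated coordinate block")
                parts = lines[i].split()
                if len(parts) != 2:
                    raise err(f"bad coordinate line {lines[i]!r}")
                try:
                    pts.append((float(parts[0]), float(parts[1])))
                except ValueError as exc:
                    raise err(f"bad coordinate line {lines[i]!r}") from exc
                i += 1
            return np.array(pts), i

        landmarks, i = read_points(2, i)
        if i >= len(lines) or not lines[i].upper().startswith("CURVES="):
            raise err("missing CURVES= (inner/outer edges required)")
        n_curves = int(lines[i].split("=", 1)[1])
        if n_curves not in (2, 3):
            raise err(f"need 2 or 3 curves (inner, outer[, handle]), got {n_curves}")
        i += 1
        curves = []
        for _ in range(n_curves):
            if i >= len(lines) or not lines[i].upper().startswith("POINTS="):
                raise err("missing POINTS= for a curve")
            n_pts = int(lines[i].split("=", 1)[1])
            i += 1
            pts, i = read_points(n_pts, i)
            curves.append(pts)
        spec_id, scale = "", 1.0
        while i < len(lines) and "=" in lines[i] and not lines[i].upper().startswith("LM="):
            key, val = lines[i].split("=", 1)
            if key.upper() == "ID":
                spec_id = val.strip()
            elif key.upper() == "SCALE":
                scale = float(val)
            i += 1
        handle = None
        if n_curves == 3:
            if len(curves[2]) != 2:
                raise err("handle curve must have exactly 2 points (tip, base)")
            handle = (curves[2][0], curves[2][1])
        try:
            outlines.append(HookOutline(
                specimen_id=spec_id or f"record{len(outlines) + 1}",
                inner_edge=curves[0], outer_edge=curves[1],
                articulation_base=landmarks[1], handle=handle,
                units_scale=scale,
            ))
        except Exception as exc:
            raise err(str(exc)) from exc
    return outlines


# ---------------------------------------------------------------------------
# labeled CSV

_CSV_COLUMNS = ["specimen_id", "edge_label", "vertex_index", "x", "y"]


def _outline_to_rows(outline: HookOutline) -> list[dict]:
    rows = []

    def add(label, arr):
        for j, (x, y) in enumerate(np.atleast_2d(arr)):
            rows.append({"specimen_id": outline.specimen_id, "edge_label": label,
                         "vertex_index": j, "x": x, "y": y})

    add("tip", outline.tip)
    add("base", outline.articulation_base)
    add("inner", outline.inner_edge)
    add("outer", outline.outer_edge)
    if outline.handle is not None:
        add("handle", np.vstack(outline.handle))
    lo, hi = outline.effective_straight_range()
    for r in rows:
        r["straight_start"], r["straight_stop"] = lo, hi
        r["units_scale"] = outline.units_scale
    return rows


def _rows_to_outlines(df: pd.DataFrame) -> list[HookOutline]:
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"labeled CSV missing columns {missing}")
    outlines = []
    for spec_id, grp in df.groupby("specimen_id", sort=False):
        def edge(label, grp=grp, spec_id=spec_id):
            e = grp[grp["edge_label"] == label].sort_values("vertex_index")
            if e.empty:
                raise ParseError(f"specimen {spec_id!r}: missing edge {label!r}")
            return e[["x", "y"]].to_numpy(dtype=float)

        labels = set(grp["edge_label"])
        bad = labels - {"tip", "base", "inner", "outer", "handle"}
        if bad:
            raise ParseError(f"specimen {spec_id!r}: unknown edge labels {sorted(bad)}")
        handle = None
        if "handle" in labels:
            h = edge("handle")
            if len(h) != 2:
                raise ParseError(f"specimen {spec_id!r}: handle needs 2 vertices")
            handle = (h[0], h[1])
        straight = None
        if "straight_start" in grp.columns and grp["straight_start"].notna().any():
            straight = (int(grp["straight_start"].iloc[0]),
                        int(grp["straight_stop"].iloc[0]))
        scale = float(grp["units_scale"].iloc[0]) if "units_scale" in grp.columns else 1.0
        try:
            outlines.append(HookOutline(
                specimen_id=str(spec_id),
                inner_edge=edge("inner"), outer_edge=edge("outer"),
                articulation_base=edge("base")[0],
                straight_range=straight, handle=handle, units_scale=scale,
            ))
        except ParseError:
            raise
        except Exception as exc:
            raise ParseError(f"specimen {spec_id!r}: {exc}") from exc
    return outlines


# ---------------------------------------------------------------------------
# public API


def write_landmarks(path, outlines: list[HookOutline], format: str = "tps",
                    header: str | None = None) -> None:
    """Write hook outlines as TPS or labeled-coordinate CSV."""
    path = Path(path)
    if format == "tps":
        buf = _io.StringIO()
        for o in outlines:
            _write_tps_record(buf, o)
        path.write_text(buf.getvalue())
    elif format == "csv":
        rows = [r for o in outlines for r in _outline_to_rows(o)]
        write_table(path, pd.DataFrame(rows), header=header)
    else:
        raise ValueError(f"unknown landmark format {format!r}")


def read_landmarks(path, format: str | None = None) -> list[HookOutline]:
    """Read hook outlines from a TPS or labeled-coordinate CSV file.

    Coordinates are converted to micrometres via the per-record SCALE /
    ``units_scale``.  Fails closed: any malformed record raises
    :class:`ParseError` and nothing is returned.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    if format is None:
        format = "tps" if path.suffix.lower() == ".tps" else "csv"
    if format == "tps":
        outlines = _parse_tps(path.read_text())
    elif format == "csv":
        df = pd.read_csv(path, comment="#")
        outlines = _rows_to_outlines(df)
    else:
        raise ValueError(f"unknown landmark format {format!r}")
    return [o.to_um() for o in outlines]


def write_measurements(path, sets_or_frame, species: dict[str, str] | None = None,
                       header: str | None = None) -> None:
    """Write a measurement table (MeasurementSet list or DataFrame) as CSV."""
    if isinstance(sets_or_frame, pd.DataFrame):
        df = sets_or_frame
    else:
        rows = []
        for ms in sets_or_frame:
            if not isinstance(ms, MeasurementSet):
                raise TypeError("expected MeasurementSet instances")
            row = {"specimen_id": ms.specimen_id,
                   "species": (species or {}).get(ms.specimen_id, "")}
            row.update(ms.as_row())
            rows.append(row)
        df = pd.DataFrame(rows, columns=["specimen_id", "species", *VARIABLE_NAMES])
    write_table(path, df, header=header)


def read_measurements(path) -> pd.DataFrame:
    """Read a measurement CSV (skipping ``#`` provenance comments)."""
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    df = pd.read_csv(path, comment="#")
    if "species" not in df.columns:
        raise ParseError(f"{path}: measurement CSV needs a 'species' column")
    unknown = set(df.columns) - {"specimen_id", "species", *VARIABLE_NAMES}
    if unknown:
        raise ParseError(f"{path}: unknown measurement columns {sorted(unknown)}")
    return df


def write_table(path, df: pd.DataFrame, header: str | None = None) -> None:
    """Write a DataFrame as CSV with optional leading ``#`` provenance lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)
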