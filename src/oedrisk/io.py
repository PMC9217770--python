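"""Plain-text DVH file format.

Tab-separated blocks, one per patient x organ::

    # patient P01
    # group PBI_MRL
    # organ thyroid
    # type differential
    # volume_cm3 15.2
    0.0<TAB>10.0
    0.1<TAB>5.2
    ...

Header keys: ``patient``, ``group``, ``organ``, ``type``
(``cumulative`` | ``differential``), ``volume_cm3`` and optional ``units``
(``cm3`` default, or ``percent``).  ``patient`` and ``group`` persist across
subsequent organ blocks of the same patient; blocks are separated by blank
lines.

Rows are ``dose_gy<TAB>volume``.  For cumulative blocks the volume column is
volume-at-or-above-dose.  For differential blocks the dose column holds bin
lower edges; a trailing zero-volume row marks the final bin edge (written by
:func:`write_dvh_file`), otherwise the last bin width is inferred from the
trailing grid spacing.  Percent volumes are converted to cm^3 with the
mandatory ``volume_cm3`` header.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

from .dvh import CumulativeDVH, DifferentialDVH, PatientRecord, cumulative_to_differential

__all__ = ["read_dvh_file", "write_dvh_file", "parse_dvh_text", "format_dvh_text"]

_HEADER_KEYS = {"patient", "group", "organ", "type", "volume_cm3", "units"}


class DVHFormatError(ValueError):
    """Malformed DVH file; the message names the offending line."""


def _fail(lineno: int, msg: str) -> None:
    raise DVHFormatError(f"line {lineno}: {msg}")


def parse_dvh_text(text: str) -> list[PatientRecord]:
    """Parse DVH dialect text into validated patient records."""
    blocks: list[tuple[dict, list[tuple[float, float]], int]] = []
    header: dict = {}
    rows: list[tuple[float, float]] = []
    block_start = 0
    context: dict = {}

    def flush(lineno: int) -> None:
        nonlocal header, rows
        if not header and not rows:
            return
        blocks.append((dict(context) | header, rows, block_start))
        header, rows = {}, []

    lineno = 0
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            flush(lineno)
            continue
        if line.startswith("#"):
            if rows:
                flush(lineno)
            parts = line[1:].strip().split(None, 1)
            if len(parts) != 2:
                _fail(lineno, f"malformed header {line!r}")
            key, value = parts[0], parts[1].strip()
            if key not in _HEADER_KEYS:
                _fail(lineno, f"unknown header key {key!r}")
            if not header:
                block_start = lineno
            header[key] = value
            if key in ("patient", "group"):
                context[key] = value
            continue
        cols = line.split("\t") if "\t" in line else line.split()
        if len(cols) != 2:
            _fail(lineno, f"expected two columns, got {line!r}")
        try:
            rows.append((float(cols[0]), float(cols[1])))
        except ValueError:
            _fail(lineno, f"non-numeric row {line!r}")
        if not header and not rows[:-1]:
            block_start = lineno
    flush(lineno)

    patients: dict[str, dict] = {}
    order: list[str] = []
    for head, rows, lineno in blocks:
        if not rows:
            continue
        for key in ("patient", "group", "organ", "type"):
            if key not in head:
                _fail(lineno, f"block is missing the '{key}' header")
        dvh = _block_to_dvh(head, rows, lineno)
        pid = head["patient"]
        if pid not in patients:
            patients[pid] = {"group": head["group"], "dvhs": {}}
            order.append(pid)
        elif patients[pid]["group"] != head["group"]:
            _fail(lineno, f"patient {pid!r} appears with two different groups")
        patients[pid]["dvhs"][head["organ"]] = dvh

    try:
        return [
            PatientRecord(pid, patients[pid]["group"], patients[pid]["dvhs"])
            for pid in order
        ]
    except ValueError as exc:  # group label / lung-volume invariants
        raise DVHFormatError(str(exc)) from exc


def _block_to_dvh(head: dict, rows: Sequence[tuple[float, float]], lineno: int) -> DifferentialDVH:
    organ = head["organ"]
    kind = head["type"]
    if kind not in ("cumulative", "differential"):
        _fail(lineno, f"unknown DVH type {kind!r}")
    units = head.get("units", "cm3")
    if units not in ("cm3", "percent"):
        _fail(lineno, f"unknown units {units!r}")
    doses = np.array([r[0] for r in rows])
    vols = np.array([r[1] for r in rows])
    if np.any(vols < 0):
        _fail(lineno, f"{organ}: negative volume in block")
    total = None
    if "volume_cm3" in head:
        total = float(head["volume_cm3"])
    if units == "percent":
        if total is None:
            _fail(lineno, f"{organ}: percent units require a 'volume_cm3' header")
        vols = vols / 100.0 * total
    try:
        if kind == "cumulative":
            return cumulative_to_differential(
                CumulativeDVH(organ, doses, vols, total)
            )
        if vols.size >= 2 and vols[-1] == 0.0:
            edges, binvols = doses, vols[:-1]
        else:  # final edge inferred from the trailing spacing
            width = doses[-1] - doses[-2] if doses.size > 1 else 1.0
            edges, binvols = np.append(doses, doses[-1] + width), vols
        return DifferentialDVH(organ, edges, binvols, total)
    except ValueError as exc:
        raise DVHFormatError(f"line {lineno}: {exc}") from exc


def format_dvh_text(records: Iterable[PatientRecord], precision: int = 10) -> str:
    """Serialize records in the DVH dialect (differential, cm^3 volumes)."""
    out: list[str] = []
    for rec in records:
        for i, (organ, dvh) in enumerate(rec.dvhs.items()):
            out.append(f"# patient {rec.patient_id}")
            out.append(f"# group {rec.group}")
            out.append(f"# organ {organ}")
            out.append("# type differential")
            out.append(f"# volume_cm3 {dvh.total_volume:.{precision}g}")
            for edge, vol in zip(dvh.bin_edges[:-1], dvh.bin_volumes):
                out.append(f"{edge:.{precision}g}\t{vol:.{precision}g}")
            out.append(f"{dvh.bin_edges[-1]:.{precision}g}\t0")
            out.append("")
    return "\n".join(out)


def read_dvh_file(path) -> list[PatientRecord]:
    """Read a DVH dialect file; cumulative blocks are converted on load."""
    with open(path, "r", encoding="utf-8") as fh:
        return parse_dvh_text(fh.read())


def write_dvh_file(path, records: Iterable[PatientRecord], precision: int = 10) -> None:
    """Write records to ``path`` in the DVH dialect."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(format_dvh_text(records, precision=precision))
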