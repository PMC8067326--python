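"""Per-step diagnostic records and their CSV serialization.

The CSV schema is fixed and versioned; two runs with the same configuration
and seed produce byte-identical files (floats are written with shortest
round-trip ``repr``).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, fields

SCHEMA_VERSION = 1
_COLUMNS = ["step", "time", "mass", "F_bulk", "F_grad", "F_total", "dissipation",
            "matrix_fraction", "membrane_fraction", "interface_measure",
            "n_membrane_components", "characteristic_length", "granule_halo_means"]


@dataclass
class TimeSeriesRecord:
    step: int
    time: float
    mass: float
    F_bulk: float
    F_grad: float
    F_total: float
    dissipation: float
    matrix_fraction: float
    membrane_fraction: float
    interface_measure: float
    n_membrane_components: int
    characteristic_length: float = float("nan")
    granule_halo_means: tuple = ()


def _fmt(value) -> str:
    if isinstance(value, float):
        return repr(value)
    return str(value)


def write_csv(records, path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(f"# chmito-timeseries v{SCHEMA_VERSION}\n")
        writer = csv.writer(fh)
        writer.writerow(_COLUMNS)
        for rec in records:
            row = []
            for col in _COLUMNS:
                val = getattr(rec, col)
                if col == "granule_halo_means":
                    row.append(";".join(repr(float(v)) for v in val))
                else:
                    row.append(_fmt(val))
            writer.writerow(row)


def read_csv(path):
    records = []
    with open(path, newline="") as fh:
        first = fh.readline()
        if not first.startswith("# chmito-timeseries"):
            raise ValueError(f"{path}: not a chmito time-series CSV")
        reader = csv.DictReader(fh)
        for row in reader:
            halo = tuple(float(v) for v in row["granule_halo_means"].split(";") if v)
            records.append(TimeSeriesRecord(
                step=int(row["step"]), time=float(row["time"]), mass=float(row["mass"]),
                F_bulk=float(row["F_bulk"]), F_grad=float(row["F_grad"]),
                F_total=float(row["F_total"]), dissipation=float(row["dissipation"]),
                matrix_fraction=float(row["matrix_fraction"]),
                membrane_fraction=float(row["membrane_fraction"]),
                interface_measure=float(row["interface_measure"]),
                n_membrane_components=int(row["n_membrane_components"]),
                characteristic_length=float(row["characteristic_length"]),
                granule_halo_means=halo))
    return records
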