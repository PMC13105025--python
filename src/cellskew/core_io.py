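"""Domain types, event-table I/O, and the background gate.

Per-cell metabolic activity arrives as flow-cytometry event tables: one row
per detected cell, with a relative-fluorescence value (RFU) from a redox
probe acting as the activity proxy, grouped into samples by ``sample_id``.
Cell-free control samples define a fluorescence threshold below which events
are treated as background and removed ("gating").
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

REGIMES = ("batch", "chemostat", "environmental", "isolate", "external")

#: metadata columns recognised in event tables, with their parsed type.
#: Units: time_h in hours, dilution_rate in 1/h, bp in uM C / h,
#: distance_m in metres; ecosystem is a free-text habitat label.
META_COLUMNS: Mapping[str, type] = {
    "time_h": float,
    "dilution_rate": float,
    "bp": float,
    "distance_m": float,
    "ecosystem": str,
}


@dataclass
class ActivitySample:
    """One sample's vector of per-cell activity values plus metadata.

    ``values`` are per-cell fluorescence intensities (RFU, dimensionless);
    after gating they are finite and strictly positive, which the
    likelihood-based downstream analysis requires.
    """

    sample_id: str
    values: np.ndarray
    regime: str = "external"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be a 1-d vector")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"sample {self.sample_id!r}: non-finite activity values")
        if self.regime not in REGIMES:
            raise ValueError(
                f"unknown regime {self.regime!r}; expected one of {REGIMES}"
            )

    @property
    def n_events(self) -> int:
        return self.values.size

    def replace_values(self, values: np.ndarray, **metadata) -> "ActivitySample":
        """Copy of this sample with new values and updated metadata."""
        meta = dict(self.metadata)
        meta.update(metadata)
        return dataclasses.replace(self, values=np.asarray(values, float), metadata=meta)


@dataclass
class ControlSample:
    """Event fluorescence from a cell-free (buffer-only) control."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("control values must be finite")
        if np.any(self.values < 0):
            raise ValueError("control values must be non-negative")

    @property
    def n_events(self) -> int:
        return self.values.size


class SchemaError(ValueError):
    """The event table is missing a required column."""


class ParseError(ValueError):
    """A cell of the event table could not be parsed."""


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def read_event_table(path, schema: Mapping[str, str] | None = None) -> list[ActivitySample]:
    """Read a long-format event table into one :class:`ActivitySample` per sample.

    The file must be delimited text (CSV, or TSV for ``.tsv``/``.tab``
    extensions) with a header and at least the columns ``sample_id`` and
    ``rfu``; ``schema`` may remap standard names to the file's column names,
    e.g. ``{"rfu": "FL1-H"}``. Optional metadata columns (``regime`` plus
    those in :data:`META_COLUMNS`) are taken from each sample's first row.
    Values appear in file order within each sample.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    colmap = {name: name for name in ("sample_id", "rfu", "regime", *META_COLUMNS)}
    if schema:
        colmap.update(schema)

    df = pd.read_csv(path, sep=_sep_for(path), dtype=str, skipinitialspace=True)
    for required in ("sample_id", "rfu"):
        if colmap[required] not in df.columns:
            raise SchemaError(
                f"{path}: missing required column {colmap[required]!r} "
                f"(have {list(df.columns)})"
            )
    if df.empty:
        return []

    raw_rfu = df[colmap["rfu"]]
    rfu = pd.to_numeric(raw_rfu, errors="coerce")
    bad = rfu.isna() & raw_rfu.notna()
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise ParseError(
            f"{path}: non-numeric rfu value {raw_rfu.iloc[i]!r} at data row {i + 1}"
        )
    if rfu.isna().any():
        i = int(np.flatnonzero(rfu.isna().to_numpy())[0])
        raise ParseError(f"{path}: missing rfu value at data row {i + 1}")
    df = df.assign(**{colmap["rfu"]: rfu.astype(float)})

    samples = []
    for sid, grp in df.groupby(colmap["sample_id"], sort=False):
        first = grp.iloc[0]
        regime = "external"
        if colmap["regime"] in grp.columns and pd.notna(first[colmap["regime"]]):
            regime = str(first[colmap["regime"]])
        metadata = {}
        for name, typ in META_COLUMNS.items():
            col = colmap[name]
            if col in grp.columns and pd.notna(first[col]):
                metadata[name] = typ(first[col])
        samples.append(
            ActivitySample(
                sample_id=str(sid),
                values=grp[colmap["rfu"]].to_numpy(),
                regime=regime,
                metadata=metadata,
            )
        )
    return samples


def write_event_table(samples: list[ActivitySample], path) -> None:
    """Write samples back to the long-format CSV/TSV event table."""
    path = Path(path)
    rows = []
    for s in samples:
        for v in s.values:
            row = {"sample_id": s.sample_id, "rfu": v, "regime": s.regime}
            row.update({k: s.metadata[k] for k in META_COLUMNS if k in s.metadata})
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=_sep_for(path), index=False)


def write_results(table: pd.DataFrame, path) -> None:
    """Write a results table as delimited text.

    Floats are written at full precision so that ``read_results(write_results(t))``
    round-trips values exactly; two writes of the same table are
    byte-identical.
    """
    if not isinstance(table, pd.DataFrame):
        table = pd.DataFrame(table)
    if table.columns.duplicated().any():
        raise ValueError("results table column names must be unique")
    path = Path(path)
    table.to_csv(path, sep=_sep_for(path), index=False)


def read_results(path) -> pd.DataFrame:
    path = Path(path)
    return pd.read_csv(path, sep=_sep_for(path))


def apply_background_gate(
    sample: ActivitySample, control: ControlSample, q: float = 0.999
) -> ActivitySample:
    """Remove background events using a cell-free control threshold.

    Retains only events with fluorescence strictly greater than the empirical
    ``q``-quantile of the control; emulates the instrument-software gate drawn
    against buffer-only controls. Records ``gate_threshold``,
    ``gate_retained_fraction`` and ``gate_warning`` (set when nothing
    survives) in the returned sample's metadata.
    """
    if control.n_events == 0:
        raise ValueError("control sample is empty")
    if not (0.0 < q <= 1.0):
        raise ValueError(f"gate quantile must be in (0, 1], got {q}")
    threshold = float(np.quantile(control.values, q))
    kept = sample.values[sample.values > threshold]
    retained = kept.size / sample.n_events if sample.n_events else 0.0
    return sample.replace_values(
        kept,
        gate_threshold=threshold,
        gate_retained_fraction=retained,
        gate_warning=kept.size == 0,
    )
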