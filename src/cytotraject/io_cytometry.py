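"""Event-table I/O and preprocessing for mass-cytometry data.

The central container is :class:`EventTable`: a cells x markers intensity
matrix plus a marker panel and per-cell annotations (patient, time-point in
months, population label). Tables can be read from / written to delimited
text (CSV, annotations as ``meta_``-prefixed columns) or FCS 3.0/3.1
(annotations as extra ``meta_`` channels carrying numeric codes, with the
code tables stored as custom TEXT keywords).

Raw ion-count intensities are variance-stabilized with the standard
cytometry transform ``asinh(x / cofactor)`` (default cofactor 5). The
transform state is recorded on the table so a double transform is
impossible.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _fcs
from .exceptions import (
    EmptySelectionError,
    InsufficientDataError,
    SchemaError,
    TransformStateError,
)

logger = logging.getLogger(__name__)

DEFAULT_COFACTOR = 5.0
UNASSIGNED = "unassigned"

#: annotation columns, in serialization order
META_COLUMNS = ("patient_id", "timepoint_months", "population")
_META_PREFIX = "meta_"

_KW_PATIENTS = "CYTOTRAJECT_PATIENTS"
_KW_POPULATIONS = "CYTOTRAJECT_POPULATIONS"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MarkerPanel:
    """Ordered antibody panel: (channel_name, marker_name, is_analysis_marker)."""

    channels: tuple[tuple[str, str, bool], ...]

    def __post_init__(self):
        names = [c[0] for c in self.channels]
        if len(set(names)) != len(names):
            raise SchemaError("panel channel names are not unique")
        if not any(c[2] for c in self.channels):
            raise SchemaError("panel has no analysis markers")

    @classmethod
    def from_markers(cls, markers) -> "MarkerPanel":
        return cls(tuple((m, m, True) for m in markers))

    @property
    def analysis_markers(self) -> list[str]:
        return [marker for _, marker, flag in self.channels if flag]

    @property
    def channel_names(self) -> list[str]:
        return [name for name, _, _ in self.channels]


@dataclass
class EventTable:
    """Single-cell intensities with panel metadata and per-cell provenance.

    ``intensities`` holds one column per *analysis* marker of ``panel``.
    ``annotations`` is a DataFrame with columns ``patient_id`` (str),
    ``timepoint_months`` (float) and ``population`` (str, ``"unassigned"``
    when not yet labeled), row-aligned with ``intensities``.
    """

    intensities: np.ndarray
    panel: MarkerPanel
    annotations: pd.DataFrame
    transform_state: str = "raw"

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        if self.intensities.ndim != 2:
            raise SchemaError("intensities must be a 2-D matrix")
        n_markers = len(self.panel.analysis_markers)
        if self.intensities.shape[1] != n_markers:
            raise SchemaError(
                f"intensity columns ({self.intensities.shape[1]}) != panel "
                f"analysis markers ({n_markers})")
        if len(self.annotations) != self.intensities.shape[0]:
            raise SchemaError("annotations not row-aligned with intensities")
        missing = set(META_COLUMNS) - set(self.annotations.columns)
        if missing:
            raise SchemaError(f"annotations missing columns: {sorted(missing)}")
        self.annotations = self.annotations.reset_index(drop=True)

    @property
    def n_cells(self) -> int:
        return self.intensities.shape[0]

    @property
    def markers(self) -> list[str]:
        return self.panel.analysis_markers

    def marker_column(self, marker: str) -> np.ndarray:
        try:
            j = self.markers.index(marker)
        except ValueError:
            raise SchemaError(f"marker {marker!r} not in panel") from None
        return self.intensities[:, j]

    def select(self, mask) -> "EventTable":
        mask = np.asarray(mask)
        return EventTable(self.intensities[mask],
                          self.panel,
                          self.annotations.loc[mask].reset_index(drop=True),
                          self.transform_state)

    def with_populations(self, labels) -> "EventTable":
        ann = self.annotations.copy()
        ann["population"] = list(labels)
        return EventTable(self.intensities.copy(), self.panel, ann,
                          self.transform_state)


def make_annotations(n: int, patient_id: str = "unknown",
                     timepoint_months: float = 0.0,
                     population: str = UNASSIGNED) -> pd.DataFrame:
    return pd.DataFrame({
        "patient_id": [patient_id] * n,
        "timepoint_months": np.full(n, float(timepoint_months)),
        "population": [population] * n,
    })


@dataclass(frozen=True)
class SampleMeta:
    """Clinical context of one sample.

    Counts are in units of 10^7 cells per litre of blood. The mononuclear
    pool used for absolute counts is ``wbc_count - neutrophil_count``.
    """

    patient_id: str
    timepoint_months: float
    wbc_count: float
    neutrophil_count: float

    def __post_init__(self):
        if not (self.wbc_count >= self.neutrophil_count >= 0):
            raise ValueError(
                f"need WBC >= neutrophils >= 0, got WBC={self.wbc_count}, "
                f"neutrophils={self.neutrophil_count}")


def check_sample_meta_unique(metas) -> None:
    keys = [(m.patient_id, m.timepoint_months) for m in metas]
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate (patient_id, timepoint_months) in metadata")


# ---------------------------------------------------------------------------
# reading / writing
# ---------------------------------------------------------------------------

def _infer_format(path) -> str:
    return "fcs" if str(path).lower().endswith(".fcs") else "delimited"


def read_event_table(path, format: str | None = None,
                     panel_override: MarkerPanel | None = None) -> EventTable:
    """Read an event table from CSV or FCS; returns a table in ``raw`` state.

    Delimited files carry annotations as ``meta_patient_id``,
    ``meta_timepoint_months`` and ``meta_population`` columns; FCS files as
    extra ``meta_*`` channels (see :func:`write_event_table`). Missing
    annotations default to patient ``"unknown"``, time-point 0 and
    population ``"unassigned"``.
    """
    fmt = format or _infer_format(path)
    if not os.path.exists(path):
        raise IOError(f"cannot read event table: no such file {path}")
    if fmt == "delimited":
        try:
            df = pd.read_csv(path)
        except Exception as exc:  # pragma: no cover - pandas message varies
            raise IOError(f"cannot parse delimited file {path}: {exc}") from exc
        meta_cols = [c for c in df.columns if c.startswith(_META_PREFIX)]
        marker_cols = [c for c in df.columns if c not in meta_cols]
        intensities = df[marker_cols].to_numpy(dtype=np.float64) \
            if len(df) else np.empty((0, len(marker_cols)))
        ann = make_annotations(len(df))
        for col in META_COLUMNS:
            src = _META_PREFIX + col
            if src in df.columns:
                ann[col] = df[src].to_numpy()
        ann["timepoint_months"] = ann["timepoint_months"].astype(float)
        ann["patient_id"] = ann["patient_id"].astype(str)
        ann["population"] = ann["population"].astype(str)
        panel = MarkerPanel.from_markers(marker_cols)
    elif fmt == "fcs":
        try:
            data, channels, markers, kw = _fcs.read_fcs(path)
        except (OSError, ValueError) as exc:
            raise IOError(f"cannot read FCS file {path}: {exc}") from exc
        is_meta = [c.startswith(_META_PREFIX) for c in channels]
        marker_idx = [i for i, m in enumerate(is_meta) if not m]
        intensities = data[:, marker_idx]
        panel = MarkerPanel(tuple(
            (channels[i], markers[i], True) for i in marker_idx))
        ann = make_annotations(data.shape[0])
        n = data.shape[0]
        if n:
            chan_pos = {c: i for i, c in enumerate(channels)}
            if _META_PREFIX + "timepoint_months" in chan_pos:
                ann["timepoint_months"] = data[:, chan_pos[_META_PREFIX + "timepoint_months"]]
            patients = kw.get(_KW_PATIENTS, "").split(";")
            populations = kw.get(_KW_POPULATIONS, "").split(";")
            if _META_PREFIX + "patient_id" in chan_pos and patients != [""]:
                codes = data[:, chan_pos[_META_PREFIX + "patient_id"]].astype(int)
                ann["patient_id"] = [patients[c] for c in codes]
            if _META_PREFIX + "population" in chan_pos and populations != [""]:
                codes = data[:, chan_pos[_META_PREFIX + "population"]].astype(int)
                ann["population"] = [populations[c] for c in codes]
    else:
        raise ValueError(f"unknown format {fmt!r}")

    if panel_override is not None:
        have = {name for name, _, _ in panel.channels}
        missing = [c for c in panel_override.channel_names if c not in have]
        if missing:
            raise SchemaError(
                f"panel_override channels missing from {path}: {missing}")
        order = [panel.channel_names.index(c)
                 for c, _, flag in panel_override.channels if flag]
        intensities = intensities[:, order]
        panel = panel_override

    return EventTable(intensities, panel, ann, transform_state="raw")


def write_event_table(events: EventTable, path, format: str | None = None):
    """Write an event table; the result is readable by :func:`read_event_table`.

    Delimited output stores markers as columns plus ``meta_`` annotation
    columns. FCS output stores annotations as extra channels
    ``meta_patient_id`` / ``meta_timepoint_months`` / ``meta_population``;
    the string-valued annotations are integer codes into semicolon-joined
    tables kept in the custom TEXT keywords ``CYTOTRAJECT_PATIENTS`` and
    ``CYTOTRAJECT_POPULATIONS``.
    """
    fmt = format or _infer_format(path)
    if fmt == "delimited":
        df = pd.DataFrame(events.intensities, columns=events.markers)
        for col in META_COLUMNS:
            df[_META_PREFIX + col] = events.annotations[col].to_numpy()
        try:
            df.to_csv(path, index=False)
        except OSError as exc:
            raise IOError(f"cannot write {path}: {exc}") from exc
    elif fmt == "fcs":
        ann = events.annotations
        patients = sorted(set(ann["patient_id"].astype(str)))
        populations = sorted(set(ann["population"].astype(str)))
        for name in patients + populations:
            if ";" in name or "/" in name:
                raise ValueError(
                    f"annotation value {name!r} cannot be stored in FCS "
                    "(contains ';' or '/')")
        p_code = {p: i for i, p in enumerate(patients)}
        l_code = {p: i for i, p in enumerate(populations)}
        meta = np.column_stack([
            [p_code[p] for p in ann["patient_id"].astype(str)],
            ann["timepoint_months"].to_numpy(float),
            [l_code[p] for p in ann["population"].astype(str)],
        ]) if events.n_cells else np.empty((0, 3))
        data = np.hstack([events.intensities, meta])
        chan_names = ([name for name, _, flag in events.panel.channels if flag]
                      + [_META_PREFIX + c for c in META_COLUMNS])
        marker_names = events.markers + [_META_PREFIX + c for c in META_COLUMNS]
        try:
            _fcs.write_fcs(path, data, chan_names, marker_names,
                           extra_keywords={
                               _KW_PATIENTS: ";".join(patients),
                               _KW_POPULATIONS: ";".join(populations),
                           })
        except OSError as exc:
            raise IOError(f"cannot write {path}: {exc}") from exc
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return path


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def arcsinh_transform(events: EventTable,
                      cofactor: float = DEFAULT_COFACTOR) -> EventTable:
    """Apply ``asinh(x / cofactor)`` to every intensity.

    Negative raw intensities (rare post-extraction artifacts) are clipped to
    zero first and the clip count is logged. Re-transforming an already
    transformed table raises :class:`TransformStateError`.
    """
    if events.transform_state != "raw":
        raise TransformStateError(
            f"table already transformed ({events.transform_state})")
    if not cofactor > 0:
        raise ValueError(f"cofactor must be positive, got {cofactor}")
    x = events.intensities
    n_neg = int(np.sum(x < 0))
    if n_neg:
        logger.info("clipping %d negative raw intensities to 0", n_neg)
        x = np.clip(x, 0.0, None)
    return EventTable(np.arcsinh(x / cofactor), events.panel,
                      events.annotations.copy(),
                      transform_state=f"arcsinh({cofactor:g})")


def merge_timepoints(tables, population: str) -> EventTable:
    """Concatenate one population's cells from several samples of one patient.

    All tables must share the panel, transform state and patient; the
    population must be present at >= 2 distinct time-points. Per-cell
    time-points and within-table cell order are preserved.
    """
    tables = list(tables)
    if not tables:
        raise EmptySelectionError("no tables given")
    panel = tables[0].panel
    state = tables[0].transform_state
    for t in tables[1:]:
        if t.panel.channels != panel.channels:
            raise SchemaError("tables have mismatched panels")
        if t.transform_state != state:
            raise TransformStateError("tables have mixed transform states")
    patients = set()
    for t in tables:
        patients.update(t.annotations["patient_id"].unique())
    if len(patients) > 1:
        raise SchemaError(f"tables span multiple patients: {sorted(patients)}")

    selected = [t.select((t.annotations["population"] == population).to_numpy())
                for t in tables]
    total = sum(s.n_cells for s in selected)
    if total == 0:
        raise EmptySelectionError(
            f"population {population!r} absent from all tables")
    tps = set()
    for s in selected:
        tps.update(s.annotations["timepoint_months"].unique())
    if len(tps) < 2:
        raise InsufficientDataError(
            f"population {population!r} present at only {len(tps)} time-point(s)")

    intensities = np.vstack([s.intensities for s in selected])
    ann = pd.concat([s.annotations for s in selected], ignore_index=True)
    return EventTable(intensities, panel, ann, transform_state=state)
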