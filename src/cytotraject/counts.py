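"""Absolute cell counts from relative frequencies and clinical labs.

Relative population frequencies hide changes in total white-cell numbers,
which are large during immune reconstitution. Each population's frequency
among PBMC is therefore rescaled by the clinical mononuclear pool,
approximated as WBC minus neutrophils (both in 10^7 cells/L):

    absolute_count(P) = frequency(P) * (WBC - neutrophils)

Cells labeled ``"unassigned"`` are analysis failures, not a biological
compartment, and are excluded from both numerator and denominator.
"""

from __future__ import annotations

import pandas as pd

from .exceptions import EmptySelectionError
from .io_cytometry import EventTable, SampleMeta, UNASSIGNED

COUNT_COLUMNS = ["patient_id", "timepoint_months", "population",
                 "frequency", "absolute_count"]


def population_frequencies(events: EventTable) -> pd.DataFrame:
    """Per-population fraction of labeled cells in one sample.

    Returns rows (patient_id, timepoint_months, population, frequency);
    frequencies sum to 1 over populations including ``"other"``.
    """
    ann = events.annotations
    keys = ann[["patient_id", "timepoint_months"]].drop_duplicates()
    if len(keys) != 1:
        raise ValueError(
            "events must come from a single (patient, timepoint) sample; "
            f"got {len(keys)} distinct keys")
    labeled = ann[ann["population"] != UNASSIGNED]
    n_total = len(labeled)
    if n_total == 0:
        raise EmptySelectionError("sample has no labeled cells")
    freq = (labeled.groupby("population").size() / n_total)
    out = freq.rename("frequency").reset_index()
    out.insert(0, "timepoint_months", float(keys.iloc[0, 1]))
    out.insert(0, "patient_id", str(keys.iloc[0, 0]))
    return out.sort_values("population", ignore_index=True)


def absolute_counts(freqs: pd.DataFrame, meta: SampleMeta) -> pd.DataFrame:
    """Rescale frequencies by the sample's mononuclear pool.

    The pool is ``wbc_count - neutrophil_count`` in 10^7 cells/L; the
    returned table adds an ``absolute_count`` column in the same units.
    """
    key = freqs[["patient_id", "timepoint_months"]].drop_duplicates()
    if len(key) != 1 or key.iloc[0, 0] != meta.patient_id \
            or float(key.iloc[0, 1]) != float(meta.timepoint_months):
        raise ValueError("frequency rows do not match the sample metadata")
    if meta.neutrophil_count > meta.wbc_count:
        raise ValueError("neutrophil count exceeds WBC count")
    pool = meta.wbc_count - meta.neutrophil_count
    out = freqs.copy()
    out["absolute_count"] = out["frequency"].to_numpy() * pool
    return out[COUNT_COLUMNS]


def cohort_count_table(labeled_tables, metas) -> pd.DataFrame:
    """Frequencies and absolute counts for every sample in a cohort."""
    by_key = {(m.patient_id, float(m.timepoint_months)): m for m in metas}
    rows = []
    for events in labeled_tables:
        ann = events.annotations
        key = (str(ann["patient_id"].iloc[0]),
               float(ann["timepoint_months"].iloc[0]))
        if key not in by_key:
            raise ValueError(f"no clinical metadata for sample {key}")
        rows.append(absolute_counts(population_frequencies(events),
                                    by_key[key]))
    return pd.concat(rows, ignore_index=True)
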