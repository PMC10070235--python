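"""Snapshot-ensemble statistics and derived gap/shift reports.

Snapshot tables hold per-frame diabatic quantities (site energies, CT
energies, couplings) in eV, keyed by snapshot id, quantity label and
provenance (vacuum or environment).  Summaries use population variance
(divisor n).  The gap/shift report derives the CT1-CT2 gap per snapshot set
and the per-label drift between two sets (e.g. the beginning and the end of
a trajectory), values rounded to two decimals only at presentation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError

__all__ = [
    "SnapshotTable",
    "ensemble_summary",
    "gap_and_shift_report",
    "env_delta",
]

logger = logging.getLogger(__name__)

COLUMNS = ("snapshot", "label", "value_eV", "provenance")


@dataclass
class SnapshotTable:
    """Tidy per-snapshot records with a set label (e.g. First50 / Last50)."""

    records: pd.DataFrame
    set_label: str = ""

    def __post_init__(self):
        df = pd.DataFrame(self.records)
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise InputError(f"snapshot table missing columns {missing}")
        df = df[list(COLUMNS)].copy()
        if not np.all(np.isfinite(df["value_eV"].to_numpy(dtype=float))):
            raise InputError("snapshot table contains non-finite values")
        dup = df.duplicated(subset=["snapshot", "label", "provenance"])
        if dup.any():
            raise InputError(
                f"duplicate (snapshot, label, provenance) keys: "
                f"{df[dup].head().to_dict('records')}"
            )
        self.records = df

    @classmethod
    def from_values(cls, values: dict[str, float], set_label: str = "",
                    provenance: str = "vacuum", snapshot=0) -> "SnapshotTable":
        rows = [
            {"snapshot": snapshot, "label": k, "value_eV": float(v),
             "provenance": provenance}
            for k, v in values.items()
        ]
        return cls(pd.DataFrame(rows), set_label=set_label)

    def labels(self) -> list[str]:
        return sorted(self.records["label"].unique())


def ensemble_summary(table: SnapshotTable, labels=None) -> pd.DataFrame:
    """Per-label, per-provenance mean and population variance (eV, eV^2)."""
    df = table.records
    if labels is not None:
        present = set(df["label"])
        for lab in labels:
            if lab not in present:
                logger.warning("label %s absent from snapshot table; skipped", lab)
        df = df[df["label"].isin(labels)]
    if df.empty:
        raise InputError("no records to summarize")
    out = (
        df.groupby(["label", "provenance"])["value_eV"]
        .agg(mean="mean", variance=lambda x: float(np.var(x, ddof=0)), n="count")
        .reset_index()
    )
    out.attrs["set_label"] = table.set_label
    return out


def _mean(summary: pd.DataFrame, label: str, provenance=None) -> float:
    sel = summary[summary["label"] == label]
    if provenance is not None:
        sel = sel[sel["provenance"] == provenance]
    if sel.empty:
        raise InputError(f"label {label!r} missing from summary")
    return float(sel["mean"].iloc[0])


def gap_and_shift_report(first: pd.DataFrame, last: pd.DataFrame) -> dict:
    """CT gaps per set and first-to-last shifts per label.

    Returns raw values plus presentation values rounded to 2 decimals.
    ``ct_gap`` is |mean(CT2) - mean(CT1)| within a set; ``shift[label]`` is
    mean(first) - mean(last), so a positive Qy2 shift is a red shift of the
    last set.
    """
    for name, summ in (("first", first), ("last", last)):
        for lab in ("CT1", "CT2", "Qy2"):
            if not (summ["label"] == lab).any():
                raise InputError(f"{name} summary missing required label {lab}")
    gaps = {
        "first": abs(_mean(first, "CT2") - _mean(first, "CT1")),
        "last": abs(_mean(last, "CT2") - _mean(last, "CT1")),
    }
    labels = sorted(set(first["label"]) & set(last["label"]))
    shifts = {lab: _mean(first, lab) - _mean(last, lab) for lab in labels}
    return {
        "ct_gap": gaps,
        "shift": shifts,
        "ct_gap_rounded": {k: round(v, 2) for k, v in gaps.items()},
        "shift_rounded": {k: round(v, 2) for k, v in shifts.items()},
    }


def env_delta(env_table: SnapshotTable, vac_table: SnapshotTable) -> pd.DataFrame:
    """Record-wise environment-minus-vacuum differences (V_DRF - V_VAC).

    Records are matched on (snapshot, label); unmatched keys are listed in a
    warning and excluded.
    """
    env = env_table.records.rename(columns={"value_eV": "env"})
    vac = vac_table.records.rename(columns={"value_eV": "vac"})
    merged = env.merge(vac, on=["snapshot", "label"], how="outer", indicator=True)
    unmatched = merged[merged["_merge"] != "both"]
    if len(unmatched):
        keys = unmatched[["snapshot", "label"]].to_dict("records")
        logger.warning("excluding %d unmatched records: %s", len(keys), keys[:10])
    both = merged[merged["_merge"] == "both"].copy()
    both["delta_eV"] = both["env"] - both["vac"]
    return both[["snapshot", "label", "delta_eV"]].reset_index(drop=True)
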