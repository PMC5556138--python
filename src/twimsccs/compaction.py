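"""Measured-vs-predicted CCS comparison: gas-phase compaction metrics.

A molecule is judged "compacted" in the gas phase by comparing its measured
CCS against one or more reference CCS values — typically the CCS predicted
from deposited coordinates (crystal/NMR structure) and the CCS of an
in vacuo MD end-point structure. Two statistics are reported per molecule
and charge state:

* **percent compaction** relative to each reference,
  (Ω_ref − Ω_meas)/Ω_ref × 100 — positive when the ion is smaller than the
  reference, negative (labelled expansion) when it is larger;
* the **nearest reference**, the reference whose CCS the measurement agrees
  with best in absolute terms — e.g. whether an ion sits closer to its
  solution structure or to its gas-phase-collapsed MD end point.

Areas are handled in nm² at this reporting layer (1 nm² = 100 Å²).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence as Seq

import pandas as pd

from .calibration import CcsMeasurement
from .projection import area_unit_convert

logger = logging.getLogger("twimsccs")

__all__ = [
    "ReferenceCcs",
    "CompactionRecord",
    "percent_compaction",
    "nearest_reference",
    "build_report",
    "report_to_csv",
    "report_to_json",
    "read_references_csv",
]

#: Recognised reference provenance categories.
REFERENCE_KINDS = ("pdb_structure", "md_endpoint", "model", "saxs")


@dataclass(frozen=True)
class ReferenceCcs:
    """A reference CCS value: its kind, area (nm²) and free-text provenance."""

    label: str
    ccs: float
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.ccs <= 0:
            raise ValueError(f"reference CCS must be positive (got {self.ccs})")


@dataclass(frozen=True)
class CompactionRecord:
    """Comparison of one (molecule, charge state) against its references."""

    molecule: str
    z: int
    measured_ccs: float  # nm²
    references: tuple[ReferenceCcs, ...]
    percent_compaction_vs: Mapping[str, float]
    nearest_reference: str


def percent_compaction(measured: float, reference: float) -> float:
    """(reference − measured)/reference × 100.

    Positive for gas-phase compaction, negative for apparent expansion.
    Both inputs must be in the same area unit; the result is unit-free.
    """
    if reference <= 0:
        raise ValueError("reference CCS must be positive")
    return (reference - measured) / reference * 100.0


def nearest_reference(measured: float, references: Seq[ReferenceCcs]) -> str:
    """Label of the reference minimising |measured − reference CCS|.

    Ties are broken in favour of the first-listed reference, with a warning.
    """
    if not references:
        raise ValueError("at least one reference is required")
    best = min(references, key=lambda r: abs(measured - r.ccs))
    best_diff = abs(measured - best.ccs)
    tied = [r.label for r in references if abs(measured - r.ccs) == best_diff]
    if len(tied) > 1:
        logger.warning(
            "references %s are equidistant from measured %.3f; keeping %r",
            tied, measured, best.label,
        )
    return best.label


def build_report(
    measurements: Iterable[CcsMeasurement],
    references: Mapping[str, Seq[ReferenceCcs]],
    *,
    measured_units: str = "A2",
) -> list[CompactionRecord]:
    """Assemble one :class:`CompactionRecord` per (molecule, charge state).

    ``measurements`` come from the calibration stage (CCS in Å² by default;
    set ``measured_units="nm2"`` if already converted); ``references`` maps
    each molecule label to its reference list, in nm². Records are sorted by
    (molecule, z) so that the report is deterministic.

    Raises
    ------
    KeyError
        If any measured molecule has no reference entry; the message lists
        every offender.
    """
    measurements = list(measurements)
    missing = sorted({m.label for m in measurements} - set(references))
    if missing:
        raise KeyError(f"no references for molecule(s): {missing}")

    records = []
    for m in sorted(measurements, key=lambda m: (m.label, m.z)):
        refs = tuple(references[m.label])
        if not refs:
            raise KeyError(f"empty reference list for molecule {m.label!r}")
        measured_nm2 = area_unit_convert(m.estimated_ccs, measured_units, "nm2")
        pct = {r.label: percent_compaction(measured_nm2, r.ccs) for r in refs}
        records.append(
            CompactionRecord(
                molecule=m.label,
                z=m.z,
                measured_ccs=measured_nm2,
                references=refs,
                percent_compaction_vs=pct,
                nearest_reference=nearest_reference(measured_nm2, refs),
            )
        )
    return records


def _records_frame(records: Seq[CompactionRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        row: dict = {
            "molecule": rec.molecule,
            "charge": rec.z,
            "measured_ccs_nm2": round(rec.measured_ccs, 3),
        }
        for ref in rec.references:
            row[f"ref_{ref.label}_nm2"] = ref.ccs
            row[f"compaction_vs_{ref.label}_pct"] = round(
                rec.percent_compaction_vs[ref.label], 3
            )
        row["nearest_reference"] = rec.nearest_reference
        rows.append(row)
    return pd.DataFrame(rows)


def report_to_csv(records: Seq[CompactionRecord], target) -> None:
    _records_frame(records).to_csv(target, index=False)


def report_to_json(records: Seq[CompactionRecord]) -> list[dict]:
    """JSON-serialisable form of a report (list of plain dicts)."""
    out = []
    for rec in records:
        out.append(
            {
                "molecule": rec.molecule,
                "charge": rec.z,
                "measured_ccs_nm2": rec.measured_ccs,
                "references": [
                    {"label": r.label, "ccs_nm2": r.ccs, "provenance": r.provenance}
                    for r in rec.references
                ],
                "percent_compaction_vs": dict(rec.percent_compaction_vs),
                "nearest_reference": rec.nearest_reference,
            }
        )
    return out


def read_references_csv(source) -> dict[str, list[ReferenceCcs]]:
    """Read a reference table (columns molecule,label,ccs_nm2[,provenance])."""
    df = pd.read_csv(source)
    required = {"molecule", "label", "ccs_nm2"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"reference CSV missing columns: {sorted(missing)}")
    refs: dict[str, list[ReferenceCcs]] = {}
    for r in df.itertuples(index=False):
        prov = str(getattr(r, "provenance", "") or "")
        refs.setdefault(str(r.molecule), []).append(
            ReferenceCcs(str(r.label), float(r.ccs_nm2), prov)
        )
    return refs
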