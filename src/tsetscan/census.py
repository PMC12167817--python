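"""AP1-gated presence/absence census of trafficking-complex subunits.

Summarizes homologue detection evidence from many genome/transcriptome
libraries into per-taxon-group prevalence counts and sector classes.  A
library only enters the census if it passes a positive-control gate: at
least two subunits of the near-universal AP1 adaptor complex must have been
detected, which screens out libraries too incomplete to interpret an
absence.  Only detections that survived phylogenetic curation
(``validated``) count toward prevalence; unvalidated hits can be folded in
for sensitivity analysis.

The census substrate is a pair of long-format tables:

* a library manifest with columns
  ``library_id, species, taxon_group, lineage, data_type``;
* a detection table with columns
  ``library_id, panel, subunit, detected, validated``.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

import pandas as pd

from .errors import ConfigurationError, InputIntegrityError, UndefinedDenominatorError

TSET_PANEL = ("TSPOON", "TCUP", "TPLATE", "TSAUCER", "TTRAY1", "TTRAY2")
AP1_PANEL = ("AP1-beta", "AP1-gamma", "AP1-mu", "AP1-sigma")


class SectorClass(str, enum.Enum):
    """Prevalence class of a subunit within a taxon group.

    ``absent``   no AP1-positive library carries the subunit;
    ``single``   exactly one library does;
    ``minority`` more than one, but fewer than 50% of libraries;
    ``majority`` at least 50% of libraries (and more than one).
    """

    ABSENT = "absent"
    SINGLE = "single"
    MINORITY = "minority"
    MAJORITY = "majority"


@dataclass
class GroupSummary:
    """Per-taxon-group census result."""

    taxon_group: str
    n_libraries_total: int
    n_ap1_positive: int
    per_subunit_counts: dict[str, int]
    per_subunit_sector: dict[str, SectorClass | None]
    n_complete_complexes: int
    undefined: bool = False  # True when no library passed the AP1 gate


def detection_percentage(count: int, total: int) -> int:
    """Integer percentage ``100*count/total`` rounded half up.

    This is the rounding used for every prevalence ratio the census
    reports (e.g. 266/330 -> 81, 30/47 -> 64).
    """
    if total <= 0:
        raise UndefinedDenominatorError(f"total must be positive, got {total}")
    if count < 0 or count > total:
        raise InputIntegrityError(f"count {count} outside [0, {total}]")
    # exact integer round-half-up: floor(100*c/t + 1/2)
    return (200 * count + total) // (2 * total)


def verify_printed_percentage(count: int, total: int, printed: int) -> tuple[int, bool]:
    """Recompute a published percentage and flag a mismatch.

    Returns ``(recomputed, discrepant)``.  Used to audit percentages quoted
    alongside their raw counts; a flagged entry means the printed figure
    does not follow from the printed counts under round-half-up.
    """
    recomputed = detection_percentage(count, total)
    discrepant = recomputed != printed
    if discrepant:
        warnings.warn(
            f"printed percentage {printed}% disagrees with {count}/{total} "
            f"= {recomputed}% (round-half-up)",
            stacklevel=2,
        )
    return recomputed, discrepant


def sector_classify(count: int, total: int) -> SectorClass:
    """Classify a detection count into a prevalence sector.

    ``single`` takes precedence over the ratio rule: one detection out of
    one library is still ``single``, not ``majority``.
    """
    if total <= 0:
        raise UndefinedDenominatorError(f"total must be positive, got {total}")
    if count < 0 or count > total:
        raise InputIntegrityError(f"count {count} outside [0, {total}]")
    if count == 0:
        return SectorClass.ABSENT
    if count == 1:
        return SectorClass.SINGLE
    if count / total >= 0.5:
        return SectorClass.MAJORITY
    return SectorClass.MINORITY


def _validated_detections(
    detections: pd.DataFrame, include_unvalidated: bool
) -> pd.DataFrame:
    det = detections[detections["detected"].astype(bool)]
    if not include_unvalidated:
        det = det[det["validated"].astype(bool)]
    return det


def _check_libraries(detections: pd.DataFrame, known_ids: set[str]) -> None:
    unknown = set(detections["library_id"]) - known_ids
    if unknown:
        raise InputIntegrityError(
            f"detections reference unknown libraries: {sorted(unknown)[:5]}"
        )


def ap1_gate(
    detections: pd.DataFrame,
    library_ids: set[str] | list[str],
    control_panel: tuple[str, ...] | list[str] = AP1_PANEL,
    min_control_subunits: int = 2,
    include_unvalidated: bool = False,
) -> set[str]:
    """Return libraries with >= ``min_control_subunits`` distinct validated
    control-panel subunits.

    Libraries failing the gate are considered too incomplete for
    presence/absence inference and are dropped from all downstream counts.
    """
    if not control_panel:
        raise ConfigurationError("control panel must not be empty")
    if min_control_subunits < 1:
        raise ConfigurationError("min_control_subunits must be >= 1")
    known = set(library_ids)
    _check_libraries(detections, known)
    det = _validated_detections(detections, include_unvalidated)
    det = det[det["subunit"].isin(set(control_panel))]
    counts = det.groupby("library_id")["subunit"].nunique()
    return set(counts.index[counts >= min_control_subunits])


def complete_complex_count(
    detections: pd.DataFrame,
    panel: tuple[str, ...] | list[str],
    eligible: set[str],
    include_unvalidated: bool = False,
) -> int:
    """Number of eligible libraries carrying every panel subunit."""
    if not panel:
        raise ConfigurationError("panel must not be empty")
    det = _validated_detections(detections, include_unvalidated)
    det = det[det["subunit"].isin(set(panel)) & det["library_id"].isin(eligible)]
    counts = det.groupby("library_id")["subunit"].nunique()
    return int((counts == len(set(panel))).sum())


def summarize_groups(
    detections: pd.DataFrame,
    manifest: pd.DataFrame,
    panel: tuple[str, ...] | list[str] = TSET_PANEL,
    control_panel: tuple[str, ...] | list[str] = AP1_PANEL,
    min_control_subunits: int = 2,
    include_unvalidated: bool = False,
) -> list[GroupSummary]:
    """Aggregate the census per taxon group.

    Per-subunit counts and sectors are computed over AP1-positive libraries
    only; a group in which no library passes the gate is emitted with
    ``undefined=True`` and no sector classes, and a warning is issued.
    """
    if manifest["library_id"].duplicated().any():
        raise InputIntegrityError("duplicate library_id in manifest")
    known = set(manifest["library_id"])
    eligible = ap1_gate(
        detections,
        known,
        control_panel=control_panel,
        min_control_subunits=min_control_subunits,
        include_unvalidated=include_unvalidated,
    )
    det = _validated_detections(detections, include_unvalidated)
    det = det[det["subunit"].isin(set(panel)) & det["library_id"].isin(eligible)]
    lib_group = manifest.set_index("library_id")["taxon_group"]

    summaries: list[GroupSummary] = []
    for group, libs in manifest.groupby("taxon_group", sort=True):
        lib_ids = set(libs["library_id"])
        pos = lib_ids & eligible
        n_pos = len(pos)
        group_det = det[det["library_id"].isin(pos)]
        counts = {
            s: int(group_det[group_det["subunit"] == s]["library_id"].nunique())
            for s in panel
        }
        if n_pos == 0:
            warnings.warn(
                f"taxon group {group!r}: no AP1-positive libraries; "
                "sectors undefined",
                stacklevel=2,
            )
            sectors: dict[str, SectorClass | None] = {s: None for s in panel}
            n_complete = 0
        else:
            sectors = {s: sector_classify(counts[s], n_pos) for s in panel}
            n_complete = complete_complex_count(
                detections, panel, pos, include_unvalidated=include_unvalidated
            )
        summaries.append(
            GroupSummary(
                taxon_group=str(group),
                n_libraries_total=len(lib_ids),
                n_ap1_positive=n_pos,
                per_subunit_counts=counts,
                per_subunit_sector=sectors,
                n_complete_complexes=n_complete,
                undefined=(n_pos == 0),
            )
        )
    return summaries


def summary_frame(summaries: list[GroupSummary]) -> pd.DataFrame:
    """Flatten GroupSummary records to a writable table (one row per group)."""
    rows = []
    for s in summaries:
        row: dict[str, object] = {
            "taxon_group": s.taxon_group,
            "n_libraries_total": s.n_libraries_total,
            "n_ap1_positive": s.n_ap1_positive,
            "n_complete_complexes": s.n_complete_complexes,
            "undefined": s.undefined,
        }
        for sub, c in s.per_subunit_counts.items():
            row[f"count_{sub}"] = c
            sector = s.per_subunit_sector.get(sub)
            row[f"sector_{sub}"] = sector.value if sector is not None else ""
            row[f"percent_{sub}"] = (
                detection_percentage(c, s.n_ap1_positive) if s.n_ap1_positive else ""
            )
        rows.append(row)
    return pd.DataFrame(rows)
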