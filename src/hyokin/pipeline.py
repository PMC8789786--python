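"""Cohort-level orchestration shared by the CLI, tests and scripts.

Ties the per-recording stages together: landmark validation (exclusion
rule), kinematic extraction, group assignment, and assembly of the
per-recording kinematics table that the statistics and ROC layers consume.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .errors import DegenerateAxisError, HyokinError, NoMotionError
from .grouping import assign_group
from .kinematics import ExtractionConfig, extract_kinematics
from .landmarks import SwallowRecording, validate_recording

KINEMATICS_COLUMNS = (
    "recording_id", "group", "pas", "mbsimp_residue", "consistency",
    "Dx", "Dy", "Dxy", "duration", "Vx", "Vy", "Vxy", "onset", "offset",
)


@dataclass(frozen=True)
class ExtractionOutcome:
    """Per-recording kinematics table plus the exclusion/failure log."""

    table: pd.DataFrame
    exclusions: pd.DataFrame

    @property
    def n_included(self) -> int:
        return len(self.table)


def extract_table(
    recordings: Iterable[SwallowRecording],
    config: ExtractionConfig | None = None,
    max_missing_fraction: float = 0.2,
    min_complete_frames: int = 10,
) -> ExtractionOutcome:
    """Validate and extract every recording, collecting results and reasons.

    Recordings rejected by the landmark exclusion rule, or flagged by the
    motion detector, end up in the exclusion log with their reason instead of
    silently vanishing or contributing zeros.
    """
    cfg = config or ExtractionConfig()
    rows: list[dict] = []
    excluded: list[dict] = []
    for recording in recordings:
        rid = recording.meta.recording_id
        outcome = validate_recording(
            recording,
            max_missing_fraction=max_missing_fraction,
            min_complete_frames=min_complete_frames,
        )
        if not outcome.included:
            excluded.append(
                {"recording_id": rid, "stage": "validation", "reason": outcome.reason}
            )
            continue
        try:
            summary = extract_kinematics(outcome.recording, cfg)
        except (NoMotionError, DegenerateAxisError, HyokinError) as exc:
            excluded.append(
                {"recording_id": rid, "stage": "extraction", "reason": str(exc)}
            )
            continue
        meta = recording.meta
        rows.append({
            "recording_id": rid,
            "group": assign_group(meta.pas, meta.mbsimp_residue).value,
            "pas": meta.pas,
            "mbsimp_residue": meta.mbsimp_residue,
            "consistency": meta.consistency,
            **summary.as_dict(),
        })
    table = pd.DataFrame(rows, columns=list(KINEMATICS_COLUMNS))
    exclusions = pd.DataFrame(
        excluded, columns=["recording_id", "stage", "reason"]
    )
    return ExtractionOutcome(table=table, exclusions=exclusions)


def table_from_summaries(summaries: Sequence[dict]) -> pd.DataFrame:
    """Build a kinematics table from already-computed summary dictionaries."""
    return pd.DataFrame(list(summaries), columns=list(KINEMATICS_COLUMNS))
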