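"""Group assignment from PAS and MBSImP pharyngeal-residue scores.

Three clinically defined categories: *normal* swallows (PAS 1 with residue
component 0-1), *aspiration* (PAS 6-8, airway invasion below the vocal
folds), and *stasis* (residue component 2-4, pooling in the pyriform
sinuses).  Recordings meeting both the aspiration and the stasis criteria
are excluded from kinematic analysis rather than prioritized; PAS 2-5 with
low residue (penetration without aspiration) fits none of the three
definitions and is left unclassified.  Every (PAS, residue) cell of the
8 x 5 score grid maps to exactly one label.
"""

from __future__ import annotations

from enum import Enum

from .errors import ValidationError


class GroupLabel(str, Enum):
    NORMAL = "normal"
    ASPIRATION = "aspiration"
    STASIS = "stasis"
    UNCLASSIFIED = "unclassified"
    EXCLUDED_BOTH = "excluded_both"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Labels that enter group statistics and ROC analyses.
CLASSIFIED_LABELS = (GroupLabel.NORMAL, GroupLabel.ASPIRATION, GroupLabel.STASIS)


def assign_group(pas: int, mbsimp_residue: int) -> GroupLabel:
    """Assign the unique group label for a (PAS, residue) score pair."""
    if int(pas) != pas or not 1 <= pas <= 8:
        raise ValidationError(f"pas must be an integer in [1, 8], got {pas}")
    if int(mbsimp_residue) != mbsimp_residue or not 0 <= mbsimp_residue <= 4:
        raise ValidationError(
            f"mbsimp_residue must be an integer in [0, 4], got {mbsimp_residue}"
        )
    aspiration = 6 <= pas <= 8
    stasis = 2 <= mbsimp_residue <= 4
    if aspiration and stasis:
        return GroupLabel.EXCLUDED_BOTH
    if aspiration:
        return GroupLabel.ASPIRATION
    if stasis:
        return GroupLabel.STASIS
    if pas == 1:
        return GroupLabel.NORMAL
    return GroupLabel.UNCLASSIFIED
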