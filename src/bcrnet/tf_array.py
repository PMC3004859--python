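"""Transcription-factor array quantification and differential calling.

Each membrane carries one spot per TF consensus binding site plus control
spots on its border.  Spot intensities are normalized to the mean of the
border controls of the same plate; the stimulated/unstimulated ratio per
replicate is then thresholded.  A TF is called *activated* at a timepoint
only if its normalized ratio exceeds the fold threshold (strictly >2 by
default) in every replicate, and *suppressed* only if the ratio falls below
the reciprocal threshold in every replicate.  The overall label across
timepoints gives precedence to activation; a TF activated at one timepoint
and suppressed at another additionally carries a conflict flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

UP_THRESHOLD = 2.0

STATUS_ACTIVATED = "activated"
STATUS_SUPPRESSED = "suppressed"
STATUS_UNAFFECTED = "unaffected"


@dataclass
class TFArrayPlate:
    """One array membrane: condition, replicate index, TF spot intensities
    and border-control intensities."""

    condition: str
    replicate: int
    spots: dict[str, float]
    border_controls: list[float]

    def __post_init__(self) -> None:
        if not self.border_controls:
            raise ValueError("a plate requires at least one border control")
        if any(v < 0 for v in self.spots.values()) or any(
            v < 0 for v in self.border_controls
        ):
            raise ValueError("spot and control intensities must be non-negative")


@dataclass
class TFCall:
    tf_id: str
    fold_by_condition: dict[str, dict[int, float]]  # condition -> replicate -> fold
    status_by_condition: dict[str, str]
    overall_status: str
    conflict: bool = False


@dataclass
class TFCallTable:
    calls: list[TFCall]
    n_activated: int = field(init=False)
    n_suppressed: int = field(init=False)
    n_unaffected: int = field(init=False)

    def __post_init__(self) -> None:
        counts = {STATUS_ACTIVATED: 0, STATUS_SUPPRESSED: 0, STATUS_UNAFFECTED: 0}
        for c in self.calls:
            counts[c.overall_status] += 1
        self.n_activated = counts[STATUS_ACTIVATED]
        self.n_suppressed = counts[STATUS_SUPPRESSED]
        self.n_unaffected = counts[STATUS_UNAFFECTED]

    def status_of(self, tf_id: str) -> str:
        for c in self.calls:
            if c.tf_id == tf_id:
                return c.overall_status
        raise KeyError(tf_id)

    @property
    def modulated(self) -> set[str]:
        """TFs whose overall status is activated or suppressed."""
        return {
            c.tf_id for c in self.calls if c.overall_status != STATUS_UNAFFECTED
        }

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.calls:
            for cond, by_rep in sorted(c.fold_by_condition.items()):
                for rep, fold in sorted(by_rep.items()):
                    rows.append(
                        {
                            "tf_id": c.tf_id,
                            "condition": cond,
                            "replicate": rep,
                            "fold": fold,
                            "status": c.status_by_condition[cond],
                            "overall_status": c.overall_status,
                            "conflict": c.conflict,
                        }
                    )
        return pd.DataFrame(rows)


def normalize_plate(plate: TFArrayPlate) -> dict[str, float]:
    """Divide every spot by the arithmetic mean of the plate's border controls."""
    control_mean = float(np.mean(plate.border_controls))
    if control_mean <= 0:
        raise ValueError(
            f"mean border-control intensity is zero on plate "
            f"({plate.condition}, replicate {plate.replicate})"
        )
    return {tf: v / control_mean for tf, v in plate.spots.items()}


def _replicate_fold(
    stim_norm: dict[str, float], unstim_norm: dict[str, float], tf: str
) -> float:
    s, u = stim_norm[tf], unstim_norm[tf]
    if u == 0:
        if s == 0:
            logger.warning("TF %s has zero signal in both conditions; treated as fold 1", tf)
            return 1.0
        return float("inf")
    return s / u


def call_tf_changes(
    stim_plates: list[TFArrayPlate],
    unstim_plates: list[TFArrayPlate],
    up_threshold: float = UP_THRESHOLD,
    down_threshold: float | None = None,
    both_replicates: bool = True,
) -> TFCallTable:
    """Call every TF activated / suppressed / unaffected per timepoint.

    Stimulated plates may span several conditions (timepoints); each is
    compared against the unstimulated plate of the same replicate index.
    ``down_threshold`` defaults to the reciprocal of ``up_threshold``.

    Raises
    ------
    ValueError
        If the plates do not carry an identical TF set, or a stimulated
        replicate lacks an unstimulated partner.
    """
    if not stim_plates or not unstim_plates:
        raise ValueError("need at least one stimulated and one unstimulated plate")
    if down_threshold is None:
        down_threshold = 1.0 / up_threshold

    tf_sets = [set(p.spots) for p in stim_plates + unstim_plates]
    reference = tf_sets[0]
    for s in tf_sets[1:]:
        if s != reference:
            diff = sorted(reference ^ s)
            raise ValueError(f"TF sets differ across plates; offending IDs: {diff[:10]}")

    unstim_by_rep = {p.replicate: normalize_plate(p) for p in unstim_plates}
    conditions = sorted({p.condition for p in stim_plates})

    # condition -> replicate -> normalized spots
    stim_norm: dict[str, dict[int, dict[str, float]]] = {c: {} for c in conditions}
    for p in stim_plates:
        if p.replicate not in unstim_by_rep:
            raise ValueError(
                f"stimulated replicate {p.replicate} has no unstimulated partner"
            )
        stim_norm[p.condition][p.replicate] = normalize_plate(p)

    calls = []
    for tf in sorted(reference):
        fold_by_condition: dict[str, dict[int, float]] = {}
        status_by_condition: dict[str, str] = {}
        for cond in conditions:
            folds = {
                rep: _replicate_fold(norm, unstim_by_rep[rep], tf)
                for rep, norm in sorted(stim_norm[cond].items())
            }
            fold_by_condition[cond] = folds
            values = list(folds.values())
            agg = all if both_replicates else any
            if agg(f > up_threshold for f in values):
                status = STATUS_ACTIVATED
            elif agg(f < down_threshold for f in values):
                status = STATUS_SUPPRESSED
            else:
                status = STATUS_UNAFFECTED
            status_by_condition[cond] = status

        statuses = set(status_by_condition.values())
        conflict = STATUS_ACTIVATED in statuses and STATUS_SUPPRESSED in statuses
        if STATUS_ACTIVATED in statuses:
            overall = STATUS_ACTIVATED
        elif STATUS_SUPPRESSED in statuses:
            overall = STATUS_SUPPRESSED
        else:
            overall = STATUS_UNAFFECTED
        if conflict:
            logger.warning(
                "TF %s activated at one timepoint and suppressed at another", tf
            )
        calls.append(
            TFCall(
                tf_id=tf,
                fold_by_condition=fold_by_condition,
                status_by_condition=status_by_condition,
                overall_status=overall,
                conflict=conflict,
            )
        )
    return TFCallTable(calls=calls)


def plates_from_frame(frame: pd.DataFrame) -> list[TFArrayPlate]:
    """Build plates from a tidy CSV table with columns
    (tf_id, condition, replicate, intensity, is_border_control)."""
    required = {"tf_id", "condition", "replicate", "intensity", "is_border_control"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"plate table missing columns: {sorted(missing)}")
    plates = []
    for (cond, rep), grp in frame.groupby(["condition", "replicate"], sort=True):
        border = grp[grp.is_border_control.astype(bool)]
        spots = grp[~grp.is_border_control.astype(bool)]
        plates.append(
            TFArrayPlate(
                condition=str(cond),
                replicate=int(rep),
                spots={str(r.tf_id): float(r.intensity) for r in spots.itertuples()},
                border_controls=[float(v) for v in border.intensity],
            )
        )
    return plates


def plates_to_frame(plates: list[TFArrayPlate]) -> pd.DataFrame:
    rows = []
    for p in plates:
        for tf, v in sorted(p.spots.items()):
            rows.append(
                {
                    "tf_id": tf,
                    "condition": p.condition,
                    "replicate": p.replicate,
                    "intensity": v,
                    "is_border_control": False,
                }
            )
        for i, v in enumerate(p.border_controls):
            rows.append(
                {
                    "tf_id": f"BORDER{i:03d}",
                    "condition": p.condition,
                    "replicate": p.replicate,
                    "intensity": v,
                    "is_border_control": True,
                }
            )
    return pd.DataFrame(rows)
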