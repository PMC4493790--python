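"""Replicate QC and presence:absence allele-dosage scoring.

Each sample x locus is assayed by two TaqMan reactions run in replicate
(nominally five wells each): one detecting the occupied site (element
present) and one the empty site (element absent).  After per-well
efficiency QC, the relative dosage is

    R = E_bar ** (Ct_absent - Ct_present)

with E_bar the mean fold efficiency over all accepted reactions of both
assays, and Ct_* the mean Ct per assay.  R is then rescaled to a score out
of 10: presence = 10 R / (1 + R), absence = 10 - presence.  One-sided
amplification failures score 10:0 for the amplifying assay; a double
failure is inconclusive (in the lab it would trigger a template control).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .amplification import ABSENCE, PRESENCE, ReactionResult
from .errors import InvalidEfficiencyError, MalformedInputError


class QcFlag(enum.Enum):
    PASS = "pass"
    REPEAT_NEEDED = "repeat_needed"
    NOT_AMPLIFIED = "not_amplified"


class CallStatus(enum.Enum):
    OK = "ok"
    PRESENCE_ONLY = "presence_only"
    ABSENCE_ONLY = "absence_only"
    REPEAT_NEEDED = "repeat_needed"
    INCONCLUSIVE = "inconclusive"


@dataclass(frozen=True)
class QcThresholds:
    """Replicate acceptance rules.

    Defaults encode the published criteria: keep reactions with efficiency
    in [90, 110]%; require at least three survivors per assay; flag for
    repeat when the within-assay Ct spread exceeds 0.5 cycles AND the summed
    spread of both assays exceeds 0.75 cycles.
    """

    eff_min_pct: float = 90.0
    eff_max_pct: float = 110.0
    min_valid: int = 3
    max_ct_spread: float = 0.5
    max_total_spread: float = 0.75

    def __post_init__(self) -> None:
        if not self.eff_min_pct < self.eff_max_pct:
            raise MalformedInputError("eff_min_pct must be < eff_max_pct")
        if self.min_valid < 2:
            raise MalformedInputError("min_valid must be >= 2")
        if self.max_ct_spread <= 0 or self.max_total_spread <= 0:
            raise MalformedInputError("Ct spread thresholds must be positive")


@dataclass
class ReplicateSet:
    """All replicate wells of one assay for one sample x locus."""

    sample_id: str
    locus_id: str
    assay: str
    reactions: list[ReactionResult]

    def __post_init__(self) -> None:
        if not self.reactions:
            raise MalformedInputError("ReplicateSet must contain at least one reaction")
        for r in self.reactions:
            if (r.sample_id, r.locus_id, r.assay) != (self.sample_id, self.locus_id, self.assay):
                raise MalformedInputError(
                    f"reaction {r.well_id!r} does not belong to "
                    f"{self.sample_id}/{self.locus_id}/{self.assay}"
                )


@dataclass
class DosageCall:
    sample_id: str
    locus_id: str
    ratio_presence_over_absence: float | None
    presence_score: float | None
    absence_score: float | None
    avg_efficiency_fold: float
    status: CallStatus

    @property
    def avg_efficiency_pct(self) -> float:
        return (self.avg_efficiency_fold - 1.0) * 100.0


def qc_replicates(
    rep: ReplicateSet, thr: QcThresholds = QcThresholds()
) -> tuple[list[ReactionResult], QcFlag]:
    """Apply the efficiency band and minimum-replicate rules to one assay.

    Accepted reactions are the amplified wells with efficiency inside
    [eff_min_pct, eff_max_pct].  If nothing in the set amplified the flag is
    NOT_AMPLIFIED; if fewer than ``min_valid`` wells survive the band the
    assay must be repeated.  The Ct-spread rule is NOT applied here: it is a
    joint condition over both assays (see :func:`cross_assay_gate`).
    """
    amplified = [r for r in rep.reactions if r.amplified]
    if not amplified:
        return [], QcFlag.NOT_AMPLIFIED
    # tiny tolerance so float representation dust cannot flip a boundary well
    accepted = [
        r
        for r in amplified
        if thr.eff_min_pct - 1e-9 <= r.efficiency_pct <= thr.eff_max_pct + 1e-9
    ]
    if len(accepted) < thr.min_valid:
        return accepted, QcFlag.REPEAT_NEEDED
    return accepted, QcFlag.PASS


def ct_spread(reactions: Sequence[ReactionResult]) -> float:
    """Max - min of the Cts of the given reactions (0 for a single well)."""
    cts = [r.ct for r in reactions if r.ct is not None]
    if not cts:
        return 0.0
    return max(cts) - min(cts)


def cross_assay_gate(
    presence_spread: float, absence_spread: float, thr: QcThresholds = QcThresholds()
) -> QcFlag:
    """Joint Ct-reproducibility rule across the two assays.

    Repeat only when BOTH conditions hold: some assay's replicate spread
    exceeds ``max_ct_spread`` and the summed spread of the two assays
    exceeds ``max_total_spread``.
    """
    if presence_spread < 0 or absence_spread < 0:
        raise MalformedInputError("Ct spreads must be non-negative")
    wide = max(presence_spread, absence_spread) > thr.max_ct_spread
    total = presence_spread + absence_spread > thr.max_total_spread
    return QcFlag.REPEAT_NEEDED if (wide and total) else QcFlag.PASS


def compute_ratio(avg_eff_fold: float, avg_ct_absent: float, avg_ct_present: float) -> float:
    """Dosage ratio R = E**(Ct_absent - Ct_present).

    R > 1 means the presence assay saw more template (lower T).  ``avg_eff_fold``
    is the fold amplification per cycle pooled over both assays' accepted
    reactions and must exceed 1.
    """
    if not avg_eff_fold > 1.0:
        raise InvalidEfficiencyError(
            f"average fold efficiency must exceed 1, got {avg_eff_fold}"
        )
    return float(avg_eff_fold ** (avg_ct_absent - avg_ct_present))


def presence_fraction(ratio: float) -> float:
    """Unrounded presence score out of 10: 10 R / (1 + R)."""
    if ratio < 0:
        raise MalformedInputError("dosage ratio must be non-negative")
    return 10.0 * ratio / (1.0 + ratio)


def to_decile(ratio: float, ndigits: int = 1) -> tuple[float, float]:
    """Map a presence:absence ratio to (presence_score, absence_score).

    Scores sum to 10 and are reported to one decimal place by default
    (``ndigits=None`` leaves them unrounded).
    """
    p = presence_fraction(ratio)
    if ndigits is not None:
        p = round(p, ndigits)
    return p, 10.0 - p


def _one_sided_call(
    sample_id: str, locus_id: str, accepted: list[ReactionResult], amplifying: str
) -> DosageCall:
    eff = float(np.mean([r.efficiency_fold for r in accepted]))
    if amplifying == PRESENCE:
        return DosageCall(sample_id, locus_id, None, 10.0, 0.0, eff, CallStatus.PRESENCE_ONLY)
    return DosageCall(sample_id, locus_id, None, 0.0, 10.0, eff, CallStatus.ABSENCE_ONLY)


def call_dosage(
    presence: ReplicateSet,
    absence: ReplicateSet,
    thr: QcThresholds = QcThresholds(),
) -> DosageCall:
    """Full per-locus pipeline: QC both assays, gate, ratio, decile score."""
    if (presence.sample_id, presence.locus_id) != (absence.sample_id, absence.locus_id):
        raise MalformedInputError("presence/absence sets must share sample and locus")
    if presence.assay != PRESENCE or absence.assay != ABSENCE:
        raise MalformedInputError("replicate sets passed in the wrong assay order")
    sample_id, locus_id = presence.sample_id, presence.locus_id

    p_acc, p_flag = qc_replicates(presence, thr)
    a_acc, a_flag = qc_replicates(absence, thr)

    if p_flag is QcFlag.NOT_AMPLIFIED and a_flag is QcFlag.NOT_AMPLIFIED:
        return DosageCall(sample_id, locus_id, None, None, None, float("nan"), CallStatus.INCONCLUSIVE)
    if p_flag is QcFlag.NOT_AMPLIFIED:
        if a_flag is QcFlag.REPEAT_NEEDED:
            return DosageCall(sample_id, locus_id, None, None, None, float("nan"), CallStatus.REPEAT_NEEDED)
        if cross_assay_gate(0.0, ct_spread(a_acc), thr) is QcFlag.REPEAT_NEEDED:
            return DosageCall(sample_id, locus_id, None, None, None, float("nan"), CallStatus.REPEAT_NEEDED)
        return _one_sided_call(sample_id, locus_id, a_acc, ABSENCE)
    if a_flag is QcFlag.NOT_AMPLIFIED:
        if p_flag is QcFlag.REPEAT_NEEDED:
            return DosageCall(sample_id, locus_id, None, None, None, float("nan"), CallStatus.REPEAT_NEEDED)
        if cross_assay_gate(ct_spread(p_acc), 0.0, thr) is QcFlag.REPEAT_NEEDED:
            return DosageCall(sample_id, locus_id, None, None, None, float("nan"), CallStatus.REPEAT_NEEDED)
        return _one_sided_call(sample_id, locus_id, p_acc, PRESENCE)
    if p_flag is QcFlag.REPEAT_NEEDED or a_flag is QcFlag.REPEAT_NEEDED:
        return DosageCall(sample_id, locus_id, None, None, None, float("nan"), CallStatus.REPEAT_NEEDED)

    p_spread, a_spread = ct_spread(p_acc), ct_spread(a_acc)
    if cross_assay_gate(p_spread, a_spread, thr) is QcFlag.REPEAT_NEEDED:
        return DosageCall(sample_id, locus_id, None, None, None, float("nan"), CallStatus.REPEAT_NEEDED)

    # average efficiency pools accepted reactions across BOTH assays
    eff = float(np.mean([r.efficiency_fold for r in p_acc + a_acc]))
    ct_p = float(np.mean([r.ct for r in p_acc]))
    ct_a = float(np.mean([r.ct for r in a_acc]))
    ratio = compute_ratio(eff, ct_a, ct_p)
    p_score, a_score = to_decile(ratio)
    return DosageCall(sample_id, locus_id, ratio, p_score, a_score, eff, CallStatus.OK)


def replicate_sets_from_results(
    results: Iterable[ReactionResult],
) -> dict[tuple[str, str], dict[str, ReplicateSet]]:
    """Group per-well results into ReplicateSets keyed by (sample, locus)."""
    grouped: dict[tuple[str, str], dict[str, list[ReactionResult]]] = {}
    for r in results:
        grouped.setdefault((r.sample_id, r.locus_id), {}).setdefault(r.assay, []).append(r)
    out: dict[tuple[str, str], dict[str, ReplicateSet]] = {}
    for (sample, locus), by_assay in grouped.items():
        out[(sample, locus)] = {
            assay: ReplicateSet(sample, locus, assay, wells)
            for assay, wells in by_assay.items()
        }
    return out


def call_plate(
    results: Iterable[ReactionResult], thr: QcThresholds = QcThresholds()
) -> list[DosageCall]:
    """Dosage calls for every sample x locus present in a plate's results.

    A sample x locus with only one assay on the plate is treated as if the
    missing assay had not amplified.
    """
    calls: list[DosageCall] = []
    for (sample, locus), sets in sorted(replicate_sets_from_results(results).items()):
        presence = sets.get(PRESENCE) or _empty_set(sample, locus, PRESENCE)
        absence = sets.get(ABSENCE) or _empty_set(sample, locus, ABSENCE)
        calls.append(call_dosage(presence, absence, thr))
    return calls


def _empty_set(sample: str, locus: str, assay: str) -> ReplicateSet:
    placeholder = ReactionResult(
        well_id=f"{sample}:{locus}:{assay}:missing",
        sample_id=sample,
        locus_id=locus,
        assay=assay,
        baseline=float("nan"),
        efficiency_fold=float("nan"),
        window=None,
        fit_r2=0.0,
        ct=None,
        amplified=False,
    )
    return ReplicateSet(sample, locus, assay, [placeholder])


def calls_to_frame(calls: Sequence[DosageCall]) -> pd.DataFrame:
    """Tabulate dosage calls (one row per sample x locus)."""
    return pd.DataFrame(
        {
            "sample": [c.sample_id for c in calls],
            "locus": [c.locus_id for c in calls],
            "ratio": [c.ratio_presence_over_absence for c in calls],
            "presence_score": [c.presence_score for c in calls],
            "absence_score": [c.absence_score for c in calls],
            "avg_efficiency_pct": [c.avg_efficiency_pct for c in calls],
            "status": [c.status.value for c in calls],
        }
    )
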