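"""Synthetic qPCR plates with known allele dosage, and LTR pairs of known age.

The plate generator embodies the same dosage model the ratio equation
inverts: for a true dosage d out of 10 at fold efficiency E, the presence
and absence assays are given target Cts satisfying

    Ct_absent - Ct_present = log_E(d / (10 - d)),

so the analysis pipeline should recover a presence score of d.  Each well's
fluorescence follows a logistic ("sigmoid") curve

    F(c) = baseline + plateau / (1 + exp(-(c - c_mid)/s)),      s = 1/ln(E),

whose early phase grows exactly E-fold per cycle; c_mid is solved so the
baseline-corrected signal crosses 1.0 at the target Ct.  Noise enters as
per-well Ct jitter, per-well efficiency jitter, and multiplicative
fluorescence noise.  d = 0 or 10 makes the corresponding assay flat
baseline noise (the "failed to amplify in all replicates" case).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .amplification import (
    ABSENCE,
    DEFAULT_CT_THRESHOLD,
    DEFAULT_GROUND_CYCLES,
    PRESENCE,
    AmplificationCurve,
    analyze_plate,
)
from .dosage import CallStatus, DosageCall, QcThresholds, call_plate
from .errors import ConfigurationError
from .ltrdating import LTRPair

#: corrected-fluorescence level at which the generator pins the target Ct
_CT_REF_LEVEL = 1.0

_BASES = np.array(list("ACGT"))
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {
    "A": ("C", "T"),
    "G": ("C", "T"),
    "C": ("A", "G"),
    "T": ("A", "G"),
}


@dataclass(frozen=True)
class PlateScenario:
    """Ground truth and noise model for one simulated plate.

    ``samples`` maps each sample id to its true per-locus dosage d in
    [0, 10].  ``plate_offset_ct`` shifts the presence assay's Cts by a
    constant, emulating a systematic cross-plate / cross-machine offset;
    ``template_scale`` multiplies the template concentration and shifts
    both assays' Cts equally by -log_E(scale).
    """

    samples: tuple[tuple[str, Mapping[str, float]], ...]
    replicates: int = 5
    true_efficiency_fold: float = 2.0
    ct_noise_sd: float = 0.15
    efficiency_noise_sd_pct: float = 2.0
    fluor_noise_frac: float = 0.01
    baseline: float = 3.0
    plateau: float = 1000.0
    n_cycles: int = 40
    base_ct: float = 24.0
    template_scale: float = 1.0
    plate_offset_ct: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ConfigurationError("replicates must be >= 1")
        if not self.true_efficiency_fold > 1.0:
            raise ConfigurationError("true_efficiency_fold must exceed 1")
        if self.template_scale <= 0:
            raise ConfigurationError("template_scale must be positive")
        if self.plateau <= _CT_REF_LEVEL:
            raise ConfigurationError("plateau must exceed the Ct reference level")
        for sample, doses in self.samples:
            for locus, d in doses.items():
                if not 0.0 <= d <= 10.0:
                    raise ConfigurationError(
                        f"dosage {d} for {sample}/{locus} outside [0, 10]"
                    )

    @property
    def loci(self) -> tuple[str, ...]:
        seen: list[str] = []
        for _, doses in self.samples:
            for locus in doses:
                if locus not in seen:
                    seen.append(locus)
        return tuple(seen)

    def noiseless(self) -> "PlateScenario":
        return replace(
            self, ct_noise_sd=0.0, efficiency_noise_sd_pct=0.0, fluor_noise_frac=0.0
        )


@dataclass(frozen=True)
class LTRScenario:
    """Forward-simulation settings for LTR pairs of known insertion age."""

    n_pairs: int = 1
    length: int = 400
    age_years: float = 3.0e5
    rate: float = 1.3e-8
    titv: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pairs < 1 or self.length < 1:
            raise ConfigurationError("n_pairs and length must be positive")
        if self.age_years < 0 or self.rate <= 0 or self.titv <= 0:
            raise ConfigurationError("age, rate and titv must be positive")
        if 2.0 * self.rate * self.age_years >= 0.75:
            raise ConfigurationError(
                "expected divergence 2*rate*age must stay below 0.75 (pre-saturation)"
            )


def dosage_series_scenario(
    dosages: Sequence[float] = tuple(range(1, 10)),
    locus: str = "locus1",
    **kwargs,
) -> PlateScenario:
    """One-locus plate with one sample per requested true dosage."""
    samples = tuple((f"s{d:g}", {locus: float(d)}) for d in dosages)
    return PlateScenario(samples=samples, **kwargs)


def _well_curve(
    rng: np.random.Generator,
    scn: PlateScenario,
    target_ct: float | None,
) -> np.ndarray:
    """Fluorescence readings for one well; flat baseline when target_ct is None."""
    cycles = np.arange(1, scn.n_cycles + 1, dtype=float)
    if target_ct is None:
        f = np.full_like(cycles, scn.baseline)
    else:
        e_well = scn.true_efficiency_fold + rng.normal(0.0, scn.efficiency_noise_sd_pct / 100.0)
        ct_well = target_ct + rng.normal(0.0, scn.ct_noise_sd)
        s = 1.0 / math.log(e_well)
        u_ref = _CT_REF_LEVEL / (scn.plateau - _CT_REF_LEVEL)
        c_mid = ct_well - s * math.log(u_ref)
        u = np.exp((cycles - c_mid) / s)
        f = scn.baseline + scn.plateau * u / (1.0 + u)
    if scn.fluor_noise_frac > 0.0:
        f = f * (1.0 + rng.normal(0.0, scn.fluor_noise_frac, size=f.shape))
    return f


def simulate_plate(scn: PlateScenario) -> list[AmplificationCurve]:
    """Simulate every well of a plate; deterministic given the scenario seed."""
    rng = np.random.default_rng(scn.seed)
    e = scn.true_efficiency_fold
    log_e = math.log(e)
    shift = -math.log(scn.template_scale) / log_e
    curves: list[AmplificationCurve] = []
    for sample, doses in scn.samples:
        for locus, d in doses.items():
            ct_abs = scn.base_ct + shift
            if d <= 0.0:
                ct_pres = None
                ct_abs_target = ct_abs
            elif d >= 10.0:
                ct_pres = ct_abs + scn.plate_offset_ct
                ct_abs_target = None
            else:
                ct_pres = ct_abs - math.log(d / (10.0 - d)) / log_e + scn.plate_offset_ct
                ct_abs_target = ct_abs
            for assay, target in ((PRESENCE, ct_pres), (ABSENCE, ct_abs_target)):
                for rep in range(1, scn.replicates + 1):
                    well = f"{sample}:{locus}:{assay}:{rep}"
                    f = _well_curve(rng, scn, target)
                    curves.append(AmplificationCurve(sample, locus, assay, well, f))
    return curves


def plate_to_frame(curves: Sequence[AmplificationCurve]) -> pd.DataFrame:
    """Long-format table (sample, locus, assay, well, cycle, fluorescence)."""
    rows = []
    for c in curves:
        for cycle, f in zip(c.cycles, c.fluorescence):
            rows.append((c.sample_id, c.locus_id, c.assay, c.well_id, int(cycle), f))
    return pd.DataFrame(
        rows, columns=["sample", "locus", "assay", "well", "cycle", "fluorescence"]
    )


def simulate_ltr_pairs(scn: LTRScenario) -> list[LTRPair]:
    """LTR pairs diverged from a common ancestor under a K2P process.

    Each copy mutates independently with per-site substitution probability
    rate*age; a substitution is a transition with probability titv/(titv+1),
    otherwise one of the two transversions with equal probability.
    """
    rng = np.random.default_rng(scn.seed)
    p_sub = scn.rate * scn.age_years
    p_ti = scn.titv / (scn.titv + 1.0)
    pairs: list[LTRPair] = []
    for i in range(scn.n_pairs):
        ancestor = rng.choice(_BASES, size=scn.length)
        copies = []
        for _ in range(2):
            seq = ancestor.copy()
            hit = rng.random(scn.length) < p_sub
            for j in np.nonzero(hit)[0]:
                base = seq[j]
                if rng.random() < p_ti:
                    seq[j] = _TRANSITION[base]
                else:
                    seq[j] = _TRANSVERSIONS[base][rng.integers(0, 2)]
            copies.append("".join(seq))
        pairs.append(
            LTRPair(f"element{i + 1}", copies[0], copies[1], aligned=True)
        )
    return pairs


def score_plate(
    curves: Sequence[AmplificationCurve],
    qc: QcThresholds = QcThresholds(),
    ct_threshold: float = DEFAULT_CT_THRESHOLD,
    ground_cycles: int = DEFAULT_GROUND_CYCLES,
) -> list[DosageCall]:
    """Run the full amplification -> dosage pipeline on simulated curves."""
    return call_plate(
        analyze_plate(curves, ct_threshold=ct_threshold, ground_cycles=ground_cycles), qc
    )


_SCORED = (CallStatus.OK, CallStatus.PRESENCE_ONLY, CallStatus.ABSENCE_ONLY)


def _score_lookup(calls: Sequence[DosageCall]) -> dict[tuple[str, str], float]:
    return {
        (c.sample_id, c.locus_id): c.presence_score
        for c in calls
        if c.status in _SCORED
    }


def run_recovery_study(
    scn: PlateScenario,
    n_plates: int,
    qc: QcThresholds = QcThresholds(),
    ct_threshold: float = DEFAULT_CT_THRESHOLD,
) -> pd.DataFrame:
    """Dosage-recovery summary over repeated simulated plates.

    Plates are simulated in duplicate pairs (seeds scn.seed, scn.seed+1, ...)
    mirroring a two-plate reproducibility design: per dosage level the table
    reports the bias and RMSE of the presence score and the max/min/mean
    absolute cross-plate difference between paired replicates.
    """
    if n_plates < 2:
        raise ConfigurationError("n_plates must be >= 2")
    truth = {
        (sample, locus): d for sample, doses in scn.samples for locus, d in doses.items()
    }
    per_plate: list[dict[tuple[str, str], float]] = []
    for i in range(n_plates):
        plate = replace(scn, seed=scn.seed + i)
        per_plate.append(_score_lookup(score_plate(simulate_plate(plate), qc, ct_threshold)))

    rows = []
    by_dosage: dict[float, dict[str, list[float]]] = {}
    for key, d in truth.items():
        slot = by_dosage.setdefault(d, {"scores": [], "pair_diffs": []})
        for scores in per_plate:
            if key in scores:
                slot["scores"].append(scores[key])
        for a, b in zip(per_plate[0::2], per_plate[1::2]):
            if key in a and key in b:
                slot["pair_diffs"].append(abs(a[key] - b[key]))
    for d in sorted(by_dosage):
        scores = np.array(by_dosage[d]["scores"])
        diffs = np.array(by_dosage[d]["pair_diffs"])
        rows.append(
            {
                "dosage": d,
                "n_calls": scores.size,
                "mean_score": scores.mean() if scores.size else np.nan,
                "bias": scores.mean() - d if scores.size else np.nan,
                "rmse": float(np.sqrt(np.mean((scores - d) ** 2))) if scores.size else np.nan,
                "rep_diff_mean": diffs.mean() if diffs.size else np.nan,
                "rep_diff_min": diffs.min() if diffs.size else np.nan,
                "rep_diff_max": diffs.max() if diffs.size else np.nan,
            }
        )
    return pd.DataFrame(rows)


def threshold_sensitivity(
    scn: PlateScenario,
    n_plates: int,
    thresholds: Sequence[float] = (0.5, 1.0, 1.5),
    qc: QcThresholds = QcThresholds(),
) -> pd.DataFrame:
    """Score shifts induced by the Ct-threshold setting on identical plates.

    Each simulated plate is re-analysed at every threshold; per dosage level
    the table reports the mean and max of (max-min) score over thresholds.
    """
    truth = {
        (sample, locus): d for sample, doses in scn.samples for locus, d in doses.items()
    }
    ranges: dict[float, list[float]] = {}
    for i in range(n_plates):
        curves = simulate_plate(replace(scn, seed=scn.seed + i))
        per_thr = [_score_lookup(score_plate(curves, qc, thr)) for thr in thresholds]
        for key, d in truth.items():
            vals = [scores[key] for scores in per_thr if key in scores]
            if len(vals) == len(thresholds):
                ranges.setdefault(d, []).append(max(vals) - min(vals))
    rows = [
        {
            "dosage": d,
            "n": len(v),
            "range_mean": float(np.mean(v)),
            "range_max": float(np.max(v)),
        }
        for d, v in sorted(ranges.items())
    ]
    return pd.DataFrame(rows)
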