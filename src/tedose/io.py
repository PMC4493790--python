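"""Readers and writers for the delimited formats the pipeline exchanges.

All tables are plain CSV.  Plates arrive in long format (one row per well
per cycle, as instrument exports are commonly reshaped); per-well reaction
results and per-sample dosage calls are written one row per record.  LTR
pairs arrive as FASTA with record ids suffixed ``_5LTR`` / ``_3LTR``.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from .amplification import AmplificationCurve, ReactionResult
from .dosage import DosageCall, QcThresholds, calls_to_frame
from .errors import MalformedInputError
from .ltrdating import LTRPair

PLATE_COLUMNS = ["sample", "locus", "assay", "well", "cycle", "fluorescence"]


def read_plate_csv(path: str | Path) -> list[AmplificationCurve]:
    """Load a long-format plate table and validate per-well completeness.

    Every well must carry a contiguous cycle series starting at 1 and
    consistent sample/locus/assay labels.
    """
    df = pd.read_csv(path)
    missing = [c for c in PLATE_COLUMNS if c not in df.columns]
    if missing:
        raise MalformedInputError(f"plate table lacks columns {missing}")
    curves: list[AmplificationCurve] = []
    for well, grp in df.groupby("well", sort=True):
        grp = grp.sort_values("cycle")
        cycles = grp["cycle"].to_numpy()
        if cycles[0] != 1 or not np.array_equal(cycles, np.arange(1, len(cycles) + 1)):
            raise MalformedInputError(f"well {well!r}: cycles must run 1..C without gaps")
        for col in ("sample", "locus", "assay"):
            if grp[col].nunique() != 1:
                raise MalformedInputError(f"well {well!r}: inconsistent {col} labels")
        first = grp.iloc[0]
        curves.append(
            AmplificationCurve(
                sample_id=str(first["sample"]),
                locus_id=str(first["locus"]),
                assay=str(first["assay"]),
                well_id=str(well),
                fluorescence=grp["fluorescence"].to_numpy(dtype=float),
            )
        )
    return curves


def write_plate_csv(curves: Sequence[AmplificationCurve], path: str | Path) -> None:
    from .synth import plate_to_frame  # local import to avoid a cycle

    plate_to_frame(curves).to_csv(path, index=False)


def reactions_to_frame(results: Sequence[ReactionResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "well": [r.well_id for r in results],
            "sample": [r.sample_id for r in results],
            "locus": [r.locus_id for r in results],
            "assay": [r.assay for r in results],
            "baseline": [r.baseline for r in results],
            "efficiency_pct": [r.efficiency_pct for r in results],
            "ct": [r.ct for r in results],
            "r2": [r.fit_r2 for r in results],
            "amplified": [r.amplified for r in results],
            "window_start": [None if r.window is None else r.window[0] for r in results],
            "window_end": [None if r.window is None else r.window[1] for r in results],
        }
    )


def write_reactions_csv(results: Sequence[ReactionResult], path: str | Path) -> None:
    reactions_to_frame(results).to_csv(path, index=False)


def read_reactions_csv(path: str | Path) -> list[ReactionResult]:
    """Rebuild per-well results from a reactions table."""
    df = pd.read_csv(path)
    out: list[ReactionResult] = []
    for row in df.itertuples(index=False):
        eff_pct = float(row.efficiency_pct)
        ct = None if pd.isna(row.ct) else float(row.ct)
        window = (
            None
            if pd.isna(row.window_start)
            else (int(row.window_start), int(row.window_end))
        )
        out.append(
            ReactionResult(
                well_id=str(row.well),
                sample_id=str(row.sample),
                locus_id=str(row.locus),
                assay=str(row.assay),
                baseline=float(row.baseline),
                efficiency_fold=math.nan if math.isnan(eff_pct) else eff_pct / 100.0 + 1.0,
                window=window,
                fit_r2=float(row.r2),
                ct=ct,
                amplified=bool(row.amplified),
            )
        )
    return out


def write_calls_csv(calls: Sequence[DosageCall], path: str | Path) -> None:
    calls_to_frame(calls).to_csv(path, index=False)


def read_calls_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    needed = {"sample", "locus", "presence_score", "status"}
    missing = needed - set(df.columns)
    if missing:
        raise MalformedInputError(f"calls table lacks columns {sorted(missing)}")
    return df


def read_qc_yaml(path: str | Path) -> QcThresholds:
    """QC thresholds from a YAML mapping; absent keys keep their defaults."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    allowed = {"eff_min_pct", "eff_max_pct", "min_valid", "max_ct_spread", "max_total_spread"}
    unknown = set(data) - allowed
    if unknown:
        raise MalformedInputError(f"unknown QC keys {sorted(unknown)}")
    return QcThresholds(**data)


def read_ltr_fasta(path: str | Path) -> list[LTRPair]:
    """Pair _5LTR/_3LTR FASTA records into LTRPairs (unaligned)."""
    five: dict[str, str] = {}
    three: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        rid = rec.id
        if rid.endswith("_5LTR"):
            five[rid[: -len("_5LTR")]] = str(rec.seq)
        elif rid.endswith("_3LTR"):
            three[rid[: -len("_3LTR")]] = str(rec.seq)
        else:
            raise MalformedInputError(
                f"record {rid!r}: ids must end in _5LTR or _3LTR"
            )
    odd = set(five) ^ set(three)
    if odd:
        raise MalformedInputError(f"unpaired LTR records for elements {sorted(odd)}")
    return [
        LTRPair(element_id=eid, ltr5=five[eid], ltr3=three[eid]) for eid in sorted(five)
    ]
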