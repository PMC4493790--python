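"""Dating LTR-retrotransposon insertions from 5'/3' LTR divergence.

The two LTRs of an element are identical at insertion time and diverge
thereafter at the neutral substitution rate, so the Kimura two-parameter
distance k between them dates the insertion through the molecular clock

    T = k / (2 r)

with r the substitution rate per site per year (default 1.3e-8, a grass
nuclear rate; the factor 2 because both LTR copies accumulate changes).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import pandas as pd
from Bio import Align

from .errors import ConfigurationError, MalformedInputError, SaturationError

#: substitutions per site per year (plant nuclear neutral rate)
DEFAULT_RATE = 1.3e-8

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")
_UNAMBIGUOUS = frozenset("ACGT")


@dataclass(frozen=True)
class LTRPair:
    """A retroelement's 5' and 3' LTR sequences (optionally pre-aligned)."""

    element_id: str
    ltr5: str
    ltr3: str
    aligned: bool = False

    def __post_init__(self) -> None:
        for name, seq in (("ltr5", self.ltr5), ("ltr3", self.ltr3)):
            if not seq:
                raise MalformedInputError(f"{self.element_id}: empty {name} sequence")
            bad = set(seq.upper()) - set("ACGTN-")
            if bad:
                raise MalformedInputError(
                    f"{self.element_id}: invalid characters in {name}: {sorted(bad)}"
                )
        if self.aligned and len(self.ltr5) != len(self.ltr3):
            raise MalformedInputError(
                f"{self.element_id}: aligned sequences must have equal length"
            )
        object.__setattr__(self, "ltr5", self.ltr5.upper())
        object.__setattr__(self, "ltr3", self.ltr3.upper())


@dataclass(frozen=True)
class DivergenceResult:
    """K2P divergence between an element's LTRs and the implied insertion age."""

    element_id: str
    k: float  # substitutions per site
    P: float  # transition proportion
    Q: float  # transversion proportion
    sites_used: int
    T: float | None = None  # years
    r: float | None = None  # substitutions/site/year

    @property
    def T_mya(self) -> float | None:
        return None if self.T is None else self.T / 1e6


def align_ltrs(
    pair: LTRPair,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -5.0,
    gap_extend: float = -1.0,
) -> LTRPair:
    """Global (Needleman-Wunsch) pairwise alignment of the two LTRs.

    Affine gap costs; the first optimal alignment reported by the aligner
    is taken, which is deterministic for fixed parameters and input.
    Already-aligned pairs are returned unchanged.
    """
    if pair.aligned:
        return pair
    if min(len(pair.ltr5), len(pair.ltr3)) < 1:
        raise MalformedInputError(f"{pair.element_id}: empty sequence")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    aln = aligner.align(pair.ltr5, pair.ltr3)[0]
    return replace(pair, ltr5=str(aln[0]), ltr3=str(aln[1]), aligned=True)


def k2p_distance(pair: LTRPair) -> DivergenceResult:
    """Kimura two-parameter distance between the aligned LTRs.

    Transitions (P) and transversions (Q) are counted over columns where
    both sequences carry an unambiguous base (gap or N columns are dropped
    pairwise), then

        k = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q).

    Raises SaturationError when divergence is too high for the correction.
    """
    if not pair.aligned:
        raise MalformedInputError(f"{pair.element_id}: align the pair first")
    transitions = transversions = used = 0
    for x, y in zip(pair.ltr5, pair.ltr3):
        if x not in _UNAMBIGUOUS or y not in _UNAMBIGUOUS:
            continue
        used += 1
        if x == y:
            continue
        if (x in _PURINES and y in _PURINES) or (x in _PYRIMIDINES and y in _PYRIMIDINES):
            transitions += 1
        else:
            transversions += 1
    if used == 0:
        raise MalformedInputError(f"{pair.element_id}: no comparable sites")
    P = transitions / used
    Q = transversions / used
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        raise SaturationError(
            f"{pair.element_id}: divergence saturated (P={P:.3f}, Q={Q:.3f})"
        )
    k = -0.5 * math.log(w1) - 0.25 * math.log(w2) + 0.0  # +0.0 normalises -0.0
    return DivergenceResult(pair.element_id, k, P, Q, used)


def insertion_date(k: float, r: float = DEFAULT_RATE) -> float:
    """Molecular-clock insertion age in years: T = k / (2 r)."""
    if r <= 0:
        raise ConfigurationError("substitution rate must be positive")
    if k < 0:
        raise MalformedInputError("divergence k must be non-negative")
    return k / (2.0 * r)


def date_element(pair: LTRPair, rate: float = DEFAULT_RATE) -> DivergenceResult:
    """Align if needed, compute K2P divergence, and apply the clock."""
    aligned = align_ltrs(pair)
    div = k2p_distance(aligned)
    return replace(div, T=insertion_date(div.k, rate), r=rate)


def date_elements(pairs: Iterable[LTRPair], rate: float = DEFAULT_RATE) -> pd.DataFrame:
    """Insertion-age table for a collection of LTR pairs."""
    rows = []
    for pair in pairs:
        res = date_element(pair, rate)
        rows.append(
            {
                "element": res.element_id,
                "k": res.k,
                "P": res.P,
                "Q": res.Q,
                "sites": res.sites_used,
                "T_years": res.T,
                "T_mya": res.T_mya,
            }
        )
    return pd.DataFrame(rows)
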