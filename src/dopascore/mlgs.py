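"""The dopamine multilocus genetic score (MLGS).

Each of the four loci contributes 0, 0.5 or 1 point: 1 for the genotype
associated with low dopamine signaling, 0 for high signaling, and 0.5 for
intermediate heterozygotes where the heterozygote is treated as
intermediate.  The DRD2 -141C Ins/Del heterozygote scores 0 (Del carriers
are grouped with Del/Del).  Totals therefore range over {0, 0.5, ..., 4},
and are dichotomized at 2.0: totals >= 2.0 form the putatively
low-dopamine-signaling group.

The rs6277 (C957T) heterozygote admits two readings: 0.5 as an
intermediate genotype (default, ``rs6277_mode="het_half"``) or 1 under a
T-carrier reading (``rs6277_mode="t_carrier"``).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .genotype import DEFAULT_LOCI, GenotypeCall, Locus

__all__ = [
    "MLGS_LOCI",
    "DEFAULT_THRESHOLD",
    "SCORE_GRID",
    "SignalingGroup",
    "ScoringMap",
    "MLGSResult",
    "ScoreFrequencyTable",
    "default_scoring_maps",
    "score_locus",
    "compute_mlgs",
    "dichotomize",
    "score_frequency_table",
]

#: loci entering the score, in reporting order
MLGS_LOCI: tuple[str, ...] = ("rs1800497", "rs1799732", "rs6277", "rs4680")

DEFAULT_THRESHOLD: float = 2.0

#: attainable totals: 0 to 4 in half-point steps
SCORE_GRID: tuple[float, ...] = tuple(i / 2 for i in range(9))

_VALID_SCORES = (0.0, 0.5, 1.0)


class SignalingGroup(str, enum.Enum):
    """Dichotomized dopamine-signaling group."""

    LOW = "low_signaling"     # MLGS >= threshold
    HIGH = "high_signaling"   # MLGS < threshold
    UNDEFINED = "undefined"   # incomplete genotyping


@dataclass(frozen=True)
class ScoringMap:
    """Per-locus genotype-class scores, each in {0, 0.5, 1}, monotone."""

    rsid: str
    score_low_hom: float
    score_het: float
    score_high_hom: float

    def __post_init__(self) -> None:
        for s in (self.score_low_hom, self.score_het, self.score_high_hom):
            if s not in _VALID_SCORES:
                raise ValueError(f"{self.rsid}: score {s} not in {{0, 0.5, 1}}")
        if not self.score_low_hom >= self.score_het >= self.score_high_hom:
            raise ValueError(f"{self.rsid}: scores must decrease from low/low to high/high")

    def score_for_class(self, genotype_class: str) -> float:
        return {
            "low_hom": self.score_low_hom,
            "het": self.score_het,
            "high_hom": self.score_high_hom,
        }[genotype_class]


def default_scoring_maps(rs6277_mode: str = "het_half") -> dict[str, ScoringMap]:
    """Scoring maps for the four loci.

    ``rs6277_mode`` selects the C957T heterozygote convention:
    ``"het_half"`` scores C/T as 0.5, ``"t_carrier"`` scores any T carrier 1.
    """
    if rs6277_mode not in ("het_half", "t_carrier"):
        raise ValueError(f"unknown rs6277_mode {rs6277_mode!r}")
    return {
        "rs1800497": ScoringMap("rs1800497", 1.0, 0.5, 0.0),
        "rs1799732": ScoringMap("rs1799732", 1.0, 0.0, 0.0),
        "rs6277": ScoringMap(
            "rs6277", 1.0, 0.5 if rs6277_mode == "het_half" else 1.0, 0.0
        ),
        "rs4680": ScoringMap("rs4680", 1.0, 0.5, 0.0),
    }


def score_locus(
    call: GenotypeCall, smap: ScoringMap, locus: Optional[Locus] = None
) -> Optional[float]:
    """Score one call against its locus map; MISSING propagates as None."""
    if call.rsid != smap.rsid:
        raise ValueError(f"call at {call.rsid} scored with map for {smap.rsid}")
    if locus is None:
        locus = DEFAULT_LOCI[smap.rsid]
    if call.is_missing:
        return None
    return smap.score_for_class(call.genotype_class(locus))


@dataclass(frozen=True)
class MLGSResult:
    """Per-subject multilocus score: per-locus parts, total and group."""

    subject_id: object
    per_locus: Mapping[str, Optional[float]]
    total: Optional[float]
    group: SignalingGroup

    @property
    def is_complete(self) -> bool:
        return self.total is not None


def dichotomize(
    total: Optional[float], threshold: float = DEFAULT_THRESHOLD
) -> SignalingGroup:
    """Split totals at the threshold (inclusive: total >= threshold is LOW)."""
    if total is None:
        return SignalingGroup.UNDEFINED
    return SignalingGroup.LOW if total >= threshold else SignalingGroup.HIGH


def compute_mlgs(
    calls: Iterable[GenotypeCall],
    maps: Optional[Mapping[str, ScoringMap]] = None,
    threshold: float = DEFAULT_THRESHOLD,
    subject_id: object = None,
    loci: Optional[Mapping[str, Locus]] = None,
) -> MLGSResult:
    """Additive MLGS over the four loci, complete-case.

    Exactly one call per MLGS locus is required (missing calls allowed).
    If any locus is missing the total and group are undefined — subjects
    must be genotyped at all four loci to enter score-grouped analyses.
    """
    if maps is None:
        maps = default_scoring_maps()
    if loci is None:
        loci = DEFAULT_LOCI

    by_rsid: dict[str, GenotypeCall] = {}
    for call in calls:
        if call.rsid in by_rsid:
            raise ValueError(f"duplicate call for {call.rsid}")
        if call.rsid not in MLGS_LOCI:
            raise ValueError(f"{call.rsid} is not an MLGS locus")
        by_rsid[call.rsid] = call
    absent = [rsid for rsid in MLGS_LOCI if rsid not in by_rsid]
    if absent:
        raise ValueError(f"missing call(s) for {', '.join(absent)}")

    per_locus = {
        rsid: score_locus(by_rsid[rsid], maps[rsid], loci[rsid]) for rsid in MLGS_LOCI
    }
    if any(score is None for score in per_locus.values()):
        total: Optional[float] = None
    else:
        total = float(sum(per_locus.values()))
    return MLGSResult(subject_id, per_locus, total, dichotomize(total, threshold))


@dataclass(frozen=True)
class ScoreFrequencyTable:
    """Distribution of MLGS totals over the nine attainable categories."""

    counts: Mapping[float, int]
    n: int
    threshold: float

    @property
    def percentages(self) -> dict[float, float]:
        return {s: 100.0 * c / self.n for s, c in self.counts.items()}

    @property
    def n_at_or_above(self) -> int:
        return sum(c for s, c in self.counts.items() if s >= self.threshold)

    @property
    def pct_at_or_above(self) -> float:
        return 100.0 * self.n_at_or_above / self.n

    def rounded_percentages(self, ndigits: int = 1) -> dict[float, float]:
        # round-half-even, matching Python's round
        return {s: round(p, ndigits) for s, p in self.percentages.items()}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "score": list(SCORE_GRID),
                "n": [self.counts[s] for s in SCORE_GRID],
                "percent": [self.percentages[s] for s in SCORE_GRID],
            }
        )


def score_frequency_table(
    results: Iterable[MLGSResult], threshold: float = DEFAULT_THRESHOLD
) -> ScoreFrequencyTable:
    """Tabulate complete-case totals over the score grid."""
    counts = {s: 0 for s in SCORE_GRID}
    n = 0
    for res in results:
        if res.total is None:
            continue
        if res.total not in counts:
            raise ValueError(f"total {res.total} outside the 0-4 half-point grid")
        counts[res.total] += 1
        n += 1
    if n == 0:
        raise ValueError("no complete-case MLGS totals to tabulate")
    return ScoreFrequencyTable(counts, n, threshold)
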