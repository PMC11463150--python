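"""Genotype representation, parsing, counting and Hardy-Weinberg testing.

The package works with four biallelic dopamine-pathway variants:

* rs1800497 (ANKK1 Taq1A, alleles A1/A2, A1 also written T),
* rs1799732 (DRD2 -141C Ins/Del, Ins also written G),
* rs6277 (DRD2 C957T, alleles T/C),
* rs4680 (COMT Val158Met, alleles Met/Val, also written A/G).

For each locus one allele is conventionally associated with *low* dopamine
signaling (A1, Ins, T, Met) and the other with *high* signaling.  Genotypes
are handled purely at the assay-label level: no strand resolution or
sequence-level normalisation is attempted, and textual synonyms ("G" for
Ins, "T" for A1) are resolved through per-locus synonym maps.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from scipy import stats

__all__ = [
    "GenotypeParseError",
    "Locus",
    "GenotypeCall",
    "LocusCountTable",
    "HWEResult",
    "DEFAULT_LOCI",
    "MISSING_TOKENS",
    "parse_genotype",
    "count_genotypes",
    "allele_frequency",
    "hwe_chi_square",
]

#: accepted spellings (lowercased) of a wholly missing genotype call
MISSING_TOKENS = frozenset({"", ".", "na", "n/a", "nan", "none", "missing", "./."})

_ALLELE_SEP = re.compile(r"[/|]")


class GenotypeParseError(ValueError):
    """A genotype string could not be resolved against a locus definition."""


@dataclass(frozen=True)
class Locus:
    """A biallelic locus with a low/high dopamine-signaling allele convention.

    Parameters
    ----------
    rsid : str
        dbSNP identifier, e.g. ``"rs1800497"``.
    gene_label : str
        Gene the variant is reported under (ANKK1, DRD2, COMT).
    allele_low, allele_high : str
        Canonical labels of the allele associated with low respectively high
        dopamine signaling.  Must differ.
    synonyms : mapping, optional
        Extra accepted spellings mapped to a canonical allele; matching is
        case-insensitive.  The canonical labels themselves are always
        accepted.
    """

    rsid: str
    gene_label: str
    allele_low: str
    allele_high: str
    synonyms: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.allele_low == self.allele_high:
            raise ValueError(f"{self.rsid}: the two alleles must differ")
        table = {str(k).lower(): v for k, v in self.synonyms.items()}
        table.setdefault(self.allele_low.lower(), self.allele_low)
        table.setdefault(self.allele_high.lower(), self.allele_high)
        for spelling, allele in table.items():
            if allele not in (self.allele_low, self.allele_high):
                raise ValueError(
                    f"{self.rsid}: synonym {spelling!r} maps to unknown allele {allele!r}"
                )
        object.__setattr__(self, "synonyms", table)

    @property
    def alleles(self) -> tuple[str, str]:
        return (self.allele_low, self.allele_high)

    def canonical_allele(self, token: str) -> Optional[str]:
        """Resolve one allele spelling to its canonical label (or None)."""
        return self.synonyms.get(str(token).strip().lower())


#: the four study loci, keyed by rsID
DEFAULT_LOCI: dict[str, Locus] = {
    "rs1800497": Locus(
        "rs1800497", "ANKK1", "A1", "A2", synonyms={"t": "A1", "c": "A2"}
    ),
    "rs1799732": Locus(
        "rs1799732", "DRD2", "Ins", "Del", synonyms={"g": "Ins", "-": "Del"}
    ),
    "rs6277": Locus("rs6277", "DRD2", "T", "C"),
    "rs4680": Locus(
        "rs4680", "COMT", "Met", "Val", synonyms={"a": "Met", "g": "Val"}
    ),
}


@dataclass(frozen=True)
class GenotypeCall:
    """A canonical, unordered diploid call at one locus.

    ``alleles`` stores the two canonical allele labels with the
    low-signaling allele first, or ``None`` for a wholly missing call
    (partial calls are not representable: a call is either complete or
    missing).
    """

    rsid: str
    alleles: Optional[tuple[str, str]]

    @property
    def is_missing(self) -> bool:
        return self.alleles is None

    def n_low(self, locus: Locus) -> int:
        """Number of low-signaling alleles carried (0, 1 or 2)."""
        self._check_locus(locus)
        return sum(a == locus.allele_low for a in self.alleles)

    def genotype_class(self, locus: Locus) -> str:
        """Classify as ``"low_hom"``, ``"het"`` or ``"high_hom"``."""
        return ("high_hom", "het", "low_hom")[self.n_low(locus)]

    def _check_locus(self, locus: Locus) -> None:
        if locus.rsid != self.rsid:
            raise ValueError(f"call at {self.rsid} classified against {locus.rsid}")
        if self.is_missing:
            raise ValueError(f"{self.rsid}: missing call has no genotype class")

    def __str__(self) -> str:
        if self.is_missing:
            return "NA"
        return "/".join(self.alleles)


def _split_joined(text: str, locus: Locus) -> Optional[tuple[str, str]]:
    # "A1A2", "GG", "MetVal": greedy split on known spellings, longest first
    lowered = text.lower()
    for spelling in sorted(locus.synonyms, key=len, reverse=True):
        if lowered.startswith(spelling):
            rest = lowered[len(spelling):]
            if rest in locus.synonyms:
                return locus.synonyms[spelling], locus.synonyms[rest]
    return None


def parse_genotype(raw: object, locus: Locus) -> GenotypeCall:
    """Parse a textual genotype (e.g. ``"A2/A1"``, ``"G/Del"``, ``"TT"``).

    Separators ``/`` and ``|`` are accepted, as are joined spellings such
    as ``"A1A2"``.  Empty strings and common NA sentinels yield a MISSING
    call.  Allele order is canonicalized (low-signaling allele first), so
    ``"A2/A1"`` and ``"A1/A2"`` parse identically.

    Raises
    ------
    GenotypeParseError
        If an allele token cannot be resolved for this locus.
    """
    if raw is None:
        return GenotypeCall(locus.rsid, None)
    text = str(raw).strip()
    if text.lower() in MISSING_TOKENS:
        return GenotypeCall(locus.rsid, None)

    tokens = [t.strip() for t in _ALLELE_SEP.split(text) if t.strip()]
    if len(tokens) == 1:
        joined = _split_joined(tokens[0], locus)
        if joined is None:
            raise GenotypeParseError(
                f"{locus.rsid}: cannot split genotype {text!r} into two alleles"
            )
        alleles = joined
    elif len(tokens) == 2:
        resolved = []
        for tok in tokens:
            allele = locus.canonical_allele(tok)
            if allele is None:
                raise GenotypeParseError(
                    f"{locus.rsid}: unrecognised allele {tok!r} in {text!r}"
                )
            resolved.append(allele)
        alleles = tuple(resolved)
    else:
        raise GenotypeParseError(
            f"{locus.rsid}: expected two alleles, got {len(tokens)} in {text!r}"
        )

    ordered = tuple(sorted(alleles, key=lambda a: a != locus.allele_low))
    return GenotypeCall(locus.rsid, ordered)


@dataclass(frozen=True)
class LocusCountTable:
    """Genotype-class counts at one locus (non-missing calls partitioned)."""

    rsid: str
    n_low_hom: int
    n_het: int
    n_high_hom: int
    n_missing: int = 0

    def __post_init__(self) -> None:
        for name in ("n_low_hom", "n_het", "n_high_hom", "n_missing"):
            if getattr(self, name) < 0:
                raise ValueError(f"{self.rsid}: negative count {name}")

    @property
    def n_typed(self) -> int:
        return self.n_low_hom + self.n_het + self.n_high_hom

    @property
    def observed(self) -> tuple[int, int, int]:
        return (self.n_low_hom, self.n_het, self.n_high_hom)


def count_genotypes(calls: Iterable[GenotypeCall], locus: Locus) -> LocusCountTable:
    """Tally genotype classes over calls at a single locus."""
    n = [0, 0, 0]  # high_hom, het, low_hom indexed by n_low
    n_missing = 0
    for call in calls:
        if call.rsid != locus.rsid:
            raise ValueError(
                f"mixed-locus input: call at {call.rsid} counted against {locus.rsid}"
            )
        if call.is_missing:
            n_missing += 1
        else:
            n[call.n_low(locus)] += 1
    return LocusCountTable(locus.rsid, n[2], n[1], n[0], n_missing)


def allele_frequency(counts: LocusCountTable) -> float:
    """Frequency of the low-signaling allele among non-missing calls."""
    total = counts.n_typed
    if total == 0:
        raise ValueError(f"{counts.rsid}: allele frequency undefined with no typed calls")
    return (2 * counts.n_low_hom + counts.n_het) / (2 * total)


@dataclass(frozen=True)
class HWEResult:
    """Pearson goodness-of-fit test of Hardy-Weinberg proportions.

    Expected counts are n*p^2, 2npq, n*q^2 with p estimated from the data;
    df = 1 (three classes, one estimated parameter).  ``applicable`` is
    False for monomorphic loci, where the test degenerates (chi2 = 0 by
    convention).
    """

    rsid: str
    p_low: float
    observed: tuple[int, int, int]
    expected: tuple[float, float, float]
    chi2: float
    df: int
    p_value: float
    applicable: bool = True


def hwe_chi_square(counts: LocusCountTable) -> HWEResult:
    """Hardy-Weinberg goodness-of-fit X^2 on a three-class count table."""
    n = counts.n_typed
    if n < 1:
        raise ValueError(f"{counts.rsid}: HWE test needs at least one typed call")
    p = allele_frequency(counts)
    q = 1.0 - p
    expected = (n * p * p, 2 * n * p * q, n * q * q)
    if p in (0.0, 1.0):
        return HWEResult(
            counts.rsid, p, counts.observed, expected, 0.0, 1, 1.0, applicable=False
        )
    chi2 = sum(
        (o - e) ** 2 / e for o, e in zip(counts.observed, expected)
    )
    p_value = float(stats.chi2.sf(chi2, df=1))
    return HWEResult(counts.rsid, p, counts.observed, expected, float(chi2), 1, p_value)
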