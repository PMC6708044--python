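"""Coordinates, map functions and interval algebra shared by all stages.

Physical positions follow the wheat RefSeq v1.0 convention: 1-based,
inclusive, in base pairs.  Two width conventions coexist in the fine-mapping
literature and both are supported explicitly:

* ``between_markers`` — the distance between two marker positions,
  ``end - start``.  This is the convention behind candidate-interval sizes
  such as "an 87-kb region between markers X and Y".
* ``inclusive_feature`` — the length of a sequence feature whose first and
  last base are both part of the feature, ``end - start + 1``.  This is the
  convention behind deletion lengths (a deletion spanning -599..-485
  relative to the start codon removes 115 bp).

Genetic distances are handled with the Kosambi (default, moderate positive
interference) and Haldane (no interference) map functions, plus the
standard recombination-fraction expansion for selfed recombinant inbred
lines, R = 2r / (1 + 2r).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Literal, Sequence

import numpy as np
import pandas as pd

#: Genotype call alphabet: parent-1 homozygote, heterozygote, parent-2
#: homozygote, missing.
GENOTYPE_CODES = ("A", "H", "B", "-")
MISSING = "-"

#: Integer encoding used internally: A=0, H=1, B=2, missing=-1.
CODE_TO_INT = {"A": 0, "H": 1, "B": 2, "-": -1}
INT_TO_CODE = {v: k for k, v in CODE_TO_INT.items()}

WidthConvention = Literal["between_markers", "inclusive_feature"]
MapKind = Literal["kosambi", "haldane"]


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero at the printed precision.

    Python's builtin ``round`` uses banker's rounding; published interval
    sizes use conventional half-up rounding, so widths are formatted with
    this helper.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class Marker:
    """A mapped marker with a physical and (optionally) genetic position."""

    name: str
    chrom: str
    pos_bp: int
    pos_cM: float | None = None

    def __post_init__(self) -> None:
        if self.pos_bp < 1:
            raise ValueError(
                f"marker {self.name}: pos_bp must be >= 1 (1-based physical "
                f"coordinates), got {self.pos_bp}"
            )
        if self.pos_cM is not None and not math.isfinite(self.pos_cM):
            raise ValueError(f"marker {self.name}: pos_cM must be finite")


@dataclass(frozen=True)
class GenomicInterval:
    """A 1-based inclusive interval on one chromosome.

    ``kind`` records which width convention is natural for the interval:
    ``marker_bounded`` intervals are delimited by marker positions and
    report ``end - start``; ``feature`` intervals are sequence features and
    report ``end - start + 1``.
    """

    chrom: str
    start_bp: int
    end_bp: int
    kind: Literal["marker_bounded", "feature"] = "marker_bounded"

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError(
                f"invalid interval on {self.chrom}: start {self.start_bp} > "
                f"end {self.end_bp}"
            )

    @property
    def default_convention(self) -> WidthConvention:
        return "inclusive_feature" if self.kind == "feature" else "between_markers"

    def width_bp(self, convention: WidthConvention | None = None) -> int:
        return interval_width(self, convention or self.default_convention)

    def contains_pos(self, chrom: str, pos_bp: float) -> bool:
        return chrom == self.chrom and self.start_bp <= pos_bp <= self.end_bp

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            other.chrom == self.chrom
            and self.start_bp <= other.start_bp
            and other.end_bp <= self.end_bp
        )

    def intersect(self, other: "GenomicInterval") -> "GenomicInterval | None":
        """Pairwise intersection; ``None`` when empty (incl. different chroms)."""
        if other.chrom != self.chrom:
            return None
        lo = max(self.start_bp, other.start_bp)
        hi = min(self.end_bp, other.end_bp)
        if lo > hi:
            return None
        return GenomicInterval(self.chrom, lo, hi, kind=self.kind)

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.intersect(other) is not None


def interval_width(interval: GenomicInterval, convention: WidthConvention) -> int:
    """Width of an interval in bp under an explicit convention."""
    if convention == "between_markers":
        return interval.end_bp - interval.start_bp
    if convention == "inclusive_feature":
        return interval.end_bp - interval.start_bp + 1
    raise ValueError(f"unknown width convention: {convention!r}")


def feature_length(start: int, end: int) -> int:
    """Length of a sequence feature given first/last coordinate (inclusive).

    Coordinates may be negative (promoter positions upstream of the start
    codon are conventionally negative); only their span matters.
    """
    if end < start:
        start, end = end, start
    return end - start + 1


def format_width(width_bp: int) -> str:
    """Render a width the way interval sizes are printed in the literature.

    >= 1 Mb: one decimal in Mb ("8.7 Mb"); >= 1 kb: integer kb ("87 kb");
    otherwise bp.  Rounding is half-up at the printed precision.
    """
    if width_bp >= 1_000_000:
        mb = Decimal(width_bp) / Decimal(1_000_000)
        return f"{mb.quantize(Decimal('0.1'), rounding=ROUND_HALF_UP)} Mb"
    if width_bp >= 1_000:
        kb = Decimal(width_bp) / Decimal(1_000)
        return f"{int(kb.quantize(Decimal('1'), rounding=ROUND_HALF_UP))} kb"
    return f"{width_bp} bp"


def intersect_intervals(intervals: Sequence[GenomicInterval]) -> GenomicInterval | None:
    """Intersection of a non-empty collection of same-chromosome intervals.

    Returns ``None`` when the common intersection is empty.  Associative and
    commutative: equal to any fold of pairwise intersections.
    """
    if not intervals:
        raise ValueError("intersect_intervals requires at least one interval")
    chroms = {iv.chrom for iv in intervals}
    if len(chroms) > 1:
        raise ValueError(f"intervals span multiple chromosomes: {sorted(chroms)}")
    lo = max(iv.start_bp for iv in intervals)
    hi = min(iv.end_bp for iv in intervals)
    if lo > hi:
        return None
    return GenomicInterval(intervals[0].chrom, lo, hi, kind=intervals[0].kind)


# ---------------------------------------------------------------------------
# Map functions
# ---------------------------------------------------------------------------

def _check_r(r: float) -> None:
    if not 0.0 <= r < 0.5:
        raise ValueError(f"recombination fraction must be in [0, 0.5), got {r}")


def haldane_to_cM(r: float) -> float:
    """Haldane map distance in cM for recombination fraction ``r``."""
    _check_r(r)
    return -50.0 * math.log(1.0 - 2.0 * r)


def haldane_from_cM(d: float) -> float:
    """Recombination fraction for a Haldane distance ``d`` in cM."""
    if d < 0:
        raise ValueError("map distance must be non-negative")
    return 0.5 * (1.0 - math.exp(-d / 50.0))


def kosambi_to_cM(r: float) -> float:
    """Kosambi map distance in cM for recombination fraction ``r``."""
    _check_r(r)
    return 25.0 * math.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))


def kosambi_from_cM(d: float) -> float:
    """Recombination fraction for a Kosambi distance ``d`` in cM."""
    if d < 0:
        raise ValueError("map distance must be non-negative")
    return 0.5 * math.tanh(d / 50.0)


_MAP_FUNCS = {
    ("kosambi", "to_cM"): kosambi_to_cM,
    ("kosambi", "from_cM"): kosambi_from_cM,
    ("haldane", "to_cM"): haldane_to_cM,
    ("haldane", "from_cM"): haldane_from_cM,
}


def map_function(
    value: float,
    direction: Literal["to_cM", "from_cM"] = "to_cM",
    kind: MapKind = "kosambi",
    ril_expansion_flag: bool = False,
) -> float:
    """Convert between recombination fraction and cM under a map function.

    With ``ril_expansion_flag`` and ``direction='to_cM'`` the input fraction
    is first expanded to the selfed-RIL scale R = 2r/(1+2r); with
    ``direction='from_cM'`` the output fraction is expanded after inversion.
    """
    try:
        func = _MAP_FUNCS[(kind, direction)]
    except KeyError:
        raise ValueError(f"unknown map function/direction: {kind!r}/{direction!r}")
    if ril_expansion_flag:
        if direction == "to_cM":
            return func(ril_expansion(value))
        return ril_expansion(func(value))
    return func(value)


def ril_expansion(r: float) -> float:
    """Expected fraction of recombinant selfed-RIL lines, R = 2r/(1+2r)."""
    _check_r(r)
    return 2.0 * r / (1.0 + 2.0 * r)


# ---------------------------------------------------------------------------
# Genetic map
# ---------------------------------------------------------------------------

@dataclass
class GeneticMap:
    """Ordered markers per chromosome plus a map-function choice.

    Genetic positions (cM) are taken from the markers when present;
    otherwise they are derived from physical positions with the
    ``cm_per_mb`` calibration scalar (cM per Mb), anchored at the first
    marker of each chromosome.
    """

    markers: list[Marker]
    map_function: MapKind = "kosambi"
    cm_per_mb: float | None = None

    def __post_init__(self) -> None:
        if not self.markers:
            raise ValueError("a genetic map requires at least one marker")
        names = [m.name for m in self.markers]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate marker names in map: {dupes}")
        self.markers = sorted(self.markers, key=lambda m: (m.chrom, m.pos_bp))
        self._by_chrom: dict[str, list[Marker]] = {}
        for m in self.markers:
            self._by_chrom.setdefault(m.chrom, []).append(m)
        for chrom, ms in self._by_chrom.items():
            pos = [m.pos_bp for m in ms]
            if len(set(pos)) != len(pos):
                raise ValueError(f"markers on {chrom} must have distinct pos_bp")
            cms = [m.pos_cM for m in ms if m.pos_cM is not None]
            if len(cms) == len(ms) and any(b < a for a, b in zip(cms, cms[1:])):
                raise ValueError(f"pos_cM must be non-decreasing with pos_bp on {chrom}")

    @property
    def chroms(self) -> list[str]:
        return sorted(self._by_chrom)

    def chrom_markers(self, chrom: str) -> list[Marker]:
        return list(self._by_chrom[chrom])

    def marker(self, name: str) -> Marker:
        for m in self.markers:
            if m.name == name:
                return m
        raise KeyError(f"marker {name!r} not in map")

    def positions_bp(self, chrom: str) -> np.ndarray:
        return np.array([m.pos_bp for m in self._by_chrom[chrom]], dtype=float)

    def positions_cM(self, chrom: str) -> np.ndarray:
        ms = self._by_chrom[chrom]
        cms = [m.pos_cM for m in ms]
        if all(c is not None for c in cms):
            return np.array(cms, dtype=float)
        if self.cm_per_mb is None:
            raise ValueError(
                f"markers on {chrom} lack pos_cM and no cm_per_mb calibration "
                "was supplied"
            )
        bp = self.positions_bp(chrom)
        return (bp - bp[0]) / 1e6 * self.cm_per_mb

    def chrom_length_cM(self, chrom: str) -> float:
        cm = self.positions_cM(chrom)
        return float(cm[-1] - cm[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "name": [m.name for m in self.markers],
                "chrom": [m.chrom for m in self.markers],
                "pos_bp": [m.pos_bp for m in self.markers],
                "pos_cM": [m.pos_cM for m in self.markers],
            }
        )


# ---------------------------------------------------------------------------
# Genotype matrix
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Lines x ordered markers with calls in {A, H, B, -}.

    ``A`` is the parent-1 homozygote, ``B`` the parent-2 homozygote, ``H``
    heterozygous, ``-`` missing.  Calls are kept in a pandas DataFrame whose
    index is the line id and whose columns follow the marker order.
    """

    calls: pd.DataFrame
    markers: list[Marker]

    def __post_init__(self) -> None:
        names = [m.name for m in self.markers]
        if list(self.calls.columns) != names:
            raise ValueError("calls columns must equal marker names, in order")
        if self.calls.index.has_duplicates:
            dupes = self.calls.index[self.calls.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate line ids: {dupes}")
        bad = ~self.calls.isin(GENOTYPE_CODES)
        if bad.to_numpy().any():
            r, c = np.argwhere(bad.to_numpy())[0]
            raise ValueError(
                f"invalid genotype code {self.calls.iat[r, c]!r} for line "
                f"{self.calls.index[r]!r} at marker {self.calls.columns[c]!r}"
            )

    @classmethod
    def from_codes(
        cls, line_ids: Sequence[str], markers: Sequence[Marker], codes: np.ndarray
    ) -> "GenotypeMatrix":
        """Build from the internal int8 encoding (A=0, H=1, B=2, -1=missing)."""
        sym = np.array(["A", "H", "B"], dtype=object)
        arr = np.where(codes < 0, MISSING, sym[np.clip(codes, 0, 2)])
        df = pd.DataFrame(arr, index=list(line_ids), columns=[m.name for m in markers])
        return cls(calls=df, markers=list(markers))

    @property
    def line_ids(self) -> list[str]:
        return list(self.calls.index)

    @property
    def marker_names(self) -> list[str]:
        return list(self.calls.columns)

    @property
    def n_lines(self) -> int:
        return len(self.calls)

    def codes(self) -> np.ndarray:
        """Calls as an int8 array (A=0, H=1, B=2, missing=-1)."""
        arr = self.calls.to_numpy()
        out = np.empty(arr.shape, dtype=np.int8)
        for code, value in CODE_TO_INT.items():
            out[arr == code] = value
        return out

    def missing_fraction(self) -> pd.Series:
        """Per-marker fraction of missing calls."""
        return (self.calls == MISSING).mean(axis=0)

    def subset_markers(self, names: Sequence[str]) -> "GenotypeMatrix":
        by_name = {m.name: m for m in self.markers}
        markers = [by_name[n] for n in names]
        return GenotypeMatrix(calls=self.calls[list(names)].copy(), markers=markers)

    def subset_region(self, chrom: str, start_bp: int, end_bp: int) -> "GenotypeMatrix":
        names = [
            m.name
            for m in self.markers
            if m.chrom == chrom and start_bp <= m.pos_bp <= end_bp
        ]
        return self.subset_markers(names)

    def subset_lines(self, line_ids: Sequence[str]) -> "GenotypeMatrix":
        return GenotypeMatrix(calls=self.calls.loc[list(line_ids)].copy(),
                              markers=list(self.markers))
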