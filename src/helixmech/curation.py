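"""Classification, symmetrization, filtering and culling of step observations.

Observed base-pair steps are grouped by sequence: the 16 dimers collapse to
10 symmetry-unique classes (a step read on the complementary strand is the
reverse complement with tilt and shift sign-flipped), and the 256 tetramers
(dimer plus flanking base pairs) collapse to 136 unique classes
(16 contexts x 6 non-self-complementary dimers + 10 x 4 self-complementary).
Within each class, outliers beyond three standard deviations in any of the
six parameters are removed round by round until none remain.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from io import StringIO
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .geometry import PARAM_NAMES, StepParameters

__all__ = [
    "StepRecord",
    "EnsembleTable",
    "StructureMeta",
    "classify_dimer",
    "complement_step",
    "classify_tetramer",
    "symmetrize_self_complementary",
    "cull_3sd",
    "redundancy_filter",
    "filter_by",
    "reverse_complement",
    "SELF_COMPLEMENTARY_DIMERS",
    "UNIQUE_DIMERS",
    "END_SENTINEL",
]

_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}
VALID_BASES = frozenset("ACGT")
SELF_COMPLEMENTARY_DIMERS = ("AT", "TA", "GC", "CG")
#: sentinel context for steps at chain ends or next to melted base pairs
END_SENTINEL = "-"

# sign pattern applied to (tilt, roll, twist, shift, slide, rise) when a step
# is read on the complementary strand
COMPLEMENT_SIGNS = np.array([-1.0, 1.0, 1.0, -1.0, 1.0, 1.0])


class InvalidBaseError(ValueError):
    """Sequence contains a letter outside {A, C, G, T}."""


def _check_bases(s: str) -> str:
    s = s.upper()
    if not set(s) <= VALID_BASES:
        raise InvalidBaseError(f"invalid base in {s!r}")
    return s


def reverse_complement(s: str) -> str:
    return "".join(_COMP[b] for b in reversed(_check_bases(s)))


def classify_dimer(dimer: str) -> tuple[str, bool]:
    """Unique-dimer label and whether the complementary reading was chosen.

    The representative of each class is the lexicographically smaller of the
    dimer and its reverse complement (self-complementary dimers map to
    themselves).  Exactly 10 labels are reachable.
    """
    dimer = _check_bases(dimer)
    if len(dimer) != 2:
        raise InvalidBaseError(f"dimer must have 2 bases, got {dimer!r}")
    rc = reverse_complement(dimer)
    if rc < dimer:
        return rc, True
    return dimer, False


#: the 10 symmetry-unique dimer labels under the lexicographic representative
UNIQUE_DIMERS = tuple(sorted({classify_dimer(a + b)[0] for a in "ACGT" for b in "ACGT"}))


def classify_tetramer(preceding: str, dimer: str, following: str) -> str:
    """Unique tetramer label: min(tetramer, reverse complement); 136 classes."""
    tet = _check_bases(preceding) + _check_bases(dimer) + _check_bases(following)
    if len(tet) != 4:
        raise InvalidBaseError(f"tetramer context must have 4 bases, got {tet!r}")
    return min(tet, reverse_complement(tet))


@dataclass(frozen=True)
class StepRecord:
    """One observed base-pair step with its provenance metadata."""

    structure_id: str
    resolution: float
    year: int
    dimer: str
    context: tuple[str, str]  # (preceding base, following base) or sentinels
    params: StepParameters
    chain_end: bool = False
    melted_adjacent: bool = False

    def __post_init__(self):
        d = _check_bases(self.dimer)
        object.__setattr__(self, "dimer", d)
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")

    @property
    def tetramer_label(self) -> str | None:
        p, f = self.context
        if p == END_SENTINEL or f == END_SENTINEL:
            return None
        return classify_tetramer(p, self.dimer, f)


def complement_step(r: StepRecord) -> StepRecord:
    """The same step read on the complementary strand.

    Dimer and context are replaced by their reverse-complement reading and
    tilt and shift change sign; roll, twist, slide, rise are unchanged.
    """
    p, f = r.context
    new_context = (
        _COMP[f] if f != END_SENTINEL else END_SENTINEL,
        _COMP[p] if p != END_SENTINEL else END_SENTINEL,
    )
    arr = r.params.as_array() * COMPLEMENT_SIGNS
    return replace(
        r,
        dimer=reverse_complement(r.dimer),
        context=new_context,
        params=StepParameters.from_array(arr),
    )


@dataclass
class EnsembleTable:
    """A curated collection of step records plus a provenance log."""

    records: list[StepRecord] = field(default_factory=list)
    provenance: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def params_array(self) -> np.ndarray:
        return np.array([r.params.as_array() for r in self.records]).reshape(-1, 6)

    def log(self, event: str) -> None:
        self.provenance.append(event)

    # -- grouping ----------------------------------------------------------
    def usable_records(self) -> list[StepRecord]:
        """Records that enter statistics: no chain-end or melted flags."""
        return [r for r in self.records if not (r.chain_end or r.melted_adjacent)]

    def group_by_dimer(self) -> dict[str, list[StepRecord]]:
        """Records keyed by unique dimer, expressed in the unique reading."""
        groups: dict[str, list[StepRecord]] = {d: [] for d in UNIQUE_DIMERS}
        for r in self.usable_records():
            label, flipped = classify_dimer(r.dimer)
            groups[label].append(complement_step(r) if flipped else r)
        return groups

    def group_by_tetramer(self) -> dict[str, list[StepRecord]]:
        """Records keyed by unique tetramer, in the representative reading."""
        groups: dict[str, list[StepRecord]] = {}
        for r in self.usable_records():
            label = r.tetramer_label
            if label is None:
                continue
            p, f = r.context
            if p + r.dimer + f != label:
                r = complement_step(r)
            groups.setdefault(label, []).append(r)
        return groups

    # -- I/O ---------------------------------------------------------------
    _COLUMNS = (
        "structure_id",
        "resolution",
        "year",
        "dimer",
        "prev",
        "next",
        *PARAM_NAMES,
        "chain_end",
        "melted_adjacent",
    )

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append(
                (
                    r.structure_id,
                    r.resolution,
                    r.year,
                    r.dimer,
                    r.context[0],
                    r.context[1],
                    *r.params.as_array(),
                    int(r.chain_end),
                    int(r.melted_adjacent),
                )
            )
        return pd.DataFrame(rows, columns=self._COLUMNS)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "EnsembleTable":
        records = []
        for row in df.itertuples(index=False):
            records.append(
                StepRecord(
                    structure_id=str(row.structure_id),
                    resolution=float(row.resolution),
                    year=int(row.year),
                    dimer=str(row.dimer),
                    context=(str(row.prev), str(getattr(row, "next"))),
                    params=StepParameters(
                        row.tilt, row.roll, row.twist, row.shift, row.slide, row.rise
                    ),
                    chain_end=bool(int(row.chain_end)),
                    melted_adjacent=bool(int(row.melted_adjacent)),
                )
            )
        return cls(records)

    def to_tsv(self, path: str | Path | StringIO) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path | StringIO) -> "EnsembleTable":
        return cls.from_dataframe(pd.read_csv(path, sep="\t"))


@dataclass(frozen=True)
class StructureMeta:
    """Metadata used by the redundancy filter."""

    structure_id: str
    resolution: float
    dna_sequences: tuple[str, ...]
    domain_ids: tuple[str, ...]  # multiset, stored sorted

    def __post_init__(self):
        if not self.dna_sequences:
            raise ValueError("at least one DNA sequence required")
        object.__setattr__(self, "dna_sequences", tuple(self.dna_sequences))
        object.__setattr__(self, "domain_ids", tuple(sorted(self.domain_ids)))


def symmetrize_self_complementary(group: Sequence[StepRecord]) -> list[StepRecord]:
    """Add the complementary-strand reading of every record.

    Only meaningful for groups sharing a self-complementary central dimer;
    forces the group means of tilt and shift to zero exactly.
    """
    group = list(group)
    for r in group:
        if r.dimer not in SELF_COMPLEMENTARY_DIMERS:
            raise ValueError(
                f"symmetrization requires a self-complementary dimer, got {r.dimer}"
            )
    # interleave each record with its complement so that sequential summation
    # cancels tilt and shift exactly, not just to rounding
    out: list[StepRecord] = []
    for r in group:
        out.append(r)
        out.append(complement_step(r))
    return out


MIN_GROUP_SIZE = 7


def cull_3sd(
    group: Sequence[StepRecord], threshold: float = 3.0, max_rounds: int = 100
) -> tuple[list[StepRecord], int]:
    """Stepwise removal of outliers beyond ``threshold`` standard deviations.

    Each round recomputes the per-parameter mean and standard deviation of
    the retained set and removes every record with |z| > threshold in any
    parameter, until a round removes nothing.  Returns (retained, rounds);
    the count includes the final no-removal round.  Groups smaller than
    ``MIN_GROUP_SIZE`` are returned unculled with a warning.
    """
    records = list(group)
    if len(records) < MIN_GROUP_SIZE:
        warnings.warn(
            f"group of {len(records)} records is too small to cull "
            f"(minimum {MIN_GROUP_SIZE}); returned unchanged"
        )
        return records, 0
    rounds = 0
    for _ in range(max_rounds):
        rounds += 1
        arr = np.array([r.params.as_array() for r in records])
        mean = arr.mean(axis=0)
        sd = arr.std(axis=0)
        ok = np.ones(len(records), dtype=bool)
        for j in range(6):
            if sd[j] == 0.0:
                continue  # zero-variance parameter: skip z-scoring this round
            ok &= np.abs(arr[:, j] - mean[j]) <= threshold * sd[j]
        if ok.all():
            break
        records = [r for r, keep in zip(records, ok) if keep]
        if len(records) < MIN_GROUP_SIZE:
            break
    return records, rounds


def _longest_common_substring(a: str, b: str) -> int:
    """Length of the longest contiguous identical stretch (simple DP)."""
    if not a or not b:
        return 0
    prev = [0] * (len(b) + 1)
    best = 0
    for ca in a:
        cur = [0] * (len(b) + 1)
        for j, cb in enumerate(b, start=1):
            if ca == cb:
                cur[j] = prev[j - 1] + 1
                if cur[j] > best:
                    best = cur[j]
        prev = cur
    return best


def _sequences_match(meta_a: StructureMeta, meta_b: StructureMeta, frac: float) -> bool:
    """True if any sequence pair shares an identical stretch > frac of the
    total DNA length (the longer of the two; both strand orientations)."""
    for sa in meta_a.dna_sequences:
        for sb in meta_b.dna_sequences:
            total = max(len(sa), len(sb))
            if total == 0:
                continue
            stretch = max(
                _longest_common_substring(sa, sb),
                _longest_common_substring(sa, reverse_complement(sb)),
            )
            if stretch > frac * total:
                return True
    return False


def redundancy_filter(
    structures: Iterable[StructureMeta], match_fraction: float = 0.70
) -> list[StructureMeta]:
    """Keep the best-resolved member of every redundant group.

    Two structures are redundant when their DNA sequences match (longest
    identical stretch > ``match_fraction`` of the total DNA length) *and*
    they carry the same multiset of protein-domain identifiers.  Processing
    is best-resolution-first, so the result does not depend on input order.
    """
    pool = sorted(structures, key=lambda m: (m.resolution, m.structure_id))
    retained: list[StructureMeta] = []
    for meta in pool:
        redundant = any(
            meta.domain_ids == kept.domain_ids
            and _sequences_match(meta, kept, match_fraction)
            for kept in retained
        )
        if not redundant:
            retained.append(meta)
    return retained


def filter_by(
    table: EnsembleTable,
    max_resolution: float | None = None,
    max_year: int | None = None,
) -> EnsembleTable:
    """Records at or better than a resolution limit and/or up to a year."""
    if max_resolution is not None and max_resolution <= 0:
        raise ValueError("max_resolution must be positive")
    kept = [
        r
        for r in table.records
        if (max_resolution is None or r.resolution <= max_resolution)
        and (max_year is None or r.year <= max_year)
    ]
    out = EnsembleTable(kept, list(table.provenance))
    out.log(
        f"filter_by(max_resolution={max_resolution}, max_year={max_year}): "
        f"{len(table)} -> {len(kept)} records"
    )
    if not kept:
        warnings.warn("filter produced an empty table")
    return out
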