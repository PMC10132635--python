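"""Binary capture matrices (individuals x monthly occasions).

The unit of analysis is one matrix per site x species: a 1 marks an
individual detected at least once in a monthly occasion, regardless of how
many photographs were submitted that month.  Rows exist only for
individuals sighted at that site, so every row carries at least one
detection.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from typing import Iterable, Sequence, TextIO

import numpy as np

from .design import StudyDesign, OutOfWindowError
from .records import SightingRecord


class EmptyMatrixError(ValueError):
    """No qualifying records for the requested site/species."""


@dataclass
class CaptureMatrix:
    """Binary detection histories over the occasions of a study design."""

    individuals: list[str]
    data: np.ndarray  # shape (n_individuals, n_occasions), values in {0, 1}
    design: StudyDesign
    site: str = ""
    species: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.int8)
        if self.data.ndim != 2:
            raise ValueError("capture matrix must be 2-D")
        if self.data.shape != (len(self.individuals), self.design.n_occasions):
            raise ValueError(
                f"shape {self.data.shape} inconsistent with "
                f"{len(self.individuals)} individuals x "
                f"{self.design.n_occasions} occasions"
            )
        if not np.isin(self.data, (0, 1)).all():
            raise ValueError("capture matrix cells must be 0 or 1")
        if self.n_individuals and not (self.data.sum(axis=1) >= 1).all():
            raise ValueError("every individual must have at least one detection")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_occasions(self) -> int:
        return self.design.n_occasions

    @property
    def primary_index(self) -> np.ndarray:
        """0-based primary period of each occasion column."""
        return np.array([o.primary - 1 for o in self.design.occasions])

    def primary_pooled(self) -> np.ndarray:
        """Collapse to binary detected/not per primary period."""
        pooled = np.zeros((self.n_individuals, self.design.n_primary), dtype=np.int8)
        for j, o in enumerate(self.design.occasions):
            pooled[:, o.primary - 1] |= self.data[:, j]
        return pooled

    def detected_per_primary(self) -> np.ndarray:
        """n_t: distinct individuals detected in each primary period."""
        return self.primary_pooled().sum(axis=0)

    # -- I/O ---------------------------------------------------------------

    def to_csv(self, stream: TextIO) -> None:
        w = csv.writer(stream)
        w.writerow(["turtle_id"] + [o.label for o in self.design.occasions])
        for ind, row in zip(self.individuals, self.data):
            w.writerow([ind] + [int(v) for v in row])

    @classmethod
    def from_csv(cls, stream: TextIO, site: str = "", species: str = "") -> "CaptureMatrix":
        reader = csv.reader(stream)
        header = next(reader)
        labels = header[1:]
        design = StudyDesign.from_window(labels[0], labels[-1])
        if [o.label for o in design.occasions] != labels:
            raise ValueError("occasion columns are not consecutive calendar months")
        individuals, rows = [], []
        for rec in reader:
            if not rec:
                continue
            individuals.append(rec[0])
            rows.append([int(v) for v in rec[1:]])
        return cls(individuals, np.array(rows, dtype=np.int8).reshape(len(rows), len(labels)),
                   design, site=site, species=species)


def build_capture_matrix(
    records: Iterable[SightingRecord],
    design: StudyDesign,
    site: str,
    species: str,
) -> CaptureMatrix:
    """Build the binary capture matrix for one site x species.

    Repeated sightings of an individual within a month collapse to a single
    detection.  Records dated outside the study window are dropped (counted
    against no one; the caller chose the window).

    Raises
    ------
    EmptyMatrixError
        If no record matches the site and species inside the window.
    """
    cells: dict[str, set[int]] = {}
    for r in records:
        if r.site != site or r.species != species:
            continue
        try:
            occ = design.occasion_of_date(r.date)
        except OutOfWindowError:
            continue
        cells.setdefault(r.turtle_id, set()).add(occ.index)
    if not cells:
        raise EmptyMatrixError(f"no qualifying records for {species} at {site}")
    individuals = sorted(cells)
    data = np.zeros((len(individuals), design.n_occasions), dtype=np.int8)
    for i, ind in enumerate(individuals):
        data[i, sorted(cells[ind])] = 1
    return CaptureMatrix(individuals, data, design, site=site, species=species)


def drop_first_primary(matrix: CaptureMatrix) -> CaptureMatrix:
    """Remove the first primary period's columns (sparse early data).

    Rows left with no detection are removed.  The design start shifts six
    months (one season) later.
    """
    keep_cols = [o.index for o in matrix.design.occasions if o.primary > 1]
    if not keep_cols:
        raise ValueError("cannot drop the only primary period")
    first = matrix.design.occasions[keep_cols[0]]
    design = StudyDesign(first.year, first.month, len(keep_cols))
    data = matrix.data[:, keep_cols]
    keep_rows = data.sum(axis=1) >= 1
    return CaptureMatrix(
        [ind for ind, k in zip(matrix.individuals, keep_rows) if k],
        data[keep_rows], design, site=matrix.site, species=matrix.species,
    )


def filter_sites(
    matrices: Sequence[CaptureMatrix],
    min_individuals: int = 10,
    omit_first: Iterable[str] = (),
) -> tuple[list[CaptureMatrix], list[str]]:
    """Apply the site-inclusion rules.

    Sites listed in ``omit_first`` have their first six-month interval
    dropped before the threshold is applied; matrices with fewer than
    ``min_individuals`` identified individuals are excluded.  Returns the
    retained matrices and a log of exclusions/modifications.
    """
    omit = set(omit_first)
    kept, log = [], []
    for m in matrices:
        key = f"{m.site}/{m.species}"
        if m.site in omit and m.design.n_primary > 1:
            before = m.n_individuals
            m = drop_first_primary(m)
            log.append(
                f"{key}: first primary omitted "
                f"({before - m.n_individuals} individuals dropped with it)"
            )
        if m.n_individuals < min_individuals:
            log.append(
                f"{key}: excluded ({m.n_individuals} < {min_individuals} individuals)"
            )
            continue
        kept.append(m)
    return kept, log


def build_all_matrices(records: Iterable[SightingRecord],
                       design: StudyDesign) -> list[CaptureMatrix]:
    """One capture matrix per (site, species) combination with any records.

    A turtle sighted at several sites contributes to each site's matrix
    independently (per-reef analyses; cross-site movement is not modeled).
    """
    records = list(records)
    keys = sorted({(r.site, r.species) for r in records})
    out = []
    for site, species in keys:
        try:
            out.append(build_capture_matrix(records, design, site, species))
        except EmptyMatrixError:
            continue
    return out


# -- MARK encounter-history interchange -----------------------------------

def write_inp(matrix: CaptureMatrix, stream: TextIO) -> None:
    """Write MARK .inp encounter histories (identical rows collapsed)."""
    counts: dict[str, int] = {}
    for row in matrix.data:
        h = "".join(str(int(v)) for v in row)
        counts[h] = counts.get(h, 0) + 1
    for h in sorted(counts):
        stream.write(f"{h} {counts[h]};\n")


def read_inp(stream: TextIO, design: StudyDesign,
             site: str = "", species: str = "") -> CaptureMatrix:
    """Read a MARK .inp file back into a capture matrix.

    Individual identities are synthesized (``H0001``...), since .inp stores
    only histories and frequencies.
    """
    rows = []
    for line in stream:
        line = line.split("/*")[0].strip().rstrip(";").strip()
        if not line:
            continue
        hist, freq = line.split()
        if len(hist) != design.n_occasions:
            raise ValueError(
                f"history length {len(hist)} != {design.n_occasions} occasions"
            )
        rows.extend([[int(c) for c in hist]] * int(freq))
    individuals = [f"H{i + 1:04d}" for i in range(len(rows))]
    return CaptureMatrix(individuals, np.array(rows, dtype=np.int8),
                         design, site=site, species=species)
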