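"""Shared fixtures and builders for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from sectorscan.alignment import Alignment, SequenceRecord
from sectorscan.sca import Sector, SectorAssignment
from sectorscan.structure import MapEntry, StructureMap


def make_alignment(rows: list[str], reference_index: int | None = 0,
                   ids: list[str] | None = None) -> Alignment:
    """Build an alignment from residue strings; row ``reference_index`` is
    flagged as the reference (pass None for no reference)."""
    ids = ids or [f"s{i}" for i in range(len(rows))]
    return Alignment(
        [
            SequenceRecord(id=ids[i], residues=row, is_reference=(i == reference_index))
            for i, row in enumerate(rows)
        ]
    )


def make_structure_map(resnums: list[int], ref_aa: str | None = None) -> StructureMap:
    """Identity-style map: column i+1 <-> ref_pos i+1 <-> resnums[i]."""
    entries = [
        MapEntry(
            column=i + 1,
            ref_pos=i + 1,
            resnum=num,
            icode="",
            aa_ref=ref_aa[i] if ref_aa else "A",
            aa_struct=ref_aa[i] if ref_aa else "A",
            match=True,
        )
        for i, num in enumerate(resnums)
    ]
    return StructureMap(entries=entries, coverage=1.0, mismatch_fraction=0.0)


def make_assignment(sector_columns: dict[str, list[int]], L: int) -> SectorAssignment:
    """Fixture SectorAssignment with unit loadings, labels in dict order."""
    sectors = [
        Sector(label=label, columns=sorted(cols),
               loadings={c: 1.0 for c in cols}, cutoff=0.5)
        for label, cols in sector_columns.items()
    ]
    member = {c for cols in sector_columns.values() for c in cols}
    unassigned = [c for c in range(1, L + 1) if c not in member]
    return SectorAssignment(sectors=sectors, unassigned=unassigned, L=L)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_alignment(rng: np.random.Generator, M: int, L: int,
                     gap_fraction: float = 0.0) -> Alignment:
    """Uniform-random alignment, optionally sprinkled with gaps."""
    from sectorscan.background import AA_ALPHABET

    lookup = np.array(list(AA_ALPHABET + "-"))
    X = rng.integers(0, 20, size=(M, L))
    if gap_fraction > 0:
        X[rng.random((M, L)) < gap_fraction] = 20
    rows = ["".join(lookup[row]) for row in X]
    return make_alignment(rows, reference_index=None)
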