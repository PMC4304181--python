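"""Synthetic data: planted-sector alignments, i.i.d. nulls, toy structures.

The planted generator uses a two-state latent-variable emission model: each
sequence draws one hidden binary state per sector, and each sector column
emits the state-linked residue with probability ``rho`` (otherwise a draw
from the background). This is the simplest construction producing
block-correlated columns detectable by covariance-based coupling analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignment import Alignment, SequenceRecord
from .background import AA_ALPHABET, AA_INDEX, BACKGROUND_FREQS, ONE_TO_THREE, validate_background

_DEFAULT_PAIRS = [("E", "K"), ("L", "F"), ("D", "R"), ("I", "T"), ("N", "S")]


@dataclass
class PlantedSector:
    """Columns (1-based), coupling strength, and the state-linked residue pair."""

    columns: list[int]
    rho: float = 0.9
    residue_pair: tuple[str, str] = ("E", "K")


@dataclass
class PlantedSectorSpec:
    """Full specification of a planted-sector alignment."""

    L: int = 100
    M: int = 500
    sectors: list[PlantedSector] = field(default_factory=list)
    conserved_columns: list[tuple[int, str, float]] = field(default_factory=list)
    q: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for s in self.sectors:
            if not 0.0 <= s.rho <= 1.0:
                raise ValueError(f"rho must be in [0, 1], got {s.rho}")
            overlap = seen & set(s.columns)
            if overlap:
                raise ValueError(f"overlapping sector columns: {sorted(overlap)}")
            seen |= set(s.columns)

    @classmethod
    def two_sector_benchmark(cls, seed: int = 0, M: int = 500, L: int = 100,
                             rho: float = 0.9) -> "PlantedSectorSpec":
        """Default desk-scale benchmark: two 10-column sectors plus 5
        conserved columns at level 0.95 (positions scale with L; at the
        default L=100 the sectors sit at columns 11-20 and 41-50)."""
        if L < 40:
            raise ValueError("two-sector benchmark needs L >= 40")
        s1 = list(range(L // 10 + 1, L // 10 + 11))
        s2 = list(range(L * 4 // 10 + 1, L * 4 // 10 + 11))
        taken = set(s1) | set(s2)
        conserved = []
        for cand, res in [(1, "G"), (L // 4 + 1, "P"), (L * 3 // 5 + 1, "W"),
                          (L * 4 // 5 + 1, "C"), (L, "H")]:
            col = cand
            while col in taken or col > L:
                col = col + 1 if col < L else 1
            taken.add(col)
            conserved.append((col, res, 0.95))
        return cls(
            L=L,
            M=M,
            sectors=[
                PlantedSector(columns=s1, rho=rho, residue_pair=("E", "K")),
                PlantedSector(columns=s2, rho=rho, residue_pair=("L", "F")),
            ],
            conserved_columns=conserved,
            seed=seed,
        )


def _decode(X: np.ndarray, prefix: str = "seq") -> list[SequenceRecord]:
    lookup = np.array(list(AA_ALPHABET))
    width = len(str(X.shape[0]))
    return [
        SequenceRecord(id=f"{prefix}{m + 1:0{width}d}", residues="".join(lookup[row]))
        for m, row in enumerate(X)
    ]


def generate_null_alignment(
    M: int, L: int, q: np.ndarray | None = None, seed: int = 0
) -> Alignment:
    """Alignment with every cell drawn i.i.d. from ``q``; pure in (M, L, q, seed)."""
    if M < 1 or L < 1:
        raise ValueError("M and L must be >= 1")
    q = BACKGROUND_FREQS if q is None else validate_background(q)
    rng = np.random.default_rng(seed)
    X = rng.choice(len(AA_ALPHABET), size=(M, L), p=q)
    return Alignment(_decode(X))


def generate_planted_alignment(spec: PlantedSectorSpec) -> tuple[Alignment, np.ndarray]:
    """Generate a planted-sector alignment and its per-column truth vector.

    Truth is length L with sector ids 1..n on planted columns and 0
    elsewhere. A gap-free consensus reference row (id ``REFERENCE``) is
    appended after the M generated rows.
    """
    q = BACKGROUND_FREQS if spec.q is None else validate_background(spec.q)
    rng = np.random.default_rng(spec.seed)
    X = rng.choice(len(AA_ALPHABET), size=(spec.M, spec.L), p=q)
    truth = np.zeros(spec.L, dtype=int)
    for sid, sector in enumerate(spec.sectors, start=1):
        r0, r1 = (AA_INDEX[r] for r in sector.residue_pair)
        states = rng.integers(0, 2, size=spec.M)
        linked = np.where(states == 1, r1, r0)
        for col in sector.columns:
            emit = rng.random(spec.M) < sector.rho
            X[emit, col - 1] = linked[emit]
            truth[col - 1] = sid
    for col, residue, level in spec.conserved_columns:
        emit = rng.random(spec.M) < level
        X[emit, col - 1] = AA_INDEX[residue]
    records = _decode(X)
    consensus = np.array(
        [np.bincount(X[:, i], minlength=len(AA_ALPHABET)).argmax() for i in range(spec.L)]
    )
    lookup = np.array(list(AA_ALPHABET))
    records.append(
        SequenceRecord(id="REFERENCE", residues="".join(lookup[consensus]), is_reference=True)
    )
    return Alignment(records), truth


def generate_toy_pdb(
    sequence: str, start_number: int = 1, chain: str = "A", out: str | None = None
) -> str:
    """Write a CA-only toy PDB: one residue per position along a straight line.

    Returns the PDB text; also writes it to ``out`` when given.
    """
    lines = []
    for i, aa in enumerate(sequence.upper()):
        resname = ONE_TO_THREE.get(aa, "UNK")
        x = 3.8 * i
        lines.append(
            f"ATOM  {i + 1:5d}  CA  {resname:>3s} {chain}{start_number + i:4d}    "
            f"{x:8.3f}{0.0:8.3f}{0.0:8.3f}{1.00:6.2f}{0.00:6.2f}           C  "
        )
    lines.append("TER")
    lines.append("END")
    text = "\n".join(lines) + "\n"
    if out is not None:
        with open(out, "w") as fh:
            fh.write(text)
    return text


@dataclass
class RecoveryResult:
    """Micro-averaged recovery of a sector assignment against planted truth."""

    precision: float
    recall: float
    table: list[dict]
    precision_undefined: bool = False


def evaluate_recovery(assignment, truth: np.ndarray) -> RecoveryResult:
    """Match recovered sectors to planted groups and score membership.

    Sectors are matched greedily (in assignment order, ties by sector order)
    to the planted group of maximal overlap. Precision is the fraction of
    assigned positions landing in their sector's matched group; recall is
    the fraction of planted positions recovered by their group's matched
    sector. An empty assignment against non-empty truth reports precision 0
    with ``precision_undefined=True``.
    """
    truth = np.asarray(truth)
    truth_groups = {
        int(g): set(np.flatnonzero(truth == g) + 1) for g in np.unique(truth) if g != 0
    }
    total_truth = sum(len(v) for v in truth_groups.values())
    assigned_sets = [(s.label, set(s.columns)) for s in assignment.sectors]
    total_assigned = sum(len(cols) for _, cols in assigned_sets)

    taken: set[int] = set()
    table = []
    tp = 0
    for label, cols in assigned_sets:
        best_gid, best_overlap = None, -1
        for gid in sorted(truth_groups):
            if gid in taken:
                continue
            overlap = len(cols & truth_groups[gid])
            if overlap > best_overlap:
                best_gid, best_overlap = gid, overlap
        if best_gid is not None:
            taken.add(best_gid)
            tp += best_overlap
        table.append(
            {
                "sector": label,
                "matched_group": best_gid,
                "overlap": max(best_overlap, 0),
                "n_assigned": len(cols),
                "n_true": len(truth_groups.get(best_gid, ())) if best_gid else 0,
            }
        )
    if total_assigned == 0:
        return RecoveryResult(
            precision=0.0,
            recall=0.0 if total_truth else 1.0,
            table=table,
            precision_undefined=True,
        )
    return RecoveryResult(
        precision=tp / total_assigned,
        recall=tp / total_truth if total_truth else 1.0,
        table=table,
    )
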