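"""Map alignment columns to author residue numbers of a PDB chain.

The chain sequence is taken from coordinate records (not SEQRES), so
unresolved residues reduce coverage. Author numbering — residue number plus
insertion code — is authoritative for all reports; internal indices are
1-based ungapped reference positions.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align
from Bio.PDB import PDBParser

from .alignment import Alignment
from .background import THREE_TO_ONE


@dataclass(frozen=True)
class ChainResidue:
    number: int
    icode: str  # '' when absent
    aa: str     # one-letter, 'X' for unknown

    @property
    def key(self) -> str:
        return f"{self.number}{self.icode}"


@dataclass
class StructureChain:
    """Ordered residues of one chain, as found in the coordinate records."""

    chain_id: str
    residues: list[ChainResidue]

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)


@dataclass(frozen=True)
class MapEntry:
    column: int      # 1-based alignment column
    ref_pos: int     # 1-based ungapped reference position
    resnum: int      # author residue number
    icode: str
    aa_ref: str
    aa_struct: str
    match: bool


@dataclass
class StructureMap:
    """Alignment-column <-> reference-position <-> author-residue mapping."""

    entries: list[MapEntry]
    coverage: float
    mismatch_fraction: float

    def column_to_residue(self) -> dict[int, tuple[int, str]]:
        return {e.column: (e.resnum, e.icode) for e in self.entries}

    def residue_to_column(self) -> dict[tuple[int, str], int]:
        return {(e.resnum, e.icode): e.column for e in self.entries}


def read_chain(path: str, chain_id: str) -> StructureChain:
    """Parse one chain from a PDB file (first model, first altloc only).

    Hetero records (waters, ligands) are skipped; unknown residue names
    translate to 'X'. Raises when the chain is absent (listing available
    chains) or holds no amino-acid residues.
    """
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("s", path)
    try:
        model = next(structure.get_models())
    except StopIteration:
        raise ValueError(f"no models found in {path}") from None
    available = [c.id for c in model]
    chain = next((c for c in model if c.id == chain_id), None)
    if chain is None:
        raise ValueError(
            f"chain {chain_id!r} not found in {path}; available chains: {available}"
        )
    residues = []
    seen: set[tuple[int, str]] = set()
    for res in chain:
        hetflag, resseq, icode = res.id
        if hetflag.strip():
            continue
        key = (resseq, icode.strip())
        if key in seen:  # duplicated chain id occurrence; keep the first
            continue
        seen.add(key)
        aa = THREE_TO_ONE.get(res.get_resname().strip().upper(), "X")
        residues.append(ChainResidue(number=resseq, icode=icode.strip(), aa=aa))
    if not residues:
        raise ValueError(f"chain {chain_id!r} in {path} holds no amino-acid residues")
    return StructureChain(chain_id=chain_id, residues=residues)


def apply_numbering_table(chain: StructureChain, path: str) -> StructureChain:
    """Renumber chain residues from a two-column TSV (position -> number).

    Positions are 1-based indices into the chain; rows for absent positions
    are ignored. Intended for homology-model structures whose files carry
    arbitrary numbering.
    """
    table: dict[int, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            pos_s, num_s = line.split("\t")[:2]
            if pos_s.lower() in {"position", "pos"}:
                continue
            table[int(pos_s)] = int(num_s)
    residues = [
        ChainResidue(number=table.get(i + 1, r.number), icode=r.icode, aa=r.aa)
        for i, r in enumerate(chain.residues)
    ]
    return StructureChain(chain_id=chain.chain_id, residues=residues)


def _reference_positions(aln: Alignment) -> tuple[str, list[int]]:
    """Ungapped reference sequence and the 1-based column of each residue."""
    ref = aln.reference
    seq, cols = [], []
    for i, c in enumerate(ref.residues):
        if c != "-":
            seq.append(c)
            cols.append(i + 1)
    return "".join(seq), cols


def map_alignment_to_chain(
    aln: Alignment,
    chain: StructureChain,
    max_mismatch_fraction: float = 0.05,
) -> StructureMap:
    """Globally align the ungapped reference to the chain sequence.

    Identity scoring with affine gaps (match 2, mismatch -1, open -2,
    extend -0.5). Each paired position yields a map entry carrying the
    author residue number; pairings with differing residues are flagged.
    Raises a reference/structure disagreement error when the mismatch
    fraction among paired positions exceeds ``max_mismatch_fraction``.
    """
    ref_seq, ref_cols = _reference_positions(aln)
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -0.5
    result = aligner.align(ref_seq, chain.sequence)[0]

    entries = []
    n_mismatch = 0
    for (r_start, r_end), (c_start, c_end) in zip(*result.aligned):
        for off in range(r_end - r_start):
            ri, ci = r_start + off, c_start + off
            res = chain.residues[ci]
            match = ref_seq[ri] == res.aa
            n_mismatch += not match
            entries.append(
                MapEntry(
                    column=ref_cols[ri],
                    ref_pos=ri + 1,
                    resnum=res.number,
                    icode=res.icode,
                    aa_ref=ref_seq[ri],
                    aa_struct=res.aa,
                    match=match,
                )
            )
    if not entries:
        raise ValueError(
            "reference/structure disagreement: no positions could be paired"
        )
    mismatch_fraction = n_mismatch / len(entries)
    if mismatch_fraction > max_mismatch_fraction:
        raise ValueError(
            f"reference/structure disagreement: mismatch fraction "
            f"{mismatch_fraction:.3f} exceeds {max_mismatch_fraction}"
        )
    coverage = len(entries) / len(chain.residues)
    return StructureMap(entries=entries, coverage=coverage, mismatch_fraction=mismatch_fraction)


def coverage_report(smap: StructureMap, chain: StructureChain) -> float:
    """Fraction of chain residues reached by the map."""
    if not chain.residues:
        return 0.0
    mapped = {(e.resnum, e.icode) for e in smap.entries}
    return len(mapped) / len(chain.residues)


def write_structure_map(smap: StructureMap, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("column\tref_pos\tresnum\ticode\taa_ref\taa_struct\tmatch\n")
        for e in smap.entries:
            fh.write(
                f"{e.column}\t{e.ref_pos}\t{e.resnum}\t{e.icode}\t"
                f"{e.aa_ref}\t{e.aa_struct}\t{int(e.match)}\n"
            )


def read_structure_map(path: str) -> StructureMap:
    """Read a map TSV written by :func:`write_structure_map`."""
    entries = []
    n_mismatch = 0
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("column\t"):
            raise ValueError(f"{path} is not a structure-map TSV")
        for line in fh:
            col, ref_pos, resnum, icode, aa_ref, aa_struct, match = line.rstrip("\n").split("\t")
            e = MapEntry(
                column=int(col), ref_pos=int(ref_pos), resnum=int(resnum),
                icode=icode, aa_ref=aa_ref, aa_struct=aa_struct, match=bool(int(match)),
            )
            n_mismatch += not e.match
            entries.append(e)
    frac = n_mismatch / len(entries) if entries else 0.0
    return StructureMap(entries=entries, coverage=float("nan"), mismatch_fraction=frac)
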