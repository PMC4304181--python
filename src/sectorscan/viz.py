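"""Structure-coloring artifacts: B-factor-encoded PDB copies, viewer scripts.

The temperature-factor field of the chosen chain encodes sector identity
(1 = red, 2 = blue, 3 = green, ..., 0 = unassigned); every other byte of
the input PDB is preserved. Viewer scripts (Jmol ``.spt`` / PyMOL ``.pml``)
select each sector's author residue numbers and color them from the fixed
palette. No viewer is launched or embedded.
"""

from __future__ import annotations

import warnings

from .sca import SectorAssignment
from .structure import StructureMap

SUPPORTED_DIALECTS = ("jmol", "pymol")


def _residue_ordinals(
    sectors: SectorAssignment, smap: StructureMap
) -> dict[tuple[int, str], int]:
    """(author residue number, icode) -> sector ordinal (1-based rank)."""
    col_to_res = smap.column_to_residue()
    ordinals: dict[tuple[int, str], int] = {}
    for rank, sector in enumerate(sectors.sectors, start=1):
        for col in sector.columns:
            res = col_to_res.get(col)
            if res is None:
                warnings.warn(
                    f"sector {sector.label!r} column {col} is absent from the "
                    "structure map; skipped"
                )
                continue
            ordinals[res] = rank
    return ordinals


def _sector_residues(sectors: SectorAssignment, smap: StructureMap) -> list[tuple[str, list[str]]]:
    """Per sector (in rank order): label and sorted author residue keys."""
    col_to_res = smap.column_to_residue()
    out = []
    for sector in sectors.sectors:
        keys = sorted(
            {col_to_res[c] for c in sector.columns if c in col_to_res},
        )
        out.append((sector.label, [f"{num}{icode}" for num, icode in keys]))
    return out


def write_sector_pdb(
    pdb_in: str,
    chain: str,
    sectors: SectorAssignment,
    smap: StructureMap,
    out: str,
) -> None:
    """Copy a PDB file with sector ordinals written into the B-factor field.

    Only ATOM/HETATM records of the chosen chain are touched; all other
    lines (and all other columns of the edited lines) pass through
    byte-identical.
    """
    ordinals = _residue_ordinals(sectors, smap)
    with open(pdb_in) as fh:
        lines = fh.readlines()
    edited = []
    for line in lines:
        if line.startswith(("ATOM  ", "HETATM")) and len(line) >= 66 and line[21] == chain:
            resseq = int(line[22:26])
            icode = line[26].strip()
            ordinal = ordinals.get((resseq, icode), 0)
            line = f"{line[:60]}{float(ordinal):6.2f}{line[66:]}"
        edited.append(line)
    with open(out, "w") as fh:
        fh.writelines(edited)


def read_sector_pdb(path: str, chain: str) -> dict[tuple[int, str], int]:
    """Recover per-residue sector ordinals from a B-factor-encoded PDB."""
    ordinals: dict[tuple[int, str], int] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith(("ATOM  ", "HETATM")) and len(line) >= 66 and line[21] == chain:
                key = (int(line[22:26]), line[26].strip())
                ordinals[key] = int(round(float(line[60:66])))
    return ordinals


def write_viewer_script(
    sectors: SectorAssignment,
    smap: StructureMap,
    dialect: str,
    out: str,
) -> None:
    """Write a Jmol or PyMOL script coloring each sector's residues.

    Scripts reference only residue numbers present in the structure map and
    list sectors in rank order, so output is deterministic.
    """
    if dialect not in SUPPORTED_DIALECTS:
        raise ValueError(
            f"unsupported dialect {dialect!r}; supported: {', '.join(SUPPORTED_DIALECTS)}"
        )
    per_sector = _sector_residues(sectors, smap)
    lines = [f"# sector coloring ({dialect}); palette rank order"]
    if dialect == "jmol":
        lines.append("select all; color gray;")
        for label, residues in per_sector:
            if not residues:
                continue
            sel = " or ".join(f"resno={r}" for r in residues)
            lines.append(f"select {sel}; color {label};")
    else:  # pymol
        lines.append("color gray80, all")
        for label, residues in per_sector:
            if not residues:
                continue
            sel = "+".join(residues)
            lines.append(f"color {label}, (resi {sel})")
    with open(out, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_region_script(
    regions: list[tuple[str, int, int, str]],
    dialect: str,
    out: str,
) -> None:
    """Pass-through residue-range coloring (e.g. domains from external
    annotation): each entry is (label, start residue, end residue, color)."""
    if dialect not in SUPPORTED_DIALECTS:
        raise ValueError(
            f"unsupported dialect {dialect!r}; supported: {', '.join(SUPPORTED_DIALECTS)}"
        )
    lines = [f"# region coloring ({dialect})"]
    for label, start, end, color in regions:
        if dialect == "jmol":
            lines.append(f"select resno>={start} and resno<={end}; color {color};  # {label}")
        else:
            lines.append(f"color {color}, (resi {start}-{end})  # {label}")
    with open(out, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def script_residue_sets(path: str) -> dict[str, set[str]]:
    """Parse a viewer script back into {color: residue-number set} (both dialects)."""
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("select ") and "; color " in line:  # jmol
                sel, color = line.split("; color ")
                color = color.rstrip(";")
                residues = {
                    tok.split("=")[1] for tok in sel[len("select "):].split(" or ")
                    if tok.startswith("resno=")
                }
                if residues:
                    out[color] = residues
            elif line.startswith("color ") and "(resi " in line:  # pymol
                color = line[len("color "):].split(",")[0]
                residues = set(line.split("(resi ")[1].rstrip(")").split("+"))
                out[color] = residues
    return out
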