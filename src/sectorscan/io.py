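"""Plain-text writers/readers for analysis artifacts (TSV matrices, JSON bundle)."""

from __future__ import annotations

import json

import numpy as np

from .alignment import Alignment
from .sca import CouplingMatrix, Sector, SectorAssignment


def write_matrix_tsv(mat: np.ndarray, path: str, row_labels=None, col_labels=None) -> None:
    mat = np.asarray(mat)
    n_rows, n_cols = mat.shape
    row_labels = row_labels or [str(i + 1) for i in range(n_rows)]
    col_labels = col_labels or [str(j + 1) for j in range(n_cols)]
    with open(path, "w") as fh:
        fh.write("\t" + "\t".join(col_labels) + "\n")
        for label, row in zip(row_labels, mat):
            fh.write(label + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")


def write_sectors_tsv(
    assignment: SectorAssignment, path: str, aln: Alignment | None = None
) -> None:
    """Sector table: column, reference position (when available), label, loading."""
    ref_pos: dict[int, int] = {}
    if aln is not None and aln.has_reference:
        pos = 0
        for i, c in enumerate(aln.reference.residues):
            if c != "-":
                pos += 1
                ref_pos[i + 1] = pos
    with open(path, "w") as fh:
        fh.write("column\tref_pos\tsector\tloading\n")
        for sector in assignment.sectors:
            for col in sector.columns:
                rp = ref_pos.get(col, "")
                fh.write(f"{col}\t{rp}\t{sector.label}\t{sector.loadings[col]:.6f}\n")
        for col in assignment.unassigned:
            rp = ref_pos.get(col, "")
            fh.write(f"{col}\t{rp}\t-\t\n")


def read_sectors_tsv(path: str) -> SectorAssignment:
    """Rebuild a :class:`SectorAssignment` from :func:`write_sectors_tsv` output.

    Sector order follows first appearance in the file; cutoffs are not
    stored in the TSV and read back as NaN.
    """
    sectors: dict[str, Sector] = {}
    unassigned: list[int] = []
    max_col = 0
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("column\t"):
            raise ValueError(f"{path} is not a sector TSV")
        for line in fh:
            col_s, _rp, label, loading_s = line.rstrip("\n").split("\t")
            col = int(col_s)
            max_col = max(max_col, col)
            if label == "-":
                unassigned.append(col)
                continue
            sector = sectors.setdefault(
                label, Sector(label=label, columns=[], loadings={}, cutoff=float("nan"))
            )
            sector.columns.append(col)
            sector.loadings[col] = float(loading_s) if loading_s else float("nan")
    return SectorAssignment(sectors=list(sectors.values()), unassigned=unassigned, L=max_col)


def write_results_json(
    cm: CouplingMatrix, assignment: SectorAssignment, path: str, extra: dict | None = None
) -> None:
    """Single bundled JSON results file for the coupling analysis."""
    payload = {
        "L": cm.L,
        "eigenvalues": None if cm.eigenvalues is None else cm.eigenvalues.tolist(),
        "k_star": cm.k_star,
        "null_quantile": cm.null_quantile,
        "n_rand": None if cm.random_spectra is None else int(cm.random_spectra.shape[0]),
        "null_top_eigenvalues": None
        if cm.random_spectra is None
        else cm.random_spectra[:, 0].tolist(),
        "sectors": [
            {
                "label": s.label,
                "columns": s.columns,
                "loadings": {str(c): v for c, v in s.loadings.items()},
                "cutoff": s.cutoff,
            }
            for s in assignment.sectors
        ],
        "unassigned": assignment.unassigned,
    }
    if extra:
        payload.update(extra)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
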