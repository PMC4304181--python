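"""Aligned-FASTA input/output and alignment curation.

Curation stages, applied in order by :func:`curate`:

1. header-pattern filtering of low-quality / partial entries,
2. redundancy clustering (greedy single-linkage at an identity/coverage
   threshold; the longest member represents each cluster),
3. removal of gap-heavy rows,
4. trimming of columns outside the reference span,
5. removal of gapped columns (with a surviving-column index map).

The reference row is immune to every removal filter: the entire downstream
structure mapping depends on it. Curation never edits residue characters;
it only removes rows or columns.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field, replace

from Bio import SeqIO

from .background import AA_ALPHABET

_VALID_CHARS = set(AA_ALPHABET) | {"X", "-"}

#: Header substrings (case-insensitive) that mark low-quality entries.
DEFAULT_LOW_QUALITY_PATTERNS: tuple[str, ...] = ("LOW QUALITY", "partial")

#: Below this many rows a warning (not an error) is emitted before analysis.
MIN_RECOMMENDED_SEQUENCES = 100


@dataclass(frozen=True)
class SequenceRecord:
    """One aligned sequence: FASTA id token, residue string, reference flag."""

    id: str
    residues: str
    is_reference: bool = False
    description: str = ""

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} is empty")

    @property
    def ungapped(self) -> str:
        return self.residues.replace("-", "")

    @property
    def gap_fraction(self) -> float:
        return self.residues.count("-") / len(self.residues)


@dataclass
class Alignment:
    """An ordered list of equal-length :class:`SequenceRecord` rows."""

    records: list[SequenceRecord]

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("alignment has no sequences")
        lengths = {len(r.residues) for r in self.records}
        if len(lengths) > 1:
            raise ValueError(f"ragged alignment: row lengths {sorted(lengths)}")
        n_ref = sum(r.is_reference for r in self.records)
        if n_ref > 1:
            raise ValueError("more than one reference sequence flagged")

    @property
    def M(self) -> int:
        return len(self.records)

    @property
    def L(self) -> int:
        return len(self.records[0].residues)

    @property
    def reference(self) -> SequenceRecord:
        for r in self.records:
            if r.is_reference:
                return r
        raise ValueError("reference not found in alignment")

    @property
    def has_reference(self) -> bool:
        return any(r.is_reference for r in self.records)

    def column(self, i: int) -> str:
        """Column ``i`` (0-based) as a string of length M."""
        return "".join(r.residues[i] for r in self.records)

    def select_columns(self, cols: list[int]) -> "Alignment":
        """New alignment keeping 0-based columns ``cols`` in the given order."""
        return Alignment(
            [replace(r, residues="".join(r.residues[c] for c in cols)) for r in self.records]
        )


@dataclass
class CurationReport:
    """Row counts after each curation stage plus per-row removal reasons."""

    n_input: int = 0
    n_after_clustering: int = 0
    n_after_gap_filter: int = 0
    n_after_trim: int = 0
    removed_ids: list[tuple[str, str]] = field(default_factory=list)

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "n_input": self.n_input,
                    "n_after_clustering": self.n_after_clustering,
                    "n_after_gap_filter": self.n_after_gap_filter,
                    "n_after_trim": self.n_after_trim,
                    "removed": [{"id": i, "reason": r} for i, r in self.removed_ids],
                },
                fh,
                indent=2,
            )

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("key\tvalue\n")
            fh.write(f"n_input\t{self.n_input}\n")
            fh.write(f"n_after_clustering\t{self.n_after_clustering}\n")
            fh.write(f"n_after_gap_filter\t{self.n_after_gap_filter}\n")
            fh.write(f"n_after_trim\t{self.n_after_trim}\n")
            for seq_id, reason in self.removed_ids:
                fh.write(f"removed\t{seq_id}: {reason}\n")


def _normalize(seq: str) -> str:
    return seq.upper().replace(".", "-")


def read_alignment(path: str, reference_id: str) -> Alignment:
    """Read an aligned FASTA file, flagging ``reference_id`` as the reference.

    Characters are uppercased and '.' gap characters normalized to '-'.
    Raises on ragged input, a missing reference, or an empty file.
    """
    records = []
    for rec in SeqIO.parse(path, "fasta"):
        records.append(
            SequenceRecord(
                id=rec.id,
                residues=_normalize(str(rec.seq)),
                is_reference=(rec.id == reference_id),
                description=rec.description,
            )
        )
    if not records:
        raise ValueError(f"empty alignment file: {path}")
    aln = Alignment(records)
    if not aln.has_reference:
        raise ValueError(f"reference not found: {reference_id!r} is not a record id in {path}")
    return aln


def write_alignment(aln: Alignment, path: str) -> None:
    with open(path, "w") as fh:
        for r in aln.records:
            fh.write(f">{r.id}\n{r.residues}\n")


def pairwise_identity(a: SequenceRecord, b: SequenceRecord) -> tuple[float, float]:
    """Gap-free global-comparison identity and coverage for two sequences.

    Gaps are stripped; the sequences are compared position-by-position from
    their starts. ``identity`` is the number of matching positions divided by
    the longer ungapped length; ``coverage`` is the shorter ungapped length
    divided by the longer. This is a deterministic surrogate for legacy
    score-based redundancy clustering.
    """
    sa, sb = a.ungapped, b.ungapped
    if not sa or not sb:
        raise ValueError("cannot compare an empty (all-gap) sequence")
    longer = max(len(sa), len(sb))
    matches = sum(x == y for x, y in zip(sa, sb))
    return matches / longer, min(len(sa), len(sb)) / longer


def cluster_redundant(
    records: list[SequenceRecord],
    identity_threshold: float = 0.85,
    coverage_threshold: float = 1.0,
) -> tuple[list[SequenceRecord], list[list[str]]]:
    """Greedy single-linkage redundancy clustering.

    Two sequences link when identity >= ``identity_threshold`` AND coverage >=
    ``coverage_threshold``; clusters are the transitive closure of the link
    relation. Sequences are processed longest-first (ties by id) so the result
    is deterministic. The longest member of each cluster is its
    representative, except that a cluster containing the reference is always
    represented by the reference.

    Returns ``(representatives, clusters)`` where each cluster is a list of
    member ids (representative first).
    """
    if not records:
        raise ValueError("no sequences to cluster")
    order = sorted(records, key=lambda r: (-len(r.ungapped), r.id))
    clusters: list[list[SequenceRecord]] = []
    for rec in order:
        linked = [
            ci
            for ci, members in enumerate(clusters)
            if any(_links(rec, m, identity_threshold, coverage_threshold) for m in members)
        ]
        if not linked:
            clusters.append([rec])
        else:
            # merge every linked cluster (keeps transitive closure exact)
            target = clusters[linked[0]]
            for ci in reversed(linked[1:]):
                target.extend(clusters.pop(ci))
            target.append(rec)
    representatives: list[SequenceRecord] = []
    cluster_ids: list[list[str]] = []
    for members in clusters:
        rep = next(
            (m for m in members if m.is_reference),
            min(members, key=lambda r: (-len(r.ungapped), r.id)),
        )
        representatives.append(rep)
        cluster_ids.append([rep.id] + sorted(m.id for m in members if m is not rep))
    return representatives, cluster_ids


def _links(a: SequenceRecord, b: SequenceRecord, id_thr: float, cov_thr: float) -> bool:
    ident, cov = pairwise_identity(a, b)
    return ident >= id_thr and cov >= cov_thr


def filter_low_quality(
    records: list[SequenceRecord],
    patterns: tuple[str, ...] = DEFAULT_LOW_QUALITY_PATTERNS,
) -> tuple[list[SequenceRecord], list[tuple[str, str]]]:
    """Drop non-reference records whose header matches a pattern (case-insensitive)."""
    kept, removed = [], []
    compiled = [(p, re.compile(re.escape(p), re.IGNORECASE)) for p in patterns]
    for r in records:
        header = f"{r.id} {r.description}"
        hit = next((p for p, c in compiled if c.search(header)), None)
        if hit is not None and not r.is_reference:
            removed.append((r.id, f"header matches low-quality pattern {hit!r}"))
        else:
            kept.append(r)
    return kept, removed


def filter_gap_heavy(
    aln: Alignment, max_gap_fraction: float = 0.25
) -> tuple[Alignment, CurationReport]:
    """Remove non-reference rows whose gap fraction exceeds ``max_gap_fraction``.

    The reference row is always retained; if it exceeds the threshold a
    warning is emitted instead.
    """
    kept, removed = [], []
    for r in aln.records:
        if r.gap_fraction > max_gap_fraction:
            if r.is_reference:
                warnings.warn(
                    f"reference {r.id!r} has gap fraction "
                    f"{r.gap_fraction:.2f} > {max_gap_fraction}; retained anyway"
                )
                kept.append(r)
            else:
                removed.append((r.id, f"row gap fraction {r.gap_fraction:.3f} > {max_gap_fraction}"))
        else:
            kept.append(r)
    report = CurationReport(
        n_input=aln.M,
        n_after_clustering=aln.M,
        n_after_gap_filter=len(kept),
        n_after_trim=len(kept),
        removed_ids=removed,
    )
    return Alignment(kept), report


def trim_to_reference(aln: Alignment) -> Alignment:
    """Remove columns before the first and after the last reference residue."""
    ref = aln.reference
    residues = ref.residues
    first = next((i for i, c in enumerate(residues) if c != "-"), None)
    if first is None:
        raise ValueError(f"reference {ref.id!r} is entirely gaps; cannot trim")
    last = max(i for i, c in enumerate(residues) if c != "-")
    return aln.select_columns(list(range(first, last + 1)))


def drop_gapped_columns(
    aln: Alignment,
    max_col_gap_fraction: float = 0.2,
    require_reference_residue: bool = True,
) -> tuple[Alignment, list[int]]:
    """Drop gap-rich columns, returning the surviving-column index map.

    A column survives when its gap fraction is <= ``max_col_gap_fraction``
    and (if ``require_reference_residue``) the reference row holds a residue
    there. ``kept_columns`` lists surviving columns as 1-based indices into
    the input alignment, in increasing order.
    """
    ref = aln.reference if (require_reference_residue and aln.has_reference) else None
    kept: list[int] = []
    for i in range(aln.L):
        col = aln.column(i)
        if col.count("-") / aln.M > max_col_gap_fraction:
            continue
        if ref is not None and ref.residues[i] == "-":
            continue
        kept.append(i)
    if not kept:
        raise ValueError("no columns survive the gap filter")
    return aln.select_columns(kept), [i + 1 for i in kept]


def curate(
    aln: Alignment,
    identity_threshold: float = 0.85,
    coverage_threshold: float = 1.0,
    max_row_gap_fraction: float = 0.25,
    max_col_gap_fraction: float = 0.2,
    low_quality_patterns: tuple[str, ...] = DEFAULT_LOW_QUALITY_PATTERNS,
) -> tuple[Alignment, list[int], CurationReport]:
    """Run the full curation pipeline.

    Returns the curated alignment, the 1-based surviving-column map into the
    input alignment, and a :class:`CurationReport`.
    """
    report = CurationReport(n_input=aln.M)
    records, removed_lq = filter_low_quality(aln.records, low_quality_patterns)
    report.removed_ids.extend(removed_lq)

    reps, _clusters = cluster_redundant(records, identity_threshold, coverage_threshold)
    rep_ids = {r.id for r in reps}
    report.removed_ids.extend(
        (r.id, "redundant (clustered with a longer representative)")
        for r in records
        if r.id not in rep_ids
    )
    # keep original row order
    aln2 = Alignment([r for r in aln.records if r.id in rep_ids])
    report.n_after_clustering = aln2.M

    aln3, gap_report = filter_gap_heavy(aln2, max_row_gap_fraction)
    report.removed_ids.extend(gap_report.removed_ids)
    report.n_after_gap_filter = aln3.M

    aln4 = trim_to_reference(aln3)
    # column indices into the trimmed alignment, shifted back to the input frame
    ref = aln3.reference
    offset = next(i for i, c in enumerate(ref.residues) if c != "-")
    aln5, kept = drop_gapped_columns(aln4, max_col_gap_fraction)
    kept_original = [k + offset for k in kept]
    report.n_after_trim = aln5.M

    if aln5.M < MIN_RECOMMENDED_SEQUENCES:
        warnings.warn(
            f"curated alignment has only {aln5.M} sequences "
            f"(< {MIN_RECOMMENDED_SEQUENCES}); coupling estimates may be noisy"
        )
    return aln5, kept_original, report
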