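"""Annotate disease-associated substitutions with sector and region labels.

Mutations arrive as a TSV with a ``substitution`` column in HGVS-like short
form (G56A, R70TER), an optional ``phenotype`` free-text column and an
optional ``domain_label`` column. Annotation is a pure join against a
sector assignment and a structure map keyed by author residue number.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass

import pandas as pd
import yaml

from .background import AA_ALPHABET
from .sca import SectorAssignment
from .structure import StructureMap

_SUBSTITUTION_RE = re.compile(
    rf"^(?P<wt>[{AA_ALPHABET}])(?P<pos>\d+)(?P<var>TER|\*|[{AA_ALPHABET}])$"
)


@dataclass(frozen=True)
class MutationRecord:
    wild_type: str
    position: int
    variant: str  # one-letter amino acid or "TER"
    phenotype: str = ""
    domain_label: str | None = None

    @property
    def name(self) -> str:
        return f"{self.wild_type}{self.position}{self.variant}"


@dataclass(frozen=True)
class ParseError:
    line: int
    text: str
    reason: str


def parse_substitution(text: str) -> tuple[str, int, str]:
    """Split 'G56A' / 'R70TER' into (wild type, position, variant)."""
    m = _SUBSTITUTION_RE.match(text.strip().upper())
    if m is None:
        raise ValueError(f"malformed substitution {text!r} (expected e.g. G56A or R70TER)")
    var = m.group("var")
    return m.group("wt"), int(m.group("pos")), "TER" if var in {"TER", "*"} else var


def parse_mutations(path: str) -> tuple[list[MutationRecord], list[ParseError]]:
    """Parse a mutation TSV; malformed rows are collected, never dropped silently.

    The file needs a header with a ``substitution`` column; ``phenotype``
    and ``domain_label`` are optional.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    cols = {c.lower(): c for c in df.columns}
    if "substitution" not in cols:
        raise ValueError(f"{path} has no 'substitution' column (found {list(df.columns)})")
    records, errors = [], []
    for idx, row in df.iterrows():
        text = str(row[cols["substitution"]])
        line = int(idx) + 2  # 1-based, after the header
        try:
            wt, pos, var = parse_substitution(text)
        except ValueError as exc:
            errors.append(ParseError(line=line, text=text, reason=str(exc)))
            continue
        records.append(
            MutationRecord(
                wild_type=wt,
                position=pos,
                variant=var,
                phenotype=str(row[cols["phenotype"]]) if "phenotype" in cols else "",
                domain_label=(str(row[cols["domain_label"]]) or None)
                if "domain_label" in cols
                else None,
            )
        )
    return records, errors


@dataclass
class RegionScheme:
    """Ordered, non-overlapping closed residue intervals in author numbering.

    Positions outside every interval classify as ``"other"``. Boundaries are
    user configuration — the N-terminal / central / C-terminal split is
    protein-specific.
    """

    regions: list[tuple[str, int, int]]
    is_default: bool = False

    def __post_init__(self) -> None:
        prev_end = None
        for name, start, end in self.regions:
            if start > end:
                raise ValueError(f"region {name!r} has start {start} > end {end}")
            if prev_end is not None and start <= prev_end:
                raise ValueError(f"region {name!r} overlaps the previous region")
            prev_end = end

    def classify(self, position: int) -> str:
        for name, start, end in self.regions:
            if start <= position <= end:
                return name
        return "other"

    @classmethod
    def tertiles(cls, start: int, end: int) -> "RegionScheme":
        """Default scheme: tertiles of the mapped residue range, flagged as such."""
        span = end - start + 1
        b1 = start + span // 3 - 1
        b2 = start + 2 * span // 3 - 1
        return cls(
            regions=[
                ("N-terminal", start, b1),
                ("central/other", b1 + 1, b2),
                ("C-terminal", b2 + 1, end),
            ],
            is_default=True,
        )

    @classmethod
    def from_yaml(cls, path: str) -> "RegionScheme":
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        regions = [(r["name"], int(r["start"]), int(r["end"])) for r in cfg["regions"]]
        return cls(regions=regions)


def classify_region(position: int, scheme: RegionScheme) -> str:
    return scheme.classify(position)


@dataclass(frozen=True)
class AnnotatedMutation:
    mutation: MutationRecord
    sector: str       # palette color or "-"
    region: str
    wild_type_match: bool | None  # None when the position is unmapped

    @property
    def domain_or_region(self) -> str:
        return self.mutation.domain_label or self.region


def annotate(
    muts: list[MutationRecord],
    sectors: SectorAssignment,
    smap: StructureMap,
    scheme: RegionScheme,
) -> list[AnnotatedMutation]:
    """Join mutations to sectors and regions by author residue number.

    A pure join: one output per input, nothing invented or dropped. The
    sector is "-" exactly when the position is unassigned or unmapped; a
    wild-type mismatch against the mapped reference residue is flagged, not
    fatal.
    """
    col_of_residue = {
        e.resnum: e.column for e in smap.entries if not e.icode
    }
    ref_aa_of_residue = {e.resnum: e.aa_ref for e in smap.entries if not e.icode}
    label_of_column = sectors.label_by_column()
    out = []
    for mut in muts:
        column = col_of_residue.get(mut.position)
        if column is None:
            sector, match = "-", None
        else:
            sector = label_of_column.get(column, "-")
            match = ref_aa_of_residue[mut.position] == mut.wild_type
        out.append(
            AnnotatedMutation(
                mutation=mut,
                sector=sector,
                region=scheme.classify(mut.position),
                wild_type_match=match,
            )
        )
    return out


def write_annotations(annotated: list[AnnotatedMutation], path: str) -> None:
    """Annotated table, mirrored on the published layout:
    Residue / Sector / Domain-Region / Effect-Phenotype plus the match flag."""
    with open(path, "w") as fh:
        fh.write("residue\tsector\tdomain_region\tphenotype\twild_type_match\n")
        for a in annotated:
            match = "" if a.wild_type_match is None else str(int(a.wild_type_match))
            fh.write(
                f"{a.mutation.name}\t{a.sector}\t{a.domain_or_region}\t"
                f"{a.mutation.phenotype}\t{match}\n"
            )


def write_annotations_json(annotated: list[AnnotatedMutation], path: str) -> None:
    with open(path, "w") as fh:
        json.dump(
            [
                {
                    "residue": a.mutation.name,
                    "wild_type": a.mutation.wild_type,
                    "position": a.mutation.position,
                    "variant": a.mutation.variant,
                    "sector": a.sector,
                    "region": a.region,
                    "domain_region": a.domain_or_region,
                    "phenotype": a.mutation.phenotype,
                    "wild_type_match": a.wild_type_match,
                }
                for a in annotated
            ],
            fh,
            indent=2,
        )
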