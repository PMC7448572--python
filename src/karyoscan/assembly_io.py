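"""Assembly sequence and layout I/O.

Reads and writes FASTA and AGP v2.x, and establishes the
scaffold -> contig -> gap decomposition (:class:`AssemblyLayout`) that the
contiguity, window-QC and feature-calling modules consume.

Coordinate conventions: FASTA/AGP coordinates are kept 1-based inclusive
internally (AGP native); every exported interval file uses 0-based
half-open BED semantics.
"""

from __future__ import annotations

import gzip
import io
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

__all__ = [
    "SequenceRecord",
    "GapRecord",
    "ComponentRecord",
    "AgpObject",
    "AssemblyLayout",
    "FastaParseError",
    "AgpError",
    "ValidationReport",
    "DEFAULT_CHROM_PATTERN",
    "read_fasta",
    "write_fasta",
    "read_agp",
    "write_agp",
    "infer_layout_from_fasta",
    "validate_layout",
]

#: Sequence names treated as chromosome assignments when only FASTA is
#: available: bare numbers, X, Y, MT (optionally "chr"-prefixed).
DEFAULT_CHROM_PATTERN = r"^(?:chr)?(\d+|X|Y|MT?)$"

_COMPONENT_TYPES = frozenset("WADFO")
_GAP_TYPES = frozenset("NU")


class FastaParseError(ValueError):
    """Malformed FASTA input; message names the offending line."""


class AgpError(ValueError):
    """Malformed or non-tiling AGP input; message names the object."""


@dataclass
class SequenceRecord:
    """A single assembled sequence (contig, scaffold or chromosome)."""

    id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def upper(self) -> str:
        """Analysis view of the sequence: soft-masking folded away."""
        return self.sequence.upper()


@dataclass
class GapRecord:
    """A gap line of an assembled object, 1-based inclusive coordinates.

    ``spanned`` gaps sit within a scaffold (AGP linkage "yes");
    ``unspanned`` gaps join scaffolds within a chromosome (linkage "no").
    """

    object_id: str
    start: int
    end: int
    gap_kind: str  # "spanned" | "unspanned"
    declared_length: int
    gap_type: str = "N"  # AGP column 5: N (known size) or U (unknown, 100)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise AgpError(f"{self.object_id}: gap start {self.start} > end {self.end}")
        if self.end - self.start + 1 != self.declared_length:
            raise AgpError(
                f"{self.object_id}: gap span {self.end - self.start + 1} != "
                f"declared length {self.declared_length}"
            )


@dataclass
class ComponentRecord:
    """An AGP component (W/A/D/F/O) line, 1-based inclusive coordinates."""

    object_id: str
    object_start: int
    object_end: int
    part_number: int
    component_id: str
    component_start: int
    component_end: int
    orientation: str = "+"
    component_type: str = "W"

    def __post_init__(self) -> None:
        if self.object_end - self.object_start != self.component_end - self.component_start:
            raise AgpError(
                f"{self.object_id}: component {self.component_id} object span "
                "differs from component span"
            )

    @property
    def length(self) -> int:
        return self.object_end - self.object_start + 1


@dataclass
class AgpObject:
    """One assembled object (scaffold or chromosome) with its parts."""

    object_id: str
    chromosome_assignment: str | None  # chromosome name, or None = unplaced
    components: list[ComponentRecord] = field(default_factory=list)
    gaps: list[GapRecord] = field(default_factory=list)

    @property
    def length(self) -> int:
        ends = [c.object_end for c in self.components] + [g.end for g in self.gaps]
        return max(ends) if ends else 0

    def parts(self) -> list[ComponentRecord | GapRecord]:
        """Components and gaps interleaved in object order."""

        def _start(p):
            return p.object_start if isinstance(p, ComponentRecord) else p.start

        return sorted([*self.components, *self.gaps], key=_start)


@dataclass
class AssemblyLayout:
    """The scaffold/contig/gap decomposition of a whole assembly."""

    objects: list[AgpObject] = field(default_factory=list)

    def __iter__(self):
        return iter(self.objects)

    def __len__(self) -> int:
        return len(self.objects)

    def get(self, object_id: str) -> AgpObject:
        for obj in self.objects:
            if obj.object_id == object_id:
                return obj
        raise KeyError(object_id)


@dataclass
class ValidationReport:
    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


def _open_text(path, mode: str = "rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path, uppercase: bool = True) -> list[SequenceRecord]:
    """Read a FASTA file (plain or gzip) into :class:`SequenceRecord` list.

    Sequences are uppercased by default; pass ``uppercase=False`` to keep
    soft-masked (lowercase) bases as written.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    with _open_text(path) as handle:
        text = handle.read()
    # Light pre-scan so parse errors can name a line number.
    stripped = text.lstrip()
    if stripped and not stripped.startswith(">"):
        first_bad = next(
            i for i, ln in enumerate(text.splitlines(), 1) if ln.strip()
        )
        raise FastaParseError(f"line {first_bad}: expected FASTA header '>'")
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        if not rec.id:
            raise FastaParseError("record with empty id")
        if rec.id in seen:
            raise FastaParseError(f"duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq)
        if not seq:
            line_no = next(
                (i for i, ln in enumerate(text.splitlines(), 1)
                 if ln.startswith(">") and ln[1:].split()[:1] == [rec.id]),
                0,
            )
            raise FastaParseError(f"line {line_no}: empty sequence for {rec.id!r}")
        records.append(SequenceRecord(rec.id, seq.upper() if uppercase else seq))
    return records


def write_fasta(records: Iterable[SequenceRecord], path, width: int = 60) -> None:
    """Write records as FASTA (gzip if the path ends in .gz)."""
    bio = [_BioRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    with _open_text(path, "wt") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(bio)


def _classify_chrom(object_id: str, chrom_pattern: str | None) -> str | None:
    if chrom_pattern is None:
        return None
    m = re.match(chrom_pattern, object_id)
    return m.group(1) if m else None


def read_agp(path, chrom_pattern: str | None = DEFAULT_CHROM_PATTERN) -> AssemblyLayout:
    """Read an AGP v2.x file into an :class:`AssemblyLayout`.

    Gap lines (type N/U) become :class:`GapRecord` with kind ``spanned``
    when linkage is "yes" and ``unspanned`` otherwise; type-U gaps default
    to the conventional declared length of 100. Objects whose name matches
    ``chrom_pattern`` are chromosome-assigned.
    """
    objects: dict[str, AgpObject] = {}
    with _open_text(path) as handle:
        for line_no, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 8:
                raise AgpError(f"line {line_no}: expected >=8 tab-separated columns")
            object_id, o_start, o_end, part, comp_type = cols[:5]
            try:
                o_start, o_end, part = int(o_start), int(o_end), int(part)
            except ValueError as exc:
                raise AgpError(f"{object_id}: non-integer coordinates at line {line_no}") from exc
            if o_start < 1 or o_end < o_start:
                raise AgpError(f"{object_id}: bad coordinates {o_start}..{o_end}")
            obj = objects.setdefault(
                object_id,
                AgpObject(object_id, _classify_chrom(object_id, chrom_pattern)),
            )
            prev_end = obj.length
            if o_start != prev_end + 1:
                raise AgpError(
                    f"{object_id}: part {part} starts at {o_start}, expected {prev_end + 1}"
                )
            n_parts = len(obj.components) + len(obj.gaps)
            if part != n_parts + 1:
                raise AgpError(f"{object_id}: part numbers not consecutive at line {line_no}")
            if comp_type in _GAP_TYPES:
                declared = int(cols[5]) if comp_type == "N" else 100
                linkage = cols[7].strip().lower()
                kind = "spanned" if linkage == "yes" else "unspanned"
                obj.gaps.append(
                    GapRecord(object_id, o_start, o_end, kind, declared, comp_type)
                )
            elif comp_type in _COMPONENT_TYPES:
                if len(cols) < 9:
                    raise AgpError(f"{object_id}: component line has <9 columns at line {line_no}")
                obj.components.append(
                    ComponentRecord(
                        object_id, o_start, o_end, part,
                        cols[5], int(cols[6]), int(cols[7]),
                        cols[8], comp_type,
                    )
                )
            else:
                raise AgpError(f"{object_id}: unknown component type {comp_type!r}")
    return AssemblyLayout(list(objects.values()))


def write_agp(layout: AssemblyLayout, path) -> None:
    """Serialize a layout as AGP v2.1."""
    with _open_text(path, "wt") as handle:
        handle.write("##agp-version\t2.1\n")
        for obj in layout:
            for i, p in enumerate(obj.parts(), 1):
                if isinstance(p, GapRecord):
                    linkage = "yes" if p.gap_kind == "spanned" else "no"
                    evidence = "paired-ends" if linkage == "yes" else "na"
                    handle.write(
                        f"{obj.object_id}\t{p.start}\t{p.end}\t{i}\t{p.gap_type}\t"
                        f"{p.declared_length}\tscaffold\t{linkage}\t{evidence}\n"
                    )
                else:
                    handle.write(
                        f"{obj.object_id}\t{p.object_start}\t{p.object_end}\t{i}\t"
                        f"{p.component_type}\t{p.component_id}\t{p.component_start}\t"
                        f"{p.component_end}\t{p.orientation}\n"
                    )


def infer_layout_from_fasta(
    records: Sequence[SequenceRecord],
    min_gap_n: int = 10,
    chrom_pattern: str | None = DEFAULT_CHROM_PATTERN,
) -> AssemblyLayout:
    """Infer a layout from sequence alone.

    Every maximal run of >= ``min_gap_n`` N characters becomes a spanned
    gap splitting contigs; shorter N runs stay inside contigs. The default
    threshold of 10 follows the NCBI assembly-stats convention.
    """
    objects = []
    gap_re = re.compile("N{%d,}" % min_gap_n)
    for rec in records:
        obj = AgpObject(rec.id, _classify_chrom(rec.id, chrom_pattern))
        seq = rec.upper
        pos = 0  # 0-based cursor
        part = 0
        n_contig = 0
        for m in gap_re.finditer(seq):
            if m.start() > pos:
                n_contig += 1
                part += 1
                obj.components.append(
                    ComponentRecord(
                        rec.id, pos + 1, m.start(), part,
                        f"{rec.id}_ctg{n_contig}", 1, m.start() - pos,
                    )
                )
            part += 1
            obj.gaps.append(
                GapRecord(rec.id, m.start() + 1, m.end(), "spanned", m.end() - m.start())
            )
            pos = m.end()
        if pos < len(seq):
            n_contig += 1
            part += 1
            obj.components.append(
                ComponentRecord(
                    rec.id, pos + 1, len(seq), part,
                    f"{rec.id}_ctg{n_contig}", 1, len(seq) - pos,
                )
            )
        objects.append(obj)
    return AssemblyLayout(objects)


def validate_layout(layout: AssemblyLayout, records: Sequence[SequenceRecord]) -> ValidationReport:
    """Cross-check a layout against the sequences it claims to describe.

    Reports (never raises): object lengths that disagree with sequence
    lengths, gap coordinates whose sequence is not N, components out of
    order or non-tiling.
    """
    report = ValidationReport()
    by_id = {r.id: r for r in records}
    for obj in layout:
        rec = by_id.get(obj.object_id)
        if rec is None:
            report.violations.append(f"{obj.object_id}: no sequence record")
            continue
        if obj.length != rec.length:
            report.violations.append(
                f"{obj.object_id}: layout length {obj.length} != sequence length {rec.length}"
            )
        seq = rec.upper
        pos = 0
        for p in obj.parts():
            start = p.object_start if isinstance(p, ComponentRecord) else p.start
            end = p.object_end if isinstance(p, ComponentRecord) else p.end
            if start != pos + 1:
                report.violations.append(
                    f"{obj.object_id}: part at {start} does not tile (expected {pos + 1})"
                )
            pos = end
            if isinstance(p, GapRecord) and end <= len(seq):
                chunk = seq[start - 1:end]
                if set(chunk) - {"N"}:
                    report.violations.append(
                        f"{obj.object_id}: gap {start}..{end} contains non-N sequence"
                    )
    return report
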