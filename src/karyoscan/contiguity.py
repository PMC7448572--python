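"""Assembly contiguity statistics under NCBI conventions.

Contigs are components split at every AGP gap line (spanned or unspanned),
scaffolds are objects split at unspanned gaps, and Nx/Lx follow the
standard descending-cumulative-sum definition. The statistics mirror the
rows of an NCBI assembly report: total/ungapped length, scaffold and
contig N50/L50, gap counts, and the placed/unplaced decomposition.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .assembly_io import (
    AgpObject,
    AssemblyLayout,
    ComponentRecord,
    GapRecord,
    SequenceRecord,
    validate_layout,
)

__all__ = ["AssemblyStats", "nx", "assembly_stats", "stats_table", "STAT_ROWS"]

#: Default names treated as the mitochondrial sequence.
MT_NAMES = frozenset({"MT", "M", "chrM", "chrMT"})

STAT_ROWS = [
    "total_length",
    "ungapped_length",
    "n_scaffolds",
    "n_unplaced_scaffolds",
    "scaffold_n50",
    "scaffold_l50",
    "n_contigs",
    "contig_n50",
    "contig_l50",
    "n_spanned_gaps",
    "n_unspanned_gaps",
    "n_chromosomes",
]


@dataclass
class AssemblyStats:
    total_length: int
    ungapped_length: int
    n_scaffolds: int
    n_unplaced_scaffolds: int
    n_unlocalized_scaffolds: int
    scaffold_n50: int
    scaffold_l50: int
    n_contigs: int
    contig_n50: int
    contig_l50: int
    n_spanned_gaps: int
    n_unspanned_gaps: int
    n_chromosomes: int

    def as_dict(self) -> dict:
        return asdict(self)


def nx(lengths: Iterable[int], x: float = 50) -> tuple[int, int]:
    """Return (Nx, Lx) of a multiset of lengths.

    Nx is the length of the element at which the descending cumulative sum
    first reaches >= x% of the total; Lx is the number of elements up to
    and including it.
    """
    lens = sorted(lengths, reverse=True)
    if not lens:
        raise ValueError("nx of an empty length set is undefined")
    if not 0 < x <= 100:
        raise ValueError(f"x must be in (0, 100], got {x}")
    threshold = x / 100.0 * sum(lens)
    cum = 0
    for i, length in enumerate(lens, 1):
        cum += length
        if cum >= threshold:
            return length, i
    return lens[-1], len(lens)  # unreachable; appease type checkers


def _contig_lengths(obj: AgpObject) -> list[int]:
    """Contig lengths of one object: component runs broken at every gap line."""
    lengths: list[int] = []
    run = 0
    for part in obj.parts():
        if isinstance(part, GapRecord):
            if run:
                lengths.append(run)
            run = 0
        else:
            run += part.length
    if run:
        lengths.append(run)
    return lengths


def _scaffold_lengths(obj: AgpObject) -> list[int]:
    """Scaffold lengths: object split at unspanned gaps, spanned gaps included."""
    lengths: list[int] = []
    run = 0
    for part in obj.parts():
        if isinstance(part, GapRecord) and part.gap_kind == "unspanned":
            if run:
                lengths.append(run)
            run = 0
        elif isinstance(part, GapRecord):
            run += part.declared_length
        else:
            run += part.length
    if run:
        lengths.append(run)
    return lengths


def assembly_stats(
    layout: AssemblyLayout,
    records: Sequence[SequenceRecord] | None = None,
    include_mt: bool = False,
    mt_names: frozenset[str] = MT_NAMES,
) -> AssemblyStats:
    """Compute assembly statistics from a validated layout.

    The mitochondrial sequence is counted in ``n_chromosomes`` but excluded
    from contig/scaffold N50 unless ``include_mt``. When ``records`` are
    given the layout is cross-checked first.
    """
    if records is not None:
        report = validate_layout(layout, records)
        if not report.ok:
            raise ValueError(
                "layout/sequence mismatch (see validate_layout): "
                + "; ".join(report.violations[:5])
            )

    total = sum(obj.length for obj in layout)
    gap_bases = sum(g.declared_length for obj in layout for g in obj.gaps)
    contig_lens: list[int] = []
    scaffold_lens: list[int] = []
    n_scaffolds = n_unplaced = n_unlocalized = 0
    n_spanned = n_unspanned = 0
    chromosomes: set[str] = set()

    for obj in layout:
        is_mt = obj.object_id in mt_names or (obj.chromosome_assignment in mt_names
                                              if obj.chromosome_assignment else False)
        if obj.chromosome_assignment is not None:
            chromosomes.add(obj.chromosome_assignment)
        sc = _scaffold_lengths(obj)
        n_scaffolds += len(sc)
        if obj.chromosome_assignment is None:
            n_unplaced += len(sc)
        elif (obj.object_id not in (obj.chromosome_assignment,
                                    "chr" + obj.chromosome_assignment)
              and not is_mt):
            # assigned to a chromosome but not the chromosome object itself
            n_unlocalized += len(sc)
        n_spanned += sum(1 for g in obj.gaps if g.gap_kind == "spanned")
        n_unspanned += sum(1 for g in obj.gaps if g.gap_kind == "unspanned")
        if is_mt and not include_mt:
            continue
        contig_lens.extend(_contig_lengths(obj))
        scaffold_lens.extend(sc)

    c_n50, c_l50 = nx(contig_lens, 50) if contig_lens else (0, 0)
    s_n50, s_l50 = nx(scaffold_lens, 50) if scaffold_lens else (0, 0)
    return AssemblyStats(
        total_length=total,
        ungapped_length=total - gap_bases,
        n_scaffolds=n_scaffolds,
        n_unplaced_scaffolds=n_unplaced,
        n_unlocalized_scaffolds=n_unlocalized,
        scaffold_n50=s_n50,
        scaffold_l50=s_l50,
        n_contigs=len(contig_lens),
        contig_n50=c_n50,
        contig_l50=c_l50,
        n_spanned_gaps=n_spanned,
        n_unspanned_gaps=n_unspanned,
        n_chromosomes=len(chromosomes),
    )


def stats_table(assemblies: Mapping[str, AssemblyStats]) -> pd.DataFrame:
    """Side-by-side comparison table: one column per assembly."""
    if not assemblies:
        raise ValueError("at least one assembly required")
    data = {name: [getattr(st, row) for row in STAT_ROWS]
            for name, st in assemblies.items()}
    return pd.DataFrame(data, index=STAT_ROWS)


def write_stats(table: pd.DataFrame, out_prefix: str) -> None:
    table.to_csv(f"{out_prefix}.tsv", sep="\t", index_label="statistic")
    with open(f"{out_prefix}.json", "w") as fh:
        json.dump({c: dict(zip(table.index, map(int, table[c]))) for c in table.columns},
                  fh, indent=2)
        fh.write("\n")
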