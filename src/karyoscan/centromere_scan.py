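"""Centromeric satellite annotation and super-region calling.

Consumes RepeatMasker ``.out`` annotation tables (default and novel repeat
libraries), filters records by divergence (> 40% removed) and by aligned
fraction of the repeat consensus (< 70% removed), locates
centromere-specific satellite monomers by k-mer seeded ungapped search,
and merges the evidence streams into candidate centromeric super-regions:
intervals closer than the collapse distance (500 bp) are unioned and
regions longer than 5 kb are retained.
"""

from __future__ import annotations

import re
import statistics
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .assembly_io import SequenceRecord
from .telomere_scan import revcomp

__all__ = [
    "RepeatRecord",
    "SatelliteHit",
    "SuperRegion",
    "CentromereCall",
    "read_repeatmasker_out",
    "filter_repeats",
    "select_centromeric",
    "search_satellite_monomers",
    "merge_and_collapse",
    "call_centromeres",
    "predict_centromeres",
]


@dataclass
class RepeatRecord:
    """One RepeatMasker hit, coordinates converted to 0-based half-open."""

    seq_id: str
    start: int
    end: int
    strand: str  # "+" | "-"
    repeat_name: str
    repeat_class: str
    pct_div: float
    consensus_aligned: int
    consensus_length: int
    score: float
    overlapped: bool = False  # trailing '*' flag

    @property
    def aligned_fraction(self) -> float:
        return self.consensus_aligned / self.consensus_length


@dataclass
class SatelliteHit:
    seq_id: str
    start: int
    end: int
    monomer_id: str
    identity: float
    strand: str = "+"


@dataclass
class SuperRegion:
    seq_id: str
    start: int
    end: int
    sources: frozenset[str] = frozenset()
    n_merged: int = 1

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class CentromereCall:
    seq_id: str
    start: int
    end: int
    sources: frozenset[str]
    n_merged: int

    @property
    def length(self) -> int:
        return self.end - self.start


def _parse_int(tok: str) -> int:
    return int(tok.strip("()"))


def read_repeatmasker_out(path) -> list[RepeatRecord]:
    """Parse a RepeatMasker ``.out`` table.

    The three header lines are skipped. Plus-strand hits carry repeat
    coordinates as (begin, end, (left)); "C" (complement) hits swap them
    to ((left), end, begin). Consensus length is repeat end + remaining
    left bases in either case; aligned length is end - begin + 1.
    """
    records: list[RepeatRecord] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            cols = line.split()
            if not cols:
                continue
            if not cols[0].lstrip("-").isdigit():
                continue  # header lines ("SW", "score", ...)
            if len(cols) < 14:
                raise ValueError(
                    f"line {line_no}: expected >=14 whitespace-delimited columns, got {len(cols)}"
                )
            score = float(cols[0])
            pct_div = float(cols[1])
            seq_id, q_begin, q_end = cols[4], int(cols[5]), int(cols[6])
            strand_tok = cols[8]
            repeat_name, repeat_class = cols[9], cols[10]
            if strand_tok == "C":
                strand = "-"
                r_left, r_end, r_begin = (_parse_int(cols[11]), _parse_int(cols[12]),
                                          _parse_int(cols[13]))
            else:
                strand = "+"
                r_begin, r_end, r_left = (_parse_int(cols[11]), _parse_int(cols[12]),
                                          _parse_int(cols[13]))
            overlapped = len(cols) > 15 and cols[15] == "*"
            records.append(
                RepeatRecord(
                    seq_id=seq_id,
                    start=q_begin - 1,
                    end=q_end,
                    strand=strand,
                    repeat_name=repeat_name,
                    repeat_class=repeat_class,
                    pct_div=pct_div,
                    consensus_aligned=r_end - r_begin + 1,
                    consensus_length=r_end + r_left,
                    score=score,
                    overlapped=overlapped,
                )
            )
    return records


def filter_repeats(
    records: Iterable[RepeatRecord],
    max_div: float = 40.0,
    min_frac: float = 0.70,
) -> list[RepeatRecord]:
    """Drop hits with divergence > ``max_div`` percent or aligned consensus
    fraction < ``min_frac``; both boundaries are kept exactly."""
    return [
        r for r in records
        if r.pct_div <= max_div and r.aligned_fraction >= min_frac
    ]


def select_centromeric(
    records: Iterable[RepeatRecord],
    class_pattern: str = r"Satellite/centr",
    name_pattern: str | None = None,
) -> list[RepeatRecord]:
    """Keep hits whose class (or, optionally, name) marks them centromeric."""
    class_re = re.compile(class_pattern)
    name_re = re.compile(name_pattern) if name_pattern else None
    return [
        r for r in records
        if class_re.search(r.repeat_class) or (name_re and name_re.search(r.repeat_name))
    ]


def _kmer_index(seq: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        index.setdefault(seq[i:i + k], []).append(i)
    return index


def _identity_at(seq: str, monomer: str, start: int) -> tuple[int, int, float]:
    """Ungapped identity of monomer laid on seq at ``start`` (clipped)."""
    a = max(start, 0)
    b = min(start + len(monomer), len(seq))
    if b <= a:
        return a, a, 0.0
    window = seq[a:b]
    mono = monomer[a - start:b - start]
    matches = sum(1 for x, y in zip(window, mono) if x == y)
    return a, b, matches / (b - a)


def search_satellite_monomers(
    records: Sequence[SequenceRecord] | SequenceRecord,
    monomers: Sequence[SequenceRecord],
    k: int = 13,
    min_identity: float = 0.70,
) -> list[SatelliteHit]:
    """k-mer seeded, ungapped search for satellite monomer copies.

    Each exact k-mer seed proposes a monomer placement; the full-length
    ungapped alignment at that placement is scored and kept when identity
    >= ``min_identity``. Both strands are searched; overlapping hits of the
    same monomer on the same strand are merged (identity averaged over the
    merged alignments, weighted by length).
    """
    if isinstance(records, SequenceRecord):
        records = [records]
    for mono in monomers:
        if mono.length < k:
            raise ValueError(f"monomer {mono.id!r} shorter than seed length {k}")
    hits: list[SatelliteHit] = []
    for rec in records:
        seq = rec.upper
        for mono in monomers:
            for strand, mseq in (("+", mono.upper), ("-", revcomp(mono.upper))):
                index = _kmer_index(mseq, k)
                raw: dict[int, tuple[int, int, float]] = {}
                for i in range(len(seq) - k + 1):
                    offsets = index.get(seq[i:i + k])
                    if not offsets:
                        continue
                    for off in offsets:
                        cand = i - off
                        if cand not in raw:
                            raw[cand] = _identity_at(seq, mseq, cand)
                spans = sorted(
                    (a, b, ident) for a, b, ident in raw.values()
                    if ident >= min_identity and b > a
                )
                # merge overlapping/adjacent alignments of this monomer+strand
                merged: list[list[float]] = []
                for a, b, ident in spans:
                    if merged and a <= merged[-1][1]:
                        cur = merged[-1]
                        cur[2] += ident * (b - a)
                        cur[3] += b - a
                        cur[1] = max(cur[1], b)
                    else:
                        merged.append([a, b, ident * (b - a), b - a])
                for a, b, wsum, w in merged:
                    hits.append(
                        SatelliteHit(rec.id, int(a), int(b), mono.id, wsum / w, strand)
                    )
    return hits


def merge_and_collapse(
    intervals: Iterable[tuple[int, int] | SuperRegion],
    collapse_dist: int = 500,
    seq_id: str = "",
) -> list[SuperRegion]:
    """Union intervals on one sequence that overlap or lie within
    ``collapse_dist`` of each other.

    The output is sorted, disjoint, and pairwise separated by more than
    ``collapse_dist``; sources are unioned and the number of merged input
    intervals counted. Idempotent by construction.
    """
    regions: list[SuperRegion] = []
    for iv in intervals:
        if isinstance(iv, SuperRegion):
            regions.append(iv)
        else:
            regions.append(SuperRegion(seq_id, iv[0], iv[1]))
    regions.sort(key=lambda r: (r.start, r.end))
    out: list[SuperRegion] = []
    for r in regions:
        if out and r.start - out[-1].end <= collapse_dist:
            prev = out[-1]
            out[-1] = SuperRegion(
                prev.seq_id or r.seq_id,
                prev.start,
                max(prev.end, r.end),
                prev.sources | r.sources,
                prev.n_merged + r.n_merged,
            )
        else:
            out.append(r)
    return out


def call_centromeres(
    super_regions: Iterable[SuperRegion],
    min_len: int = 5000,
) -> list[CentromereCall]:
    """Retain super-regions strictly longer than ``min_len`` bases."""
    return [
        CentromereCall(r.seq_id, r.start, r.end, r.sources, r.n_merged)
        for r in super_regions
        if r.length > min_len
    ]


def predict_centromeres(
    evidence: Mapping[str, Iterable[RepeatRecord | SatelliteHit]],
    collapse_dist: int = 500,
    min_len: int = 5000,
) -> tuple[list[CentromereCall], dict[str, float]]:
    """Merge named evidence streams into centromere calls.

    ``evidence`` maps a source label (e.g. "default_library",
    "novel_library", "monomer_search") to repeat records or satellite hits.
    Returns the retained calls plus a summary with the median and mean
    length of the pre-retention merged regions.
    """
    per_seq: dict[str, list[SuperRegion]] = {}
    for source, items in evidence.items():
        for item in items:
            per_seq.setdefault(item.seq_id, []).append(
                SuperRegion(item.seq_id, item.start, item.end, frozenset({source}))
            )
    calls: list[CentromereCall] = []
    merged_lengths: list[int] = []
    for seq_id in sorted(per_seq):
        merged = merge_and_collapse(per_seq[seq_id], collapse_dist=collapse_dist)
        merged_lengths.extend(r.length for r in merged)
        calls.extend(call_centromeres(merged, min_len=min_len))
    summary = {
        "n_merged_regions": float(len(merged_lengths)),
        "median_region_length": float(statistics.median(merged_lengths)) if merged_lengths else 0.0,
        "mean_region_length": float(statistics.fmean(merged_lengths)) if merged_lengths else 0.0,
    }
    return calls, summary
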