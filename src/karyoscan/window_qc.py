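"""Window-based assembly quality classification from read alignments.

Fixed-width non-overlapping windows are summarised from coordinate-sorted
alignments (depth, GC, proper-pairing and insert-size fractions), depth is
normalized within GC bins to remove platform GC bias, and each window is
flagged:

* ``HC`` — high GC-normalized coverage (collapsed duplications),
* ``LC`` — low GC-normalized coverage,
* ``LPP`` — low proportion of properly paired reads,
* ``LLI`` / ``LSI`` — high proportion of large / small insert sizes.

``LQ`` (low quality) is the union of HC, LPP, LLI and LSI; ``LQLC`` adds
LC. Windows are carried as a pandas DataFrame with one row per window.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
from intervaltree import IntervalTree

from .assembly_io import SequenceRecord

__all__ = [
    "QcThresholds",
    "WINDOW_COLUMNS",
    "windows_from_alignments",
    "read_windows",
    "write_windows",
    "gc_normalize",
    "classify_windows",
    "subtract_mask",
    "qc_summary",
]

WINDOW_COLUMNS = [
    "seq_id", "start", "end", "gc", "depth",
    "frac_proper", "frac_large_insert", "frac_small_insert", "n_reads",
]

FLAG_COLUMNS = ["HC", "LC", "LPP", "LLI", "LSI"]

#: Table categories reported by :func:`qc_summary`.
CATEGORIES = {
    "high_coverage": "HC",
    "low_coverage": "LC",
    "low_proper_paired": "LPP",
    "high_large_inserts": "LLI",
    "high_small_inserts": "LSI",
    "lq": "lq",
    "total_lqlc": "lqlc",
}


@dataclass
class QcThresholds:
    """Classification cut-offs; every value is explicit and configurable.

    ``insert_small_bp``/``insert_large_bp`` define improper insert sizes
    as |template length| outside their range; left as None they are
    estimated at 0.5x and 2x the modal insert of the data.
    """

    lc_norm_depth_max: float = 0.25
    hc_norm_depth_min: float = 2.0
    proper_min: float = 0.80
    large_insert_max: float = 0.10
    small_insert_max: float = 0.10
    min_reads: int = 4
    insert_small_bp: int | None = None
    insert_large_bp: int | None = None

    def __post_init__(self) -> None:
        if not self.lc_norm_depth_max < 1 < self.hc_norm_depth_min:
            raise ValueError("need lc_norm_depth_max < 1 < hc_norm_depth_min")

    def as_dict(self) -> dict:
        return asdict(self)


def _gc_fraction(seq: str) -> float:
    acgt = sum(seq.count(b) for b in "ACGT")
    if acgt == 0:
        return 0.0
    return (seq.count("G") + seq.count("C")) / acgt


def _estimate_modal_insert(path, max_reads: int = 1_000_000) -> int:
    """Modal |template length| over the first reads, binned to 10 bp."""
    counts: dict[int, int] = {}
    seen = 0
    with pysam.AlignmentFile(str(path), require_index=False) as af:
        for read in af.fetch(until_eof=True):
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            tlen = abs(read.template_length)
            if tlen == 0 or read.template_length < 0:
                continue
            b = tlen // 10
            counts[b] = counts.get(b, 0) + 1
            seen += 1
            if seen >= max_reads:
                break
    if not counts:
        return 0
    return max(counts, key=counts.get) * 10 + 5


def windows_from_alignments(
    path,
    records: Sequence[SequenceRecord],
    window: int = 1000,
    insert_bounds: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Summarise a coordinate-sorted SAM/BAM into per-window statistics.

    Depth is aligned bases overlapping the window divided by window width;
    a read is counted (pairing/insert fractions, ``n_reads``) in the window
    containing its leftmost aligned base. When ``insert_bounds`` is not
    given it defaults to (0.5x, 2x) the modal insert size of the data.
    """
    if insert_bounds is None:
        modal = _estimate_modal_insert(path)
        insert_bounds = (modal // 2, modal * 2) if modal else (0, np.inf)
    lo, hi = insert_bounds

    seq_by_id = {r.id: r for r in records}
    acc: dict[str, dict[str, np.ndarray]] = {}
    lengths: dict[str, int] = {}

    def _ensure(seq_id: str) -> dict[str, np.ndarray]:
        if seq_id not in acc:
            if seq_id not in seq_by_id:
                raise ValueError(f"alignment reference {seq_id!r} not in assembly records")
            n = -(-seq_by_id[seq_id].length // window)
            lengths[seq_id] = seq_by_id[seq_id].length
            acc[seq_id] = {
                k: np.zeros(n, dtype=float)
                for k in ("bases", "n_reads", "proper", "large", "small")
            }
        return acc[seq_id]

    last: tuple[str, int] | None = None
    order: list[str] = []
    with pysam.AlignmentFile(str(path), require_index=False) as af:
        for read in af.fetch(until_eof=True):
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            ref = read.reference_name
            pos = read.reference_start
            if last is not None and last[0] == ref and pos < last[1]:
                raise ValueError("alignments are not coordinate-sorted")
            if ref in acc and (last is None or last[0] != ref):
                raise ValueError("alignments are not coordinate-sorted (reference revisited)")
            if ref not in acc:
                order.append(ref)
            last = (ref, pos)
            a = _ensure(ref)
            w = pos // window
            a["n_reads"][w] += 1
            if read.is_paired and read.is_proper_pair:
                a["proper"][w] += 1
            tlen = abs(read.template_length)
            if read.is_paired and tlen:
                if tlen > hi:
                    a["large"][w] += 1
                elif tlen < lo:
                    a["small"][w] += 1
            # distribute aligned span over windows it overlaps
            start, end = pos, read.reference_end or pos
            wi = start // window
            while start < end:
                nxt = min(end, (wi + 1) * window)
                a["bases"][wi] += nxt - start
                start = nxt
                wi += 1

    # every record gets windows, covered or not
    for rec in records:
        if rec.id not in acc:
            order.append(rec.id)
            _ensure(rec.id)

    rows = []
    for seq_id in order:
        a = acc[seq_id]
        seq = seq_by_id[seq_id].upper
        n = len(a["bases"])
        for w in range(n):
            start = w * window
            end = min((w + 1) * window, lengths[seq_id])
            nr = a["n_reads"][w]
            rows.append(
                (
                    seq_id, start, end,
                    _gc_fraction(seq[start:end]),
                    a["bases"][w] / (end - start),
                    a["proper"][w] / nr if nr else 0.0,
                    a["large"][w] / nr if nr else 0.0,
                    a["small"][w] / nr if nr else 0.0,
                    int(nr),
                )
            )
    return pd.DataFrame(rows, columns=WINDOW_COLUMNS)


def read_windows(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(WINDOW_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"window table missing columns: {sorted(missing)}")
    return df[WINDOW_COLUMNS].copy()


def write_windows(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def gc_normalize(
    windows: pd.DataFrame,
    gc_bin_width: float = 0.02,
    min_bin_windows: int = 50,
) -> pd.DataFrame:
    """Add ``norm_depth`` = depth / median depth of the window's GC bin.

    Bins holding fewer than ``min_bin_windows`` windows fall back to the
    global median depth. The median is used (not the mean) so collapsed
    repeats cannot drag the reference depth upward.
    """
    df = windows.copy()
    global_median = float(df["depth"].median())
    if global_median == 0:
        raise ValueError("cannot GC-normalize: median depth is zero")
    bins = np.floor(df["gc"].to_numpy() / gc_bin_width).astype(int)
    df["_gc_bin"] = bins
    med = df.groupby("_gc_bin")["depth"].transform("median")
    cnt = df.groupby("_gc_bin")["depth"].transform("size")
    denom = med.where(cnt >= min_bin_windows, global_median)
    denom = denom.where(denom > 0, global_median)
    df["norm_depth"] = df["depth"] / denom
    return df.drop(columns="_gc_bin")


def classify_windows(windows: pd.DataFrame, thresholds: QcThresholds | None = None) -> pd.DataFrame:
    """Attach the flag columns HC/LC/LPP/LLI/LSI plus lq and lqlc.

    Windows with fewer than ``min_reads`` reads are classified LC
    (their fractional statistics are too noisy to interpret otherwise).
    """
    t = thresholds or QcThresholds()
    if "norm_depth" not in windows.columns:
        raise ValueError("run gc_normalize first (norm_depth column required)")
    df = windows.copy()
    low_n = df["n_reads"] < t.min_reads
    df["LC"] = (df["norm_depth"] < t.lc_norm_depth_max) | low_n
    df["HC"] = (df["norm_depth"] > t.hc_norm_depth_min) & ~low_n
    df["LPP"] = (df["frac_proper"] < t.proper_min) & ~low_n
    df["LLI"] = (df["frac_large_insert"] > t.large_insert_max) & ~low_n
    df["LSI"] = (df["frac_small_insert"] > t.small_insert_max) & ~low_n
    df["lq"] = df[["HC", "LPP", "LLI", "LSI"]].any(axis=1)
    df["lqlc"] = df["lq"] | df["LC"]
    return df


def _mask_trees(mask: Iterable[tuple[str, int, int]] | str) -> dict[str, IntervalTree]:
    if isinstance(mask, (str, bytes)) or hasattr(mask, "read"):
        intervals = []
        with open(mask) as fh:
            for line_no, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                cols = line.split("\t")
                if len(cols) < 3:
                    raise ValueError(f"BED line {line_no}: fewer than 3 columns")
                try:
                    intervals.append((cols[0], int(cols[1]), int(cols[2])))
                except ValueError as exc:
                    raise ValueError(f"BED line {line_no}: non-integer coordinates") from exc
        mask = intervals
    trees: dict[str, IntervalTree] = {}
    for chrom, start, end in mask:
        if end > start:
            trees.setdefault(chrom, IntervalTree()).addi(start, end)
    return trees


def subtract_mask(
    classes: pd.DataFrame,
    mask: Iterable[tuple[str, int, int]] | str,
) -> tuple[pd.DataFrame, int]:
    """LQLC windows whose interval does not intersect the mask by >= 1 bp.

    Returns the surviving windows and their total base count. ``mask`` is
    BED intervals (path or (chrom, start, end) triples, 0-based half-open).
    """
    trees = _mask_trees(mask)
    lqlc = classes[classes["lqlc"]]
    keep = [
        not (row.seq_id in trees and trees[row.seq_id].overlap(row.start, row.end))
        for row in lqlc.itertuples()
    ]
    out = lqlc[np.asarray(keep, dtype=bool)] if len(lqlc) else lqlc
    total = int((out["end"] - out["start"]).sum()) if len(out) else 0
    return out, total


def qc_summary(classes: pd.DataFrame) -> pd.DataFrame:
    """Per-category base counts and percent of analysed bases.

    Also reports the mean GC of LQLC windows — high values indicate
    platform GC bias rather than true assembly defects.
    """
    total_bases = int((classes["end"] - classes["start"]).sum())
    widths = classes["end"] - classes["start"]
    rows = []
    for label, col in CATEGORIES.items():
        bases = int(widths[classes[col]].sum())
        rows.append((label, bases, 100.0 * bases / total_bases if total_bases else 0.0))
    lqlc = classes[classes["lqlc"]]
    mean_gc = float(lqlc["gc"].mean()) if len(lqlc) else float("nan")
    df = pd.DataFrame(rows, columns=["category", "bases", "pct_genome"])
    df.attrs["total_bases"] = total_bases
    df.attrs["lqlc_mean_gc"] = mean_gc
    return df
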