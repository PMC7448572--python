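"""SNP-chip probe order versus assembly placement order.

Markers are ranked by their manifest coordinates (chromosomes in
karyotype order) and independently by their placement coordinates in an
assembly; markers that fail to map are penalized with an assembly rank of
-1. Agreement between the two orders is summarised by Spearman's rank
correlation (average ranks over the -1 tie block), and placed markers
yield spacing statistics including the largest marker desert. The same
rank-pair machinery serves radiation-hybrid-map-vs-assembly collinearity
dotplots.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .assembly_io import SequenceRecord
from .telomere_scan import revcomp

__all__ = [
    "karyotype_sort_key",
    "karyotype_order",
    "normalize_chrom",
    "assign_ranks",
    "spearman_rho",
    "marker_spacing",
    "place_probes_exact",
    "dotplot_export",
    "ConcordanceReport",
    "SpacingReport",
]

MANIFEST_COLUMNS = ["marker_id", "chip", "manifest_chrom", "manifest_pos"]
PLACEMENT_COLUMNS = ["marker_id", "assembly_chrom", "assembly_pos"]

_SEX_ORDER = {"X": 0, "Y": 1, "MT": 2, "M": 2}


def _natural_key(name: str) -> tuple:
    return tuple(int(tok) if tok.isdigit() else tok
                 for tok in re.split(r"(\d+)", name) if tok)


def karyotype_sort_key(name) -> tuple:
    """Sort key: numeric chromosomes ascending, then X, Y, MT, then
    non-chromosome scaffolds in natural sort order (highest ranks)."""
    if name is None or (isinstance(name, float) and np.isnan(name)):
        return (3, (), "")
    name = str(name)
    bare = name[3:] if name.lower().startswith("chr") else name
    if bare.isdigit():
        return (0, (int(bare),), "")
    if bare.upper() in _SEX_ORDER:
        return (1, (_SEX_ORDER[bare.upper()],), "")
    return (2, _natural_key(name), name)


def karyotype_order(chrom_names) -> list[str]:
    """Total ordering of a set of chromosome/scaffold names."""
    return sorted({str(c) for c in chrom_names}, key=karyotype_sort_key)


def normalize_chrom(name: str, aliases: Mapping[str, str] | None = None) -> str:
    """Normalize manifest chromosome dialects (e.g. "SSC1" -> "1")."""
    name = str(name)
    if aliases and name in aliases:
        return aliases[name]
    m = re.match(r"^(?:SSC|chr|Chr)?(\d+|X|Y|MT?)$", name)
    return m.group(1) if m else name


@dataclass
class ConcordanceReport:
    rho: float
    pvalue: float
    n_markers: int
    n_unmapped: int
    per_chip: pd.DataFrame | None = None


@dataclass
class SpacingReport:
    mean_spacing: float
    sd_spacing: float
    n_spacings: int
    max_desert_chrom: str
    max_desert_start: int
    max_desert_end: int

    @property
    def max_desert_length(self) -> int:
        return self.max_desert_end - self.max_desert_start


def assign_ranks(
    manifest: pd.DataFrame,
    placements: pd.DataFrame,
) -> pd.DataFrame:
    """Build rank pairs from a manifest and a placement table.

    Manifest rank is 1..N over markers sorted by (karyotype order of
    manifest chromosome, manifest position, marker id); assembly rank is
    1..M over mapped markers sorted the same way on assembly coordinates,
    with every unmapped marker assigned the penalty rank -1. Placements
    for unknown markers raise a warning and are ignored.
    """
    man = manifest.copy()
    missing = set(MANIFEST_COLUMNS) - set(man.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    known = set(man["marker_id"])
    plc = placements.copy()
    unknown = set(plc["marker_id"]) - known
    if unknown:
        warnings.warn(f"{len(unknown)} placements for unknown markers ignored")
        plc = plc[plc["marker_id"].isin(known)]
    plc = plc.dropna(subset=["assembly_chrom", "assembly_pos"])
    if "unique" in plc.columns:
        plc = plc[plc["unique"].astype(bool)]

    man["_key"] = man["manifest_chrom"].map(karyotype_sort_key)
    man = man.sort_values(["_key", "manifest_pos", "marker_id"],
                          kind="mergesort").drop(columns="_key")
    man["manifest_rank"] = np.arange(1, len(man) + 1)

    plc = plc.copy()
    plc["_key"] = plc["assembly_chrom"].map(karyotype_sort_key)
    plc = plc.sort_values(["_key", "assembly_pos", "marker_id"],
                          kind="mergesort").drop(columns="_key")
    plc["assembly_rank"] = np.arange(1, len(plc) + 1)

    out = man.merge(
        plc[["marker_id", "assembly_chrom", "assembly_pos", "assembly_rank"]],
        on="marker_id", how="left",
    )
    out["assembly_rank"] = out["assembly_rank"].fillna(-1).astype(int)
    return out.reset_index(drop=True)


def spearman_rho(rank_pairs: pd.DataFrame) -> ConcordanceReport:
    """Spearman rho between manifest and assembly ranks.

    Unmapped markers enter as the literal value -1, forming a tie block
    handled by average ranks (the standard Spearman tie convention); the
    two-sided test against rho = 0 is reported.
    """
    if len(rank_pairs) < 3:
        raise ValueError("need at least 3 rank pairs")
    x = rank_pairs["manifest_rank"].to_numpy(dtype=float)
    y = rank_pairs["assembly_rank"].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return ConcordanceReport(float("nan"), float("nan"), len(x),
                                 int((y == -1).sum()))
    res = stats.spearmanr(x, y)
    per_chip = None
    if "chip" in rank_pairs.columns and rank_pairs["chip"].nunique() > 1:
        rows = []
        for chip, grp in rank_pairs.groupby("chip"):
            xr, yr = grp["manifest_rank"], grp["assembly_rank"]
            if len(grp) >= 3 and yr.nunique() > 1:
                r = stats.spearmanr(xr, yr)
                rows.append((chip, r.statistic, len(grp), int((yr == -1).sum())))
        per_chip = pd.DataFrame(rows, columns=["chip", "rho", "n_markers", "n_unmapped"])
    return ConcordanceReport(
        float(res.statistic), float(res.pvalue), len(x), int((y == -1).sum()), per_chip
    )


def marker_spacing(placements: pd.DataFrame) -> SpacingReport:
    """Spacing statistics over mapped markers.

    Spacings are distances between consecutive mapped markers within each
    chromosome (never across); the mean and sample (n-1) standard
    deviation are taken over all spacings, and the largest spacing is
    reported as the marker desert with its interval. A single spacing has
    SD 0 by convention.
    """
    plc = placements.dropna(subset=["assembly_chrom", "assembly_pos"]).copy()
    plc["_key"] = plc["assembly_chrom"].map(karyotype_sort_key)
    plc = plc.sort_values(["_key", "assembly_pos"], kind="mergesort")
    spacings: list[float] = []
    desert = ("", 0, 0)
    for chrom, grp in plc.groupby("assembly_chrom", sort=False):
        pos = grp["assembly_pos"].to_numpy(dtype=float)
        if len(pos) < 2:
            continue
        d = np.diff(pos)
        spacings.extend(d)
        i = int(np.argmax(d))
        if d[i] > desert[2] - desert[1]:
            desert = (str(chrom), int(pos[i]), int(pos[i + 1]))
    if not spacings:
        raise ValueError("fewer than 2 mapped markers on every chromosome")
    arr = np.asarray(spacings)
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    return SpacingReport(float(arr.mean()), sd, len(arr), *desert)


def _count_occurrences(hay: str, needle: str, limit: int = 2) -> list[int]:
    found = []
    i = hay.find(needle)
    while i != -1 and len(found) < limit:
        found.append(i)
        i = hay.find(needle, i + 1)
    return found


def place_probes_exact(
    records: Sequence[SequenceRecord],
    manifest: pd.DataFrame,
    anchor: str = "start",
) -> pd.DataFrame:
    """Exact-occurrence probe placement for synthetic assemblies.

    A probe maps iff its sequence has exactly one exact occurrence in the
    assembly counting both strands; zero or multiple occurrences leave it
    unmapped. ``anchor`` selects the reported coordinate: the occurrence
    start ("start") or the base adjacent to the probe 3' end
    ("three_prime", strand-aware). Real read mapping belongs to an
    external aligner; this placer exists for simulation-backed tests.
    """
    if "probe_seq" not in manifest.columns:
        raise ValueError("manifest has no probe_seq column")
    if anchor not in ("start", "three_prime"):
        raise ValueError(f"unknown anchor {anchor!r}")
    seqs = [(r.id, r.upper) for r in records]
    rows = []
    for row in manifest.itertuples():
        probe = str(row.probe_seq).upper()
        hits: list[tuple[str, int, str]] = []
        for seq_id, seq in seqs:
            for strand, needle in (("+", probe), ("-", revcomp(probe))):
                for pos in _count_occurrences(seq, needle):
                    hits.append((seq_id, pos, strand))
            if len(hits) > 1:
                break
        if len(hits) == 1:
            seq_id, pos, strand = hits[0]
            if anchor == "three_prime":
                pos = pos + len(probe) - 1 if strand == "+" else pos
            rows.append((row.marker_id, seq_id, pos, strand, True))
        else:
            rows.append((row.marker_id, None, np.nan, None, False))
    return pd.DataFrame(
        rows, columns=["marker_id", "assembly_chrom", "assembly_pos", "strand", "unique"]
    )


def dotplot_export(rank_pairs: pd.DataFrame, path=None) -> pd.DataFrame:
    """Rank pairs as a plotting-ready table (one row per marker).

    Unmapped markers keep assembly_rank -1; a per-chromosome facet column
    (the manifest chromosome) supports faceted collinearity plots.
    """
    cols = ["marker_id", "manifest_rank", "assembly_rank"]
    out = rank_pairs[cols].copy()
    out["facet_chrom"] = rank_pairs["manifest_chrom"].astype(str)
    if "chip" in rank_pairs.columns:
        out["chip"] = rank_pairs["chip"]
    if path is not None:
        out.to_csv(path, sep="\t", index=False)
    return out
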