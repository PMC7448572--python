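"""Synthetic genomes with known truth for every pipeline stage.

The generator emulates the feature structure of a chromosome-scale
mammalian assembly: GC-heterogeneous background sequence, terminal
telomeric TTAGGG arrays (optionally mutated per base), a centromeric
satellite monomer array, spanned and unspanned gaps emitted both as
N-runs in the FASTA and as matching AGP lines, per-window alignment
summaries with planted coverage/pairing anomalies, and probe sets with
known order, dropout and inversion-induced disorder. Every generator is
byte-deterministic under a fixed seed, and every planted feature is
recorded in a :class:`TruthSet` so detectors can be scored against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .assembly_io import (
    AgpObject,
    AssemblyLayout,
    ComponentRecord,
    GapRecord,
    SequenceRecord,
)
from .telomere_scan import revcomp

__all__ = [
    "TelomereSpec",
    "CentromereSpec",
    "GapSpec",
    "AnomalySpec",
    "ProbeSpec",
    "SimConfig",
    "TruthSet",
    "simulate_genome",
    "simulate_window_track",
    "simulate_probe_set",
    "apply_structural_edit",
    "lift_coordinate",
]

_BASES = np.array(list("ACGT"))
TELOMERE_UNIT = "TTAGGG"


@dataclass
class TelomereSpec:
    """Terminal tandem arrays: 334 pure units (~2 kb) per end by default,
    matching a comfortably retained vertebrate telomere."""

    units_per_end: int = 334
    mutation_rate: float = 0.0


@dataclass
class CentromereSpec:
    """One satellite array per chromosome; the monomer defaults to a
    seed-derived random 340-mer (the length scale of known pig
    centromeric satellite monomers)."""

    monomer: str | None = None
    monomer_length: int = 340
    array_length: int = 50_000
    divergence: float = 0.0


@dataclass
class GapSpec:
    n_spanned: int = 2
    spanned_length: int = 500
    n_unspanned: int = 1
    unspanned_length: int = 100  # AGP type-U convention


@dataclass
class AnomalySpec:
    """Planted window-track anomalies as (chrom, start, end) intervals.

    LC intervals run at 0.15x the nominal depth (assembly sequence absent
    from the sample), HC at 2.5x (collapsed duplication), misassembly
    intervals keep nominal depth but halve proper pairing and inflate
    improper-insert fractions.
    """

    lc_intervals: list[tuple[str, int, int]] = field(default_factory=list)
    hc_intervals: list[tuple[str, int, int]] = field(default_factory=list)
    misassembly_intervals: list[tuple[str, int, int]] = field(default_factory=list)


@dataclass
class ProbeSpec:
    n_probes: int = 300
    probe_length: int = 70
    dropout: float = 0.0
    inversions: list[tuple[str, int, int]] = field(default_factory=list)


@dataclass
class SimConfig:
    """Study conditions for one synthetic genome."""

    seed: int = 0
    chromosomes: list[tuple[str, int, float]] = field(
        default_factory=lambda: [("1", 600_000, 0.40), ("2", 450_000, 0.46), ("3", 300_000, 0.52)]
    )
    telomere: TelomereSpec = field(default_factory=TelomereSpec)
    centromere: CentromereSpec = field(default_factory=CentromereSpec)
    gaps: GapSpec = field(default_factory=GapSpec)
    anomalies: AnomalySpec = field(default_factory=AnomalySpec)
    probes: ProbeSpec = field(default_factory=ProbeSpec)
    mean_depth: float = 30.0
    #: NB dispersion of per-window read counts; 100 gives a count CV of
    #: ~0.1 at nominal depth, typical of GC-corrected Illumina coverage
    #: in 1 kb windows.
    nb_dispersion: float = 100.0
    window: int = 1000


@dataclass
class TruthSet:
    """Planted-feature intervals (0-based half-open) and probe truth."""

    telomeres: list[tuple[str, int, int]] = field(default_factory=list)
    centromeres: list[tuple[str, int, int]] = field(default_factory=list)
    gaps: list[tuple[str, int, int, str]] = field(default_factory=list)
    anomalies: list[tuple[str, int, int, str]] = field(default_factory=list)
    inversions: list[tuple[str, int, int]] = field(default_factory=list)
    probes: pd.DataFrame | None = None
    monomer: str | None = None  # the satellite monomer actually planted


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=length, p=p)])


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.array(list(seq))
    hit = rng.random(len(arr)) < rate
    if hit.any():
        # substitute with a uniformly random *different* base
        subs = _BASES[(np.searchsorted(_BASES, arr[hit]) + rng.integers(1, 4, hit.sum())) % 4]
        arr[hit] = subs
    return "".join(arr)


def _tandem_array(rng: np.random.Generator, monomer: str, total_length: int,
                  divergence: float) -> str:
    n = -(-total_length // len(monomer))
    return _mutate(rng, (monomer * n)[:total_length], divergence)


def _scrub_motifs(seq: np.ndarray, start: int, end: int) -> None:
    """Destroy chance telomere-motif occurrences in seq[start:end].

    Planted telomere arrays must have well-defined boundaries: a chance
    TTAGGG/CCCTAA in the background adjacent to an array would otherwise
    legitimately extend the chained-scan interval past the planted truth.
    The middle base of each offending occurrence is flipped.
    """
    for _ in range(5):
        s = "".join(seq[max(start, 0):min(end + 5, len(seq))])
        dirty = False
        for motif in (TELOMERE_UNIT, revcomp(TELOMERE_UNIT)):
            i = s.find(motif)
            while i != -1:
                j = max(start, 0) + i + 2
                seq[j] = "C" if seq[j] != "C" else "A"
                dirty = True
                i = s.find(motif, i + 1)
        if not dirty:
            return


def simulate_genome(config: SimConfig) -> tuple[list[SequenceRecord], AssemblyLayout, TruthSet]:
    """Generate FASTA records, a matching AGP layout and the truth set.

    Each chromosome is background sequence at its configured GC with
    telomere arrays overwriting both ends, a centromeric satellite array
    at the midpoint, and gaps written over interior positions as N runs
    (so planted features keep their coordinates). Features must fit: a
    chromosome too short for its features raises a config error.
    """
    rng = np.random.default_rng(config.seed)
    cen = config.centromere
    monomer = cen.monomer or _random_seq(rng, cen.monomer_length, 0.5)
    records: list[SequenceRecord] = []
    objects: list[AgpObject] = []
    truth = TruthSet(monomer=monomer)

    tel_len = 6 * config.telomere.units_per_end
    for name, length, gc in config.chromosomes:
        needed = 2 * tel_len + cen.array_length + 40_000
        if length < needed:
            raise ValueError(
                f"chromosome {name}: length {length} cannot hold the configured "
                f"features (needs >= {needed})"
            )
        seq = np.array(list(_random_seq(rng, length, gc)))

        # telomeres at both ends; q-end array on the reverse strand
        p_arr = _mutate(rng, TELOMERE_UNIT * config.telomere.units_per_end,
                        config.telomere.mutation_rate)
        q_arr = _mutate(rng, revcomp(TELOMERE_UNIT * config.telomere.units_per_end),
                        config.telomere.mutation_rate)
        seq[:tel_len] = list(p_arr)
        seq[length - tel_len:] = list(q_arr)
        truth.telomeres.append((name, 0, tel_len))
        truth.telomeres.append((name, length - tel_len, length))
        _scrub_motifs(seq, tel_len, tel_len + 2000)
        _scrub_motifs(seq, length - tel_len - 2000, length - tel_len)

        # centromeric satellite array centred on the chromosome midpoint;
        # a whole number of monomer copies so the planted extent is exact
        n_copies = max(1, round(cen.array_length / len(monomer)))
        c_len = n_copies * len(monomer)
        c_start = (length - c_len) // 2
        seq[c_start:c_start + c_len] = list(
            _tandem_array(rng, monomer, c_len, cen.divergence)
        )
        truth.centromeres.append((name, c_start, c_start + c_len))

        # gaps: N runs written over interior background, away from features
        gap_plan = (
            [("spanned", config.gaps.spanned_length)] * config.gaps.n_spanned
            + [("unspanned", config.gaps.unspanned_length)] * config.gaps.n_unspanned
        )
        zones = [
            (tel_len + 5000, c_start - 5000),
            (c_start + cen.array_length + 5000, length - tel_len - 5000),
        ]
        placed: list[tuple[int, int, str]] = []
        for kind, glen in gap_plan:
            for _ in range(200):
                zi = int(rng.integers(0, len(zones)))
                lo, hi = zones[zi]
                if hi - lo <= glen:
                    continue
                start = int(rng.integers(lo, hi - glen))
                if all(start + glen + 1000 <= s or e + 1000 <= start for s, e, _ in placed):
                    placed.append((start, start + glen, kind))
                    break
            else:
                raise ValueError(f"chromosome {name}: could not place a {kind} gap")
        for start, end, kind in sorted(placed):
            seq[start:end] = "N"
            truth.gaps.append((name, start, end, kind))

        records.append(SequenceRecord(name, "".join(seq)))
        obj = AgpObject(name, name)
        pos = 0
        part = 0
        n_ctg = 0
        for start, end, kind in sorted(placed):
            if start > pos:
                n_ctg += 1
                part += 1
                obj.components.append(
                    ComponentRecord(name, pos + 1, start, part,
                                    f"{name}_ctg{n_ctg}", 1, start - pos)
                )
            part += 1
            gap_type = "N" if kind == "spanned" else "U"
            obj.gaps.append(GapRecord(name, start + 1, end, kind, end - start, gap_type))
            pos = end
        if pos < length:
            n_ctg += 1
            part += 1
            obj.components.append(
                ComponentRecord(name, pos + 1, length, part,
                                f"{name}_ctg{n_ctg}", 1, length - pos)
            )
        objects.append(obj)

    return records, AssemblyLayout(objects), truth


def _gc_bias(gc: np.ndarray) -> np.ndarray:
    """Smooth unimodal GC bias: unit depth at GC 0.45, falling toward the
    extremes (the short-read platform's well-known behaviour)."""
    return 0.2 + 0.8 * np.exp(-((gc - 0.45) ** 2) / (2 * 0.15 ** 2))


def simulate_window_track(
    records: Sequence[SequenceRecord],
    config: SimConfig,
    truth: TruthSet | None = None,
) -> tuple[pd.DataFrame, TruthSet]:
    """Per-window alignment summaries with planted anomalies.

    Depth is negative-binomial around a GC-bias-scaled mean; planted LC
    intervals run at 0.15x, HC at 2.5x; misassembly intervals halve the
    properly-paired fraction and inflate improper-insert fractions. Gap
    (all-N) windows carry no reads. Anomaly truth is appended to
    ``truth`` (or a fresh TruthSet) window-quantized.
    """
    rng = np.random.default_rng(config.seed + 1)
    truth = truth or TruthSet()
    window = config.window
    anomalies = {
        "LC": config.anomalies.lc_intervals,
        "HC": config.anomalies.hc_intervals,
        "MIS": config.anomalies.misassembly_intervals,
    }
    rows = []
    for rec in records:
        seq = rec.upper
        n_win = -(-rec.length // window)
        for w in range(n_win):
            start, end = w * window, min((w + 1) * window, rec.length)
            chunk = seq[start:end]
            n_count = chunk.count("N")
            acgt = len(chunk) - n_count
            gc = (chunk.count("G") + chunk.count("C")) / acgt if acgt else 0.0
            if acgt == 0:
                rows.append((rec.id, start, end, 0.0, 0.0, 0.0, 0.0, 0.0, 0))
                continue
            label = None
            for kind, ivs in anomalies.items():
                if any(c == rec.id and s < end and start < e for c, s, e in ivs):
                    label = kind
                    break
            mu = config.mean_depth * float(_gc_bias(np.array([gc]))[0])
            if label == "LC":
                mu *= 0.15
            elif label == "HC":
                mu *= 2.5
            # read-count model: NB on the number of 150 bp reads in the
            # window, depth derived from it (windowed depth is far less
            # noisy than a direct NB draw on depth itself)
            r = config.nb_dispersion
            mu_reads = mu * (end - start) / 150.0
            n_reads = (int(rng.negative_binomial(r, r / (r + mu_reads)))
                       if mu_reads > 0 else 0)
            depth = n_reads * 150.0 / (end - start)
            if label == "MIS":
                frac_proper = float(np.clip(rng.normal(0.5, 0.02), 0, 1))
                frac_large = float(np.clip(rng.normal(0.25, 0.03), 0, 1))
                frac_small = float(np.clip(rng.normal(0.15, 0.03), 0, 1))
            else:
                frac_proper = float(np.clip(rng.beta(490, 10), 0, 1))
                frac_large = float(np.clip(rng.beta(10, 490), 0, 1))
                frac_small = float(np.clip(rng.beta(10, 490), 0, 1))
            if n_reads == 0:
                frac_proper = frac_large = frac_small = 0.0
            rows.append((rec.id, start, end, gc, depth,
                         frac_proper, frac_large, frac_small, n_reads))
    for kind, ivs in anomalies.items():
        for c, s, e in ivs:
            truth.anomalies.append((c, s, e, kind))
    df = pd.DataFrame(rows, columns=[
        "seq_id", "start", "end", "gc", "depth",
        "frac_proper", "frac_large_insert", "frac_small_insert", "n_reads",
    ])
    return df, truth


def apply_structural_edit(
    records: Sequence[SequenceRecord],
    edits: Sequence[tuple[str, str, int, int]],
) -> tuple[list[SequenceRecord], pd.DataFrame]:
    """Apply inversions and deletions; return edited records + lift table.

    ``edits`` rows are (kind, seq_id, start, end) with kind "inversion" or
    "deletion", 0-based half-open, non-overlapping per sequence. The lift
    table maps truth coordinates to edited coordinates: one row per
    maximal segment with its offset, plus "deleted" rows.
    """
    by_seq: dict[str, list[tuple[str, int, int]]] = {}
    for kind, seq_id, start, end in edits:
        if kind not in ("inversion", "deletion"):
            raise ValueError(f"unknown edit kind {kind!r}")
        by_seq.setdefault(seq_id, []).append((kind, start, end))
    for seq_id, evs in by_seq.items():
        evs.sort(key=lambda e: e[1])
        for (_, s1, e1), (_, s2, e2) in zip(evs, evs[1:]):
            if s2 < e1:
                raise ValueError(f"{seq_id}: overlapping edits at {s1}..{e1} and {s2}..{e2}")

    out_records: list[SequenceRecord] = []
    lift_rows = []
    for rec in records:
        evs = by_seq.get(rec.id, [])
        seq = rec.sequence
        pieces = []
        pos = 0
        shift = 0
        for kind, start, end in evs:
            if end > len(seq):
                raise ValueError(f"{rec.id}: edit {start}..{end} beyond sequence end")
            pieces.append(seq[pos:start])
            lift_rows.append((rec.id, pos, start, "identity", shift))
            if kind == "inversion":
                pieces.append(revcomp(seq[start:end]))
                lift_rows.append((rec.id, start, end, "inverted", shift))
            else:
                lift_rows.append((rec.id, start, end, "deleted", 0))
                shift -= end - start
            pos = end
        pieces.append(seq[pos:])
        lift_rows.append((rec.id, pos, len(seq), "identity", shift))
        out_records.append(SequenceRecord(rec.id, "".join(pieces)))
    lift = pd.DataFrame(lift_rows, columns=["seq_id", "start", "end", "kind", "offset"])
    return out_records, lift


def lift_coordinate(lift: pd.DataFrame, seq_id: str, pos: int) -> int | None:
    """Map a truth coordinate through a lift table (None if deleted)."""
    seg = lift[(lift["seq_id"] == seq_id) & (lift["start"] <= pos) & (pos < lift["end"])]
    if seg.empty:
        return None
    row = seg.iloc[0]
    if row["kind"] == "deleted":
        return None
    if row["kind"] == "inverted":
        return int(row["start"] + row["offset"] + (row["end"] - 1 - pos))
    return int(pos + row["offset"])


def simulate_probe_set(
    records: Sequence[SequenceRecord],
    config: SimConfig,
    truth: TruthSet | None = None,
) -> tuple[pd.DataFrame, list[SequenceRecord], TruthSet]:
    """Sample unique probes and derive an edited "assembly" to map against.

    Probes are unique 70-mers (both strands, genome-wide) drawn uniformly
    from non-gap, non-planted-repeat sequence; the manifest records their
    truth coordinates. The derived assembly applies the configured
    inversions, then deletes (overwrites) the sites of a ``dropout``
    fraction of probes so those probes become unmappable. Probe truth
    (true position, expected mapped flag) is recorded.
    """
    rng = np.random.default_rng(config.seed + 2)
    spec = config.probes
    truth = truth or TruthSet()
    avoid: dict[str, list[tuple[int, int]]] = {}
    for c, s, e in truth.telomeres + truth.centromeres:
        avoid.setdefault(c, []).append((s, e))
    for c, s, e, _ in truth.gaps:
        avoid.setdefault(c, []).append((s, e))

    total = sum(r.length for r in records)
    genome = [(r.id, r.upper) for r in records]
    probes: list[tuple[str, str, int, str]] = []
    used: set[str] = set()
    attempts = 0
    max_attempts = spec.n_probes * 200
    while len(probes) < spec.n_probes:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                "could not find enough unique probes; use longer probes or fewer of them"
            )
        u = rng.random() * total
        acc = 0
        for seq_id, seq in genome:
            if u < acc + len(seq):
                pos = min(int(u - acc), len(seq) - spec.probe_length)
                break
            acc += len(seq)
        else:
            continue
        end = pos + spec.probe_length
        if any(s < end and pos < e for s, e in avoid.get(seq_id, [])):
            continue
        p = seq[pos:end]
        if "N" in p or p in used:
            continue
        n_hits = 0
        for _, s in genome:
            n_hits += s.count(p) + s.count(revcomp(p))
            if n_hits > 1:
                break
        if n_hits != 1:
            continue
        used.add(p)
        probes.append((f"M{len(probes):05d}", seq_id, pos, p))

    probes.sort(key=lambda t: (t[1], t[2]))
    manifest = pd.DataFrame(
        [(mid, "SIM", chrom, pos, p) for mid, chrom, pos, p in probes],
        columns=["marker_id", "chip", "manifest_chrom", "manifest_pos", "probe_seq"],
    )

    edits = [("inversion", c, s, e) for c, s, e in spec.inversions]
    assembly, _lift = apply_structural_edit(records, edits)
    truth.inversions.extend(spec.inversions)

    n_drop = int(round(spec.dropout * len(manifest)))
    drop_idx = set(rng.choice(len(manifest), size=n_drop, replace=False)) if n_drop else set()
    if drop_idx:
        seqs = {r.id: np.array(list(r.sequence)) for r in assembly}
        for i in sorted(drop_idx):
            row = manifest.iloc[i]
            # find the probe in the edited assembly and overwrite its site
            for seq_id, arr in seqs.items():
                s = "".join(arr)
                for needle in (row.probe_seq, revcomp(row.probe_seq)):
                    j = s.find(needle)
                    if j != -1:
                        arr[j:j + len(needle)] = list(
                            _random_seq(rng, len(needle), 0.5)
                        )
                        break
                else:
                    continue
                break
        assembly = [SequenceRecord(r.id, "".join(seqs[r.id])) for r in assembly]

    truth.probes = manifest.assign(
        true_chrom=manifest["manifest_chrom"],
        true_pos=manifest["manifest_pos"],
        expected_mapped=[i not in drop_idx for i in range(len(manifest))],
    )
    return manifest, assembly, truth
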