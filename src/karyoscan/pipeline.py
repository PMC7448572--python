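"""Stage orchestration and combined reporting.

`run_pipeline` executes the requested analyses (stats, window QC,
telomeres, centromeres, markers) on one assembly and writes per-stage
outputs plus a combined JSON report carrying the package version, the
effective parameter set, and SHA-256 digests of every file written.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Any

import pandas as pd

from . import __version__ as _version
from .assembly_io import read_agp, read_fasta, infer_layout_from_fasta
from .contiguity import assembly_stats, stats_table, write_stats
from .window_qc import (
    QcThresholds,
    classify_windows,
    gc_normalize,
    qc_summary,
    read_windows,
    subtract_mask,
    windows_from_alignments,
    write_windows,
    FLAG_COLUMNS,
)
from .telomere_scan import scan_telomeres
from .centromere_scan import (
    filter_repeats,
    predict_centromeres,
    read_repeatmasker_out,
    search_satellite_monomers,
    select_centromeric,
)
from .marker_concordance import (
    assign_ranks,
    dotplot_export,
    marker_spacing,
    place_probes_exact,
    spearman_rho,
)

log = logging.getLogger("karyoscan")


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _timed(name):
    class _T:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s: start", name)
            return self

        def __exit__(self, *exc):
            log.info("stage %s: %.2fs", name, time.perf_counter() - self.t0)

    return _T()


def run_pipeline(config: dict[str, Any]) -> dict[str, Any]:
    """Run the analyses named in ``config`` and write a report bundle.

    Required keys: ``fasta``, ``out_prefix``, and ``analyses`` (a list of
    "stats", "windowqc", "telomeres", "centromeres", "markers"). Optional
    inputs: ``agp``, ``windows``/``bam``, ``mask``, ``rm_out`` (list),
    ``monomers``, ``manifest``, ``placements``, plus per-stage parameter
    dictionaries (``thresholds``, ``telomere``, ``centromere``).
    Missing inputs are reported before any stage runs.
    """
    analyses = config.get("analyses") or []
    if not analyses:
        raise ValueError("no analyses requested")
    missing = [k for k in ("fasta", "out_prefix") if not config.get(k)]
    need = {
        "windowqc": ["windows_or_bam"],
        "centromeres": ["rm_out_or_monomers"],
        "markers": ["manifest"],
    }
    for a in analyses:
        if a == "windowqc" and not (config.get("windows") or config.get("bam")):
            missing.append("windows|bam (for windowqc)")
        if a == "centromeres" and not (config.get("rm_out") or config.get("monomers")):
            missing.append("rm_out|monomers (for centromeres)")
        if a == "markers" and not config.get("manifest"):
            missing.append("manifest (for markers)")
    if missing:
        raise ValueError(f"missing inputs: {', '.join(missing)}")

    prefix = Path(config["out_prefix"])
    prefix.parent.mkdir(parents=True, exist_ok=True)
    records = read_fasta(config["fasta"])
    layout = (read_agp(config["agp"]) if config.get("agp")
              else infer_layout_from_fasta(records))
    outputs: list[Path] = []
    report: dict[str, Any] = {
        "version": _version,
        "parameters": {k: v for k, v in config.items() if k != "analyses"},
        "analyses": {},
    }

    if "stats" in analyses:
        with _timed("stats"):
            st = assembly_stats(layout, records,
                                include_mt=bool(config.get("include_mt")))
            table = stats_table({Path(config["fasta"]).stem: st})
            write_stats(table, f"{prefix}.stats")
            outputs += [Path(f"{prefix}.stats.tsv"), Path(f"{prefix}.stats.json")]
            report["analyses"]["stats"] = st.as_dict()

    if "windowqc" in analyses:
        with _timed("windowqc"):
            thr = QcThresholds(**config.get("thresholds", {}))
            if config.get("windows"):
                win = read_windows(config["windows"])
            else:
                win = windows_from_alignments(config["bam"], records,
                                              window=int(config.get("window", 1000)))
            classes = classify_windows(gc_normalize(win), thr)
            out_tsv = Path(f"{prefix}.windows.tsv")
            write_windows(classes, out_tsv)
            outputs.append(out_tsv)
            for flag in FLAG_COLUMNS + ["lqlc"]:
                bed = Path(f"{prefix}.{flag.lower()}.bed")
                sub = classes[classes[flag]]
                sub[["seq_id", "start", "end"]].to_csv(
                    bed, sep="\t", index=False, header=False)
                outputs.append(bed)
            summary = qc_summary(classes)
            if config.get("mask"):
                _, unmasked = subtract_mask(classes, config["mask"])
                summary.attrs["lqlc_bases_outside_mask"] = unmasked
            report["analyses"]["windowqc"] = {
                "categories": summary.set_index("category")["bases"].to_dict(),
                "pct": summary.set_index("category")["pct_genome"].round(4).to_dict(),
                "lqlc_mean_gc": summary.attrs["lqlc_mean_gc"],
                **({"lqlc_bases_outside_mask": summary.attrs["lqlc_bases_outside_mask"]}
                   if "lqlc_bases_outside_mask" in summary.attrs else {}),
            }

    if "telomeres" in analyses:
        with _timed("telomeres"):
            tp = config.get("telomere", {})
            calls = scan_telomeres(records, **tp)
            rows = [(c.array.seq_id, c.array.start, c.array.end, c.array.n_exact_units,
                     round(c.array.density, 4), c.array.strand, c.position_class)
                    for c in calls]
            df = pd.DataFrame(rows, columns=["seq_id", "start", "end", "n_units",
                                             "density", "strand", "position"])
            out = Path(f"{prefix}.telomeres.tsv")
            df.to_csv(out, sep="\t", index=False)
            df[["seq_id", "start", "end"]].to_csv(
                Path(f"{prefix}.telomeres.bed"), sep="\t", index=False, header=False)
            outputs += [out, Path(f"{prefix}.telomeres.bed")]
            report["analyses"]["telomeres"] = {
                "n_calls": len(calls),
                "positions": df["position"].value_counts().to_dict(),
            }

    if "centromeres" in analyses:
        with _timed("centromeres"):
            cp = config.get("centromere", {})
            evidence: dict[str, list] = {}
            for i, rm in enumerate(config.get("rm_out") or []):
                recs = read_repeatmasker_out(rm)
                if not config.get("no_repeat_filter"):
                    recs = filter_repeats(recs)
                recs = select_centromeric(
                    recs, name_pattern=config.get("centromere_name_pattern"))
                evidence["default_library" if i == 0 else f"novel_library_{i}"] = recs
            if config.get("monomers"):
                monomers = read_fasta(config["monomers"])
                evidence["monomer_search"] = search_satellite_monomers(
                    records, monomers,
                    k=int(cp.get("k", 13)),
                    min_identity=float(cp.get("min_identity", 0.70)))
            calls, summary = predict_centromeres(
                evidence,
                collapse_dist=int(cp.get("collapse_dist", 500)),
                min_len=int(cp.get("min_len", 5000)))
            df = pd.DataFrame(
                [(c.seq_id, c.start, c.end, c.length, ",".join(sorted(c.sources)),
                  c.n_merged) for c in calls],
                columns=["seq_id", "start", "end", "length", "sources", "n_merged"])
            out = Path(f"{prefix}.centromeres.tsv")
            df.to_csv(out, sep="\t", index=False)
            df[["seq_id", "start", "end"]].to_csv(
                Path(f"{prefix}.centromeres.bed"), sep="\t", index=False, header=False)
            outputs += [out, Path(f"{prefix}.centromeres.bed")]
            report["analyses"]["centromeres"] = {"n_calls": len(calls), **summary}

    if "markers" in analyses:
        with _timed("markers"):
            manifest = pd.read_csv(config["manifest"], sep=None, engine="python")
            if config.get("placements"):
                placements = pd.read_csv(config["placements"], sep="\t")
            else:
                placements = place_probes_exact(records, manifest)
            pairs = assign_ranks(manifest, placements)
            conc = spearman_rho(pairs)
            dot = Path(f"{prefix}.dotplot.tsv")
            dotplot_export(pairs, dot)
            outputs.append(dot)
            block = {
                "rho": conc.rho,
                "pvalue": conc.pvalue,
                "n_markers": conc.n_markers,
                "n_unmapped": conc.n_unmapped,
            }
            try:
                sp = marker_spacing(placements)
                block["spacing"] = {
                    "mean_bp": sp.mean_spacing,
                    "sd_bp": sp.sd_spacing,
                    "max_desert": [sp.max_desert_chrom, sp.max_desert_start,
                                   sp.max_desert_end],
                }
            except ValueError:
                block["spacing"] = None
            report["analyses"]["markers"] = block

    report["outputs"] = {str(p): _digest(p) for p in outputs}
    report_path = Path(f"{prefix}.report.json")
    report_path.write_text(json.dumps(report, indent=2, default=str) + "\n")
    return report
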