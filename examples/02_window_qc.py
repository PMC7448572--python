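"""Window-based quality classification with planted anomalies.

Simulates a per-window read-alignment track with one low-coverage region,
one collapsed duplication and one misassembly junction, GC-normalizes the
depth and classifies every 1 kb window.
"""

from karyoscan import classify_windows, gc_normalize, qc_summary
from karyoscan.simulate import AnomalySpec, SimConfig, simulate_genome, simulate_window_track

cfg = SimConfig(
    seed=2,
    anomalies=AnomalySpec(
        lc_intervals=[("1", 100_000, 110_000)],
        hc_intervals=[("2", 200_000, 210_000)],
        misassembly_intervals=[("3", 150_000, 155_000)],
    ),
)
records, layout, truth = simulate_genome(cfg)
windows, truth = simulate_window_track(records, cfg, truth)
classes = classify_windows(gc_normalize(windows))
summary = qc_summary(classes)
print(summary.to_string(index=False))
print()
print(
    "Each row is a quality category in bases and as a percent of the genome:\n"
    "LC = low GC-normalized coverage, LQ = union of high-coverage, pairing\n"
    "and insert-size flags, and Total LQLC = LQ or LC. The planted 10 kb\n"
    "low-coverage region accounts for the low_coverage bases."
)
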