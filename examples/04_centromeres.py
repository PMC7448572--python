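"""Centromere calling from satellite monomer evidence.

Plants a diverged 50 kb satellite array, recovers it with the k-mer
seeded monomer search, and merges the hits into centromeric
super-regions (collapse distance 500 bp, retention > 5 kb).
"""

from karyoscan import predict_centromeres, search_satellite_monomers
from karyoscan.assembly_io import SequenceRecord
from karyoscan.simulate import CentromereSpec, SimConfig, simulate_genome

cfg = SimConfig(
    seed=4,
    chromosomes=[("1", 250_000, 0.44)],
    centromere=CentromereSpec(array_length=50_000, divergence=0.08),
)
records, layout, truth = simulate_genome(cfg)
hits = search_satellite_monomers(records, [SequenceRecord("monomer", truth.monomer)])
calls, summary = predict_centromeres({"monomer_search": hits})

for c in calls:
    print(f"centromere call: {c.seq_id}:{c.start}-{c.end} "
          f"({c.length:,} bp, sources={sorted(c.sources)})")
print(f"planted truth:   {truth.centromeres[0][0]}:"
      f"{truth.centromeres[0][1]}-{truth.centromeres[0][2]}")
print(f"merged-region mean length: {summary['mean_region_length']:,.0f} bp")
print()
print(
    "The single call contains the planted array despite 8% per-base\n"
    "divergence: individual monomer hits at ~0.92 identity merge into one\n"
    "super-region longer than the 5 kb retention threshold."
)
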