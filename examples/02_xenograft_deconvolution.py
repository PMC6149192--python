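"""Separate human tumor reads from mouse stromal reads by k-mer matching.

A patient-derived xenograft read set mixes the two species; every read is
scored against canonical 15-mer indexes of both references and kept,
discarded, or set aside as ambiguous.
"""

from pdxkit import SimulationConfig, build_kmer_index, partition
from pdxkit import simulate as sim

config = SimulationConfig(seed=2, contamination_fraction=0.2, n_reads=2_000)
human, mouse = sim.gen_reference_pair(config)
reads = sim.gen_reads(config, (human, mouse))

human_index = build_kmer_index(human, k=15)
mouse_index = build_kmer_index(mouse, k=15)
groups, summary = partition(
    ((r.read_id, r.sequence) for r in reads), human_index, mouse_index, k=15
)

truth = {r.read_id: r.origin for r in reads}
correct = sum(
    truth[rid] == call for call in ("human", "mouse") for rid in groups[call]
)
called = summary["counts"]["human"] + summary["counts"]["mouse"]

print(f"input reads:      {summary['total']}")
print(f"called human:     {summary['counts']['human']}")
print(f"called mouse:     {summary['counts']['mouse']} "
      f"(true contamination {config.contamination_fraction:.0%})")
print(f"ambiguous:        {summary['counts']['ambiguous']} (excluded downstream)")
print(f"accuracy on called reads: {correct / called:.4f}")
print("At 10% reference divergence a 15-mer almost never survives in both")
print("genomes, so the two scores separate cleanly and mouse reads can be")
print("discarded before copy-number or expression analysis.")
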