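"""Partition a synthetic metatranscriptome into host / symbiont /
specific bins: e-value sweep, exclusive-hit binning, composition
classifier for dual-database hits, GC profile per bin."""

from holopart import (SimulationConfig, gc_profile, generate_hit_table,
                      generate_transcriptome, partition_pipeline)
from holopart.simulate import HOST_MODEL, SYMBIONT_MODEL

cfg = SimulationConfig(n_host=600, n_symbiont=600, p_hit_true=1.0,
                       p_hit_cross=0.2, p_nohit=0.3,
                       evalue_log10_range=(-50, -5), seed=7)
host = generate_transcriptome(HOST_MODEL, cfg.n_host, cfg, seed=7)
sym = generate_transcriptome(SYMBIONT_MODEL, cfg.n_symbiont, cfg, seed=8)
transcripts = host + sym
hits, truth = generate_hit_table(transcripts, cfg)

result = partition_pipeline(hits, transcripts, seed=7)
print(f"chosen e-value cutoff: {result.chosen_cutoff:g}")
for cut, row in sorted(result.sweep_table.items()):
    print(f"  cutoff {cut:g}: unclassified {row['n_unclassified']}, "
          f"ambiguous {row['n_ambiguous']}")

n = len(transcripts)
for b in ("host", "symbiont", "specific"):
    c = sum(1 for v in result.assignments.values() if v == b)
    print(f"{b}: {c} ({100 * c / n:.1f}%)")

resolved = [t for t, p in result.provenance.items() if p == "classifier"]
correct = sum(1 for t in resolved if result.assignments[t] == truth[t])
if resolved:
    print(f"classifier resolved {len(resolved)} ambiguous transcripts, "
          f"accuracy vs planted truth {correct / len(resolved):.3f}")

prof = gc_profile(result.assignments, transcripts)
for b, h in prof.items():
    print(f"GC mode [{b}]: {h['mode']:.2f}")
print("Host and symbiont GC modes recover the generating targets")
print("(0.43 / 0.54); 'specific' collects the planted no-hit fraction.")
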