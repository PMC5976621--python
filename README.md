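# holopart

Partitioning and functional profiling of coral **holobiont**
metatranscriptomes.

RNA-seq of a symbiotic coral captures a mixture of transcripts: some from
the cnidarian host, some from its dinoflagellate endosymbionts
(*Symbiodinium*), and some matching neither reference set. `holopart`
implements the desk half of that analysis for researchers who have an
assembled transcript set and tabular alignment results in hand:

- **Preprocessing** — Trimmomatic-style sliding-window quality trimming of
  paired reads, removal of transcripts shorter than 300 bp, longest
  ATG-to-stop ORF extraction (≥ 100 aa) per transcript, CD-HIT-style greedy
  redundancy clustering at 95 % identity, and N50/GC summaries.
- **Partitioning** — every transcript is assigned to exactly one of
  `host | symbiont | specific`. Transcripts hitting only the host database
  (at an e-value cutoff chosen by a sweep over {1e-4, 1e-5, 1e-8, 1e-10}
  that minimises the unclassified count) are host; only the symbiont
  database, symbiont; both databases, resolved by a linear SVM over
  tetranucleotide composition (strand + reverse complement pooled,
  normalised frequencies) trained on the exclusive-hit bins; neither,
  holobiont-specific.
- **Profiling** — per-bin GC histograms and modes; one-sided Fisher-exact
  (hypergeometric upper-tail) GO term enrichment; normalised
  log10(1 + counts per 10⁴ peptides) PFAM domain matrices; annotation-rate
  tables with rounded percentages.
- **Ortholog groups** — the ≥3-member filter and the taxon-subset (Venn)
  partition of OrthoMCL-style group tables.
- **Metabolic complementation** — per-KEGG-pathway percentages of enzymes
  represented by host, symbiont, both, or specific transcripts, plus a key
  enzyme report flagging symbiont-only biosynthetic steps.
- **Synthetic holobiont generator** — ground-truth-labelled transcripts
  (host GC mode 0.43, symbiont 0.54), paired reads, hit tables with
  controllable cross-database leakage and no-hit fractions, annotation and
  ortholog tables with exactly plantable structure, so the whole pipeline
  is testable offline.

The classifier statistic at the core is simple: for a transcript with
sequence $s$, the feature vector $x(s)$ holds the relative frequencies of
all $4^k$ k-mers ($k=4$) counted on $s$ and its reverse complement, and the
decision is $\operatorname{sign}(w^\top x + b)$ with $(w, b)$ fitted by a
linear maximum-margin classifier on the exclusive-hit training bins.
Enrichment p-values are $P(X \ge a)$ for
$X \sim \mathrm{Hypergeom}(d, c, b)$ where $a$ of the $b$ focal members
carry a term carried by $c$ of the $d$ background members.

## Worked example

```bash
holopart demo --out demo_run --seed 7
# or: python examples/07_full_pipeline_demo.py demo_run
```

generates a 4,000-transcript synthetic holobiont (2,000 per origin,
per-origin no-hit rates planting an overall 24 / 29 / 47 host / symbiont /
specific split) and runs the full pipeline. The report it prints includes:

```
"chosen_cutoff": 1e-05,
"bins": {
  "host":     {"count":  956, "pct": 24},
  "symbiont": {"count": 1113, "pct": 28},
  "specific": {"count": 1931, "pct": 48}
},
"gc_modes": {"host": 0.435, "specific": 0.425, "symbiont": 0.545},
"truth": {"accuracy_with_hits": 0.9995, ...}
```

Reading this: the sweep chose 1e-05 (all cutoffs tie on unclassified
counts here, and ties resolve toward stringency); the recovered bin
fractions match the planted 0.24/0.29/0.47 within binomial sampling noise;
the per-bin GC modes recover the generating targets 0.43/0.54 at 0.01
resolution; and 99.95 % of hit-bearing transcripts — including the
dual-database ones resolved by the composition classifier — were returned
to their true origin. Stage outputs (assignment, sweep, GC-histogram,
enrichment, Venn and pathway-coverage tables) are written under
`demo_run/results/`.

Each script in `examples/` demonstrates one capability on a small input
and explains the numbers it prints.

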