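"""Design a hybridization-ligation probe panel for a marker-gene set.

Builds the synthetic transcriptome shipped with the package, designs one
probe pair per gene (two for the redundant-QC genes) under the four design
rules — 27-nt arms, per-arm GC in 40-60%, exon-spanning junction preferred,
no SNP at the ligation junction, no off-target 27-mer sharing — and prints
the first few pairs.
"""

from phdsq import datasets
from phdsq.panel import panel_to_frame

res = datasets.default_panel()
frame = panel_to_frame(res.panel)

print(f"designed {len(res.panel)} probe pairs over "
      f"{len(res.panel.gene_to_probes)} genes; failures: {len(res.failures)}")
print(frame.head(6).to_string(index=False))
print("\nEach row is one ligation probe pair: the left and right 27-nt arms "
      "anneal side by side on the transcript and their ligated 54-mer is the "
      "unit that gets sequenced and counted. junction_pos is the transcript "
      "coordinate of the nick; exon_spanning pairs cannot ligate on genomic DNA.")
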