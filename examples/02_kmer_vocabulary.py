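"""Build a canonical 8-mer vocabulary from enhancers vs matched controls.

Each k-mer (pooled with its reverse complement) is tested for enrichment
in enhancer sequence against GC/repeat/length-matched controls with a
one-sided Fisher exact test; Bonferroni-significant enriched k-mers form
the `top` class and carry log2 enrichment weights.
"""

from enfragility import (WorldConfig, build_vocabulary,
                         count_distinct_canonical, generate_world,
                         sample_control_set)

world = generate_world(WorldConfig(seed=42, genome_length=400_000,
                                   n_enhancers=(20, 20), n_pos=150,
                                   n_neg=150))
controls = sample_control_set(world.genome, world.enhancers, n=5, seed=1)
print(f"controls: {controls.sampled_fraction():.0%} genome-sampled, "
      f"rest shuffled")

enh_seqs = [world.genome.fetch(e) for e in world.enhancers]
vocab = build_vocabulary(enh_seqs, controls.sequences, k=8)
sizes = vocab.class_sizes()
print(f"canonical 8-mer universe: {count_distinct_canonical(8):,}")
print(f"classes: {sizes['top']} top / {sizes['neutral']} neutral / "
      f"{sizes['background']:,} background")

# every planted consensus 8-mer should be recovered as `top`
motif = world.config.motifs[0]
for i in range(len(motif.consensus) - 7):
    word = motif.consensus[i:i + 8]
    print(f"  {motif.name} 8-mer {word}: class={vocab.class_of(word)}, "
          f"weight={vocab.weights.get(vocab.canonical_code(word), 0):.2f}")
# Positive weights mean the word is that much (log2) denser in enhancers
# than in the matched background.
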