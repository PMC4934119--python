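"""Cluster the per-chunk pulse frequencies of one bird.

Fits the best pulse to each of 12 chunks of a simulated bird and groups the
frequencies by agglomerative UPGMA clustering on the log10 scale
(dissimilarity threshold 0.025). For a bird with one stable song tempo, the
dominant cluster should hold most chunks and sit at the generating 25 Hz.
"""

from songpulse import synth
from songpulse.clustering import cluster_frequencies, largest_cluster
from songpulse.pulse import gat_best_pulse

chunks = [t[0] for t in synth.bird_chunks(25.0, 12, seed=3, jitter_sd=0.002,
                                          bird_id="demo")]
freqs = [gat_best_pulse(c).frequency for c in chunks]
print("per-chunk pulse frequencies (Hz):",
      ", ".join(f"{f:.2f}" for f in sorted(freqs)))

clusters = cluster_frequencies(freqs)
for i, c in enumerate(clusters):
    print(f"cluster {i}: {c.n_members} chunks ({100 * c.fraction:.0f}%), "
          f"mean {c.mean_hz:.2f} Hz, std {c.std_hz:.3f} Hz")
best = largest_cluster(clusters)
print(f"dominant tempo: {best.mean_hz:.2f} Hz carrying "
      f"{100 * best.fraction:.0f}% of chunks")
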