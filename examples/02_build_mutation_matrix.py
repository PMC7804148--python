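"""From per-sample copy-number segments to the gene-level mutation matrix.

Segments are quality-filtered (>= 5 kb, >= 10 probes, non-neutral), then
intersected with the gene annotation; each (sample, gene) entry becomes
+1 (gain), -1 (loss) or 0 (neutral).
"""

import netmodmut as nm

bundle = nm.make_two_cohorts(nm.SimConfig(seed=11))
cohort = bundle.discovery

kept = nm.filter_segments(cohort.segments, min_length_bp=5_000, min_probes=10)
print(f"segments: {len(cohort.segments)} raw -> {len(kept)} after the quality filter")

matrix = nm.build_matrix(kept, bundle.annotation, list(cohort.states.index))
n_gain = int((matrix.to_numpy() == 1).sum())
n_loss = int((matrix.to_numpy() == -1).sum())
print(f"mutation matrix: {matrix.shape[0]} samples x {matrix.shape[1]} genes, "
      f"{n_gain} gain and {n_loss} loss calls")
print(matrix.iloc[:4, :6])
# Rows are samples, columns genes; this matrix feeds every downstream stage.
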