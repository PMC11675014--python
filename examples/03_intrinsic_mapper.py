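"""Intrinsic Mapper: no embedding, bins from graph landmarks.

Instead of projecting to a low-dimensional lens, the intrinsic variant
works directly on the penalized reciprocal k-NN graph: farthest-point
sampling picks landmark time points, and each bin collects everything
within a geodesic radius of its landmark.
"""

from neuromapper import (MapperConfig, evaluate_result, g_schedule,
                         run_mapper, smooth_downsample, synth_circular_bold)

data = smooth_downsample(synth_circular_bold(seed=1), factor=3)
config = MapperConfig(lens_algorithm="intrinsic", bin_kind="intrinsic",
                      resolution=20, gain=60)
result = run_mapper(data, config)
evaluate_result(result, data)

cover = result.cover
print(f"landmarks: {cover.resolution}, ball radius: {cover.meta['radius']:.3f}"
      f" (geodesic), epsilon: {cover.meta['epsilon']:.3f}")
print(f"uncovered points: {cover.n_uncovered()} of {cover.n_points}")
print(f"shape graph: {result.graph.n_nodes} nodes, "
      f"{len(result.graph.edges)} edges; beta = {result.validation.beta:.1f}%")
print("Uncovered points (outside every landmark ball) lower the coverage"
      " criterion beta; raise the gain to shrink that set.")
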