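from meavocab.bursts import Burst
from meavocab.synthetic import realization_intensity, render_burst_matrix


def render_bursts(template, geometry, rng, n, noise_scale=1.0, **kw):
    """Expected-count burst matrices straight from the realization model."""
    out = []
    for _ in range(n):
        m = render_burst_matrix(
            realization_intensity(template, geometry, rng, noise_scale,
                                  0.6, 0.3, 0.1, **kw))
        out.append(Burst(matrix=m, initial_state=m[:, 0].copy(), start_ms=0.0))
    return out
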