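import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fiber_recovery_batch():
    """Trace 20 seeded straight-fiber renders and pair them with ground truth.

    Shared by the tracer unit tests and the parameter-recovery acceptance
    test; returns per-fiber (truth, traced) pairs and the per-image counts.
    """
    from mechanoscape import synthetic as syn
    from mechanoscape.fibers import trace_fibers

    pairs, counts = [], []
    for seed in range(20):
        image, truth = syn.gen_fiber_image(syn.FiberRenderSpec(n_fibers=5, seed=seed))
        traced = trace_fibers(image)
        counts.append((len(truth), len(traced)))
        used = set()
        for f in truth:
            mid = f.path[len(f.path) // 2]
            best, best_d = None, np.inf
            for j, g in enumerate(traced):
                if j in used:
                    continue
                d = float(np.linalg.norm(g.path - mid, axis=1).min())
                if d < best_d:
                    best, best_d = j, d
            if best is not None and best_d < 10.0:
                used.add(best)
                pairs.append((f, traced.fibers[best]))
    return pairs, counts
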