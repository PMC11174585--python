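import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def kinect_graph():
    from gaitfreq import load_layout

    return load_layout("kinect25").graph()


@pytest.fixture(scope="session")
def kinect_partition(kinect_graph):
    from gaitfreq import default_partition

    return default_partition(kinect_graph, "kinect25")


def random_graph(rng, n_joints):
    """A random connected skeleton-like graph (spanning tree + extra edges)."""
    from gaitfreq import build_skeleton_graph

    edges = set()
    for j in range(1, n_joints):
        edges.add((int(rng.integers(0, j)), j))
    max_edges = n_joints * (n_joints - 1) // 2
    target = min(len(edges) + int(rng.integers(0, n_joints)), max_edges)
    for _ in range(10 * n_joints):
        if len(edges) >= target:
            break
        i, j = rng.integers(0, n_joints, size=2)
        if i != j:
            edges.add((min(int(i), int(j)), max(int(i), int(j))))
    return build_skeleton_graph(sorted(edges), n_joints)


def numeric_grad(f, arr, eps=1e-6):
    """Central finite differences of a scalar function of `arr` (in place)."""
    g = np.zeros_like(arr)
    it = np.nditer(arr, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        orig = arr[i]
        arr[i] = orig + eps
        fp = f()
        arr[i] = orig - eps
        fm = f()
        arr[i] = orig
        g[i] = (fp - fm) / (2 * eps)
    return g


def rel_err(approx, exact):
    scale = max(np.abs(exact).max(), 1e-8)
    return np.abs(approx - exact).max() / scale
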