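import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from mbgag.gag_models import MBMolecule, Pose, build_gag
from mbgag.trajectory import Trajectory, make_topology


@pytest.fixture(scope="session")
def mb_template() -> MBMolecule:
    return MBMolecule.template()


@pytest.fixture(scope="session")
def hp_chain():
    return build_gag("HP", 10)


def traj_from_poses(poses, template=None, n_frames=1):
    """Build a GAG-free trajectory from a list of (rotation, translation)."""
    template = template or MBMolecule.template()
    topology = make_topology(None, len(poses), template)
    frame = np.concatenate(
        [template.place(Pose(r, t)) for r, t in poses], axis=0
    )
    coords = np.repeat(frame[None], n_frames, axis=0)
    return Trajectory(coords, topology)


def random_poses(rng, n, box=12.0):
    """Random rigid poses in a cube, for oracle-equivalence sweeps."""
    out = []
    for _ in range(n):
        rot = Rotation.random(random_state=rng).as_matrix()
        out.append((rot, rng.uniform(-box / 2, box / 2, 3)))
    return out


# ---------------------------------------------------------------------------
# test-local brute-force oracles, written independently of the package
# ---------------------------------------------------------------------------


def oracle_plane(points):
    centroid = points.mean(axis=0)
    _, _, vt = np.linalg.svd(points - centroid)
    return centroid, vt[2]


def oracle_edge(ring_a, ring_b, d_max=4.5, angle_max=30.0, lateral_max=3.0):
    ca, na = oracle_plane(ring_a)
    cb, nb = oracle_plane(ring_b)
    d = 0.5 * (abs(np.dot(cb - ca, na)) + abs(np.dot(ca - cb, nb)))
    ang = np.degrees(np.arccos(min(1.0, abs(float(np.dot(na, nb))))))
    delta = cb - ca
    lat = max(
        np.linalg.norm(delta - np.dot(delta, na) * na),
        np.linalg.norm(delta - np.dot(delta, nb) * nb),
    )
    return d <= d_max and ang <= angle_max and lat <= lateral_max


def oracle_components(ring_sets, **thresholds):
    """Union-find over the pairwise edge criterion."""
    n = len(ring_sets)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if oracle_edge(ring_sets[i], ring_sets[j], **thresholds):
                parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(i)
    return sorted(frozenset(g) for g in groups.values())
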