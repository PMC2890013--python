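import numpy as np
import pytest

from hippofc.synthetic import GroupSimSpec, ToyAtlasSpec, make_toy_atlas


@pytest.fixture(scope="session")
def atlas():
    """The default desk-scale toy atlas (32x32x16, 2 mm voxels)."""
    return make_toy_atlas()


@pytest.fixture(scope="session")
def small_atlas():
    """A smaller atlas for fast end-to-end tests."""
    return make_toy_atlas(
        ToyAtlasSpec(grid_shape=(24, 24, 12), roi_centers=((7, 12, 6), (16, 12, 6)),
                     roi_radius_vox=2, network_extent_vox=4)
    )


def tiny_group_spec(**overrides):
    """A fast-to-simulate group spec for plumbing tests (T=53 -> 48 frames)."""
    defaults = dict(n_subjects=2, runs_per_subject=1, volumes_per_run=53, rng_seed=11)
    defaults.update(overrides)
    return GroupSimSpec(**defaults)


# ---------------------------------------------------------------- oracles

def pearson_oracle(x, y):
    """Textbook Pearson correlation, written independently of the package."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mx, my = x.mean(), y.mean()
    num = ((x - mx) * (y - my)).sum()
    den = np.sqrt(((x - mx) ** 2).sum() * ((y - my) ** 2).sum())
    return num / den


def pooled_t_oracle(xs, ys):
    """Textbook pooled-variance two-sample t statistic and df."""
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    n1, n2 = len(xs), len(ys)
    m1, m2 = xs.mean(), ys.mean()
    s2 = (((xs - m1) ** 2).sum() + ((ys - m2) ** 2).sum()) / (n1 + n2 - 2)
    se = np.sqrt(s2 * (1.0 / n1 + 1.0 / n2))
    return (m1 - m2) / se, n1 + n2 - 2


def flood_fill_labels(mask, neighborhood):
    """Exhaustive flood-fill connected-component count for a 3D binary mask.

    ``neighborhood`` is a list of integer offset triples defining adjacency.
    """
    mask = np.asarray(mask, dtype=bool)
    visited = np.zeros_like(mask)
    sizes = []
    coords = list(zip(*np.nonzero(mask)))
    for start in coords:
        if visited[start]:
            continue
        stack = [start]
        visited[start] = True
        size = 0
        while stack:
            c = stack.pop()
            size += 1
            for off in neighborhood:
                nb = tuple(c[i] + off[i] for i in range(3))
                if any(n < 0 or n >= mask.shape[i] for i, n in enumerate(nb)):
                    continue
                if mask[nb] and not visited[nb]:
                    visited[nb] = True
                    stack.append(nb)
        sizes.append(size)
    return sizes


def neighborhood_offsets(connectivity):
    """All offsets within the given neuroimaging connectivity (6/18/26)."""
    out = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) == (0, 0, 0):
                    continue
                manhattan = abs(dx) + abs(dy) + abs(dz)
                if connectivity == 6 and manhattan > 1:
                    continue
                if connectivity == 18 and manhattan > 2:
                    continue
                out.append((dx, dy, dz))
    return out
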