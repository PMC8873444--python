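import numpy as np
import pytest

from ki67pi import classifier as clf
from ki67pi import fragments as fr
from ki67pi import synthetic as syn


@pytest.fixture(scope="session")
def default_slide() -> syn.SyntheticSlide:
    """One moderately proliferative synthetic slide shared across tests."""
    return syn.generate_slide(syn.SynthesisConfig(seed=11, target_pi=0.3))


def _toy_fragments(n_per_class: int = 20, size: int = 24, seed: int = 3):
    """Tiny well-separated fragment pool: white background vs stained disks."""
    rng = np.random.default_rng(seed)
    xs, ys = [], []
    for label in (0, 1):
        for _ in range(n_per_class):
            dab = np.zeros((size, size))
            hema = np.zeros((size, size))
            if label:
                cy, cx = rng.uniform(size * 0.3, size * 0.7, size=2)
                yy, xx = np.mgrid[0:size, 0:size]
                inside = (yy - cy) ** 2 + (xx - cx) ** 2 < (size * 0.3) ** 2
                (dab if rng.random() < 0.5 else hema)[inside] = rng.uniform(0.08, 0.13)
            dab += np.clip(rng.normal(0, 0.0015, dab.shape), 0, None)
            img = syn.render_from_stain_densities(dab, hema)
            xs.append(img.pixels)
            ys.append(label)
    return np.stack(xs), np.asarray(ys)


@pytest.fixture(scope="session")
def toy_pool():
    return _toy_fragments()


@pytest.fixture(scope="session")
def toy_model(toy_pool) -> clf.ModelArtifact:
    """A quickly trained compact CNN for contract-level tests."""
    x, y = toy_pool
    return clf.train_model(x, y, clf.TrainingConfig(epochs=6, batch_size=16, seed=5))


@pytest.fixture(scope="session")
def separable_pool():
    """Well-separated fragment pool from rendered slides.

    Positives are fragments holding at least 3 annotated nuclei, negatives
    hold none; single- and double-nucleus edge fragments are dropped so the
    two classes are visually unambiguous.
    """
    xs, ys = [], []
    for k in range(4):
        slide = syn.generate_slide(syn.SynthesisConfig(seed=500 + k, target_pi=0.3))
        grid = fr.build_grid(slide.image.height, slide.image.width, 48, 48)
        counts = np.zeros(len(grid), dtype=int)
        for i, (r, c) in enumerate(grid.origins):
            for p in slide.annotations.points:
                if r <= p.y < r + 48 and c <= p.x < c + 48:
                    counts[i] += 1
        keep = (counts == 0) | (counts >= 3)
        frs = fr.extract_all_fragments(slide.image, grid)
        xs.append(frs[keep])
        ys.append((counts[keep] > 0).astype(int))
    return np.concatenate(xs), np.concatenate(ys)


@pytest.fixture(scope="session")
def separable_model(separable_pool) -> clf.ModelArtifact:
    """Full-budget training run on the well-separated pool."""
    x, y = separable_pool
    return clf.train_model(x, y, clf.TrainingConfig(epochs=50, seed=1))
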