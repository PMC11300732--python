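import numpy as np
import pytest

from histocp.formats import ClassMap, NucleiInstance
from histocp.synthetic import SceneSpec, generate_dataset


@pytest.fixture
def three_class_map() -> ClassMap:
    return ClassMap.from_labels(["tumor", "lymphocyte", "fibroblast"])


def make_square_instance(instance_id=1, label="tumor", category_id=1,
                         x=2, y=2, side=5, crop_value=120):
    """A solid square nucleus, the simplest valid instance."""
    mask = np.ones((side, side), dtype=bool)
    crop = np.full((side, side, 3), crop_value, dtype=np.uint8)
    return NucleiInstance(
        instance_id=instance_id, class_label=label, category_id=category_id,
        mask=mask, bbox=(x, y, side, side), crop=crop,
    )


@pytest.fixture
def square_instance():
    return make_square_instance()


@pytest.fixture(scope="session")
def imbalanced_dataset():
    """Small severely imbalanced dataset (50:1 sampling odds), seeded."""
    p = np.array([50.0, 10.0, 5.0, 2.0, 1.0])
    spec = SceneSpec(
        class_labels=("tumor", "lymphocyte", "fibroblast", "macrophage", "eosinophil"),
        class_probabilities=tuple(p / p.sum()),
    )
    records, triplets, doc = generate_dataset(spec, 10, seed=11)
    return spec, records, triplets, doc
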