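import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def smoke_run():
    """Shared desk-scale training run: full variant, 60 synthetic scenes at
    160x160, 30 epochs, fixed seed.  Session-scoped because it is the
    expensive fixture behind the learnability checks."""
    from pestdet.netgraph import VariantFlags
    from pestdet.synthpest import SceneSpec, generate_scene
    from pestdet.train import TrainConfig, train

    scenes = [generate_scene(SceneSpec(size=160, seed=1000 + i)) for i in range(60)]
    images = [s.image.transpose(2, 0, 1).astype(np.float32) / 255.0 for s in scenes]
    labels = [s.labels for s in scenes]
    cfg = TrainConfig(epochs=30, imgsz=160, batch=8, seed=0, lr=0.02)
    logrec, model = train(cfg, VariantFlags.full(), images, labels)
    return {"log": logrec, "model": model, "images": images, "labels": labels}
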