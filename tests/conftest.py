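import numpy as np
import pytest

from synfma.types import EMGRecording, TaskEpoch, TaskEpochs


def make_epochs(n_items: int = 37, frames_per_item: int = 20, gap: int = 0
                ) -> TaskEpochs:
    items, cursor = [], 0
    for i in range(1, n_items + 1):
        items.append(TaskEpoch(i, cursor, cursor + frames_per_item))
        cursor += frames_per_item + gap
    return TaskEpochs(items)


@pytest.fixture
def small_recording() -> EMGRecording:
    """A compact 4-muscle healthy trial with 37 valid epochs."""
    rng = np.random.default_rng(0)
    epochs = make_epochs(frames_per_item=20)
    n = epochs.max_frame
    return EMGRecording(
        subject_id="H01",
        trial_index=1,
        group="healthy",
        fma_score=None,
        sampling_rate=100.0,
        muscle_labels=["m1", "m2", "m3", "m4"],
        samples=rng.normal(size=(n, 4)),
        epochs=epochs,
    )
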