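import pytest

import heartsound as hs


@pytest.fixture(scope="session")
def normal_recording() -> hs.PCGRecording:
    """Clean 10 s normal recording at 70 bpm."""
    return hs.generate_recording(hs.SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def murmur_recording() -> hs.PCGRecording:
    return hs.generate_recording(hs.SimulationConfig(
        sound_class=hs.SoundClass.SYSTOLIC_MURMUR, murmur_intensity=0.5, seed=2))


@pytest.fixture(scope="session")
def small_training_data():
    """A small balanced cycle-level training set (features, labels)."""
    from heartsound.pipeline import prepare_training_set
    recs = hs.generate_dataset(6, seed=5)
    return prepare_training_set(recs)
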