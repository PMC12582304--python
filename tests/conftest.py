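import numpy as np
import pandas as pd
import pytest

from symcensus import GeneratorConfig, ParticleTable, SceneParams, sample_dataset


@pytest.fixture
def simple_table():
    """A minimal particle table with angles, parent keys and class numbers."""
    df = pd.DataFrame(
        {
            "_rlnMicrographName": ["m1.mrc", "m1.mrc", "m2.mrc"],
            "_rlnImageName": ["1@s.mrcs", "2@s.mrcs", "1@t.mrcs"],
            "_rlnCoordinateX": [100.0, 250.5, 100.0],
            "_rlnCoordinateY": [80.0, 90.0, 80.0],
            "_rlnAngleRot": [10.0, 170.0, -30.0],
            "_rlnAngleTilt": [40.0, 90.0, 120.0],
            "_rlnAnglePsi": [-7.0, 15.0, 60.0],
        }
    )
    return ParticleTable(df=df)


@pytest.fixture(scope="session")
def clean_dataset():
    """2000 noiseless-label pentamers with random anchors (session-wide)."""
    gc = GeneratorConfig(n_particles=2000, label_error_rate=0.0, seed=1234)
    truths, table = sample_dataset(gc)
    return gc, truths, table


@pytest.fixture(scope="session")
def default_scene():
    return SceneParams()
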