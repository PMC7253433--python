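import pytest

from rg4kit import qgrs, simulate as sim


@pytest.fixture(scope="session")
def small_transcriptome():
    """A 50-transcript simulated transcriptome with planted G4s, shared by
    prediction and enrichment tests."""
    cfg = sim.SimTranscriptomeConfig(n_transcripts=50, seed=1)
    transcripts, truth = sim.simulate_transcriptome(cfg)
    return cfg, transcripts, truth


@pytest.fixture(scope="session")
def small_catalog(small_transcriptome):
    _, transcripts, _ = small_transcriptome
    return qgrs.predict_catalog(transcripts, qgrs.RG4Params())
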