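import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from contextpp.types import ClusterSet, MirnaFamily, TranscriptModel

settings.register_profile("suite", derandomize=True, deadline=None)
settings.load_profile("suite")


@pytest.fixture
def family():
    """Seed family of the worked examples: seed GGAAUGU (miRNA nt 2-8)."""
    return MirnaFamily(
        family_id="miR-ex",
        seed7="GGAAUGU",
        members=("UGGAAUGUAAAGAAGUAUGUAU",),
        conservation_class="broadly_conserved",
    )


@pytest.fixture
def transcript(family):
    """Transcript with one 8mer site to `family` at utr3 offsets [20, 28)."""
    utr3 = "C" * 20 + "ACAUUCCA" + "G" * 72  # 100-nt 3' UTR
    return TranscriptModel(
        transcript_id="tx1",
        gene_id="g1",
        utr5="G" * 10,
        orf="AUG" + "GCC" * 8 + "UAA",
        utr3=utr3,
    )


@pytest.fixture
def single_dataset_clusters():
    return ClusterSet(
        records=pd.DataFrame(
            {
                "transcript_id": ["tx1", "tx1"],
                "end_offset": [50, 100],
                "tag_count": [50, 50],
                "dataset_id": ["ds0", "ds0"],
            }
        )
    )


@pytest.fixture(scope="session")
def small_world():
    """Session-scoped simulated world shared by the integration tests."""
    from contextpp.profiles import build_profiles
    from contextpp.simulate import SimulationConfig, simulate_profiles, simulate_transcriptome

    config = SimulationConfig(n_transcripts=40, n_mirnas=4, n_experiments=4, seed=42)
    transcripts, families, registry = simulate_transcriptome(config)
    clusters, truth = simulate_profiles(transcripts, config)
    profiles = build_profiles(transcripts, clusters)
    return {
        "config": config,
        "transcripts": transcripts,
        "families": families,
        "registry": registry,
        "clusters": clusters,
        "isoform_truth": truth,
        "profiles": profiles,
    }
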