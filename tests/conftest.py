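import pytest
from hypothesis import settings

from cladescan import conservation as cv
from cladescan import motif_toolkit as mt
from cladescan import synthetic_data as sd

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def family_genome():
    """Default synthetic family: 18 members (2 truncated), 12 annotated."""
    return sd.generate_family_genome(seed=7)


@pytest.fixture(scope="session")
def seed_alignment(family_genome):
    """Gap-free alignment of the full-length members (equal-length proteins)."""
    _, _, truth = family_genome
    full = {k: v for k, v in truth.proteins.items() if len(v) == 280}
    return cv.Alignment(list(full), list(full.values()))


@pytest.fixture(scope="session")
def motif_models(seed_alignment):
    return mt.discover_motifs(seed_alignment)


@pytest.fixture(scope="session")
def anchor_motifs(motif_models, seed_alignment):
    """(first, last) anchor models by mean position in the seed proteins."""
    seqs = dict(zip(seed_alignment.ids, seed_alignment.rows))
    mean_start = {}
    for model in motif_models:
        starts = [mt.scan_protein(s, model).start for s in seqs.values()]
        mean_start[model.motif_id] = sum(starts) / len(starts)
    first_id = min(mean_start, key=mean_start.get)
    last_id = max(mean_start, key=mean_start.get)
    by_id = {m.motif_id: m for m in motif_models}
    return by_id[first_id], by_id[last_id]
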