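import numpy as np
import pytest

from motifdisrupt import SequenceSource
from motifdisrupt.fixtures import make_bundle
from motifdisrupt.motifs import Motif, smooth_matrix


@pytest.fixture(scope="session")
def bundle_dir(tmp_path_factory):
    """The seeded synthetic fixture bundle, built once per session."""
    d = tmp_path_factory.mktemp("bundle")
    make_bundle(str(d), seed=1)
    return d


@pytest.fixture(scope="session")
def bundle_manifest(bundle_dir):
    from motifdisrupt.fixtures import FixtureManifest

    return FixtureManifest.from_json(str(bundle_dir / "manifest.json"))


@pytest.fixture(scope="session")
def bundle_genome(bundle_dir):
    return SequenceSource.from_fasta(str(bundle_dir / "genome.fa"))


@pytest.fixture(scope="session")
def bundle_motifs(bundle_dir):
    from motifdisrupt import read_jaspar_pfm

    return read_jaspar_pfm(str(bundle_dir / "motifs.jaspar"))


@pytest.fixture
def rng():
    return np.random.default_rng(20240)


def _motif_from_counts(counts, motif_id="T1", tf="TF1", pseudocount=0.8):
    counts = np.asarray(counts, dtype=float)
    bg = np.full(4, 0.25)
    return Motif(
        id=motif_id,
        tf_name=tf,
        ppm=smooth_matrix(counts, bg, pseudocount),
        background=bg,
        pseudocount=pseudocount,
        counts=counts,
    )


@pytest.fixture
def motif_from_counts():
    return _motif_from_counts


@pytest.fixture
def sharp_motif():
    """Width-6 motif with consensus ACGTAC and a strong base preference."""
    cons = "ACGTAC"
    counts = np.full((6, 4), 2.0)
    for i, b in enumerate(cons):
        counts[i, "ACGT".index(b)] = 94.0
    return _motif_from_counts(counts)


@pytest.fixture
def dict_genome():
    """In-memory genome wrapper around a plain dict of sequences."""

    def make(seqs: dict[str, str]) -> SequenceSource:
        return SequenceSource(seqs)

    return make
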