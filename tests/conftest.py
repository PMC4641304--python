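import numpy as np
import pytest

from seqppi.features import PairFeature


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def toy_fasta(tmp_path):
    """Three proteins of length >= 50 plus one 30-residue fragment."""
    long_a = "ACDEFGHIKLMNPQRSTVWY" * 3  # 60 aa
    long_b = "MKVLAWSTYF" * 5  # 50 aa
    long_c = "GGSSAALLMMKKRRDDEEFF" * 4  # 80 aa
    short = "ACDEFGHIKLMNPQRSTVWYACDEFGHIKL"  # 30 aa
    path = tmp_path / "toy.fasta"
    path.write_text(
        f">protA\n{long_a}\n>protB\n{long_b}\n>protC\n{long_c}\n>frag\n{short}\n"
    )
    return path


@pytest.fixture
def toy_pairs_file(tmp_path):
    path = tmp_path / "toy_pairs.tsv"
    path.write_text(
        "id_a\tid_b\tlabel\n"
        "protA\tprotB\t1\n"
        "protB\tprotC\t0\n"
        "protA\tfrag\t1\n"
    )
    return path


def make_features(rng, n_samples: int, dim: int = 8, n_classes: int = 2):
    """Random labelled pair features with both classes present."""
    labels = np.arange(n_samples) % n_classes
    return [
        PairFeature(rng.standard_normal(dim), (f"a{i}", f"b{i}"), int(labels[i]))
        for i in range(n_samples)
    ]


@pytest.fixture
def feature_factory(rng):
    def factory(n_samples, dim=8, n_classes=2):
        return make_features(rng, n_samples, dim, n_classes)

    return factory
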