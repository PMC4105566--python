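import random

import pytest

from transqc.simulate import gen_assembly_variants, gen_reads, gen_transcriptome


@pytest.fixture(scope="session")
def small_dataset():
    """Error-free reads on 8 unrelated transcripts, with assembly variants."""
    transcripts = gen_transcriptome(8, (300, 900), seed=11)
    reads, truth = gen_reads(transcripts, n_reads=60, mean_len=150, seed=11)
    variants = gen_assembly_variants(transcripts, reads, truth, mutation_rate=0.05)
    return {
        "transcripts": transcripts,
        "reads": reads,
        "reads_by_id": {r.id: r for r in reads},
        "truth": truth,
        "variants": variants,
    }


@pytest.fixture()
def rng():
    return random.Random(20240721)


def random_dna(rng, length, alphabet="ACGT"):
    return "".join(rng.choice(alphabet) for _ in range(length))
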