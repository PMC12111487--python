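import pytest
from hypothesis import HealthCheck, settings

from cubkit import build_codon_space

settings.register_profile(
    "repro",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def space():
    return build_codon_space()


def make_cds(body_codons, stop="TAA", pad_to=303):
    """Assemble ATG + body + stop, padding with AAA/GAA codons to pad_to nt.

    Padding codons are Lys/Glu (never stops), so the result passes every
    filter as long as the caller's body codons are sense codons.
    """
    body = list(body_codons)
    pad = ["AAA", "GAA"]
    i = 0
    while (len(body) + 2) * 3 < pad_to:
        body.append(pad[i % 2])
        i += 1
    return "ATG" + "".join(body) + stop


@pytest.fixture
def cds_builder():
    return make_cds
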