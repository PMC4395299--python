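import pytest

from deepamp.simulate import KD_AMPLICON, alk_like_model


@pytest.fixture(scope="session")
def kd_model():
    """The kinase-domain fixture: 2043-nt cDNA, 680-aa WT protein."""
    return alk_like_model()


@pytest.fixture(scope="session")
def kd_amplicon():
    return KD_AMPLICON


@pytest.fixture(scope="session")
def kd_reference(kd_model, kd_amplicon):
    a0, a1 = kd_amplicon
    return kd_model.cdna_seq[a0 - 1 : a1]


def variant_read(model, amplicon, kind, *args):
    """Construct the error-free amplicon read of a variant haplotype."""
    a0, a1 = amplicon
    ref = model.cdna_seq[a0 - 1 : a1]
    if kind == "wt":
        return ref
    if kind == "deletion":
        s, e = args
        return ref[: s - a0] + ref[e - a0 + 1 :]
    if kind == "insertion":
        anchor, seq = args
        i = anchor - a0 + 1
        return ref[:i] + seq + ref[i:]
    pos, alt = args
    i = pos - a0
    return ref[:i] + alt + ref[i + 1 :]
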