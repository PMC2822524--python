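import numpy as np
import pytest

from profhmm.profile_model import DNA, build_plan7


def random_model(rng, n, local=False, alphabet=DNA):
    """A valid Plan 7 model with Dirichlet(1)-random parameter groups."""
    m = build_plan7(n, alphabet, local_mode=local)
    A = alphabet.size
    m.match_emissions = rng.dirichlet(np.ones(A), size=n)
    m.insert_emissions = rng.dirichlet(np.ones(A))
    for p in range(n):
        if local:
            m.set_m_out(p, rng.dirichlet(np.ones(4)))
        else:
            mm, mi, md = rng.dirichlet(np.ones(3))
            m.tmm[p], m.tmi[p], m.tmd[p], m.tmo[p] = mm, mi, md, 0.0
        m.tim[p], m.tii[p] = rng.dirichlet(np.ones(2))
        m.tdm[p], m.tdd[p] = rng.dirichlet(np.ones(2))
    if local:
        m.begin = rng.dirichlet(np.ones(3))
        m.z_cont, m.z_exit = rng.dirichlet(np.ones(2))
        m.o_cont, m.o_exit = rng.dirichlet(np.ones(2))
    else:
        bm, bd = rng.dirichlet(np.ones(2))
        m.begin = np.array([bm, bd, 0.0])
    return m


def random_dna(rng, k):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=k))


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
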