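import numpy as np
import pytest

from hdxpipe.chemistry import ExchangeConditions
from hdxpipe.synthetic import (
    H3_SEQ,
    Peptide,
    PeptidePool,
    generate_digest,
    generate_state,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def cond():
    """Study conditions: pD 7, on ice, 75% D2O."""
    return ExchangeConditions(pD=7.0, temperature_K=273.15, d2o_fraction=0.75)


# a 40-residue single-chain state with four rate-class blocks; C2-C6 only so
# every protection factor is realizable (>=1) and noiseless recovery is exact
TOY_CLASSES = {"C2": (1, 10), "C4": (11, 20), "C3": (21, 30), "C5": (31, 40)}


def toy_template():
    chains = {"X": H3_SEQ[:40]}
    segments = [
        {"chain": "X", "start": s, "end": e, "rate_class": c}
        for c, (s, e) in TOY_CLASSES.items()
    ]
    return {"chains": chains, "default_class": "C3", "segments": segments}


def toy_truth_class(index: int) -> str:
    for c, (s, e) in TOY_CLASSES.items():
        if s <= index <= e:
            return c
    raise KeyError(index)


@pytest.fixture(scope="session")
def toy_state(cond):
    return generate_state(toy_template(), seed=3, cond=cond, state_id="toy")


@pytest.fixture(scope="session")
def toy_pool(toy_state):
    return generate_digest(toy_state.chains, mean_len=9, len_sd=2, target_redundancy=3, seed=4)


@pytest.fixture(scope="session")
def toy_dataset_noiseless(toy_state, toy_pool, cond):
    return simulate_dataset(
        toy_state, toy_pool, cond,
        noise_sd=0.0, intensity_floor=0.0, backexchange_sd=0.0, seed=5,
    )


@pytest.fixture(scope="session")
def toy_dataset_noisy(toy_state, toy_pool, cond):
    return simulate_dataset(toy_state, toy_pool, cond, seed=6)


def make_peptide(chain_seq: str, chain: str, start: int, end: int, charges=(2,), pid="pep"):
    return Peptide(pid, chain, start, end, chain_seq[start - 1 : end], tuple(charges))


@pytest.fixture()
def toy_pdb(tmp_path):
    """Poly-alanine helix PDB written through gemmi; synthetic fixture."""
    import gemmi

    st = gemmi.Structure()
    st.name = "toyhelix"
    model = gemmi.Model("1")
    chain = gemmi.Chain("A")
    for i in range(12):
        res = gemmi.Residue()
        res.name = "ALA"
        res.seqid = gemmi.SeqId(i + 1, " ")
        t = i * 100.0 / 180.0 * np.pi
        base = np.array([2.3 * np.cos(t), 2.3 * np.sin(t), 1.5 * i])
        for name, el, off in [
            ("N", "N", (0.0, 0.0, 0.0)),
            ("CA", "C", (0.8, 0.8, 0.0)),
            ("C", "C", (1.6, 0.0, 0.0)),
            ("O", "O", (1.6, -1.2, 0.0)),
            ("CB", "C", (0.8, 1.6, 1.0)),
        ]:
            a = gemmi.Atom()
            a.name = name
            a.element = gemmi.Element(el)
            a.pos = gemmi.Position(*(base + np.array(off)))
            res.add_atom(a)
        chain.add_residue(res)
    model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    path = tmp_path / "toy_helix.pdb"
    st.write_pdb(str(path))
    return path
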