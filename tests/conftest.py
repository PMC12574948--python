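import numpy as np
import pytest

from tcrkit.fixtures import ToyComplexSpec, make_toy_complex
from tcrkit.model import AA1_TO_AA3, Atom, Chain, Residue
from tcrkit.structure_io import assemble_complexes, classify_model


def build_complexes(**spec_kwargs):
    """Toy structure -> classified model -> assembled complexes."""
    sm, truth = make_toy_complex(ToyComplexSpec(**spec_kwargs))
    model = classify_model(sm.first)
    return assemble_complexes(model, structure_id=sm.id), truth


def build_complex(**spec_kwargs):
    complexes, _ = build_complexes(**spec_kwargs)
    assert len(complexes) == 1
    return complexes[0]


@pytest.fixture
def toy_complex():
    return build_complex(seed=5)


@pytest.fixture
def toy_structure():
    sm, truth = make_toy_complex(ToyComplexSpec(seed=5))
    return sm, truth


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix via quaternions."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def apply_rigid(complex_or_model, R: np.ndarray, t: np.ndarray) -> None:
    """Rotate+translate every atom of a TCRComplex or Model in place."""
    chains = getattr(complex_or_model, "chains", None)
    for ch in chains:
        for res in ch.residues:
            for atom in res.atoms:
                atom.coords = R @ atom.coords + t


def make_residue(name3: str, number: int, atoms: dict[str, np.ndarray]) -> Residue:
    elems = {"N": "N", "O": "O", "S": "S", "C": "C"}
    return Residue(name=name3, number=number, atoms=[
        Atom(name=an, element=elems.get(an[0], "C"), coords=np.asarray(xyz, float))
        for an, xyz in atoms.items()])


def make_chain_from_seq(cid: str, seq: str, chain_type, spacing: float = 3.8,
                        origin=(0.0, 0.0, 0.0)) -> Chain:
    """Straight Calpha-only chain carrying a given sequence."""
    o = np.asarray(origin, float)
    residues = [
        Residue(name=AA1_TO_AA3[aa], number=i + 1,
                atoms=[Atom(name="CA", element="C",
                            coords=o + np.array([i * spacing, 0.0, 0.0]))])
        for i, aa in enumerate(seq)]
    ch = Chain(id=cid, residues=residues)
    ch.chain_type = chain_type
    return ch
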