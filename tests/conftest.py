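import numpy as np
import pytest

from lysoscreen.similarity import DescriptorProfile
from lysoscreen.synthetic import FixtureSpec, gen_receptor_manifest, gen_score_matrix


def make_profile(lid: str, seed: int, dim: int = 16, bits: int = 64, on: int = 16) -> DescriptorProfile:
    rng = np.random.default_rng(seed)
    fp = np.zeros(bits, dtype=bool)
    fp[rng.choice(bits, size=on, replace=False)] = True
    return DescriptorProfile(lid, rng.standard_normal(dim), fp, rng.standard_normal(dim))


@pytest.fixture
def desk_spec() -> FixtureSpec:
    """Small screening fixture: 60 ligands, 60 receptors, planted structure."""
    return FixtureSpec(
        seed=11,
        n_ligands=60,
        n_references=5,
        planted_hit_ids=("LIG00001", "LIG00002", "LIG00003", "LIG00004"),
        planted_antitarget_binder_ids=("LIG00010", "LIG00011"),
        n_receptors_total=60,
        n_missing_structure=4,
        n_pocketless=5,
        n_antitarget_receptors=3,
    )


@pytest.fixture
def desk_matrix(desk_spec):
    receptors, _ = gen_receptor_manifest(desk_spec)
    matrix, truth = gen_score_matrix(desk_spec, desk_spec.ligand_ids(), receptors)
    return matrix, truth
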