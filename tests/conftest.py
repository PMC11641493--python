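import numpy as np
import pytest

from trajdiff.structure_io import Atom, StructureModel, TrajectoryEnsemble


def ca_structure(positions, residue_indices=None, chain="A", resname="ALA"):
    """Build a CA-trace StructureModel from an N x 3 array."""
    positions = np.asarray(positions, dtype=float)
    if residue_indices is None:
        residue_indices = range(1, len(positions) + 1)
    atoms = [
        Atom(
            serial=k + 1,
            name="CA",
            element="C",
            residue_index=int(r),
            residue_name=resname,
            chain=chain,
            position=positions[k],
        )
        for k, r in enumerate(residue_indices)
    ]
    return StructureModel(atoms=atoms)


def ensemble_from_frames(frames, structure=None, label="toy"):
    frames = np.asarray(frames, dtype=float)
    if structure is None:
        structure = ca_structure(frames[0])
    return TrajectoryEnsemble(reference=structure, frames=frames, label=label)


@pytest.fixture
def rng():
    return np.random.default_rng(20240)
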