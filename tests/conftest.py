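import numpy as np
import pytest

from voxtraj import Frame, FrameSlice, Topology

ELEMENTS = ("C", "N", "O", "S", "H")


def make_topology(
    n,
    resnames=None,
    parts=None,
    elements=None,
    atom_names=None,
    residue_index=None,
):
    """Small hand-rolled topology for unit tests."""
    elements = list(elements) if elements is not None else [ELEMENTS[i % 5] for i in range(n)]
    resnames = list(resnames) if resnames is not None else ["DUM"] * n
    parts = list(parts) if parts is not None else [0] * n
    atom_names = list(atom_names) if atom_names is not None else list(elements)
    residue_index = (
        list(residue_index) if residue_index is not None else [i // 4 for i in range(n)]
    )
    return Topology(
        element=np.array(elements, dtype=object),
        atom_name=np.array(atom_names, dtype=object),
        residue_name=np.array(resnames, dtype=object),
        residue_index=np.array(residue_index, dtype=int),
        part_annotation=np.array(parts, dtype=int),
    )


def make_slice(coords_per_frame, topology=None, slice_index=0):
    """FrameSlice from a (W, n, 3) array (topology defaulted)."""
    coords = np.asarray(coords_per_frame, dtype=float)
    if topology is None:
        topology = make_topology(coords.shape[1])
    frames = [Frame(coordinates=coords[t], time_index=t) for t in range(coords.shape[0])]
    return FrameSlice(topology=topology, frames=frames, slice_index=slice_index)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
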