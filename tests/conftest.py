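import numpy as np
import pytest

from probemap.core_io import AtomRecord, ParameterizedSystem


def make_atom(serial=1, name="CA", element="C", resname="GLY", resid=1,
              chain="A", pos=(0.0, 0.0, 0.0), charge=0.0, eps=0.1,
              rmin_half=1.9, mass=12.011):
    return AtomRecord(serial=serial, name=name, element=element,
                      residue_name=resname, residue_id=resid, chain=chain,
                      position=np.asarray(pos, float), charge=charge,
                      lj_epsilon=eps, lj_rmin_half=rmin_half, mass=mass)


@pytest.fixture
def make_system():
    """Factory: build a ParameterizedSystem from (resid, pos, kwargs) specs."""

    def _build(atom_specs, probes=()):
        atoms = []
        for i, spec in enumerate(atom_specs):
            resid, pos = spec[0], spec[1]
            kwargs = spec[2] if len(spec) > 2 else {}
            atoms.append(make_atom(serial=i + 1, resid=resid, pos=pos, **kwargs))
        return ParameterizedSystem(atoms, probes)

    return _build


@pytest.fixture
def toy_receptor():
    from probemap.synthetic_fixtures import ToyReceptorSpec, make_toy_receptor

    return make_toy_receptor(ToyReceptorSpec(seed=7))
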