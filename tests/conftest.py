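"""Shared fixtures: all structures are generated programmatically."""

from __future__ import annotations

import numpy as np
import pytest

from filadyn import synthetic
from filadyn.structio import ca_array, extract_ca

FIXTURE_SEED = 1


@pytest.fixture(scope="session")
def compact_chain():
    return synthetic.make_compact_chain(40, seed=3)


@pytest.fixture(scope="session")
def chain_trace(compact_chain):
    trace = extract_ca(compact_chain)
    return trace, ca_array(trace)


@pytest.fixture(scope="session")
def tetramer_pair():
    return synthetic.make_tetramer_analog(40, seed=FIXTURE_SEED)


@pytest.fixture(scope="session")
def octamer_pair():
    return synthetic.make_octamer_analog(40, seed=FIXTURE_SEED)


@pytest.fixture(scope="session")
def helix_fixture():
    return synthetic.make_helical_fixture(twist=40.0, rise=50.0, n=3, seed=2)


@pytest.fixture()
def tiny_pdb(tmp_path):
    """Hand-written minimal PDB: one chain, three residues, plus a ligand."""
    text = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  C   ALA A   1      10.747   5.427  -4.092  1.00  0.00           C
ATOM      4  CA  GLY A   2      12.142   8.500  -3.000  1.00  0.00           C
ATOM      5  CA  SER A   3      14.500  10.000  -1.500  1.00  0.00           C
HETATM    6  P1  LIG L   1       5.000   5.000   5.000  1.00  0.00           P
END
"""
    path = tmp_path / "tiny.pdb"
    path.write_text(text)
    return path
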