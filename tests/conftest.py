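"""Shared fixtures: hand-written PDB texts and session-scoped synthetic
scaffolds (the expensive objects are built once per session)."""

import textwrap

import pytest

from kinoforge.classifiers import default_config
from kinoforge.synthetic_fixtures import (ScaffoldParams, make_acceptor,
                                          make_donor_library,
                                          make_labeled_grid, make_scaffold)


def pdb_line(serial, name, resname, chain, resseq, x, y, z, occ=1.0,
             bfac=10.0, element=None, altloc=" ", icode=" "):
    element = element or name[0]
    pad_name = f" {name:<3s}" if len(name) < 4 else name
    return (f"ATOM  {serial:5d} {pad_name}{altloc}{resname:<3s} {chain}"
            f"{resseq:4d}{icode}   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}"
            f"{bfac:6.2f}          {element:>2s}")


@pytest.fixture
def tiny_pdb(tmp_path):
    """Three complete residues in one chain."""
    lines = []
    serial = 1
    for i, resname in enumerate(["ALA", "GLY", "ASP"]):
        for name, dx in [("N", 0.0), ("CA", 1.5), ("C", 2.5), ("O", 3.0)]:
            lines.append(pdb_line(serial, name, resname, "A", i + 1,
                                  i * 4.0 + dx, 0.0, 0.0))
            serial += 1
    path = tmp_path / "tiny.pdb"
    path.write_text("\n".join(lines) + "\nEND\n")
    return path


@pytest.fixture
def two_model_pdb(tmp_path):
    body = []
    for model in (1, 2):
        body.append(f"MODEL     {model}")
        body.append(pdb_line(1, "CA", "ALA", "A", 1, float(model), 0.0, 0.0))
        body.append("ENDMDL")
    path = tmp_path / "two_model.pdb"
    path.write_text("\n".join(body) + "\nEND\n")
    return path


@pytest.fixture
def two_chain_pdb(tmp_path):
    lines = [pdb_line(1, "CA", "ALA", "A", 1, 0.0, 0.0, 0.0),
             pdb_line(2, "CA", "GLY", "B", 1, 5.0, 0.0, 0.0),
             pdb_line(3, "CA", "SER", "B", 2, 9.0, 0.0, 0.0)]
    path = tmp_path / "two_chain.pdb"
    path.write_text("\n".join(lines) + "\nEND\n")
    return path


@pytest.fixture
def altloc_pdb(tmp_path):
    lines = [pdb_line(1, "CA", "SER", "A", 1, 0.0, 0.0, 0.0, occ=0.6,
                      altloc="A"),
             pdb_line(2, "CA", "SER", "A", 1, 1.0, 0.0, 0.0, occ=0.4,
                      altloc="B")]
    path = tmp_path / "altloc.pdb"
    path.write_text("\n".join(lines) + "\nEND\n")
    return path


@pytest.fixture(scope="session")
def config():
    return default_config()


@pytest.fixture(scope="session")
def default_scaffold(config):
    """DFG-in acceptor-style scaffold, the generator's default pose."""
    return make_scaffold(ScaffoldParams(seed=11), config)


@pytest.fixture(scope="session")
def labeled_grid(config):
    return make_labeled_grid(config, seed=5)


@pytest.fixture(scope="session")
def donor_library(config):
    return make_donor_library(config, seed=7)


@pytest.fixture(scope="session")
def acceptor(config):
    return make_acceptor(config, seed=7)
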