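import numpy as np
import pytest

from serpinkin.simulate import DEFAULT_SCHEME, ArrheniusRate, SimScheme


@pytest.fixture(scope="session")
def default_scheme() -> SimScheme:
    return DEFAULT_SCHEME


@pytest.fixture(scope="session")
def scheme_ea280() -> SimScheme:
    """Melt scheme with a round 280 kJ/mol denaturation barrier."""
    return SimScheme(
        denaturation=ArrheniusRate(1e43, 280e3),
        activation=DEFAULT_SCHEME.activation,
        reversion=DEFAULT_SCHEME.reversion,
        association=DEFAULT_SCHEME.association,
    )


@pytest.fixture
def write_csv(tmp_path):
    def _write(name: str, text: str):
        path = tmp_path / name
        path.write_text(text)
        return path

    return _write


def make_pdb_text(residues, chain="A"):
    """Fixed-column PDB text from [(resseq, resname, [(name, altloc, occ, b,
    xyz), ...]), ...]; synthetic fixture helper."""
    lines = []
    serial = 1
    for resseq, resname, atoms in residues:
        for name, altloc, occ, b, (x, y, z) in atoms:
            pad_name = f" {name:<3}" if len(name) < 4 else name
            record = "HETATM" if resname in ("HOH", "LIG") else "ATOM  "
            lines.append(
                f"{record}{serial:>5} {pad_name}{altloc}{resname:>3} "
                f"{chain}{resseq:>4}    {x:8.3f}{y:8.3f}{z:8.3f}"
                f"{occ:6.2f}{b:6.2f}          {name[0]:>2}"
            )
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


@pytest.fixture
def toy_pdb(tmp_path):
    """Three-residue synthetic protein, per-residue B = 10/20/30."""
    residues = []
    for i, b in enumerate([10.0, 20.0, 30.0], start=1):
        atoms = [(name, " ", 1.0, b, (float(i), float(j), 0.0))
                 for j, name in enumerate(["N", "CA", "C", "O"])]
        residues.append((i, "ALA", atoms))
    path = tmp_path / "toy3.pdb"
    path.write_text(make_pdb_text(residues))
    return path
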