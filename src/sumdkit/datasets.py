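"""Built-in synthetic reference fixtures.

Everything here is generated, not experimental data; fixtures are labelled
synthetic and exist so that geometry-analysis code paths (PDB parsing,
coordination counting, pocket volume) can be exercised without external
structure downloads.
"""

from __future__ import annotations

import numpy as np


def synthetic_sodium_site_pdb() -> str:
    """SYNTHETIC stand-in for a class-A GPCR allosteric sodium pocket.

    A Na+ ion coordinated by exactly five oxygen atoms within 3.0 A — one
    aspartate carboxylate oxygen, one serine hydroxyl oxygen and three
    ordered water oxygens, the canonical trigonal-bipyramidal arrangement —
    plus surrounding side-chain atoms (asparagine amide, carbons) that lie
    outside the coordination shell. Geometry is idealised (Na-O ~ 2.4 A),
    not taken from any deposited structure.
    """
    na = np.zeros(3)
    # five coordinating oxygens ~2.4 A away: trigonal bipyramid
    d = 2.40
    oxy = d * np.array(
        [
            [0.0, 0.0, 1.0],                      # water O
            [0.0, 0.0, -1.0],                     # water O
            [1.0, 0.0, 0.0],                      # Asp OD1
            [-0.5, np.sqrt(3) / 2, 0.0],          # Ser OG
            [-0.5, -np.sqrt(3) / 2, 0.0],         # water O
        ]
    )
    records = []

    def rec(serial, name, resname, resid, chain, pos, element):
        records.append(
            f"HETATM{serial:5d} {name:<4.4s} {resname:<3.3s} {chain}{resid:4d}    "
            f"{pos[0]:8.3f}{pos[1]:8.3f}{pos[2]:8.3f}  1.00  0.00          {element:>2.2s}"
        )

    rec(1, "NA", "NA", 500, "A", na, "NA")
    rec(2, "OD1", "ASP", 52, "A", oxy[2], "O")
    # second carboxylate oxygen points away (> 3 A)
    rec(3, "OD2", "ASP", 52, "A", np.array([2.2, -1.9, 1.4]), "O")
    rec(4, "CG", "ASP", 52, "A", np.array([3.3, -0.8, 0.5]), "C")
    rec(5, "OG", "SER", 91, "A", oxy[3], "O")
    rec(6, "CB", "SER", 91, "A", np.array([-2.1, 3.1, 0.8]), "C")
    rec(7, "OD1", "ASN", 280, "A", np.array([1.8, 1.8, -2.2]), "O")  # 3.36 A
    rec(8, "ND2", "ASN", 280, "A", np.array([2.6, 2.4, -1.8]), "N")
    rec(9, "O", "HOH", 601, "W", oxy[0], "O")
    rec(10, "O", "HOH", 602, "W", oxy[1], "O")
    rec(11, "O", "HOH", 603, "W", oxy[4], "O")
    rec(12, "O", "HOH", 604, "W", np.array([-3.4, 0.4, 2.1]), "O")  # outer shell
    header = (
        "REMARK   synthetic sodium-site fixture (idealised geometry, no PDB source)\n"
    )
    return header + "\n".join(records) + "\nEND\n"
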