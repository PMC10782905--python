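"""Deriving binding labels from a protein-nucleic-acid complex structure.

A residue is labeled binding iff some heavy atom lies within
(vdW radius sum + 0.5 A) of some nucleic-acid atom (strict inequality).
This example builds a tiny PDB file by hand: one glycine within contact
range of a DNA phosphate, one far away.
"""

from pathlib import Path
from tempfile import TemporaryDirectory

from nabind.structure import VDW_RADII, label_structure_file

d_touch = VDW_RADII["C"] + VDW_RADII["P"] + 0.2  # gap 0.2 A < 0.5 -> binding


def pdb_line(serial, name, resname, chain, resseq, x, record="ATOM", element="C"):
    return (f"{record:<6}{serial:>5} {name:<4} {resname:>3} {chain}{resseq:>4}    "
            f"{x:8.3f}{0.0:8.3f}{0.0:8.3f}{1.0:6.2f}  0.00          {element:>2}\n")


with TemporaryDirectory() as tmp:
    pdb = Path(tmp) / "toy.pdb"
    pdb.write_text(
        pdb_line(1, "CA", "GLY", "A", 1, d_touch)
        + pdb_line(2, "CA", "GLY", "A", 2, 80.0)
        + pdb_line(3, "P", "DA", "B", 1, 0.0, element="P")
        + "END\n"
    )
    seqs, tracks = label_structure_file(pdb)
    for cid in tracks:
        print(f"chain {cid}: sequence {seqs[cid]}  labels {tracks[cid].labels}")
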