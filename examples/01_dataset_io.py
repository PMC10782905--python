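"""Reading and writing sequence/label data.

A dataset is a FASTA file of protein sequences plus a parallel "label track"
file: the same '>id' headers, each followed by a 0/1 string aligned
one-to-one with the residues (1 = binding residue).
"""

from pathlib import Path
from tempfile import TemporaryDirectory

from nabind import LabeledDataset, LabelTrack, ProteinRecord
from nabind.seqio import dataset_stats, load_dataset, write_fasta, write_labels

records = [
    ProteinRecord("protA", "MKRYACDEFGHIKLMN"),
    ProteinRecord("protB", "GGSTKKRRYAV"),
]
labels = [
    LabelTrack("protA", (0, 1, 1, 1, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0)),
    LabelTrack("protB", (0, 0, 0, 0, 1, 1, 1, 1, 1, 0, 0)),
]

with TemporaryDirectory() as tmp:
    fasta = Path(tmp) / "seqs.fasta"
    tracks = Path(tmp) / "labels.txt"
    write_fasta(records, fasta)
    write_labels(labels, tracks)

    # round trip: loading validates the sequence/label bijection and lengths
    ds: LabeledDataset = load_dataset(fasta, tracks)
    stats = dataset_stats(ds)
    print(f"proteins:             {stats.n_proteins}")
    print(f"binding residues:     {stats.n_pos}")
    print(f"non-binding residues: {stats.n_neg}")
    print(f"percent binding:      {stats.pct_pos:.2f}%")
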