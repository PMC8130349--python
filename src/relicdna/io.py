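"""File-format surfaces: FASTA via Biopython, SAM via pysam, BED via pandas.

All writers are deterministic (no timestamps, fixed ordering) so that a
rerun of the same scenario is byte-identical.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .simulate import SimRead

__all__ = ["write_fasta", "read_fasta", "write_sam", "open_alignments",
           "read_bed_loci"]


def write_fasta(genomes: Mapping[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=gid, description="")
               for gid, seq in genomes.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


_RC = str.maketrans("ACGTN", "TGCAN")


def write_sam(reads: Sequence[SimRead], genome_lengths: Mapping[str, int],
              path, sort: bool = True) -> None:
    """Write simulated reads as a headered SAM (1-based on disk).

    SEQ is stored in reference-forward orientation per the SAM convention;
    reverse-strand reads carry flag 16.
    """
    names = list(genome_lengths)
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate" if sort else "unsorted"},
        "SQ": [{"SN": g, "LN": int(genome_lengths[g])} for g in names],
    }
    ref_id = {g: i for i, g in enumerate(names)}
    ordered = (sorted(reads, key=lambda r: (ref_id[r.genome_id], r.ref_start,
                                            r.name))
               if sort else list(reads))
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for r in ordered:
            a = pysam.AlignedSegment(out.header)
            a.query_name = r.name
            a.flag = 16 if r.strand == "-" else 0
            a.reference_id = ref_id[r.genome_id]
            a.reference_start = r.ref_start
            a.mapping_quality = 60
            a.cigartuples = [(0, len(r.seq))]
            seq = r.seq if r.strand == "+" else r.seq.translate(_RC)[::-1]
            a.query_sequence = seq
            a.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
            out.write(a)


def open_alignments(source) -> Iterable[pysam.AlignedSegment]:
    """Iterate alignments from a SAM path or pass through an iterable."""
    if isinstance(source, (str, bytes)) or hasattr(source, "__fspath__"):
        with pysam.AlignmentFile(str(source), "r", check_sq=False) as fh:
            yield from fh
    else:
        yield from source


def read_bed_loci(path) -> dict[str, tuple[str, int, int]]:
    """BED with a name column -> {name: (chrom, start, end)} (0-based)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2, 3],
                     names=["chrom", "start", "end", "name"])
    return {str(row["name"]): (str(row.chrom), int(row.start), int(row.end))
            for _, row in df.iterrows()}
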