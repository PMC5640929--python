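"""Reading and writing contigs, per-base depth tables and profile exports.

Contigs are plain FASTA (via Biopython). Per-base depth comes in two dialects:

* three-column TSV ``(sequence id, 1-based position, depth)``; positions absent
  from the table get depth 0 (the convention of per-base depth tools that omit
  zero rows);
* four-column bedGraph ``(id, start, end, depth)`` with 0-based half-open
  intervals.

Within-contig coordinates are 0-based everywhere else in the package.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import reverse_complement as _bio_revcomp

IUPAC_DNA = set("ACGTRYSWKMBDHVN")


@dataclass(frozen=True)
class ContigSeq:
    """A named DNA sequence (a contig, a reference genome, a pseudo-molecule)."""

    id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


def reverse_complement(seq: str) -> str:
    """Reverse complement of an IUPAC DNA string."""
    return str(_bio_revcomp(seq))


def read_contigs(path: str | Path) -> list[ContigSeq]:
    """Read a FASTA file into a list of :class:`ContigSeq`, order preserved.

    Raises ``ValueError`` on an empty file, duplicate record ids, or characters
    outside the IUPAC DNA alphabet (the offending record is named).
    """
    path = Path(path)
    contigs: list[ContigSeq] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate contig id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        bad = set(seq) - IUPAC_DNA
        if bad:
            raise ValueError(
                f"contig {rec.id!r} contains non-IUPAC characters: {sorted(bad)}"
            )
        if not seq:
            raise ValueError(f"contig {rec.id!r} has an empty sequence")
        contigs.append(ContigSeq(rec.id, seq))
    if not contigs:
        raise ValueError(f"no contigs found in {path}")
    return contigs


def write_contigs(contigs: Iterable[ContigSeq], path: str | Path, width: int = 70) -> None:
    """Write sequences as FASTA (fixed line width)."""
    with open(path, "w") as fh:
        for c in contigs:
            fh.write(f">{c.id}\n")
            for i in range(0, c.length, width):
                fh.write(c.sequence[i : i + width] + "\n")


def load_depth(path: str | Path, contigs: list[ContigSeq]) -> dict[str, np.ndarray]:
    """Load per-base depth for every contig.

    The dialect (3-column 1-based TSV vs 4-column bedGraph) is detected from the
    column count. Every contig gets a vector of exactly its length; positions
    absent from the table are depth 0. Unknown contig ids and out-of-range
    positions are hard errors.
    """
    path = Path(path)
    lengths = {c.id: c.length for c in contigs}
    table = pd.read_csv(
        path, sep=r"\s+", header=None, comment="#",
        skip_blank_lines=True, dtype={0: str},
    )
    if table.shape[1] not in (3, 4):
        raise ValueError(
            f"depth table {path} has {table.shape[1]} columns; expected 3 (TSV) or 4 (bedGraph)"
        )
    unknown = sorted(set(table[0]) - set(lengths))
    if unknown:
        raise ValueError(f"depth table {path} names unknown contig ids: {unknown}")

    depth = {cid: np.zeros(n, dtype=float) for cid, n in lengths.items()}
    if table.shape[1] == 3:
        for cid, sub in table.groupby(0, sort=False):
            pos = sub[1].to_numpy(dtype=np.int64)  # 1-based
            if pos.min() < 1 or pos.max() > lengths[cid]:
                raise ValueError(
                    f"depth position out of range for contig {cid!r} "
                    f"(length {lengths[cid]})"
                )
            depth[cid][pos - 1] = sub[2].to_numpy(dtype=float)
    else:
        for cid, sub in table.groupby(0, sort=False):
            starts = sub[1].to_numpy(dtype=np.int64)
            ends = sub[2].to_numpy(dtype=np.int64)
            if starts.min() < 0 or ends.max() > lengths[cid] or (starts >= ends).any():
                raise ValueError(
                    f"bedGraph interval out of range for contig {cid!r} "
                    f"(length {lengths[cid]})"
                )
            vals = sub[3].to_numpy(dtype=float)
            for s, e, v in zip(starts, ends, vals):
                depth[cid][s:e] = v
    return depth


def write_depth_tsv(depth: Mapping[str, np.ndarray], path: str | Path) -> None:
    """Write per-base depth in the 3-column (id, 1-based position, depth) dialect."""
    frames = []
    for cid, vec in depth.items():
        frames.append(
            pd.DataFrame(
                {"id": cid, "pos": np.arange(1, len(vec) + 1), "depth": vec}
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(
        path, sep="\t", header=False, index=False
    )
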