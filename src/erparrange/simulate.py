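"""Synthetic replication-profile datasets with full ground truth.

Generates a circular genome, imposes the ori->ter copy-number gradient of a
steady-state exponential culture, samples noisy per-base depth, and fragments
the genome into shuffled, randomly oriented contigs — a stand-in for the
wet-lab sampling / sequencing / assembly steps, so the arrangement method is
testable without any sequencing data.

The copy-number model: bidirectional forks leave ori at equal speed and stop at
ter, so a locus whose replication fraction is ``a(x)`` (arc distance from ori
toward ter, normalised per replichore) has relative copy number
``n(x) = r**(1 - a(x))`` where ``r`` is the ori:ter copy-number ratio
(``2**(C/tau)`` in Cooper-Helmstetter terms). ``n`` is log-linear on each arm,
equals ``r`` at ori and 1 at ter; unequal arm lengths give unequal slopes and a
shift point at ter (the inversion-mutant phenotype). For growth consistent with
exponential sampling ``r`` stays below ~3, so the profile is near-linear; an
exactly linear mode (``shape="linear"``) is provided for closed-form oracle
tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io import ContigSeq, reverse_complement, write_contigs, write_depth_tsv

NOISE_NONE = "none"
NOISE_POISSON = "poisson"


@dataclass
class GenomeSpec:
    """Circular-genome and replication parameters.

    ``copy_ratio`` is the ori:ter copy-number ratio (>= 1; 1 reproduces a
    stationary-phase flat profile). ``ter`` defaults to the antipode of
    ``ori``. ``gc`` is the genome GC fraction (default B. subtilis-like).
    """

    length: int = 4_200_000
    ori: int = 0
    ter: int | None = None
    copy_ratio: float = 2.0
    gc: float = 0.435
    seed: int = 0
    shape: str = "exponential"  # or "linear"

    def __post_init__(self):
        if self.length < 1000:
            raise ValueError("genome length < 1000 bp is degenerate")
        if self.ter is None:
            self.ter = (self.ori + self.length // 2) % self.length
        if not (0 <= self.ori < self.length and 0 <= self.ter < self.length):
            raise ValueError("ori/ter positions must lie on the genome")
        if self.ori == self.ter:
            raise ValueError("ori and ter must differ")
        if self.copy_ratio < 1:
            raise ValueError("copy_ratio must be >= 1")
        if not 0 < self.gc <= 1:
            raise ValueError("gc must be in (0, 1]")
        if self.shape not in ("exponential", "linear"):
            raise ValueError(f"unknown profile shape {self.shape!r}")


@dataclass
class DepthSpec:
    """Sequencing-depth parameters: mean depth at the terminus and noise model."""

    depth_at_ter: float = 100.0
    noise: str = NOISE_POISSON
    seed: int = 0

    def __post_init__(self):
        if self.depth_at_ter <= 0:
            raise ValueError("depth_at_ter must be > 0")
        if self.noise not in (NOISE_NONE, NOISE_POISSON):
            raise ValueError(f"unknown noise model {self.noise!r}")


@dataclass
class FragmentationSpec:
    """How the genome is cut into contigs (stands in for assembly).

    ``first_cut="ori"`` places the linearization cut at the replication origin;
    a contig straddling ori has a tent-shaped profile whose orientation a
    single line fit cannot determine, so the default keeps the recovery problem
    well-posed. ``first_cut="random"`` is available for robustness studies.
    ``cut_sites`` forces additional deterministic cut positions (e.g. ter, for
    oracle-style recovery experiments where both replichore ends are contig
    boundaries).
    """

    n_contigs: int = 12
    min_len: int = 5000
    shuffle: bool = True
    random_orientation: bool = True
    seed: int = 0
    first_cut: str = "ori"  # or "random"
    cut_sites: tuple[int, ...] = ()

    def __post_init__(self):
        if self.n_contigs < 1:
            raise ValueError("n_contigs must be >= 1")
        if self.min_len < 1:
            raise ValueError("min_len must be >= 1")
        if self.first_cut not in ("ori", "random"):
            raise ValueError(f"unknown first_cut {self.first_cut!r}")


@dataclass(frozen=True)
class TruthEntry:
    contig_id: str
    start: int  # 0-based on the circular genome; end may exceed length (wrap)
    end: int
    strand: str
    rank: int  # circular order index, starting at the first cut


@dataclass
class TruthTable:
    """Ground-truth contig placement on the circular genome."""

    entries: list[TruthEntry]
    genome_length: int
    ori: int
    ter: int

    def by_id(self) -> dict[str, TruthEntry]:
        return {e.contig_id: e for e in self.entries}

    def validate_tiling(self) -> None:
        """Check the intervals tile the circle exactly once."""
        ordered = sorted(self.entries, key=lambda e: e.rank)
        total = sum(e.end - e.start for e in ordered)
        if total != self.genome_length:
            raise ValueError("truth intervals do not tile the circle")
        for a, b in zip(ordered, ordered[1:]):
            if a.end % self.genome_length != b.start:
                raise ValueError("truth intervals overlap or leave gaps")
        if ordered[-1].end % self.genome_length != ordered[0].start:
            raise ValueError("truth intervals do not close the circle")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(e) for e in self.entries])

    def write_tsv(self, path) -> None:
        df = self.to_frame()
        df.attrs = {}
        with open(path, "w") as fh:
            fh.write(
                f"# genome_length={self.genome_length}\tori={self.ori}\tter={self.ter}\n"
            )
            df.to_csv(fh, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "TruthTable":
        with open(path) as fh:
            header = fh.readline().lstrip("# ").strip()
            meta = dict(kv.split("=") for kv in header.split("\t"))
            df = pd.read_csv(fh, sep="\t")
        entries = [
            TruthEntry(str(r.contig_id), int(r.start), int(r.end), str(r.strand), int(r.rank))
            for r in df.itertuples()
        ]
        return cls(
            entries=entries,
            genome_length=int(meta["genome_length"]),
            ori=int(meta["ori"]),
            ter=int(meta["ter"]),
        )


def simulate_genome(spec: GenomeSpec) -> ContigSeq:
    """Uniform-random circular genome sequence at the requested GC content."""
    rng = np.random.default_rng(spec.seed)
    at, gc = (1 - spec.gc) / 2, spec.gc / 2
    codes = rng.choice(4, size=spec.length, p=[at, gc, gc, at])
    seq = np.frombuffer(b"ACGT", dtype=np.uint8)[codes].tobytes().decode()
    return ContigSeq("genome", seq)


def copy_number_profile(spec: GenomeSpec) -> np.ndarray:
    """Relative copy number n(x) for every position of the circular genome.

    n(ori) = copy_ratio, n(ter) = 1; log-linear (or linear, for
    ``shape="linear"``) on each replichore.
    """
    L = spec.length
    x = np.arange(L)
    arc_from_ori = (x - spec.ori) % L
    arm1 = (spec.ter - spec.ori) % L  # ori -> ter clockwise
    arm2 = L - arm1
    on_arm1 = arc_from_ori <= arm1
    a = np.where(on_arm1, arc_from_ori / arm1, ((spec.ori - x) % L) / arm2)
    if spec.shape == "linear":
        return 1.0 + (spec.copy_ratio - 1.0) * (1.0 - a)
    return spec.copy_ratio ** (1.0 - a)


def simulate_depth(profile: np.ndarray, dspec: DepthSpec) -> np.ndarray:
    """Per-base depth: ``depth_at_ter * n(x)``, optionally Poisson-sampled."""
    mean = dspec.depth_at_ter * np.asarray(profile, dtype=float)
    if dspec.noise == NOISE_NONE:
        return mean
    rng = np.random.default_rng(dspec.seed)
    return rng.poisson(mean).astype(float)


def fragment_genome(
    genome: ContigSeq, fspec: FragmentationSpec, ori: int = 0
) -> tuple[list[ContigSeq], TruthTable]:
    """Cut the circular genome into contigs; returns (contigs, truth).

    ``fspec.n_contigs - 1`` breakpoints are placed around the circle in
    addition to the first cut; contig lengths are ``min_len`` plus a uniform
    (Dirichlet) split of the remaining bases — the distribution of uniform
    breakpoints conditioned on every gap honouring ``min_len``. Contigs are
    renamed, shuffled and strand-randomised per the spec; the truth table
    records the original circular placement.
    """
    L = genome.length
    if fspec.n_contigs * fspec.min_len > L:
        raise ValueError("n_contigs * min_len exceeds genome length")
    rng = np.random.default_rng(fspec.seed)
    first = ori if fspec.first_cut == "ori" else int(rng.integers(L))
    n = fspec.n_contigs
    # Mandatory cuts, as arc offsets from the first cut around the circle.
    mand = sorted({0} | {(s - first) % L for s in fspec.cut_sites})
    if n < len(mand):
        raise ValueError("n_contigs smaller than the number of forced cut sites")
    if n == len(mand):
        arcs = np.array(mand)
    else:
        seg_lens = np.diff(mand + [L])
        n_free = n - len(mand)
        # Breakpoints per segment, proportional to length, feasibility-aware.
        alloc = np.zeros(len(mand), dtype=int)
        if (seg_lens < fspec.min_len).any():
            raise ValueError("forced cut sites closer together than min_len")
        for _ in range(n_free):
            score = np.where((alloc + 2) * fspec.min_len <= seg_lens,
                             seg_lens / (alloc + 1), -np.inf)
            if not np.isfinite(score).any():
                raise ValueError(
                    "cannot honour min_len between the forced cut sites"
                )
            alloc[int(np.argmax(score))] += 1
        arcs_list = []
        for start, seg_len, k in zip(mand, seg_lens, alloc):
            m = k + 1  # contigs in this segment
            budget = seg_len - m * fspec.min_len
            extra = np.floor(rng.dirichlet(np.ones(m)) * budget).astype(int)
            extra[-1] += budget - extra.sum()
            gaps = extra + fspec.min_len
            arcs_list.append(start + np.concatenate([[0], np.cumsum(gaps[:-1])]))
        arcs = np.concatenate(arcs_list)
    cuts = (first + arcs) % L

    seq2 = genome.sequence + genome.sequence  # wrap-free slicing
    entries = []
    seqs = []
    for rank in range(n):
        s = int(cuts[rank])
        e = int(cuts[(rank + 1) % n])
        if e <= s:
            e += L
        seqs.append(seq2[s:e])
        entries.append((s, e, rank))

    display = list(range(n))
    if fspec.shuffle:
        rng.shuffle(display)
    contigs = []
    truth_entries = []
    for i, rank in enumerate(display):
        cid = f"ctg{i + 1:04d}"
        s, e, _ = entries[rank]
        seq = seqs[rank]
        strand = "+"
        if fspec.random_orientation and rng.random() < 0.5:
            strand = "-"
            seq = reverse_complement(seq)
        contigs.append(ContigSeq(cid, seq))
        truth_entries.append(TruthEntry(cid, s, e, strand, rank))
    truth = TruthTable(truth_entries, L, ori=ori, ter=-1)
    return contigs, truth


def apply_inversion(genome: ContigSeq, start: int, end: int) -> ContigSeq:
    """Replace segment [start, end) by its reverse complement (inversion mutant)."""
    if not 0 <= start < end <= genome.length:
        raise ValueError("inversion interval out of range")
    seq = genome.sequence
    return ContigSeq(
        genome.id, seq[:start] + reverse_complement(seq[start:end]) + seq[end:]
    )


def project_depth(
    genome_depth: np.ndarray, truth: TruthTable
) -> dict[str, np.ndarray]:
    """Transfer genome per-base depth onto contig coordinates, respecting strand."""
    L = truth.genome_length
    wrapped = np.concatenate([genome_depth, genome_depth])
    out = {}
    for e in truth.entries:
        vec = wrapped[e.start : e.end].copy()
        if e.strand == "-":
            vec = vec[::-1]
        out[e.contig_id] = vec
    return out


@dataclass
class SimulatedDataset:
    """In-memory bundle of one simulated replication-profile experiment."""

    gspec: GenomeSpec
    dspec: DepthSpec
    fspec: FragmentationSpec
    genome: ContigSeq
    profile: np.ndarray
    genome_depth: np.ndarray
    contigs: list[ContigSeq]
    depths: dict[str, np.ndarray]
    truth: TruthTable


def simulate_dataset(
    gspec: GenomeSpec, dspec: DepthSpec, fspec: FragmentationSpec
) -> SimulatedDataset:
    """Run the full generator: genome -> profile -> depth -> fragmentation."""
    genome = simulate_genome(gspec)
    profile = copy_number_profile(gspec)
    genome_depth = simulate_depth(profile, dspec)
    contigs, truth = fragment_genome(genome, fspec, ori=gspec.ori)
    truth.ter = gspec.ter
    depths = project_depth(genome_depth, truth)
    return SimulatedDataset(
        gspec, dspec, fspec, genome, profile, genome_depth, contigs, depths, truth
    )


def make_dataset(
    gspec: GenomeSpec,
    dspec: DepthSpec,
    fspec: FragmentationSpec,
    outdir,
) -> dict[str, Path]:
    """Write a complete dataset (genome, contigs, depth, truth, params) to disk."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ds = simulate_dataset(gspec, dspec, fspec)
    paths = {
        "genome": outdir / "genome.fasta",
        "contigs": outdir / "contigs.fasta",
        "depth": outdir / "depth.tsv",
        "truth": outdir / "truth.tsv",
        "params": outdir / "params.json",
    }
    write_contigs([ds.genome], paths["genome"])
    write_contigs(ds.contigs, paths["contigs"])
    write_depth_tsv(ds.depths, paths["depth"])
    ds.truth.write_tsv(paths["truth"])
    with open(paths["params"], "w") as fh:
        json.dump(
            {"genome": asdict(gspec), "depth": asdict(dspec), "fragmentation": asdict(fspec)},
            fh, indent=2, sort_keys=True,
        )
        fh.write("\n")
    return paths
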