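"""Validation metrics: dot-plot genome coverage, null baseline, truth accuracy.

The headline metric mirrors the published validation design: the arranged
pseudo-molecule is compared with the reference genome through a dot-plot-style
collinearity measure, and the *coverage rate* is the arranged order's genome
coverage as a percentage of the correct order's. A randomly shuffled contig
order/orientation (100 replicates by default) serves as the negative control.

Instead of wrapping an external whole-genome aligner, collinearity is measured
with unique-k-mer anchors: k-mers whose canonical form occurs exactly once in
both sequences define anchors (with a strand); anchors on a common diagonal and
strand form collinear blocks, and the best chain of blocks whose reference
intervals increase with query position gives the covered reference fraction.
The metric is evaluated for the query and its reverse complement and the larger
value is kept, so an arrangement and its global mirror score identically.
Spacer Ns contribute no anchors. On unique-sequence genomes this agrees with
alignment-based dot-plot coverage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .arrange import Arrangement, OrientedContig, apply_arrangement, FORWARD, REVERSE
from .io import ContigSeq, reverse_complement
from .simulate import TruthTable


@dataclass
class EvalResult:
    """Coverage-rate evaluation plus (optional) truth-based accuracy."""

    genome_coverage_arranged: float
    genome_coverage_correct: float
    coverage_rate: float  # percent; may slightly exceed 100, reported as-is
    adjacency_accuracy: float | None = None
    orientation_accuracy: float | None = None
    null_mean: float | None = None
    null_sd: float | None = None
    n_null: int = 0


_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


def _unique_kmer_arrays(seq: str, k: int):
    """Canonical-k-mer table of a sequence, restricted to unique k-mers.

    Returns sorted arrays (keys, positions, strands): ``keys`` are exact 2-bit
    integer encodings of the canonical k-mer (k <= 31 fits in int64), so there
    are no hash collisions; k-mers containing non-ACGT characters (e.g. spacer
    Ns) are skipped, and odd k rules out reverse-complement palindromes.
    """
    codes = _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    n = codes.size
    if n < k:
        return (np.empty(0, dtype=np.int64),) * 3
    valid_base = codes < 4
    # windows with any invalid base are dropped
    bad = np.convolve((~valid_base).astype(np.int64), np.ones(k, dtype=np.int64))
    valid = bad[k - 1 : n] == 0
    pow4 = (4 ** np.arange(k - 1, -1, -1)).astype(np.int64)
    win = np.lib.stride_tricks.sliding_window_view(
        np.where(valid_base, codes, 0).astype(np.int64), k
    )
    fwd = win @ pow4
    rc_codes = (3 - np.where(valid_base, codes, 0))[::-1].astype(np.int64)
    rc_win = np.lib.stride_tricks.sliding_window_view(rc_codes, k)
    rc_all = rc_win @ pow4
    rev = rc_all[::-1]  # rev[i] = hash of RC of the window starting at i
    canon = np.minimum(fwd, rev)
    strand = np.where(fwd <= rev, 1, -1).astype(np.int8)
    pos = np.nonzero(valid)[0]
    vals = canon[valid]
    keys, first, counts = np.unique(vals, return_index=True, return_counts=True)
    uniq = counts == 1
    return keys[uniq], pos[first[uniq]], strand[valid][first[uniq]].astype(np.int64)


class AnchorIndex:
    """Unique-k-mer index of a reference for repeated coverage queries."""

    def __init__(self, reference: ContigSeq | str, k: int = 31):
        seq = reference.sequence if hasattr(reference, "sequence") else str(reference)
        if k % 2 == 0:
            raise ValueError("k must be odd")
        if not 1 <= k <= 31:
            raise ValueError("k must be between 1 and 31")
        if k > len(seq):
            raise ValueError("k larger than the reference sequence")
        self.k = k
        self.ref_len = len(seq)
        self._keys, self._pos, self._strand = _unique_kmer_arrays(seq, k)

    def _anchors(self, query: str) -> list[tuple[int, int, int]]:
        """(query_pos, ref_pos, strand) anchors for k-mers unique in both."""
        qkeys, qpos, qstrand = _unique_kmer_arrays(query, self.k)
        _, ridx, qidx = np.intersect1d(
            self._keys, qkeys, assume_unique=True, return_indices=True
        )
        strand = self._strand[ridx] * qstrand[qidx]
        order = np.argsort(qpos[qidx], kind="stable")
        return list(
            zip(
                qpos[qidx][order].tolist(),
                self._pos[ridx][order].tolist(),
                strand[order].tolist(),
            )
        )

    def _chain_coverage(self, query: str) -> float:
        """Covered reference fraction of the best collinear chain of blocks."""
        k = self.k
        anchors = self._anchors(query)
        if not anchors:
            return 0.0
        # Split query-ordered anchors into same-strand, same-diagonal blocks.
        blocks: list[list[tuple[int, int, int]]] = []
        for a in anchors:
            q, r, s = a
            diag = q - r if s == 1 else q + r
            if blocks:
                q0, r0, s0 = blocks[-1][-1]
                diag0 = q0 - r0 if s0 == 1 else q0 + r0
                if s == s0 and diag == diag0:
                    blocks[-1].append(a)
                    continue
            blocks.append([a])
        # Per block: merged reference intervals and their covered-base weight.
        summaries = []
        intervals = []
        for blk in blocks:
            rpos = sorted(r for _, r, _ in blk)
            ivs = []
            lo = hi = None
            for r in rpos:
                if hi is not None and r <= hi:
                    hi = max(hi, r + k)
                else:
                    if hi is not None:
                        ivs.append((lo, hi))
                    lo, hi = r, r + k
            ivs.append((lo, hi))
            weight = sum(e - s for s, e in ivs)
            summaries.append((rpos[0], rpos[-1] + k, weight))
            intervals.append(ivs)
        # Weighted chain over blocks: reference intervals increasing with query
        # order (blocks are already in query order). The reference chromosome
        # is circular, so the chain may wrap once: an arrangement linearized at
        # a different junction than the reference (a rotation) scores as well
        # as the reference's own linearization.
        nb = len(summaries)
        NEG = float("-inf")
        best = [[NEG, NEG] for _ in range(nb)]  # [no wrap, one wrap]
        parent: list[list[tuple[int, int] | None]] = [[None, None] for _ in range(nb)]
        for i in range(nb):
            lo_i, _, w_i = summaries[i]
            best[i][0] = w_i
            for j in range(i):
                if summaries[j][1] <= lo_i:
                    if best[j][0] + w_i > best[i][0]:
                        best[i][0] = best[j][0] + w_i
                        parent[i][0] = (j, 0)
                    if best[j][1] + w_i > best[i][1]:
                        best[i][1] = best[j][1] + w_i
                        parent[i][1] = (j, 1)
                else:
                    if best[j][0] + w_i > best[i][1]:  # consume the wrap here
                        best[i][1] = best[j][0] + w_i
                        parent[i][1] = (j, 0)
        end_i, end_w = max(
            ((i, w) for i in range(nb) for w in (0, 1)),
            key=lambda t: best[t[0]][t[1]],
        )
        chosen = []
        node: tuple[int, int] | None = (end_i, end_w)
        while node is not None:
            chosen.append(node[0])
            node = parent[node[0]][node[1]]
        # Covered reference bases: union over the chained blocks' intervals.
        ivs = sorted(iv for i in chosen for iv in intervals[i])
        covered = 0
        cur_lo, cur_hi = ivs[0]
        for lo, hi in ivs[1:]:
            if lo <= cur_hi:
                cur_hi = max(cur_hi, hi)
            else:
                covered += cur_hi - cur_lo
                cur_lo, cur_hi = lo, hi
        covered += cur_hi - cur_lo
        return covered / self.ref_len

    def coverage(self, query: ContigSeq | str) -> float:
        """Covered reference fraction; mirror-invariant (max over query, RC)."""
        seq = query.sequence if hasattr(query, "sequence") else str(query)
        if self.k > len(seq):
            raise ValueError("k larger than the query sequence")
        return max(
            self._chain_coverage(seq),
            self._chain_coverage(reverse_complement(seq)),
        )


def dotplot_coverage(
    pseudo_molecule: ContigSeq, reference: ContigSeq, k: int = 31
) -> float:
    """Fraction of the reference covered collinearly by the pseudo-molecule."""
    return AnchorIndex(reference, k).coverage(pseudo_molecule)


def coverage_rate(
    arranged: ContigSeq,
    correct: ContigSeq,
    reference: ContigSeq,
    k: int = 31,
    index: AnchorIndex | None = None,
) -> float:
    """100 x (coverage of the arranged order) / (coverage of the correct order)."""
    idx = index if index is not None else AnchorIndex(reference, k)
    cov_correct = idx.coverage(correct)
    if cov_correct <= 0:
        raise ValueError("correct arrangement covers none of the reference")
    return 100.0 * idx.coverage(arranged) / cov_correct


def correct_arrangement(truth: TruthTable) -> Arrangement:
    """The truth-derived arrangement: circular order linearized at ori.

    Contigs are ordered by genome position, rotated so the contig containing
    ori leads, with orientations taken from the truth strands. The shift index
    is placed at the first contig lying past ter (arc-wise from ori).
    """
    truth.validate_tiling()
    L = truth.genome_length
    ordered = sorted(truth.entries, key=lambda e: e.rank)
    lead = next(
        (i for i, e in enumerate(ordered)
         if (truth.ori - e.start) % L < (e.end - e.start)),
        0,
    )
    rotated = ordered[lead:] + ordered[:lead]
    arc_ter = (truth.ter - truth.ori) % L if truth.ter >= 0 else L // 2
    shift = len(rotated)
    for i, e in enumerate(rotated):
        mid = (e.start + (e.end - e.start) // 2 - truth.ori) % L
        if mid > arc_ter:
            shift = i
            break
    order = [
        OrientedContig(e.contig_id, FORWARD if e.strand == "+" else REVERSE)
        for e in rotated
    ]
    return Arrangement(order=order, shift_index=max(1, shift))


def random_baseline(
    contigs: list[ContigSeq],
    reference: ContigSeq,
    correct: ContigSeq,
    n: int = 100,
    seed: int = 0,
    k: int = 31,
    spacer_n: int = 100,
    index: AnchorIndex | None = None,
) -> tuple[float, float, list[float]]:
    """Coverage rates of randomly shuffled orders/orientations (negative control).

    Returns (null_mean, null_sd, samples); the standard deviation is reported
    as 0 when n == 1.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    idx = index if index is not None else AnchorIndex(reference, k)
    cov_correct = idx.coverage(correct)
    if cov_correct <= 0:
        raise ValueError("correct arrangement covers none of the reference")
    rng = np.random.default_rng(seed)
    samples = []
    ids = list(range(len(contigs)))
    for _ in range(n):
        perm = rng.permutation(ids)
        order = [
            OrientedContig(
                contigs[i].id, FORWARD if rng.random() < 0.5 else REVERSE
            )
            for i in perm
        ]
        arr = Arrangement(order=order, shift_index=1)
        pm, _ = apply_arrangement(arr, contigs, spacer_n=spacer_n)
        samples.append(100.0 * idx.coverage(pm) / cov_correct)
    mean = float(np.mean(samples))
    sd = float(np.std(samples, ddof=1)) if n > 1 else 0.0
    return mean, sd, samples


def adjacency_accuracy(
    arr: Arrangement, truth: TruthTable
) -> tuple[float, float]:
    """(adjacency, orientation) accuracy of an arrangement against truth.

    Adjacency: fraction of adjacent pairs in the arrangement that are adjacent
    on the true circle (unordered adjacency, hence rotation- and
    mirror-invariant). Orientation: fraction of contigs whose strand matches
    truth, maximised over the two mirror images.
    """
    by_id = truth.by_id()
    missing = [oc.contig_id for oc in arr.order if oc.contig_id not in by_id]
    if missing:
        raise KeyError(f"arrangement names contigs absent from truth: {missing}")
    n_total = len(truth.entries)
    ranks = {e.contig_id: e.rank for e in truth.entries}
    pairs = list(zip(arr.order, arr.order[1:]))
    if pairs:
        hits = sum(
            1
            for a, b in pairs
            if min(
                (ranks[a.contig_id] - ranks[b.contig_id]) % n_total,
                (ranks[b.contig_id] - ranks[a.contig_id]) % n_total,
            )
            == 1
        )
        adjacency = hits / len(pairs)
    else:
        adjacency = 1.0
    strands = [
        (FORWARD if by_id[oc.contig_id].strand == "+" else REVERSE) == oc.orientation
        for oc in arr.order
    ]
    frac = float(np.mean(strands))
    orientation = max(frac, 1.0 - frac)
    return adjacency, orientation


def evaluate_arrangement(
    arr: Arrangement,
    contigs: list[ContigSeq],
    reference: ContigSeq,
    truth: TruthTable | None = None,
    k: int = 31,
    null_reps: int = 100,
    seed: int = 0,
    spacer_n: int = 100,
) -> EvalResult:
    """Full evaluation of an arrangement against a reference (and truth)."""
    kept_ids = {oc.contig_id for oc in arr.order}
    kept = [c for c in contigs if c.id in kept_ids]
    idx = AnchorIndex(reference, k)
    arranged_pm, _ = apply_arrangement(arr, kept, spacer_n=spacer_n)
    cov_arr = idx.coverage(arranged_pm)
    adjacency = orientation = None
    if truth is not None:
        correct = correct_arrangement(truth)
        correct_kept = Arrangement(
            order=[oc for oc in correct.order if oc.contig_id in kept_ids],
            shift_index=correct.shift_index,
        )
        correct_pm, _ = apply_arrangement(correct_kept, kept, spacer_n=spacer_n)
        adjacency, orientation = adjacency_accuracy(arr, truth)
    else:
        correct_pm = reference
    cov_correct = idx.coverage(correct_pm)
    if cov_correct <= 0:
        raise ValueError("correct arrangement covers none of the reference")
    rate = 100.0 * cov_arr / cov_correct
    null_mean = null_sd = None
    if null_reps > 0:
        null_mean, null_sd, _ = random_baseline(
            kept, reference, correct_pm, n=null_reps, seed=seed, k=k,
            spacer_n=spacer_n, index=idx,
        )
    return EvalResult(
        genome_coverage_arranged=cov_arr,
        genome_coverage_correct=cov_correct,
        coverage_rate=rate,
        adjacency_accuracy=adjacency,
        orientation_accuracy=orientation,
        null_mean=null_mean,
        null_sd=null_sd,
        n_null=null_reps,
    )
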