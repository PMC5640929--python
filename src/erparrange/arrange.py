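"""Greedy V-shape arrangement of contigs from their fitted coverage slopes.

The chromosome of an exponentially growing bacterium, linearized at the
replication origin, shows a V-shaped depth profile: high at both ends (ori),
minimal at the centre (ter). The arranger reconstructs that V from per-contig
line fits alone:

1. every contig is oriented so its slope is non-positive and the one with the
   highest mean coverage becomes the base (an ori-proximal contig);
2. the descending branch grows by repeatedly appending the remaining contig
   whose predicted start depth best continues the current tail's predicted end
   depth (smallest junction delta);
3. when the ascending continuation fits better than any descending one, the
   terminus shift point is recorded, remaining contigs are re-oriented to
   positive slope, and the ascending branch grows the same way.

"Coverage difference" is always taken between regression-predicted junction
endpoint depths (cov_end of the tail vs cov_start of the candidate), not contig
means: endpoint continuity is what makes the gradient continuous, and means
would misplace long contigs.

The output is defined up to a global mirror (reverse the order, flip every
orientation); the base-contig rule makes it deterministic and the evaluator
treats mirrors as equivalent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .io import ContigSeq, reverse_complement
from .profiles import SlopeFit

FORWARD = "+"
REVERSE = "-"


@dataclass(frozen=True)
class OrientedContig:
    contig_id: str
    orientation: str  # "+" (forward) or "-" (reverse complement emitted)
    ambiguous: bool = False


@dataclass
class Arrangement:
    """Ordered, oriented contig list with the terminus shift index.

    ``shift_index`` is the position of the first contig of the ascending
    branch; the replication terminus lies at the junction ``shift_index - 1`` /
    ``shift_index``. A purely descending arrangement has
    ``shift_index == len(order)``.
    """

    order: list[OrientedContig]
    shift_index: int
    junction_deltas: list[float] = field(default_factory=list)
    total_delta: float = 0.0

    @property
    def ids(self) -> list[str]:
        return [oc.contig_id for oc in self.order]

    def mirror(self) -> "Arrangement":
        """The equally valid reversed-and-flipped arrangement."""
        n = len(self.order)
        order = [
            OrientedContig(
                oc.contig_id,
                FORWARD if oc.orientation == REVERSE else REVERSE,
                oc.ambiguous,
            )
            for oc in reversed(self.order)
        ]
        return Arrangement(
            order=order,
            shift_index=max(1, n - self.shift_index),
            junction_deltas=list(reversed(self.junction_deltas)),
            total_delta=self.total_delta,
        )


def oriented_endpoints(fit: SlopeFit, orientation: str) -> tuple[float, float, float]:
    """(cov_start, cov_end, slope) of a fit viewed in the given orientation."""
    if orientation == FORWARD:
        return fit.cov_start, fit.cov_end, fit.slope
    return fit.cov_end, fit.cov_start, -fit.slope


def is_ambiguous(fit: SlopeFit, depth_tol: float, r2_tol: float = 0.0) -> bool:
    """Whether a fit's orientation cannot be trusted from its slope sign.

    Either the predicted depth change across the contig is below ``depth_tol``
    (the two orientations are indistinguishable at junction-matching scale), or
    the fit is strongly non-linear (``r_squared`` below ``r2_tol``), as happens
    when a contig straddles the origin or terminus.
    """
    return abs(fit.slope) * fit.length < depth_tol or fit.r_squared < r2_tol


def orient_negative(
    fit: SlopeFit, zero_slope_tol: float = 1.0
) -> tuple[OrientedContig, float, float]:
    """Orient a contig so its slope is non-positive (descending-branch view).

    A contig whose predicted depth change is below ``zero_slope_tol`` keeps
    forward orientation and is flagged ambiguous.
    """
    if is_ambiguous(fit, zero_slope_tol):
        return (
            OrientedContig(fit.contig_id, FORWARD, ambiguous=True),
            fit.cov_start,
            fit.cov_end,
        )
    orientation = REVERSE if fit.slope > 0 else FORWARD
    start, end, _ = oriented_endpoints(fit, orientation)
    return OrientedContig(fit.contig_id, orientation), start, end


def _branch_orientations(fit: SlopeFit, branch: str, depth_tol: float, r2_tol: float) -> list[str]:
    """Candidate orientations of a fit for the descending/ascending branch."""
    if is_ambiguous(fit, depth_tol, r2_tol):
        return [FORWARD, REVERSE]
    if branch == "desc":
        return [REVERSE if fit.slope > 0 else FORWARD]
    return [REVERSE if fit.slope < 0 else FORWARD]


def _best_candidate(
    remaining: list[SlopeFit],
    tail_end: float,
    branch: str,
    slack: float,
    depth_tol: float,
    r2_tol: float,
    constrained: bool = True,
):
    """Best (delta, -length, id, orientation, fit) continuation, or None."""
    best = None
    for fit in remaining:
        for orientation in _branch_orientations(fit, branch, depth_tol, r2_tol):
            start, _, _ = oriented_endpoints(fit, orientation)
            if constrained:
                if branch == "desc" and start > tail_end + slack:
                    continue
                if branch == "asc" and start < tail_end - slack:
                    continue
            key = (abs(start - tail_end), -fit.length, fit.contig_id, orientation)
            if best is None or key < best[0]:
                best = (key, fit, orientation)
    return best


def arrange(
    fits: list[SlopeFit],
    slack_frac: float = 0.05,
    zero_slope_tol: float = 1.0,
    ambiguity_r2: float = 0.5,
) -> Arrangement:
    """Order and orient contigs into a single-shift V coverage gradient.

    ``slack_frac`` (fraction of the base contig's mean coverage) is the noise
    tolerance on the monotonicity constraints; ``zero_slope_tol`` (depth units)
    and ``ambiguity_r2`` control when a contig's orientation is decided by
    junction-delta minimisation instead of its slope sign. All contigs are
    placed; ties break by longer contig first, then lexicographic id.
    """
    if not fits:
        raise ValueError("arrange() requires at least one contig fit")
    slack = slack_frac * max(f.mean_cov for f in fits)
    depth_tol = max(zero_slope_tol, slack)

    # Base contig: negative-oriented contig with the highest mean coverage.
    base = max(fits, key=lambda f: (f.mean_cov, f.length, f.contig_id))
    remaining = [f for f in fits if f is not base]

    base_amb = is_ambiguous(base, depth_tol, ambiguity_r2)
    if base_amb and remaining:
        # An ambiguous base (e.g. an origin-straddling contig) is oriented
        # jointly with its first junction.
        scored = []
        for orientation in (FORWARD, REVERSE):
            _, end, _ = oriented_endpoints(base, orientation)
            cand = _best_candidate(remaining, end, "desc", slack, depth_tol, ambiguity_r2)
            delta = cand[0][0] if cand else float("inf")
            scored.append((delta, orientation))
        base_orient = min(scored)[1]
    else:
        base_orient = REVERSE if (base.slope > 0 and not base_amb) else FORWARD

    order = [OrientedContig(base.contig_id, base_orient, ambiguous=base_amb)]
    _, tail_end, _ = oriented_endpoints(base, base_orient)
    deltas: list[float] = []
    shift_index: int | None = None

    while remaining:
        choice = None
        if shift_index is None:
            desc = _best_candidate(remaining, tail_end, "desc", slack, depth_tol, ambiguity_r2)
            asc = _best_candidate(remaining, tail_end, "asc", slack, depth_tol, ambiguity_r2)
            # Switch branches only when descending is stuck, or when the best
            # descending and ascending continuations are the same contig and
            # the ascending junction fits strictly better (the terminus case:
            # appending that contig reverse-oriented would only absorb an
            # ascending-branch contig into the descending branch).
            if desc is not None and not (
                asc is not None and asc[1] is desc[1] and asc[0][0] < desc[0][0]
            ):
                choice = desc
            else:
                shift_index = len(order)
                choice = asc
        else:
            choice = _best_candidate(remaining, tail_end, "asc", slack, depth_tol, ambiguity_r2)
        if choice is None:
            # Nothing satisfies the ascending constraint either: place the
            # closest remaining contig regardless (everything must be placed).
            choice = _best_candidate(
                remaining, tail_end, "asc", slack, depth_tol, ambiguity_r2,
                constrained=False,
            )
            if shift_index is None:
                shift_index = len(order)
        key, fit, orientation = choice
        start, end, _ = oriented_endpoints(fit, orientation)
        deltas.append(abs(start - tail_end))
        order.append(
            OrientedContig(
                fit.contig_id, orientation,
                ambiguous=is_ambiguous(fit, depth_tol, ambiguity_r2),
            )
        )
        tail_end = end
        remaining.remove(fit)

    if shift_index is None:
        shift_index = len(order)
    shift_index = max(1, shift_index)
    return Arrangement(
        order=order,
        shift_index=shift_index,
        junction_deltas=deltas,
        total_delta=float(sum(deltas)),
    )


def apply_arrangement(
    arr: Arrangement,
    contigs: list[ContigSeq],
    spacer_n: int = 100,
) -> tuple[ContigSeq, pd.DataFrame]:
    """Concatenate contigs in arrangement order into a pseudo-molecule.

    Reverse-oriented contigs are emitted as reverse complements; contigs are
    joined by runs of ``spacer_n`` Ns. The placement table records each
    contig's (start, end, strand) on the pseudo-molecule, 0-based half-open.
    """
    by_id = {c.id: c for c in contigs}
    missing = [oc.contig_id for oc in arr.order if oc.contig_id not in by_id]
    if missing:
        raise KeyError(f"arrangement names contigs absent from input: {missing}")
    parts: list[str] = []
    rows = []
    pos = 0
    for i, oc in enumerate(arr.order):
        if i > 0 and spacer_n > 0:
            parts.append("N" * spacer_n)
            pos += spacer_n
        seq = by_id[oc.contig_id].sequence
        if oc.orientation == REVERSE:
            seq = reverse_complement(seq)
        parts.append(seq)
        rows.append(
            {
                "contig_id": oc.contig_id,
                "start": pos,
                "end": pos + len(seq),
                "strand": oc.orientation,
            }
        )
        pos += len(seq)
    molecule = ContigSeq("pseudo_molecule", "".join(parts))
    return molecule, pd.DataFrame(rows)


def junction_report(arr: Arrangement, fits: list[SlopeFit]) -> pd.DataFrame:
    """Per-junction QC table: abutting predicted depths, delta, terminus flag."""
    by_id = {f.contig_id: f for f in fits}
    rows = []
    for i in range(len(arr.order) - 1):
        left, right = arr.order[i], arr.order[i + 1]
        _, left_end, _ = oriented_endpoints(by_id[left.contig_id], left.orientation)
        right_start, _, _ = oriented_endpoints(by_id[right.contig_id], right.orientation)
        rows.append(
            {
                "left_id": left.contig_id,
                "right_id": right.contig_id,
                "left_depth": left_end,
                "right_depth": right_start,
                "delta": abs(left_end - right_start),
                "is_terminus": i + 1 == arr.shift_index,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["left_id", "right_id", "left_depth", "right_depth", "delta", "is_terminus"],
    )


def arrangement_table(arr: Arrangement, fits: list[SlopeFit]) -> pd.DataFrame:
    """Arrangement as a table (rank, contig_id, orientation, fit summary, branch)."""
    by_id = {f.contig_id: f for f in fits}
    rows = []
    for rank, oc in enumerate(arr.order):
        fit = by_id[oc.contig_id]
        start, end, slope = oriented_endpoints(fit, oc.orientation)
        rows.append(
            {
                "rank": rank,
                "contig_id": oc.contig_id,
                "orientation": oc.orientation,
                "cov_start": start,
                "cov_end": end,
                "slope": slope,
                "branch": "descending" if rank < arr.shift_index else "ascending",
                "ambiguous": oc.ambiguous,
            }
        )
    return pd.DataFrame(rows)


def read_arrangement_tsv(path) -> Arrangement:
    """Read an arrangement table written by :func:`arrangement_table`."""
    df = pd.read_csv(path, sep="\t")
    order = [
        OrientedContig(str(r.contig_id), str(r.orientation), bool(getattr(r, "ambiguous", False)))
        for r in df.sort_values("rank").itertuples()
    ]
    shift = int((df["branch"] == "descending").sum())
    return Arrangement(order=order, shift_index=max(1, shift))


def write_agp(arr: Arrangement, contigs: list[ContigSeq], path, spacer_n: int = 100,
              object_name: str = "pseudo_molecule") -> None:
    """Write the arrangement as AGP v2.1 (contig components + U gaps)."""
    by_id = {c.id: c for c in contigs}
    lines = ["##agp-version\t2.1"]
    pos = 1
    part = 1
    for i, oc in enumerate(arr.order):
        if i > 0 and spacer_n > 0:
            lines.append(
                f"{object_name}\t{pos}\t{pos + spacer_n - 1}\t{part}\tU\t{spacer_n}"
                "\tscaffold\tyes\tna"
            )
            pos += spacer_n
            part += 1
        n = by_id[oc.contig_id].length
        lines.append(
            f"{object_name}\t{pos}\t{pos + n - 1}\t{part}\tW\t{oc.contig_id}\t1\t{n}"
            f"\t{oc.orientation}"
        )
        pos += n
        part += 1
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
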